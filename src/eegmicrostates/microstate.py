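"""Microstate segmentation: GFP, peak maps, modified k-means, backfitting.

The analysis follows the classic four-archetype microstate approach.  Global
field power (GFP) is the per-sample root-mean-square of the channel
potentials around their mean,

    GFP(t) = sqrt( sum_i (V_i(t) - V_mean(t))^2 / N ),

a reference-free measure of momentary field strength.  Topographies at GFP
local maxima — where the signal-to-noise ratio is highest — are clustered by
a polarity-invariant ("modified") k-means into k=4 templates, the clustering
objective being the global explained variance (GEV): the GFP^2-weighted
squared spatial correlation between each map and its assigned template,
normalised by total GFP^2.  Because spontaneous EEG topographies flip sign,
both the assignment step (squared spatial correlation) and the template
update (first principal direction of the assigned maps) ignore polarity.
Of ``n_reruns`` random initialisations the run with the highest GEV is kept.
Templates are then labelled A-D by optimal matching against canonical
orientation maps, and every sample of every epoch is backfit to the template
with maximal squared correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .montage import ARCHETYPES, CHANNELS_1020, canonical_archetype_maps
from .preprocess import Epoch

__all__ = [
    "GFPSeries",
    "MicrostateModel",
    "LabelSequence",
    "compute_gfp",
    "find_gfp_peaks",
    "extract_peak_maps",
    "modified_kmeans",
    "compute_gev",
    "backfit_labels",
    "assign_archetypes",
    "fit_microstates",
]


@dataclass
class GFPSeries:
    """Per-sample global field power (uV) of one epoch."""

    values: np.ndarray
    rate_hz: float


@dataclass
class MicrostateModel:
    """Fitted microstate templates.

    ``maps`` is (k, n_channels), each row zero-mean and unit-norm.
    ``archetype_labels`` maps row index -> archetype letter once
    :func:`assign_archetypes` has run; ``gev`` is the global explained
    variance of the selected re-run on the training peak maps.
    """

    maps: np.ndarray
    k: int = 4
    gev: float = np.nan
    archetype_labels: tuple[str, ...] | None = None
    match_scores: tuple[float, ...] | None = None
    n_reruns: int = 20
    convergence_threshold: float = 1e-6
    max_iterations: int = 1000
    seed: int | None = None

    def map_for(self, archetype: str) -> np.ndarray:
        if self.archetype_labels is None:
            raise ValueError("model has no archetype labels yet")
        return self.maps[self.archetype_labels.index(archetype)]

    def ordered_maps(self) -> np.ndarray:
        """Maps re-ordered to archetype order A, B, C, D."""
        if self.archetype_labels is None:
            raise ValueError("model has no archetype labels yet")
        idx = [self.archetype_labels.index(a) for a in ARCHETYPES[: self.k]]
        return self.maps[idx]


@dataclass
class LabelSequence:
    """Per-sample microstate class labels for one epoch.

    ``labels`` holds integer classes 0..k-1 in archetype order (0=A ... 3=D);
    ``correlation`` the per-sample |spatial correlation| with the assigned
    template.
    """

    labels: np.ndarray
    rate_hz: float
    correlation: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.labels)

    def letters(self) -> list[str]:
        return [ARCHETYPES[i] for i in self.labels]


def _centered(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=0, keepdims=True)


def compute_gfp(epoch: Epoch | np.ndarray, rate_hz: float | None = None) -> GFPSeries:
    """Global field power of an epoch: per-sample RMS about the channel mean."""
    if isinstance(epoch, Epoch):
        data, rate = epoch.data, epoch.rate_hz
    else:
        data = np.asarray(epoch, dtype=float)
        rate = rate_hz if rate_hz is not None else np.nan
    if data.shape[0] < 2:
        raise ValueError("GFP requires at least 2 channels")
    values = np.sqrt(np.mean(_centered(data) ** 2, axis=0))
    return GFPSeries(values=values, rate_hz=rate)


def find_gfp_peaks(gfp: GFPSeries | np.ndarray) -> np.ndarray:
    """Indices of local maxima of the GFP series.

    A sample t is a peak when gfp[t-1] < gfp[t] >= gfp[t+1]; for a plateau
    the first plateau sample qualifies.  Endpoints are never peaks.  May
    return an empty array.
    """
    v = gfp.values if isinstance(gfp, GFPSeries) else np.asarray(gfp, dtype=float)
    if len(v) < 3:
        raise ValueError("peak finding requires at least 3 samples")
    rising = v[1:-1] > v[:-2]
    not_falling_after = v[1:-1] >= v[2:]
    return np.nonzero(rising & not_falling_after)[0] + 1


def extract_peak_maps(epochs: Iterable[Epoch]) -> np.ndarray:
    """Pool the average-referenced topographies at GFP peaks of many epochs.

    Returns (n_peaks, n_channels).  This is the clustering input: maps at
    GFP maxima carry the highest signal-to-noise topographies.
    """
    collected = []
    for ep in epochs:
        data = _centered(ep.data)
        gfp = np.sqrt(np.mean(data**2, axis=0))
        if len(gfp) < 3:
            continue
        peaks = find_gfp_peaks(gfp)
        if len(peaks):
            collected.append(data[:, peaks].T)
    if not collected:
        return np.empty((0, 0))
    return np.vstack(collected)


def _principal_direction(maps: np.ndarray) -> np.ndarray:
    """First principal direction of a set of centered maps (rows).

    This is the polarity-invariant 'mean': the unit vector a maximising
    sum_t (V_t . a)^2, i.e. the top eigenvector of V^T V.
    """
    # eigh on the small channel x channel matrix; maps are n x c with c ~ 19
    m = maps.T @ maps
    w, vec = np.linalg.eigh(m)
    a = vec[:, -1]
    a = a - a.mean()
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("degenerate cluster: zero principal direction")
    return a / n


def _sign_aligned_mean(maps: np.ndarray) -> np.ndarray:
    ref = maps[0]
    signs = np.sign(maps @ ref)
    signs[signs == 0] = 1.0
    a = (maps * signs[:, None]).mean(axis=0)
    a = a - a.mean()
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("degenerate cluster: zero aligned mean")
    return a / n


def _gev_of_assignment(
    maps_c: np.ndarray, templates: np.ndarray, labels: np.ndarray, sq_norms: np.ndarray
) -> float:
    # GEV = sum_t gfp_t^2 corr_t^2 / sum gfp_t^2 = sum_t (V_t . a_{L_t})^2 / sum |V_t|^2
    proj = np.einsum("ij,ij->i", maps_c, templates[labels])
    total = sq_norms.sum()
    if total == 0:
        raise ValueError("degenerate input: all-zero maps")
    return float((proj**2).sum() / total)


def _top_eig(s: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(s)[-1])


def _greedy_refine(
    maps_c: np.ndarray, labels: np.ndarray, k: int, swap_limit: int = 128
) -> tuple[np.ndarray, float]:
    """Polish a partition by local moves until none improves the GEV.

    The partition GEV is the sum of top scatter eigenvalues over total
    squared deviation; moving one map updates two scatter matrices by a
    rank-1 term.  Single-map reassignments are always explored
    (first-improvement sweeps, clusters kept non-empty); on inputs of at
    most ``swap_limit`` maps, exchanges of two maps between their clusters
    are explored as well, which escapes the narrow local optima single
    moves cannot leave.  The result is locally optimal under the explored
    neighbourhood.
    """
    n = len(maps_c)
    total = float((maps_c**2).sum())
    scat = [maps_c[labels == j].T @ maps_c[labels == j] for j in range(k)]
    lam = [_top_eig(s) for s in scat]
    sizes = np.bincount(labels, minlength=k)
    tol = 1e-12 * total

    def apply_move(t: int, j: int, vv: np.ndarray, lam_wo: float) -> None:
        cur = labels[t]
        scat[cur] -= vv
        scat[j] += vv
        lam[cur] = lam_wo
        lam[j] = _top_eig(scat[j])
        sizes[cur] -= 1
        sizes[j] += 1
        labels[t] = j

    improved = True
    while improved:
        improved = False
        for t in range(n):
            cur = labels[t]
            if sizes[cur] <= 1:
                continue
            vv = np.outer(maps_c[t], maps_c[t])
            lam_wo = _top_eig(scat[cur] - vv)
            for j in range(k):
                if j == cur:
                    continue
                gain = lam_wo + _top_eig(scat[j] + vv) - lam[cur] - lam[j]
                if gain > tol:
                    apply_move(t, j, vv, lam_wo)
                    improved = True
                    break
        if improved or n > swap_limit:
            continue
        # swap moves: exchange maps t and u between their clusters
        for t in range(n):
            for u in range(t + 1, n):
                a, b = labels[t], labels[u]
                if a == b:
                    continue
                vt = np.outer(maps_c[t], maps_c[t])
                vu = np.outer(maps_c[u], maps_c[u])
                new_a = _top_eig(scat[a] - vt + vu)
                new_b = _top_eig(scat[b] - vu + vt)
                if new_a + new_b - lam[a] - lam[b] > tol:
                    scat[a] += vu - vt
                    scat[b] += vt - vu
                    lam[a], lam[b] = new_a, new_b
                    labels[t], labels[u] = b, a
                    improved = True
                    break
            if improved:
                break
    return labels, float(sum(lam) / total)


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int = 4,
    n_reruns: int = 20,
    threshold: float = 1e-6,
    max_iterations: int = 1000,
    seed: int | None = None,
    update_rule: str = "principal",
    refine: bool = True,
) -> MicrostateModel:
    """Polarity-invariant k-means clustering of GFP-peak topographies.

    Each map is assigned to the template with maximal squared spatial
    correlation (polarity ignored, ties to the lowest template index); each
    template is then re-estimated as the first principal direction of its
    assigned maps (``update_rule="mean"`` selects a sign-aligned mean
    instead).  Iterations stop when the relative GEV change drops below
    ``threshold`` or after ``max_iterations``.  Of ``n_reruns`` random
    initialisations (k distinct peak maps as seeds) the re-run with the
    highest GEV is returned.  GEV is non-decreasing within a run by
    construction of both steps.

    With ``refine=True`` (default) the winning re-run's partition is then
    polished by greedy single-map reassignment until no move improves the
    GEV, removing the residual local-optimum risk of plain k-means on
    small inputs; templates are re-estimated from the polished partition.
    """
    peak_maps = np.asarray(peak_maps, dtype=float)
    if peak_maps.ndim != 2 or peak_maps.shape[0] < k:
        raise ValueError(f"need at least k={k} peak maps")
    maps_c = _centered(peak_maps.T).T  # re-centering is idempotent on avg-ref input
    sq_norms = np.einsum("ij,ij->i", maps_c, maps_c)
    if not sq_norms.any():
        raise ValueError("degenerate input: all-zero maps")
    update = _principal_direction if update_rule == "principal" else _sign_aligned_mean
    rng = np.random.default_rng(seed)
    nonzero = np.nonzero(sq_norms > 0)[0]
    if len(nonzero) < k:
        raise ValueError("fewer than k non-degenerate peak maps")

    # On tiny inputs the number of distinct k-subsets of seed maps can be
    # smaller than the rerun budget; enumerating them all then explores every
    # seed basin instead of re-drawing duplicates.
    from itertools import combinations
    from math import comb

    if comb(len(nonzero), k) <= n_reruns:
        inits: list[np.ndarray] = [np.array(c) for c in combinations(nonzero, k)]
    else:
        inits = [rng.choice(nonzero, size=k, replace=False) for _ in range(n_reruns)]

    best_gev = -np.inf
    best_templates = None
    best_labels = None
    for init_idx in inits:
        templates = np.vstack(
            [maps_c[i] / np.linalg.norm(maps_c[i]) for i in init_idx]
        )
        prev_gev = 0.0
        for _ in range(max_iterations):
            # assignment by squared projection == squared spatial correlation
            proj = maps_c @ templates.T
            labels = np.argmax(proj**2, axis=1)
            for j in range(k):
                member = labels == j
                if not member.any():
                    # re-seed an empty cluster from the worst-fit map
                    fit = np.max(proj**2, axis=1) / np.where(sq_norms > 0, sq_norms, 1.0)
                    labels[int(np.argmin(fit))] = j
                    member = labels == j
                templates[j] = update(maps_c[member])
            gev = _gev_of_assignment(maps_c, templates, labels, sq_norms)
            if prev_gev > 0 and abs(gev - prev_gev) / prev_gev < threshold:
                prev_gev = gev
                break
            prev_gev = gev
        if prev_gev > best_gev:
            best_gev = prev_gev
            best_templates = templates.copy()
            best_labels = labels.copy()

    if refine and best_labels is not None:
        best_labels, _ = _greedy_refine(maps_c, best_labels, k)
        best_templates = np.vstack(
            [update(maps_c[best_labels == j]) for j in range(k)]
        )
        best_gev = _gev_of_assignment(maps_c, best_templates, best_labels, sq_norms)

    return MicrostateModel(
        maps=best_templates,
        k=k,
        gev=best_gev,
        n_reruns=n_reruns,
        convergence_threshold=threshold,
        max_iterations=max_iterations,
        seed=seed,
    )


def compute_gev(
    maps: np.ndarray,
    samples: np.ndarray,
    labels: np.ndarray,
    gfp: np.ndarray | GFPSeries | None = None,
) -> float:
    """Global explained variance of a labelling.

    GEV = sum_t GFP(t)^2 corr(V_t, map_{L_t})^2 / sum_t GFP(t)^2, with corr
    the spatial (Pearson) correlation across channels.  ``samples`` is
    (n_samples, n_channels).  When ``gfp`` is omitted it is derived from the
    samples themselves (the usual case); passing it separately supports
    labelled sub-sequences.
    """
    samples = np.asarray(samples, dtype=float)
    labels = np.asarray(labels)
    maps = np.asarray(maps, dtype=float)
    sc = _centered(samples.T).T
    norms = np.linalg.norm(sc, axis=1)
    if gfp is None:
        gfp_v = norms / np.sqrt(samples.shape[1])
    else:
        gfp_v = gfp.values if isinstance(gfp, GFPSeries) else np.asarray(gfp, dtype=float)
    denom = (gfp_v**2).sum()
    if denom == 0:
        raise ValueError("degenerate input: all-zero GFP")
    mc = _centered(maps.T).T
    mc = mc / np.linalg.norm(mc, axis=1, keepdims=True)
    proj = np.einsum("ij,ij->i", sc, mc[labels])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr2 = np.where(norms > 0, (proj / np.where(norms > 0, norms, 1.0)) ** 2, 0.0)
    return float((gfp_v**2 * corr2).sum() / denom)


def backfit_labels(model: MicrostateModel, epoch: Epoch | np.ndarray,
                   rate_hz: float | None = None) -> LabelSequence:
    """Assign every sample to the template with maximal squared correlation.

    Polarity is ignored; ties break to the lowest archetype index (A < B <
    C < D when the model is archetype-labelled, template order otherwise).
    No temporal smoothing is applied.
    """
    if isinstance(epoch, Epoch):
        data, rate = epoch.data, epoch.rate_hz
    else:
        data = np.asarray(epoch, dtype=float)
        rate = rate_hz if rate_hz is not None else np.nan
    maps = model.ordered_maps() if model.archetype_labels is not None else model.maps
    sc = _centered(data)
    norms = np.linalg.norm(sc, axis=0)
    proj = maps @ sc  # (k, n_samples)
    labels = np.argmax(proj**2, axis=0).astype(np.int8)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.take_along_axis(proj, labels[None].astype(int), axis=0)[0])
        corr = np.where(norms > 0, corr / np.where(norms > 0, norms, 1.0), 0.0)
    return LabelSequence(labels=labels, rate_hz=rate, correlation=corr)


def assign_archetypes(
    model: MicrostateModel,
    channels: Sequence[str] = CHANNELS_1020,
) -> MicrostateModel:
    """Label the k=4 templates A-D by optimal matching to canonical maps.

    The bijective assignment maximising the summed |spatial correlation|
    with the canonical orientation templates is found over all 24
    permutations (via the linear assignment problem, which is exact).
    Polarity is ignored.  Per-map match scores are recorded.
    """
    if model.k != 4 or model.maps.shape[0] != 4:
        raise ValueError("archetype assignment requires exactly 4 maps")
    from scipy.optimize import linear_sum_assignment

    canon = canonical_archetype_maps(channels)
    mc = _centered(model.maps.T).T
    mc = mc / np.linalg.norm(mc, axis=1, keepdims=True)
    score = np.abs(mc @ canon.T)  # rows: model maps, cols: archetypes
    row, col = linear_sum_assignment(-score)
    labels = [""] * 4
    scores = [0.0] * 4
    for r, c in zip(row, col):
        labels[r] = ARCHETYPES[c]
        scores[r] = float(score[r, c])
    model.archetype_labels = tuple(labels)
    model.match_scores = tuple(scores)
    return model


def fit_microstates(
    epochs: Sequence[Epoch],
    k: int = 4,
    n_reruns: int = 20,
    threshold: float = 1e-6,
    max_iterations: int = 1000,
    seed: int | None = None,
    channels: Sequence[str] = CHANNELS_1020,
) -> MicrostateModel:
    """Convenience: pool GFP-peak maps of the epochs, cluster, label A-D."""
    peak_maps = extract_peak_maps(epochs)
    model = modified_kmeans(
        peak_maps, k=k, n_reruns=n_reruns, threshold=threshold,
        max_iterations=max_iterations, seed=seed,
    )
    if k == 4:
        assign_archetypes(model, channels)
    return model
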