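"""Synthetic multichannel EEG with known microstate ground truth.

The generator produces what the downstream pipeline is supposed to recover:
a piecewise-constant sequence of four quasi-stable topographies.  Segment
lengths follow a truncated-geometric dwell law (memoryless, minimum one
sample) with configurable per-class mean in the physiological 60-120 ms
range; successor classes follow a row-stochastic, zero-diagonal transition
matrix.  Each segment's amplitude traces a raised half-sine (the GFP rises
and falls within a microstate, with troughs at transitions at about half
the peak value, as in real spontaneous EEG), and the segment's polarity is
a fair +/-1 coin flip, exercising the polarity invariance of the
clustering.  Spatially correlated Gaussian noise (smooth covariance over
the electrode layout) is added at a configurable signal-to-noise RMS
ratio and the result is average-referenced.

A two-group cohort ("good"/"poor" arithmetic performers; 26/10 subjects,
one 3-min rest and one 1-min task recording each, 500 Hz, 19 channels)
mirrors the study design; group-by-condition parameter overrides plant
known effects (e.g. a longer class-D dwell during the task in good
performers only) for end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .montage import ARCHETYPES, CHANNELS_1020, canonical_archetype_maps, montage_positions
from .microstate import LabelSequence
from .preprocess import Recording

__all__ = [
    "SyntheticGroundTruth",
    "CohortSpec",
    "SubjectRecording",
    "generate_topographies",
    "generate_state_sequence",
    "synthesize_eeg",
    "generate_cohort",
    "default_ground_truth",
]


def uniform_transition_matrix(k: int = 4) -> np.ndarray:
    m = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class SyntheticGroundTruth:
    """Generating parameters of one synthetic EEG condition.

    ``topographies``: (4, n_channels), zero-mean unit-norm rows.
    ``transition_matrix``: 4x4 row-stochastic with zero diagonal.
    ``dwell_mean_ms``: per-class mean segment duration (broadcast from a
    scalar).  ``gfp_peak_uv``/``gfp_trough_frac`` parameterise the
    raised-half-sine per-segment GFP law (peak about 5 uV, matching typical
    band-passed scalp EEG field strength).  ``snr`` is the RMS ratio of the
    noiseless signal to the added noise; ``np.inf`` disables noise.
    """

    topographies: np.ndarray
    transition_matrix: np.ndarray = field(default_factory=uniform_transition_matrix)
    dwell_mean_ms: np.ndarray | float = 80.0
    dwell_distribution: str = "truncated_geometric"
    gfp_peak_uv: float = 5.0
    gfp_trough_frac: float = 0.5
    noise_length_scale: float = 0.5
    snr: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.topographies = np.asarray(self.topographies, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = self.topographies.shape[0]
        if k != 4:
            raise ValueError("exactly 4 topographies are required")
        if not np.allclose(self.topographies.mean(axis=1), 0, atol=1e-9):
            raise ValueError("topographies must be zero-mean (average-referenced)")
        if not np.allclose(np.linalg.norm(self.topographies, axis=1), 1, atol=1e-9):
            raise ValueError("topographies must be unit-norm")
        t = self.transition_matrix
        if t.shape != (k, k):
            raise ValueError("transition matrix must be 4x4")
        if np.any(np.diag(t) != 0):
            raise ValueError("transition matrix diagonal must be exactly 0")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(t < 0):
            raise ValueError("transition probabilities must be nonnegative")
        self.dwell_mean_ms = np.broadcast_to(
            np.asarray(self.dwell_mean_ms, dtype=float), (k,)
        ).copy()
        if np.any(self.dwell_mean_ms <= 0):
            raise ValueError("dwell_mean_ms must be positive")
        if self.dwell_distribution != "truncated_geometric":
            raise ValueError(f"unknown dwell distribution: {self.dwell_distribution}")
        if not self.snr > 0:
            raise ValueError("snr must be positive")

    @property
    def n_channels(self) -> int:
        return self.topographies.shape[1]


@dataclass
class CohortSpec:
    """Design of a synthetic two-group cohort.

    Defaults mirror the study: 26 good and 10 poor performers, a 3-min
    eyes-closed rest and the first minute of the arithmetic task per
    subject, 500 Hz, 19 channels, 2-s epochs.  ``effects`` maps
    ``(group, condition)`` to field overrides of the base ground truth;
    ``dwell_scale`` therein multiplies the per-class dwell means, e.g.
    ``{("good", "task"): {"dwell_scale": {"D": 1.2}}}``.
    """

    truth: SyntheticGroundTruth
    n_good: int = 26
    n_poor: int = 10
    rest_length_s: float = 180.0
    task_length_s: float = 60.0
    rate_hz: float = 500.0
    epoch_length_s: float = 2.0
    effects: Mapping[tuple[str, str], Mapping[str, object]] = field(default_factory=dict)

    def truth_for(self, group: str, condition: str) -> SyntheticGroundTruth:
        """Ground truth for one cohort cell, with overrides applied."""
        override = dict(self.effects.get((group, condition), {}))
        truth = self.truth
        scale = override.pop("dwell_scale", None)
        kwargs = dict(override)
        if scale is not None:
            dwell = np.array(truth.dwell_mean_ms, dtype=float).copy()
            if isinstance(scale, Mapping):
                for cls, f in scale.items():
                    dwell[ARCHETYPES.index(cls)] *= f
            else:
                dwell *= float(scale)
            kwargs["dwell_mean_ms"] = dwell
        return replace(truth, **kwargs) if kwargs else truth


@dataclass
class SubjectRecording:
    """One generated recording together with its generating truth."""

    recording: Recording
    truth: SyntheticGroundTruth
    labels: LabelSequence


def generate_topographies(
    n_channels: int = 19,
    seed: int | None = None,
    channels: Sequence[str] = CHANNELS_1020,
    jitter: float = 0.05,
) -> np.ndarray:
    """Four unit-norm ground-truth topographies on the 10-20 layout.

    The canonical archetype orientation maps (A/B lateral mirror pair, C
    anterior-posterior, D fronto-central focus) are perturbed with a small
    seeded Gaussian jitter so distinct seeds give distinct, realistic maps
    while the dominant orientation of each is preserved.  Rows are zero-mean
    and unit-norm with pairwise |correlation| < 0.95.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    if len(channels) != n_channels:
        raise ValueError("channel list length must equal n_channels")
    canon = canonical_archetype_maps(channels)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(canon.shape) * jitter
    maps = canon + noise
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    cross = np.abs(maps @ maps.T)
    np.fill_diagonal(cross, 0.0)
    if cross.max() >= 0.95:
        raise ValueError("generated maps are too collinear; reduce jitter")
    return maps


def _dwell_p(mean_ms: np.ndarray, rate_hz: float) -> np.ndarray:
    mean_samples = np.maximum(mean_ms * rate_hz / 1000.0, 1.0)
    return 1.0 / mean_samples


def generate_state_sequence(
    truth: SyntheticGroundTruth,
    n_samples: int,
    rate_hz: float = 500.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> LabelSequence:
    """Sample a piecewise-constant class sequence from the dwell/transition law.

    Segment lengths are geometric with minimum 1 sample and per-class mean
    ``dwell_mean_ms``; successors are drawn from the transition matrix; the
    initial class is uniform.  Deterministic under ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = _dwell_p(np.asarray(truth.dwell_mean_ms), rate_hz)
    k = truth.transition_matrix.shape[0]
    labels = np.empty(n_samples, dtype=np.int8)
    state = int(rng.integers(k))
    pos = 0
    while pos < n_samples:
        length = int(rng.geometric(p[state]))
        end = min(pos + length, n_samples)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(k, p=truth.transition_matrix[state]))
    return LabelSequence(labels=labels, rate_hz=rate_hz)


def _noise_chol(truth: SyntheticGroundTruth, channels: Sequence[str]) -> np.ndarray:
    pos = montage_positions(channels)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2 * truth.noise_length_scale**2))
    cov += 1e-9 * np.eye(len(channels))
    return np.linalg.cholesky(cov)


def synthesize_eeg(
    truth: SyntheticGroundTruth,
    labels: LabelSequence,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    channels: Sequence[str] = CHANNELS_1020,
    subject_id: str | None = None,
    condition: str | None = None,
    group: str | None = None,
) -> Recording:
    """Render a label sequence into a multichannel recording (uV).

    Sample t of a segment of length L with class c reads
    ``sign * a(t) * sqrt(N) * topography_c`` with the raised half-sine
    amplitude ``a(t) = peak * (trough + (1-trough) * sin(pi (t+0.5)/L))``,
    so the noiseless per-sample GFP equals a(t) and peaks mid-segment.
    ``sign`` is +/-1 per segment with equal probability.  Spatially
    correlated, average-referenced Gaussian noise is added so that
    signal RMS / noise RMS equals ``truth.snr``; the output is exactly
    average-referenced.
    """
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    if rng is None:
        rng = np.random.default_rng(seed)
    lab = labels.labels
    n = len(lab)
    n_ch = truth.n_channels
    # per-segment run-length view
    change = np.nonzero(np.diff(lab))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    amp = np.empty(n)
    sign = np.empty(n)
    tf = truth.gfp_trough_frac
    for s, e in zip(starts, ends):
        ln = e - s
        tau = (np.arange(ln) + 0.5) / ln
        amp[s:e] = truth.gfp_peak_uv * (tf + (1 - tf) * np.sin(np.pi * tau))
        sign[s:e] = 1.0 if rng.random() < 0.5 else -1.0
    signal = (sign * amp)[None, :] * (np.sqrt(n_ch) * truth.topographies[lab]).T
    if np.isfinite(truth.snr):
        chol = _noise_chol(truth, channels)
        noise = chol @ rng.standard_normal((n_ch, n))
        noise -= noise.mean(axis=0, keepdims=True)
        sig_rms = np.sqrt(np.mean(signal**2))
        noise_rms = np.sqrt(np.mean(noise**2))
        noise *= sig_rms / (truth.snr * noise_rms)
        data = signal + noise
    else:
        data = signal
    data = data - data.mean(axis=0, keepdims=True)
    return Recording(
        data=data,
        channel_labels=tuple(channels),
        rate_hz=labels.rate_hz,
        subject_id=subject_id,
        condition=condition,
        group=group,
    )


def default_ground_truth(seed: int | None = 0, snr: float = 5.0,
                         dwell_mean_ms: float | np.ndarray = 80.0) -> SyntheticGroundTruth:
    """Ground truth at the package's standard study conditions."""
    return SyntheticGroundTruth(
        topographies=generate_topographies(seed=seed),
        transition_matrix=uniform_transition_matrix(),
        dwell_mean_ms=dwell_mean_ms,
        snr=snr,
        seed=seed,
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[SubjectRecording]:
    """Generate the full cohort: one rest and one task recording per subject.

    Subjects are named g01.., p01..; group/condition effects are applied via
    :meth:`CohortSpec.truth_for`.  Per-recording random streams are spawned
    from ``seed`` so the cohort is bit-reproducible and individual
    recordings are independent.
    """
    ss = np.random.SeedSequence(seed)
    out: list[SubjectRecording] = []
    subjects = [("good", f"g{i + 1:02d}") for i in range(spec.n_good)] + [
        ("poor", f"p{i + 1:02d}") for i in range(spec.n_poor)
    ]
    channels = CHANNELS_1020[: spec.truth.n_channels]
    streams = ss.spawn(len(subjects) * 2)
    i = 0
    for group, sid in subjects:
        for condition, length_s in (("rest", spec.rest_length_s), ("task", spec.task_length_s)):
            rng = np.random.default_rng(streams[i])
            i += 1
            truth = spec.truth_for(group, condition)
            n_samples = int(round(length_s * spec.rate_hz))
            labels = generate_state_sequence(truth, n_samples, spec.rate_hz, rng=rng)
            rec = synthesize_eeg(
                truth, labels, rng=rng, channels=channels,
                subject_id=sid, condition=condition, group=group,
            )
            out.append(SubjectRecording(recording=rec, truth=truth, labels=labels))
    return out
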