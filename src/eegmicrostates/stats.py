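"""Nonparametric group comparisons of microstate feature tables.

Epoch-level features rarely pass normality checks, so group contrasts use
the two-sided Mann-Whitney rank-sum test (normal approximation with tie and
continuity correction, z signed so positive means the first sample is
stochastically larger) with step-down Bonferroni-Holm control of the
family-wise error rate within each contrast's feature family.  Directional
predominances are additionally tested against zero with a sign-flip
permutation test (their null of syntactic symmetry is a symmetric
distribution around zero).

The unit of analysis is the epoch, not the subject; epochs of one subject
are correlated, so p-values are anti-conservative for subject-level claims.
A subject-level mode (feature means per subject) is available through
``aggregate="subject"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

__all__ = [
    "ComparisonResult",
    "mann_whitney",
    "holm_correction",
    "compare_states",
    "test_vs_zero",
    "STATE_CONTRASTS",
]

#: The study's three contrasts as ((group, condition), (group, condition)).
STATE_CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "PR_vs_PT": (("poor", "rest"), ("poor", "task")),
    "GR_vs_GT": (("good", "rest"), ("good", "task")),
    "PT_vs_GT": (("poor", "task"), ("good", "task")),
}

#: Feature families for Holm correction (applied per contrast per family).
FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "microstate": tuple(FEATURE_NAMES[:18]),
    "transition": tuple(FEATURE_NAMES[18:]),
}


@dataclass
class ComparisonResult:
    feature: str
    contrast: str
    z_value: float
    p_raw: float
    p_adjusted: float = np.nan
    significant: bool = False


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (z, p).

    Normal approximation with tie correction and a 0.5 continuity
    correction; z is signed so that positive means x tends to be larger
    than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2  # number of (x > y) pairs, ties half-counted
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * (n + 1 - tie_term)
    if var == 0:
        return 0.0, 1.0
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def holm_correction(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Step-down Holm adjustment, returned in the input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotone non-decreasing adjusted values, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _cell(table: pd.DataFrame, group: str, condition: str) -> pd.DataFrame:
    return table[(table["group"] == group) & (table["condition"] == condition)]


def compare_states(
    table: pd.DataFrame,
    contrasts: dict[str, tuple[tuple[str, str], tuple[str, str]]] | None = None,
    features: tuple[str, ...] | None = None,
    families: dict[str, tuple[str, ...]] | None = None,
    alpha: float = 0.05,
    aggregate: str = "epoch",
) -> pd.DataFrame:
    """Mann-Whitney contrasts over a feature table, Holm-corrected.

    ``table`` holds one row per epoch with ``group``/``condition``/
    ``subject_id`` metadata and feature columns.  For every contrast and
    every feature a two-sided rank test is run; Holm is applied per
    contrast within each feature family.  Returns a tidy frame with the
    per-cell means and SDs, z, raw and adjusted p, and the significance
    flag at ``alpha``.
    """
    contrasts = contrasts or STATE_CONTRASTS
    if features is None:
        features = tuple(f for f in FEATURE_NAMES if f in table.columns)
    families = families or {
        name: tuple(f for f in fam if f in features)
        for name, fam in FEATURE_FAMILIES.items()
    }
    if aggregate == "subject":
        table = (
            table.groupby(["subject_id", "group", "condition"], as_index=False)[list(features)]
            .mean()
        )
    elif aggregate != "epoch":
        raise ValueError(f"unknown aggregate level: {aggregate}")

    rows = []
    for cname, ((g1, c1), (g2, c2)) in contrasts.items():
        t1, t2 = _cell(table, g1, c1), _cell(table, g2, c2)
        if len(t1) == 0 or len(t2) == 0:
            continue
        for feat in features:
            x, y = t1[feat].to_numpy(), t2[feat].to_numpy()
            z, p = mann_whitney(x, y)
            rows.append(
                {
                    "feature": feat,
                    "contrast": cname,
                    "mean_1": x.mean(),
                    "sd_1": x.std(ddof=1) if len(x) > 1 else np.nan,
                    "mean_2": y.mean(),
                    "sd_2": y.std(ddof=1) if len(y) > 1 else np.nan,
                    "z_value": z,
                    "p_raw": p,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adjusted"] = np.nan
    for cname in out["contrast"].unique():
        for fam in families.values():
            mask = (out["contrast"] == cname) & out["feature"].isin(fam)
            if mask.any():
                out.loc[mask, "p_adjusted"] = holm_correction(out.loc[mask, "p_raw"].to_numpy())
    # features outside every family: correct them as their own family
    orphan = out["p_adjusted"].isna()
    out.loc[orphan, "p_adjusted"] = out.loc[orphan, "p_raw"]
    out["significant"] = out["p_adjusted"] < alpha
    return out


def test_vs_zero(
    values: np.ndarray,
    method: str = "sign-flip",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided one-sample test of location zero.

    ``sign-flip`` (default): permutation test flipping the sign of each
    value independently with probability 1/2 and comparing |mean| against
    the null distribution (add-one estimator).  ``wilcoxon`` selects the
    signed-rank test instead.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if method == "wilcoxon":
        if np.allclose(values, 0):
            return 1.0
        return float(sps.wilcoxon(values)[1])
    if method != "sign-flip":
        raise ValueError(f"unknown method: {method}")
    rng = np.random.default_rng(seed)
    observed = abs(values.mean())
    signs = rng.integers(0, 2, size=(n_permutations, len(values))) * 2 - 1
    null = np.abs((signs * values).mean(axis=1))
    exceed = int((null >= observed - 1e-12).sum())
    return (1 + exceed) / (n_permutations + 1)
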