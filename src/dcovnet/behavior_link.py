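"""Linking a per-subject network statistic to behavioral measures.

Confounding measures (age, body size, blood pressure, brain volume) are
regressed out of the per-subject efficiency values; the residuals are then
correlated with every behavioral measure on pairwise-complete subjects and
the measures ranked by the significance of their correlation.  Measures
with too many missing entries are excluded before ranking; p-values are
reported raw (no multiple-testing correction).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import pearsonr

from .containers import BehaviorCorrelation, BehaviorTable

__all__ = ["regress_confounds", "rank_correlations"]


def regress_confounds(values: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Least-squares residuals of ``values`` on an intercept plus confounds.

    Collinear confound columns are dropped (with a warning) so the design
    has full column rank.
    """
    values = np.asarray(values, dtype=float)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != values.size:
        confounds = confounds.T
    n, c = confounds.shape
    if n != values.size:
        raise ValueError("confound rows must match subject count")
    if c >= n:
        raise ValueError("need fewer confounds than subjects")
    X = np.column_stack([np.ones(n), confounds])
    # drop columns that add no rank (QR with running rank check)
    keep = [0]
    for col in range(1, X.shape[1]):
        trial = X[:, keep + [col]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(col)
    if len(keep) < X.shape[1]:
        warnings.warn(
            f"dropped {X.shape[1] - len(keep)} collinear confound column(s)",
            RuntimeWarning,
        )
        X = X[:, keep]
    beta, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def rank_correlations(
    residuals: np.ndarray,
    bm: BehaviorTable,
    max_missing: int = 200,
    include_confounds: bool = False,
) -> list[BehaviorCorrelation]:
    """Pearson correlation of residual efficiency with each measure,
    sorted by ascending p-value.

    Measures with more than ``max_missing`` missing entries are excluded;
    each correlation uses the pairwise-complete subjects for that measure.
    Constant measures are skipped with a warning.  Confound measures are
    excluded from the ranking unless requested.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size != len(bm.subjects):
        raise ValueError("residuals must have one value per subject")
    out: list[BehaviorCorrelation] = []
    for name in bm.measure_names:
        if not include_confounds and name in bm.confound_names:
            continue
        col = bm.column(name)
        n_missing = int(np.isnan(col).sum())
        if n_missing > max_missing:
            continue
        ok = ~np.isnan(col) & ~np.isnan(residuals)
        x, y = residuals[ok], col[ok]
        if x.size < 3 or np.ptp(y) == 0 or np.ptp(x) == 0:
            warnings.warn(f"measure {name!r} is constant or too short; skipped",
                          RuntimeWarning)
            continue
        r, p = pearsonr(x, y)
        out.append(BehaviorCorrelation(name, float(r), float(p), int(x.size)))
    out.sort(key=lambda c: (c.p, c.measure_name))
    return out
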