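"""Significance Analysis of Microarrays (SAM) for two-group comparisons.

SAM scores each gene with a penalised relative difference

    d_i = (mean2_i - mean1_i) / (s_i + s0),

where ``s_i`` is the pooled standard error of the mean difference and the
exchangeability ("fudge") constant ``s0`` damps the explosion of ordinary
t-statistics at small ``s_i``.  ``s0`` is chosen on a percentile grid of
the ``s_i`` values to minimise the coefficient of variation of the
d-statistic's spread across the range of ``s`` (Tusher's construction).
Significance is assessed from a quantile-quantile plot of the observed
order statistics ``d_(i)`` against their permutation-based expectations
``dbar_(i)``: for a threshold delta, genes beyond the first departure of
at least delta on each side of the origin are called, and the false
discovery rate is estimated from the average number of permuted scores
falling outside the resulting cut points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .linmod import ExpressionData
from .resampling import ResamplePlan, _group_indices, permutation_assignments

__all__ = [
    "SAMStatistics",
    "SAMCall",
    "sam_statistic",
    "sam_permutation_null",
    "sam_call",
    "sam_select_delta",
]

# percentile grid searched for the fudge factor, after Tusher et al.
S0_PERCENTILES = np.arange(0, 101, 5)
# number of s-quantile windows used when assessing spread stability
_CV_WINDOWS = 100


@dataclass(frozen=True)
class SAMStatistics:
    """Penalised d-statistics with their standard errors and fudge factor."""

    d: np.ndarray
    s: np.ndarray
    s0: float
    numerator: np.ndarray


@dataclass(frozen=True)
class SAMCall:
    """Outcome of thresholding the SAM plot at a given delta."""

    delta: float
    cut_up: float
    cut_low: float
    significant_pos: np.ndarray   # gene indices called up
    significant_neg: np.ndarray   # gene indices called down
    expected_false: float         # estimated E(V)
    fdr_est: float                # E(V) / R, 0 when R = 0

    @property
    def n_called(self) -> int:
        return self.significant_pos.size + self.significant_neg.size

    def called_mask(self, m: int) -> np.ndarray:
        mask = np.zeros(m, dtype=bool)
        mask[self.significant_pos] = True
        mask[self.significant_neg] = True
        return mask


def _relative_difference(Y: np.ndarray, i1: np.ndarray, i2: np.ndarray):
    """Mean difference and pooled standard error per gene (Tusher's r_i, s_i)."""
    n1, n2 = len(i1), len(i2)
    m1 = Y[:, i1].mean(axis=1)
    m2 = Y[:, i2].mean(axis=1)
    ss1 = ((Y[:, i1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((Y[:, i2] - m2[:, None]) ** 2).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(a * (ss1 + ss2))
    return m2 - m1, s


def _cv_of_window_spread(r: np.ndarray, s: np.ndarray, s0: float, order: np.ndarray, edges: np.ndarray) -> float:
    """Coefficient of variation of the d-spread across s-quantile windows.

    The spread within each window is measured by the median absolute
    deviation of d = r/(s+s0); a well-chosen s0 makes this spread
    independent of s, i.e. minimises its CV across windows.
    """
    d = r / (s + s0)
    mads = []
    for k in range(len(edges) - 1):
        idx = order[edges[k]:edges[k + 1]]
        if idx.size == 0:
            continue
        dk = d[idx]
        mads.append(np.median(np.abs(dk - np.median(dk))))
    mads = np.asarray(mads)
    mu = mads.mean()
    if mu == 0:
        return math.inf
    return float(mads.std(ddof=1) / mu) if mads.size > 1 else math.inf


def sam_statistic(data: ExpressionData, groups: Sequence) -> SAMStatistics:
    """Compute the penalised d-statistic with a grid-searched fudge factor.

    Candidate ``s0`` values are the {0, 5, ..., 100} percentiles of the
    per-gene standard errors; the one minimising the coefficient of
    variation of the windowed d-spread is kept.
    """
    i1, i2 = _group_indices(groups)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError("SAM requires at least 2 arrays per group")
    if data.weights is not None and not np.all(data.weights > 0):
        raise ValueError("SAM requires complete data (no zero-weight cells)")
    r, s = _relative_difference(data.Y, i1, i2)
    if np.all(s == 0) and np.all(np.percentile(s, S0_PERCENTILES) == 0):
        raise ValueError("all standard errors are zero; d-statistic undefined")
    order = np.argsort(s, kind="stable")
    # quantile windows need a handful of genes each to carry a stable MAD
    n_windows = max(1, min(_CV_WINDOWS, len(s) // 5))
    edges = np.linspace(0, len(s), n_windows + 1).astype(int)
    candidates = np.percentile(s, S0_PERCENTILES)
    best_s0, best_cv = float(candidates[0]), math.inf
    for s0c in candidates:
        cv = _cv_of_window_spread(r, s, float(s0c), order, edges)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0c)
    if best_s0 == 0.0 and np.any(s == 0):
        positive = candidates[candidates > 0]
        if positive.size == 0:
            raise ValueError("all standard errors are zero; d-statistic undefined")
        best_s0 = float(positive[0])
    d = r / (s + best_s0)
    return SAMStatistics(d=d, s=s, s0=best_s0, numerator=r)


def sam_permutation_null(
    data: ExpressionData,
    groups: Sequence,
    B: int,
    seed: int = 0,
    s0: float | None = None,
    exhaustive: bool = False,
):
    """Permutation order statistics of d and their expectations.

    Returns ``(dbar, perm_sorted)`` where ``perm_sorted`` is the B x m
    matrix of sorted permuted d-statistics and ``dbar`` its column mean.
    The fudge factor is held fixed at its observed-data value across
    permutations (pass ``s0`` to skip recomputing it).
    """
    i1, i2 = _group_indices(groups)
    if s0 is None:
        s0 = sam_statistic(data, groups).s0
    plan = ResamplePlan(method="permutation", B=B, seed=seed, exhaustive=exhaustive)
    cols = np.concatenate([i1, i2])
    n1 = len(i1)
    Y = data.Y
    perm_sorted = np.empty((plan.B if not exhaustive else math.comb(len(cols), n1), Y.shape[0]))
    count = 0
    for assign in permutation_assignments(n1, len(i2), plan):
        j1, j2 = cols[assign[:n1]], cols[assign[n1:]]
        r, s = _relative_difference(Y, j1, j2)
        perm_sorted[count] = np.sort(r / (s + s0))
        count += 1
    perm_sorted = perm_sorted[:count]
    dbar = perm_sorted.mean(axis=0)
    return dbar, perm_sorted


def sam_call(
    d: np.ndarray,
    dbar: np.ndarray,
    delta: float,
    perm_sorted: np.ndarray,
) -> SAMCall:
    """Call significant genes at threshold delta and estimate the FDR.

    Walking up the SAM plot from the origin, the first ordered gene with
    ``d_(i) - dbar_(i) >= delta`` opens the positive calls; the symmetric
    walk down opens the negative calls (comparisons inclusive).  E(V) is
    the mean number of permuted scores at or beyond the resulting cut
    points.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    m = d.size
    order = np.argsort(d, kind="stable")
    ds = d[order]
    diff = ds - dbar
    origin = int(np.searchsorted(dbar, 0.0, side="left"))  # first index with dbar >= 0

    up_hits = np.nonzero(diff[origin:] >= delta)[0]
    i_up = origin + int(up_hits[0]) if up_hits.size else None
    low_hits = np.nonzero(-diff[:origin] >= delta)[0]
    i_low = int(low_hits[-1]) if low_hits.size else None

    pos = order[i_up:] if i_up is not None else np.array([], dtype=int)
    neg = order[: i_low + 1] if i_low is not None else np.array([], dtype=int)
    cut_up = ds[i_up] if i_up is not None else math.inf
    cut_low = ds[i_low] if i_low is not None else -math.inf

    flat = np.sort(perm_sorted, axis=None)
    n_null = flat.size
    B = perm_sorted.shape[0]
    above = n_null - np.searchsorted(flat, cut_up, side="left") if i_up is not None else 0
    below = np.searchsorted(flat, cut_low, side="right") if i_low is not None else 0
    expected_false = (above + below) / B
    R = pos.size + neg.size
    fdr = expected_false / R if R > 0 else 0.0
    return SAMCall(
        delta=float(delta),
        cut_up=float(cut_up),
        cut_low=float(cut_low),
        significant_pos=pos,
        significant_neg=neg,
        expected_false=float(expected_false),
        fdr_est=float(fdr),
    )


def sam_select_delta(
    data: ExpressionData,
    groups: Sequence,
    B: int,
    fdr_target: float = 0.05,
    seed: int = 0,
    exhaustive: bool = False,
):
    """Choose the smallest delta whose estimated FDR meets the target.

    Scans the thresholds at which the called set changes (the observed
    departures ``|d_(i) - dbar_(i)|``), keeping the largest rejection set
    whose estimated FDR is at or below ``fdr_target``.  Returns
    ``(call, stats, dbar, perm_sorted)``.
    """
    if not (0 <= fdr_target <= 1):
        raise ValueError("fdr_target must lie in [0, 1]")
    stats = sam_statistic(data, groups)
    dbar, perm_sorted = sam_permutation_null(data, groups, B=B, seed=seed, s0=stats.s0, exhaustive=exhaustive)
    ds = np.sort(stats.d)
    departures = np.abs(ds - dbar)
    grid = np.unique(np.concatenate([[0.0], departures, [departures.max() + 1.0]]))
    best = None
    for delta in grid:
        call = sam_call(stats.d, dbar, float(delta), perm_sorted)
        if call.fdr_est <= fdr_target:
            best = call
            break
    if best is None:  # unreachable: the sentinel delta calls nothing
        best = sam_call(stats.d, dbar, float(grid[-1]), perm_sorted)
    return best, stats, dbar, perm_sorted
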