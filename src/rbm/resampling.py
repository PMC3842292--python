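"""Resampling-based empirical Bayes tests (permutation and bootstrap).

The moderated t-statistic borrows strength across genes, but its
parametric p-value leans on normality of the underlying data.  The
resampling-based variants implemented here instead build the null
reference distribution empirically:

1. compute the moderated t-statistics (and their parametric p-values)
   on the observed data;
2. resample the arrays under the complete null — by permuting group
   labels, or by bootstrap resampling of within-group mean-centred
   arrays — and rerun the full moderation pipeline on every resample;
3. compare each observed statistic against the pooled ensemble of
   resampled statistics (or p-values) across all genes and resamples.

Resampling whole arrays preserves the inter-gene correlation structure.
Pooling across genes treats the ensemble as draws from the complete null
and gives p-value resolution of 1/(mB) rather than 1/B; with the add-one
correction the smallest attainable p-value is 1/(mB + 1).

Four variants arise from crossing the resampling scheme with the
measure of extremeness:

====== ============ ==============================
name   resampling   extremeness measured on
====== ============ ==============================
TSBP   permutation  |moderated t|
TSBB   bootstrap    |moderated t|
PBP    permutation  parametric p-value (smaller = more extreme)
PBB    bootstrap    parametric p-value
====== ============ ==============================
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

from .designs import DesignMatrix, DesignSpec, build_design, contrast_of_interest
from .linmod import (
    EBayesPrior,
    ExpressionData,
    ModeratedResult,
    estimate_prior,
    fit_gene_models,
    moderate,
)

__all__ = [
    "ResamplePlan",
    "NullEnsemble",
    "ResamplingResult",
    "VARIANTS",
    "permutation_assignments",
    "permute_labels",
    "bootstrap_null",
    "build_ensemble",
    "rbm_pvalue_stat",
    "rbm_pvalue_p",
    "rbm_test",
]

VARIANTS = ("tsbp", "tsbb", "pbp", "pbb")

# exhaustive enumeration of label assignments is only offered for small
# experiments where C(n, n1) stays manageable
_EXHAUSTIVE_MAX_ARRAYS = 12


@dataclass(frozen=True)
class ResamplePlan:
    """How to build the null ensemble: scheme, resample count, seed."""

    method: str  # "permutation" | "bootstrap"
    B: int
    seed: int = 0
    exhaustive: bool = False

    def __post_init__(self):
        if self.method not in ("permutation", "bootstrap"):
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.exhaustive and self.method != "permutation":
            raise ValueError("exhaustive enumeration applies to permutation only")


@dataclass(frozen=True)
class NullEnsemble:
    """genes x B matrices of null moderated t-statistics and p-values."""

    stat_null: np.ndarray
    p_null: np.ndarray

    @property
    def B(self) -> int:
        return self.stat_null.shape[1]


@dataclass(frozen=True)
class ResamplingResult:
    """Observed moderated statistics plus their resampling p-values."""

    observed: ModeratedResult
    p_rbm: np.ndarray
    variant: str
    ensemble: NullEnsemble | None = None


def _group_indices(groups: Sequence) -> tuple[np.ndarray, np.ndarray]:
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {labels}")
    g = np.asarray(groups)
    return np.where(g == labels[0])[0], np.where(g == labels[1])[0]


def permutation_assignments(n1: int, n2: int, plan: ResamplePlan) -> Iterator[np.ndarray]:
    """Yield column orders re-assigning arrays to the two groups.

    Each yielded array ``order`` of length ``n1 + n2`` lists the columns
    taking the first group's design rows followed by the second group's.
    Exhaustive mode enumerates every C(n1+n2, n1) assignment exactly
    once, starting with the identity; otherwise ``plan.B`` uniformly
    random permutations of the arrays are drawn.
    """
    n = n1 + n2
    if plan.exhaustive:
        if n > _EXHAUSTIVE_MAX_ARRAYS:
            raise ValueError(f"exhaustive enumeration limited to {_EXHAUSTIVE_MAX_ARRAYS} arrays")
        total = math.comb(n, n1)
        if plan.B > total:
            raise ValueError(f"B={plan.B} exceeds the {total} distinct assignments")
        count = 0
        for chosen in combinations(range(n), n1):
            rest = [i for i in range(n) if i not in chosen]
            yield np.array(list(chosen) + rest)
            count += 1
            if count == plan.B:
                return
        return
    rng = np.random.default_rng(plan.seed)
    for _ in range(plan.B):
        yield rng.permutation(n)


def permute_labels(data: ExpressionData, groups: Sequence, plan: ResamplePlan) -> Iterator[np.ndarray]:
    """Whole-array label permutations matching the complete null.

    Yields column-index arrays; ``data.Y[:, idx]`` is the relabelled
    dataset.  Relabelling whole arrays preserves gene-gene correlation.
    """
    if plan.method != "permutation":
        raise ValueError("plan.method must be 'permutation'")
    i1, i2 = _group_indices(groups)
    slots = np.concatenate([i1, i2])
    for assign in permutation_assignments(len(i1), len(i2), plan):
        idx = np.empty(len(slots), dtype=int)
        idx[slots] = assign  # group-1 slots take assign[:n1], group-2 slots the rest
        yield idx


def bootstrap_null(data: ExpressionData, groups: Sequence, plan: ResamplePlan):
    """Bootstrap resampling under the imposed complete null.

    Arrays are first mean-centred within each group per gene (removing
    any group effect, true or spurious), then drawn with replacement
    within group.  Returns ``(Y_centred, iterator_of_column_indices)``.
    """
    if plan.method != "bootstrap":
        raise ValueError("plan.method must be 'bootstrap'")
    i1, i2 = _group_indices(groups)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError("bootstrap requires at least 2 arrays per group")
    Yc = data.Y.copy()
    Yc[:, i1] -= Yc[:, i1].mean(axis=1, keepdims=True)
    Yc[:, i2] -= Yc[:, i2].mean(axis=1, keepdims=True)

    def _draws() -> Iterator[np.ndarray]:
        rng = np.random.default_rng(plan.seed)
        for _ in range(plan.B):
            idx = np.empty(len(groups), dtype=int)
            idx[: len(i1)] = rng.choice(i1, size=len(i1), replace=True)
            idx[len(i1):] = rng.choice(i2, size=len(i2), replace=True)
            yield idx

    return Yc, _draws()


def build_ensemble(
    Y: np.ndarray,
    design: DesignMatrix,
    contrast: int,
    resamples,
    refit_prior: bool = True,
    frozen_prior: EBayesPrior | None = None,
) -> NullEnsemble:
    """Run the full moderation pipeline on every resample.

    ``resamples`` yields column-index arrays into ``Y``.  By default the
    prior ``(d0, s0^2)`` is re-estimated within each resample, treating
    the hyperparameter estimation as part of the procedure being
    resampled; pass ``refit_prior=False`` with a ``frozen_prior`` to
    hold it fixed (sensitivity analysis).
    """
    if not refit_prior and frozen_prior is None:
        raise ValueError("frozen_prior is required when refit_prior=False")
    X = design.X
    n, p = X.shape
    q, r = np.linalg.qr(X)
    rinv = np.linalg.inv(r)
    cov_diag = np.diag(rinv @ rinv.T)
    df = n - p
    if df <= 0:
        raise ValueError("resampling requires positive residual degrees of freedom")
    m = Y.shape[0]
    stat_cols, p_cols = [], []
    for b_index, idx in enumerate(resamples):
        Yb = Y[:, idx]
        # same operation order as fit_gene_models so that the identity
        # permutation reproduces the observed statistics bit for bit
        beta = np.linalg.solve(r, q.T @ Yb.T).T
        resid = Yb - beta @ X.T
        s2 = np.einsum("ij,ij->i", resid, resid) / df
        # rows fit exactly (e.g. constant genes) leave rounding dust in
        # the residuals; snap their variance to a true zero
        msq = np.einsum("ij,ij->i", Yb, Yb) / n
        s2[s2 <= 1e-24 * msq] = 0.0
        fit = _FastFit(beta, s2, df, cov_diag, m, p)
        try:
            if refit_prior:
                prior = estimate_prior(fit)
            else:
                prior = frozen_prior
        except ValueError as exc:
            if frozen_prior is not None:
                prior = frozen_prior
            elif np.all(s2 == 0.0):
                # fully degenerate resample: any positive prior variance
                # gives null statistics of (numerically) zero
                prior = EBayesPrior(d0=math.inf, s0_2=1.0)
            else:
                raise RuntimeError(f"prior estimation failed in resample {b_index}: {exc}") from exc
        mod = moderate(fit, prior, contrast)
        stat_cols.append(mod.t_mod)
        p_cols.append(mod.p_param)
    stat_null = np.column_stack(stat_cols)
    p_null = np.column_stack(p_cols)
    # degenerate resamples (all arrays identical within a group) can yield
    # 0/0 statistics; treat them as unexceptional nulls
    bad = ~np.isfinite(stat_null)
    if bad.any():
        stat_null = np.where(bad, 0.0, stat_null)
        p_null = np.where(~np.isfinite(p_null), 1.0, p_null)
    return NullEnsemble(stat_null=stat_null, p_null=p_null)


class _FastFit:
    """Duck-typed GeneFit for the shared-design resampling fast path."""

    __slots__ = ("beta", "sigma2", "df_resid", "cov_diag", "n_obs", "ok", "coef_names", "n_genes")

    def __init__(self, beta, s2, df, cov_diag, m, p):
        self.beta = beta
        self.sigma2 = s2 if df > 0 else np.full(m, np.nan)
        self.df_resid = np.full(m, float(df))
        self.cov_diag = np.broadcast_to(cov_diag, (m, p))
        self.n_obs = np.full(m, float(beta.shape[0]))
        self.ok = np.ones(m, dtype=bool)
        self.coef_names = ()
        self.n_genes = m


def rbm_pvalue_stat(t_obs: np.ndarray, ensemble: NullEnsemble, pooled: bool = True) -> np.ndarray:
    """Resampling p-values from statistic extremeness (TSBP/TSBB).

    ``p_g = (1 + #{(l,b): |t_null[l,b]| >= |t_obs[g]|}) / (1 + mB)``
    with the null pool shared across all genes; ``pooled=False`` restricts
    each gene to its own row of the ensemble (denominator ``1 + B``).
    """
    a = np.abs(np.asarray(t_obs, dtype=float))
    null_abs = np.abs(ensemble.stat_null)
    if pooled:
        flat = np.sort(null_abs, axis=None)
        ge = flat.size - np.searchsorted(flat, a, side="left")
        return (1.0 + ge) / (1.0 + flat.size)
    rows = np.sort(null_abs, axis=1)
    B = rows.shape[1]
    ge = B - np.array([np.searchsorted(rows[g], a[g], side="left") for g in range(rows.shape[0])])
    return (1.0 + ge) / (1.0 + B)


def rbm_pvalue_p(p_obs: np.ndarray, ensemble: NullEnsemble, pooled: bool = True) -> np.ndarray:
    """Resampling p-values from p-value extremeness (PBP/PBB).

    ``p_g = (1 + #{(l,b): p_null[l,b] <= p_obs[g]}) / (1 + mB)``.
    """
    a = np.asarray(p_obs, dtype=float)
    if pooled:
        flat = np.sort(ensemble.p_null, axis=None)
        le = np.searchsorted(flat, a, side="right")
        return (1.0 + le) / (1.0 + flat.size)
    rows = np.sort(ensemble.p_null, axis=1)
    B = rows.shape[1]
    le = np.array([np.searchsorted(rows[g], a[g], side="right") for g in range(rows.shape[0])])
    return (1.0 + le) / (1.0 + B)


def rbm_test(
    data: ExpressionData,
    groups: Sequence,
    variant: str,
    B: int = 1000,
    seed: int = 0,
    pooled: bool = True,
    refit_prior: bool = True,
    exhaustive: bool = False,
    keep_ensemble: bool = False,
) -> ResamplingResult:
    """Run one resampling-based empirical Bayes test on a two-group dataset.

    ``variant`` is one of ``tsbp``, ``tsbb``, ``pbp``, ``pbb``.
    """
    variant = variant.lower()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if data.weights is not None and not np.all(data.weights > 0):
        raise ValueError("resampling requires complete data (no zero-weight cells)")
    spec = DesignSpec("two_group", tuple(groups))
    design = build_design(spec)
    contrast = contrast_of_interest(design)
    fit = fit_gene_models(data, design)
    prior = estimate_prior(fit)
    observed = moderate(fit, prior, contrast)

    scheme = "permutation" if variant in ("tsbp", "pbp") else "bootstrap"
    plan = ResamplePlan(method=scheme, B=B, seed=seed, exhaustive=exhaustive)
    if scheme == "permutation":
        Ybase = data.Y
        draws = permute_labels(data, groups, plan)
    else:
        Ybase, draws = bootstrap_null(data, groups, plan)
    ensemble = build_ensemble(
        Ybase, design, contrast, draws,
        refit_prior=refit_prior, frozen_prior=None if refit_prior else prior,
    )
    if variant in ("tsbp", "tsbb"):
        p_rbm = rbm_pvalue_stat(observed.t_mod, ensemble, pooled=pooled)
    else:
        p_rbm = rbm_pvalue_p(observed.p_param, ensemble, pooled=pooled)
    return ResamplingResult(
        observed=observed,
        p_rbm=p_rbm,
        variant=variant,
        ensemble=ensemble if keep_ensemble else None,
    )
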