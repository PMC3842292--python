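"""Gene-wise linear models and empirical Bayes variance moderation.

Each gene g is fit by (weighted) least squares

    y_g = X beta_g + e_g,      Var(e_g) = sigma_g^2 W_g^{-1},

giving coefficients ``beta_g``, residual variance ``s_g^2`` on ``d_g``
degrees of freedom, and unscaled coefficient variances ``v_gj`` from the
diagonal of ``(X' W_g X)^{-1}``.  Residual variances are then shrunk
towards a common prior value ``s0^2`` carrying ``d0`` prior degrees of
freedom, both estimated from the ensemble of genes by matching the first
two moments of ``log s_g^2`` under a scaled chi-square sampling model.
The resulting moderated t-statistic

    t_g = beta_gj / (s~_g sqrt(v_gj)),   s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

is referred to a t distribution on ``d_g + d0`` degrees of freedom.
Borrowing strength across genes stabilises the denominator for genes with
few residual degrees of freedom, the regime where the ordinary t-statistic
is notoriously unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special, stats

from .designs import DesignMatrix

__all__ = [
    "ExpressionData",
    "GeneFit",
    "EBayesPrior",
    "ModeratedResult",
    "fit_gene_models",
    "estimate_prior",
    "moderate",
    "ordinary_t",
    "pm_pipeline",
    "trigamma_inverse",
]

# d0 larger than this is reported as +inf (numerically indistinguishable
# from no inter-gene variance heterogeneity).
D0_CAP = 1e6


@dataclass(frozen=True)
class ExpressionData:
    """A genes x arrays matrix of normalised log2 values.

    ``weights`` is an optional non-negative matrix of the same shape;
    zero weight marks a missing observation.
    """

    Y: np.ndarray
    gene_ids: tuple = ()
    weights: np.ndarray | None = None

    def __init__(self, Y, gene_ids: Sequence[str] | None = None, weights=None):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if gene_ids is None:
            width = len(str(Y.shape[0]))
            gene_ids = tuple(f"g{i + 1:0{width}d}" for i in range(Y.shape[0]))
        else:
            gene_ids = tuple(gene_ids)
            if len(gene_ids) != Y.shape[0]:
                raise ValueError("gene_ids length must match the number of rows")
            if len(set(gene_ids)) != len(gene_ids):
                raise ValueError("gene_ids must be unique")
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != Y.shape:
                raise ValueError("weights must have the same shape as Y")
            if np.any(weights < 0):
                raise ValueError("weights must be non-negative")
            if not np.all(np.isfinite(Y[weights > 0])):
                raise ValueError("Y must be finite wherever weight > 0")
        else:
            if not np.all(np.isfinite(Y)):
                raise ValueError("Y contains non-finite values; use zero weights for missing cells")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "weights", weights)

    @property
    def n_genes(self) -> int:
        return self.Y.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class GeneFit:
    """Per-gene least-squares results.

    ``sigma2`` is NaN for genes with zero residual degrees of freedom
    (saturated fits) and ``ok`` is False for genes whose weighted design
    was singular.
    """

    beta: np.ndarray          # genes x p
    sigma2: np.ndarray        # genes
    df_resid: np.ndarray      # genes
    cov_diag: np.ndarray      # genes x p, diagonal of (X' W X)^{-1}
    n_obs: np.ndarray         # genes, observations with positive weight
    ok: np.ndarray            # genes, fit succeeded
    coef_names: tuple = ()

    @property
    def n_genes(self) -> int:
        return self.beta.shape[0]


@dataclass(frozen=True)
class EBayesPrior:
    """Prior degrees of freedom ``d0`` and prior variance ``s0^2``.

    ``d0 = inf`` signals no detectable variance heterogeneity beyond
    chi-square sampling noise (every gene shares the prior variance).
    """

    d0: float
    s0_2: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ValueError("prior degrees of freedom must be positive")
        if not (self.s0_2 > 0):
            raise ValueError("prior variance must be positive")


@dataclass(frozen=True)
class ModeratedResult:
    """Moderated t-statistics with their parametric p-values."""

    s_tilde2: np.ndarray
    t_mod: np.ndarray
    df_total: np.ndarray
    p_param: np.ndarray
    contrast: int
    prior: EBayesPrior


def fit_gene_models(data: ExpressionData, design: DesignMatrix) -> GeneFit:
    """Fit the gene-wise (weighted) least-squares models.

    With no weights, all genes share the design and the fit is a single
    vectorised QR solve.  With weights, genes are fit individually; a
    gene whose weighted design loses rank is flagged ``ok=False`` rather
    than raising, and saturated genes carry ``sigma2 = NaN``.
    """
    X = design.X
    Y = data.Y
    m, n = Y.shape
    p = X.shape[1]
    if n != X.shape[0]:
        raise ValueError(f"data has {n} arrays but design has {X.shape[0]} rows")

    if data.weights is None:
        q, r = np.linalg.qr(X)
        beta = np.linalg.solve(r, q.T @ Y.T).T
        resid = Y - beta @ X.T
        df = n - p
        rss = np.einsum("ij,ij->i", resid, resid)
        if df > 0:
            sigma2 = rss / df
        else:
            sigma2 = np.full(m, np.nan)
        rinv = np.linalg.inv(r)
        cov = rinv @ rinv.T
        cov_diag = np.broadcast_to(np.diag(cov), (m, p)).copy()
        return GeneFit(
            beta=beta,
            sigma2=sigma2,
            df_resid=np.full(m, float(df)),
            cov_diag=cov_diag,
            n_obs=np.full(m, float(n)),
            ok=np.ones(m, dtype=bool),
            coef_names=design.coef_names,
        )

    beta = np.full((m, p), np.nan)
    sigma2 = np.full(m, np.nan)
    df_resid = np.zeros(m)
    cov_diag = np.full((m, p), np.nan)
    n_obs = np.zeros(m)
    ok = np.zeros(m, dtype=bool)
    for g in range(m):
        w = data.weights[g]
        use = w > 0
        n_g = int(use.sum())
        n_obs[g] = n_g
        sw = np.sqrt(w[use])
        Xw = X[use] * sw[:, None]
        yw = Y[g, use] * sw
        if n_g < p or np.linalg.matrix_rank(Xw) < p:
            continue  # singular weighted design: flagged unfit
        xtx = Xw.T @ Xw
        xtx_inv = np.linalg.inv(xtx)
        b = xtx_inv @ (Xw.T @ yw)
        beta[g] = b
        cov_diag[g] = np.diag(xtx_inv)
        d_g = n_g - p
        df_resid[g] = d_g
        if d_g > 0:
            resid = yw - Xw @ b
            sigma2[g] = float(resid @ resid) / d_g
        ok[g] = True
    return GeneFit(
        beta=beta,
        sigma2=sigma2,
        df_resid=df_resid,
        cov_diag=cov_diag,
        n_obs=n_obs,
        ok=ok,
        coef_names=design.coef_names,
    )


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve ``trigamma(y) = x`` for ``y > 0`` by monotone Newton iteration."""
    if not np.isfinite(x) or x <= 0:
        raise ValueError("trigamma_inverse requires a positive finite argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def estimate_prior(fit: GeneFit) -> EBayesPrior:
    """Estimate ``(d0, s0^2)`` by moment matching on ``z_g = log s_g^2``.

    Under the hierarchical model, ``e_g = z_g - digamma(d_g/2) +
    log(d_g/2)`` has mean ``log s0^2 - digamma(d0/2) + log(d0/2)`` and
    variance ``trigamma(d_g/2) + trigamma(d0/2)``; equating empirical to
    expected first and second moments gives ``d0`` by inverting the
    trigamma function and then ``s0^2`` in closed form.  When the observed
    spread of ``z_g`` does not exceed its pure-sampling expectation, the
    moment equation has no positive solution and ``d0 = +inf`` is
    returned with ``s0^2`` the (geometric-mean based) common variance.
    """
    use = (fit.df_resid > 0) & np.isfinite(fit.sigma2) & (fit.sigma2 > 0) & fit.ok
    m = int(use.sum())
    if m == 0:
        raise ValueError("no residual degrees of freedom: cannot estimate a variance prior")
    if m < 2:
        raise ValueError("at least 2 genes with positive residual df are required")
    s2 = fit.sigma2[use]
    d = fit.df_resid[use]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(np.sum((e - emean) ** 2) / (m - 1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        if d0 > D0_CAP:
            return EBayesPrior(d0=math.inf, s0_2=math.exp(emean))
        s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        return EBayesPrior(d0=d0, s0_2=s0_2)
    return EBayesPrior(d0=math.inf, s0_2=math.exp(emean))


def moderate(fit: GeneFit, prior: EBayesPrior, contrast: int) -> ModeratedResult:
    """Compute posterior variances, moderated t and parametric p-values.

    Genes with undefined sample variance (zero residual df) fall back to
    the prior: ``s~^2 = s0^2`` on ``d0`` total degrees of freedom, so the
    shrinkage estimator remains defined for saturated fits.
    """
    if not (0 <= contrast < fit.beta.shape[1]):
        raise IndexError(f"contrast index {contrast} out of range")
    d = fit.df_resid.astype(float)
    s2 = np.where(np.isfinite(fit.sigma2), fit.sigma2, 0.0)
    d_eff = np.where(np.isfinite(fit.sigma2), d, 0.0)
    if math.isinf(prior.d0):
        s_tilde2 = np.full(fit.n_genes, prior.s0_2)
        df_total = np.full(fit.n_genes, np.inf)
    else:
        s_tilde2 = (prior.d0 * prior.s0_2 + d_eff * s2) / (prior.d0 + d_eff)
        df_total = d_eff + prior.d0
    b = fit.beta[:, contrast]
    v = fit.cov_diag[:, contrast]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = b / np.sqrt(s_tilde2 * v)
    p = _two_sided_p(t, df_total)
    return ModeratedResult(
        s_tilde2=s_tilde2, t_mod=t, df_total=df_total, p_param=p,
        contrast=contrast, prior=prior,
    )


def ordinary_t(fit: GeneFit, contrast: int):
    """Ordinary t-statistic and two-sided p-value on ``d_g`` df.

    Genes with no residual degrees of freedom get NaN statistics.
    """
    b = fit.beta[:, contrast]
    v = fit.cov_diag[:, contrast]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(fit.df_resid > 0, b / np.sqrt(fit.sigma2 * v), np.nan)
    p = _two_sided_p(t, fit.df_resid)
    return t, p


def _two_sided_p(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), t.shape)
    p = np.full(t.shape, np.nan)
    finite_df = np.isfinite(df) & (df > 0) & np.isfinite(t)
    inf_df = np.isinf(df) & np.isfinite(t)
    if finite_df.any():
        p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df[finite_df])
    if inf_df.any():
        p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
    return p


def pm_pipeline(data: ExpressionData, design: DesignMatrix, contrast: int | None = None):
    """Convenience wrapper: fit, estimate the prior, and moderate.

    Returns ``(fit, prior, moderated)``.
    """
    from .designs import contrast_of_interest

    fit = fit_gene_models(data, design)
    prior = estimate_prior(fit)
    if contrast is None:
        contrast = contrast_of_interest(design)
    mod = moderate(fit, prior, contrast)
    return fit, prior, mod
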