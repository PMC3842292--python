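import math

import numpy as np
import pytest
from scipy import special, stats

import rbm
from rbm.designs import DesignSpec, build_design
from rbm.linmod import (
    EBayesPrior,
    ExpressionData,
    GeneFit,
    estimate_prior,
    fit_gene_models,
    moderate,
    ordinary_t,
    trigamma_inverse,
)

TWO_GROUP = build_design(DesignSpec("two_group", ("A", "A", "B", "B")))


def _lstsq_oracle(y, X):
    """Independent least-squares reference: coefficients, s2, df."""
    beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    df = len(y) - rank
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    s2 = rss / df if df > 0 else np.nan
    return beta, s2, df


def test_fit_matches_least_squares_oracle():
    y = np.array([0.0, 2.0, 1.0, 3.0])
    fit = fit_gene_models(ExpressionData(y), TWO_GROUP)
    beta_o, s2_o, df_o = _lstsq_oracle(y, TWO_GROUP.X)
    np.testing.assert_allclose(fit.beta[0], beta_o)
    assert fit.beta[0, 1] == pytest.approx(1.0)  # group means 1 and 2
    assert fit.sigma2[0] == pytest.approx(s2_o) == pytest.approx(2.0)
    assert fit.df_resid[0] == df_o == 2
    # v for the difference coefficient of a balanced 2+2 design
    xtx_inv = np.linalg.inv(TWO_GROUP.X.T @ TWO_GROUP.X)
    np.testing.assert_allclose(fit.cov_diag[0], np.diag(xtx_inv))
    t, p = ordinary_t(fit, 1)
    assert t[0] == pytest.approx(beta_o[1] / math.sqrt(s2_o * xtx_inv[1, 1]))
    assert p[0] == pytest.approx(2 * stats.t.sf(abs(t[0]), 2))


def test_saturated_gene_flagged_undefined():
    design = build_design(DesignSpec("two_group", ("A", "B")))
    fit = fit_gene_models(ExpressionData(np.array([1.0, 3.0])), design)
    assert fit.df_resid[0] == 0
    assert np.isnan(fit.sigma2[0])
    t, _ = ordinary_t(fit, 1)
    assert np.isnan(t[0])


def test_weight_scaling_leaves_t_unchanged(rng):
    y = rng.normal(size=(7, 4))
    w1 = np.ones_like(y)
    w2 = 3.7 * np.ones_like(y)
    f1 = fit_gene_models(ExpressionData(y, weights=w1), TWO_GROUP)
    f2 = fit_gene_models(ExpressionData(y, weights=w2), TWO_GROUP)
    np.testing.assert_allclose(f1.beta, f2.beta)
    t1, _ = ordinary_t(f1, 1)
    t2, _ = ordinary_t(f2, 1)
    np.testing.assert_allclose(t1, t2)


def test_zero_weight_equals_dropped_observation(rng):
    design = build_design(DesignSpec("two_group", ("A", "A", "A", "B", "B", "B")))
    y = rng.normal(size=(5, 6))
    w = np.ones_like(y)
    w[2, 4] = 0.0
    fit = fit_gene_models(ExpressionData(y, weights=w), design)
    # same gene fit on the 5 remaining arrays
    sub = build_design(DesignSpec("two_group", ("A", "A", "A", "B", "B")))
    y_sub = np.delete(y[2], 4)[None, :]
    fit_sub = fit_gene_models(ExpressionData(y_sub), sub)
    np.testing.assert_allclose(fit.beta[2], fit_sub.beta[0])
    assert fit.sigma2[2] == pytest.approx(fit_sub.sigma2[0])
    assert fit.df_resid[2] == fit_sub.df_resid[0] == 3


def _make_fit(s2, d):
    m = len(s2)
    return GeneFit(
        beta=np.zeros((m, 1)),
        sigma2=np.asarray(s2, float),
        df_resid=np.full(m, float(d)),
        cov_diag=np.ones((m, 1)),
        n_obs=np.full(m, d + 1.0),
        ok=np.ones(m, dtype=bool),
    )


def test_prior_equal_variances_gives_infinite_d0():
    # at large residual df the log-variance bias correction vanishes and
    # the common value is recovered
    fit = _make_fit(np.full(200, 2.5), d=200)
    prior = estimate_prior(fit)
    assert math.isinf(prior.d0)
    assert prior.s0_2 == pytest.approx(2.5, rel=0.01)


def test_prior_requires_at_least_two_genes():
    with pytest.raises(ValueError):
        estimate_prior(_make_fit([1.0], d=4))
    with pytest.raises(ValueError, match="residual degrees of freedom"):
        estimate_prior(_make_fit([np.nan, np.nan], d=0))


def test_prior_recovery_on_synthetic_variances():
    """(d0, s0^2) recovered within 15% when sample variances follow the
    hierarchical model: sigma_g^2 ~ scaled inverse chi2(d0=4, s0^2=1),
    s_g^2 | sigma_g^2 ~ sigma_g^2 chi2_6 / 6, m=5000."""
    rng = np.random.default_rng(5)
    m, d0, s0_2, d = 5000, 4.0, 1.0, 6
    sigma2 = d0 * s0_2 / rng.chisquare(d0, m)
    s2 = sigma2 * rng.chisquare(d, m) / d
    prior = estimate_prior(_make_fit(s2, d))
    assert prior.d0 == pytest.approx(d0, rel=0.15)
    assert prior.s0_2 == pytest.approx(s0_2, rel=0.15)
    # independent oracle: bisection on the trigamma moment equation
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2.0)
    lo, hi = 1e-3, 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > evar:
            lo = mid
        else:
            hi = mid
    assert prior.d0 == pytest.approx(2 * lo, rel=1e-4)


def test_trigamma_inverse_roundtrip():
    for y in [0.01, 0.5, 2.0, 37.0]:
        x = float(special.polygamma(1, y))
        assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)
    with pytest.raises(ValueError):
        trigamma_inverse(-1.0)


def test_posterior_variance_arithmetic():
    fit = _make_fit([4.0], d=2)
    mod = moderate(fit, EBayesPrior(d0=4.0, s0_2=1.0), 0)
    assert mod.s_tilde2[0] == pytest.approx((4 * 1 + 2 * 4) / 6)
    assert mod.df_total[0] == pytest.approx(6.0)


def test_moderation_limits(rng):
    """d0 -> 0 recovers the ordinary t; d0 -> inf gives the s0-studentised
    statistic with a normal reference."""
    y = rng.normal(size=(30, 4)) + 0.5
    fit = fit_gene_models(ExpressionData(y), TWO_GROUP)
    t_ord, _ = ordinary_t(fit, 1)

    tiny = moderate(fit, EBayesPrior(d0=1e-10, s0_2=7.7), 1)
    np.testing.assert_allclose(tiny.t_mod, t_ord, rtol=1e-6)

    s0_2 = 0.9
    inf_prior = moderate(fit, EBayesPrior(d0=math.inf, s0_2=s0_2), 1)
    expected = fit.beta[:, 1] / np.sqrt(s0_2 * fit.cov_diag[:, 1])
    np.testing.assert_allclose(inf_prior.t_mod, expected)
    assert np.all(np.isinf(inf_prior.df_total))
    np.testing.assert_allclose(
        inf_prior.p_param, 2 * stats.norm.sf(np.abs(expected)), rtol=1e-12
    )


def test_null_effect_gives_p_one():
    fit = GeneFit(
        beta=np.array([[0.0, 0.0]]),
        sigma2=np.array([1.0]),
        df_resid=np.array([2.0]),
        cov_diag=np.ones((1, 2)),
        n_obs=np.array([4.0]),
        ok=np.array([True]),
    )
    mod = moderate(fit, EBayesPrior(d0=4.0, s0_2=1.0), 1)
    assert mod.t_mod[0] == 0.0
    assert mod.p_param[0] == pytest.approx(1.0)


def test_shrinkage_bound_and_monotonicity(rng):
    s2 = rng.chisquare(4, size=300)
    fit = _make_fit(s2, d=5)
    prior = EBayesPrior(d0=3.0, s0_2=1.2)
    mod = moderate(fit, prior, 0)
    lo = np.minimum(s2, prior.s0_2)
    hi = np.maximum(s2, prior.s0_2)
    assert np.all(mod.s_tilde2 >= lo - 1e-12)
    assert np.all(mod.s_tilde2 <= hi + 1e-12)
    # |t| is non-increasing in the posterior variance for fixed beta, v
    beta, v = 1.3, 0.5
    svals = np.sort(mod.s_tilde2)
    tvals = np.abs(beta / np.sqrt(svals * v))
    assert np.all(np.diff(tvals) <= 1e-12)


def test_saturated_gene_borrows_prior():
    fit = GeneFit(
        beta=np.array([[0.0, 1.0]]),
        sigma2=np.array([np.nan]),
        df_resid=np.array([0.0]),
        cov_diag=np.ones((1, 2)),
        n_obs=np.array([2.0]),
        ok=np.array([True]),
    )
    prior = EBayesPrior(d0=4.0, s0_2=2.0)
    mod = moderate(fit, prior, 1)
    assert mod.s_tilde2[0] == pytest.approx(2.0)
    assert mod.df_total[0] == pytest.approx(4.0)
    assert np.isfinite(mod.p_param[0])


def test_null_pvalues_approximately_uniform():
    """Complete null, normal data: parametric moderated-t p-values are
    close to Uniform(0,1) (KS statistic < 0.05 at m=2000, n=12)."""
    cfg = rbm.ScenarioConfig(m=2000, n=12, pi1=0.0, effect=0.0, seed=77)
    ds = rbm.generate_dataset(cfg, 0)
    design = build_design(DesignSpec("two_group", ds.groups))
    _, _, mod = rbm.pm_pipeline(ds.data, design)
    ks = stats.kstest(mod.p_param, "uniform").statistic
    assert ks < 0.05
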