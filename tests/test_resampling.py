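import math
from itertools import combinations

import numpy as np
import pytest

import rbm
from rbm.designs import DesignSpec, build_design, contrast_of_interest
from rbm.linmod import ExpressionData, estimate_prior, fit_gene_models, moderate
from rbm.resampling import (
    NullEnsemble,
    ResamplePlan,
    bootstrap_null,
    build_ensemble,
    permutation_assignments,
    permute_labels,
    rbm_pvalue_p,
    rbm_pvalue_stat,
    rbm_test,
)

GROUPS6 = ("A", "A", "A", "B", "B", "B")


def test_exhaustive_enumeration_counts_and_identity():
    plan = ResamplePlan("permutation", B=20, seed=0, exhaustive=True)
    assigns = list(permutation_assignments(3, 3, plan))
    assert len(assigns) == math.comb(6, 3) == 20
    keys = {tuple(sorted(a[:3])) for a in assigns}
    assert len(keys) == 20  # each label assignment exactly once
    assert (0, 1, 2) in keys  # identity among them


def test_exhaustive_rejects_oversized_B():
    plan = ResamplePlan("permutation", B=21, seed=0, exhaustive=True)
    with pytest.raises(ValueError, match="distinct assignments"):
        list(permutation_assignments(3, 3, plan))


def test_permutation_sequence_deterministic(toy_two_group):
    plan = ResamplePlan("permutation", B=7, seed=42)
    a = list(permute_labels(toy_two_group.data, toy_two_group.groups, plan))
    b = list(permute_labels(toy_two_group.data, toy_two_group.groups, plan))
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_bootstrap_centering_and_shape(toy_two_group):
    plan = ResamplePlan("bootstrap", B=3, seed=1)
    Yc, draws = bootstrap_null(toy_two_group.data, toy_two_group.groups, plan)
    n = toy_two_group.config.n
    np.testing.assert_allclose(Yc[:, :n].mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(Yc[:, n:].mean(axis=1), 0.0, atol=1e-12)
    idx = list(draws)
    assert len(idx) == 3
    for i in idx:
        assert i.shape == (2 * n,)
        assert set(i[:n]) <= set(range(n))          # within-group draws
        assert set(i[n:]) <= set(range(n, 2 * n))


def test_bootstrap_requires_two_per_group():
    data = ExpressionData(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        bootstrap_null(data, ("A", "B", "B"), ResamplePlan("bootstrap", B=2))


@pytest.mark.parametrize(
    "null_abs,obs,expected",
    [
        ([1.0, 2.0, 3.0, 4.0], 2.5, (1 + 2) / 5),   # brute-force count
        ([1.0, 2.0, 3.0, 4.0], 0.0, 1.0),           # nothing less extreme
        ([1.0, 2.0, 3.0, 4.0], 9.0, 1 / 5),         # beyond every null value
        ([1.0, 2.0, 3.0, 4.0], 2.0, (1 + 3) / 5),   # tie counts as >= obs
    ],
)
def test_statistic_counting_rule(null_abs, obs, expected):
    ens = NullEnsemble(
        stat_null=np.asarray(null_abs, float)[None, :],
        p_null=np.full((1, len(null_abs)), 0.5),
    )
    assert rbm_pvalue_stat(np.array([obs]), ens)[0] == pytest.approx(expected)


@pytest.mark.parametrize(
    "null_p,obs,expected",
    [
        ([0.2, 0.4, 0.6, 0.8], 0.5, (1 + 2) / 5),
        ([0.2, 0.4, 0.6, 0.8], 1.0, 1.0),
        ([0.2, 0.4, 0.6, 0.8], 0.1, 1 / 5),
    ],
)
def test_pvalue_counting_rule(null_p, obs, expected):
    ens = NullEnsemble(
        stat_null=np.zeros((1, len(null_p))),
        p_null=np.asarray(null_p, float)[None, :],
    )
    assert rbm_pvalue_p(np.array([obs]), ens)[0] == pytest.approx(expected)


def test_pooled_minimum_p_is_one_over_mB_plus_one(rng):
    ens = NullEnsemble(
        stat_null=rng.normal(size=(10, 30)),
        p_null=rng.random((10, 30)),
    )
    extreme = np.array([1e9])
    assert rbm_pvalue_stat(extreme, ens)[0] == pytest.approx(1 / (10 * 30 + 1))
    assert rbm_pvalue_p(np.array([0.0]), ens)[0] == pytest.approx(1 / (10 * 30 + 1))


def test_rbm_pvalues_monotone_in_statistic(rng):
    ens = NullEnsemble(stat_null=rng.normal(size=(20, 40)), p_null=rng.random((20, 40)))
    t_obs = rng.normal(size=20) * 2
    p = rbm_pvalue_stat(t_obs, ens)
    order = np.argsort(-np.abs(t_obs))
    assert np.all(np.diff(p[order]) >= 0)
    p_obs = rng.random(20)
    q = rbm_pvalue_p(p_obs, ens)
    order = np.argsort(p_obs)
    assert np.all(np.diff(q[order]) >= 0)


def test_tsbp_matches_exhaustive_bruteforce_oracle(rng):
    """Pooled permutation p-values at n=3+3 equal a plain-Python
    enumeration over all 20 label assignments."""
    m = 8
    Y = rng.normal(size=(m, 6))
    Y[:3, 3:] += 1.0
    data = ExpressionData(Y)
    res = rbm_test(data, GROUPS6, "tsbp", B=20, seed=0, exhaustive=True)

    # oracle: enumerate assignments, run the moderation pipeline per
    # relabelled dataset, count extremeness by loops
    design = build_design(DesignSpec("two_group", GROUPS6))
    c = contrast_of_interest(design)
    fit = fit_gene_models(data, design)
    t_obs = moderate(fit, estimate_prior(fit), c).t_mod
    null_vals = []
    for chosen in combinations(range(6), 3):
        rest = [i for i in range(6) if i not in chosen]
        Yb = Y[:, list(chosen) + rest]
        fb = fit_gene_models(ExpressionData(Yb), design)
        null_vals.extend(moderate(fb, estimate_prior(fb), c).t_mod.tolist())
    expected = np.empty(m)
    for g in range(m):
        count = sum(1 for v in null_vals if abs(v) >= abs(t_obs[g]))
        expected[g] = (1 + count) / (1 + len(null_vals))
    np.testing.assert_allclose(res.p_rbm, expected, rtol=1e-12)


def test_sign_flip_leaves_tsbp_unchanged(toy_two_group):
    data = toy_two_group.data
    flipped = ExpressionData(-data.Y)
    a = rbm_test(data, toy_two_group.groups, "tsbp", B=30, seed=5)
    b = rbm_test(flipped, toy_two_group.groups, "tsbp", B=30, seed=5)
    np.testing.assert_allclose(a.p_rbm, b.p_rbm)


def test_rbm_test_deterministic(toy_two_group):
    a = rbm_test(toy_two_group.data, toy_two_group.groups, "pbb", B=25, seed=9)
    b = rbm_test(toy_two_group.data, toy_two_group.groups, "pbb", B=25, seed=9)
    np.testing.assert_array_equal(a.p_rbm, b.p_rbm)


def test_constant_data_yields_null_statistics():
    Y = np.tile(np.arange(5.0)[:, None], (1, 6))  # identical across arrays
    design = build_design(DesignSpec("two_group", GROUPS6))
    plan = ResamplePlan("permutation", B=4, seed=0)
    draws = permute_labels(ExpressionData(Y), GROUPS6, plan)
    ens = build_ensemble(Y, design, 1, draws)
    np.testing.assert_allclose(ens.stat_null, 0.0, atol=1e-9)
    np.testing.assert_allclose(ens.p_null, 1.0, atol=1e-9)
    assert ens.B == 4


def test_per_gene_option_uses_row_nulls(rng):
    stat = np.vstack([np.full(10, 5.0), np.full(10, 0.1)])
    ens = NullEnsemble(stat_null=stat, p_null=rng.random((2, 10)))
    obs = np.array([1.0, 1.0])
    pooled = rbm_pvalue_stat(obs, ens, pooled=True)
    per_gene = rbm_pvalue_stat(obs, ens, pooled=False)
    assert pooled[0] == pooled[1]
    assert per_gene[0] == 1.0                 # all row nulls exceed it
    assert per_gene[1] == pytest.approx(1 / 11)  # none do
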