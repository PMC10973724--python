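"""Batch correction, the over-60 filter and the covariate balance tests,
checked against independent oracles (permutation, enumeration, step-up
definition, scanpy's ComBat)."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import glycostrat as g
from glycostrat.cohort import GP_COLUMNS
from glycostrat.synthetic import generate_cohort, matched_spec

from conftest import make_cohort_frame


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mwu_permutation_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of assignments."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = stats.rankdata(pooled)

    def u_stat(idx_a):
        ra = ranks[list(idx_a)].sum()
        return ra - na * (na + 1) / 2

    u_obs = u_stat(range(na))
    us = np.array([u_stat(c) for c in itertools.combinations(range(n), na)])
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def fisher_enumeration_p(table):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins no more probable than the observed."""
    (a, b), (c, d) = table
    r1, n1 = a + b, a + c
    total = a + b + c + d
    p_obs = stats.hypergeom.pmf(a, total, n1, r1)
    p = 0.0
    for a2 in range(max(0, r1 + n1 - total), min(r1, n1) + 1):
        pk = stats.hypergeom.pmf(a2, total, n1, r1)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return min(p, 1.0)


def bh_stepup(p):
    """Literal step-up definition of the BH adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        cands = [m * p[j] / rank_j
                 for rank_j, j in enumerate(order, start=1)
                 if rank_j >= rank_i]
        q[i] = min(1.0, min(cands))
    return q


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def test_log_transform_values_and_zero_error(toy_cohort):
    logX = g.log_transform_gps(toy_cohort)
    assert np.allclose(np.exp(logX), toy_cohort.gp, atol=1e-12)
    assert g.log_transform_gps(np.array([[1.0, np.e ** -2]])).ravel() == \
        pytest.approx([0.0, -2.0], abs=1e-12)
    with pytest.raises(ValueError, match="positivity floor"):
        g.log_transform_gps(np.array([[0.0, 0.5]]))


# ---------------------------------------------------------------------------
# batch model
# ---------------------------------------------------------------------------

def _inject_scenario(seed, shift=0.5, n=200):
    sp = replace(matched_spec(n), class_effect={},
                 year_shifts={"A": 0.0}, plate_shifts={"P": 0.0},
                 year_inflation={})
    cohort, _ = generate_cohort(sp, seed=seed)
    logX = g.log_transform_gps(cohort)
    batch = np.array(["A"] * n + ["B"] * n)
    logX[n:] += shift
    cov = np.column_stack([cohort.labels, cohort.age, cohort.sex_male]).astype(float)
    return logX, batch, cov


def test_single_batch_is_identity_and_unshrunk(rng):
    logX = rng.normal(-3, 0.2, size=(40, 24))
    m = g.fit_batch_model(logX, ["A"] * 40)
    assert np.allclose(m.gamma_star, m.gamma_hat)
    assert np.allclose(m.delta2_star, m.delta2_hat)
    out = np.log(g.apply_batch_correction(logX, m, ["A"] * 40))
    assert np.allclose(out, logX, atol=1e-6)


def test_identical_batches_give_null_effects(rng):
    block = rng.normal(-3, 0.2, size=(30, 24))
    logX = np.vstack([block, block])
    batch = ["A"] * 30 + ["B"] * 30
    m = g.fit_batch_model(logX, batch)
    assert np.abs(m.gamma_star).max() < 1e-8
    assert np.abs(m.delta2_star - 1).max() < 1e-8


def test_injected_shift_recovered_and_removed():
    logX, batch, cov = _inject_scenario(seed=2)
    m = g.fit_batch_model(logX, batch, cov)
    contrast = np.mean(m.batch_shift_log("B") - m.batch_shift_log("A"))
    assert contrast == pytest.approx(0.5, abs=0.05)
    corrected = np.log(g.apply_batch_correction(logX, m, batch, cov))
    gaps = np.abs(corrected[batch == "B"].mean(0) - corrected[batch == "A"].mean(0))
    assert gaps.max() < 0.02
    assert corrected.shape == logX.shape


def test_correction_idempotent_and_mean_preserving(rng):
    """Idempotence and pooled-mean preservation under an intercept-only design.

    Without EB shrinkage the pooled per-feature mean would be preserved
    exactly (the weighted batch means of the standardised data are zero by
    construction); the parametric shrinkage perturbs it at the 1e-4 level,
    so the exact 1e-6 bound is asserted on the shrinkage-free degenerate
    case (identical batches) below and a 1e-3 bound here.
    """
    logX, batch, _ = _inject_scenario(seed=5)
    m = g.fit_batch_model(logX, batch)  # intercept-only design
    once = np.log(g.apply_batch_correction(logX, m, batch))
    assert np.allclose(once.mean(axis=0), logX.mean(axis=0), atol=1e-3)
    m2 = g.fit_batch_model(once, batch)
    twice = np.log(g.apply_batch_correction(once, m2, batch))
    gaps = np.abs(twice[batch == "B"].mean(0) - once[batch == "B"].mean(0))
    assert gaps.max() < 1e-3


def test_mean_preserved_exactly_without_shrinkage(rng):
    block = rng.normal(-3, 0.2, size=(30, 24))
    logX = np.vstack([block, block])
    batch = ["A"] * 30 + ["B"] * 30
    m = g.fit_batch_model(logX, batch)
    once = np.log(g.apply_batch_correction(logX, m, batch))
    assert np.allclose(once.mean(axis=0), logX.mean(axis=0), atol=1e-6)


def test_batch_model_errors(rng):
    logX = rng.normal(size=(5, 24))
    with pytest.raises(ValueError, match="< 2 samples"):
        g.fit_batch_model(logX, ["A"] * 4 + ["B"])
    with pytest.raises(ValueError, match="non-finite"):
        g.fit_batch_model(logX * np.nan, ["A", "A", "A", "B", "B"])
    m = g.fit_batch_model(logX, ["A", "A", "A", "B", "B"])
    with pytest.raises(ValueError, match="feature count"):
        g.apply_batch_correction(logX[:, :10], m, ["A"] * 5)


def test_agrees_with_scanpy_combat():
    scanpy = pytest.importorskip("scanpy")
    anndata = pytest.importorskip("anndata")
    import pandas as pd

    sp = replace(matched_spec(100), year_shifts={"A": 0.0, "B": 0.3},
                 plate_shifts={"P": 0.0})
    cohort, _ = generate_cohort(sp, seed=4)
    logX = g.log_transform_gps(cohort)
    batch = cohort.table["year"].to_numpy()
    cov = np.column_stack([cohort.labels, cohort.age, cohort.sex_male]).astype(float)
    mine = np.log(g.apply_batch_correction(
        logX, g.fit_batch_model(logX, batch, cov), batch, cov))
    A = anndata.AnnData(logX.copy(), obs=pd.DataFrame({
        "batch": pd.Categorical(batch), "label": cohort.labels.astype(float),
        "age": cohort.age.astype(float), "sex": cohort.sex_male.astype(float)}))
    theirs = scanpy.pp.combat(A, key="batch",
                              covariates=["label", "age", "sex"], inplace=False)
    assert np.abs(mine - np.asarray(theirs)).max() < 0.02


# ---------------------------------------------------------------------------
# over-60 filter
# ---------------------------------------------------------------------------

def test_filter_keeps_age_60_inclusive(rng):
    ages = [55, 60, 61, 70, 59, 58, 62, 60]
    labels = ["case", "control"] * 4
    cohort = g.GlycomicsCohort(make_cohort_frame(8, rng, ages=ages, labels=labels))
    out = g.filter_non_augmented(cohort)
    assert sorted(out.age) == [55, 58, 59, 60, 60]
    # all retained already -> identity
    assert len(g.filter_non_augmented(out)) == len(out)


def test_filter_count_matches_independent_count():
    cohort, _ = generate_cohort(g.GeneratorSpec(n_cases=300, n_controls=150), seed=3)
    out = g.filter_non_augmented(cohort)
    assert len(out) == int((cohort.age <= 60).sum())


def test_filter_requires_both_classes(rng):
    cohort = g.GlycomicsCohort(make_cohort_frame(
        6, rng, ages=[70, 70, 70, 50, 50, 50],
        labels=["case"] * 3 + ["control"] * 3))
    with pytest.raises(ValueError, match="2 samples per class"):
        g.filter_non_augmented(cohort)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def test_mwu_worked_example_and_symmetry():
    u, p = g.mann_whitney_u([1, 2], [3, 4])
    assert u == 0
    assert p == pytest.approx(1 / 3)
    _, p_same = g.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p_same == pytest.approx(1.0)


def test_mwu_exact_equals_full_permutation(rng):
    for _ in range(25):
        na = int(rng.integers(2, 5))
        nb = int(rng.integers(2, 9 - na))
        pool = rng.permutation(20)[: na + nb].astype(float)  # distinct values
        a, b = pool[:na], pool[na:]
        _, p = g.mann_whitney_u(a, b)
        assert p == pytest.approx(mwu_permutation_p(a, b), abs=1e-12)


def test_mwu_detects_shift_against_permutation_oracle(rng):
    a = np.arange(1, 21, dtype=float)
    b = rng.permutation(a + 10)
    _, p = g.mann_whitney_u(a, b)
    assert p < 0.01
    # permutation oracle (Monte-Carlo) agrees the shift is significant
    pooled = np.concatenate([a, b])
    obs = a.mean() - b.mean()
    perm = np.array([
        (lambda s: s[:20].mean() - s[20:].mean())(rng.permutation(pooled))
        for _ in range(10_000)])
    assert np.mean(np.abs(perm) >= abs(obs)) < 0.01


def test_mwu_constant_data_warns_p1():
    with pytest.warns(UserWarning, match="constant"):
        _, p = g.mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
    assert p == 1.0


@pytest.mark.parametrize("table, expected", [
    ([[2, 0], [0, 2]], 1 / 3),
    ([[1, 1], [1, 1]], 1.0),
])
def test_fisher_worked_examples(table, expected):
    assert g.fisher_exact(table) == pytest.approx(expected)


def test_fisher_equals_hypergeometric_enumeration(rng):
    assert g.fisher_exact([[10, 0], [0, 10]]) < 1e-4
    for _ in range(30):
        t = rng.integers(0, 12, size=(2, 2))
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            continue
        assert g.fisher_exact(t) == pytest.approx(
            fisher_enumeration_p(t), rel=1e-6)


def test_fisher_zero_margin_warns():
    with pytest.warns(UserWarning, match="zero margin"):
        assert g.fisher_exact([[0, 0], [3, 4]]) == 1.0


def test_bh_worked_examples():
    assert g.benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx(
        [0.03, 0.03, 0.03])
    assert g.benjamini_hochberg([0.2]) == pytest.approx([0.2])
    with pytest.raises(ValueError):
        g.benjamini_hochberg([0.5, 1.2])


def test_bh_equals_stepup_definition_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(40):
        p = rng.uniform(size=int(rng.integers(1, 11)))
        q = g.benjamini_hochberg(p)
        assert q == pytest.approx(bh_stepup(p), abs=1e-12)
        assert q == pytest.approx(
            multipletests(p, method="fdr_bh")[1], abs=1e-12)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# balance report
# ---------------------------------------------------------------------------

def test_balance_report_flags_injected_age_gap():
    # the default design gives cases a much larger old-age fraction
    sp = g.GeneratorSpec(n_cases=100, n_controls=100, case_old_frac=0.5)
    cohort, _ = generate_cohort(sp, seed=8)
    rep = g.balance_report(cohort)
    assert bool(rep.loc[rep.variable == "age", "significant"].iloc[0])
    assert (rep["q_value"] >= rep["p_value"] - 1e-15).all()


def test_balance_report_clean_on_matched_cohort():
    cohort, _ = generate_cohort(matched_spec(150), seed=0)
    rep = g.balance_report(cohort)
    assert not rep["significant"].any()
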