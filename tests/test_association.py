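import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from snpburden._glm import fit_logistic_batch
from snpburden.association import (AssociationResult, fit_additive,
                                   fit_genotype_models, fit_polytomous,
                                   heterogeneity_test, hwe_test,
                                   interaction_lrt,
                                   permutation_adjusted_pvalues,
                                   stratified_fit, syndrome_pattern)
from snpburden.cohort import Cohort, SubjectRecord
from snpburden.genotypes import GenotypeMatrix
from snpburden.panel import SnpPanel, SnpRecord


# -- Hardy-Weinberg QC -----------------------------------------------------

def test_hwe_exact_proportions():
    stat, p, mono = hwe_test(25, 50, 25)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    assert not mono


def test_hwe_hand_computed_example():
    # minor freq 0.2 over 100 -> expected 64/32/4; chi2 = 36/64+144/32+36/4
    stat, p, mono = hwe_test(70, 20, 10)
    assert stat == pytest.approx(14.0625)
    assert not mono


def test_hwe_monomorphic_flag():
    stat, p, mono = hwe_test(100, 0, 0)
    assert mono and p == 1.0


# -- single-SNP fits vs an independent oracle ------------------------------

def _fixed_dataset(rng, n=40, beta=0.6):
    g = rng.binomial(2, 0.35, n).astype(float)
    age = rng.normal(66, 7, n)
    y = (rng.random(n) < expit(-0.3 + beta * g)).astype(float)
    idx = [f"S{i}" for i in range(n)]
    return (pd.Series(g, idx, name="rs_t"), pd.Series(y, idx),
            pd.Series(age, idx))


def _oracle_logit(y, X):
    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    def grad(b):
        return -X.T @ (y - expit(X @ b))

    return minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                    options={"gtol": 1e-12, "maxiter": 1000}).x


def test_fit_additive_matches_likelihood_oracle(rng):
    g, y, age = _fixed_dataset(rng)
    res = fit_additive(g, y, age)
    X = np.column_stack([np.ones(len(g)), g, age])
    oracle = _oracle_logit(y.to_numpy(), X)
    assert res.converged
    assert res.beta == pytest.approx(oracle[1], abs=1e-6)


def test_genotype_models_match_likelihood_oracle(rng):
    g, y, age = _fixed_dataset(rng, n=120)
    out = fit_genotype_models(g, y, age)
    n = len(g)
    X_dom = np.column_stack([np.ones(n), (g >= 1).astype(float), age])
    assert out["dominant"].beta == pytest.approx(
        _oracle_logit(y.to_numpy(), X_dom)[1], abs=1e-6)
    X_cod = np.column_stack([np.ones(n), (g == 1).astype(float),
                             (g == 2).astype(float), age])
    oracle = _oracle_logit(y.to_numpy(), X_cod)
    assert out["codominant_het"].beta == pytest.approx(oracle[1], abs=1e-6)
    assert out["codominant_hom"].beta == pytest.approx(oracle[2], abs=1e-6)


def test_dominant_approximates_codominant_when_effects_equal(rng):
    # construct equal heterozygote and homozygote effects
    n = 4000
    g = rng.binomial(2, 0.4, n).astype(float)
    age = rng.normal(66, 7, n)
    y = (rng.random(n) < expit(-0.5 + 0.7 * (g >= 1))).astype(float)
    idx = pd.RangeIndex(n)
    out = fit_genotype_models(pd.Series(g, idx), pd.Series(y, idx),
                              pd.Series(age, idx))
    assert out["dominant"].or_value == pytest.approx(
        out["codominant_het"].or_value, rel=0.15)


def test_recessive_without_homozygotes_is_flagged(rng):
    n = 60
    g = rng.integers(0, 2, n).astype(float)  # only 0/1
    age = rng.normal(66, 7, n)
    y = rng.integers(0, 2, n).astype(float)
    idx = pd.RangeIndex(n)
    out = fit_genotype_models(pd.Series(g, idx), pd.Series(y, idx),
                              pd.Series(age, idx))
    assert not out["recessive"].converged
    assert "homozygot" in out["recessive"].note
    assert not out["codominant_het"].converged  # downgraded with flag


def test_codominant_loglik_dominates_additive(assoc_results, small_study):
    """The additive coding is nested in the codominant coding."""
    panel, matrix, cohort = small_study
    status = cohort.status_series().loc[matrix.subject_ids]
    age = cohort.age_series().loc[matrix.subject_ids]
    checked = 0
    for sid in matrix.snp_ids[:8]:
        add = fit_additive(matrix.dosages(sid), status, age, snp_id=sid)
        cod = fit_genotype_models(matrix.dosages(sid), status, age,
                                  snp_id=sid)["codominant_het"]
        if add.converged and cod.converged:
            assert cod.loglik >= add.loglik - 1e-8
            checked += 1
    assert checked >= 5


def test_fits_invariant_to_row_order(small_study, rng):
    panel, matrix, cohort = small_study
    status = cohort.status_series().loc[matrix.subject_ids]
    age = cohort.age_series().loc[matrix.subject_ids]
    sid = "rs6983267"
    base = fit_additive(matrix.dosages(sid), status, age)
    shuffled = list(rng.permutation(matrix.subject_ids))
    perm = fit_additive(matrix.dosages(sid).loc[shuffled],
                        status.loc[shuffled], age.loc[shuffled])
    assert perm.beta == pytest.approx(base.beta, abs=1e-9)
    assert perm.p == pytest.approx(base.p, abs=1e-9)


def test_insufficient_data_flagged():
    idx = ["a", "b", "c"]
    res = fit_additive(pd.Series([0, 1, 2], idx), pd.Series([0, 1, 0], idx),
                       pd.Series([60, 61, 62], idx))
    assert not res.converged and "insufficient" in res.note


# -- permutation multiplicity ----------------------------------------------

def _null_study(rng, n=150, n_snps=12):
    panel = SnpPanel([
        SnpRecord(f"rs{i:03d}", f"{1 + i % 22}q11", "A", "G",
                  0.1 + 0.03 * (i % 10))
        for i in range(n_snps)
    ])
    from snpburden.simulate import simulate_genotypes
    mat = simulate_genotypes(panel, n, seed=int(rng.integers(2**31)))
    status = rng.permutation(np.repeat([0, 1], n // 2))
    cohort = Cohort([
        SubjectRecord(subject_id=s, status="case" if st else "control",
                      age=float(a))
        for s, st, a in zip(mat.subject_ids, status, rng.normal(66, 8, n))
    ])
    return mat, cohort


def test_adjusted_p_strictly_positive_and_bounded(rng):
    mat, cohort = _null_study(rng)
    res = permutation_adjusted_pvalues(mat, cohort, n_perm=99, seed=1)
    assert np.all(res.adjusted_p > 0)
    assert np.all(res.adjusted_p <= 1)
    assert res.adjusted_p.min() >= 1 / 100  # +1 convention floor


def test_plus_one_convention_floor(rng):
    """An overwhelmingly associated SNP attains exactly 1/(B+1)."""
    n = 400
    g = np.repeat([0.0, 2.0], n // 2)
    status = (g > 0).astype(int) * 0  # build status strongly tied to g
    p_case = np.where(g > 0, 0.95, 0.05)
    status = (rng.random(n) < p_case).astype(int)
    panel = SnpPanel([SnpRecord("rs_strong", "1q11", "A", "G", 0.5)])
    mat = GenotypeMatrix(pd.DataFrame(
        {"rs_strong": g}, index=[f"S{i}" for i in range(n)]), panel)
    cohort = Cohort([
        SubjectRecord(subject_id=f"S{i}", status="case" if s else "control",
                      age=float(a))
        for i, (s, a) in enumerate(zip(status, rng.normal(66, 8, n)))
    ])
    res = permutation_adjusted_pvalues(mat, cohort, n_perm=99, seed=2)
    assert res.adjusted_p[0] == pytest.approx(1 / 100)


def test_permutation_requires_minimum_b(rng):
    mat, cohort = _null_study(rng)
    with pytest.raises(ValueError, match="99"):
        permutation_adjusted_pvalues(mat, cohort, n_perm=10, seed=1)


# -- polytomous subtype fits -----------------------------------------------

def _subtype_data(rng, n=500, beta_na=0.0, beta_ag=0.4):
    g = rng.binomial(2, 0.3, n).astype(float)
    age = rng.normal(66, 7, n)
    denom = 1 + np.exp(-1.0 + beta_na * g) + np.exp(-1.2 + beta_ag * g)
    u = rng.random(n)
    p_na = np.exp(-1.0 + beta_na * g) / denom
    p_ag = np.exp(-1.2 + beta_ag * g) / denom
    k = np.where(u < p_na, "non_aggressive",
                 np.where(u < p_na + p_ag, "aggressive", "control"))
    idx = [f"S{i}" for i in range(n)]
    return (pd.Series(g, idx, name="rs_t"), pd.Series(k, idx),
            pd.Series(age, idx))


def _oracle_multinomial(g, k, age):
    """Direct maximisation of the 3-category multinomial likelihood."""
    X = np.column_stack([np.ones(len(g)), g, age])
    levels = ["control", "non_aggressive", "aggressive"]
    Y = np.column_stack([(k == lev).to_numpy(dtype=float) for lev in levels])

    def nll(theta):
        B = theta.reshape(2, 3)  # two non-reference equations
        eta = X @ B.T  # (n, 2)
        denom = np.logaddexp.reduce(
            np.column_stack([np.zeros(len(g)), eta]), axis=1)
        ll = Y[:, 1] * eta[:, 0] + Y[:, 2] * eta[:, 1] - denom
        return -ll.sum()

    res = minimize(nll, np.zeros(6), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    return res.x.reshape(2, 3)


def test_polytomous_matches_multinomial_oracle(rng):
    g, k, age = _subtype_data(rng, n=300)
    res = fit_polytomous(g, k, age)
    oracle = _oracle_multinomial(g, k, age)
    assert res.converged
    assert res.or_nonaggressive.beta == pytest.approx(oracle[0, 1], abs=1e-5)
    assert res.or_aggressive.beta == pytest.approx(oracle[1, 1], abs=1e-5)


def test_polytomous_null_ors_near_one(rng):
    g, k, age = _subtype_data(rng, n=4000, beta_na=0.0, beta_ag=0.0)
    res = fit_polytomous(g, k, age)
    assert res.or_nonaggressive.or_value == pytest.approx(1.0, abs=0.15)
    assert res.or_aggressive.or_value == pytest.approx(1.0, abs=0.15)


def test_polytomous_empty_stratum_is_error(rng):
    g, k, age = _subtype_data(rng, n=200)
    k = k.replace("aggressive", "non_aggressive")
    with pytest.raises(ValueError, match="aggressive"):
        fit_polytomous(g, k, age)


def test_heterogeneity_zero_for_identical_strata():
    same = AssociationResult("rs_t", "x", beta=0.3, or_value=np.exp(0.3),
                             ci_low=np.exp(0.3 - 0.2), ci_high=np.exp(0.3 + 0.2),
                             p=0.01, n_used=100, converged=True)
    from snpburden.association import SubtypeResult
    res = SubtypeResult("rs_t", same, same, beta_cov=0.0, n_used=100,
                        converged=True)
    assert heterogeneity_test(res) == pytest.approx(1.0)


def test_heterogeneity_null_calibration(rng):
    """Equal true stratum effects reject at roughly the nominal 5% rate."""
    rejections = 0
    n_reps = 250
    for _ in range(n_reps):
        g, k, age = _subtype_data(rng, n=450, beta_na=0.3, beta_ag=0.3)
        try:
            p = heterogeneity_test(fit_polytomous(g, k, age))
        except ValueError:
            continue
        if np.isfinite(p) and p <= 0.05:
            rejections += 1
    assert 0.015 <= rejections / n_reps <= 0.10


def test_heterogeneity_detects_divergent_effects(rng):
    g, k, age = _subtype_data(rng, n=2500, beta_na=0.0, beta_ag=0.55)
    p = heterogeneity_test(fit_polytomous(g, k, age))
    assert p < 0.01


# -- stratified and interaction analyses -----------------------------------

def test_stratified_fit_recovers_distinct_effects(rng):
    n = 4000
    stratum = rng.integers(0, 2, n)
    g = rng.binomial(2, 0.3, n).astype(float)
    age = rng.normal(66, 7, n)
    beta = np.where(stratum == 0, np.log(2.0), 0.0)
    y = (rng.random(n) < expit(-0.8 + beta * g)).astype(float)
    idx = pd.RangeIndex(n)
    out = stratified_fit(pd.Series(g, idx), pd.Series(y, idx),
                         pd.Series(age, idx), pd.Series(stratum, idx))
    assert out["0"].or_value == pytest.approx(2.0, rel=0.15)
    assert out["1"].or_value == pytest.approx(1.0, abs=0.15)


def test_thin_stratum_reported_absent(rng):
    n = 60
    stratum = np.zeros(n, dtype=int)
    stratum[0] = 1  # a single subject
    g = rng.binomial(2, 0.3, n).astype(float)
    y = rng.integers(0, 2, n).astype(float)
    idx = pd.RangeIndex(n)
    out = stratified_fit(pd.Series(g, idx), pd.Series(y, idx),
                         pd.Series(np.full(n, 66.0), idx),
                         pd.Series(stratum, idx))
    assert out["1"] is None


def test_interaction_lrt_nonnegative_and_null_calibrated(rng):
    """LRT statistic is nonnegative; null rejection rate ~ 5%."""
    rejections = 0
    n_reps = 1000
    n = 350
    for _ in range(n_reps):
        g = rng.binomial(2, 0.3, n).astype(float)
        m = rng.integers(0, 2, n).astype(float)
        age = rng.normal(66, 7, n)
        y = (rng.random(n) < expit(-0.4 + 0.3 * g + 0.2 * m)).astype(float)
        idx = pd.RangeIndex(n)
        try:
            res = interaction_lrt(pd.Series(g, idx), pd.Series(y, idx),
                                  pd.Series(age, idx), pd.Series(m, idx))
        except RuntimeError:
            continue
        assert res.lrt_stat >= 0.0
        assert res.lrt_df == 1
        if res.lrt_p <= 0.05:
            rejections += 1
    assert 0.032 <= rejections / n_reps <= 0.071


def test_interaction_lrt_detects_strong_modification(rng):
    n = 2000
    g = rng.binomial(2, 0.3, n).astype(float)
    m = rng.integers(0, 2, n).astype(float)
    age = rng.normal(66, 7, n)
    # stratum OR ratio of 2: beta 0 vs ln(2)
    y = (rng.random(n) < expit(-0.6 + np.log(2.0) * g * m)).astype(float)
    idx = pd.RangeIndex(n)
    res = interaction_lrt(pd.Series(g, idx), pd.Series(y, idx),
                          pd.Series(age, idx), pd.Series(m, idx))
    assert res.lrt_p < 0.01


def test_interaction_genotype_coding_uses_two_df(rng):
    n = 800
    g = rng.binomial(2, 0.4, n).astype(float)
    m = rng.integers(0, 2, n).astype(float)
    y = rng.integers(0, 2, n).astype(float)
    idx = pd.RangeIndex(n)
    res = interaction_lrt(pd.Series(g, idx), pd.Series(y, idx),
                          pd.Series(np.full(n, 66.0), idx),
                          pd.Series(m, idx), coding="genotype")
    assert res.lrt_df == 2


# -- syndrome-pattern classification ---------------------------------------

def _contrast(p, or_value=1.5):
    return AssociationResult("rs_t", "contrast", beta=np.log(or_value),
                             or_value=or_value, ci_low=or_value * 0.8,
                             ci_high=or_value * 1.2, p=p, n_used=100,
                             converged=True)


@pytest.mark.parametrize("pa, pb, pc, ora, orb, expected", [
    (0.01, 0.60, 0.60, 1.5, 1.5, "syndrome_like"),
    (0.01, 0.02, 0.60, 1.5, 1.45, "prca_specific"),
    (0.60, 0.60, 0.01, 1.5, 1.5, "other_cancer_linked"),
    (0.01, 0.60, 0.01, 1.5, 1.5, "other_cancer_linked"),  # C takes precedence
    (0.01, 0.02, 0.60, 2.5, 1.2, "indeterminate"),  # dissimilar ORs
    (0.60, 0.60, 0.60, 1.5, 1.5, "indeterminate"),
])
def test_syndrome_pattern_rules(pa, pb, pc, ora, orb, expected):
    out = syndrome_pattern(_contrast(pa, ora), _contrast(pb, orb),
                           _contrast(pc))
    assert out == expected


def test_syndrome_pattern_missing_contrast_is_error():
    with pytest.raises(ValueError, match="contrast"):
        syndrome_pattern(_contrast(0.01), None, _contrast(0.5))


# -- additive-fit type-I error calibration ---------------------------------

def test_additive_type_one_error_calibrated(rng):
    """Null rejection rate at alpha = 0.05 over 10,000 replicates.

    Runs through the batched Newton engine, whose equivalence to the
    statsmodels path is asserted separately to 1e-6.
    """
    R, n = 10_000, 400
    g = rng.binomial(2, 0.3, (R, n)).astype(float)
    age = rng.normal(66, 8, (R, n))
    y = (rng.random((R, n)) < 0.45).astype(float)
    X = np.empty((R, n, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = g
    X[:, :, 2] = age
    fit = fit_logistic_batch(y, X)
    p = fit.wald_p()[:, 1]
    ok = fit.converged & np.isfinite(p)
    rate = (p[ok] <= 0.05).mean()
    assert ok.mean() > 0.99
    assert 0.04 <= rate <= 0.06
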