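import numpy as np
import pandas as pd
import pytest

from snpburden.genotypes import GenotypeMatrix
from snpburden.panel import SnpPanel, SnpRecord
from snpburden.score import (DEFAULT_FORCED, QuartileCuts, RiskScoreModel,
                             ScoreDefinition, control_quartile_cuts,
                             cumulative_scores, exact_score_distribution,
                             orient_risk_alleles, quartile_association,
                             quartile_cuts_from_pmf, select_score_snps)


# -- selection and orientation ---------------------------------------------

def test_published_selection_yields_seventeen(panel):
    """15 nominally associated SNPs + 2 forced borderline = 17 (16 + 1 X)."""
    pvals = {r.snp_id: r.published_p for r in panel}
    fifteen = select_score_snps(pvals, alpha=0.05, forced=(), panel=panel)
    assert len(fifteen) == 15
    selected = select_score_snps(pvals, alpha=0.05, forced=DEFAULT_FORCED,
                                 panel=panel)
    assert len(selected) == 17
    d = ScoreDefinition.from_published(panel)
    assert d.n_autosomal == 16 and d.n_x == 1
    assert "rs5945619" in d.snp_ids
    assert selected == [s for s in panel.snp_ids if s in set(selected)]  # order


def test_selection_edge_cases(panel):
    pvals = {r.snp_id: r.published_p for r in panel}
    assert select_score_snps(pvals, alpha=0.0, forced=(), panel=panel) == []
    with pytest.raises(KeyError, match="rs000"):
        select_score_snps(pvals, alpha=0.05, forced=("rs000",), panel=panel)


def test_orientation_flip_rule():
    ors = {"a": 1.34, "b": 0.80, "c": 1.0}
    out = orient_risk_alleles(ors, ["a", "b", "c"])
    assert out == {"a": "minor", "b": "major", "c": "minor"}
    with pytest.raises(ValueError, match="rs_q"):
        orient_risk_alleles({}, ["rs_q"])


# -- per-subject scores ----------------------------------------------------

@pytest.fixture()
def tiny():
    panel = SnpPanel([
        SnpRecord("rs_a", "1q1", "A", "G", 0.3),
        SnpRecord("rs_b", "2q2", "C", "T", 0.4),
        SnpRecord("rs_x", "Xp1", "A", "G", 0.2),
    ])
    df = pd.DataFrame(
        {"rs_a": [1.0, 2.0, 0.0, np.nan],
         "rs_b": [1.0, 2.0, 2.0, 1.0],
         "rs_x": [1.0, 0.0, 1.0, 1.0]},
        index=["S1", "S2", "S3", "S4"],
    )
    return panel, GenotypeMatrix(df, panel)


def test_cumulative_scores_orientation_and_exclusion(tiny):
    panel, mat = tiny
    d = ScoreDefinition.build(panel, ["rs_a", "rs_b", "rs_x"],
                              {"rs_a": "minor", "rs_b": "major",
                               "rs_x": "minor"})
    vec = cumulative_scores(mat, d, panel=panel)
    # S1: 1 + (2-1) + 1 = 3; S2: 2 + 0 + 0 = 2 (dosage 2 at major-risk -> 0)
    assert vec.complete().loc["S1"] == 3
    assert vec.complete().loc["S2"] == 2
    # S4 missing rs_a -> excluded
    assert bool(vec.excluded.loc["S4"])
    assert pd.isna(vec.scores.loc["S4"])
    assert d.max_score == 2 * 2 + 1


def test_scores_invariant_to_snp_order(tiny):
    panel, mat = tiny
    ori = {"rs_a": "minor", "rs_b": "minor", "rs_x": "minor"}
    d1 = ScoreDefinition.build(panel, ["rs_a", "rs_b", "rs_x"], ori)
    d2 = ScoreDefinition.build(panel, ["rs_x", "rs_a", "rs_b"], ori)
    v1 = cumulative_scores(mat, d1, panel=panel).scores
    v2 = cumulative_scores(mat, d2, panel=panel).scores
    assert v1.equals(v2)


def test_orientation_flip_conservation(tiny):
    """Flipping one autosomal SNP changes the contribution to 2 - dosage."""
    panel, mat = tiny
    base = {"rs_a": "minor", "rs_b": "minor", "rs_x": "minor"}
    flip = dict(base, rs_a="major")
    d1 = ScoreDefinition.build(panel, ["rs_a", "rs_b", "rs_x"], base)
    d2 = ScoreDefinition.build(panel, ["rs_a", "rs_b", "rs_x"], flip)
    s1 = cumulative_scores(mat, d1, panel=panel).complete()
    s2 = cumulative_scores(mat, d2, panel=panel).complete()
    g = mat.data["rs_a"].dropna()
    for sid in s1.index:
        assert (s2[sid] - s1[sid]) == 2 - 2 * g[sid]


def test_expected_dosage_imputation_keeps_everyone(tiny):
    panel, mat = tiny
    d = ScoreDefinition.build(panel, ["rs_a", "rs_b"],
                              {"rs_a": "minor", "rs_b": "minor"})
    vec = cumulative_scores(mat, d, impute_expected=True, panel=panel)
    assert not vec.excluded.any()
    assert vec.scores.loc["S4"] == pytest.approx(1 + 2 * 0.3)


# -- quartile cuts ---------------------------------------------------------

def test_uniform_scores_cut_into_equal_quartiles():
    scores = pd.Series(np.repeat(np.arange(1, 9), 10))
    cuts = control_quartile_cuts(scores)
    assert cuts.as_tuple() == (2, 4, 6)


def test_exact_convolution_reproduces_study_bins(panel):
    """Cutting the theoretical control distribution gives 13/15/17."""
    d = ScoreDefinition.from_published(panel)
    dist = exact_score_distribution(d, d.risk_frequencies(panel), panel=panel)
    cuts = quartile_cuts_from_pmf(dist.values, dist.pmf)
    assert cuts.as_tuple() == (13, 15, 17)


def test_degenerate_distributions_rejected():
    with pytest.raises(ValueError, match="8"):
        control_quartile_cuts(pd.Series([5, 5, 5]))
    with pytest.raises(ValueError, match="distinct"):
        control_quartile_cuts(pd.Series([5] * 20))
    with pytest.raises(ValueError):
        QuartileCuts(3, 2, 1)


# -- quartile association --------------------------------------------------

def test_null_quartile_ors_near_one():
    rng = np.random.default_rng(0)
    n = 6000
    scores = pd.Series(rng.integers(8, 25, n), index=pd.RangeIndex(n))
    status = pd.Series(rng.integers(0, 2, n), index=scores.index)
    age = pd.Series(rng.normal(66, 8, n), index=scores.index)
    cuts = control_quartile_cuts(scores[status == 0])
    qa = quartile_association(scores, cuts, status, age)
    for r in qa.per_quartile:
        assert r.converged
        assert r.or_value == pytest.approx(1.0, abs=0.2)
    assert qa.trend_p > 0.01


def test_trend_p_shrinks_with_sample_size(rng):
    def trend_at(n):
        scores = pd.Series(rng.integers(8, 25, n), index=pd.RangeIndex(n))
        age = pd.Series(rng.normal(66, 8, n), index=scores.index)
        p_case = 1 / (1 + np.exp(-(-2.0 + 0.12 * scores)))
        status = pd.Series((rng.random(n) < p_case).astype(int),
                           index=scores.index)
        cuts = control_quartile_cuts(scores[status == 0])
        return quartile_association(scores, cuts, status, age).trend_p

    assert trend_at(4000) < trend_at(400) * 1.5  # monotone up to MC noise


# -- exact score distribution ----------------------------------------------

def test_single_snp_pmf():
    panel = SnpPanel([SnpRecord("rs_a", "1q1", "A", "G", 0.5)])
    d = ScoreDefinition.build(panel, ["rs_a"], {"rs_a": "minor"})
    dist = exact_score_distribution(d, {"rs_a": 0.5}, panel=panel)
    np.testing.assert_allclose(dist.pmf, [0.25, 0.5, 0.25])


def test_two_snp_pmf_matches_enumeration():
    panel = SnpPanel([SnpRecord("rs_a", "1q1", "A", "G", 0.5),
                      SnpRecord("rs_b", "2q1", "C", "T", 0.5)])
    d = ScoreDefinition.build(panel, ["rs_a", "rs_b"],
                              {"rs_a": "minor", "rs_b": "minor"})
    dist = exact_score_distribution(d, {"rs_a": 0.5, "rs_b": 0.5},
                                    panel=panel)
    np.testing.assert_allclose(dist.pmf, np.array([1, 4, 6, 4, 1]) / 16)


def test_pmf_moments_match_analytic(panel):
    d = ScoreDefinition.from_published(panel)
    dist = exact_score_distribution(d, d.risk_frequencies(panel), panel=panel)
    assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-12)
    assert (dist.values * dist.pmf).sum() == pytest.approx(dist.mean,
                                                           abs=1e-9)
    var_pmf = (dist.values**2 * dist.pmf).sum() - dist.mean**2
    assert var_pmf == pytest.approx(dist.variance, abs=1e-9)


# -- model orchestration ---------------------------------------------------

def test_risk_score_model_from_association(assoc_results):
    model = RiskScoreModel.from_association(assoc_results, alpha=0.05,
                                            forced=())
    res = model.fit()
    ss = res.score_summary()
    assert ss["n_cases"] + ss["n_controls"] + ss["n_excluded"] == \
        len(assoc_results.model.matrix.subject_ids)
    # cases carry more risk alleles on average in this non-null simulation
    assert ss["mean_cases"] > ss["mean_controls"]
    assert "quartile cuts" in res.summary()
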