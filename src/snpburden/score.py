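"""Cumulative risk-allele score: selection, orientation, quartiles, theory.

The score is the unweighted count of risk alleles over a selected SNP set:
SNPs associated at a nominal p-threshold plus any forced-in borderline
SNPs, with the *major* allele taken as the risk allele for SNPs inversely
associated with disease (OR < 1).  Autosomal SNPs contribute 0-2 alleles,
the hemizygous X SNP 0-1.  Subjects missing any selected genotype carry no
score (strict complete case; an expected-dosage fill-in from control
frequencies is available but off by default).

Quartile categories are cut on the *control* score distribution: integer
cutpoints minimising the maximum deviation of the four control bin
proportions from 25%, ties broken toward equal outer bins.  The exact
score distribution under HWE — a sequential convolution of Binomial(2, f)
and Bernoulli(f) terms — serves as a closed-form oracle for the empirical
distribution and the cutpoint rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .association import AssociationResult, _logit, _result_from_fit
from .genotypes import GenotypeMatrix
from .panel import SnpPanel

__all__ = [
    "ScoreDefinition",
    "ScoreVector",
    "QuartileCuts",
    "ScoreDistribution",
    "select_score_snps",
    "orient_risk_alleles",
    "cumulative_scores",
    "control_quartile_cuts",
    "quartile_cuts_from_pmf",
    "assign_quartiles",
    "quartile_association",
    "exact_score_distribution",
    "RiskScoreModel",
    "RiskScoreResults",
]

_Z975 = norm.ppf(0.975)

#: Borderline SNPs forced into the default score definition (nominal p just
#: above 0.05 in the packaged panel: 0.055 and 0.057).
DEFAULT_FORCED = ("rs2660753", "rs7679673")


# --------------------------------------------------------------------------
# definition


@dataclass(frozen=True)
class ScoreDefinition:
    """Which SNPs enter the score and which allele counts as risk."""

    snp_ids: tuple[str, ...]
    orientation: Mapping[str, str]  # snp_id -> "minor" | "major"
    n_autosomal: int
    n_x: int

    def __post_init__(self) -> None:
        if self.n_autosomal + self.n_x != len(self.snp_ids):
            raise ValueError("n_autosomal + n_x must equal number of SNPs")
        missing = [s for s in self.snp_ids if s not in self.orientation]
        if missing:
            raise ValueError(f"orientation undefined for {missing}")

    @property
    def max_score(self) -> int:
        return 2 * self.n_autosomal + self.n_x

    @classmethod
    def build(cls, panel: SnpPanel, snp_ids: Sequence[str],
              orientation: Mapping[str, str]) -> "ScoreDefinition":
        sub = panel.subset(snp_ids)
        return cls(
            snp_ids=tuple(sub.snp_ids),
            orientation={s: orientation[s] for s in sub.snp_ids},
            n_autosomal=len(sub.autosomal_ids),
            n_x=len(sub.x_ids),
        )

    @classmethod
    def from_published(cls, panel: SnpPanel, alpha: float = 0.05,
                       forced: Sequence[str] = DEFAULT_FORCED,
                       ) -> "ScoreDefinition":
        """Definition from the panel's published p-values and ORs."""
        pvals = {r.snp_id: r.published_p for r in panel}
        ors = {r.snp_id: r.published_or for r in panel}
        selected = select_score_snps(pvals, alpha=alpha, forced=forced,
                                     panel=panel)
        orientation = orient_risk_alleles(ors, selected)
        return cls.build(panel, selected, orientation)

    def risk_frequencies(self, panel: SnpPanel) -> dict[str, float]:
        """Control frequency of the risk allele per selected SNP."""
        out = {}
        for sid in self.snp_ids:
            maf = panel[sid].control_maf
            out[sid] = maf if self.orientation[sid] == "minor" else 1.0 - maf
        return out


def select_score_snps(pvalues: Mapping[str, float | None], alpha: float,
                      forced: Sequence[str], panel: SnpPanel) -> list[str]:
    """Union of {p <= alpha} and the forced list, in panel order."""
    for sid in forced:
        if sid not in panel:
            raise KeyError(f"forced SNP {sid!r} not in panel")
    forced_set = set(forced)
    out = []
    for sid in panel.snp_ids:
        p = pvalues.get(sid)
        if sid in forced_set or (p is not None and p <= alpha):
            out.append(sid)
    return out


def orient_risk_alleles(ors: Mapping[str, float | None],
                        selected: Sequence[str]) -> dict[str, str]:
    """OR >= 1 -> minor allele is risk; OR < 1 -> major allele is risk."""
    out = {}
    for sid in selected:
        or_val = ors.get(sid)
        if or_val is None or not np.isfinite(or_val):
            raise ValueError(f"no odds ratio available for {sid}")
        out[sid] = "minor" if or_val >= 1.0 else "major"
    return out


# --------------------------------------------------------------------------
# per-subject scores


@dataclass
class ScoreVector:
    """Integer score per subject; excluded subjects carry no score."""

    scores: pd.Series      # Int64, NA for excluded subjects
    excluded: pd.Series    # bool, True where any selected SNP was missing
    definition: ScoreDefinition

    def complete(self) -> pd.Series:
        return self.scores.dropna().astype(int)


def cumulative_scores(matrix: GenotypeMatrix, definition: ScoreDefinition,
                      impute_expected: bool = False,
                      panel: SnpPanel | None = None) -> ScoreVector:
    """Sum risk-allele counts over the selected SNPs for every subject.

    The risk count at an autosomal SNP is the dosage itself when the minor
    allele is the risk allele and ``2 - dosage`` otherwise (``1 - dosage``
    on X).  By default subjects missing any selected genotype are excluded;
    ``impute_expected=True`` instead fills missing risk counts with their
    control-frequency expectation (2f or f) — a documented alternative, off
    by default.
    """
    missing_cols = [s for s in definition.snp_ids if s not in matrix.snp_ids]
    if missing_cols:
        raise KeyError(f"selected SNP(s) absent from matrix: {missing_cols}")
    panel = panel if panel is not None else matrix.panel
    x_ids = set(panel.x_ids) if panel is not None else set()
    contrib = {}
    for sid in definition.snp_ids:
        g = matrix.data[sid]
        ploidy = 1.0 if sid in x_ids else 2.0
        if definition.orientation[sid] == "minor":
            r = g
        else:
            r = ploidy - g
        if impute_expected:
            if panel is None:
                raise ValueError("expected-dosage imputation needs a panel")
            f_risk = definition.risk_frequencies(panel)[sid]
            r = r.fillna(ploidy * f_risk)
        contrib[sid] = r
    rc = pd.DataFrame(contrib, index=matrix.data.index)
    excluded = rc.isna().any(axis=1)
    total = rc.sum(axis=1)
    total[excluded] = np.nan
    scores = total.round().astype("Int64") if not impute_expected else total
    if impute_expected:
        scores = total  # fractional scores allowed under imputation
        excluded = pd.Series(False, index=rc.index)
    return ScoreVector(scores=scores, excluded=excluded, definition=definition)


# --------------------------------------------------------------------------
# control-based quartiles


@dataclass(frozen=True)
class QuartileCuts:
    """Integer cutpoints; bins are S<=c1, c1<S<=c2, c2<S<=c3, S>c3."""

    c1: int
    c2: int
    c3: int

    def __post_init__(self) -> None:
        if not self.c1 <= self.c2 <= self.c3:
            raise ValueError("cutpoints must be non-decreasing")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.c1, self.c2, self.c3)

    def labels(self, lo: int, hi: int) -> list[str]:
        return [f"{lo}-{self.c1}", f"{self.c1 + 1}-{self.c2}",
                f"{self.c2 + 1}-{self.c3}", f"{self.c3 + 1}-{hi}"]


def quartile_cuts_from_pmf(values: Sequence[int],
                           probs: Sequence[float]) -> QuartileCuts:
    """Integer cutpoints minimising max |bin probability - 1/4|.

    Works on any discrete distribution (empirical or exact).  Ties are
    broken by preferring more equal outer bins (|p1 - p4|), then more
    equal inner bins, then lexicographically smallest cuts.
    """
    values = np.asarray(values)
    probs = np.asarray(probs, dtype=float)
    keep = probs > 0
    support = values[keep]
    if len(np.unique(support)) < 4:
        raise ValueError("need at least 4 distinct score values for quartiles")
    cdf_vals = np.sort(np.unique(values))
    cdf = np.array([probs[values <= v].sum() for v in cdf_vals])

    def cum(v: int) -> float:
        idx = np.searchsorted(cdf_vals, v, side="right") - 1
        return 0.0 if idx < 0 else float(cdf[idx])

    candidates = [int(v) for v in cdf_vals[:-1]]
    best: tuple | None = None
    best_cuts: tuple[int, int, int] | None = None
    for c1, c2, c3 in combinations(candidates, 3):
        p1 = cum(c1)
        p2 = cum(c2) - p1
        p3 = cum(c3) - cum(c2)
        p4 = 1.0 - cum(c3)
        if min(p1, p2, p3, p4) <= 0.0:
            continue
        bins = (p1, p2, p3, p4)
        key = (max(abs(b - 0.25) for b in bins), abs(p1 - p4), abs(p2 - p3),
               (c1, c2, c3))
        if best is None or key < best:
            best = key
            best_cuts = (c1, c2, c3)
    if best_cuts is None:
        raise ValueError("no valid cutpoints (degenerate distribution)")
    return QuartileCuts(*best_cuts)


def control_quartile_cuts(control_scores: pd.Series | Sequence[int]) -> QuartileCuts:
    """Cutpoints from the empirical control score distribution.

    Requires at least 8 control scores and 4 distinct values; every control
    bin is guaranteed non-empty by construction.
    """
    s = pd.Series(control_scores).dropna().astype(int)
    if len(s) < 8:
        raise ValueError("need at least 8 control scores")
    counts = s.value_counts().sort_index()
    return quartile_cuts_from_pmf(counts.index.to_numpy(),
                                  counts.to_numpy() / counts.sum())


def assign_quartiles(scores: pd.Series, cuts: QuartileCuts) -> pd.Series:
    """Quartile index 1-4 per subject (NA propagates)."""
    s = scores.astype("Float64")
    q = pd.Series(pd.NA, index=s.index, dtype="Int64")
    q[s <= cuts.c1] = 1
    q[(s > cuts.c1) & (s <= cuts.c2)] = 2
    q[(s > cuts.c2) & (s <= cuts.c3)] = 3
    q[s > cuts.c3] = 4
    return q


# --------------------------------------------------------------------------
# quartile association and trend


@dataclass
class QuartileAssociation:
    """Age-adjusted quartile ORs (Q1 reference) plus an ordinal trend p."""

    per_quartile: list[AssociationResult]  # Q2, Q3, Q4 vs Q1
    trend_p: float
    counts: pd.DataFrame  # quartile × status counts


def quartile_association(scores: pd.Series, cuts: QuartileCuts,
                         status: pd.Series, age: pd.Series,
                         ) -> QuartileAssociation:
    """Logistic fit of status on quartile indicators + age, Q1 reference.

    The trend p comes from a separate fit using the quartile index 0-3 as
    a single ordinal term.  An empty quartile × status cell yields a
    flagged (non-converged) estimate for that quartile, never a crash.
    """
    q = assign_quartiles(scores, cuts)
    df = pd.concat([q.rename("q"), status.rename("y"), age.rename("age")],
                   axis=1, join="inner").dropna()
    counts = pd.crosstab(df["q"], df["y"])
    if 1 not in counts.index or counts.loc[1].min() == 0:
        raise ValueError("reference quartile Q1 must contain both statuses")
    n = len(df)
    y = df["y"].to_numpy(dtype=float)
    age_v = df["age"].to_numpy(dtype=float)
    qv = df["q"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), (qv == 2).astype(float),
                         (qv == 3).astype(float), (qv == 4).astype(float),
                         age_v])
    res, conv = _logit(y, X)
    per_q = []
    for k, term in ((2, 1), (3, 2), (4, 3)):
        empty = k not in counts.index or counts.loc[k].min() == 0
        r = _result_from_fit(res, conv and not empty, "score", f"Q{k}_vs_Q1",
                             term, n,
                             note="empty quartile-status cell" if empty else "")
        per_q.append(r)
    Xt = np.column_stack([np.ones(n), qv - 1.0, age_v])
    res_t, conv_t = _logit(y, Xt)
    if conv_t:
        se = float(res_t.bse[1])
        trend_p = float(2 * norm.sf(abs(float(res_t.params[1]) / se)))
    else:
        trend_p = float("nan")
    return QuartileAssociation(per_quartile=per_q, trend_p=trend_p,
                               counts=counts)


def quartile_association_subtypes(scores: pd.Series, cuts: QuartileCuts,
                                  subtype: pd.Series, age: pd.Series,
                                  ) -> dict[str, QuartileAssociation]:
    """Polytomous variant: each case stratum against the same controls."""
    out = {}
    for stratum in ("non_aggressive", "aggressive"):
        keep = subtype.isin(["control", stratum])
        y = (subtype[keep] == stratum).astype(int)
        out[stratum] = quartile_association(scores.loc[scores.index.intersection(y.index)],
                                            cuts, y, age.loc[age.index.intersection(y.index)])
    return out


# --------------------------------------------------------------------------
# exact score distribution (theory oracle)


@dataclass
class ScoreDistribution:
    """Exact pmf of the cumulative risk-allele count under HWE."""

    values: np.ndarray
    pmf: np.ndarray
    mean: float
    variance: float

    def median(self) -> int:
        cdf = np.cumsum(self.pmf)
        return int(self.values[np.searchsorted(cdf, 0.5)])

    def sample_tv_distance(self, sample: Sequence[int]) -> float:
        """Total-variation distance between a sample and the exact pmf."""
        s = pd.Series(sample).value_counts(normalize=True)
        emp = np.array([s.get(v, 0.0) for v in self.values])
        extra = 1.0 - emp.sum()  # sample mass outside the support
        return 0.5 * (np.abs(emp - self.pmf).sum() + abs(extra))


def exact_score_distribution(definition: ScoreDefinition,
                             risk_frequencies: Mapping[str, float],
                             panel: SnpPanel | None = None,
                             ) -> ScoreDistribution:
    """Sequential convolution of per-SNP risk-allele count distributions.

    Autosomal SNPs contribute Binomial(2, f) terms with pmf
    ((1-f)^2, 2f(1-f), f^2); the X SNP contributes Bernoulli(f).  The
    analytic mean (sum of 2f autosomal + f on X) and variance must equal
    the pmf moments; both are returned.
    """
    pmf = np.array([1.0])
    mean = 0.0
    var = 0.0
    for sid in definition.snp_ids:
        f = float(risk_frequencies[sid])
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{sid}: risk frequency {f} outside [0, 1]")
        is_x = panel is not None and sid in set(panel.x_ids)
        if panel is None:
            # infer ploidy from the definition counts: X SNPs are the ones
            # beyond the autosomal tally; callers should pass a panel when
            # the SNP mix is ambiguous.
            is_x = False
        if is_x:
            term = np.array([1.0 - f, f])
            mean += f
            var += f * (1.0 - f)
        else:
            term = np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f ** 2])
            mean += 2.0 * f
            var += 2.0 * f * (1.0 - f)
        pmf = np.convolve(pmf, term)
    pmf = pmf / pmf.sum()
    return ScoreDistribution(values=np.arange(len(pmf)), pmf=pmf,
                             mean=mean, variance=var)


# --------------------------------------------------------------------------
# Model / Results orchestrators


class RiskScoreModel:
    """Cumulative risk-allele score analysis over a genotyped cohort.

    Builds the score definition from association results (nominal-p
    selection with forced-in borderline SNPs and the OR<1 orientation
    flip), computes per-subject scores and control quartiles, and fits the
    quartile odds-ratio / trend models.
    """

    def __init__(self, matrix: GenotypeMatrix, cohort, panel: SnpPanel,
                 definition: ScoreDefinition):
        self.matrix = matrix
        self.cohort = cohort
        self.panel = panel
        self.definition = definition

    @classmethod
    def from_association(cls, results, alpha: float = 0.05,
                         forced: Sequence[str] = DEFAULT_FORCED,
                         ) -> "RiskScoreModel":
        """Build from fitted :class:`SnpAssociationResults`."""
        panel = results.model.panel
        selected = select_score_snps(results.pvalues(), alpha=alpha,
                                     forced=forced, panel=panel)
        orientation = orient_risk_alleles(results.odds_ratios(), selected)
        definition = ScoreDefinition.build(panel, selected, orientation)
        return cls(results.model.matrix, results.model.cohort, panel,
                   definition)

    def fit(self, cuts: QuartileCuts | None = None) -> "RiskScoreResults":
        vec = cumulative_scores(self.matrix, self.definition, panel=self.panel)
        status = self.cohort.status_series().loc[self.matrix.subject_ids]
        age = self.cohort.age_series().loc[self.matrix.subject_ids]
        control_scores = vec.scores[status == 0].dropna()
        if cuts is None:
            cuts = control_quartile_cuts(control_scores)
        qa = quartile_association(vec.scores, cuts, status, age)
        return RiskScoreResults(self, vec, cuts, qa, status, age)


class RiskScoreResults:
    """Scores, quartile cuts and quartile association for one cohort."""

    def __init__(self, model: RiskScoreModel, scores: ScoreVector,
                 cuts: QuartileCuts, quartiles: QuartileAssociation,
                 status: pd.Series, age: pd.Series):
        self.model = model
        self.scores = scores
        self.cuts = cuts
        self.quartiles = quartiles
        self._status = status
        self._age = age

    def score_summary(self) -> dict[str, float]:
        s = self.scores.scores
        cases = s[self._status == 1].dropna()
        controls = s[self._status == 0].dropna()
        return {
            "mean_cases": float(cases.mean()),
            "mean_controls": float(controls.mean()),
            "median_cases": float(cases.median()),
            "median_controls": float(controls.median()),
            "n_cases": int(len(cases)),
            "n_controls": int(len(controls)),
            "n_excluded": int(self.scores.excluded.sum()),
        }

    def exact_distribution(self) -> ScoreDistribution:
        freqs = self.model.definition.risk_frequencies(self.model.panel)
        return exact_score_distribution(self.model.definition, freqs,
                                        panel=self.model.panel)

    def stratified(self, stratum: pd.Series) -> dict[str, QuartileAssociation]:
        out = {}
        for level in sorted(stratum.dropna().unique(), key=str):
            ids = stratum.index[stratum == level]
            out[str(level)] = quartile_association(
                self.scores.scores.loc[self.scores.scores.index.intersection(ids)],
                self.cuts,
                self._status.loc[self._status.index.intersection(ids)],
                self._age.loc[self._age.index.intersection(ids)])
        return out

    def summary(self) -> str:
        ss = self.score_summary()
        lines = [
            f"Risk-allele score over {len(self.model.definition.snp_ids)} SNPs "
            f"({self.model.definition.n_autosomal} autosomal, "
            f"{self.model.definition.n_x} X-linked)",
            f"control mean {ss['mean_controls']:.1f} (median "
            f"{ss['median_controls']:.0f}); case mean {ss['mean_cases']:.1f} "
            f"(median {ss['median_cases']:.0f})",
            f"quartile cuts {self.cuts.as_tuple()}",
        ]
        for r in self.quartiles.per_quartile:
            lines.append(f"  {r.model}: OR {r.or_value:.2f} "
                         f"({r.ci_low:.2f}-{r.ci_high:.2f})")
        lines.append(f"  trend p {self.quartiles.trend_p:.2g}")
        return "\n".join(lines)
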