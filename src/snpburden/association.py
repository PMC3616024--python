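"""Per-SNP association models, HWE QC, permutation multiplicity, subtypes.

All fits are age-adjusted unconditional logistic regressions (statsmodels
maximum likelihood), complete-case per SNP: each SNP uses every subject
non-missing at that SNP, so the effective n varies with missingness.  Age
enters as a continuous covariate.  Confidence intervals and p-values are
Wald, two-sided.

The multiplicity correction is an order-statistic permutation (minP-style)
procedure: case/control labels and ages are permuted *jointly* across
subjects — preserving any age-status relationship so that age-adjusted
p-values remain meaningful under the null — genotypes stay fixed, all
SNPs are refitted per permutation, and the k-th smallest observed p-value
is compared with the permutation distribution of k-th smallest p-values.
The +1 convention keeps adjusted p-values strictly positive.

Subtype (control / non-aggressive / aggressive) contrasts use a polytomous
(multinomial) logit with controls as the common reference; heterogeneity
between case strata is a Wald test using the joint information matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from ._glm import fit_logistic_batch
from .cohort import Cohort
from .genotypes import GenotypeMatrix
from .panel import SnpPanel

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "PermutationResult",
    "SubtypeResult",
    "InteractionResult",
    "hwe_test",
    "fit_additive",
    "fit_genotype_models",
    "permutation_adjusted_pvalues",
    "fit_polytomous",
    "heterogeneity_test",
    "stratified_fit",
    "interaction_lrt",
    "syndrome_pattern",
    "SnpAssociationModel",
    "SnpAssociationResults",
]

_Z975 = norm.ppf(0.975)


# --------------------------------------------------------------------------
# result containers


@dataclass
class AssociationResult:
    """One fitted genotype-disease contrast.

    ``model`` tags the genotype coding: additive, codominant_het,
    codominant_hom, dominant, recessive (or a polytomous stratum tag).
    ``beta`` is the log odds ratio for the coded genotype term; CI bounds
    are 95% Wald on the OR scale.
    """

    snp_id: str
    model: str
    beta: float
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    converged: bool
    note: str = ""
    loglik: float = float("nan")


@dataclass
class PermutationResult:
    """Order-statistic permutation adjustment over the SNP family."""

    n_perm: int
    snp_order: list[str]            # SNP ids sorted by observed p (ascending)
    observed_sorted_p: np.ndarray
    adjusted_p: np.ndarray          # per order statistic, +1 convention
    seed: int
    n_failed_fits: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_order,
                "observed_p": self.observed_sorted_p,
                "adjusted_p": self.adjusted_p,
            }
        )

    def adjusted_for(self, snp_id: str) -> float:
        return float(self.adjusted_p[self.snp_order.index(snp_id)])


@dataclass
class SubtypeResult:
    """Polytomous fit of one SNP against disease subtypes.

    Both case strata are contrasted against the same control group; the
    covariance between the two dosage coefficients comes from the joint
    information matrix and feeds the heterogeneity test.
    """

    snp_id: str
    or_nonaggressive: AssociationResult
    or_aggressive: AssociationResult
    beta_cov: float  # Cov(beta_nonagg, beta_agg) from the joint fit
    n_used: int
    converged: bool


@dataclass
class InteractionResult:
    """Stratum-specific effects plus a likelihood-ratio interaction test."""

    snp_id: str
    stratum_variable: str
    stratum_estimates: dict[str, AssociationResult | None]
    lrt_stat: float
    lrt_df: int
    lrt_p: float


# --------------------------------------------------------------------------
# Hardy-Weinberg QC


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> tuple[float, float, bool]:
    """1-df chi-square test of Hardy-Weinberg proportions.

    Takes genotype counts among controls for an autosomal SNP (major
    homozygote, heterozygote, minor homozygote) and compares them with the
    HWE-expected counts at the sample allele frequency.  Returns
    ``(chi2, p, monomorphic)``; a monomorphic SNP gets (0.0, 1.0, True).
    """
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotyped control")
    q = (n_het + 2 * n_hom_minor) / (2 * n)
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0, True
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * n
    observed = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1)), False


# --------------------------------------------------------------------------
# single-SNP logistic fits (statsmodels)


def _complete_case(*series: pd.Series) -> pd.DataFrame:
    df = pd.concat(series, axis=1, join="inner")
    return df.dropna()


def _logit(y: np.ndarray, X: np.ndarray):
    """statsmodels Logit fit; returns (result, converged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception:  # PerfectSeparationError and kin
            return None, False
        conv = bool(res.mle_retvals.get("converged", False))
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
            conv = False
        return res, conv


def _result_from_fit(res, conv: bool, snp_id: str, model: str, term: int,
                     n_used: int, note: str = "") -> AssociationResult:
    if res is None or not conv:
        return AssociationResult(snp_id, model, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, n_used, False,
                                 note or "fit did not converge")
    beta = float(res.params[term])
    se = float(res.bse[term])
    return AssociationResult(
        snp_id=snp_id, model=model, beta=beta, or_value=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        p=float(2 * norm.sf(abs(beta / se))), n_used=n_used, converged=True,
        note=note, loglik=float(res.llf),
    )


def fit_additive(dosage: pd.Series, status: pd.Series, age: pd.Series,
                 snp_id: str = "") -> AssociationResult:
    """Age-adjusted allelic additive (per-allele) logistic model.

    status ~ dosage + age; the OR is per counted (minor) allele.  Requires
    at least 10 complete-case rows with both statuses present.
    """
    snp_id = snp_id or (dosage.name or "")
    df = _complete_case(dosage.rename("g"), status.rename("y"), age.rename("age"))
    n = len(df)
    if n < 10 or df["y"].nunique() < 2:
        return AssociationResult(snp_id, "additive", np.nan, np.nan, np.nan,
                                 np.nan, np.nan, n, False,
                                 "insufficient complete-case data")
    X = np.column_stack([np.ones(n), df["g"].to_numpy(), df["age"].to_numpy()])
    res, conv = _logit(df["y"].to_numpy(), X)
    return _result_from_fit(res, conv, snp_id, "additive", 1, n)


def fit_genotype_models(dosage: pd.Series, status: pd.Series, age: pd.Series,
                        snp_id: str = "") -> dict[str, AssociationResult]:
    """Codominant, dominant and recessive codings of one SNP.

    Codominant: heterozygote and minor-homozygote indicators against the
    major-homozygote reference (two ORs).  Dominant: carrier indicator.
    Recessive: minor-homozygote indicator.  An empty genotype class
    downgrades the affected coding with an explicit flag instead of
    producing an unstable estimate.
    """
    snp_id = snp_id or (dosage.name or "")
    df = _complete_case(dosage.rename("g"), status.rename("y"), age.rename("age"))
    n = len(df)
    out: dict[str, AssociationResult] = {}
    classes = set(df["g"].unique())
    y = df["y"].to_numpy()
    age_v = df["age"].to_numpy()
    g = df["g"].to_numpy()

    def _flagged(model: str, why: str) -> AssociationResult:
        return AssociationResult(snp_id, model, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, n, False, why)

    if classes >= {0.0, 1.0, 2.0}:
        X = np.column_stack([np.ones(n), (g == 1).astype(float),
                             (g == 2).astype(float), age_v])
        res, conv = _logit(y, X)
        out["codominant_het"] = _result_from_fit(res, conv, snp_id,
                                                 "codominant_het", 1, n)
        out["codominant_hom"] = _result_from_fit(res, conv, snp_id,
                                                 "codominant_hom", 2, n)
    else:
        missing = sorted({0.0, 1.0, 2.0} - classes)
        why = f"empty genotype class(es) {missing}; codominant downgraded"
        out["codominant_het"] = _flagged("codominant_het", why)
        out["codominant_hom"] = _flagged("codominant_hom", why)

    X = np.column_stack([np.ones(n), (g >= 1).astype(float), age_v])
    res, conv = _logit(y, X)
    out["dominant"] = _result_from_fit(res, conv, snp_id, "dominant", 1, n)

    if 2.0 in classes:
        X = np.column_stack([np.ones(n), (g == 2).astype(float), age_v])
        res, conv = _logit(y, X)
        out["recessive"] = _result_from_fit(res, conv, snp_id, "recessive", 1, n)
    else:
        out["recessive"] = _flagged("recessive",
                                    "no minor-allele homozygotes; recessive not estimable")
    return out


# --------------------------------------------------------------------------
# joint (label, age) permutation multiplicity procedure


def _batched_observed_p(G: np.ndarray, w: np.ndarray, y: np.ndarray,
                        age: np.ndarray) -> tuple[np.ndarray, int]:
    """Additive age-adjusted Wald p for every SNP at once.

    G: (n, S) dosages with missing as 0 and weight 0; returns (p, n_failed)
    where a failed fit contributes p = 1.
    """
    n, S = G.shape
    X = np.empty((S, n, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = G.T
    X[:, :, 2] = age[None, :]
    fit = fit_logistic_batch(y, X, weights=w.T)
    p = fit.wald_p()[:, 1]
    failed = ~fit.converged | ~np.isfinite(p)
    p = np.where(failed, 1.0, p)
    return p, int(failed.sum())


def permutation_adjusted_pvalues(
    matrix: GenotypeMatrix,
    cohort: Cohort,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Joint (status, age) permutation adjustment for the SNP family.

    For each permutation the (status, age) pairs are shuffled jointly
    across subjects while genotype rows stay fixed; the additive
    age-adjusted model is refitted for every SNP.  The adjusted p-value
    for order statistic k is ``(1 + #{b : p(k)_b <= p(k)_obs}) /
    (n_perm + 1)``, so it can never be 0 and the identity permutation
    cannot push it below 1/(n_perm+1).  Permutation fits that fail to
    converge contribute p = 1 and are tallied.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    ids = matrix.subject_ids
    y = cohort.status_series().loc[ids].to_numpy(dtype=float)
    age = cohort.age_series().loc[ids].to_numpy(dtype=float)
    Gdf = matrix.data
    w = (~Gdf.isna()).to_numpy(dtype=float)
    G = Gdf.fillna(0.0).to_numpy(dtype=float)
    snp_ids = list(Gdf.columns)

    obs_p, n_failed = _batched_observed_p(G, w, y, age)
    order = np.argsort(obs_p, kind="stable")
    obs_sorted = obs_p[order]
    snp_order = [snp_ids[i] for i in order]

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(snp_ids), dtype=int)
    n, S = G.shape
    # batch permutations × SNPs through single Newton solves, chunked to
    # bound memory (~5e7 design-matrix elements per chunk)
    chunk = max(1, int(5e7 / (3 * S * n)))
    done = 0
    while done < n_perm:
        C = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(C)])
        X = np.empty((C, S, n, 3))
        X[:, :, :, 0] = 1.0
        X[:, :, :, 1] = G.T[None, :, :]
        X[:, :, :, 2] = age[perms][:, None, :]
        yb = np.broadcast_to(y[perms][:, None, :], (C, S, n))
        wb = np.broadcast_to(w.T[None, :, :], (C, S, n))
        fit = fit_logistic_batch(yb.reshape(C * S, n), X.reshape(C * S, n, 3),
                                 weights=wb.reshape(C * S, n))
        p_b = fit.wald_p()[:, 1].reshape(C, S)
        failed = (~fit.converged | ~np.isfinite(fit.wald_p()[:, 1])).reshape(C, S)
        p_b = np.where(failed, 1.0, p_b)
        n_failed += int(failed.sum())
        counts += (np.sort(p_b, axis=1) <= obs_sorted[None, :]).sum(axis=0)
        done += C
    adjusted = (1.0 + counts) / (n_perm + 1.0)
    if n_failed:
        logger.info("permutation procedure: %d non-converged fits set to p=1",
                    n_failed)
    return PermutationResult(
        n_perm=n_perm, snp_order=snp_order, observed_sorted_p=obs_sorted,
        adjusted_p=adjusted, seed=seed, n_failed_fits=n_failed,
    )


# --------------------------------------------------------------------------
# polytomous subtype models and heterogeneity


def fit_polytomous(dosage: pd.Series, subtype: pd.Series, age: pd.Series,
                   snp_id: str = "") -> SubtypeResult:
    """Multinomial logit of subtype (control / non_aggressive / aggressive).

    Controls are the reference outcome; per-allele ORs are reported per
    case stratum.  Subjects labelled ``unclassifiable`` are excluded; an
    empty outcome class is an error naming the class.
    """
    snp_id = snp_id or (dosage.name or "")
    sub = subtype[subtype != "unclassifiable"]
    df = _complete_case(dosage.rename("g"), sub.rename("k"), age.rename("age"))
    levels = ["control", "non_aggressive", "aggressive"]
    for lev in levels:
        if (df["k"] == lev).sum() == 0:
            raise ValueError(f"empty subtype stratum: {lev}")
    codes = pd.Categorical(df["k"], categories=levels).codes
    n = len(df)
    X = np.column_stack([np.ones(n), df["g"].to_numpy(), df["age"].to_numpy()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(codes, X).fit(disp=0, maxiter=200)
            conv = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res, conv = None, False

    def _stratum(tag: str, eq: int) -> AssociationResult:
        if res is None or not conv:
            return AssociationResult(snp_id, tag, np.nan, np.nan, np.nan,
                                     np.nan, np.nan, n, False,
                                     "polytomous fit did not converge")
        beta = float(np.asarray(res.params)[1, eq])
        se = float(np.asarray(res.bse)[1, eq])
        return AssociationResult(
            snp_id=snp_id, model=tag, beta=beta, or_value=float(np.exp(beta)),
            ci_low=float(np.exp(beta - _Z975 * se)),
            ci_high=float(np.exp(beta + _Z975 * se)),
            p=float(2 * norm.sf(abs(beta / se))), n_used=n, converged=True,
        )

    cov_b = np.nan
    if res is not None and conv:
        # params are stacked per equation (k_exog rows × J-1 equations);
        # cov_params follows the same column-major order.
        k_exog = res.params.shape[0]
        cov = np.asarray(res.cov_params())
        cov_b = float(cov[1, 1 + k_exog])  # (eq0, dosage) × (eq1, dosage)
    return SubtypeResult(
        snp_id=snp_id,
        or_nonaggressive=_stratum("polytomous_non_aggressive", 0),
        or_aggressive=_stratum("polytomous_aggressive", 1),
        beta_cov=cov_b, n_used=n, converged=bool(res is not None and conv),
    )


def heterogeneity_test(result: SubtypeResult) -> float:
    """Wald test of equal per-allele effects across case strata.

    Statistic: (b_agg - b_nonagg)^2 / (Var_agg + Var_nonagg - 2 Cov),
    1-df chi-square.  Falls back to the independence approximation (Cov=0)
    with a logged warning if the joint covariance is unavailable.
    """
    na, ag = result.or_nonaggressive, result.or_aggressive
    if not (na.converged and ag.converged):
        return float("nan")
    se_na = (np.log(na.ci_high) - np.log(na.ci_low)) / (2 * _Z975)
    se_ag = (np.log(ag.ci_high) - np.log(ag.ci_low)) / (2 * _Z975)
    cov = result.beta_cov
    if not np.isfinite(cov):
        logger.warning("%s: missing joint covariance; using independence "
                       "approximation for heterogeneity", result.snp_id)
        cov = 0.0
    var = se_na ** 2 + se_ag ** 2 - 2.0 * cov
    if var <= 0:
        return float("nan")
    stat = (ag.beta - na.beta) ** 2 / var
    return float(chi2.sf(stat, df=1))


# --------------------------------------------------------------------------
# stratified and interaction analyses


def stratified_fit(dosage: pd.Series, status: pd.Series, age: pd.Series,
                   stratum: pd.Series, snp_id: str = "",
                   ) -> dict[str, AssociationResult | None]:
    """Independent additive fits within each level of ``stratum``.

    A thin stratum (fewer than 10 complete rows or a single status) is
    reported as ``None`` rather than an unstable estimate.
    """
    snp_id = snp_id or (dosage.name or "")
    out: dict[str, AssociationResult | None] = {}
    for level in sorted(stratum.dropna().unique(), key=str):
        keep = stratum.index[stratum == level]
        res = fit_additive(dosage.loc[dosage.index.intersection(keep)],
                           status.loc[status.index.intersection(keep)],
                           age.loc[age.index.intersection(keep)],
                           snp_id=snp_id)
        out[str(level)] = res if res.converged else None
    return out


def interaction_lrt(dosage: pd.Series, status: pd.Series, age: pd.Series,
                    modifier: pd.Series, snp_id: str = "",
                    coding: str = "additive") -> InteractionResult:
    """Likelihood-ratio test for genotype × modifier effect modification.

    Compares status ~ g + age + m + g:m against status ~ g + age + m.
    ``coding="additive"`` uses the allele count (1-df interaction);
    ``coding="genotype"`` uses heterozygote/homozygote indicators (2-df).
    """
    snp_id = snp_id or (dosage.name or "")
    df = _complete_case(dosage.rename("g"), status.rename("y"),
                        age.rename("age"), modifier.rename("m"))
    n = len(df)
    y = df["y"].to_numpy()
    g = df["g"].to_numpy()
    m = df["m"].to_numpy(dtype=float)
    age_v = df["age"].to_numpy()
    if coding == "additive":
        g_cols = [g]
    elif coding == "genotype":
        g_cols = [(g == 1).astype(float), (g == 2).astype(float)]
    else:
        raise ValueError(f"unknown coding {coding!r}")
    base = np.column_stack([np.ones(n), *g_cols, age_v, m])
    inter = np.column_stack([c * m for c in g_cols])
    full = np.column_stack([base, inter])
    res_red, conv_red = _logit(y, base)
    res_full, conv_full = _logit(y, full)
    if not (conv_red and conv_full):
        raise RuntimeError(f"{snp_id}: interaction LRT fits did not converge")
    stat = 2.0 * (res_full.llf - res_red.llf)
    stat = max(stat, 0.0)
    df_lrt = len(g_cols)
    strata = stratified_fit(dosage, status, age, modifier, snp_id=snp_id)
    return InteractionResult(
        snp_id=snp_id, stratum_variable=str(modifier.name or "modifier"),
        stratum_estimates=strata, lrt_stat=float(stat), lrt_df=df_lrt,
        lrt_p=float(chi2.sf(stat, df=df_lrt)),
    )


# --------------------------------------------------------------------------
# syndrome-pattern classification


def syndrome_pattern(contrast_case_fh: AssociationResult,
                     contrast_case_nofh: AssociationResult,
                     contrast_control_fh: AssociationResult,
                     alpha: float = 0.05,
                     similar_or_tol: float = 0.20) -> str:
    """Classify a SNP × family-history pattern from three contrasts.

    The contrasts, all against controls without the family history:
    (A) cases *with* the FH, (B) cases *without* the FH, (C) controls
    *with* the FH.  Logic: a significant C means the risk genotype tracks
    the other cancer itself (``other_cancer_linked``); A significant with
    B null suggests a shared syndrome (``syndrome_like``); A and B both
    significant with similar ORs (ratio within ``similar_or_tol``) means
    the association is specific to the index disease (``prca_specific``);
    anything else is ``indeterminate``.
    """
    for name, c in (("A", contrast_case_fh), ("B", contrast_case_nofh),
                    ("C", contrast_control_fh)):
        if c is None or not np.isfinite(c.p):
            raise ValueError(f"missing contrast {name}")
    a_sig = contrast_case_fh.p <= alpha
    b_sig = contrast_case_nofh.p <= alpha
    c_sig = contrast_control_fh.p <= alpha
    if c_sig:
        return "other_cancer_linked"
    if a_sig and not b_sig:
        return "syndrome_like"
    if a_sig and b_sig:
        ratio = abs(np.log(contrast_case_fh.or_value)
                    - np.log(contrast_case_nofh.or_value))
        if ratio <= np.log1p(similar_or_tol):
            return "prca_specific"
    return "indeterminate"


# --------------------------------------------------------------------------
# Model / Results orchestrators


class SnpAssociationModel:
    """Per-SNP association analysis over a genotyped cohort.

    Parameters
    ----------
    matrix : GenotypeMatrix
    cohort : Cohort
    panel : SnpPanel, optional
        Defaults to the matrix's own panel.

    ``fit()`` runs the age-adjusted additive model and control HWE QC for
    every SNP and returns :class:`SnpAssociationResults`.
    """

    def __init__(self, matrix: GenotypeMatrix, cohort: Cohort,
                 panel: SnpPanel | None = None):
        self.matrix = matrix
        self.cohort = cohort
        self.panel = panel if panel is not None else matrix.panel
        if self.panel is None:
            raise ValueError("a SnpPanel is required")
        missing = set(matrix.subject_ids) - set(cohort.subject_ids)
        if missing:
            raise ValueError(f"genotyped subjects absent from cohort: "
                             f"{sorted(missing)[:5]}")

    def _vectors(self) -> tuple[pd.Series, pd.Series]:
        ids = self.matrix.subject_ids
        return (self.cohort.status_series().loc[ids],
                self.cohort.age_series().loc[ids])

    def fit(self) -> "SnpAssociationResults":
        status, age = self._vectors()
        control_ids = status.index[status == 0]
        additive: dict[str, AssociationResult] = {}
        hwe: dict[str, tuple[float, float, bool]] = {}
        x_ids = set(self.panel.x_ids)
        for sid in self.matrix.snp_ids:
            g = self.matrix.dosages(sid)
            additive[sid] = fit_additive(g, status, age, snp_id=sid)
            if sid in x_ids:
                hwe[sid] = (np.nan, np.nan, False)
            else:
                gc = g.loc[control_ids].dropna()
                hwe[sid] = hwe_test(int((gc == 0).sum()), int((gc == 1).sum()),
                                    int((gc == 2).sum()))
        return SnpAssociationResults(self, additive, hwe)


class SnpAssociationResults:
    """Fitted per-SNP association results with downstream analyses."""

    def __init__(self, model: SnpAssociationModel,
                 additive: dict[str, AssociationResult],
                 hwe: dict[str, tuple[float, float, bool]]):
        self.model = model
        self.additive = additive
        self.hwe = hwe
        self._permutation: PermutationResult | None = None

    @property
    def snp_ids(self) -> list[str]:
        return list(self.additive)

    def pvalues(self) -> dict[str, float]:
        return {s: r.p for s, r in self.additive.items()}

    def odds_ratios(self) -> dict[str, float]:
        return {s: r.or_value for s, r in self.additive.items()}

    def permutation_adjusted(self, n_perm: int = 10_000,
                             seed: int = 0) -> PermutationResult:
        self._permutation = permutation_adjusted_pvalues(
            self.model.matrix, self.model.cohort, n_perm=n_perm, seed=seed)
        return self._permutation

    def fit_subtypes(self) -> dict[str, SubtypeResult]:
        status, age = self.model._vectors()
        subtype = self.model.cohort.aggressiveness_series().loc[status.index]
        out = {}
        for sid in self.model.matrix.snp_ids:
            out[sid] = fit_polytomous(self.model.matrix.dosages(sid),
                                      subtype, age, snp_id=sid)
        return out

    def genotype_models(self) -> dict[str, dict[str, AssociationResult]]:
        status, age = self.model._vectors()
        return {
            sid: fit_genotype_models(self.model.matrix.dosages(sid), status,
                                     age, snp_id=sid)
            for sid in self.model.matrix.snp_ids
        }

    def to_frame(self) -> pd.DataFrame:
        """Per-SNP additive results, HWE and (if run) adjusted p-values."""
        rows = []
        for sid, r in self.additive.items():
            chi, p_hwe, mono = self.hwe[sid]
            row = {
                "snp_id": sid, "or": r.or_value, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "p": r.p, "n_used": r.n_used,
                "converged": r.converged, "hwe_p": p_hwe,
                "hwe_monomorphic": mono,
            }
            if self._permutation is not None:
                row["adjusted_p"] = self._permutation.adjusted_for(sid)
            rows.append(row)
        return pd.DataFrame(rows).set_index("snp_id")

    def summary(self) -> str:
        df = self.to_frame()
        with pd.option_context("display.float_format", "{:.4g}".format):
            return (
                "Age-adjusted allelic additive associations "
                f"({len(df)} SNPs)\n" + df.to_string()
            )
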