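"""Synthetic case-control cohorts with the structure the analysis assumes.

The generator emulates a candidate-SNP case-control study in an all-male
founder population: Hardy-Weinberg genotypes at panel control frequencies
(hemizygous 0/1 on X), disease assigned by a log-additive logistic model
at configurable per-allele odds ratios, retrospective sampling of cases
and controls from a large simulated population, status-conditional age and
family-history structure, a Gleason/pathology mix for cases, and per-SNP
missingness.

Defaults reproduce the study conditions: 979 cases / 1,251 controls, ages
~65 (cases) / ~68 (controls) truncated at 40, first-degree family history
of prostate cancer 28% in cases vs 14% in controls, roughly two thirds of
cases Gleason 2-6 / 25% Gleason 7 / 12% Gleason 8-10, and per-SNP
missingness in (0.01, 0.11) averaging 2%.

Randomness: one master seed spawns named substreams (genotypes, disease,
sampling, ages, family history, pathology, missingness), so each stage is
independently reproducible and outputs are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import Cohort, FH_COLUMNS, PATH_FEATURES, SubjectRecord
from .genotypes import GenotypeMatrix
from .panel import SnpPanel

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "assign_disease",
    "calibrate_intercept",
    "inject_missingness",
    "simulate_cohort",
    "default_orientation",
    "default_betas",
]

_STREAMS = ("genotypes", "disease", "sampling", "ages", "fh",
            "pathology", "missingness")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def default_orientation(panel: SnpPanel) -> dict[str, str]:
    """Risk-allele orientation from published ORs: OR >= 1 -> minor allele."""
    out = {}
    for rec in panel:
        if rec.published_or is None:
            out[rec.snp_id] = "minor"
        else:
            out[rec.snp_id] = "minor" if rec.published_or >= 1.0 else "major"
    return out


def default_betas(panel: SnpPanel) -> dict[str, float]:
    """Per-risk-allele log-ORs: |ln(published OR)|, 0 where unpublished."""
    out = {}
    for rec in panel:
        if rec.published_or is None:
            out[rec.snp_id] = 0.0
        else:
            out[rec.snp_id] = abs(math.log(rec.published_or))
    return out


@dataclass
class SimulationConfig:
    """Study-condition parameters for :func:`simulate_cohort`.

    ``betas`` are per-*risk*-allele log odds ratios (nonnegative by
    convention; orientation carries the direction).  ``None`` means the
    natural logs of the panel's published ORs with the OR<1 SNPs flipped to
    the major allele.  ``missingness`` is either a mapping snp_id -> rate
    or ``None`` to draw rates from 0.01 + 0.10*Beta(1, 9) (range (0.01,
    0.11), mean 0.02).
    """

    panel: SnpPanel
    n_cases: int = 979
    n_controls: int = 1251
    prevalence: float = 0.10
    population_size: int | None = None
    betas: dict[str, float] | None = None
    orientation: dict[str, str] | None = None
    age_mean_cases: float = 65.0
    age_mean_controls: float = 68.0
    age_sd: float = 8.0
    age_min: float = 40.0
    fh_prostate_cases: float = 0.28
    fh_prostate_controls: float = 0.14
    other_fh_probs: dict[str, float] = field(default_factory=lambda: {
        "fh_lung": 0.10, "fh_colorectal": 0.08, "fh_breast": 0.15,
        "fh_ovarian": 0.03, "fh_bladder": 0.03,
    })
    gleason_mixture: tuple[float, float, float] = (0.63, 0.25, 0.12)
    pathology_missing_rate: float = 0.06
    feature_prob_low: float = 0.12    # per-feature P for Gleason 2-6
    feature_prob_mid: float = 0.30    # Gleason 7
    feature_prob_high: float = 0.50   # Gleason 8-10
    missingness: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.gleason_mixture) - 1.0) > 1e-9:
            raise ValueError("Gleason mixture must sum to 1")
        probs = [self.prevalence, self.fh_prostate_cases,
                 self.fh_prostate_controls, self.pathology_missing_rate,
                 *self.other_fh_probs.values()]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.missingness is not None:
            if not all(0.0 <= r <= 1.0 for r in self.missingness.values()):
                raise ValueError("missingness rates must lie in [0, 1]")


def simulate_genotypes(
    panel: SnpPanel, n: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """HWE genotypes: Binomial(2, f) autosomal, Bernoulli(f) on X (males)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {}
    for rec in panel:
        if rec.is_x:
            cols[rec.snp_id] = rng.binomial(1, rec.control_maf, size=n).astype(float)
        else:
            cols[rec.snp_id] = rng.binomial(2, rec.control_maf, size=n).astype(float)
    ids = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    return GenotypeMatrix(pd.DataFrame(cols, index=ids), panel)


def _risk_counts(matrix: GenotypeMatrix, orientation: dict[str, str]) -> pd.DataFrame:
    """Risk-allele counts from minor-allele dosages given an orientation."""
    panel = matrix.panel
    x_ids = set(panel.x_ids) if panel is not None else set()
    out = {}
    for sid in matrix.snp_ids:
        if sid not in orientation:
            raise ValueError(f"unresolved risk-allele orientation for {sid}")
        g = matrix.data[sid]
        if orientation[sid] == "minor":
            out[sid] = g
        else:
            out[sid] = (1.0 - g) if sid in x_ids else (2.0 - g)
    return pd.DataFrame(out, index=matrix.data.index)


def calibrate_intercept(
    matrix: GenotypeMatrix,
    betas: dict[str, float],
    orientation: dict[str, str],
    prevalence: float,
) -> float:
    """Intercept such that mean disease probability equals ``prevalence``."""
    r = _risk_counts(matrix, orientation)
    lin = sum(betas[s] * r[s].to_numpy() for s in matrix.snp_ids)
    lin = np.asarray(lin, dtype=float)

    def f(b0: float) -> float:
        return float(expit(b0 + lin).mean()) - prevalence

    return brentq(f, -30.0, 30.0)


def assign_disease(
    matrix: GenotypeMatrix,
    betas: dict[str, float],
    intercept: float,
    orientation: dict[str, str],
    seed: int | np.random.Generator,
) -> pd.Series:
    """Bernoulli disease status under the log-additive logistic model.

    P(case) = expit(intercept + sum_i beta_i * r_i) with r_i the
    risk-allele count at SNP i under ``orientation``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = _risk_counts(matrix, orientation)
    lin = intercept + sum(betas[s] * r[s].to_numpy() for s in matrix.snp_ids)
    p = expit(np.asarray(lin, dtype=float))
    status = rng.random(len(p)) < p
    return pd.Series(status.astype(int), index=matrix.data.index, name="status")


def inject_missingness(
    matrix: GenotypeMatrix,
    rates: dict[str, float],
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Independently blank each cell with its SNP's missingness rate."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = matrix.data.copy()
    n = len(data)
    for sid in data.columns:
        rate = rates.get(sid, 0.0)
        if rate < 0 or rate > 1:
            raise ValueError(f"{sid}: missingness rate {rate} outside [0, 1]")
        if rate > 0:
            mask = rng.random(n) < rate
            data.loc[mask, sid] = np.nan
    return GenotypeMatrix(data, matrix.panel)


def _draw_missing_rates(panel: SnpPanel, rng: np.random.Generator) -> dict[str, float]:
    # 0.01 + 0.10*Beta(1,9): support (0.01, 0.11), mean exactly 0.02
    return {rec.snp_id: float(0.01 + 0.10 * rng.beta(1.0, 9.0))
            for rec in panel}


def _truncated_ages(mean: float, sd: float, lo: float, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    a = (lo - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


_GLEASON_WITHIN_LOW = ((2, 0.01), (3, 0.03), (4, 0.08), (5, 0.26), (6, 0.62))
_GLEASON_WITHIN_HIGH = ((8, 0.60), (9, 0.30), (10, 0.10))


def _draw_gleason(n: int, mixture: tuple[float, float, float],
                  rng: np.random.Generator) -> np.ndarray:
    band = rng.choice(3, size=n, p=list(mixture))
    out = np.empty(n, dtype=int)
    low_vals = [v for v, _ in _GLEASON_WITHIN_LOW]
    low_p = [p for _, p in _GLEASON_WITHIN_LOW]
    high_vals = [v for v, _ in _GLEASON_WITHIN_HIGH]
    high_p = [p for _, p in _GLEASON_WITHIN_HIGH]
    out[band == 0] = rng.choice(low_vals, size=int((band == 0).sum()), p=low_p)
    out[band == 1] = 7
    out[band == 2] = rng.choice(high_vals, size=int((band == 2).sum()), p=high_p)
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[SnpPanel, GenotypeMatrix, Cohort]:
    """Generate a complete synthetic study dataset.

    A large population is simulated at HWE, disease is assigned by the
    logistic model with the intercept calibrated to ``prevalence``, and the
    requested numbers of cases and controls are sampled without
    replacement (retrospective design).  Phenotypes are then attached
    conditionally on status, and per-SNP missingness is injected last.

    Returns (panel, genotypes, cohort); genotype subject order is cases
    first, then controls.
    """
    cfg = config
    rngs = _rngs(cfg.seed)
    panel = cfg.panel
    orientation = cfg.orientation or default_orientation(panel)
    betas = cfg.betas or default_betas(panel)
    n_pop = cfg.population_size
    if n_pop is None:
        need = max(cfg.n_cases / max(cfg.prevalence, 1e-9),
                   cfg.n_controls / max(1.0 - cfg.prevalence, 1e-9))
        n_pop = int(math.ceil(need * 1.3))
    population = simulate_genotypes(panel, n_pop, rngs["genotypes"])
    intercept = calibrate_intercept(population, betas, orientation, cfg.prevalence)
    status = assign_disease(population, betas, intercept, orientation, rngs["disease"])
    case_ids = status.index[status == 1].to_numpy()
    control_ids = status.index[status == 0].to_numpy()
    if len(case_ids) < cfg.n_cases or len(control_ids) < cfg.n_controls:
        raise ValueError(
            f"population of {n_pop} yielded {len(case_ids)} cases / "
            f"{len(control_ids)} controls; need {cfg.n_cases}/{cfg.n_controls}. "
            "Increase population_size."
        )
    samp = rngs["sampling"]
    picked_cases = samp.choice(case_ids, size=cfg.n_cases, replace=False)
    picked_controls = samp.choice(control_ids, size=cfg.n_controls, replace=False)

    age_rng = rngs["ages"]
    ages_cases = _truncated_ages(cfg.age_mean_cases, cfg.age_sd, cfg.age_min,
                                 cfg.n_cases, age_rng)
    ages_controls = _truncated_ages(cfg.age_mean_controls, cfg.age_sd,
                                    cfg.age_min, cfg.n_controls, age_rng)

    fh_rng = rngs["fh"]
    path_rng = rngs["pathology"]
    gleason = _draw_gleason(cfg.n_cases, cfg.gleason_mixture, path_rng)
    path_missing = path_rng.random(cfg.n_cases) < cfg.pathology_missing_rate

    subjects: list[SubjectRecord] = []
    new_ids: list[str] = []

    def _fh_flags(is_case: bool) -> dict[str, bool]:
        p_pr = cfg.fh_prostate_cases if is_case else cfg.fh_prostate_controls
        flags = {"fh_prostate": bool(fh_rng.random() < p_pr)}
        for col in FH_COLUMNS[1:]:
            flags[col] = bool(fh_rng.random() < cfg.other_fh_probs.get(col, 0.0))
        return flags

    for i in range(cfg.n_cases):
        sid = f"case_{i:05d}"
        new_ids.append(sid)
        if path_missing[i]:
            gl, feats = None, None
        else:
            gl = int(gleason[i])
            if gl >= 8:
                fp = cfg.feature_prob_high
            elif gl == 7:
                fp = cfg.feature_prob_mid
            else:
                fp = cfg.feature_prob_low
            feats = {f: bool(path_rng.random() < fp) for f in PATH_FEATURES}
        subjects.append(SubjectRecord(
            subject_id=sid, status="case", age=float(ages_cases[i]),
            fh=_fh_flags(True), gleason=gl, path_features=feats,
        ))
    for i in range(cfg.n_controls):
        sid = f"ctrl_{i:05d}"
        new_ids.append(sid)
        subjects.append(SubjectRecord(
            subject_id=sid, status="control", age=float(ages_controls[i]),
            fh=_fh_flags(False),
        ))

    picked = np.concatenate([picked_cases, picked_controls])
    geno = population.data.loc[picked].copy()
    geno.index = pd.Index(new_ids, name="subject_id")
    matrix = GenotypeMatrix(geno, panel)

    rates = cfg.missingness
    if rates is None:
        rates = _draw_missing_rates(panel, rngs["missingness"])
    matrix = inject_missingness(matrix, rates, rngs["missingness"])

    return panel, matrix, Cohort(subjects)
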