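"""Simulation-based power for the age-adjusted log-additive test.

Per replicate, control genotypes are drawn from HWE at the given minor
allele frequency and case genotypes from the case genotype distribution a
per-allele odds ratio implies under a rare-disease log-additive model:
HWE probabilities tilted by OR^g and renormalised.  An age covariate with
no genotype or status effect is added so the fitted model matches the
analysis model (status ~ dosage + age).  Power is the fraction of
replicates with two-sided Wald p <= alpha, with a Wilson score interval.

A closed-form normal-approximation power for the allele-count (2×2) test
is provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from ._glm import fit_logistic_batch

__all__ = [
    "PowerConfig",
    "PowerResult",
    "case_genotype_probs",
    "simulate_power",
    "analytic_allele_power",
]


@dataclass
class PowerConfig:
    """Design parameters for one power estimate."""

    n_cases: int = 936
    n_controls: int = 1223
    maf: float = 0.20
    or_per_allele: float = 1.35
    alpha: float = 0.002
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1 or self.n_reps < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")
        if self.or_per_allele <= 0:
            raise ValueError("or_per_allele must be positive")


@dataclass
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_reps: int
    n_rejected: int


def case_genotype_probs(maf: float, or_per_allele: float) -> np.ndarray:
    """Case genotype distribution under the rare-disease approximation.

    HWE genotype probabilities at the control frequency are tilted by
    OR^g and renormalised.
    """
    f = maf
    hwe = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
    tilt = hwe * or_per_allele ** np.arange(3)
    return tilt / tilt.sum()


def simulate_power(config: PowerConfig) -> PowerResult:
    """Monte-Carlo power of the two-sided age-adjusted additive Wald test."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    R = cfg.n_reps
    n = cfg.n_cases + cfg.n_controls
    g_controls = rng.binomial(2, cfg.maf, size=(R, cfg.n_controls))
    p_case = case_genotype_probs(cfg.maf, cfg.or_per_allele)
    g_cases = rng.choice(3, size=(R, cfg.n_cases), p=p_case)
    G = np.concatenate([g_cases, g_controls], axis=1).astype(float)
    y = np.concatenate([np.ones(cfg.n_cases), np.zeros(cfg.n_controls)])
    age = rng.normal(65.0, 8.0, size=(R, n))  # independent of both
    X = np.empty((R, n, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = G
    X[:, :, 2] = age
    fit = fit_logistic_batch(y, X)
    p = fit.wald_p()[:, 1]
    rejected = fit.converged & np.isfinite(p) & (p <= cfg.alpha)
    k = int(rejected.sum())
    lo, hi = proportion_confint(k, R, alpha=0.05, method="wilson")
    return PowerResult(power=k / R, ci_low=float(lo), ci_high=float(hi),
                       n_reps=R, n_rejected=k)


def power_grid(or_values, maf_values, base: PowerConfig) -> "list[dict]":
    """Power over an OR × MAF sweep (each cell reuses the base design)."""
    from dataclasses import replace

    rows = []
    for i, or_v in enumerate(or_values):
        for j, maf in enumerate(maf_values):
            cfg = replace(base, or_per_allele=float(or_v), maf=float(maf),
                          seed=base.seed + 1000 * i + j)
            res = simulate_power(cfg)
            rows.append({"or_per_allele": float(or_v), "maf": float(maf),
                         "power": res.power, "ci_low": res.ci_low,
                         "ci_high": res.ci_high})
    return rows


def analytic_allele_power(n_cases: int, n_controls: int, maf: float,
                          or_per_allele: float, alpha: float) -> float:
    """Normal-approximation power of the allele-count two-proportion test.

    Case allele frequency comes from the tilted genotype distribution;
    the test statistic is the difference of allele frequencies over its
    null/alternative standard error.  Used as an independent cross-check
    on :func:`simulate_power`.
    """
    p0 = maf
    pc = case_genotype_probs(maf, or_per_allele)
    p1 = float((pc * np.arange(3)).sum() / 2.0)
    m1, m0 = 2 * n_cases, 2 * n_controls  # allele counts
    se_alt = np.sqrt(p1 * (1 - p1) / m1 + p0 * (1 - p0) / m0)
    pbar = (m1 * p1 + m0 * p0) / (m1 + m0)
    se_null = np.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m0))
    z_crit = norm.ppf(1 - alpha / 2)
    delta = abs(p1 - p0)
    return float(norm.sf((z_crit * se_null - delta) / se_alt)
                 + norm.cdf((-z_crit * se_null - delta) / se_alt))
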