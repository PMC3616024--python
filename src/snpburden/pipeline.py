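"""End-to-end analysis pipeline and report rendering.

Ties the stages together in the study's order — simulate (or load) →
per-SNP association with permutation multiplicity → subtype contrasts →
cumulative risk-allele score with control quartiles → nested-model AUC →
design power — and writes publication-shaped TSV tables, a JSON manifest
(config, seeds, thresholds, outputs) and a run log.  Re-running with the
same config and seed reproduces every output byte for byte; the manifest
deliberately carries no timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .association import SnpAssociationModel
from .cohort import Cohort, read_cohort
from .genotypes import GenotypeMatrix, allele_frequency, read_genotypes
from .panel import SnpPanel, load_gwas_panel, read_panel
from .power import PowerConfig, simulate_power
from .prediction import RiskPredictionModel
from .score import RiskScoreModel
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_association_table",
           "render_subtype_table", "render_quartile_table"]

_ALL_STAGES = ("assoc", "score", "predict", "power")


@dataclass
class RunConfig:
    """Pipeline configuration: either input paths or a simulation block.

    ``alpha`` is the nominal two-sided level; the Bonferroni-corrected
    per-SNP threshold alpha / n_snps is derived and recorded in the
    manifest.  ``n_perm`` is the permutation count B.
    """

    inputs: dict | None = None        # {"panel": ..., "genotypes": ..., "phenotypes": ...}
    simulate: dict | None = None      # kwargs for SimulationConfig (minus panel)
    stages: tuple[str, ...] = _ALL_STAGES
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    power: dict = field(default_factory=dict)
    genotype_models: bool = False  # also emit codominant/dominant/recessive

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of 'inputs' and 'simulate' must be given")
        if self.inputs is not None:
            for key in ("panel", "genotypes", "phenotypes"):
                if key not in self.inputs:
                    raise ValueError(f"inputs missing {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise FileNotFoundError(self.inputs[key])
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs, "simulate": self.simulate,
            "stages": list(self.stages), "alpha": self.alpha,
            "n_perm": self.n_perm, "seed": self.seed, "power": self.power,
            "genotype_models": self.genotype_models,
        }


# --------------------------------------------------------------------------
# table rendering


def _fmt_ci(lo: float, hi: float) -> str:
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return "NA"
    return f"{lo:.2f}-{hi:.2f}"


def render_association_table(panel: SnpPanel, assoc_frame: pd.DataFrame,
                             maf: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP table: alleles, control MAF, OR, CI, p, HWE p, adjusted p."""
    rows = []
    for rec in panel:
        sid = rec.snp_id
        if sid not in assoc_frame.index:
            continue
        r = assoc_frame.loc[sid]
        row = {
            "snp_id": sid,
            "chrom": rec.chrom_label,
            "alleles": f"{rec.major_allele}/{rec.minor_allele}",
            "maf_controls": round(float(maf.loc[sid, "freq"]), 3)
            if sid in maf.index else np.nan,
            "or": round(float(r["or"]), 2),
            "ci_95": _fmt_ci(r["ci_low"], r["ci_high"]),
            "p": float(r["p"]),
            "hwe_p": float(r["hwe_p"]),
        }
        if "adjusted_p" in assoc_frame.columns:
            row["adjusted_p"] = float(r["adjusted_p"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("snp_id")


def render_subtype_table(panel: SnpPanel, subtypes: dict) -> pd.DataFrame:
    """Subtype table: per-SNP non-aggressive and aggressive ORs + het p."""
    from .association import heterogeneity_test

    rows = []
    for rec in panel:
        if rec.snp_id not in subtypes:
            continue
        s = subtypes[rec.snp_id]
        na, ag = s.or_nonaggressive, s.or_aggressive
        rows.append({
            "snp_id": rec.snp_id,
            "chrom": rec.chrom_label,
            "alleles": f"{rec.major_allele}/{rec.minor_allele}",
            "or_non_aggressive": round(na.or_value, 2) if na.converged else np.nan,
            "ci_non_aggressive": _fmt_ci(na.ci_low, na.ci_high),
            "p_non_aggressive": na.p,
            "or_aggressive": round(ag.or_value, 2) if ag.converged else np.nan,
            "ci_aggressive": _fmt_ci(ag.ci_low, ag.ci_high),
            "p_aggressive": ag.p,
            "heterogeneity_p": heterogeneity_test(s),
        })
    return pd.DataFrame(rows).set_index("snp_id")


def render_quartile_table(counts_controls: list[int], counts_cases: list[int],
                          or_results=None, trend_p: float | None = None,
                          labels: list[str] | None = None) -> pd.DataFrame:
    """Quartile table with ``n (%)`` cells (row percents) and OR rows.

    Percentages are row percents to one decimal, so each status row sums
    to 100% up to rounding.
    """
    labels = labels or [f"Q{i}" for i in range(1, 5)]

    def fmt_row(counts: list[int]) -> list[str]:
        total = sum(counts)
        return [f"{c} ({100.0 * c / total:.1f})" for c in counts]

    rows = {
        f"controls_n_{sum(counts_controls)}": fmt_row(counts_controls),
        f"cases_n_{sum(counts_cases)}": fmt_row(counts_cases),
    }
    if or_results is not None:
        or_cells = ["1.00"]
        for r in or_results:
            if r.converged:
                or_cells.append(f"{r.or_value:.2f} ({_fmt_ci(r.ci_low, r.ci_high)})")
            else:
                or_cells.append("NA")
        rows["or_95ci"] = or_cells
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    if trend_p is not None:
        df["p_trend"] = ""
        if "or_95ci" in df.index:
            df.loc["or_95ci", "p_trend"] = f"{trend_p:.2g}"
    return df


# --------------------------------------------------------------------------
# pipeline


def _load_inputs(cfg: RunConfig) -> tuple[SnpPanel, GenotypeMatrix, Cohort]:
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        panel_path = sim_kwargs.pop("panel", None)
        panel = read_panel(panel_path) if panel_path else load_gwas_panel()
        sim_kwargs.setdefault("seed", cfg.seed)
        sim_cfg = SimulationConfig(panel=panel, **sim_kwargs)
        return simulate_cohort(sim_cfg)
    panel = read_panel(cfg.inputs["panel"])
    cohort = read_cohort(cfg.inputs["phenotypes"])
    matrix = read_genotypes(cfg.inputs["genotypes"], panel, cohort)
    return panel, matrix, cohort


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the requested stages; returns the manifest dict.

    Outputs land in ``outdir``: the three data TSVs, association and
    subtype tables, per-subject scores and the quartile table, ROC points
    and AUC summary, a power estimate, ``manifest.json`` and ``run.log``.
    A stage failure aborts with the stage named; completed outputs are
    preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("snpburden")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {
        "package": "snpburden",
        "version": _pkg_version("snpburden"),
        "config": config.to_dict(),
        "outputs": {},
        "thresholds": {},
        "seeds": {"master": config.seed},
    }
    stage = "load"
    try:
        panel, matrix, cohort = _load_inputs(config)
        n_snps = len(matrix.snp_ids)
        manifest["thresholds"] = {
            "alpha_nominal": config.alpha,
            "n_tests": n_snps,
            "alpha_bonferroni": config.alpha / n_snps,
        }
        panel.to_tsv(outdir / "panel.tsv")
        matrix.to_tsv(outdir / "genotypes.tsv")
        cohort.to_tsv(outdir / "phenotypes.tsv")
        manifest["outputs"]["data"] = ["panel.tsv", "genotypes.tsv",
                                       "phenotypes.tsv"]
        logger.info("loaded %d subjects × %d SNPs", len(matrix.subject_ids),
                    n_snps)

        results = None
        if "assoc" in config.stages:
            stage = "assoc"
            model = SnpAssociationModel(matrix, cohort, panel)
            results = model.fit()
            perm = results.permutation_adjusted(n_perm=config.n_perm,
                                                seed=config.seed + 1)
            manifest["seeds"]["permutation"] = config.seed + 1
            controls = [s.subject_id for s in cohort if s.status == "control"]
            maf = allele_frequency(matrix, panel, controls)
            t1 = render_association_table(panel, results.to_frame(), maf)
            t1.to_csv(outdir / "association.tsv", sep="\t", na_rep="NA")
            subtypes = results.fit_subtypes()
            t2 = render_subtype_table(panel, subtypes)
            t2.to_csv(outdir / "association_subtypes.tsv", sep="\t",
                      na_rep="NA")
            manifest["outputs"]["assoc"] = ["association.tsv",
                                            "association_subtypes.tsv"]
            if config.genotype_models:
                rows = []
                for sid, models in results.genotype_models().items():
                    for tag, r in models.items():
                        rows.append({
                            "snp_id": sid, "model": tag, "or": r.or_value,
                            "ci_low": r.ci_low, "ci_high": r.ci_high,
                            "p": r.p, "n_used": r.n_used,
                            "converged": r.converged, "note": r.note,
                        })
                pd.DataFrame(rows).to_csv(
                    outdir / "association_genotype_models.tsv", sep="\t",
                    index=False, na_rep="NA")
                manifest["outputs"]["assoc"].append(
                    "association_genotype_models.tsv")

        score_res = None
        if "score" in config.stages:
            stage = "score"
            if results is None:
                results = SnpAssociationModel(matrix, cohort, panel).fit()
            score_model = RiskScoreModel.from_association(results,
                                                          alpha=config.alpha)
            score_res = score_model.fit()
            sv = score_res.scores.scores.rename("score")
            sv.to_frame().to_csv(outdir / "scores.tsv", sep="\t", na_rep="NA")
            counts = score_res.quartiles.counts
            ctrl = [int(counts.loc[q, 0]) if q in counts.index else 0
                    for q in (1, 2, 3, 4)]
            case = [int(counts.loc[q, 1]) if q in counts.index else 0
                    for q in (1, 2, 3, 4)]
            smin = int(score_res.scores.complete().min())
            smax = int(score_res.scores.complete().max())
            t3 = render_quartile_table(
                ctrl, case, score_res.quartiles.per_quartile,
                score_res.quartiles.trend_p,
                labels=score_res.cuts.labels(smin, smax))
            t3.to_csv(outdir / "score_quartiles.tsv", sep="\t", na_rep="NA")
            definition = score_res.model.definition
            with open(outdir / "score_definition.json", "w") as fh:
                json.dump({
                    "snp_ids": list(definition.snp_ids),
                    "orientation": dict(definition.orientation),
                    "n_autosomal": definition.n_autosomal,
                    "n_x": definition.n_x,
                    "quartile_cuts": list(score_res.cuts.as_tuple()),
                }, fh, indent=2, sort_keys=True)
            manifest["outputs"]["score"] = ["scores.tsv",
                                            "score_quartiles.tsv",
                                            "score_definition.json"]

        if "predict" in config.stages:
            stage = "predict"
            if score_res is None:
                raise RuntimeError("predict stage requires the score stage")
            scores_f = score_res.scores.scores.astype("Float64").astype(float)
            pred = RiskPredictionModel(
                scores_f, cohort.status_series(), cohort.age_series(),
                cohort.fh_series("fh_prostate")).fit()
            pred.auc_table().to_csv(outdir / "auc.tsv", sep="\t")
            roc_rows = []
            for name, r in pred.rocs.items():
                for fpr, tpr in zip(r.fpr, r.tpr):
                    roc_rows.append({"model": name, "fpr": fpr, "tpr": tpr})
            pd.DataFrame(roc_rows).to_csv(outdir / "roc_points.tsv",
                                          sep="\t", index=False)
            # aggressive-disease variant: aggressive cases vs all controls
            agg = cohort.aggressiveness_series()
            keep = agg.isin(["control", "aggressive"])
            status_agg = (agg[keep] == "aggressive").astype(int)
            pred_agg = RiskPredictionModel(
                scores_f.loc[scores_f.index.intersection(status_agg.index)],
                status_agg, cohort.age_series().loc[status_agg.index],
                cohort.fh_series("fh_prostate").loc[status_agg.index]).fit()
            pred_agg.auc_table().to_csv(outdir / "auc_aggressive.tsv",
                                        sep="\t")
            manifest["outputs"]["predict"] = ["auc.tsv", "roc_points.tsv",
                                              "auc_aggressive.tsv"]

        if "power" in config.stages:
            stage = "power"
            pw_kwargs = dict(config.power)
            pw_kwargs.setdefault("seed", config.seed + 2)
            manifest["seeds"]["power"] = pw_kwargs["seed"]
            pw = simulate_power(PowerConfig(**pw_kwargs))
            pd.DataFrame([{
                "power": pw.power, "ci_low": pw.ci_low, "ci_high": pw.ci_high,
                "n_reps": pw.n_reps,
            }]).to_csv(outdir / "power.tsv", sep="\t", index=False)
            manifest["outputs"]["power"] = ["power.tsv"]
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    root.removeHandler(handler)
    handler.close()
    return manifest
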