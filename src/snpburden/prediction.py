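"""Nested risk-prediction models compared by ROC/AUC (C-statistic).

Three logistic models are fitted on the same subject rows: score only;
age + family history of the disease; and score + age + family history.
Discrimination is the in-sample (apparent) AUC — no cross-validation or
optimism correction, a documented limitation.  The AUC is computed as the
Mann-Whitney pair-count statistic (ties count one half) and equals the
trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .association import _logit

__all__ = [
    "RocResult",
    "roc_auc",
    "fit_prediction_models",
    "compare_auc",
    "RiskPredictionModel",
    "RiskPredictionResults",
]


@dataclass
class RocResult:
    """ROC curve and AUC for one model's predicted scores."""

    model: str
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_cases: int
    n_controls: int

    def trapezoid_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_auc(predicted: pd.Series | np.ndarray, labels: pd.Series | np.ndarray,
            model: str = "model") -> RocResult:
    """AUC by the rank (pair-counting) statistic plus the empirical ROC.

    AUC = (#concordant + 0.5 #tied) / (n_cases × n_controls), computed via
    midranks.  Requires both labels present.
    """
    pred = np.asarray(predicted, dtype=float)
    y = np.asarray(labels, dtype=float)
    if pred.shape != y.shape:
        raise ValueError("predicted and labels must align")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(pred)  # midranks handle ties as 0.5 per pair
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, _ = roc_curve(y, pred)
    return RocResult(model=model, auc=float(auc), fpr=fpr, tpr=tpr,
                     n_cases=n1, n_controls=n0)


def fit_prediction_models(scores: pd.Series, status: pd.Series,
                          age: pd.Series, fh: pd.Series,
                          ) -> dict[str, pd.Series]:
    """Fit the three nested logistic models on identical subject rows.

    Returns predicted case probabilities per model, indexed alike:
    ``score_only`` (score), ``age_fh`` (age + family history), and
    ``full`` (score + age + family history).  Rows are the complete-case
    intersection of all covariates.  Non-convergence raises, naming the
    model.
    """
    df = pd.concat(
        [scores.rename("s"), status.rename("y"), age.rename("age"),
         fh.rename("fh")], axis=1, join="inner",
    ).dropna().astype(float)
    n = len(df)
    y = df["y"].to_numpy()
    designs = {
        "score_only": np.column_stack([np.ones(n), df["s"]]),
        "age_fh": np.column_stack([np.ones(n), df["age"], df["fh"]]),
        "full": np.column_stack([np.ones(n), df["s"], df["age"], df["fh"]]),
    }
    out = {}
    for name, X in designs.items():
        res, conv = _logit(y, X)
        if not conv:
            raise RuntimeError(f"prediction model {name!r} did not converge")
        out[name] = pd.Series(res.predict(X), index=df.index, name=name)
    out["_status"] = df["y"]
    return out


def compare_auc(results: list[RocResult]) -> pd.DataFrame:
    """Table of AUCs and all pairwise differences (no significance test).

    All results must come from identical subject sets (same case/control
    counts are checked as a proxy).
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    sizes = {(r.n_cases, r.n_controls) for r in results}
    if len(sizes) != 1:
        raise ValueError("AUCs computed on mismatched subject sets")
    rows = []
    for r in results:
        row = {"model": r.model, "auc": r.auc}
        for other in results:
            if other.model != r.model:
                row[f"delta_vs_{other.model}"] = r.auc - other.auc
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


class RiskPredictionModel:
    """Nested-model discrimination analysis for a scored cohort."""

    def __init__(self, scores: pd.Series, status: pd.Series, age: pd.Series,
                 fh: pd.Series):
        self.scores = scores
        self.status = status
        self.age = age
        self.fh = fh

    def fit(self) -> "RiskPredictionResults":
        preds = fit_prediction_models(self.scores, self.status, self.age,
                                      self.fh)
        y = preds.pop("_status")
        rocs = {name: roc_auc(p, y, model=name) for name, p in preds.items()}
        return RiskPredictionResults(rocs, y)


class RiskPredictionResults:
    def __init__(self, rocs: dict[str, RocResult], status: pd.Series):
        self.rocs = rocs
        self.status = status

    def auc_table(self) -> pd.DataFrame:
        return compare_auc(list(self.rocs.values()))

    def summary(self) -> str:
        lines = ["In-sample discrimination (apparent AUC):"]
        for name, r in self.rocs.items():
            lines.append(f"  {name}: AUC {r.auc:.3f} "
                         f"({r.n_cases} cases / {r.n_controls} controls)")
        return "\n".join(lines)
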