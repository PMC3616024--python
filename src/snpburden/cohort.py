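"""Phenotype table: case/control status, age, family history, pathology.

Ages mix two definitions by design, mirroring the study questionnaire: age
at diagnosis for cases, age at participation for controls.  Family-history
flags are first-degree relatives with the named cancer.  Pathology
(Gleason score and five report features) exists for cases only; controls
must have it absent.

The aggressiveness composite used throughout subtype analyses is:
Gleason >= 7, OR at least two of {tumor invasiveness, positive surgical
margins, prostate capsule invasion, seminal vesicle involvement, lymph
node involvement}.  Cases with neither Gleason nor any feature recorded
are *unclassifiable* and are excluded from subtype analyses only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FH_COLUMNS",
    "PATH_FEATURES",
    "SubjectRecord",
    "Cohort",
    "CohortError",
    "read_cohort",
    "classify_aggressiveness",
]

FH_COLUMNS = (
    "fh_prostate",
    "fh_lung",
    "fh_colorectal",
    "fh_breast",
    "fh_ovarian",
    "fh_bladder",
)

PATH_FEATURES = (
    "tumor_invasiveness",
    "positive_margins",
    "capsule_invasion",
    "seminal_vesicle",
    "lymph_nodes",
)

NON_AGGRESSIVE = "non_aggressive"
AGGRESSIVE = "aggressive"
UNCLASSIFIABLE = "unclassifiable"


class CohortError(ValueError):
    """Invalid phenotype data."""


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject.

    ``gleason`` is an integer 2–10 or ``None``; ``path_features`` maps the
    five pathology feature names to booleans (``None`` if the pathology
    report is absent).  Controls carry no pathology at all.
    """

    subject_id: str
    status: str  # "case" | "control"
    age: float
    fh: dict[str, bool] = field(default_factory=dict)
    gleason: int | None = None
    path_features: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise CohortError(f"{self.subject_id}: bad status {self.status!r}")
        if not self.age > 0:
            raise CohortError(f"{self.subject_id}: age must be positive")
        if self.gleason is not None and not 2 <= self.gleason <= 10:
            raise CohortError(f"{self.subject_id}: Gleason {self.gleason} outside 2-10")
        if self.status == "control" and (
            self.gleason is not None or self.path_features is not None
        ):
            raise CohortError(
                f"{self.subject_id}: controls cannot carry pathology data"
            )


def classify_aggressiveness(subject: SubjectRecord) -> str:
    """Composite disease-severity label for a case.

    ``aggressive`` iff Gleason >= 7 or at least two of the five pathology
    features are present; ``unclassifiable`` iff Gleason and all features
    are absent; ``non_aggressive`` otherwise.  Pure function; calling it on
    a control is an error.
    """
    if subject.status != "case":
        raise CohortError(
            f"{subject.subject_id}: aggressiveness defined for cases only"
        )
    if subject.gleason is None and subject.path_features is None:
        return UNCLASSIFIABLE
    if subject.gleason is not None and subject.gleason >= 7:
        return AGGRESSIVE
    n_feat = sum(bool(v) for v in (subject.path_features or {}).values())
    return AGGRESSIVE if n_feat >= 2 else NON_AGGRESSIVE


class Cohort:
    """Collection of :class:`SubjectRecord`, keyed by unique subject id."""

    def __init__(self, subjects: Sequence[SubjectRecord]):
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate subject ids")
        self._subjects = list(subjects)
        self._by_id = {s.subject_id: s for s in self._subjects}

    def __len__(self) -> int:
        return len(self._subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self._subjects)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._by_id

    def __getitem__(self, subject_id: str) -> SubjectRecord:
        return self._by_id[subject_id]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self._subjects]

    @property
    def n_cases(self) -> int:
        return sum(1 for s in self._subjects if s.status == "case")

    @property
    def n_controls(self) -> int:
        return sum(1 for s in self._subjects if s.status == "control")

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per subject, booleans as 0/1, missing as NA."""
        rows = []
        for s in self._subjects:
            row: dict[str, object] = {
                "subject_id": s.subject_id,
                "status": s.status,
                "age": s.age,
            }
            for c in FH_COLUMNS:
                row[c] = int(s.fh.get(c, False))
            row["gleason"] = s.gleason
            for f in PATH_FEATURES:
                row[f] = None if s.path_features is None else int(s.path_features[f])
            rows.append(row)
        df = pd.DataFrame(rows).set_index("subject_id")
        df["gleason"] = df["gleason"].astype("Int64")
        for f in PATH_FEATURES:
            df[f] = df[f].astype("Int64")
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        subjects = []
        for sid, row in df.iterrows():
            gleason = row.get("gleason")
            gleason = None if pd.isna(gleason) else int(gleason)
            feats_raw = {f: row.get(f) for f in PATH_FEATURES}
            if all(pd.isna(v) for v in feats_raw.values()):
                feats = None
            else:
                feats = {f: bool(int(v)) if not pd.isna(v) else False
                         for f, v in feats_raw.items()}
            if row["status"] == "control":
                gleason, feats = None, None
            subjects.append(
                SubjectRecord(
                    subject_id=str(sid),
                    status=str(row["status"]),
                    age=float(row["age"]),
                    fh={c: bool(int(row[c])) for c in FH_COLUMNS if c in row},
                    gleason=gleason,
                    path_features=feats,
                )
            )
        return cls(subjects)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")

    # -- derived vectors used by the analysis stages ---------------------

    def status_series(self) -> pd.Series:
        return pd.Series(
            [1 if s.status == "case" else 0 for s in self._subjects],
            index=self.subject_ids, name="status",
        )

    def age_series(self) -> pd.Series:
        return pd.Series([s.age for s in self._subjects],
                         index=self.subject_ids, name="age")

    def fh_series(self, column: str = "fh_prostate") -> pd.Series:
        if column not in FH_COLUMNS:
            raise CohortError(f"unknown family-history column {column!r}")
        return pd.Series(
            [int(s.fh.get(column, False)) for s in self._subjects],
            index=self.subject_ids, name=column,
        )

    def aggressiveness_series(self) -> pd.Series:
        """Per-subject label; controls get the literal ``"control"``."""
        vals = []
        for s in self._subjects:
            vals.append("control" if s.status == "control"
                        else classify_aggressiveness(s))
        return pd.Series(vals, index=self.subject_ids, name="aggressiveness")


def read_cohort(path: str | Path) -> Cohort:
    """Read a phenotype TSV written by :meth:`Cohort.to_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col="subject_id",
                     na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    return Cohort.from_frame(df)
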