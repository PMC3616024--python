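"""Genotype storage, TSV/VCF input, and allele frequencies.

Genotypes are stored as minor-allele dosages: the count of the panel's
designated minor allele per subject and SNP, 0/1/2 for autosomal SNPs and
0/1 for X-linked SNPs in this all-male setting (hemizygous males carry a
single X allele).  Risk-allele orientation is an analysis step and is never
applied at storage time.  Missing genotypes are the literal ``NA`` on disk
and ``NaN`` in memory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import SnpPanel

__all__ = [
    "GenotypeMatrix",
    "GenotypeError",
    "read_genotypes",
    "import_vcf",
    "allele_frequency",
]


class GenotypeError(ValueError):
    """Invalid genotype data (bad dosage, unknown subject/SNP, X violation)."""


class GenotypeMatrix:
    """Subjects × SNPs minor-allele dosage matrix.

    Wraps a float ``pandas.DataFrame`` (``NaN`` = missing) indexed by
    subject id with one column per SNP, validated against a
    :class:`~snpburden.panel.SnpPanel`: autosomal entries in {0, 1, 2},
    X-linked entries in {0, 1} (all-male cohort, hemizygous coding).
    """

    def __init__(self, data: pd.DataFrame, panel: SnpPanel | None = None):
        data = data.astype(float)
        if data.index.has_duplicates:
            raise GenotypeError("duplicate subject ids")
        if data.columns.has_duplicates:
            raise GenotypeError("duplicate SNP columns")
        vals = data.to_numpy()
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid dosage {vals[i, j]!r} at subject "
                f"{data.index[i]!r}, SNP {data.columns[j]!r}"
            )
        if panel is not None:
            unknown = set(data.columns) - set(panel.snp_ids)
            if unknown:
                raise GenotypeError(f"SNP column(s) not in panel: {sorted(unknown)}")
            for sid in panel.x_ids:
                if sid in data.columns and (data[sid] == 2.0).any():
                    subj = data.index[(data[sid] == 2.0)][0]
                    raise GenotypeError(
                        f"X-linked SNP {sid}: dosage 2 for male subject "
                        f"{subj!r}; hemizygous males must be coded 0/1"
                    )
        self._data = data
        self.panel = panel

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def subject_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def dosages(self, snp_id: str) -> pd.Series:
        return self._data[snp_id]

    def missing_fraction(self) -> float:
        return float(self._data.isna().to_numpy().mean())

    def subset_subjects(self, subject_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self._data.loc[list(subject_ids)], self.panel)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        a, b = self._data, other._data
        return (
            a.index.equals(b.index)
            and a.columns.equals(b.columns)
            and ((a.values == b.values) | (np.isnan(a.values) & np.isnan(b.values))).all()
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self._data.copy()
        # integers on disk, NA for missing
        out = out.astype("Int64")
        out.index.name = "subject_id"
        out.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes(
    path: str | Path,
    panel: SnpPanel,
    cohort: "Cohort | None" = None,
) -> GenotypeMatrix:
    """Read a genotype TSV (first column ``subject_id``, cells 0/1/2/NA).

    Columns are validated against ``panel`` and, if given, rows against
    ``cohort``.  Errors cite the offending (subject, SNP) cell.
    """
    df = pd.read_csv(path, sep="\t", index_col="subject_id",
                     na_values=["NA"], keep_default_na=False)
    for col in df.columns:
        ser = df[col]
        nonnum = ser[~ser.isna()]
        try:
            as_float = nonnum.astype(float)
        except (TypeError, ValueError):
            bad = nonnum[~nonnum.astype(str).str.fullmatch(r"[0-9.]+")]
            subj = bad.index[0] if len(bad) else nonnum.index[0]
            raise GenotypeError(
                f"non-integer genotype at subject {subj!r}, SNP {col!r}"
            ) from None
        frac, _ = np.modf(as_float)
        if (frac != 0).any():
            subj = as_float.index[(frac != 0)][0]
            raise GenotypeError(
                f"non-integer genotype at subject {subj!r}, SNP {col!r}"
            )
    df = df.astype(float)
    if cohort is not None:
        unknown = set(df.index) - set(cohort.subject_ids)
        if unknown:
            raise GenotypeError(
                f"subject(s) not in cohort: {sorted(unknown)[:5]}"
            )
    return GenotypeMatrix(df, panel)


def import_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Import genotypes from a VCF (GT field only) for panel SNPs.

    Dosage is the per-call count of the panel's *minor* allele.  The VCF
    REF/ALT pair must equal the panel's {major, minor} set (either order);
    a mismatch is an error naming the SNP.  Records whose ID is not in the
    panel are ignored.  Missing calls (``./.``) become ``NaN``.  Haploid
    calls (X in males) contribute a single allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for rec in vcf:
        sid = rec.ID
        if sid is None or sid not in panel:
            continue
        snp = panel[sid]
        alleles = {rec.REF} | set(rec.ALT)
        expected = {snp.major_allele, snp.minor_allele}
        if alleles != expected:
            raise GenotypeError(
                f"SNP {sid}: VCF alleles {sorted(alleles)} do not match "
                f"panel alleles {sorted(expected)}"
            )
        minor_is_alt = rec.ALT and rec.ALT[0] == snp.minor_allele
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(rec.genotypes):
            calls = [a for a in gt[:-1] if a >= 0]
            if not calls:
                continue
            n_alt = sum(1 for a in calls if a > 0)
            col[i] = n_alt if minor_is_alt else len(calls) - n_alt
        columns[sid] = col
    order = [s for s in panel.snp_ids if s in columns]
    df = pd.DataFrame({s: columns[s] for s in order}, index=pd.Index(samples, name="subject_id"))
    return GenotypeMatrix(df, panel.subset(order) if order else panel)


def allele_frequency(
    matrix: GenotypeMatrix,
    panel: SnpPanel,
    subjects: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP frequency of the designated (panel minor) allele.

    For autosomal SNPs the denominator is two alleles per non-missing
    subject; for X-linked SNPs in this all-male cohort it is one.  Returns a
    frame with columns ``freq``, ``n_subjects`` (non-missing) and
    ``not_minor`` — a flag raised when the designated minor allele has
    frequency > 0.5 in the requested subset.  A SNP with no non-missing
    subjects gets ``freq = NaN`` (flagged absent, never zero).
    """
    data = matrix.data
    if subjects is not None:
        data = data.loc[list(subjects)]
    x_ids = set(panel.x_ids)
    rows = []
    for sid in data.columns:
        col = data[sid].dropna()
        n = len(col)
        if n == 0:
            rows.append({"snp_id": sid, "freq": np.nan, "n_subjects": 0,
                         "not_minor": False})
            continue
        denom = n if sid in x_ids else 2 * n
        freq = float(col.sum()) / denom
        rows.append({"snp_id": sid, "freq": freq, "n_subjects": n,
                     "not_minor": freq > 0.5})
    return pd.DataFrame(rows).set_index("snp_id")
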