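"""SNP panel metadata: per-SNP alleles, frequencies and risk orientation.

A *panel* is the ordered set of candidate SNPs a study genotypes.  Each SNP
carries its chromosome-band label, major/minor allele letters, the minor
allele frequency (MAF) observed in controls, and optionally a published
per-allele odds ratio and p-value from the study that nominated it.  The
panel is pure metadata: genotypes live in
:class:`snpburden.genotypes.GenotypeMatrix`.

A 31-SNP prostate-cancer panel (GWAS-nominated loci, one X-linked) ships
with the package and is returned by :func:`load_gwas_panel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "SnpRecord",
    "SnpPanel",
    "read_panel",
    "load_gwas_panel",
    "PanelError",
]

_VALID_ALLELES = frozenset("ACGT")


class PanelError(ValueError):
    """Malformed panel input (bad allele, duplicate id, MAF out of range)."""


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP.

    Parameters
    ----------
    snp_id : str
        dbSNP identifier (e.g. ``"rs6983267"``).
    chrom_label : str
        Cytogenetic band, e.g. ``"8q24"``; X-linked SNPs start with ``"X"``.
    major_allele, minor_allele : str
        Single-letter allele labels; the minor allele is the rarer one in
        controls and is the allele counted by the stored dosage.
    control_maf : float
        Minor allele frequency among controls, in [0, 0.5].
    published_or : float or None
        Previously reported per-minor-allele odds ratio, if any.
    published_p : float or None
        Previously reported two-sided p-value for the additive model.
    risk_allele : str or None
        ``"minor"`` or ``"major"`` once orientation has been resolved by an
        association fit (or from ``published_or``); ``None`` while
        undetermined.
    """

    snp_id: str
    chrom_label: str
    major_allele: str
    minor_allele: str
    control_maf: float
    published_or: float | None = None
    published_p: float | None = None
    risk_allele: str | None = None

    @property
    def is_x(self) -> bool:
        """True for X-linked SNPs (chromosome label starts with "X")."""
        return self.chrom_label.upper().startswith("X")

    def __post_init__(self) -> None:
        if self.major_allele not in _VALID_ALLELES:
            raise PanelError(
                f"{self.snp_id}: invalid major allele {self.major_allele!r}"
            )
        if self.minor_allele not in _VALID_ALLELES:
            raise PanelError(
                f"{self.snp_id}: invalid minor allele {self.minor_allele!r}"
            )
        if self.major_allele == self.minor_allele:
            raise PanelError(f"{self.snp_id}: major and minor alleles identical")
        if not (0.0 <= self.control_maf <= 0.5):
            raise PanelError(
                f"{self.snp_id}: control MAF {self.control_maf} outside [0, 0.5]"
            )
        if self.published_or is not None and not self.published_or > 0:
            raise PanelError(f"{self.snp_id}: published OR must be positive")
        if self.risk_allele not in (None, "minor", "major"):
            raise PanelError(f"{self.snp_id}: risk_allele must be minor/major/None")

    def risk_allele_frequency(self) -> float:
        """Control frequency of the resolved risk allele.

        Raises if orientation is still undetermined.
        """
        if self.risk_allele is None:
            raise PanelError(f"{self.snp_id}: risk allele undetermined")
        if self.risk_allele == "minor":
            return self.control_maf
        return 1.0 - self.control_maf


class SnpPanel:
    """Ordered, uniquely-keyed collection of :class:`SnpRecord`.

    Iteration order is the input order and is stable across read/write
    round trips.
    """

    def __init__(self, records: Sequence[SnpRecord]):
        ids = [r.snp_id for r in records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelError(f"duplicate snp_id(s): {sorted(dupes)}")
        self._records = list(records)
        self._by_id = {r.snp_id: r for r in self._records}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self._records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def __getitem__(self, snp_id: str) -> SnpRecord:
        try:
            return self._by_id[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpPanel):
            return NotImplemented
        return self._records == other._records

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self._records]

    @property
    def autosomal_ids(self) -> list[str]:
        return [r.snp_id for r in self._records if not r.is_x]

    @property
    def x_ids(self) -> list[str]:
        return [r.snp_id for r in self._records if r.is_x]

    def subset(self, snp_ids: Sequence[str]) -> "SnpPanel":
        """New panel restricted to ``snp_ids``, keeping panel order."""
        keep = set(snp_ids)
        missing = keep - set(self.snp_ids)
        if missing:
            raise PanelError(f"SNP(s) not in panel: {sorted(missing)}")
        return SnpPanel([r for r in self._records if r.snp_id in keep])

    def with_orientation(self, orientation: dict[str, str]) -> "SnpPanel":
        """New panel with ``risk_allele`` set from an orientation map."""
        out = []
        for r in self._records:
            if r.snp_id in orientation:
                out.append(replace(r, risk_allele=orientation[r.snp_id]))
            else:
                out.append(r)
        return SnpPanel(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self._records:
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "chrom": r.chrom_label,
                    "major": r.major_allele,
                    "minor": r.minor_allele,
                    "control_maf": r.control_maf,
                    "published_or": r.published_or,
                    "published_p": r.published_p,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_panel(path: str | Path) -> SnpPanel:
    """Read a SNP panel from a TSV file.

    Expected header columns: ``snp_id``, ``chrom``, ``major``, ``minor``,
    ``control_maf`` and optionally ``published_or`` / ``published_p``.
    X-linkage is derived from the ``chrom`` column.  Errors name the
    offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str,
                                            "major": str, "minor": str},
                     na_values=["NA", ""], keep_default_na=False)
    required = {"snp_id", "chrom", "major", "minor", "control_maf"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file missing column(s): {sorted(missing)}")
    records: list[SnpRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pub_or = getattr(row, "published_or", None)
        pub_p = getattr(row, "published_p", None)
        if pub_or is not None and (isinstance(pub_or, float) and math.isnan(pub_or)):
            pub_or = None
        if pub_p is not None and (isinstance(pub_p, float) and math.isnan(pub_p)):
            pub_p = None
        try:
            records.append(
                SnpRecord(
                    snp_id=row.snp_id,
                    chrom_label=row.chrom,
                    major_allele=row.major,
                    minor_allele=row.minor,
                    control_maf=float(row.control_maf),
                    published_or=None if pub_or is None else float(pub_or),
                    published_p=None if pub_p is None else float(pub_p),
                )
            )
        except PanelError as exc:
            raise PanelError(f"row {i}: {exc}") from None
    try:
        return SnpPanel(records)
    except PanelError as exc:
        raise PanelError(str(exc)) from None


def load_gwas_panel() -> SnpPanel:
    """The packaged 31-SNP prostate-cancer GWAS panel.

    One SNP (rs5945619, Xp11) is X-linked; published per-allele ORs and
    p-values accompany each SNP.
    """
    with resources.as_file(
        resources.files("snpburden.datasets") / "gwas31_panel.tsv"
    ) as p:
        return read_panel(p)
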