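"""Shared in-memory containers and plain-text IO.

The pipeline's central objects are a genotype matrix (sites x individuals,
integer-coded diploid calls) and a panel-label table mapping individuals to
species and geographic class.  Genotype codes double as alternate-allele
dosages:

    -1 missing, 0 hom-ref, 1 het, 2 hom-alt

Coordinates are 0-based half-open everywhere in memory; VCF output is the
only place 1-based positions appear.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

#: columns of a per-site pileup table (allele depths from one subgenome alignment)
PILEUP_COLUMNS = ["scaffold", "pos0", "ref", "alt", "depth", "alt_count"]

#: columns of a panel-label table
LABEL_COLUMNS = ["individual_id", "species", "geo_class", "is_bourbon_typica"]


@dataclasses.dataclass
class PanelLabels:
    """Individual -> species / geographic class / reference-panel flag."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(LABEL_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"label table lacks columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def individuals(self) -> list[str]:
        return list(self.table["individual_id"])

    def species_of(self, individuals: Iterable[str]) -> np.ndarray:
        lookup = dict(zip(self.table["individual_id"], self.table["species"]))
        return np.array([lookup[i] for i in individuals])

    def members(self, species: str) -> list[str]:
        sel = self.table["species"] == species
        return list(self.table.loc[sel, "individual_id"])

    def bourbon_typica(self) -> list[str]:
        sel = self.table["is_bourbon_typica"].astype(bool)
        return list(self.table.loc[sel, "individual_id"])


@dataclasses.dataclass
class GenotypeMatrix:
    """Diploid genotype calls at variant sites.

    ``codes`` has shape (n_sites, n_individuals).  ``sites`` is a DataFrame
    with at least columns ``scaffold``, ``pos0``, ``ref``, ``alt``; extra
    columns (``provenance``, ``truth_kind`` ...) travel along untouched.
    ``informative_nucleotides`` is the number of surveyed bases (monomorphic
    plus polymorphic), the denominator used for per-base diversity.
    """

    individuals: list[str]
    sites: pd.DataFrame
    codes: np.ndarray
    informative_nucleotides: int
    group_informative: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sites), len(self.individuals)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.individuals)} individuals"
            )
        if self.informative_nucleotides < len(self.sites):
            raise ValueError("informative_nucleotides < number of sites")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def column_indices(self, individuals: Iterable[str] | None) -> np.ndarray:
        if individuals is None:
            return np.arange(self.n_individuals)
        pos = {name: i for i, name in enumerate(self.individuals)}
        return np.array([pos[i] for i in individuals], dtype=int)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            individuals=self.individuals,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            codes=self.codes[idx],
            informative_nucleotides=self.informative_nucleotides,
            group_informative=self.group_informative,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, wrap: int = 60) -> None:
    """Write sequences wrapped at ``wrap`` columns (case preserved: lower case
    marks repeat-masked bases)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_pileups(pileups: pd.DataFrame, path: str | Path) -> None:
    pileups.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileups(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "ref": str, "alt": str})
    missing = set(PILEUP_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"pileup table lacks columns: {sorted(missing)}")
    return table


def write_labels(labels: PanelLabels, path: str | Path) -> None:
    labels.table.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> PanelLabels:
    table = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "species": str})
    table["is_bourbon_typica"] = table["is_bourbon_typica"].astype(bool)
    return PanelLabels(table)


# ---------------------------------------------------------------------------
# VCF (v4.2, GT[:DP:AD])
# ---------------------------------------------------------------------------

_GT_OF_CODE = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    depths: np.ndarray | None = None,
    allele_depths: tuple[np.ndarray, np.ndarray] | None = None,
) -> None:
    """Write one VCF record per variant site, 1-based positions.

    ``depths`` (n_sites, n_individuals) and ``allele_depths`` (ref, alt
    arrays of the same shape) populate DP and AD when available.
    """
    header = pysam.VariantHeader()
    header.add_meta("fileformat", "VCFv4.2")
    header.add_meta("informative_nucleotides", str(matrix.informative_nucleotides))
    for scaffold, sub in matrix.sites.groupby("scaffold", sort=False):
        length = int(sub["pos0"].max()) + 2
        header.contigs.add(str(scaffold), length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allele depths")
    for name in matrix.individuals:
        header.add_sample(name)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, row in enumerate(matrix.sites.itertuples(index=False)):
            rec = vcf.new_record(
                contig=str(row.scaffold),
                start=int(row.pos0),
                stop=int(row.pos0) + 1,
                alleles=(str(row.ref), str(row.alt)),
            )
            for j, sample in enumerate(matrix.individuals):
                code = int(matrix.codes[i, j])
                rec.samples[sample]["GT"] = _GT_OF_CODE[code]
                if depths is not None:
                    rec.samples[sample]["DP"] = int(depths[i, j])
                if allele_depths is not None:
                    rec.samples[sample]["AD"] = (
                        int(allele_depths[0][i, j]),
                        int(allele_depths[1][i, j]),
                    )
            vcf.write(rec)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    with pysam.VariantFile(str(path)) as vcf:
        individuals = list(vcf.header.samples)
        informative = None
        for rec in vcf.header.records:
            if rec.key == "informative_nucleotides":
                informative = int(rec.value)
        rows = []
        codes = []
        for rec in vcf:
            rows.append(
                {
                    "scaffold": rec.contig,
                    "pos0": rec.start,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                }
            )
            site_codes = []
            for sample in individuals:
                gt = rec.samples[sample].get("GT", (None, None))
                if gt is None or any(a is None for a in gt):
                    site_codes.append(MISSING)
                else:
                    site_codes.append(int(sum(gt)))
            codes.append(site_codes)
    sites = pd.DataFrame(rows, columns=["scaffold", "pos0", "ref", "alt"])
    codes_arr = np.array(codes, dtype=np.int8).reshape(len(sites), len(individuals))
    if informative is None:
        informative = max(len(sites), 1)
    return GenotypeMatrix(
        individuals=individuals,
        sites=sites,
        codes=codes_arr,
        informative_nucleotides=informative,
    )
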