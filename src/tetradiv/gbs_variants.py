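"""Genotype calling from GBS allele depths and the species-aware filter
cascade.

Calling rule per genotype: a site/individual with fewer than 10 reads is
missing; an allele fraction inside the closed band [0.25, 0.75] is a
heterozygote; outside the band the call is homozygous only when the
minor-allele reads are within a small error allowance (<= 1 read or <= 10%
of depth, whichever is larger), otherwise the call is set missing.

After calling against the two composite references, the merge step keeps
only variant sites on native scaffolds of each subgenome.  Three
species-aware filters then remove alignment artifacts:

* residual homoeologous: all eugenioides hom-ref and all canephora hom-alt
  (or mirrored) — a fixed inter-species difference masquerading as a SNP;
* parent-missing / arabica-het: both parent species entirely missing and
  more than 95% heterozygous calls in arabica;
* reference-panel missing: 7 or 8 missing calls among the 8 Bourbon/Typica
  accessions (read as misalignment).

Each filter reports examined / dropped / retained counts, and the three
species-aware predicates are logically independent, so their relative order
does not change the final retained set.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .containers import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, PanelLabels


@dataclasses.dataclass
class FilterParams:
    min_site_depth: int = 10
    het_af_low: float = 0.25
    het_af_high: float = 0.75
    locus_presence_r: float = 0.75
    parent_fixed_filter: bool = True
    arabica_het_frac: float = 0.95
    reference_panel_max_missing: int = 6  # of the 8 Bourbon/Typica accessions
    hom_error_reads: int = 1
    hom_error_af: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.het_af_low < self.het_af_high < 1:
            raise ValueError("require 0 < het_af_low < het_af_high < 1")
        if not 0 < self.locus_presence_r <= 1:
            raise ValueError("require 0 < locus_presence_r <= 1")


@dataclasses.dataclass
class GenotypeCall:
    state: str  # hom_ref / het / hom_alt / missing
    depth: int
    alt_fraction: float


_STATE_OF_CODE = {MISSING: "missing", HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt"}


def call_genotypes(
    ref_depths: np.ndarray,
    alt_depths: np.ndarray,
    params: FilterParams = FilterParams(),
) -> np.ndarray:
    """Vectorised genotype calling; returns an int8 code array of the same
    shape (missing -1, hom-ref 0, het 1, hom-alt 2)."""
    ref = np.asarray(ref_depths)
    alt = np.asarray(alt_depths)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("allele depths must be non-negative")
    depth = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    allowance = np.maximum(params.hom_error_reads, params.hom_error_af * depth)

    codes = np.full(ref.shape, MISSING, dtype=np.int8)
    enough = depth >= params.min_site_depth
    het = enough & (af >= params.het_af_low) & (af <= params.het_af_high)
    hom_ref = enough & (af < params.het_af_low) & (alt <= allowance)
    hom_alt = enough & (af > params.het_af_high) & (ref <= allowance)
    codes[het] = HET
    codes[hom_ref] = HOM_REF
    codes[hom_alt] = HOM_ALT
    return codes


def call_genotype(ref_depth: int, alt_depth: int, params: FilterParams = FilterParams()) -> GenotypeCall:
    """Single-genotype convenience wrapper around :func:`call_genotypes`."""
    code = call_genotypes(np.array([[ref_depth]]), np.array([[alt_depth]]), params)[0, 0]
    depth = ref_depth + alt_depth
    af = alt_depth / depth if depth > 0 else 0.0
    return GenotypeCall(state=_STATE_OF_CODE[int(code)], depth=int(depth), alt_fraction=float(af))


def is_variant(codes: np.ndarray) -> np.ndarray:
    """Per-site flag: at least one non-missing, non-hom-ref call."""
    return ((codes == HET) | (codes == HOM_ALT)).any(axis=1)


# ---------------------------------------------------------------------------
# Filter report plumbing
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FilterReport:
    """Ordered per-rule bookkeeping; examined = dropped + retained."""

    rows: list[dict] = dataclasses.field(default_factory=list)

    def add(self, rule: str, examined: int, retained: int) -> None:
        self.rows.append(
            {"rule": rule, "examined": examined, "dropped": examined - retained,
             "retained": retained}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rule", "examined", "dropped", "retained"])

    def extend(self, other: "FilterReport") -> None:
        self.rows.extend(other.rows)


# ---------------------------------------------------------------------------
# Dual-reference merge
# ---------------------------------------------------------------------------

def merge_dual_references(
    sites_a: pd.DataFrame,
    codes_a: np.ndarray,
    sites_b: pd.DataFrame,
    codes_b: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Keep native-provenance sites from each run; drop complement and
    unassigned scaffolds; collapse duplicated native sites.

    Each ``sites`` frame needs a ``provenance`` column; a duplicate
    (scaffold, pos0) with conflicting alleles raises.
    """
    frames, code_blocks = [], []
    for sites, codes in ((sites_a, codes_a), (sites_b, codes_b)):
        if "provenance" not in sites.columns:
            raise ValueError("sites need a 'provenance' column")
        keep = (sites["provenance"] == "native").to_numpy()
        frames.append(sites.loc[keep])
        code_blocks.append(codes[keep])
    merged = pd.concat(frames, ignore_index=True)
    codes = np.concatenate(code_blocks, axis=0) if code_blocks else np.empty((0, 0), np.int8)

    key = merged["scaffold"].astype(str) + ":" + merged["pos0"].astype(str)
    first = ~key.duplicated(keep="first")
    dup_groups = merged.loc[~first, ["scaffold", "pos0"]]
    if len(dup_groups):
        lookup = merged.loc[first].set_index(["scaffold", "pos0"])[["ref", "alt"]]
        for row in merged.loc[~first].itertuples(index=False):
            kept = lookup.loc[(row.scaffold, row.pos0)]
            if (kept["ref"], kept["alt"]) != (row.ref, row.alt):
                raise ValueError(
                    f"conflicting alleles at {row.scaffold}:{row.pos0} across references"
                )
    return merged.loc[first].reset_index(drop=True), codes[first.to_numpy()]


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_locus_presence(
    sites: pd.DataFrame,
    codes: np.ndarray,
    r: float,
    n_individuals: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, FilterReport]:
    """Retain sites genotyped in at least ceil(r * n_individuals)
    individuals."""
    if not 0 < r <= 1:
        raise ValueError("r must be in (0, 1]")
    n = n_individuals if n_individuals is not None else codes.shape[1]
    need = math.ceil(r * n)
    keep = (codes != MISSING).sum(axis=1) >= need
    report = FilterReport()
    report.add(f"locus_presence(r={r})", len(sites), int(keep.sum()))
    return sites.loc[keep].reset_index(drop=True), codes[keep], report


def _species_masks(labels: PanelLabels, individuals: list[str]):
    species = labels.species_of(individuals)
    return species == "eugenioides", species == "canephora", species == "arabica"


def residual_homoeologous_mask(codes: np.ndarray, euge: np.ndarray, cane: np.ndarray) -> np.ndarray:
    """True where all non-missing eugenioides calls are hom-ref and all
    non-missing canephora calls hom-alt, or vice versa; both species need at
    least one non-missing call."""
    def _all_state(cols: np.ndarray, state: int) -> tuple[np.ndarray, np.ndarray]:
        sub = codes[:, cols]
        non_missing = sub != MISSING
        has_data = non_missing.any(axis=1)
        conforms = ((sub == state) | ~non_missing).all(axis=1)
        return has_data, conforms

    e_data, e_ref = _all_state(euge, HOM_REF)
    _, e_alt = _all_state(euge, HOM_ALT)
    c_data, c_ref = _all_state(cane, HOM_REF)
    _, c_alt = _all_state(cane, HOM_ALT)
    both = e_data & c_data
    return both & ((e_ref & c_alt) | (e_alt & c_ref))


def filter_residual_homoeologous(
    sites: pd.DataFrame,
    codes: np.ndarray,
    labels: PanelLabels,
    individuals: list[str],
) -> tuple[pd.DataFrame, np.ndarray, FilterReport]:
    euge, cane, _ = _species_masks(labels, individuals)
    drop = residual_homoeologous_mask(codes, euge, cane)
    keep = ~drop
    report = FilterReport()
    report.add("residual_homoeologous", len(sites), int(keep.sum()))
    return sites.loc[keep].reset_index(drop=True), codes[keep], report


def filter_parent_missing_het(
    sites: pd.DataFrame,
    codes: np.ndarray,
    labels: PanelLabels,
    individuals: list[str],
    het_frac: float = 0.95,
) -> tuple[pd.DataFrame, np.ndarray, FilterReport]:
    """Drop sites where both parent species are entirely missing and the
    arabica heterozygote fraction exceeds ``het_frac``."""
    euge, cane, arab = _species_masks(labels, individuals)
    parents = euge | cane
    parents_missing = (codes[:, parents] == MISSING).all(axis=1) if parents.any() else np.ones(len(sites), bool)
    arab_codes = codes[:, arab]
    non_missing = (arab_codes != MISSING).sum(axis=1)
    het = (arab_codes == HET).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(non_missing > 0, het / np.maximum(non_missing, 1), 0.0)
    drop = parents_missing & (frac > het_frac)
    keep = ~drop
    report = FilterReport()
    report.add(f"parent_missing_het(>{het_frac})", len(sites), int(keep.sum()))
    return sites.loc[keep].reset_index(drop=True), codes[keep], report


def filter_reference_panel_missing(
    sites: pd.DataFrame,
    codes: np.ndarray,
    labels: PanelLabels,
    individuals: list[str],
    max_missing: int = 6,
) -> tuple[pd.DataFrame, np.ndarray, FilterReport]:
    """Drop sites with more than ``max_missing`` missing calls among the 8
    Bourbon/Typica reference accessions (7-or-8-of-8 by default)."""
    flagged = set(labels.bourbon_typica())
    cols = np.array([i for i, ind in enumerate(individuals) if ind in flagged])
    if cols.size != 8:
        raise ValueError(f"reference panel needs exactly 8 flagged accessions, found {cols.size}")
    n_missing = (codes[:, cols] == MISSING).sum(axis=1)
    keep = n_missing <= max_missing
    report = FilterReport()
    report.add("reference_panel_missing", len(sites), int(keep.sum()))
    return sites.loc[keep].reset_index(drop=True), codes[keep], report


def run_filter_cascade(
    sites: pd.DataFrame,
    codes: np.ndarray,
    labels: PanelLabels,
    individuals: list[str],
    params: FilterParams = FilterParams(),
    apply_reference_panel: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, FilterReport]:
    """Presence -> residual homoeologous -> parent-missing/het ->
    reference-panel-missing, with a chained report."""
    report = FilterReport()
    sites, codes, r = apply_locus_presence(sites, codes, params.locus_presence_r,
                                           len(individuals))
    report.extend(r)
    if params.parent_fixed_filter:
        sites, codes, r = filter_residual_homoeologous(sites, codes, labels, individuals)
        report.extend(r)
    sites, codes, r = filter_parent_missing_het(sites, codes, labels, individuals,
                                                params.arabica_het_frac)
    report.extend(r)
    if apply_reference_panel:
        sites, codes, r = filter_reference_panel_missing(
            sites, codes, labels, individuals, params.reference_panel_max_missing
        )
        report.extend(r)
    return sites, codes, report


def count_informative_nucleotides(locus_lengths) -> int:
    """Sum of retained GBS locus lengths — the π denominator."""
    return int(sum(int(x) for x in locus_lengths))


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def genotype_experiment(
    experiment,
    params: FilterParams = FilterParams(),
    apply_reference_panel: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Call genotypes against both composite references, merge, and run the
    filter cascade on a :class:`~tetradiv.synthetic_data.GbsExperiment`.

    Returns the surviving variant sites as a GenotypeMatrix (site truth
    columns preserved) plus the filter report.
    """
    individuals = experiment.labels.individuals

    def _run(ref_d, alt_d, provenance_col):
        codes = call_genotypes(ref_d, alt_d, params)
        sites = experiment.sites.copy()
        sites["provenance"] = experiment.sites[provenance_col]
        variant = is_variant(codes)
        return sites.loc[variant].reset_index(drop=True), codes[variant]

    sites_a, codes_a = _run(experiment.ref_depth_a, experiment.alt_depth_a, "provenance_a")
    sites_b, codes_b = _run(experiment.ref_depth_b, experiment.alt_depth_b, "provenance_b")
    merged_sites, merged_codes = merge_dual_references(sites_a, codes_a, sites_b, codes_b)
    report = FilterReport()
    report.add("dual_reference_merge", len(sites_a) + len(sites_b), len(merged_sites))
    out_sites, out_codes, cascade = run_filter_cascade(
        merged_sites, merged_codes, experiment.labels, individuals, params,
        apply_reference_panel=apply_reference_panel,
    )
    report.extend(cascade)
    matrix = GenotypeMatrix(
        individuals=individuals,
        sites=out_sites,
        codes=out_codes,
        informative_nucleotides=max(len(out_sites), 1),
    )
    return matrix, report
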