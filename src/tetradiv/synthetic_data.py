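"""Ground-truth generators for every pipeline input.

The generators emulate an allotetraploid of the *Coffea arabica* kind: two
parental genomes (canephora-like and eugenioides-like) diverged at about
3.1e-2 substitutions per base, a tetraploid that is their union — optionally
carrying a planted homoeologous-replacement segment — repeat-masked
scaffolds, pileups of tetraploid reads against a single subgenome where
homoeologous differences surface at ~0.5 allele fraction, and three-species
genotype panels with target per-base diversities, selfing-driven
heterozygote deficit and missing data.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    PanelLabels,
    write_fasta,
    write_labels,
    write_pileups,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# default inter-subgenome divergence: hemi-SNP diversity between subgenomes
DEFAULT_DIVERGENCE = 3.1e-2


# ---------------------------------------------------------------------------
# Parent genomes and the tetraploid
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ParentGenomePair:
    """Two equal-length parental genomes with shared repeat annotation.

    Repeat intervals are 0-based half-open, sorted, non-overlapping, and
    shared between the two sequences (they mark the same coordinates in
    both).  Masked bases are lower case in the sequences.
    """

    sequence_a: str
    sequence_b: str
    divergence_d: float
    repeat_intervals: list[tuple[int, int]]
    seed: int

    @property
    def length(self) -> int:
        return len(self.sequence_a)


@dataclasses.dataclass
class ReplacementTruth:
    scaffold_id: str  # recipient scaffold
    start: int
    end: int
    donor: str  # donor subgenome name


@dataclasses.dataclass
class TetraploidGenome:
    """Union of two subgenomes with a known homoeolog correspondence.

    Scaffold ``i`` of subgenome A is homoeologous to scaffold ``i`` of
    subgenome B over identical coordinates.
    """

    subgenome_a: dict[str, str]
    subgenome_b: dict[str, str]
    name_a: str = "canephora"
    name_b: str = "eugenioides"
    replacement_truth: ReplacementTruth | None = None

    def subgenome(self, name: str) -> dict[str, str]:
        if name == self.name_a:
            return self.subgenome_a
        if name == self.name_b:
            return self.subgenome_b
        raise ValueError(f"unknown subgenome {name!r}; have {self.name_a!r}, {self.name_b!r}")

    def other_name(self, name: str) -> str:
        self.subgenome(name)
        return self.name_b if name == self.name_a else self.name_a

    def homoeolog_id(self, scaffold_id: str) -> str:
        """Scaffold id of the homoeologous partner (same positional index)."""
        for own, other in (
            (self.subgenome_a, self.subgenome_b),
            (self.subgenome_b, self.subgenome_a),
        ):
            if scaffold_id in own:
                idx = list(own).index(scaffold_id)
                return list(other)[idx]
        raise KeyError(scaffold_id)

    def subgenome_of(self, scaffold_id: str) -> str:
        if scaffold_id in self.subgenome_a:
            return self.name_a
        if scaffold_id in self.subgenome_b:
            return self.name_b
        raise KeyError(scaffold_id)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Per-base independent substitutions at probability ``rate`` (each hit
    goes to one of the three other bases uniformly)."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, out[hits])  # base -> 0..3 (ACGT sorted)
        out[hits] = _BASES[(idx + shift) % 4]
    return out


def _apply_mask(seq: np.ndarray, intervals: Sequence[tuple[int, int]]) -> str:
    text = seq.tobytes().decode("ascii")
    if not intervals:
        return text
    parts = []
    prev = 0
    for start, end in intervals:
        parts.append(text[prev:start])
        parts.append(text[start:end].lower())
        prev = end
    parts.append(text[prev:])
    return "".join(parts)


def simulate_parent_genomes(
    length_bp: int,
    divergence: float = DEFAULT_DIVERGENCE,
    repeat_fraction: float = 0.0,
    seed: int = 0,
    repeat_length: int = 2000,
) -> ParentGenomePair:
    """Simulate two parental genomes diverged by independent substitutions.

    ``repeat_fraction`` of the length is covered by non-overlapping repeat
    intervals of ``repeat_length`` bases (lower-cased in both sequences, at
    shared coordinates).
    """
    if length_bp < 1000:
        raise ValueError("length_bp must be >= 1000")
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    if not 0.0 <= repeat_fraction <= 0.5:
        raise ValueError("repeat_fraction must be in [0, 0.5]")

    rng = np.random.default_rng(seed)
    seq_a = _random_sequence(rng, length_bp)
    seq_b = _mutate(rng, seq_a, divergence)

    intervals: list[tuple[int, int]] = []
    if repeat_fraction > 0:
        n_repeats = max(1, int(round(repeat_fraction * length_bp / repeat_length)))
        # evenly spaced starts keep intervals sorted and non-overlapping
        stride = length_bp // n_repeats
        for i in range(n_repeats):
            start = i * stride
            end = min(start + repeat_length, length_bp)
            if end > start:
                intervals.append((start, end))

    return ParentGenomePair(
        sequence_a=_apply_mask(seq_a, intervals),
        sequence_b=_apply_mask(seq_b, intervals),
        divergence_d=divergence,
        repeat_intervals=intervals,
        seed=seed,
    )


def observed_divergence(pair: ParentGenomePair) -> float:
    """Mismatch fraction outside repeat intervals (the realized d)."""
    a = np.frombuffer(pair.sequence_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(pair.sequence_b.upper().encode(), dtype=np.uint8)
    keep = np.ones(a.size, dtype=bool)
    for start, end in pair.repeat_intervals:
        keep[start:end] = False
    if not keep.any():
        return float("nan")
    return float(np.mean(a[keep] != b[keep]))


def make_tetraploid(
    pair: ParentGenomePair,
    n_scaffolds: int = 1,
    name_a: str = "canephora",
    name_b: str = "eugenioides",
) -> TetraploidGenome:
    """Split the parent pair into homoeologous scaffold sets.

    Scaffolds are contiguous equal slices; scaffold ``i`` of each subgenome
    covers the same parental coordinates, so homoeologs align base-to-base.
    """
    bounds = np.linspace(0, pair.length, n_scaffolds + 1).astype(int)
    sub_a = {
        f"{name_a}_scf{i:04d}": pair.sequence_a[bounds[i]:bounds[i + 1]]
        for i in range(n_scaffolds)
    }
    sub_b = {
        f"{name_b}_scf{i:04d}": pair.sequence_b[bounds[i]:bounds[i + 1]]
        for i in range(n_scaffolds)
    }
    return TetraploidGenome(sub_a, sub_b, name_a=name_a, name_b=name_b)


def plant_replacement(
    genome: TetraploidGenome,
    scaffold_id: str,
    span: tuple[int, int],
    donor: str,
) -> TetraploidGenome:
    """Overwrite ``span`` of the recipient scaffold with the donor homoeolog.

    The recipient scaffold must belong to the subgenome opposite ``donor``.
    An empty span returns the genome unchanged with no truth recorded.
    """
    start, end = span
    recipient_sub = genome.subgenome_of(scaffold_id)
    if recipient_sub == donor:
        raise ValueError("donor subgenome must differ from the recipient's")
    recipient_seq = genome.subgenome(recipient_sub)[scaffold_id]
    if not (0 <= start <= end <= len(recipient_seq)):
        raise ValueError(f"span {span} out of bounds for scaffold of length {len(recipient_seq)}")
    if start == end:
        return genome

    donor_id = genome.homoeolog_id(scaffold_id)
    donor_seq = genome.subgenome(donor)[donor_id]
    new_seq = recipient_seq[:start] + donor_seq[start:end] + recipient_seq[end:]

    sub_a = dict(genome.subgenome_a)
    sub_b = dict(genome.subgenome_b)
    target = sub_a if recipient_sub == genome.name_a else sub_b
    target[scaffold_id] = new_seq
    return TetraploidGenome(
        sub_a,
        sub_b,
        name_a=genome.name_a,
        name_b=genome.name_b,
        replacement_truth=ReplacementTruth(scaffold_id, start, end, donor),
    )


def hemi_site_positions(genome: TetraploidGenome, scaffold_id: str) -> np.ndarray:
    """0-based positions where a scaffold differs from its homoeolog
    (case-insensitive comparison)."""
    other_id = genome.homoeolog_id(scaffold_id)
    own = genome.subgenome(genome.subgenome_of(scaffold_id))[scaffold_id]
    other = genome.subgenome(genome.subgenome_of(other_id))[other_id]
    a = np.frombuffer(own.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(other.upper().encode(), dtype=np.uint8)
    return np.flatnonzero(a != b)


# ---------------------------------------------------------------------------
# Pileups and coverage of tetraploid reads vs one subgenome
# ---------------------------------------------------------------------------

def _replacement_span_on(genome: TetraploidGenome, scaffold_id: str) -> tuple[str, int, int] | None:
    """If a replacement touches this scaffold, return its role and span.

    Role is "recipient" (scaffold lost its own sequence) or "donor"
    (scaffold is the homoeolog whose sequence now exists in four copies).
    """
    truth = genome.replacement_truth
    if truth is None:
        return None
    if scaffold_id == truth.scaffold_id:
        return ("recipient", truth.start, truth.end)
    if scaffold_id == genome.homoeolog_id(truth.scaffold_id):
        return ("donor", truth.start, truth.end)
    return None


def simulate_subgenome_pileups(
    genome: TetraploidGenome,
    target_subgenome: str,
    mean_depth: float = 30.0,
    mismap_rate: float = 0.0,
    error_rate: float = 0.002,
    invariant_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Allele-depth table of tetraploid WGS reads aligned to one subgenome.

    Both subgenomes contribute ~Poisson(mean_depth) reads per site, so total
    depth centers on 2x mean_depth; at homoeologous differences the
    homoeolog's reads carry the alternative base (allele fraction ~0.5).
    Inside a replacement span the recipient scaffold receives ~no reads
    (every read of the quadruplicated donor sequence maps to the donor
    homoeolog, whose depth doubles) and no hemi-SNPs occur.

    ``invariant_fraction`` of the non-divergent positions are also emitted so
    that error-only sites appear in the table.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    scaffolds = genome.subgenome(target_subgenome)  # raises on unknown label
    rng = np.random.default_rng(seed)

    frames = []
    for scaffold_id, seq in scaffolds.items():
        other_id = genome.homoeolog_id(scaffold_id)
        other_seq = genome.subgenome(genome.subgenome_of(other_id))[other_id]
        a = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        b = np.frombuffer(other_seq.upper().encode(), dtype=np.uint8)

        div = np.flatnonzero(a != b)
        positions = div
        if invariant_fraction > 0:
            inv = np.flatnonzero(a == b)
            take = rng.random(inv.size) < invariant_fraction
            positions = np.sort(np.concatenate([div, inv[take]]))
        if positions.size == 0:
            continue
        is_div = np.isin(positions, div, assume_unique=False)

        depth_self = rng.poisson(mean_depth, size=positions.size)
        depth_homo = rng.poisson(mean_depth, size=positions.size)
        role = _replacement_span_on(genome, scaffold_id)
        if role is not None:
            kind, start, end = role
            inside = (positions >= start) & (positions < end)
            if kind == "recipient":
                depth_self = np.where(inside, rng.poisson(mismap_rate * mean_depth, positions.size), depth_self)
                depth_homo = np.where(inside, 0, depth_homo)
            else:  # donor: four identical copies map here
                extra = rng.poisson(2 * mean_depth, size=positions.size)
                depth_self = np.where(inside, depth_self + extra, depth_self)
                depth_homo = np.where(inside, 0, depth_homo)

        alt_from_homo = rng.binomial(depth_homo, 1.0 - error_rate)
        alt_err = rng.binomial(depth_self, error_rate)
        alt_count = np.where(is_div, alt_from_homo + alt_err, rng.binomial(depth_self + depth_homo, error_rate))
        depth = depth_self + depth_homo
        alt_count = np.minimum(alt_count, depth)

        ref_bases = np.array(list(seq.upper()))[positions]
        alt_bases = np.array(list(other_seq.upper()))[positions]
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold_id,
                    "pos0": positions,
                    "ref": ref_bases,
                    "alt": np.where(is_div, alt_bases, "N"),
                    "depth": depth,
                    "alt_count": alt_count,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["scaffold", "pos0", "ref", "alt", "depth", "alt_count"])
    return pd.concat(frames, ignore_index=True)


def simulate_coverage_tracks(
    genome: TetraploidGenome,
    target_subgenome: str,
    mean_depth: float = 30.0,
    window: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean read depth of tetraploid reads in non-overlapping windows of the
    target subgenome (the Fig.-1-style track: ~2x mean_depth baseline, ~4x on
    a replacement donor span, ~0 on a recipient span)."""
    scaffolds = genome.subgenome(target_subgenome)
    rng = np.random.default_rng(seed)
    rows = []
    for scaffold_id, seq in scaffolds.items():
        length = len(seq)
        factor = np.full(length, 2.0)
        role = _replacement_span_on(genome, scaffold_id)
        if role is not None:
            kind, start, end = role
            factor[start:end] = 0.0 if kind == "recipient" else 4.0
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        lam = np.add.reduceat(factor * mean_depth, starts)
        depth = rng.poisson(lam) / (ends - starts)
        for s, e, d in zip(starts, ends, depth):
            rows.append((scaffold_id, int(s), int(e), float(d)))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "depth"])


# ---------------------------------------------------------------------------
# Species genotype panels
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PanelSpec:
    """Target composition of one species' genotype panel.

    ``rare_fraction`` switches the site-frequency model: ``None`` draws every
    site's allele frequency from a rare-skewed Beta; a value w in (0, 1)
    plants w of the sites as young private mutations (carried by exactly one
    individual, occasionally two) and draws the rest from a symmetric Beta
    whose shape is solved so the panel's expected heterozygosity still hits
    ``target_pi`` — the singleton-dominated spectrum of a recently founded
    selfing population.
    """

    species_name: str
    n_individuals: int
    target_pi: float
    selfing_generations: int = 0
    missing_rate: float = 0.0
    n_sites: int = 500
    informative_nucleotides: int = 193_873
    rare_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.rare_fraction is not None and not 0 < self.rare_fraction < 1:
            raise ValueError("rare_fraction must be in (0, 1)")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.target_pi < 0:
            raise ValueError("target_pi must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if self.informative_nucleotides < self.n_sites:
            raise ValueError("informative_nucleotides must be >= n_sites")


def default_panel_specs() -> list[PanelSpec]:
    """The three-species study panel: a large selfing arabica sample and the
    two outcrossing progenitor panels, with per-base diversity targets of
    2.3e-4, 2.6e-3 and 1.1e-3 over a common 193,873-base surveyed footprint."""
    return [
        PanelSpec("arabica", 736, 2.3e-4, selfing_generations=5, missing_rate=0.2,
                  n_sites=652, informative_nucleotides=193_873, rare_fraction=0.84),
        PanelSpec("canephora", 35, 2.6e-3, selfing_generations=0, missing_rate=0.2,
                  n_sites=4000, informative_nucleotides=193_873),
        PanelSpec("eugenioides", 10, 1.1e-3, selfing_generations=0, missing_rate=0.2,
                  n_sites=2000, informative_nucleotides=193_873),
    ]


def _rare_skewed_frequencies(
    rng: np.random.Generator, n_sites: int, mean_het: float, alpha: float = 0.25
) -> np.ndarray:
    """Draw site allele frequencies from Beta(alpha, beta) with beta solved so
    E[2p(1-p)] = mean_het; the larger root keeps the spectrum rare-skewed.
    The best of 20 draws (closest realized sum of 2pq) is returned so the
    panel's expected diversity tracks the target tightly."""

    def expected_het(beta: float) -> float:
        return 2 * alpha * beta / ((alpha + beta) * (alpha + beta + 1))

    peak_b = math.sqrt(alpha * (alpha + 1))
    if mean_het >= expected_het(peak_b):
        raise ValueError(f"mean per-site heterozygosity {mean_het:.3g} unattainable for alpha={alpha}")
    beta = brentq(lambda b: expected_het(b) - mean_het, peak_b, 1e6)

    target_sum = mean_het * n_sites
    best, best_err = None, np.inf
    for _ in range(20):
        p = rng.beta(alpha, beta, size=n_sites)
        err = abs(np.sum(2 * p * (1 - p)) - target_sum)
        if err < best_err:
            best, best_err = p, err
    return best


#: probability that a young private mutation has spread to a second carrier
RARE_TWO_CARRIER = 0.15


def _selfing_transform(rng: np.random.Generator, geno: np.ndarray, generations: int) -> np.ndarray:
    """Replace heterozygotes with homozygotes (random side) with probability
    1 - 2^(-generations): the equilibrium inbreeding of repeated selfing."""
    if generations <= 0:
        return geno
    s = 1.0 - 0.5 ** generations
    het = geno == HET
    fix = het & (rng.random(het.shape) < s)
    to_alt = rng.random(het.shape) < 0.5
    return np.where(fix & to_alt, HOM_ALT, np.where(fix & ~to_alt, HOM_REF, geno))


def _pair_diff_value(copies: int, n_alleles: int) -> float:
    """Unbiased per-site π given a fixed derived-copy count."""
    return 2.0 * copies * (n_alleles - copies) / (n_alleles * (n_alleles - 1))


def _spec_genotypes(rng: np.random.Generator, spec: PanelSpec, n_members: int) -> np.ndarray:
    """Genotype block (n_sites x n_members) realizing the spec's spectrum."""
    mean_het = spec.target_pi * spec.informative_nucleotides / spec.n_sites
    if spec.rare_fraction is None:
        freqs = _rare_skewed_frequencies(rng, spec.n_sites, mean_het)
        u = rng.random((spec.n_sites, n_members, 2))
        geno = (u < freqs[:, None, None]).sum(axis=2).astype(np.int8)
        return _selfing_transform(rng, geno, spec.selfing_generations)

    # mixture: young private mutations + Beta standing variation
    n_alleles = 2 * n_members
    n_rare = int(round(spec.rare_fraction * spec.n_sites))
    n_common = spec.n_sites - n_rare
    f_inbr = 1.0 - 0.5 ** spec.selfing_generations
    v1, v2, v3, v4 = (_pair_diff_value(j, n_alleles) for j in (1, 2, 3, 4))
    e_one = f_inbr * v2 + (1 - f_inbr) * v1
    e_two = (f_inbr**2 * v4 + 2 * f_inbr * (1 - f_inbr) * v3 + (1 - f_inbr) ** 2 * v2)
    e_rare = (1 - RARE_TWO_CARRIER) * e_one + RARE_TWO_CARRIER * e_two

    geno = np.zeros((spec.n_sites, n_members), dtype=np.int8)
    two_carriers = rng.random(n_rare) < RARE_TWO_CARRIER
    for i in range(n_rare):
        carriers = rng.choice(n_members, size=2 if two_carriers[i] else 1, replace=False)
        hom = rng.random(carriers.size) < f_inbr
        geno[i, carriers] = np.where(hom, HOM_ALT, HET)

    if n_common > 0:
        e_common = (mean_het * spec.n_sites - n_rare * e_rare) / n_common
        if not 0 < e_common < 0.5:
            raise ValueError(
                f"target_pi unattainable with rare_fraction={spec.rare_fraction}: "
                f"standing component would need E[2pq]={e_common:.3f}"
            )
        a = e_common / (1.0 - 2.0 * e_common)  # symmetric Beta(a, a) mean het
        freqs = rng.beta(a, a, size=n_common)
        u = rng.random((n_common, n_members, 2))
        common = (u < freqs[:, None, None]).sum(axis=2).astype(np.int8)
        geno[n_rare:] = _selfing_transform(rng, common, spec.selfing_generations)
    return geno


def simulate_species_panels(
    specs: Sequence[PanelSpec],
    homoeo_artifact_rate: float = 0.0,
    seed: int = 0,
    scaffold: str = "canephora_scf0000",
) -> tuple[GenotypeMatrix, PanelLabels]:
    """Generate a multi-species genotype panel with known site truth.

    Each spec contributes a block of sites segregating in that species only
    (other species are homozygous reference, apart from missing data).  A
    fraction ``homoeo_artifact_rate`` of additional sites are planted
    residual-homoeologous artifacts: every non-missing eugenioides call is
    hom-ref and every canephora call hom-alt (or mirrored), with arabica
    heterozygous — exactly the fixed-difference predicate the variant filter
    targets.  Site truth is recorded in the ``truth_kind`` column of
    ``matrix.sites`` (values ``snp`` / ``residual_homoeologous``).

    Selfing replaces heterozygotes with homozygotes with probability
    1 - 2^(-selfing_generations); missingness is uniform per call.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)

    individuals: list[str] = []
    species_of_ind: list[str] = []
    for spec in specs:
        for i in range(spec.n_individuals):
            individuals.append(f"{spec.species_name}_{i:04d}")
            species_of_ind.append(spec.species_name)
    species_arr = np.array(species_of_ind)
    n_ind = len(individuals)

    blocks = []
    truth_kinds = []
    for spec in specs:
        cols = np.flatnonzero(species_arr == spec.species_name)
        block = np.full((spec.n_sites, n_ind), HOM_REF, dtype=np.int8)
        block[:, cols] = _spec_genotypes(rng, spec, cols.size)
        blocks.append(block)
        truth_kinds.extend(["snp"] * spec.n_sites)

    total_snp_sites = sum(spec.n_sites for spec in specs)
    n_artifacts = int(round(homoeo_artifact_rate * total_snp_sites))
    if n_artifacts > 0:
        art = np.full((n_artifacts, n_ind), HOM_REF, dtype=np.int8)
        euge = species_arr == "eugenioides"
        cane = species_arr == "canephora"
        arab = species_arr == "arabica"
        mirrored = rng.random(n_artifacts) < 0.5
        for i in range(n_artifacts):
            art[i, euge] = HOM_ALT if mirrored[i] else HOM_REF
            art[i, cane] = HOM_REF if mirrored[i] else HOM_ALT
            art[i, arab] = HET
        blocks.append(art)
        truth_kinds.extend(["residual_homoeologous"] * n_artifacts)

    codes = np.concatenate(blocks, axis=0)
    # uniform missingness per call, per originating spec's rate (artifacts
    # inherit the first spec's rate)
    rates = np.concatenate(
        [np.full(spec.n_sites, spec.missing_rate) for spec in specs]
        + ([np.full(n_artifacts, specs[0].missing_rate)] if n_artifacts else [])
    )
    drop = rng.random(codes.shape) < rates[:, None]
    codes = np.where(drop, MISSING, codes)

    n_sites_total = codes.shape[0]
    order = rng.permutation(n_sites_total)
    codes = codes[order]
    truth = np.array(truth_kinds)[order]

    ref = np.array(list("ACGT"))[rng.integers(0, 4, n_sites_total)]
    alt_shift = rng.integers(1, 4, n_sites_total)
    base_idx = np.searchsorted(np.array(list("ACGT")), ref)
    alt = np.array(list("ACGT"))[(base_idx + alt_shift) % 4]
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos0": np.arange(n_sites_total) * 97 + 11,
            "ref": ref,
            "alt": alt,
            "provenance": "native",
            "truth_kind": truth,
        }
    )

    geo_classes = ["Landrace cultivated", "Survey Ethiopia", "Yemen", "Bourbon/Typica"]
    geo = [geo_classes[i % len(geo_classes)] for i in range(n_ind)]
    is_bt = np.zeros(n_ind, dtype=bool)
    arab_idx = np.flatnonzero(species_arr == "arabica")
    is_bt[arab_idx[: min(8, arab_idx.size)]] = True
    labels = PanelLabels(
        pd.DataFrame(
            {
                "individual_id": individuals,
                "species": species_of_ind,
                "geo_class": geo,
                "is_bourbon_typica": is_bt,
            }
        )
    )

    common_informative = max(spec.informative_nucleotides for spec in specs)
    matrix = GenotypeMatrix(
        individuals=individuals,
        sites=sites,
        codes=codes,
        informative_nucleotides=common_informative,
        group_informative={s.species_name: s.informative_nucleotides for s in specs},
    )
    return matrix, labels


# ---------------------------------------------------------------------------
# Dual-reference GBS experiment (end-to-end masking-efficacy input)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GbsExperiment:
    """Per-individual allele depths of one GBS run against each composite
    reference, with per-site truth.

    ``sites`` columns include ``provenance_a``/``provenance_b`` (where the
    site surfaces when aligning against composite reference A resp. B:
    ``native``, ``complement`` or ``absent``) and ``truth_kind`` in
    {``snp``, ``hemi_clean``, ``residual_homoeologous``}.
    """

    sites: pd.DataFrame
    ref_depth_a: np.ndarray
    alt_depth_a: np.ndarray
    ref_depth_b: np.ndarray
    alt_depth_b: np.ndarray
    labels: PanelLabels
    true_codes: np.ndarray


def simulate_gbs_experiment(
    n_arabica: int = 200,
    n_canephora: int = 35,
    n_eugenioides: int = 10,
    n_true_snps: int = 400,
    n_hemi_sites: int = 2000,
    residual_rate: float = 0.05,
    mean_depth: float = 30.0,
    dropout_rate: float = 0.1,
    error_rate: float = 0.002,
    seed: int = 0,
    composite: bool = True,
) -> GbsExperiment:
    """Simulate a dual-reference GBS genotyping run.

    True allelic SNPs segregate within arabica (rare-skewed frequencies) and
    live half on canephora-native, half on eugenioides-native scaffolds.
    Homoeologous (hemi) sites are fixed differences between subgenomes: with
    ``composite=True`` the complement absorbs the homoeolog's reads so the
    site yields clean hom-ref calls, except for a ``residual_rate`` fraction
    where the complement substitution failed and the classic artifact
    surfaces (arabica ~0.5 allele fraction, parents fixed opposite).  With
    ``composite=False`` every hemi site shows the artifact pattern —
    the single-reference (no complement) baseline.
    """
    rng = np.random.default_rng(seed)
    species = (["arabica"] * n_arabica + ["canephora"] * n_canephora
               + ["eugenioides"] * n_eugenioides)
    individuals = [f"{sp}_{i:04d}" for i, sp in enumerate(species)]
    species_arr = np.array(species)
    n_ind = len(individuals)
    arab = species_arr == "arabica"
    cane = species_arr == "canephora"
    euge = species_arr == "eugenioides"

    rows = []
    true_codes = []

    # --- true allelic SNPs, segregating in arabica ---
    freqs = _rare_skewed_frequencies(rng, n_true_snps, mean_het=0.12)
    for i in range(n_true_snps):
        native = "canephora" if i % 2 == 0 else "eugenioides"
        rows.append(
            {
                "scaffold": f"{native}_scf{i % 40:04d}",
                "pos0": 100 + i * 53,
                "ref": "A",
                "alt": "G",
                "truth_kind": "snp",
                "native_subgenome": native,
            }
        )
        u = rng.random((n_ind, 2))
        geno = (u < freqs[i]).sum(axis=1).astype(np.int8)
        geno[~arab] = HOM_REF  # private to arabica
        # arabica selfing: most hets fixed
        s = 1.0 - 0.5 ** 5
        het = (geno == HET) & arab
        fix = het & (rng.random(n_ind) < s)
        geno = np.where(fix, np.where(rng.random(n_ind) < 0.5, HOM_ALT, HOM_REF), geno)
        true_codes.append(geno)

    # --- homoeologous sites ---
    n_residual = int(round(residual_rate * n_hemi_sites)) if composite else n_hemi_sites
    residual_flags = np.zeros(n_hemi_sites, dtype=bool)
    residual_flags[rng.choice(n_hemi_sites, size=n_residual, replace=False)] = True
    for i in range(n_hemi_sites):
        native = "canephora" if i % 2 == 0 else "eugenioides"
        kind = "residual_homoeologous" if residual_flags[i] else "hemi_clean"
        rows.append(
            {
                "scaffold": f"{native}_scf{i % 40:04d}",
                "pos0": 25_000 + i * 31,
                "ref": "C",
                "alt": "T",
                "truth_kind": kind,
                "native_subgenome": native,
            }
        )
        true_codes.append(np.full(n_ind, HOM_REF, dtype=np.int8))

    sites = pd.DataFrame(rows)
    true_codes = np.vstack(true_codes)
    n_sites = len(sites)

    def _depths_for_run(run_native: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Allele depths when aligning against the composite reference whose
        native subgenome is ``run_native``.  Returns (ref, alt, provenance)."""
        ref_d = np.zeros((n_sites, n_ind), dtype=np.int64)
        alt_d = np.zeros((n_sites, n_ind), dtype=np.int64)
        provenance = np.empty(n_sites, dtype=object)
        present = rng.random((n_sites, n_ind)) >= dropout_rate
        for i in range(n_sites):
            native = sites.at[i, "native_subgenome"]
            provenance[i] = "native" if native == run_native else "complement"
            kind = sites.at[i, "truth_kind"]
            depth = rng.poisson(mean_depth, n_ind) * present[i]
            if kind == "snp":
                af = np.where(
                    true_codes[i] == HET, 0.5,
                    np.where(true_codes[i] == HOM_ALT, 1.0 - error_rate, error_rate),
                )
                alt = rng.binomial(depth, af)
            else:
                artifact = kind == "residual_homoeologous" or not composite
                if artifact:
                    # both subgenomes of the tetraploid pile up on the native copy
                    depth = depth + arab * rng.poisson(mean_depth, n_ind) * present[i]
                    af = np.zeros(n_ind)
                    af[arab] = 0.5
                    # parents are diploids of one subgenome: the parent matching
                    # the native subgenome reads ref, the other reads alt
                    if native == "canephora":
                        af[cane], af[euge] = error_rate, 1.0 - error_rate
                    else:
                        af[euge], af[cane] = error_rate, 1.0 - error_rate
                    alt = rng.binomial(depth, af)
                else:
                    alt = rng.binomial(depth, error_rate)
            ref_d[i], alt_d[i] = depth - alt, alt
        return ref_d, alt_d, provenance

    ref_a, alt_a, prov_a = _depths_for_run("canephora")
    ref_b, alt_b, prov_b = _depths_for_run("eugenioides")
    sites["provenance_a"] = prov_a
    sites["provenance_b"] = prov_b

    geo = ["collection"] * n_ind
    is_bt = np.zeros(n_ind, dtype=bool)
    is_bt[np.flatnonzero(arab)[:8]] = True
    labels = PanelLabels(
        pd.DataFrame(
            {
                "individual_id": individuals,
                "species": species,
                "geo_class": geo,
                "is_bourbon_typica": is_bt,
            }
        )
    )
    return GbsExperiment(sites, ref_a, alt_a, ref_b, alt_b, labels, true_codes)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixtures(objects: Mapping[str, object], directory: str | Path) -> list[Path]:
    """Write generated objects to plain-text files named after their keys.

    Dispatch by type: ParentGenomePair and TetraploidGenome -> FASTA,
    pileup/track DataFrames -> TSV, (GenotypeMatrix, PanelLabels) handled as
    VCF resp. TSV.  Truth tables are written with a ``truth_`` prefix.
    Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in objects.items():
        if isinstance(obj, ParentGenomePair):
            path = directory / f"{name}.fasta"
            write_fasta({"parent_a": obj.sequence_a, "parent_b": obj.sequence_b}, path)
        elif isinstance(obj, TetraploidGenome):
            path = directory / f"{name}.fasta"
            write_fasta({**obj.subgenome_a, **obj.subgenome_b}, path)
            if obj.replacement_truth is not None:
                tpath = directory / f"truth_{name}_replacement.tsv"
                t = obj.replacement_truth
                pd.DataFrame(
                    [[t.scaffold_id, t.start, t.end, t.donor]],
                    columns=["scaffold", "start", "end", "donor"],
                ).to_csv(tpath, sep="\t", index=False)
                written.append(tpath)
        elif isinstance(obj, GenotypeMatrix):
            path = directory / f"{name}.vcf"
            write_vcf(obj, path)
            if "truth_kind" in obj.sites.columns:
                tpath = directory / f"truth_{name}_sites.tsv"
                obj.sites.to_csv(tpath, sep="\t", index=False)
                written.append(tpath)
        elif isinstance(obj, PanelLabels):
            path = directory / f"{name}.tsv"
            write_labels(obj, path)
        elif isinstance(obj, pd.DataFrame):
            path = directory / f"{name}.tsv"
            if set(["scaffold", "pos0", "depth", "alt_count"]).issubset(obj.columns):
                write_pileups(obj, path)
            else:
                obj.to_csv(path, sep="\t", index=False)
        else:
            raise TypeError(f"no fixture writer for {type(obj).__name__}")
        written.append(path)
    return sorted(written)
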