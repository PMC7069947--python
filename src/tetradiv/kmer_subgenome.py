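"""k-mer counting, spectrum-based depth/genome-size estimation, and
subgenome classification of assembly scaffolds.

An allotetraploid assembly is partitioned by comparing each scaffold's
(repeat-masked) 51-mers against k-mer profiles built from reads of the two
candidate parental species: a scaffold is assigned to the parent it shares
more k-mers with, and left unassigned when too few k-mers are available
(< 1000 by default) or the shared counts are too similar (relative
difference < 10%).

Masked bases are lower case or N; any k-mer window touching one is skipped,
so repeats never contribute to classification.  Canonical k-mers (the
lexicographic minimum of a k-mer and its reverse complement) are used
throughout because sequencing reads are unstranded.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_VALID_RUN = re.compile(r"[ACGT]+")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

UNASSIGNED = "unassigned"


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclasses.dataclass
class KmerProfile:
    """Canonical (or stranded) k-mer counts."""

    k: int
    canonical: bool
    counts: Counter

    @property
    def kmers(self) -> set:
        return set(self.counts)

    @property
    def total_occurrences(self) -> int:
        return sum(self.counts.values())


@dataclasses.dataclass
class KmerSpectrum:
    """Histogram multiplicity -> number of distinct k-mers."""

    k: int
    histogram: dict[int, int]


@dataclasses.dataclass
class DepthEstimate:
    M: float
    L: float
    K: int
    N: float
    genome_size: float | None = None


@dataclasses.dataclass
class SubgenomeCall:
    scaffold_id: str
    shared_a: int
    shared_b: int
    available: int
    label: str
    rel_diff: float


def _iter_sequences(sequences) -> Iterable[str]:
    if isinstance(sequences, str):
        yield sequences
    elif isinstance(sequences, Mapping):
        yield from sequences.values()
    else:
        yield from sequences


def _valid_windows(sequence: str, k: int) -> Iterable[str]:
    """Yield every length-k window over an unmasked A/C/G/T run.  Lower-case
    (repeat-masked) and N bases break runs, so no window touches them."""
    for match in _VALID_RUN.finditer(sequence):
        run = match.group()
        for i in range(len(run) - k + 1):
            yield run[i:i + k]


def count_kmers(sequences, k: int, canonical_kmers: bool = True) -> KmerProfile:
    """Count k-mers over sequences or reads.

    Windows containing non-ACGT symbols (including masked lower-case bases)
    are skipped.  An empty result (k longer than every valid run) is allowed
    but logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    n_seq = 0
    for seq in _iter_sequences(sequences):
        n_seq += 1
        if canonical_kmers:
            for kmer in _valid_windows(seq, k):
                counts[canonical(kmer)] += 1
        else:
            for kmer in _valid_windows(seq, k):
                counts[kmer] += 1
    if n_seq == 0:
        raise ValueError("sequences must be non-empty")
    if not counts:
        logger.warning("no valid %d-mer windows found; profile is empty", k)
    return KmerProfile(k=k, canonical=canonical_kmers, counts=counts)


def scaffold_kmer_set(scaffold: str, k: int, canonical_kmers: bool = True) -> set:
    """Distinct (canonical) k-mers of one scaffold, masked windows excluded."""
    if canonical_kmers:
        return {canonical(kmer) for kmer in _valid_windows(scaffold, k)}
    return set(_valid_windows(scaffold, k))


def kmer_spectrum(profile: KmerProfile) -> KmerSpectrum:
    hist: Counter = Counter(profile.counts.values())
    return KmerSpectrum(k=profile.k, histogram=dict(hist))


def modal_coverage(spectrum: KmerSpectrum, error_multiplicity_cutoff: int = 5) -> int:
    """Multiplicity with the largest distinct-k-mer count among multiplicities
    above the low-multiplicity error peak."""
    candidates = {
        m: c for m, c in spectrum.histogram.items() if m > error_multiplicity_cutoff
    }
    if not candidates:
        raise ValueError(
            f"no spectrum mass above multiplicity cutoff {error_multiplicity_cutoff}"
        )
    # deterministic tie-break: smallest multiplicity among maxima
    best_count = max(candidates.values())
    return min(m for m, c in candidates.items() if c == best_count)


def estimate_depth(M: float, L: float, K: int) -> float:
    """Effective sequencing depth N = M*L/(L-K+1) from the modal k-mer
    multiplicity M, read length L and k-mer length K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if L <= K:
        raise ValueError("read length L must exceed k-mer length K")
    if M <= 0:
        raise ValueError("M must be > 0")
    return M * L / (L - K + 1)


def estimate_genome_size(total_yield_bases: float, N: float) -> float:
    """Genome size = sequencing yield / effective depth N."""
    if N <= 0:
        raise ValueError("N must be > 0")
    return total_yield_bases / N


@dataclasses.dataclass
class ClassifierParams:
    k: int = 51
    min_available: int = 1000
    min_rel_diff: float = 0.10


def classify_scaffold(
    scaffold: str,
    scaffold_id: str,
    profile_a: KmerProfile,
    profile_b: KmerProfile,
    params: ClassifierParams = ClassifierParams(),
) -> SubgenomeCall:
    """Assign one scaffold to subgenome a, subgenome b or leave it
    unassigned.

    available = distinct unmasked k-mers of the scaffold; shared_x = those
    present in profile_x (presence, not multiplicity); rel_diff =
    |shared_a - shared_b| / max(shared_a, shared_b), zero when both are zero.
    Unassigned when available < min_available or rel_diff < min_rel_diff.
    """
    if profile_a.k != profile_b.k or profile_a.canonical != profile_b.canonical:
        raise ValueError("parent profiles must share k and canonicality")
    if profile_a.k != params.k:
        raise ValueError(f"profiles built with k={profile_a.k}, classifier expects k={params.k}")

    kmers = scaffold_kmer_set(scaffold, params.k, profile_a.canonical)
    available = len(kmers)
    shared_a = len(kmers & profile_a.kmers)
    shared_b = len(kmers & profile_b.kmers)
    top = max(shared_a, shared_b)
    rel_diff = abs(shared_a - shared_b) / top if top > 0 else 0.0

    if available < params.min_available or rel_diff < params.min_rel_diff:
        label = UNASSIGNED
    elif shared_a > shared_b:
        label = "subgenome_a"
    else:
        label = "subgenome_b"
    return SubgenomeCall(scaffold_id, shared_a, shared_b, available, label, rel_diff)


def partition_assembly(
    scaffolds: Mapping[str, str],
    profile_a: KmerProfile,
    profile_b: KmerProfile,
    params: ClassifierParams = ClassifierParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every scaffold; return (per-scaffold calls, per-label totals).

    Totals carry scaffold counts and summed lengths per label and conserve
    the assembly totals exactly.
    """
    calls = []
    for scaffold_id, seq in scaffolds.items():
        call = classify_scaffold(seq, scaffold_id, profile_a, profile_b, params)
        calls.append(
            {
                "scaffold_id": scaffold_id,
                "shared_a": call.shared_a,
                "shared_b": call.shared_b,
                "available": call.available,
                "rel_diff": call.rel_diff,
                "label": call.label,
                "length": len(seq),
            }
        )
    report = pd.DataFrame(
        calls,
        columns=["scaffold_id", "shared_a", "shared_b", "available", "rel_diff", "label", "length"],
    )
    if report.empty:
        totals = pd.DataFrame(columns=["label", "count", "total_length"])
    else:
        totals = (
            report.groupby("label")
            .agg(count=("scaffold_id", "size"), total_length=("length", "sum"))
            .reset_index()
        )
    return report, totals


def write_profile(profile: KmerProfile, path: str | Path) -> None:
    """Persist a profile as a sorted two-column TSV (kmer, count)."""
    with open(path, "w") as fh:
        fh.write("kmer\tcount\n")
        for kmer in sorted(profile.counts):
            fh.write(f"{kmer}\t{profile.counts[kmer]}\n")


def read_profile(path: str | Path, canonical_kmers: bool = True) -> KmerProfile:
    table = pd.read_csv(path, sep="\t", dtype={"kmer": str, "count": int})
    counts = Counter(dict(zip(table["kmer"], table["count"])))
    k = len(next(iter(counts))) if counts else 0
    return KmerProfile(k=k, canonical=canonical_kmers, counts=counts)
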