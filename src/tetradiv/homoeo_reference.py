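"""Homoeologous-site detection, composite in-silico references, and
replacement-segment detection.

When whole-genome reads of a tetraploid are aligned against a single
assembled subgenome, fixed differences between subgenomes (hemi-SNPs) show
up as ~0.5-allele-fraction "heterozygous" pileups.  Sites passing a depth
and allele-fraction rule (depth >= 50, AF in [0.25, 0.75]) are taken as
homoeologous; substituting their alternative alleles into the other
subgenome yields a homoeologous complement, and a composite reference
(native subgenome + complement of the other + unassigned scaffolds) gives
reads from either subgenome a near-exact mapping target, suppressing false
allelic SNP calls.

A homoeologous replacement (one subgenome's segment overwritten by its
homoeolog, leaving four identical copies) is detectable as a run of windows
with doubled coverage on the donor homoeolog and a collapse of hemi-SNP
density.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

COMPLEMENT_SUFFIX = "_homoeocomp"


# ---------------------------------------------------------------------------
# Hemi-SNP detection
# ---------------------------------------------------------------------------

def detect_homoeologous_sites(
    pileups: pd.DataFrame,
    min_depth: int = 50,
    af_low: float = 0.25,
    af_high: float = 0.75,
) -> pd.DataFrame:
    """Sites with depth >= min_depth and allele fraction within the closed
    band [af_low, af_high] (the hemi-SNP signature).

    Input must carry the pileup columns (scaffold, pos0, ref, alt, depth,
    alt_count); rows violating 0 <= alt_count <= depth raise with their row
    number.
    """
    required = {"scaffold", "pos0", "ref", "alt", "depth", "alt_count"}
    missing = required - set(pileups.columns)
    if missing:
        raise ValueError(f"pileup table lacks columns: {sorted(missing)}")
    bad = (pileups["alt_count"] < 0) | (pileups["alt_count"] > pileups["depth"])
    if bad.any():
        raise ValueError(f"malformed pileup row {int(np.flatnonzero(bad)[0])}: alt_count outside [0, depth]")

    depth = pileups["depth"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(depth > 0, pileups["alt_count"].to_numpy() / np.maximum(depth, 1), 0.0)
    keep = (depth >= min_depth) & (af >= af_low) & (af <= af_high)
    return pileups.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Complement and composite reference
# ---------------------------------------------------------------------------

def build_complement(
    source_subgenome: Mapping[str, str],
    homoeo_sites: pd.DataFrame,
) -> dict[str, str]:
    """Substitute the alternative homoeologous allele at every homoeologous
    site of the source scaffolds; everything else is copied verbatim.

    The site's ref base must match the source (case-insensitively); a
    mismatch raises naming the site.
    """
    out = {sid: list(seq) for sid, seq in source_subgenome.items()}
    for row in homoeo_sites.itertuples(index=False):
        if row.scaffold not in out:
            raise KeyError(f"homoeologous site on unknown scaffold {row.scaffold!r}")
        seq = out[row.scaffold]
        pos = int(row.pos0)
        if not 0 <= pos < len(seq):
            raise ValueError(f"site {row.scaffold}:{pos} out of scaffold bounds")
        if seq[pos].upper() != str(row.ref).upper():
            raise ValueError(
                f"reference mismatch at {row.scaffold}:{pos}: "
                f"source has {seq[pos]!r}, site says {row.ref!r}"
            )
        base = str(row.alt)
        seq[pos] = base.lower() if seq[pos].islower() else base.upper()
    return {sid: "".join(seq) for sid, seq in out.items()}


@dataclasses.dataclass
class CompositeReference:
    """One subgenome's alignment target: its native scaffolds, the
    homoeologous complement of the other subgenome (ids suffixed with
    ``_homoeocomp``), and the unassigned scaffolds."""

    scaffolds: dict[str, str]
    provenance: dict[str, str]  # scaffold id -> native / complement / unassigned

    def sequences(self, provenance: str) -> dict[str, str]:
        return {
            sid: seq for sid, seq in self.scaffolds.items()
            if self.provenance[sid] == provenance
        }


def assemble_composite_reference(
    native: Mapping[str, str],
    complement: Mapping[str, str],
    unassigned: Mapping[str, str] | None = None,
) -> CompositeReference:
    """Combine native, complement and unassigned scaffold sets.

    Complement ids get the ``_homoeocomp`` suffix so provenance survives a
    round trip through plain FASTA; any id collision raises.
    """
    unassigned = unassigned or {}
    scaffolds: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for group, mapping in (
        ("native", native),
        ("complement", {f"{sid}{COMPLEMENT_SUFFIX}": seq for sid, seq in complement.items()}),
        ("unassigned", unassigned),
    ):
        for sid, seq in mapping.items():
            if sid in scaffolds:
                raise ValueError(f"duplicate scaffold id {sid!r} in composite reference")
            scaffolds[sid] = seq
            provenance[sid] = group
    return CompositeReference(scaffolds, provenance)


def provenance_from_ids(scaffold_ids: Sequence[str], native_ids: set[str]) -> list[str]:
    """Recover provenance labels from suffixed FASTA ids."""
    out = []
    for sid in scaffold_ids:
        if sid.endswith(COMPLEMENT_SUFFIX):
            out.append("complement")
        elif sid in native_ids:
            out.append("native")
        else:
            out.append("unassigned")
    return out


# ---------------------------------------------------------------------------
# Hemi-SNP density and replacement detection
# ---------------------------------------------------------------------------

def hemi_snp_density(
    homoeo_sites: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """Hemi-SNP density (sites per kb) in non-overlapping windows tiling each
    scaffold half-open; scaffolds without sites get all-zero tracks."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    rows = []
    for scaffold, length in scaffold_lengths.items():
        starts = np.arange(0, length, window_bp)
        ends = np.minimum(starts + window_bp, length)
        counts = np.zeros(starts.size, dtype=int)
        if len(homoeo_sites):
            pos = homoeo_sites.loc[homoeo_sites["scaffold"] == scaffold, "pos0"].to_numpy()
            if pos.size:
                idx, c = np.unique(pos // window_bp, return_counts=True)
                counts[idx] = c
        density = counts / ((ends - starts) / 1000.0)
        for s, e, d in zip(starts, ends, density):
            rows.append((scaffold, int(s), int(e), float(d)))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "density"])


@dataclasses.dataclass
class ReplacementSegment:
    scaffold_id: str
    start: int
    end: int
    mean_coverage_ratio: float
    hemi_density: float


@dataclasses.dataclass
class ReplacementParams:
    #: moving-average half-support in windows (25 x 2 kb = 50 kb default)
    smoothing_windows: int = 25
    #: smoothed donor/recipient coverage ratio flagging a duplicated homoeolog
    ratio_threshold: float = 1.5
    #: hemi density must drop below this fraction of the genome median
    density_fraction: float = 0.10
    min_segment_length: int = 100_000


def detect_replacement(
    coverage_donor: pd.DataFrame,
    coverage_recipient: pd.DataFrame,
    hemi_track: pd.DataFrame,
    params: ReplacementParams = ReplacementParams(),
) -> list[ReplacementSegment]:
    """Detect homoeologous-replacement segments from matched window tracks.

    ``coverage_donor`` and ``coverage_recipient`` are per-window mean depths
    of a homoeologous scaffold pair (donor = the subgenome whose sequence is
    duplicated), and ``hemi_track`` the hemi-SNP density on the same window
    grid.  A segment is a maximal run of windows where the smoothed
    donor/recipient coverage ratio >= ratio_threshold AND hemi density <=
    density_fraction x genome-median density, of length >=
    min_segment_length.  Reported coordinates are on the recipient scaffold
    (identical to the donor's homoeologous coordinates).
    """
    segments: list[ReplacementSegment] = []
    if len(coverage_donor) != len(coverage_recipient) or len(coverage_donor) != len(hemi_track):
        raise ValueError("coverage and hemi tracks must cover the same windows")
    median_density = float(np.median(hemi_track["density"])) if len(hemi_track) else 0.0
    density_threshold = params.density_fraction * median_density

    recipient_scaffold = (
        coverage_recipient["scaffold"].iloc[0] if len(coverage_recipient) else ""
    )
    donor_depth = coverage_donor["depth"].to_numpy(dtype=float)
    recip_depth = coverage_recipient["depth"].to_numpy(dtype=float)
    density = hemi_track["density"].to_numpy(dtype=float)

    size = max(1, params.smoothing_windows)
    sm_donor = uniform_filter1d(donor_depth, size=size, mode="nearest")
    sm_recip = uniform_filter1d(recip_depth, size=size, mode="nearest")
    ratio = sm_donor / np.maximum(sm_recip, 1e-9)

    mask = (ratio >= params.ratio_threshold) & (density <= density_threshold)
    starts = coverage_donor["start"].to_numpy()
    ends = coverage_donor["end"].to_numpy()

    i = 0
    n = mask.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        seg_start, seg_end = int(starts[i]), int(ends[j - 1])
        if seg_end - seg_start >= params.min_segment_length:
            seg = slice(i, j)
            segments.append(
                ReplacementSegment(
                    scaffold_id=str(recipient_scaffold),
                    start=seg_start,
                    end=seg_end,
                    mean_coverage_ratio=float(np.mean(ratio[seg])),
                    hemi_density=float(np.mean(density[seg])),
                )
            )
        i = j
    return segments


def segments_to_bed(segments: Sequence[ReplacementSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.scaffold_id, s.start, s.end, f"ratio={s.mean_coverage_ratio:.2f}")
         for s in segments],
        columns=["chrom", "start", "end", "name"],
    )
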