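"""Diversity and frequency-spectrum statistics on genotype matrices.

Per-base nucleotide diversity uses the unbiased pairwise estimator on
allele counts, site π = 2·p̂·q̂·n/(n−1) with n the non-missing allele count
at the site, summed over sites and divided by the number of informative
(surveyed) nucleotides — monomorphic plus polymorphic — so the statistic is
on the per-base scale of whole-locus surveys rather than per-SNP.

Tajima's D follows the 1989 formulas; on genotype matrices the 2N
chromosomes are the sequences and sites with missing data contribute with
their site-specific allele count.  Missing data elsewhere are handled by
per-site complete-case allele counts, except PCA which mean-imputes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, PanelLabels


@dataclasses.dataclass
class DiversityResult:
    pi: float
    segregating_sites: int
    informative_nucleotides: int
    group: str = "all"
    n_all_missing_sites: int = 0


@dataclasses.dataclass
class TajimaResult:
    D: float  # nan when S == 0
    theta_pi: float
    theta_w: float
    n_sequences: int
    segregating_sites: int


@dataclasses.dataclass
class HWEClassification:
    state: str  # conform / het_excess / het_deficit
    p_value: float


def _allele_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (non-missing allele count n, alt-allele count)."""
    non_missing = codes != MISSING
    n = 2 * non_missing.sum(axis=1)
    alt = np.where(non_missing, codes, 0).sum(axis=1)
    return n, alt


def _site_pi(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site π (average pairwise difference) and its n."""
    n, alt = _allele_counts(codes)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        pi = np.where(n > 1, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1), 0.0)
    return pi, n


def _segregating(codes: np.ndarray) -> np.ndarray:
    n, alt = _allele_counts(codes)
    return (alt > 0) & (alt < n)


def _group_codes(matrix: GenotypeMatrix, group: Iterable[str] | None) -> np.ndarray:
    return matrix.codes[:, matrix.column_indices(group)]


def nucleotide_diversity(
    matrix: GenotypeMatrix,
    group: Iterable[str] | None = None,
    informative_nucleotides: int | None = None,
    group_name: str = "all",
) -> DiversityResult:
    """Per-base π for a subset of individuals.

    The denominator defaults to the matrix's informative-nucleotide count
    (or a group-specific value registered by the generator); all-missing
    sites contribute zero and are tallied.
    """
    codes = _group_codes(matrix, group)
    if codes.shape[1] < 2:
        raise ValueError("group must have >= 2 individuals")
    denom = informative_nucleotides
    if denom is None and matrix.group_informative:
        denom = matrix.group_informative.get(group_name)
    if denom is None:
        denom = matrix.informative_nucleotides
    if denom <= 0:
        raise ValueError("informative_nucleotides must be > 0")
    pi, n = _site_pi(codes)
    return DiversityResult(
        pi=float(pi.sum() / denom),
        segregating_sites=int(_segregating(codes).sum()),
        informative_nucleotides=int(denom),
        group=group_name,
        n_all_missing_sites=int((n == 0).sum()),
    )


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


def tajimas_d(matrix: GenotypeMatrix, group: Iterable[str] | None = None) -> TajimaResult:
    """Tajima's D with the 1989 constants.

    θπ is the summed unbiased per-site π, θW = Σ_s 1/a1(n_s) over segregating
    sites with site-specific allele counts n_s, and the variance constants
    use the rounded mean n over segregating sites (for complete data this is
    exactly the textbook computation).  S = 0 yields D = nan, flagged rather
    than zero.
    """
    codes = _group_codes(matrix, group)
    if 2 * codes.shape[1] < 4:
        raise ValueError("need >= 4 sequences (2 diploid individuals)")
    seg = _segregating(codes)
    S = int(seg.sum())
    pi_sites, n_sites = _site_pi(codes)
    theta_pi = float(pi_sites.sum())
    if S == 0:
        return TajimaResult(float("nan"), theta_pi, 0.0, 2 * codes.shape[1], 0)

    n_seg = n_sites[seg]
    theta_w = float(np.sum([1.0 / _harmonic(int(m)) for m in n_seg]))
    n = int(round(float(np.mean(n_seg))))

    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    D = (theta_pi - theta_w) / np.sqrt(var) if var > 0 else float("nan")
    return TajimaResult(float(D), theta_pi, theta_w, n, S)


def private_allele_fraction(matrix: GenotypeMatrix, group: Iterable[str] | None = None) -> float:
    """Fraction of segregating sites whose minor (or non-reference) allele is
    carried by exactly one individual, het or hom."""
    codes = _group_codes(matrix, group)
    if codes.shape[1] < 2:
        raise ValueError("group must have >= 2 individuals")
    seg = _segregating(codes)
    if not seg.any():
        return float("nan")
    sub = codes[seg]
    n, alt = _allele_counts(sub)
    alt_is_minor = alt * 2 <= n
    carriers_alt = ((sub == HET) | (sub == HOM_ALT)).sum(axis=1)
    carriers_ref = ((sub == HET) | (sub == HOM_REF)).sum(axis=1)
    carriers = np.where(alt_is_minor, carriers_alt, carriers_ref)
    return float(np.mean(carriers == 1))


def maf_spectrum(
    matrix: GenotypeMatrix,
    group: Iterable[str] | None = None,
    threshold: float = 0.05,
    bins: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Minor-allele-frequency spectrum over segregating sites plus the
    fraction strictly below ``threshold``."""
    codes = _group_codes(matrix, group)
    if codes.shape[1] < 2:
        raise ValueError("group must have >= 2 individuals")
    seg = _segregating(codes)
    sub = codes[seg]
    n, alt = _allele_counts(sub)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    counts, edges = np.histogram(maf, bins=bins, range=(0.0, 0.5))
    total = max(maf.size, 1)
    spectrum = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts,
         "fraction": counts / total}
    )
    below = float(np.mean(maf < threshold)) if maf.size else float("nan")
    return spectrum, below


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_exact_p(n_rr: int, n_ra: int, n_aa: int) -> float:
    """Exact conditional test: probability mass of heterozygote counts no
    more likely than the observed one, given the allele counts."""
    n = n_rr + n_ra + n_aa
    n_a = n_ra + 2 * n_aa  # rare-or-not does not matter: symmetric in alleles
    n_r = 2 * n - n_a

    def log_prob(h: int) -> float:
        # P(het = h | allele counts) ∝ n! / (n_rr! n_ra! n_aa!) * 2^h
        hom_a = (n_a - h) // 2
        hom_r = (n_r - h) // 2
        return (
            gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(h + 1) - gammaln(hom_a + 1)
            + h * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_r + 1) - gammaln(2 * n + 1)
        )

    h_values = [h for h in range(min(n_a, n_r) % 2, min(n_a, n_r) + 1, 2)]
    logs = np.array([log_prob(h) for h in h_values])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    observed = probs[h_values.index(n_ra)]
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


def hwe_classify(n_rr: int, n_ra: int, n_aa: int, alpha: float = 0.05) -> HWEClassification:
    """Classify one site as HWE-conform, heterozygote excess or deficit by
    the exact conditional test at level ``alpha``."""
    total = n_rr + n_ra + n_aa
    if total < 1:
        raise ValueError("need at least one genotype")
    p_val = _hwe_exact_p(n_rr, n_ra, n_aa)
    if p_val >= alpha:
        return HWEClassification("conform", p_val)
    p = (n_ra + 2 * n_aa) / (2 * total)
    expected_het = 2 * p * (1 - p) * total
    state = "het_excess" if n_ra > expected_het else "het_deficit"
    return HWEClassification(state, p_val)


def hwe_class_fractions(
    matrix: GenotypeMatrix,
    group: Iterable[str] | None = None,
    alpha: float = 0.05,
    min_carriers: int = 2,
) -> dict[str, float]:
    """HWE class fractions over segregating sites carried by at least
    ``min_carriers`` individuals (singleton-individual sites are excluded,
    as the test has no power there and the study statistic is defined on
    multi-individual variants)."""
    codes = _group_codes(matrix, group)
    seg = _segregating(codes)
    sub = codes[seg]
    carriers = ((sub == HET) | (sub == HOM_ALT)).sum(axis=1)
    sub = sub[carriers >= min_carriers]
    tallies = {"conform": 0, "het_excess": 0, "het_deficit": 0}
    for row in sub:
        n_rr = int(np.sum(row == HOM_REF))
        n_ra = int(np.sum(row == HET))
        n_aa = int(np.sum(row == HOM_ALT))
        tallies[hwe_classify(n_rr, n_ra, n_aa, alpha).state] += 1
    total = max(sum(tallies.values()), 1)
    return {k: v / total for k, v in tallies.items()}


# ---------------------------------------------------------------------------
# Species partition and PCA
# ---------------------------------------------------------------------------

def species_partition(matrix: GenotypeMatrix, labels: PanelLabels) -> dict[str, int]:
    """Count variant sites by the subset of species in which they segregate
    (both alleles observed among the species' non-missing calls).  Keys are
    '+'-joined sorted species names; sites segregating nowhere are dropped
    so the counts sum to the total of segregating sites."""
    species = labels.species_of(matrix.individuals)
    partition: dict[str, int] = {}
    masks = {sp: species == sp for sp in sorted(set(species))}
    seg_by_species = {sp: _segregating(matrix.codes[:, m]) for sp, m in masks.items()}
    for i in range(matrix.n_sites):
        members = sorted(sp for sp, seg in seg_by_species.items() if seg[i])
        if members:
            key = "+".join(members)
            partition[key] = partition.get(key, 0) + 1
    return partition


def pca(
    matrix: GenotypeMatrix,
    group: Iterable[str] | None = None,
    n_components: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centered genotype dosage matrix (0/1/2, missing calls
    mean-imputed per site).  Returns (coordinates, variance fractions)."""
    codes = _group_codes(matrix, group).astype(float).T  # individuals x sites
    if codes.shape[0] < 3:
        raise ValueError("need >= 3 individuals")
    missing = codes < 0
    col_mean = np.where(
        (~missing).sum(axis=0) > 0,
        np.nansum(np.where(missing, np.nan, codes), axis=0) / np.maximum((~missing).sum(axis=0), 1),
        0.0,
    )
    filled = np.where(missing, col_mean[None, :], codes)
    centered = filled - filled.mean(axis=0, keepdims=True)
    total_var = float(np.sum(centered**2))
    if total_var == 0:
        raise ValueError("degenerate zero-variance genotype matrix")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, s.size)
    coords = u[:, :k] * s[:k]
    var_frac = (s[:k] ** 2) / total_var
    return coords, var_frac


def stats_report(
    matrix: GenotypeMatrix,
    labels: PanelLabels,
    groups: Mapping[str, list[str]] | None = None,
) -> pd.DataFrame:
    """One summary row per group: π, S, informative nt, Tajima's D, private
    fraction, MAF<0.05 fraction."""
    if groups is None:
        groups = {sp: labels.members(sp) for sp in sorted(set(labels.table["species"]))}
    rows = []
    for name, members in groups.items():
        if len(members) < 2:
            continue
        div = nucleotide_diversity(matrix, members, group_name=name)
        taj = tajimas_d(matrix, members)
        _, below = maf_spectrum(matrix, members)
        rows.append(
            {
                "group": name,
                "n_individuals": len(members),
                "pi": div.pi,
                "segregating_sites": div.segregating_sites,
                "informative_nucleotides": div.informative_nucleotides,
                "tajimas_d": taj.D,
                "private_fraction": private_allele_fraction(matrix, members),
                "maf_below_0.05": below,
            }
        )
    return pd.DataFrame(rows)
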