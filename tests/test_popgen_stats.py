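"""Diversity statistics against brute-force oracles and textbook examples."""

import numpy as np
import pandas as pd
import pytest

import tetradiv as td
from tetradiv.containers import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from tetradiv.popgen_stats import hwe_class_fractions, stats_report
from .conftest import random_complete_matrix


def _matrix(codes, informative=100):
    codes = np.asarray(codes, dtype=np.int8)
    sites = pd.DataFrame(
        {"scaffold": "s", "pos0": np.arange(codes.shape[0]), "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(
        individuals=[f"i{j}" for j in range(codes.shape[1])],
        sites=sites,
        codes=codes,
        informative_nucleotides=informative,
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_pi(codes, informative):
    """Average pairwise difference over all chromosome pairs, complete data."""
    total = 0.0
    for site in codes:
        chroms = []
        for g in site:
            chroms += {HOM_REF: [0, 0], HET: [0, 1], HOM_ALT: [1, 1]}[int(g)]
        n = len(chroms)
        diffs = sum(
            chroms[i] != chroms[j] for i in range(n) for j in range(i + 1, n)
        )
        total += diffs / (n * (n - 1) / 2)
    return total / informative


def brute_force_tajimas_d(codes):
    """Tajima (1989) from first principles on complete-data genotypes."""
    n = 2 * codes.shape[1]
    alt = codes.sum(axis=1)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    theta_pi = sum(
        a * (n - a) / (n * (n - 1) / 2) for a in alt[seg]
    )
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    theta_w = S / a1
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (theta_pi - theta_w) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestNucleotideDiversity:
    def test_diploid_pair_single_fixed_difference(self):
        # one diploid pair differing by a hom site over 100 nt: 4 chromosomes,
        # 2 ref / 2 alt, site pi = 2*2*2/(4*3) = 2/3
        m = _matrix([[HOM_REF, HOM_ALT]], informative=100)
        div = td.nucleotide_diversity(m, informative_nucleotides=100)
        assert div.pi == pytest.approx((2 * 2 * 2) / (4 * 3) / 100)

    def test_four_haplotypes_worked_example(self):
        # haplotypes (A,A,T,T) at one site: 4 of 6 pairs differ -> 2/3,
        # over 10 informative nt -> 0.0667
        m = _matrix([[HOM_REF, HOM_ALT]], informative=10)
        div = td.nucleotide_diversity(m)
        assert div.pi == pytest.approx(0.6667 / 10, rel=1e-3)

    def test_monomorphic_matrix(self):
        m = _matrix(np.zeros((5, 4)), informative=50)
        assert td.nucleotide_diversity(m).pi == 0.0

    def test_matches_brute_force_on_complete_data(self, rng):
        for _ in range(10):
            m = random_complete_matrix(rng, rng.integers(2, 10), 30)
            div = td.nucleotide_diversity(m)
            oracle = brute_force_pi(m.codes, m.informative_nucleotides)
            assert div.pi == pytest.approx(oracle, abs=1e-12)

    def test_all_missing_site_counts_zero_and_tallied(self):
        codes = np.array([[MISSING, MISSING], [HOM_REF, HOM_ALT]])
        div = td.nucleotide_diversity(_matrix(codes))
        assert div.n_all_missing_sites == 1

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            td.nucleotide_diversity(_matrix(np.zeros((1, 3))), group=["i0"])


class TestTajimasD:
    def test_balanced_sfs_gives_zero(self):
        # n=4 chromosomes: a1 = 1 + 1/2 + 1/3; SFS proportional to 1/i means
        # 6 singleton + 3 doubleton + 2 tripleton sites -> theta_pi == theta_w
        codes = []
        for count, reps in [(1, 6), (2, 3), (3, 2)]:
            for _ in range(reps):
                site = [HOM_REF, HOM_REF]
                # distribute `count` alt copies over 2 diploids
                site[0] = HOM_ALT if count >= 2 else HET
                if count == 3:
                    site[1] = HET
                codes.append(site)
        res = td.tajimas_d(_matrix(np.array(codes)))
        assert res.D == pytest.approx(0.0, abs=1e-10)

    def test_single_singleton_negative_and_exact(self):
        # n=4, S=1 singleton: hand-computed from the published constants
        codes = np.array([[HET, HOM_REF]])
        res = td.tajimas_d(_matrix(codes))
        n = 4
        theta_pi = 1 * 3 / 6  # one singleton: 3 of 6 pairs differ
        a1 = 11 / 6
        a2 = 1 + 1 / 4 + 1 / 9
        theta_w = 1 / a1
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (theta_pi - theta_w) / np.sqrt(e1)
        assert res.D == pytest.approx(expected, abs=1e-12)
        assert res.D < 0

    def test_intermediate_excess_positive(self):
        codes = np.tile([HOM_REF, HOM_ALT, HET, HET], (8, 1))
        assert td.tajimas_d(_matrix(codes)).D > 0

    def test_no_segregation_flagged_not_zero(self):
        res = td.tajimas_d(_matrix(np.zeros((3, 4))))
        assert np.isnan(res.D) and res.segregating_sites == 0

    def test_matches_independent_implementation(self, rng):
        for _ in range(20):
            m = random_complete_matrix(rng, int(rng.integers(2, 11)), 50)
            res = td.tajimas_d(m)
            assert res.D == pytest.approx(brute_force_tajimas_d(m.codes), abs=1e-10)


class TestPrivateAlleles:
    def test_three_of_four_singletons(self):
        codes = np.array(
            [
                [HET, HOM_REF, HOM_REF],   # singleton
                [HOM_ALT, HOM_REF, HOM_REF],  # singleton (2 copies, 1 individual)
                [HET, HET, HOM_REF],       # shared
                [HET, HOM_REF, HOM_REF],   # singleton
            ]
        )
        assert td.private_allele_fraction(_matrix(codes)) == pytest.approx(0.75)

    def test_all_shared(self):
        codes = np.tile([HET, HET, HOM_REF], (4, 1))
        assert td.private_allele_fraction(_matrix(codes)) == 0.0

    def test_matches_exhaustive_scan(self, rng):
        m = random_complete_matrix(rng, 8, 60)
        expected_hits = 0
        total = 0
        for site in m.codes:
            alt = site.sum()
            n = 2 * site.size
            if alt == 0 or alt == n:
                continue
            total += 1
            minor_is_alt = 2 * alt <= n
            if minor_is_alt:
                carriers = int(((site == HET) | (site == HOM_ALT)).sum())
            else:
                carriers = int(((site == HET) | (site == HOM_REF)).sum())
            expected_hits += carriers == 1
        assert td.private_allele_fraction(m) == pytest.approx(expected_hits / total)


class TestMafSpectrum:
    def test_threshold_strict(self):
        codes = np.zeros((2, 700), dtype=np.int8)
        codes[0, 0] = HET          # MAF 1/1400 -> counted
        codes[1, :350] = HOM_ALT   # MAF 0.5 -> not counted
        _, below = td.maf_spectrum(_matrix(codes))
        assert below == pytest.approx(0.5)

    def test_bins_normalised(self, rng):
        m = random_complete_matrix(rng, 10, 50)
        spectrum, _ = td.maf_spectrum(m)
        assert spectrum["fraction"].sum() == pytest.approx(1.0)


class TestHWE:
    @pytest.mark.parametrize(
        "counts,state",
        [((25, 50, 25), "conform"), ((50, 0, 50), "het_deficit"), ((0, 100, 0), "het_excess")],
    )
    def test_textbook_classes(self, counts, state):
        assert td.hwe_classify(*counts).state == state

    def test_exact_p_matches_rational_enumeration(self):
        import math

        def levene_p(n_rr, n_ra, n_aa):
            n = n_rr + n_ra + n_aa
            na = n_ra + 2 * n_aa
            nr = 2 * n - na
            def prob(h):
                return (
                    math.factorial(n)
                    / (math.factorial((nr - h) // 2) * math.factorial(h) * math.factorial((na - h) // 2))
                    * 2**h
                    * math.factorial(na) * math.factorial(nr) / math.factorial(2 * n)
                )
            hs = range(min(na, nr) % 2, min(na, nr) + 1, 2)
            probs = {h: prob(h) for h in hs}
            obs = probs[n_ra]
            return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))

        for counts in [(5, 2, 3), (10, 5, 1), (3, 3, 3), (7, 0, 1)]:
            ours = td.hwe_classify(*counts).p_value
            assert ours == pytest.approx(levene_p(*counts), rel=1e-9)

    def test_selfing_panel_modal_class_is_het_deficit(self, small_panel):
        matrix, labels = small_panel
        clean = matrix.take_sites(matrix.sites["truth_kind"].to_numpy() == "snp")
        fractions = hwe_class_fractions(clean, labels.members("arabica"))
        assert fractions["het_deficit"] == max(fractions.values())

    def test_selfing_panel_private_fraction_exceeds_half(self, small_panel):
        matrix, labels = small_panel
        clean = matrix.take_sites(matrix.sites["truth_kind"].to_numpy() == "snp")
        assert td.private_allele_fraction(clean, labels.members("arabica")) > 0.5


class TestSpeciesPartition:
    def test_partition_bins_and_conservation(self, small_panel):
        matrix, labels = small_panel
        partition = td.species_partition(matrix, labels)
        from tetradiv.popgen_stats import _segregating

        species = labels.species_of(matrix.individuals)
        any_seg = np.zeros(matrix.n_sites, dtype=bool)
        for sp in ("arabica", "canephora", "eugenioides"):
            any_seg |= _segregating(matrix.codes[:, species == sp])
        assert sum(partition.values()) == int(any_seg.sum())
        # species-private blocks dominate in this generator
        assert partition.get("arabica", 0) > 0 and partition.get("canephora", 0) > 0

    def test_single_species_site(self):
        labels = td.PanelLabels(
            pd.DataFrame(
                [["a1", "arabica", "x", False], ["a2", "arabica", "x", False],
                 ["c1", "canephora", "x", False], ["c2", "canephora", "x", False]],
                columns=["individual_id", "species", "geo_class", "is_bourbon_typica"],
            )
        )
        codes = np.array([[HET, HOM_REF, HOM_REF, HOM_REF],
                          [HET, HOM_REF, HET, HOM_REF]])
        m = _matrix(codes)
        m.individuals = ["a1", "a2", "c1", "c2"]
        partition = td.species_partition(m, labels)
        assert partition == {"arabica": 1, "arabica+canephora": 1}


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        codes = np.zeros((20, 10), dtype=np.int8)
        codes[:, 5:] = HOM_ALT
        coords, frac = td.pca(_matrix(codes))
        assert np.ptp(np.sign(coords[:5, 0])) == 0
        assert np.all(np.sign(coords[:5, 0]) != np.sign(coords[5:, 0]))
        assert frac[0] > 0.99

    def test_duplicated_individual_identical_coordinates(self, rng):
        m = random_complete_matrix(rng, 6, 30)
        m.codes[:, 3] = m.codes[:, 2]
        coords, _ = td.pca(m)
        assert np.allclose(coords[2], coords[3])

    def test_variance_fractions_match_dense_eigendecomposition(self, rng):
        m = random_complete_matrix(rng, 10, 20)
        _, frac = td.pca(m)
        x = m.codes.astype(float).T
        x -= x.mean(axis=0)
        eig = np.linalg.eigvalsh(x @ x.T)[::-1]
        expected = eig[: len(frac)] / np.sum(x**2)
        assert np.allclose(np.sort(frac)[::-1], np.sort(expected[: len(frac)])[::-1], atol=1e-10)
        assert np.all(np.diff(frac) <= 1e-12) and frac.sum() <= 1 + 1e-9

    def test_zero_variance_degenerate(self):
        with pytest.raises(ValueError):
            td.pca(_matrix(np.zeros((5, 4))))


def test_stats_report_covers_all_species(small_panel):
    matrix, labels = small_panel
    report = stats_report(matrix, labels)
    assert set(report["group"]) == {"arabica", "canephora", "eugenioides"}
    assert (report["pi"] > 0).all()
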