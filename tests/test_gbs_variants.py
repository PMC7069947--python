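"""Genotype calling rules, dual-reference merge and the filter cascade."""

import numpy as np
import pandas as pd
import pytest

import tetradiv as td
from tetradiv.containers import HET, HOM_ALT, HOM_REF, MISSING, PanelLabels
from tetradiv.gbs_variants import (
    FilterParams,
    call_genotypes,
    filter_parent_missing_het,
    filter_reference_panel_missing,
    filter_residual_homoeologous,
    genotype_experiment,
    is_variant,
)


class TestCallGenotype:
    @pytest.mark.parametrize(
        "ref,alt,state",
        [
            (5, 15, "het"),       # AF 0.75 sits inside the closed band
            (15, 5, "het"),       # AF 0.25 likewise
            (4, 5, "missing"),    # depth 9 < 10
            (20, 2, "hom_ref"),   # AF 0.091 with small error allowance
            (2, 20, "hom_alt"),
            (0, 10, "hom_alt"),
            (10, 0, "hom_ref"),
            (16, 4, "missing"),   # AF 0.2: outside band, too many alt reads
        ],
    )
    def test_state_rules(self, ref, alt, state):
        assert td.call_genotype(ref, alt).state == state

    def test_negative_depths_rejected(self):
        with pytest.raises(ValueError):
            td.call_genotype(-1, 5)

    def test_vectorised_matches_scalar(self, rng):
        ref = rng.integers(0, 40, size=(30, 6))
        alt = rng.integers(0, 40, size=(30, 6))
        codes = call_genotypes(ref, alt)
        states = {"missing": MISSING, "hom_ref": HOM_REF, "het": HET, "hom_alt": HOM_ALT}
        for i in range(30):
            for j in range(6):
                assert codes[i, j] == states[td.call_genotype(int(ref[i, j]), int(alt[i, j])).state]


def _sites(n, provenance="native"):
    return pd.DataFrame(
        {"scaffold": [f"s{i % 3}" for i in range(n)], "pos0": np.arange(n),
         "ref": "A", "alt": "T", "provenance": provenance}
    )


class TestMerge:
    def test_complement_sites_dropped_and_native_kept(self):
        sa = _sites(4, provenance=["native", "complement", "native", "unassigned"])
        sb = _sites(2, provenance="complement")
        ca = np.full((4, 3), HET, np.int8)
        cb = np.full((2, 3), HET, np.int8)
        merged, codes = td.merge_dual_references(sa, ca, sb, cb)
        assert list(merged["provenance"].unique()) == ["native"]
        assert len(merged) == 2 and codes.shape == (2, 3)

    def test_duplicate_native_site_collapsed(self):
        sa = _sites(2)
        merged, codes = td.merge_dual_references(sa, np.zeros((2, 2), np.int8),
                                                 sa.copy(), np.zeros((2, 2), np.int8))
        assert len(merged) == 2

    def test_conflicting_alleles_raise(self):
        sa = _sites(1)
        sb = _sites(1)
        sb.loc[0, "alt"] = "G"
        with pytest.raises(ValueError, match="conflicting"):
            td.merge_dual_references(sa, np.zeros((1, 2), np.int8), sb, np.zeros((1, 2), np.int8))


class TestLocusPresence:
    def test_ceiling_boundary(self):
        n_ind = 700
        codes = np.full((2, n_ind), HET, np.int8)
        codes[0, 525:] = MISSING  # exactly 525 = ceil(0.75 * 700) present
        codes[1, 524:] = MISSING  # 524 present -> dropped
        sites = _sites(2)
        kept, _, report = td.apply_locus_presence(sites, codes, 0.75)
        assert len(kept) == 1 and kept["pos0"].iloc[0] == 0
        assert report.rows[0]["dropped"] == 1

    def test_r_zero_rejected(self):
        with pytest.raises(ValueError):
            td.apply_locus_presence(_sites(1), np.zeros((1, 4), np.int8), 0.0)


def _labels(n_euge=10, n_cane=35, n_arab=20, n_bt=8):
    rows = []
    for i in range(n_euge):
        rows.append((f"e{i}", "eugenioides", "wild", False))
    for i in range(n_cane):
        rows.append((f"c{i}", "canephora", "wild", False))
    for i in range(n_arab):
        rows.append((f"a{i}", "arabica", "collection", i < n_bt))
    return PanelLabels(pd.DataFrame(rows, columns=["individual_id", "species", "geo_class", "is_bourbon_typica"]))


class TestSpeciesFilters:
    def setup_method(self):
        self.labels = _labels()
        self.individuals = self.labels.individuals
        self.species = self.labels.species_of(self.individuals)

    def _codes(self, euge, cane, arab):
        n = len(self.individuals)
        codes = np.empty((1, n), dtype=np.int8)
        codes[0, self.species == "eugenioides"] = euge
        codes[0, self.species == "canephora"] = cane
        codes[0, self.species == "arabica"] = arab
        return codes

    def test_fixed_difference_dropped(self):
        codes = self._codes(HOM_REF, HOM_ALT, HET)
        kept, _, _ = filter_residual_homoeologous(_sites(1), codes, self.labels, self.individuals)
        assert len(kept) == 0
        # mirrored condition fires too
        kept, _, _ = filter_residual_homoeologous(
            _sites(1), self._codes(HOM_ALT, HOM_REF, HET), self.labels, self.individuals
        )
        assert len(kept) == 0

    def test_single_het_parent_breaks_predicate(self):
        codes = self._codes(HOM_REF, HOM_ALT, HET)
        codes[0, np.flatnonzero(self.species == "canephora")[0]] = HET
        kept, _, _ = filter_residual_homoeologous(_sites(1), codes, self.labels, self.individuals)
        assert len(kept) == 1

    def test_all_missing_parent_disables_predicate(self):
        codes = self._codes(MISSING, HOM_ALT, HET)
        kept, _, _ = filter_residual_homoeologous(_sites(1), codes, self.labels, self.individuals)
        assert len(kept) == 1

    def test_parent_missing_het_rule(self):
        # parents all missing + 100% arabica het -> dropped
        codes = self._codes(MISSING, MISSING, HET)
        kept, _, _ = filter_parent_missing_het(_sites(1), codes, self.labels, self.individuals)
        assert len(kept) == 0
        # 50% het retained
        codes = self._codes(MISSING, MISSING, HET)
        arab_cols = np.flatnonzero(self.species == "arabica")
        codes[0, arab_cols[: len(arab_cols) // 2]] = HOM_ALT
        kept, _, _ = filter_parent_missing_het(_sites(1), codes, self.labels, self.individuals)
        assert len(kept) == 1
        # one parent call present -> retained even at 100% het
        codes = self._codes(MISSING, MISSING, HET)
        codes[0, np.flatnonzero(self.species == "canephora")[0]] = HOM_REF
        kept, _, _ = filter_parent_missing_het(_sites(1), codes, self.labels, self.individuals)
        assert len(kept) == 1

    @pytest.mark.parametrize("n_missing,kept", [(8, 0), (7, 0), (6, 1), (0, 1)])
    def test_reference_panel_missing_boundary(self, n_missing, kept):
        codes = self._codes(HOM_REF, HOM_REF, HET)
        bt_cols = [i for i, ind in enumerate(self.individuals)
                   if ind in set(self.labels.bourbon_typica())]
        codes[0, bt_cols[:n_missing]] = MISSING
        out, _, _ = filter_reference_panel_missing(_sites(1), codes, self.labels, self.individuals)
        assert len(out) == kept

    def test_reference_panel_needs_exactly_eight(self):
        labels = _labels(n_bt=5)
        codes = np.zeros((1, len(labels.individuals)), np.int8)
        with pytest.raises(ValueError):
            filter_reference_panel_missing(_sites(1), codes, labels, labels.individuals)


@pytest.fixture(scope="module")
def experiment():
    return td.simulate_gbs_experiment(
        n_arabica=60, n_true_snps=150, n_hemi_sites=400, seed=5
    )


class TestCascadeProperties:

    def test_report_conserves_counts(self, experiment):
        _, report = genotype_experiment(experiment)
        for row in report.rows:
            assert row["examined"] == row["dropped"] + row["retained"]

    def test_species_filters_order_independent(self, experiment):
        from tetradiv.gbs_variants import call_genotypes, merge_dual_references
        codes_a = call_genotypes(experiment.ref_depth_a, experiment.alt_depth_a)
        sites = experiment.sites.copy()
        sites["provenance"] = sites["provenance_a"]
        var = is_variant(codes_a)
        sites, codes = sites.loc[var].reset_index(drop=True), codes_a[var]
        labels, inds = experiment.labels, experiment.labels.individuals

        orders = [
            (filter_residual_homoeologous, filter_parent_missing_het),
            (filter_parent_missing_het, filter_residual_homoeologous),
        ]
        results = []
        for f1, f2 in orders:
            s, c, _ = f1(sites, codes, labels, inds)
            s, c, _ = f2(s, c, labels, inds)
            results.append(set(zip(s["scaffold"], s["pos0"])))
        assert results[0] == results[1]

    def test_filters_idempotent(self, experiment):
        matrix, _ = genotype_experiment(experiment)
        sites, codes = matrix.sites, matrix.codes
        labels, inds = experiment.labels, matrix.individuals
        for f in (filter_residual_homoeologous, filter_parent_missing_het):
            s1, c1, _ = f(sites, codes, labels, inds)
            s2, c2, _ = f(s1, c1, labels, inds)
            assert len(s1) == len(s2) and np.array_equal(c1, c2)

    def test_artifact_removal_and_snp_retention(self, experiment):
        matrix, _ = genotype_experiment(experiment)
        hemi_total = int((experiment.sites["truth_kind"] != "snp").sum())
        surviving_artifacts = int((matrix.sites["truth_kind"] != "snp").sum())
        assert surviving_artifacts <= 0.01 * hemi_total
        truly_seg = ((experiment.true_codes > 0).any(axis=1)
                     & (experiment.sites["truth_kind"] == "snp").to_numpy())
        kept = set(zip(matrix.sites["scaffold"], matrix.sites["pos0"]))
        all_keys = list(zip(experiment.sites["scaffold"], experiment.sites["pos0"]))
        retained = np.array([k in kept for k in all_keys])
        assert retained[truly_seg].mean() >= 0.95


class TestInformativeNucleotides:
    def test_uniform_loci(self):
        assert td.count_informative_nucleotides([73] * 100) == 7300

    def test_empty(self):
        assert td.count_informative_nucleotides([]) == 0

    def test_mixed_lengths_exact_sum(self, rng):
        lengths = rng.choice([73, 30], size=500)
        assert td.count_informative_nucleotides(lengths) == int(lengths.sum())
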