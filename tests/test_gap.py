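import itertools
import math

import numpy as np
import pytest

from barcodebin import (
    accumulation_curve,
    build_distance_matrix,
    intra_cluster_summary,
    species_gap_table,
    taxon_summary,
)
from barcodebin.simulate import ScenarioSpec, generate

from conftest import make_assignment, make_dataset


def brute_force_gap_rows(ds, dm):
    """Oracle: direct enumeration of all specimen pairs per species."""
    species_of = ds.species_of()
    genus_of = {r.species: r.genus for r in ds.records}
    out = {}
    species_list = []
    for r in ds.records:
        if r.species not in species_list:
            species_list.append(r.species)
    for sp in species_list:
        own = [s for s in dm.ids if species_of[s] == sp]
        intra = [
            dm.distance(a, b)
            for a, b in itertools.combinations(own, 2)
            if not math.isnan(dm.distance(a, b))
        ]
        inter = [
            (dm.distance(a, b), species_of[b])
            for a in own
            for b in dm.ids
            if species_of[b] != sp and not math.isnan(dm.distance(a, b))
        ]
        cong = [
            d for d, other in inter if genus_of[other] == genus_of[sp]
        ]
        nn = min(inter, default=(math.nan, ""))
        out[sp] = {
            "mean_intra": float(np.mean(intra)) if intra else math.nan,
            "max_intra": max(intra) if intra else math.nan,
            "nn_distance": nn[0],
            "nn_species": nn[1],
            "mean_congeneric": float(np.mean(cong)) if cong else math.nan,
        }
    return out


def _approx_or_both_nan(a, b):
    if isinstance(a, float) and math.isnan(a):
        return isinstance(b, float) and math.isnan(b)
    return a == pytest.approx(b, abs=1e-12)


@pytest.fixture(scope="module")
def small_synthetic():
    ds, _ = generate(
        ScenarioSpec(n_species=6, n_genera=2, mean_specimens=4.0, max_specimens=8, seed=21)
    )
    ds = ds.subset(ds.specimen_ids[:28])
    return ds, build_distance_matrix(ds)


class TestSpeciesGapTable:
    def test_singleton_species_has_no_intra_but_has_nn(self):
        ds = make_dataset(
            [
                dict(specimen_id="a1", sequence="ACGT" * 165, species="Genus01 a"),
                dict(specimen_id="b1", sequence="ACGA" * 165, species="Genus01 b"),
            ]
        )
        rows = species_gap_table(build_distance_matrix(ds), ds)
        row = rows[rows["species"] == "Genus01 a"].iloc[0]
        assert math.isnan(row["mean_intra"]) and math.isnan(row["max_intra"])
        assert row["nn_distance"] > 0 and row["nn_species"] == "Genus01 b"

    def test_two_specimens_mean_equals_max(self):
        base = "ACGT" * 165
        ds = make_dataset(
            [
                dict(specimen_id="a1", sequence=base, species="Genus01 a"),
                dict(specimen_id="a2", sequence="G" + base[1:], species="Genus01 a"),
                dict(specimen_id="b1", sequence="TT" + base[2:], species="Genus01 b"),
            ]
        )
        rows = species_gap_table(build_distance_matrix(ds), ds)
        row = rows[rows["species"] == "Genus01 a"].iloc[0]
        assert row["mean_intra"] == pytest.approx(row["max_intra"])
        assert row["mean_intra"] > 0

    def test_rows_equal_brute_force_enumeration(self, small_synthetic):
        ds, dm = small_synthetic
        rows = species_gap_table(dm, ds).set_index("species")
        oracle = brute_force_gap_rows(ds, dm)
        assert set(rows.index) == set(oracle)
        for sp, exp in oracle.items():
            got = rows.loc[sp]
            for col in ("mean_intra", "max_intra", "nn_distance", "mean_congeneric"):
                assert _approx_or_both_nan(got[col], exp[col]), (sp, col)
            if not math.isnan(exp["nn_distance"]):
                assert got["nn_species"] == exp["nn_species"]

    def test_intra_bounded_by_max(self, small_synthetic):
        ds, dm = small_synthetic
        rows = species_gap_table(dm, ds)
        multi = rows[rows["n_specimens"] >= 2]
        assert (multi["mean_intra"] <= multi["max_intra"] + 1e-15).all()


class TestTaxonSummary:
    def test_group_means_equal_weighted_brute_force(self, small_synthetic):
        ds, dm = small_synthetic
        rows = species_gap_table(dm, ds)
        tx = taxon_summary(rows, dm, ds, grouping="genus").set_index("taxon")
        oracle = brute_force_gap_rows(ds, dm)
        genus_of = {r.species: r.genus for r in ds.records}
        species_of = ds.species_of()
        for genus in tx.index:
            sp_in = [sp for sp in oracle if genus_of[sp] == genus]
            exp_intra = np.nanmean([oracle[sp]["mean_intra"] for sp in sp_in])
            exp_nn = np.nanmean([oracle[sp]["nn_distance"] for sp in sp_in])
            # all congeneric specimen pairs, counted once
            ids = [s for s in dm.ids if genus_of[species_of[s]] == genus]
            pairs = [
                dm.distance(a, b)
                for a, b in itertools.combinations(ids, 2)
                if species_of[a] != species_of[b] and not math.isnan(dm.distance(a, b))
            ]
            assert tx.loc[genus, "mean_intra"] == pytest.approx(exp_intra, abs=1e-12)
            assert tx.loc[genus, "mean_nn"] == pytest.approx(exp_nn, abs=1e-12)
            assert tx.loc[genus, "mean_congeneric"] == pytest.approx(
                float(np.mean(pairs)), abs=1e-12
            )

    def test_single_species_group_has_undefined_congeneric_mean(self):
        ds = make_dataset(
            [
                dict(specimen_id="a1", sequence="ACGT" * 165, species="Genus01 a"),
                dict(specimen_id="b1", sequence="TTTT" * 165, species="Genus02 b"),
            ]
        )
        dm = build_distance_matrix(ds)
        rows = species_gap_table(dm, ds)
        tx = taxon_summary(rows, dm, ds, grouping="genus").set_index("taxon")
        assert math.isnan(tx.loc["Genus01", "mean_congeneric"])

    def test_recovers_planted_divergences(self):
        ds, _ = generate(ScenarioSpec(n_species=30, n_genera=3, seed=13))
        dm = build_distance_matrix(ds)
        tx = taxon_summary(species_gap_table(dm, ds), dm, ds, grouping="all")
        assert tx["mean_intra"][0] == pytest.approx(0.007, abs=0.002)
        assert tx["mean_congeneric"][0] == pytest.approx(0.088, rel=0.15)

    def test_invalid_grouping_rejected(self, small_synthetic):
        ds, dm = small_synthetic
        with pytest.raises(ValueError, match="grouping"):
            taxon_summary(species_gap_table(dm, ds), dm, ds, grouping="family")


class TestIntraClusterSummary:
    def test_all_singletons_summarise_zero_clusters(self):
        ds = make_dataset(
            [
                dict(specimen_id="a1", sequence="ACGT" * 165, species="Genus01 a"),
                dict(specimen_id="b1", sequence="TTTT" * 165, species="Genus01 b"),
            ]
        )
        dm = build_distance_matrix(ds)
        ca = make_assignment({"X": {"a1"}, "Y": {"b1"}})
        out = intra_cluster_summary(dm, ca)
        assert out.n_multi_clusters == 0
        assert math.isnan(out.grand_mean_intra)

    def test_three_member_cluster_mean_of_three_pairs(self):
        base = "ACGT" * 165
        ds = make_dataset(
            [
                dict(specimen_id="a1", sequence=base, species="Genus01 a"),
                dict(specimen_id="a2", sequence="G" + base[1:], species="Genus01 a"),
                dict(specimen_id="a3", sequence="GG" + base[2:], species="Genus01 a"),
            ]
        )
        dm = build_distance_matrix(ds)
        ca = make_assignment({"X": {"a1", "a2", "a3"}})
        out = intra_cluster_summary(dm, ca)
        pairs = [dm.distance(*p) for p in (("a1", "a2"), ("a1", "a3"), ("a2", "a3"))]
        assert out.per_cluster["mean_intra"][0] == pytest.approx(np.mean(pairs))
        assert out.per_cluster["max_intra"][0] == pytest.approx(max(pairs))

    def test_cluster_variation_bounded_by_species_variation_when_clusters_refine(
        self, fixture_data
    ):
        """OTUs refine species on the fixture, so within-cluster maxima
        cannot exceed the within-species maxima they are nested in."""
        ds, dm, ca = fixture_data["ds"], fixture_data["dm"], fixture_data["ca"]
        rows = species_gap_table(dm, ds).set_index("species")
        out = intra_cluster_summary(dm, ca)
        species_of = ds.species_of()
        for rec in out.per_cluster.itertuples(index=False):
            members = fixture_data["ca"].clusters[rec.cluster_id]
            species = {species_of[m] for m in members}
            if len(species) == 1:  # nested case only
                sp_max = rows.loc[next(iter(species)), "max_intra"]
                assert rec.max_intra <= sp_max + 1e-12


class TestAccumulationCurve:
    def _tiny(self):
        return make_dataset(
            [
                dict(specimen_id=f"s{i}", sequence="ACGT" * 165, species=sp)
                for i, sp in enumerate(
                    ["Genus01 a"] * 3 + ["Genus01 b"] * 2 + ["Genus02 c"]
                )
            ]
        )

    def test_terminal_value_is_total_richness(self):
        curve = accumulation_curve(self._tiny(), "species", iterations=5, seed=0)
        assert curve.mean_richness[-1] == 3
        assert curve.x[-1] == 6

    def test_monotone_and_bounded(self):
        curve = accumulation_curve(self._tiny(), "species", iterations=20, seed=1)
        assert np.all(np.diff(curve.mean_richness) >= 0)
        assert np.all(curve.per_iteration <= 3)

    def test_fixed_seed_reproducible(self):
        a = accumulation_curve(self._tiny(), "species", iterations=1, seed=7)
        b = accumulation_curve(self._tiny(), "species", iterations=1, seed=7)
        assert np.array_equal(a.per_iteration, b.per_iteration)

    def test_extending_iterations_preserves_earlier_streams(self):
        a = accumulation_curve(self._tiny(), "species", iterations=3, seed=7)
        b = accumulation_curve(self._tiny(), "species", iterations=6, seed=7)
        assert np.array_equal(a.per_iteration, b.per_iteration[:3])

    def test_matches_exact_expectation_oracle(self):
        """Randomised curve agrees with the closed-form expected richness.

        Under uniform random accumulation the expected richness after x of N
        specimens is S - sum_sp C(N - n_sp, x) / C(N, x) (hypergeometric
        absence probabilities); the Monte-Carlo curve must sit within three
        standard errors of it at every x.
        """
        from math import comb

        ds, _ = generate(
            ScenarioSpec(n_species=6, n_genera=2, mean_specimens=3.5, max_specimens=6, seed=3)
        )
        ds = ds.subset(ds.specimen_ids[:20])
        counts = {}
        for r in ds.records:
            counts[r.species] = counts.get(r.species, 0) + 1
        N, S = len(ds), len(counts)
        expected = np.array(
            [
                S - sum(comb(N - n, x) / comb(N, x) for n in counts.values())
                for x in range(1, N + 1)
            ]
        )
        curve = accumulation_curve(ds, "species", iterations=400, seed=5)
        se = curve.per_iteration.std(axis=0) / math.sqrt(curve.iterations)
        diff = np.abs(curve.mean_richness - expected)
        assert np.all(diff <= 3 * np.maximum(se, 1e-9) + 1e-9)

    def test_cluster_labels_require_assignment(self):
        with pytest.raises(ValueError, match="ClusterAssignment"):
            accumulation_curve(self._tiny(), "cluster", iterations=1, seed=0)
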