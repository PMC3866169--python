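import math

import dendropy
import numpy as np
import pytest

from barcodebin import (
    RefinedSingleLinkage,
    assign_cluster_ids,
    build_distance_matrix,
    cluster_dataset,
    mcl_refine,
    neighbor_joining,
    single_linkage_seed,
)
from barcodebin.cluster import mcl_cluster
from barcodebin.distance import DistanceMatrix
from barcodebin.simulate import ScenarioSpec, generate

from conftest import make_assignment


def dm_from_square(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(ids), d, np.full_like(d, 658, dtype=np.int64))


def brute_force_components(ids, d, threshold):
    """Oracle: breadth-first search over the explicit threshold graph."""
    unvisited = set(range(len(ids)))
    comps = []
    while unvisited:
        start = min(unvisited)
        stack, comp = [start], set()
        unvisited.discard(start)
        while stack:
            i = stack.pop()
            comp.add(i)
            for j in list(unvisited):
                if not math.isnan(d[i][j]) and d[i][j] <= threshold:
                    unvisited.discard(j)
                    stack.append(j)
        comps.append(frozenset(ids[i] for i in comp))
    return set(comps)


class TestSingleLinkage:
    def test_pair_links_and_distant_singleton(self):
        dm = dm_from_square("ABC", [[0, 0.010, 0.050], [0.010, 0, 0.050], [0.050, 0.050, 0]])
        ca = single_linkage_seed(dm, 0.022)
        assert set(map(frozenset, ca.clusters.values())) == {
            frozenset("AB"),
            frozenset("C"),
        }

    def test_all_distances_above_threshold_gives_singletons(self):
        dm = dm_from_square("ABC", [[0, 0.1, 0.1], [0.1, 0, 0.1], [0.1, 0.1, 0]])
        ca = single_linkage_seed(dm, 0.022)
        assert len(ca) == 3

    def test_chaining_joins_despite_large_end_to_end_distance(self):
        dm = dm_from_square("ABC", [[0, 0.02, 0.04], [0.02, 0, 0.02], [0.04, 0.02, 0]])
        ca = single_linkage_seed(dm, 0.022)
        assert set(ca.clusters.values()) == {frozenset("ABC")}

    def test_undefined_distances_are_non_edges(self):
        nan = math.nan
        dm = dm_from_square("AB", [[0, nan], [nan, 0]])
        assert len(single_linkage_seed(dm, 0.022)) == 2

    def test_empty_matrix_gives_empty_assignment(self):
        dm = DistanceMatrix([], np.zeros((0, 0)), np.zeros((0, 0), dtype=np.int64))
        assert len(single_linkage_seed(dm, 0.022)) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_components_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        d = rng.random((n, n)) * 0.08
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        d[rng.random((n, n)) < 0.05] = math.nan  # some undefined pairs
        d = np.where(np.isnan(d) | np.isnan(d.T), math.nan, d)
        np.fill_diagonal(d, 0.0)
        ids = [f"t{i:02d}" for i in range(n)]
        threshold = float(rng.uniform(0.01, 0.05))
        ca = single_linkage_seed(DistanceMatrix(ids, d, np.zeros_like(d, dtype=np.int64)), threshold)
        assert set(ca.clusters.values()) == brute_force_components(ids, d, threshold)


def two_clique_bridge_dm():
    """Two 3-cliques (internal d=0.005) with one 0.035 bridge; other cross
    pairs at 0.05 so the seed diameter exceeds the 0.04 refinement trigger."""
    ids = list("ABCDEF")
    d = np.full((6, 6), 0.05)
    for grp in ((0, 1, 2), (3, 4, 5)):
        for i in grp:
            for j in grp:
                d[i, j] = 0.0 if i == j else 0.005
    d[2, 3] = d[3, 2] = 0.035  # the bridge pair
    return dm_from_square(ids, d)


class TestMclRefinement:
    def test_two_cliques_with_bridge_split(self):
        dm = two_clique_bridge_dm()
        seed = make_assignment({"seed.0": set("ABCDEF")})
        seed.params["seed_threshold"] = 0.022
        out = mcl_refine(seed, dm, refine_threshold=0.04)
        assert set(out.clusters.values()) == {frozenset("ABC"), frozenset("DEF")}

    def test_transition_matrix_stays_column_stochastic(self):
        dm = two_clique_bridge_dm()
        w = 1.0 - dm.d / 0.04
        np.clip(w, 0.0, None, out=w)
        np.fill_diagonal(w, 1.0)
        sums = []
        mcl_cluster(w, iterate_callback=lambda m: sums.append(m.sum(axis=0)))
        assert len(sums) >= 1
        for s in sums:
            assert np.allclose(s, 1.0, atol=1e-9)

    def test_singleton_seed_cluster_unchanged(self):
        dm = dm_from_square("A", [[0.0]])
        seed = make_assignment({"seed.0": {"A"}})
        out = mcl_refine(seed, dm)
        assert set(out.clusters.values()) == {frozenset("A")}

    def test_tight_cluster_below_trigger_not_refined(self):
        d = np.full((4, 4), 0.005)
        np.fill_diagonal(d, 0.0)
        dm = dm_from_square("ABCD", d)
        seed = make_assignment({"seed.0": set("ABCD")})
        out = mcl_refine(seed, dm, refine_threshold=0.04)
        assert set(out.clusters.values()) == {frozenset("ABCD")}

    def test_refinement_is_a_refinement_of_the_seed_partition(self, fixture_data):
        dm = fixture_data["dm"]
        seed = single_linkage_seed(dm, 0.022)
        refined = mcl_refine(seed, dm)
        seed_of = seed.cluster_of
        for members in refined.clusters.values():
            assert len({seed_of[m] for m in members}) == 1

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError, match="inflation"):
            mcl_cluster(np.eye(2), inflation=1.0)


class TestClusterIds:
    def test_ids_allocated_by_smallest_member(self):
        ca = assign_cluster_ids(make_assignment({"x": {"B", "A"}, "y": {"C"}}))
        assert ca.cluster_of == {"A": "OTU.0001", "B": "OTU.0001", "C": "OTU.0002"}

    def test_empty_partition(self):
        ca = assign_cluster_ids(make_assignment({}))
        assert ca.cluster_of == {}

    def test_permuting_input_order_gives_identical_ids(self):
        ds, _ = generate(ScenarioSpec(n_species=8, n_genera=2, mean_specimens=3.0, seed=4))
        ca1 = cluster_dataset(build_distance_matrix(ds))
        shuffled = ds.subset(list(reversed(ds.specimen_ids)))
        ca2 = cluster_dataset(build_distance_matrix(shuffled))
        assert ca1.cluster_of == ca2.cluster_of


class TestRefinedSingleLinkageEstimator:
    def test_fit_predict_on_square_matrix(self):
        dm = two_clique_bridge_dm()
        est = RefinedSingleLinkage(seed_threshold=0.04, refine_threshold=0.03)
        labels = est.fit_predict(dm.d)
        assert est.n_clusters_ == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_get_set_params_roundtrip(self):
        est = RefinedSingleLinkage(seed_threshold=0.01)
        params = est.get_params()
        assert params["seed_threshold"] == 0.01
        est.set_params(mcl_inflation=3.0)
        assert est.mcl_inflation == 3.0

    def test_rejects_non_square_input(self):
        with pytest.raises(ValueError, match="square"):
            RefinedSingleLinkage().fit(np.zeros((2, 3)))

    def test_matches_functional_pipeline_on_distance_matrix(self, fixture_data):
        dm = fixture_data["dm"]
        est = RefinedSingleLinkage().fit(dm)
        assert est.assignment_.cluster_of == fixture_data["ca"].cluster_of


def patristic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = dm_from_square("ABC", [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        nwk = neighbor_joining(dm)
        dist = patristic(nwk)
        # three-point formulas: a=0.05, b=0.15, c=0.25
        assert dist("A", "B") == pytest.approx(0.2, abs=1e-9)
        assert dist("A", "C") == pytest.approx(0.3, abs=1e-9)
        assert dist("B", "C") == pytest.approx(0.4, abs=1e-9)
        assert ":0.05" in nwk and ":0.15" in nwk and ":0.25" in nwk

    def test_recovers_additive_four_taxon_tree(self):
        # tree ((A:1,B:2):1,C:1.5,D:2.5) scaled by 0.01
        ids = list("ABCD")
        d = np.array(
            [
                [0.0, 0.03, 0.035, 0.045],
                [0.03, 0.0, 0.045, 0.055],
                [0.035, 0.045, 0.0, 0.04],
                [0.045, 0.055, 0.04, 0.0],
            ]
        )
        nwk = neighbor_joining(dm_from_square(ids, d))
        dist = patristic(nwk)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert dist(a, b) == pytest.approx(d[i, j], abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_reproduces_random_additive_distances_and_agrees_with_skbio(self, seed):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        ids = [f"t{i}" for i in range(n)]
        # random additive matrix: patristic distances of a random tree
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n,
            rng=__import__("random").Random(seed),
        )
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = ids[i]
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        d = np.array([[pdm.patristic_distance(taxa[a], taxa[b]) for b in ids] for a in ids])
        dm = dm_from_square(ids, d)
        ours = patristic(neighbor_joining(dm))
        sk_tree = skbio_nj(skbio.DistanceMatrix(d, ids))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert ours(a, b) == pytest.approx(d[i, j], abs=1e-8)
                    sk_d = sk_tree.find(a).distance(sk_tree.find(b))
                    assert sk_d == pytest.approx(d[i, j], abs=1e-8)

    def test_equidistant_taxa_resolve_with_equal_path_lengths(self):
        d = np.full((4, 4), 0.2)
        np.fill_diagonal(d, 0.0)
        nwk = neighbor_joining(dm_from_square("ABCD", d))
        dist = patristic(nwk)
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert dist(a, b) == pytest.approx(0.2, abs=1e-9)

    def test_undefined_distances_raise_with_guidance(self):
        d = np.array([[0, 0.1, math.nan], [0.1, 0, 0.1], [math.nan, 0.1, 0]])
        with pytest.raises(ValueError, match="exclude"):
            neighbor_joining(dm_from_square("ABC", d))

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(dm_from_square("AB", [[0, 0.1], [0.1, 0]]))


class TestPlantedRecovery:
    def test_pipeline_recovers_well_separated_planted_partition(self):
        from sklearn.metrics import adjusted_rand_score

        ds, truth = generate(
            ScenarioSpec(n_species=12, n_genera=3, mean_specimens=4.0, target_intra=0.005, seed=9)
        )
        dm = build_distance_matrix(ds)
        ca = cluster_dataset(dm)
        ari = adjusted_rand_score(truth.planted_labels(dm.ids), ca.labels(dm.ids))
        assert ari == 1.0
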