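"""Louvain modules, edge strata and the homotopic exceedance test."""

import networkx as nx
import numpy as np
import pytest

import connstab as cs
from connstab.errors import InvalidArgumentError
from connstab.stratification import MIN_STRATUM_EDGES


def _two_cliques(size=5):
    """Two disconnected unit-weight cliques."""
    n = 2 * size
    w = np.zeros((n, n))
    w[:size, :size] = 1.0
    w[size:, size:] = 1.0
    np.fill_diagonal(w, 0.0)
    return w


class TestLouvain:
    def test_planted_two_cliques_recovered_with_known_q(self):
        w = _two_cliques(5)
        part = cs.louvain_partition(w, n_runs=10, seed=1)
        assert part.n_modules == 2
        a = part.assignment
        assert len(set(a[:5])) == 1 and len(set(a[5:])) == 1
        # hand formula: Q = sum_c (e_c/m - (deg_c/2m)^2) = 2(1/2 - 1/4)
        assert part.q == pytest.approx(0.5, abs=1e-12)

    def test_single_clique_gives_one_module_zero_q(self):
        n = 6
        w = 1.0 - np.eye(n)
        part = cs.louvain_partition(w, n_runs=5, seed=2)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_fixed_seed_reproducible(self, flat_connectivity):
        z = flat_connectivity.grand_mean()
        a = cs.louvain_partition(z, n_runs=20, seed=3)
        b = cs.louvain_partition(z, n_runs=20, seed=3)
        assert np.array_equal(a.assignment, b.assignment)
        assert a.q == b.q

    def test_all_zero_weights_flagged_degenerate(self):
        part = cs.louvain_partition(np.zeros((4, 4)), n_runs=3, seed=4)
        assert part.degenerate
        assert part.n_modules == 1
        assert part.q == 0.0

    def test_stored_q_matches_recomputed_modularity(self, flat_connectivity):
        z = flat_connectivity.grand_mean()
        part = cs.louvain_partition(z, n_runs=10, seed=5)
        w = np.where(z > 0, z, 0.0)
        np.fill_diagonal(w, 0.0)
        assert cs.modularity(w, part.assignment) == pytest.approx(
            part.q, abs=1e-12
        )

    def test_modularity_agrees_with_networkx(self, rng):
        w = _two_cliques(4) + 0.1
        np.fill_diagonal(w, 0.0)
        assignment = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        g = nx.from_numpy_array(w)
        communities = [{0, 1, 2, 3}, {4, 5, 6, 7}]
        oracle = nx.community.modularity(g, communities, weight="weight")
        assert cs.modularity(w, assignment) == pytest.approx(oracle, abs=1e-12)


class TestClassifyEdges:
    def test_mirror_pair_is_inter_and_homotopic(self):
        parc = cs.make_parcellation(2, 0, 60.0, seed=1)
        strata = cs.classify_edges(parc)
        # node order is L1, R1, L2, R2; edge (0,1) = (L1, R1)
        assert strata.hemisphere_class[0] == "inter"
        assert strata.homotopy_class[0] == "homotopic"

    def test_same_hemisphere_edge_is_intra(self):
        parc = cs.make_parcellation(2, 0, 60.0, seed=1)
        strata = cs.classify_edges(parc)
        iu, ju = np.triu_indices(4, k=1)
        idx = [k for k in range(len(iu)) if (iu[k], ju[k]) == (0, 2)][0]  # L1-L2
        assert strata.hemisphere_class[idx] == "intra"
        assert strata.homotopy_class[idx] == "not_applicable"

    def test_paired_parcellation_has_exactly_h_homotopic_edges(self):
        parc = cs.make_parcellation(7, 0, 90.0, seed=2)
        strata = cs.classify_edges(parc)
        assert int(strata.mask("inter_homotopic").sum()) == 7

    def test_strata_partition_all_edges(self, parcellation):
        a = np.abs(np.random.default_rng(0).normal(size=(14, 14)))
        part = cs.louvain_partition((a + a.T) / 2, n_runs=3, seed=1)
        strata = cs.classify_edges(parcellation, part)
        total = cs.n_edges(parcellation.n_nodes)
        assert (
            strata.mask("module_within").sum()
            + strata.mask("module_between").sum()
            == total
        )
        assert (
            strata.mask("hemisphere_intra").sum()
            + strata.mask("hemisphere_inter").sum()
            == total
        )
        # homotopic edges are inter-hemispheric by construction
        assert not np.any(
            strata.mask("inter_homotopic") & strata.mask("hemisphere_intra")
        )


class TestStratifiedAnalysis:
    def test_sparse_strata_are_skipped_not_fatal(self):
        # 30 mirror pairs: hemisphere strata are dense, but a random
        # matching almost never retains 10 homotopic pairs, and with no
        # partition every edge is 'within', leaving 'between' empty
        parc = cs.make_parcellation(30, 0, 140.0, seed=1)
        vals = np.random.default_rng(2).normal(size=cs.n_edges(60))
        cmap = cs.EdgeChangeMap(
            kind="salience",
            values=cs.EdgeVector(vals, 60),
            distances=cs.upper_triangle_vector(cs.distance_matrix(parc)),
        )
        strata = cs.classify_edges(parc)
        results = cs.stratified_distance_analysis(
            cmap, strata, n_samples=30, seed=3
        )
        by_name = {r.name: r for r in results}
        assert by_name["module_between"].status == "skipped"
        assert by_name["module_between"].n_edges < MIN_STRATUM_EDGES
        assert by_name["inter_homotopic"].status == "skipped"
        for name in ("hemisphere_intra", "hemisphere_inter"):
            r = by_name[name]
            assert r.status == "ok"
            assert r.pairs is not None and r.descriptive is not None

    def test_positive_control_detected_within_and_between_modules(self):
        parc = cs.make_parcellation(30, 0, 140.0, seed=31)
        truth = cs.default_truth(parc, effect_profile="increasing", seed=32)
        ds = cs.sample_dataset(parc, truth, 20, 200, seed=33)
        cds = cs.connectivity_from_timeseries(ds)
        model = cs.fit_pls(cds)
        cmap = cs.salience_change_map(model, parc)
        part = cs.louvain_partition(cds.grand_mean(), n_runs=20, seed=34)
        strata = cs.classify_edges(parc, part)
        results = cs.stratified_distance_analysis(
            cmap, strata, n_samples=200, seed=35,
            stratum_names=("module_within", "module_between"),
        )
        for r in results:
            assert r.status == "ok"
            assert r.pairs.p_less < 0.025  # planted increasing trend


class TestHomotopicStability:
    def _strata(self, parc):
        return cs.classify_edges(parc)

    def test_zero_homotopic_change_never_exceeds(self):
        parc = cs.make_parcellation(12, 0, 100.0, seed=3)
        strata = self._strata(parc)
        vals = np.random.default_rng(4).normal(size=cs.n_edges(parc.n_nodes))
        vals[strata.mask("inter_homotopic")] = 0.0
        cmap = cs.EdgeChangeMap(
            kind="salience",
            values=cs.EdgeVector(vals, parc.n_nodes),
            distances=cs.upper_triangle_vector(cs.distance_matrix(parc)),
        )
        res = cs.homotopic_stability_test(cmap, strata)
        assert res.proportion_homotopic == 0.0
        assert res.proportion_non_homotopic > 0.0

    def test_iid_classes_both_near_five_percent(self):
        parc = cs.make_parcellation(40, 0, 140.0, seed=5)
        strata = self._strata(parc)
        inter = strata.mask("hemisphere_inter")
        vals = np.zeros(cs.n_edges(parc.n_nodes))
        vals[inter] = np.random.default_rng(6).normal(size=int(inter.sum()))
        cmap = cs.EdgeChangeMap(
            kind="salience",
            values=cs.EdgeVector(vals, parc.n_nodes),
            distances=cs.upper_triangle_vector(cs.distance_matrix(parc)),
        )
        res = cs.homotopic_stability_test(cmap, strata)
        # ~5% of pooled i.i.d. values fall outside their own 95% interval
        assert res.proportion_non_homotopic == pytest.approx(0.05, abs=0.02)
        assert res.proportion_homotopic == pytest.approx(0.05, abs=0.08)

    def test_degenerate_pool_collapses_bounds(self):
        parc = cs.make_parcellation(6, 0, 80.0, seed=7)
        strata = self._strata(parc)
        cmap = cs.EdgeChangeMap(
            kind="salience",
            values=cs.EdgeVector(np.full(cs.n_edges(12), 0.3), 12),
            distances=cs.upper_triangle_vector(cs.distance_matrix(parc)),
        )
        res = cs.homotopic_stability_test(cmap, strata)
        assert res.degenerate
        assert res.proportion_homotopic == 0.0
        assert res.proportion_non_homotopic == 0.0

    def test_requires_both_classes(self):
        parc = cs.Parcellation(
            ("a", "b", "c"),
            np.eye(3),
            ("medial", "medial", "medial"),
            (None, None, None),
        )
        strata = cs.classify_edges(parc)
        cmap = cs.EdgeChangeMap(
            kind="salience",
            values=cs.EdgeVector(np.arange(3.0), 3),
            distances=cs.upper_triangle_vector(cs.distance_matrix(parc)),
        )
        with pytest.raises(InvalidArgumentError):
            cs.homotopic_stability_test(cmap, strata)

    def test_stable_homotopic_generator_recovered(self):
        parc = cs.make_parcellation(30, 0, 140.0, seed=8)
        truth = cs.default_truth(
            parc, effect_profile="flat", homotopic_stability=0.0, seed=9
        )
        ds = cs.sample_dataset(parc, truth, 20, 200, seed=10)
        cds = cs.connectivity_from_timeseries(ds)
        cmap = cs.salience_change_map(cs.fit_pls(cds), parc)
        res = cs.homotopic_stability_test(cmap, self._strata(parc))
        assert res.proportion_homotopic < res.proportion_non_homotopic
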