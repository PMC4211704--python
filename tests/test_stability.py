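"""Change maps, independent-pairs inference, PCA diagnostic, density."""

import numpy as np
import pytest
from scipy import stats

import connstab as cs
from connstab.errors import DegenerateInputError, InvalidArgumentError


def _change_map(values, parc):
    return cs.EdgeChangeMap(
        kind="correlation_difference",
        values=cs.EdgeVector(values, parc.n_nodes),
        distances=cs.upper_triangle_vector(cs.distance_matrix(parc)),
    )


class TestCorrelationDifference:
    def test_same_cell_gives_zero_map(self, flat_connectivity):
        cell = flat_connectivity.design[0]
        cmap = cs.correlation_difference(flat_connectivity, cell, cell)
        assert np.allclose(cmap.values.values, 0.0)

    def test_toy_matrices_match_hand_subtraction(self):
        parc = cs.make_parcellation(1, 1, 50.0, seed=0)  # 3 nodes
        za = np.array([[0, 0.5, 0.2], [0.5, 0, -0.1], [0.2, -0.1, 0]])
        zb = np.array([[0, 0.1, 0.4], [0.1, 0, 0.3], [0.4, 0.3, 0]])
        ds = cs.ConnectivityDataset(
            parc,
            [("g", "A"), ("g", "B")],
            {("g", "A"): za[None], ("g", "B"): zb[None]},
        )
        cmap = cs.correlation_difference(ds, ("g", "A"), ("g", "B"))
        assert np.allclose(cmap.values.values, [0.4, -0.2, -0.4])
        # and the matrix form is symmetric
        assert np.allclose(cmap.values.to_matrix(), cmap.values.to_matrix().T)

    def test_unknown_cell_rejected(self, flat_connectivity):
        with pytest.raises(InvalidArgumentError):
            cs.correlation_difference(
                flat_connectivity, ("g1", "A"), ("nope", "B")
            )

    def test_absolute_variant_shares_code_path(self, flat_connectivity):
        a, b = flat_connectivity.design[:2]
        cmap = cs.correlation_difference(flat_connectivity, a, b)
        amap = cmap.absolute()
        assert amap.kind == "abs_correlation_difference"
        assert np.array_equal(amap.values.values, np.abs(cmap.values.values))
        # downstream ops accept both identically
        cs.change_distance_correlation(amap)
        cs.independent_pairs_correlation(amap, n_samples=20, seed=0)


class TestIndependentPairs:
    def test_116_nodes_give_58_pairs(self, rng):
        parc = cs.make_parcellation(58, 0, 140.0, seed=1)
        cmap = _change_map(rng.normal(size=cs.n_edges(116)), parc)
        res = cs.independent_pairs_correlation(cmap, n_samples=5, seed=2)
        assert res.n_pairs_per_sample == 58

    def test_odd_node_count_drops_one(self, rng):
        parc = cs.make_parcellation(3, 1, 60.0, seed=1)  # 7 nodes
        cmap = _change_map(rng.normal(size=cs.n_edges(7)), parc)
        res = cs.independent_pairs_correlation(cmap, n_samples=5, seed=2)
        assert res.n_pairs_per_sample == 3

    def test_change_equal_to_distance_gives_rho_one(self, parcellation):
        d = cs.upper_triangle_vector(cs.distance_matrix(parcellation))
        cmap = _change_map(d.values.copy(), parcellation)
        res = cs.independent_pairs_correlation(cmap, n_samples=50, seed=3)
        assert np.allclose(res.rho_samples, 1.0)
        assert res.p_greater == 1.0
        assert res.p_less == 0.0

    def test_tail_probabilities_sum_to_one(self, parcellation, rng):
        cmap = _change_map(
            rng.normal(size=cs.n_edges(parcellation.n_nodes)), parcellation
        )
        res = cs.independent_pairs_correlation(cmap, n_samples=200, seed=4)
        assert res.p_greater + res.p_less == pytest.approx(1.0)

    def test_determinism(self, parcellation, rng):
        cmap = _change_map(
            rng.normal(size=cs.n_edges(parcellation.n_nodes)), parcellation
        )
        a = cs.independent_pairs_correlation(cmap, n_samples=100, seed=5)
        b = cs.independent_pairs_correlation(cmap, n_samples=100, seed=5)
        assert np.array_equal(a.rho_samples, b.rho_samples)

    def test_se_is_sampling_distribution_spread(self, parcellation, rng):
        cmap = _change_map(
            rng.normal(size=cs.n_edges(parcellation.n_nodes)), parcellation
        )
        res = cs.independent_pairs_correlation(cmap, n_samples=100, seed=6)
        assert res.se == pytest.approx(res.rho_samples.std(ddof=1))
        assert res.se_of_mean == pytest.approx(res.se / 10.0)

    def test_vacuous_eligibility_mask_changes_nothing(self, parcellation, rng):
        cmap = _change_map(
            rng.normal(size=cs.n_edges(parcellation.n_nodes)), parcellation
        )
        full = cs.independent_pairs_correlation(cmap, n_samples=50, seed=7)
        masked = cs.independent_pairs_correlation(
            cmap,
            n_samples=50,
            seed=7,
            eligible=np.ones(len(cmap.values), dtype=bool),
            min_pairs=1,
        )
        assert np.array_equal(full.rho_samples, masked.rho_samples)


class TestChangeDistanceCorrelation:
    def test_change_proportional_to_distance(self, parcellation):
        d = cs.upper_triangle_vector(cs.distance_matrix(parcellation))
        cmap = _change_map(2.5 * d.values, parcellation)
        out = cs.change_distance_correlation(cmap, "pearson")
        assert out["coefficient"] == pytest.approx(1.0)
        assert "non-independent" in out["label"]

    def test_constant_change_rejected(self, parcellation):
        cmap = _change_map(
            np.full(cs.n_edges(parcellation.n_nodes), 0.7), parcellation
        )
        with pytest.raises(DegenerateInputError):
            cs.change_distance_correlation(cmap)

    def test_matches_second_implementation(self, parcellation, rng):
        vals = rng.normal(size=cs.n_edges(parcellation.n_nodes))
        cmap = _change_map(vals, parcellation)
        out = cs.change_distance_correlation(cmap, "spearman")
        # oracle: rank transform + product-moment correlation
        d = cmap.distances.values
        rx = stats.rankdata(d)
        ry = stats.rankdata(vals)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert out["coefficient"] == pytest.approx(oracle, abs=1e-12)


class TestPcaOutliers:
    def _map_from_points(self, x, y):
        n_nodes = int((1 + np.sqrt(1 + 8 * x.size)) / 2)
        parc = cs.Parcellation(
            tuple(f"m{i}" for i in range(n_nodes)),
            np.zeros((n_nodes, 3)),
            ("medial",) * n_nodes,
            (None,) * n_nodes,
        )
        dm = cs.edge_vector_to_matrix(x, n_nodes)
        cmap = cs.EdgeChangeMap(
            kind="salience",
            values=cs.EdgeVector(y, n_nodes),
            distances=cs.EdgeVector(x, n_nodes),
        )
        return cmap

    def test_collinear_points_report_degenerate(self):
        x = np.linspace(0, 10, 28)
        cmap = self._map_from_points(x, 3.0 * x + 1.0)
        rep = cs.pca_outlier_diagnostic(cmap)
        assert rep.degenerate
        assert np.allclose(rep.displacements, 0.0, atol=1e-10)
        assert np.isnan(rep.outlier_correlation)

    def test_five_percent_of_hundred_flags_five_each_side(self, rng):
        x = rng.normal(size=105)  # 15-node parcellation -> 105 edges
        y = rng.normal(size=105)
        cmap = self._map_from_points(x, y)
        rep = cs.pca_outlier_diagnostic(cmap, tail_fraction=0.05)
        assert rep.upper_indices.size == 6  # ceil(0.05 * 105)
        assert rep.lower_indices.size == 6

    def test_principal_axis_matches_closed_form_eigensolve(self, rng):
        x = rng.normal(size=45)
        y = 0.5 * x + rng.normal(scale=0.5, size=45)
        cmap = self._map_from_points(x, y)
        rep = cs.pca_outlier_diagnostic(cmap)
        # closed form for the leading eigenvector of a 2x2 covariance
        xs = (x - x.mean()) / x.std()
        ys = (y - y.mean()) / y.std()
        c = np.cov(np.vstack([xs, ys]))
        theta = 0.5 * np.arctan2(2 * c[0, 1], c[0, 0] - c[1, 1])
        axis = np.array([np.cos(theta), np.sin(theta)])
        if axis[0] < 0:
            axis = -axis
        assert np.allclose(np.abs(rep.principal_axis @ axis), 1.0, atol=1e-10)


class TestDensityHistogram:
    def test_counts_conserve_edge_total(self, parcellation, rng):
        cmap = _change_map(
            rng.normal(size=cs.n_edges(parcellation.n_nodes)), parcellation
        )
        hist = cs.density_histogram_2d(cmap, 8, 8)
        assert hist["counts"].sum() == cs.n_edges(parcellation.n_nodes)

    def test_point_mass_lands_in_single_bin(self):
        parc = cs.Parcellation(
            tuple(f"m{i}" for i in range(5)),
            np.zeros((5, 3)),
            ("medial",) * 5,
            (None,) * 5,
        )
        cmap = cs.EdgeChangeMap(
            kind="salience",
            values=cs.EdgeVector(np.full(10, 1.0), 5),
            distances=cs.EdgeVector(np.full(10, 2.0), 5),
        )
        hist = cs.density_histogram_2d(cmap, 4, 4)
        assert hist["counts"].max() == 10
        assert (hist["counts"] > 0).sum() == 1
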