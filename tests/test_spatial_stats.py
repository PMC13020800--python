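"""Moran's I: weights construction, oracle equivalence, permutation nulls."""

import numpy as np
import pytest

from chronotopo import synthetic_data as sd
from chronotopo import spatial_stats as ss
from oracles import brute_global_moran, brute_local_moran


def rook_neighbors(n_rows, n_cols):
    """Side-adjacent neighbor lists on a lattice (oracle-side helper)."""
    out = []
    for i in range(n_rows * n_cols):
        r, c = divmod(i, n_cols)
        nb = []
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols:
                nb.append(rr * n_cols + cc)
        out.append(nb)
    return out


class TestKnnWeights:
    def test_two_by_two_sides_beat_diagonal(self):
        patch = sd.make_patch(2, 2, 1.0)
        w, _ = ss.knn_weights(patch, 2)
        for i, nb in enumerate(w.neighbors):
            d = np.linalg.norm(patch.coords[nb] - patch.coords[i], axis=1)
            assert np.allclose(d, 1.0)  # the two side-adjacent vertices

    def test_rows_standardized_to_one(self, lattice_20):
        w, _ = ss.knn_weights(lattice_20, 12)
        assert np.allclose(w.row_sums(), 1.0)
        assert all(len(nb) == 12 for nb in w.neighbors)

    def test_no_self_neighbors_and_tie_break_by_id(self, small_patch):
        w, _ = ss.knn_weights(small_patch, 4)
        for i, nb in enumerate(w.neighbors):
            assert i not in nb

    def test_neighborhood_size_rule(self):
        # one-fourth of the smallest ROI in scope
        assert ss.moran_neighborhood_size([240, 480]) == 60
        assert ss.moran_neighborhood_size([59 * 4, 1000]) == 59

    def test_k_must_be_smaller_than_scope(self, small_patch):
        with pytest.raises(ValueError):
            ss.knn_weights(small_patch, 100)

    def test_restrict_roi_keeps_neighbors_within_roi(self):
        blocks = [sd.RoiBlock("a", 50), sd.RoiBlock("b", 50)]
        patch = sd.make_patch(10, 10, 1.0, blocks)
        w, ids = ss.knn_weights(patch, 6, restrict="roi")
        for i, nb in enumerate(w.neighbors):
            assert np.all(patch.roi[ids[nb]] == patch.roi[ids[i]])


class TestLocalMoran:
    def test_three_vertex_path_matches_hand_computation(self):
        # path 0-1-2 with values (1,2,3); k=1 neighbors: ends point to the
        # middle, the middle to vertex 0 (tie broken by id)
        patch = sd.make_patch(3, 2, 1.0, [sd.RoiBlock("a", 6)])
        values = np.array([1.0, 2.0, 3.0])
        nb = [[1], [0], [1]]
        w = ss.SpatialWeights.from_neighbor_lists(nb)
        res = ss.local_morans_i(values, w, n_perm=19, seed=0)
        assert np.allclose(res.local_i, brute_local_moran(values, nb))

    def test_matches_brute_force_on_random_fields(self, lattice_20, rng):
        w, _ = ss.knn_weights(lattice_20, 8)
        for _ in range(20):
            vals = rng.uniform(0.2, 0.8, lattice_20.n_vertices)
            res = ss.local_morans_i(vals, w, n_perm=9, seed=1)
            brute = brute_local_moran(vals, w.neighbors)
            assert np.abs(res.local_i - brute).max() < 1e-10
            assert res.global_i == pytest.approx(res.local_i.mean(), abs=1e-12)

    def test_constant_field_rejected(self, small_patch):
        w, _ = ss.knn_weights(small_patch, 4)
        with pytest.raises(ValueError):
            ss.local_morans_i(np.full(100, 0.5), w)

    def test_permutation_determinism(self, small_patch, rng):
        w, _ = ss.knn_weights(small_patch, 6)
        vals = rng.uniform(0.2, 0.8, 100)
        a = ss.local_morans_i(vals, w, n_perm=99, seed=42)
        b = ss.local_morans_i(vals, w, n_perm=99, seed=42)
        assert np.array_equal(a.pseudo_p, b.pseudo_p)

    def test_external_center_shifts_quadrants(self):
        """A boundary-tuned ROI centered at 0.5 classifies HH when the
        hemisphere mean is pulled below it by a short-preferring region."""
        patch = sd.make_patch(8, 8, 1.0)
        vals = np.random.default_rng(3).normal(0.5, 0.01, 64)
        w, _ = ss.knn_weights(patch, 8)
        res = ss.local_morans_i(vals, w, center=0.4, n_perm=199, seed=0)
        sig = res.quadrant != "ns"
        assert sig.any()
        assert set(res.quadrant[sig]) == {"HH"}


class TestGlobalMoran:
    def test_checkerboard_with_rook_weights_is_minus_one(self):
        rows, cols = np.divmod(np.arange(36), 6)
        vals = np.where((rows + cols) % 2 == 0, 1.0, -1.0) * 0.7
        w = ss.SpatialWeights.from_neighbor_lists(rook_neighbors(6, 6))
        gi, _ = ss.global_morans_i(vals, w, n_perm=19, seed=0)
        assert gi == pytest.approx(-1.0, abs=1e-12)

    def test_smooth_gradient_strongly_positive_and_matches_oracle(self, lattice_20):
        vals = sd.plant_field(lattice_20, "gradient", {"axis": "x"}, seed=0).mu_true
        w, _ = ss.knn_weights(lattice_20, 12)
        gi, p = ss.global_morans_i(vals, w, n_perm=199, seed=0)
        assert gi > 0.5
        assert gi == pytest.approx(brute_global_moran(vals, w.neighbors), abs=1e-10)
        assert p < 0.05

    def test_vertex_relabeling_equivariance(self, small_patch, rng):
        vals = rng.uniform(0.2, 0.8, 100)
        w, _ = ss.knn_weights(small_patch, 6)
        gi, _ = ss.global_morans_i(vals, w, n_perm=9, seed=0)
        perm = rng.permutation(100)
        inv = np.argsort(perm)
        w_perm = ss.SpatialWeights.from_neighbor_lists(
            [inv[w.neighbors[perm[i]]] for i in range(100)]
        )
        gi_perm, _ = ss.global_morans_i(vals[perm], w_perm, n_perm=9, seed=0)
        assert gi_perm == pytest.approx(gi, abs=1e-12)


class TestQuadrantSummary:
    def _result(self, quadrants):
        n = len(quadrants)
        z = np.zeros(n)
        return ss.MoranResult(
            np.arange(n), z, np.ones(n), np.asarray(quadrants, dtype=object),
            z, z, 0.0, None, 9, 0.05, 0
        )

    def test_all_ns(self):
        res = self._result(["ns"] * 10)
        out = ss.summarize_quadrants(res, np.array(["a"] * 10))
        row = out.iloc[0]
        assert row["frac_ns"] == 1.0 and row["ll_minus_hh"] == 0.0

    def test_all_ll_gives_difference_one(self):
        res = self._result(["LL"] * 6 + ["HH"] * 4)
        out = ss.summarize_quadrants(res, np.array(["a"] * 6 + ["b"] * 4))
        assert out.set_index("roi").loc["a", "ll_minus_hh"] == 1.0
        assert out.set_index("roi").loc["b", "ll_minus_hh"] == -1.0

    def test_fractions_sum_to_one(self, small_patch, rng):
        vals = sd.plant_field(small_patch, "grf", {"correlation_length_mm": 4.0}, seed=2).mu_true
        w, _ = ss.knn_weights(small_patch, 8)
        res = ss.local_morans_i(vals, w, n_perm=99, seed=0)
        out = ss.summarize_quadrants(res, small_patch.roi)
        fr = out[[f"frac_{q.lower()}" for q in ss.QUADRANTS]].sum(axis=1)
        assert np.allclose(fr, 1.0, atol=1e-12)


def test_hl_lh_nearly_absent_on_smooth_gradients(lattice_20):
    """Smooth planted gradients produce almost no HL/LH associations."""
    vals = sd.plant_field(lattice_20, "gradient", {"axis": "x"}, seed=0).mu_true
    w, _ = ss.knn_weights(lattice_20, 12)
    res = ss.local_morans_i(vals, w, n_perm=999, seed=7)
    frac_hl_lh = np.isin(res.quadrant, ["HL", "LH"]).mean()
    assert frac_hl_lh < 0.02
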