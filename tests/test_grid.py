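"""Tests for the grid-based weighted COOP pipeline."""

import math

import numpy as np
import pandas as pd
import pytest

import coorient as co
from coorient import synth
from coorient.grid import (
    GridSpec,
    WeightedPairGrid,
    consistency_matrix,
    grid_partition,
    grid_weights,
    multi_sample_angle_stats,
    weighted_coop,
)


def lattice(width, height):
    """Integer pixel coordinates covering a width x height raster."""
    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


class TestGridPartition:
    def test_single_square_constant_field(self):
        coords = lattice(30, 30)
        f = co.OrientationField(np.full(len(coords), 0.7), coords=coords)
        g = grid_partition(f, GridSpec(square_size=30, extent=(30, 30)))
        assert len(g.table) == 1
        row = g.table.iloc[0]
        assert row["director"] == pytest.approx(0.7, abs=1e-12)
        assert row["oop"] == pytest.approx(1.0, abs=1e-12)
        assert row["rho"] == pytest.approx(len(coords) / 900)

    def test_block_constant_field_two_squares(self):
        coords = lattice(60, 30)
        angles = np.where(coords[:, 0] < 30, 0.0, math.pi / 2)
        f = co.OrientationField(angles, coords=coords)
        g = grid_partition(f, GridSpec(square_size=30, extent=(60, 30)))
        tab = g.table.sort_values("ix")
        assert len(tab) == 2
        assert tab.iloc[0]["director"] == pytest.approx(0.0, abs=1e-12)
        assert tab.iloc[1]["director"] == pytest.approx(math.pi / 2, abs=1e-12)

    def test_per_square_matches_direct_tensor(self, rng):
        coords = lattice(60, 60)
        angles = rng.uniform(0, math.pi, len(coords))
        f = co.OrientationField(angles, coords=coords)
        g = grid_partition(f, GridSpec(square_size=30, extent=(60, 60)))
        for _, row in g.table.iterrows():
            mask = ((coords[:, 0] // 30 == row["ix"]) & (coords[:, 1] // 30 == row["iy"]))
            expected, _ = co.oop(angles[mask])
            assert row["oop"] == pytest.approx(expected, abs=1e-12)

    def test_empty_squares_recorded_with_zero_density(self):
        coords = np.array([[5.0, 5.0], [6.0, 5.0]])
        f = co.OrientationField([0.3, 0.3], coords=coords)
        g = grid_partition(f, GridSpec(square_size=30, extent=(60, 60)))
        assert len(g.table) == 4
        empty = g.table[g.table["count"] == 0]
        assert len(empty) == 3
        assert (empty["rho"] == 0).all()
        assert empty["director"].isna().all()

    def test_partial_edge_square_uses_clipped_area(self):
        # 45 x 30 extent: second column of squares is 15 px wide
        coords = lattice(45, 30)
        f = co.OrientationField(np.full(len(coords), 0.2), coords=coords)
        g = grid_partition(f, GridSpec(square_size=30, extent=(45, 30)))
        edge = g.table[g.table["ix"] == 1].iloc[0]
        assert edge["area"] == pytest.approx(15 * 30)
        assert edge["rho"] == pytest.approx(edge["count"] / (15 * 30))

    def test_out_of_bounds_coords_rejected(self):
        f = co.OrientationField([0.1], coords=[[100.0, 5.0]])
        with pytest.raises(ValueError, match="outside extent"):
            grid_partition(f, GridSpec(square_size=30, extent=(60, 60)))

    def test_missing_coords_rejected(self):
        with pytest.raises(ValueError):
            grid_partition(co.OrientationField([0.1]), GridSpec(square_size=30, extent=(30, 30)))


class TestGridWeights:
    @staticmethod
    def summaries(width=60, height=60, seed=0):
        g = np.random.default_rng(seed)
        coords = lattice(width, height)
        spec = GridSpec(square_size=30, extent=(width, height))
        p = grid_partition(co.OrientationField(g.uniform(0, math.pi, len(coords)),
                                               coords=coords), spec)
        q = grid_partition(co.OrientationField(g.uniform(0, math.pi, len(coords)),
                                               coords=coords), spec)
        return p, q

    def test_weight_product_formula(self):
        p, q = self.summaries()
        wpg = grid_weights(p, q)
        for _, row in wpg.table.iterrows():
            assert row["weight"] == pytest.approx(
                row["oop_p"] * row["oop_q"] * row["rho_p"] * row["rho_q"], abs=1e-12)

    def test_square_empty_in_one_construct_gets_zero_weight(self):
        coords = lattice(30, 30)
        spec = GridSpec(square_size=30, extent=(60, 30))
        p = grid_partition(co.OrientationField(np.full(len(coords), 0.3),
                                               coords=coords), spec)
        far = coords + [30.0, 0.0]
        q = grid_partition(co.OrientationField(np.full(len(coords), 0.3), coords=far), spec)
        wpg = grid_weights(p, q)
        assert (wpg.table["weight"] == 0).all()

    def test_mismatched_grids_rejected(self):
        p, _ = self.summaries()
        other = GridSpec(square_size=15, extent=(60, 60))
        coords = lattice(60, 60)
        q = grid_partition(co.OrientationField(np.full(len(coords), 0.3),
                                               coords=coords), other)
        with pytest.raises(ValueError, match="incompatible"):
            grid_weights(p, q)


def _pair_grid(directors_p, directors_q, weights):
    """Hand-build a WeightedPairGrid from per-square director angles."""
    k = len(directors_p)
    table = pd.DataFrame({
        "ix": np.arange(k), "iy": np.zeros(k, dtype=int),
        "director_p": directors_p, "director_q": directors_q,
        "oop_p": np.ones(k), "oop_q": np.ones(k),
        "rho_p": np.ones(k), "rho_q": np.ones(k),
        "weight": weights,
    })
    spec = GridSpec(square_size=1.0, extent=(float(k), 1.0))
    return WeightedPairGrid(spec=spec, table=table)


class TestWeightedCoop:
    def test_constant_offset_across_squares_gives_unit_coop(self, rng):
        d = rng.uniform(0, math.pi, 50)
        res = weighted_coop(_pair_grid(d, d + 0.6, rng.uniform(0.2, 1.0, 50)))
        assert res.coop == pytest.approx(1.0, abs=1e-12)
        assert res.theta0 == pytest.approx(0.6, abs=1e-12)

    def test_half_parallel_half_perpendicular_cancels(self):
        d_p = np.zeros(4)
        d_q = np.array([0.0, 0.0, math.pi / 2, math.pi / 2])
        res = weighted_coop(_pair_grid(d_p, d_q, np.ones(4)))
        assert res.coop == pytest.approx(0.0, abs=1e-12)

    def test_downweighting_recovers_dominant_mode(self):
        d_p = np.zeros(4)
        d_q = np.array([0.0, 0.0, math.pi / 2, math.pi / 2])
        res = weighted_coop(_pair_grid(d_p, d_q, np.array([1, 1, 1e-9, 1e-9])))
        assert res.coop == pytest.approx(1.0, abs=1e-6)

    def test_zero_weight_squares_are_inert(self, rng):
        d_p = rng.uniform(0, math.pi, 10)
        d_q = rng.uniform(0, math.pi, 10)
        w = rng.uniform(0.1, 1.0, 10)
        full = weighted_coop(_pair_grid(d_p, d_q, w))
        w2 = np.concatenate([w, [0.0, 0.0]])
        d_p2 = np.concatenate([d_p, [0.1, 0.2]])
        d_q2 = np.concatenate([d_q, [1.0, 1.3]])
        padded = weighted_coop(_pair_grid(d_p2, d_q2, w2))
        assert padded.coop == pytest.approx(full.coop, abs=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            weighted_coop(_pair_grid(np.zeros(3), np.zeros(3), np.zeros(3)))

    def test_one_pixel_per_square_reduces_to_pixel_coop(self, rng):
        """Refinement limit: unit squares with one pixel each == plain COOP."""
        n = 400
        p_angles = rng.uniform(0, math.pi, n)
        q_angles = (p_angles + rng.normal(0, 0.3, n)) % math.pi
        coords = lattice(20, 20)
        spec = GridSpec(square_size=1.0, extent=(20, 20))
        gp = grid_partition(co.OrientationField(p_angles, coords=coords), spec)
        gq = grid_partition(co.OrientationField(q_angles, coords=coords), spec)
        res = weighted_coop(grid_weights(gp, gq))
        ref = co.coop(co.PairedField(p_angles, q_angles))
        assert res.coop == pytest.approx(ref.coop, abs=1e-10)
        assert res.oop_p == pytest.approx(ref.oop_p, abs=1e-10)


class TestConsistencyMatrix:
    @staticmethod
    def noisy_samples(k=4, seed=0):
        g = np.random.default_rng(seed)
        coords = lattice(40, 40)
        base = g.uniform(0, math.pi, len(coords))
        spec = GridSpec(square_size=10, extent=(40, 40))
        out = []
        for i in range(k):
            angles = (base + g.normal(0, 0.25, len(base))) % math.pi
            out.append(grid_partition(
                co.OrientationField(angles, coords=coords, label=f"cell_{i + 1}"), spec))
        return out

    def test_symmetric_with_unit_diagonal(self):
        mat = consistency_matrix(self.noisy_samples())
        arr = mat.to_numpy()
        assert np.allclose(arr, arr.T, atol=1e-12)
        assert np.allclose(np.diag(arr), 1.0, atol=1e-12)

    def test_off_diagonal_below_one_for_noisy_copies(self):
        arr = consistency_matrix(self.noisy_samples()).to_numpy()
        off = arr[~np.eye(len(arr), dtype=bool)]
        assert np.all(off < 1.0)
        assert np.all(off > 0.0)

    def test_incompatible_grids_rejected(self):
        samples = self.noisy_samples(2)
        coords = lattice(40, 40)
        odd = grid_partition(
            co.OrientationField(np.full(len(coords), 0.3), coords=coords),
            GridSpec(square_size=20, extent=(40, 40)))
        with pytest.raises(ValueError, match="incompatible"):
            consistency_matrix(samples + [odd])


class TestMultiSampleAngleStats:
    @staticmethod
    def directors(degrees):
        return [np.array([math.cos(math.radians(d)), math.sin(math.radians(d))])
                for d in degrees]

    def test_identical_directors(self):
        mean, std = multi_sample_angle_stats(self.directors([40, 40, 40]))
        assert mean == pytest.approx(math.radians(40), abs=1e-12)
        assert std == pytest.approx(0.0, abs=1e-12)

    def test_vertical_cluster_uses_arccos_branch(self):
        mean, std = multi_sample_angle_stats(self.directors([80, 90, 100]))
        assert mean == pytest.approx(math.pi / 2, abs=1e-12)
        assert std == pytest.approx(math.radians(10), abs=1e-12)

    def test_horizontal_cluster_avoids_wraparound(self):
        mean, _ = multi_sample_angle_stats(self.directors([-5, 0, 5]))
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_near_isotropic_directors_warn(self):
        with pytest.warns(UserWarning, match="unstable"):
            multi_sample_angle_stats(self.directors([0, 45, 90, 135]))


class TestGridLevelBoundRecovery:
    def test_correlated_pair_ratio_recovered_at_grid_level(self):
        """A noise-coupled synthetic image recovers min/max at grid scale."""
        n = 10**4
        sp = synth.TruncatedGaussianSpec(mean=0.5, sigma=synth.sigma_for_oop(0.8))
        pf = synth.gen_correlated_pair(sp, 0.5, n, seed=17)
        coords = lattice(100, 100)
        spec = GridSpec(square_size=1.0, extent=(100, 100))
        gp = grid_partition(co.OrientationField(pf.p_angles, coords=coords), spec)
        gq = grid_partition(co.OrientationField(pf.q_angles, coords=coords), spec)
        res = weighted_coop(grid_weights(gp, gq))
        assert res.coop == pytest.approx(0.5 / res.oop_p, abs=3 / math.sqrt(n))
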