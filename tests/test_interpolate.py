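"""Grid assignment and ordinary kriging against independent dense oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aodgp.grids import GridSpec
from aodgp.interpolate import (
    PROV_INTERPOLATED,
    PROV_MISSING,
    PROV_OBSERVED,
    SingularKrigingError,
    assign_points_to_grid,
    buffer_gapfill,
    ordinary_kriging,
)
from aodgp.variogram import VariogramModel, correlation


def ok_oracle(obs_coords, obs_values, target, vg):
    """Brute-force ordinary kriging: assemble and solve the full (n+1) system.

    Written independently of the production path: semivariances are built
    element by element from the correlation function and the system is
    solved with a plain dense solve.
    """
    n = len(obs_coords)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            if i != j:
                h = float(np.linalg.norm(np.asarray(obs_coords[i]) - np.asarray(obs_coords[j])))
                A[i, j] = vg.tau2 + vg.sigma2 * (1 - float(correlation(vg.family, h, vg.phi, vg.nu)))
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        h = float(np.linalg.norm(np.asarray(obs_coords[i]) - np.asarray(target)))
        if h > 0:
            b[i] = vg.tau2 + vg.sigma2 * (1 - float(correlation(vg.family, h, vg.phi, vg.nu)))
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    w = sol[:n]
    return float(w @ obs_values), w, float(sol[n])


SPH = VariogramModel("spherical", tau2=0.0, sigma2=1.0, phi=0.5)


class TestAssignPoints:
    def test_point_at_center_maps_to_its_cell(self, small_grid):
        centers = small_grid.cell_centers()
        pts = pd.DataFrame({"lon": [centers[7, 0]], "lat": [centers[7, 1]], "value": [1.0]})
        cells, rejects = assign_points_to_grid(pts, small_grid)
        assert rejects.empty
        assert cells["cell_id"].tolist() == [7]

    def test_two_monitors_in_one_cell_averaged(self, small_grid):
        lon = small_grid.lon_min + 0.05
        lat = small_grid.lat_min + 0.05
        pts = pd.DataFrame({"lon": [lon, lon + 0.01], "lat": [lat, lat], "value": [40.0, 60.0]})
        cells, _ = assign_points_to_grid(pts, small_grid)
        assert len(cells) == 1
        assert cells["value"].iloc[0] == pytest.approx(50.0)
        assert cells["n_points"].iloc[0] == 2

    def test_shared_edge_goes_to_west_south_cell(self, small_grid):
        # exactly on the boundary between cells 0 and 1: belongs to cell 1
        edge_lon = small_grid.lon_min + small_grid.cell_size
        pts = pd.DataFrame({"lon": [edge_lon], "lat": [small_grid.lat_min + 0.05], "value": [1.0]})
        cells, _ = assign_points_to_grid(pts, small_grid)
        assert cells["cell_id"].tolist() == [1]

    def test_out_of_bounds_point_reported_not_dropped(self, small_grid):
        pts = pd.DataFrame(
            {"lon": [small_grid.lon_min - 1.0, small_grid.lon_min + 0.05],
             "lat": [small_grid.lat_min + 0.05] * 2, "value": [1.0, 2.0]}
        )
        cells, rejects = assign_points_to_grid(pts, small_grid)
        assert len(rejects) == 1 and len(cells) == 1


class TestOrdinaryKriging:
    def test_exact_interpolation_at_observation_with_zero_nugget(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        vals = np.array([1.0, 2.0, 3.0])
        sol = ordinary_kriging(coords, vals, coords[1][None, :], SPH)[0]
        assert sol.value == pytest.approx(2.0, abs=1e-10)
        assert sol.variance == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_pair_gives_half_weights(self):
        coords = np.array([[-1.0, 0.0], [1.0, 0.0]])
        vals = np.array([10.0, 20.0])
        sol = ordinary_kriging(coords, vals, np.array([[0.0, 0.5]]), SPH)[0]
        np.testing.assert_allclose(sol.weights, [0.5, 0.5], atol=1e-12)
        assert sol.value == pytest.approx(15.0)

    def test_three_observation_case_matches_dense_oracle(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        vals = np.array([1.0, 2.0, 3.0])
        target = np.array([0.25, 0.25])
        sol = ordinary_kriging(coords, vals, target[None, :], SPH)[0]
        expect, w, mu = ok_oracle(coords, vals, target, SPH)
        assert sol.value == pytest.approx(expect, abs=1e-10)
        np.testing.assert_allclose(sol.weights, w, atol=1e-10)
        assert sol.lagrange == pytest.approx(mu, abs=1e-10)

    @given(seed=st.integers(0, 200))
    def test_random_configurations_match_oracle_and_weights_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        coords = rng.uniform(0, 5, (n, 2))
        vals = rng.normal(50, 10, n)
        vg = VariogramModel("spherical", tau2=float(rng.uniform(0, 2)), sigma2=5.0, phi=0.4)
        target = rng.uniform(0, 5, 2)
        sol = ordinary_kriging(coords, vals, target[None, :], vg)[0]
        expect, w, _ = ok_oracle(coords, vals, target, vg)
        assert sol.value == pytest.approx(expect, abs=1e-8)
        assert abs(sol.weights.sum() - 1.0) < 1e-10
        assert sol.variance >= 0.0

    def test_duplicate_observations_rejected(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(SingularKrigingError, match="duplicate"):
            ordinary_kriging(coords, np.ones(3), np.array([[0.5, 0.5]]), SPH)

    def test_fewer_than_two_observations_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ordinary_kriging(np.array([[0.0, 0.0]]), np.array([1.0]), np.array([[1.0, 1.0]]), SPH)


def _toy_field(grid, observed_cells):
    """NaN field with the listed flat cell indices observed (value = index)."""
    f = np.full(grid.n_cells, np.nan)
    f[observed_cells] = np.asarray(observed_cells, dtype=float)
    return f.reshape(grid.shape)


class TestBufferGapfill:
    # 0.1-degree cells; range 0.25 deg -> donors within 2.5 cell widths
    VG = VariogramModel("spherical", tau2=0.0, sigma2=1.0, phi=4.0)

    def test_fill_rule_matches_combinatorial_oracle(self, small_grid):
        rng = np.random.default_rng(5)
        obs = np.sort(rng.choice(small_grid.n_cells, 60, replace=False))
        field = _toy_field(small_grid, obs)
        filled, prov, report = buffer_gapfill(field, small_grid, self.VG)
        centers = small_grid.cell_centers()
        obs_set = set(obs.tolist())
        for cid in range(small_grid.n_cells):
            d = np.linalg.norm(centers - centers[cid], axis=1)
            n_donors = sum(1 for j in obs_set if d[j] <= self.VG.effective_range)
            iy, ix = divmod(cid, small_grid.n_lon)
            if cid in obs_set:
                assert prov[iy, ix] == PROV_OBSERVED
            elif n_donors >= 5:
                assert prov[iy, ix] == PROV_INTERPOLATED
            else:
                assert prov[iy, ix] == PROV_MISSING
        assert report.n_filled == (prov == PROV_INTERPOLATED).sum()

    def test_four_donors_left_missing_five_filled(self):
        grid = GridSpec(0.0, 1.0, 0.0, 1.0, 0.1)
        # target cell center (0.55, 0.55) = cell id 55; donors in a ring
        target = 55
        ring4 = [54, 56, 45, 65]
        field4 = _toy_field(grid, ring4)
        _, prov4, rep4 = buffer_gapfill(field4, grid, self.VG)
        assert prov4.ravel()[target] == PROV_MISSING
        ring5 = ring4 + [44]
        field5 = _toy_field(grid, ring5)
        filled5, prov5, rep5 = buffer_gapfill(field5, grid, self.VG)
        assert prov5.ravel()[target] == PROV_INTERPOLATED
        assert np.isfinite(filled5.ravel()[target])

    def test_fully_observed_field_unchanged(self, small_grid, rng):
        field = rng.random(small_grid.shape)
        filled, prov, report = buffer_gapfill(field, small_grid, self.VG)
        np.testing.assert_array_equal(filled, field)
        assert report.n_filled == 0
        assert (prov == PROV_OBSERVED).all()

    def test_observed_cells_never_altered_and_fill_idempotent(self, small_grid):
        rng = np.random.default_rng(8)
        obs = np.sort(rng.choice(small_grid.n_cells, 80, replace=False))
        field = _toy_field(small_grid, obs)
        filled, prov, _ = buffer_gapfill(field, small_grid, self.VG)
        np.testing.assert_array_equal(
            filled.ravel()[obs], field.ravel()[obs]
        )
        # second pass on the observed-only view fills nothing new
        second_input = np.where(prov == PROV_OBSERVED, filled, np.nan)
        _, prov2, rep2 = buffer_gapfill(second_input, small_grid, self.VG)
        assert rep2.n_filled == (prov == PROV_INTERPOLATED).sum()
        np.testing.assert_array_equal(prov2, prov)
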