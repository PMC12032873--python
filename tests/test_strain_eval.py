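"""Strain evaluation: phase conversion, unwrapping, grid fit, tracking."""

import numpy as np
import pytest

from densesim.fourier import grid_coords
from densesim.strain_eval import (
    EulerianField,
    MaterialGrid,
    RegularizedFitConfig,
    bilinear_matrix,
    build_gridfit_system,
    laplacian_matrix,
    phase_to_eulerian,
    solve_gridfit,
    strain_from_trajectories,
    temporal_fit,
    unwrap_series,
)


class TestPhaseToEulerian:
    def test_closed_form_and_linearity(self):
        masks = np.ones((1, 4, 4), bool)
        f = phase_to_eulerian(np.full((1, 4, 4), np.pi), np.zeros((1, 4, 4)),
                              0.1, masks, [0.0])
        assert np.allclose(f.ux, 5.0)  # pi/(2 pi 0.1) = 5 mm
        f2 = phase_to_eulerian(np.full((1, 4, 4), np.pi / 2), np.zeros((1, 4, 4)),
                               0.1, masks, [0.0])
        assert np.allclose(f.ux, 2 * f2.ux)
        assert f.period == pytest.approx(10.0)

    def test_nonpositive_ke_rejected(self):
        with pytest.raises(ValueError):
            phase_to_eulerian(np.zeros((1, 2, 2)), np.zeros((1, 2, 2)), 0.0,
                              np.ones((1, 2, 2), bool), [0.0])


def _wrap(u, period):
    return (u + period / 2) % period - period / 2


class TestUnwrap:
    period = 10.0

    def _field(self, ux, masks):
        T = ux.shape[0]
        return EulerianField(ux, np.zeros_like(ux), masks,
                             np.arange(T, dtype=float), self.period, wrapped=True)

    def test_wrap_free_input_unchanged(self):
        rng = np.random.default_rng(0)
        ux = rng.uniform(-2, 2, (3, 16, 16))
        masks = np.ones((3, 16, 16), bool)
        out = unwrap_series(self._field(ux.copy(), masks))
        assert np.abs(out.ux - ux).max() < 1e-9

    def test_linear_ramp_recovered(self):
        # ramp 0 -> 8 mm wraps at 5 mm; recovery up to a global constant
        n = 32
        ramp = np.linspace(0, 8, n)[None, :].repeat(n, axis=0)
        ux = _wrap(ramp, self.period)[None]
        masks = np.ones((1, n, n), bool)
        out = unwrap_series(self._field(ux, masks))
        resid = out.ux[0] - ramp
        resid -= np.round(np.mean(resid) / self.period) * self.period
        assert np.sqrt(np.mean(resid**2)) < 0.1

    def test_gauge_freedom_full_period_offset(self):
        rng = np.random.default_rng(1)
        ux = rng.uniform(-2, 2, (1, 16, 16))
        masks = np.ones((1, 16, 16), bool)
        a = unwrap_series(self._field(ux.copy(), masks))
        b = unwrap_series(self._field(_wrap(ux + self.period, self.period), masks))
        diff = b.ux - a.ux
        assert np.abs(diff - np.round(diff[0, 0, 0] / self.period) * self.period).max() < 1e-9

    def test_disconnected_mask_warns(self):
        ux = np.zeros((1, 16, 16))
        masks = np.zeros((1, 16, 16), bool)
        masks[0, 2:5, 2:5] = True
        masks[0, 10:13, 10:13] = True
        with pytest.warns(UserWarning, match="components"):
            unwrap_series(self._field(ux, masks))


def _toy_grid(n=10, spacing=1.0):
    ax = (np.arange(n) + 0.5 - n / 2) * spacing
    mask = np.ones((n, n), bool)
    return MaterialGrid(ax, ax, (n, n), mask)


class TestGridFit:
    def test_zero_smoothness_interpolates_node_samples(self):
        g = _toy_grid(8)
        pts = g.node_points().reshape(-1, 2)
        rng = np.random.default_rng(0)
        vals = rng.normal(size=len(pts))
        A, L, lam = build_gridfit_system(pts, g.x, g.y, k=0.0)
        out = solve_gridfit(A, L, lam, vals)
        assert np.abs(out[:, 0] - vals).max() < 1e-8

    def test_high_smoothness_flattens_noisy_constant(self):
        g = _toy_grid(12)
        pts = g.node_points().reshape(-1, 2)
        rng = np.random.default_rng(1)
        vals = 3.0 + rng.normal(0, 0.5, len(pts))
        A, L, lam = build_gridfit_system(pts, g.x, g.y, k=0.999)
        out = solve_gridfit(A, L, lam, vals)[:, 0]
        assert out.std() < vals.std()
        assert abs(out.mean() - vals.mean()) < 0.05

    def test_solution_minimizes_objective(self):
        g = _toy_grid(10)
        pts = g.node_points().reshape(-1, 2)
        rng = np.random.default_rng(2)
        vals = rng.normal(size=len(pts))
        A, L, lam = build_gridfit_system(pts, g.x, g.y, k=0.6)
        u = solve_gridfit(A, L, lam, vals)[:, 0]

        def objective(v):
            return np.sum((A @ v - vals) ** 2) + lam * np.sum((L @ v) ** 2)

        base = objective(u)
        for _ in range(20):
            pert = u + 1e-3 * rng.standard_normal(u.size)
            assert objective(pert) > base

    @pytest.mark.parametrize("n", [6, 12])
    @pytest.mark.parametrize("k", [0.1, 0.9])
    def test_sparse_solution_matches_dense_solve(self, n, k):
        g = _toy_grid(n)
        rng = np.random.default_rng(3)
        # scattered (off-node) samples
        pts = rng.uniform(g.x[0], g.x[-1], (3 * n * n, 2))
        vals = np.sin(pts[:, 0]) + pts[:, 1] ** 2 / 10
        A, L, lam = build_gridfit_system(pts, g.x, g.y, k)
        sparse_sol = solve_gridfit(A, L, lam, vals)[:, 0]
        Ad, Ld = A.toarray(), L.toarray()
        dense_sol = np.linalg.solve(Ad.T @ Ad + lam * (Ld.T @ Ld), Ad.T @ vals)
        assert np.abs(sparse_sol - dense_sol).max() < 1e-8

    def test_underdetermined_zero_smoothness_falls_back_to_ridge(self):
        g = _toy_grid(8)
        pts = g.node_points().reshape(-1, 2)[:10]  # most nodes unconstrained
        A, L, lam = build_gridfit_system(pts, g.x, g.y, k=0.0)
        with pytest.warns(UserWarning, match="ridge"):
            out = solve_gridfit(A, L, lam, np.ones(10))
        assert np.all(np.isfinite(out))

    def test_bilinear_matrix_partitions_unity(self):
        g = _toy_grid(9)
        rng = np.random.default_rng(4)
        pts = rng.uniform(g.x[0], g.x[-1], (50, 2))
        A = bilinear_matrix(pts, g.x, g.y)
        assert np.allclose(np.asarray(A.sum(axis=1)).ravel(), 1.0)

    def test_laplacian_annihilates_linear_fields(self):
        L = laplacian_matrix((7, 7))
        X, Y = np.meshgrid(np.arange(7), np.arange(7))
        lin = (2.0 + 0.3 * X - 1.2 * Y).ravel()
        assert np.abs(L @ lin).max() < 1e-12


class TestTemporalFit:
    def test_polynomial_trajectory_reproduced_exactly(self):
        t = np.linspace(0, 1000, 40)
        s = (t - t.mean()) / 500
        traj = (1.5 * s**3 - 0.2 * s + 0.7)[:, None, None] * np.ones((1, 2))
        out = temporal_fit(traj, t, order=10)
        assert np.abs(out - traj).max() < 1e-9

    def test_constant_trajectory_preserved(self):
        t = np.linspace(0, 500, 20)
        traj = np.full((20, 3, 2), 2.5)
        assert np.abs(temporal_fit(traj, t, 10) - traj).max() < 1e-10

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1000, 40)
        clean = np.sin(2 * np.pi * t / 1000)[:, None, None] * np.ones((1, 2))
        noisy = clean + rng.normal(0, 0.2, clean.shape)
        out = temporal_fit(noisy, t, order=10)
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_order_reduced_with_warning_when_frames_scarce(self):
        t = np.linspace(0, 100, 6)
        traj = np.ones((6, 1, 2))
        with pytest.warns(UserWarning, match="reducing"):
            temporal_fit(traj, t, order=10)


class TestStrainFromTrajectories:
    def _grid_and_geometry(self, small_annulus, n=64):
        from densesim.motion import DeformationModel, MotionParams

        lm, geo = small_annulus
        model = DeformationModel(lm, geo, MotionParams(peak_ecc_scale=0.18))
        mask = model.deformed_mask(0.0, n, lm.fov / n)
        ax = grid_coords(n, lm.fov)
        grid = MaterialGrid(ax, ax, (n, n), mask)
        return grid, geo, model

    def test_ground_truth_trajectories_give_zero_error(self, small_annulus):
        # shared operator: feeding the true trajectories reproduces the
        # ground-truth strain exactly (ASE = 0)
        from densesim.strain_eval import ground_truth_on_grid

        grid, geo, model = self._grid_and_geometry(small_annulus)
        times = [0.0, 150.0, 300.0]
        ref = grid.node_points()[grid.ref_mask]
        traj = np.stack([model.map_points(ref, t) for t in times])
        est = strain_from_trajectories(traj, times, grid, geo)
        gt = ground_truth_on_grid(model, geo, grid, times)
        v = est.valid & gt.valid
        assert np.array_equal(est.err[:, v], gt.err[:, v])
        assert np.array_equal(est.ecc[:, v], gt.ecc[:, v])

    def test_uniform_scaling_closed_form(self, small_annulus):
        grid, geo, _ = self._grid_and_geometry(small_annulus)
        ref = grid.node_points()[grid.ref_mask]
        center = geo.center
        traj = np.stack([ref, center + 0.8 * (ref - center)])
        sm = strain_from_trajectories(traj, [0.0, 100.0], grid, geo)
        v = sm.valid
        assert np.nanmax(np.abs(sm.err[1][v] + 0.18)) < 1e-9
        assert np.nanmax(np.abs(sm.ecc[1][v] + 0.18)) < 1e-9


class TestEndToEndNoiseFree:
    def test_cartesian_pipeline_recovers_strain(self, cartesian_case):
        from densesim.strain_eval import (evaluate_series, ground_truth_on_grid,
                                          prepare_eulerian)

        c = cartesian_case
        fov = c["labelmap"].fov
        prep = prepare_eulerian(c["series"], c["model"], fov)
        gt = ground_truth_on_grid(c["model"], c["geometry"], prep[1],
                                  c["series"].frame_times)
        est = evaluate_series(c["series"], c["model"], c["geometry"], fov,
                              RegularizedFitConfig(k=0.1), prepared=prep)
        es = c["series"].es_index
        v = gt.valid & est.valid
        ecc_ase = np.nanmean((gt.ecc[es] - est.ecc[es])[v])
        assert abs(ecc_ase) < 0.02

    def test_estimated_transmural_profile_matches_truth(self, cartesian_case):
        from densesim.cohort import transmural_profile
        from densesim.strain_eval import (evaluate_series, ground_truth_on_grid,
                                          prepare_eulerian)

        c = cartesian_case
        fov = c["labelmap"].fov
        prep = prepare_eulerian(c["series"], c["model"], fov)
        gt = ground_truth_on_grid(c["model"], c["geometry"], prep[1],
                                  c["series"].frame_times)
        est = evaluate_series(c["series"], c["model"], c["geometry"], fov,
                              RegularizedFitConfig(k=0.1), prepared=prep)
        es = c["series"].es_index
        for frame_map in (gt, est):
            frame_map.valid &= gt.valid & est.valid
        _, m_gt, _ = transmural_profile(gt, es, "Ecc", n_bins=3)
        _, m_est, _ = transmural_profile(est, es, "Ecc", n_bins=3)
        assert np.nanmax(np.abs(m_gt - m_est)) < 0.02
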