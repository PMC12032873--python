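"""Acquisition module: timing, signal model, gridding, windowing, noise."""

import numpy as np
import pytest

from densesim.acquisition import (
    AcqParams,
    ConfigError,
    DEFAULT_TISSUES,
    TissueProperty,
    apply_excitation_window,
    assign_tissue_properties,
    build_spiral_schedule,
    calibrate_noise,
    combine_encodings,
    combine_phase_cycles,
    excitation_window_profile,
    flip_angle_schedule,
    grid_isochromats,
    measure_snr,
    simulate_dense_signal,
    stimulated_echo_amplitude,
)
from densesim.motion import MotionField

FOV = 192.0


# ---------------------------------------------------------------------------
# spiral schedule
# ---------------------------------------------------------------------------


class TestSchedule:
    def test_interleaf_times_match_protocol_example(self):
        # interleave 1 at [15, 45, 75] ms, interleave 2 at [30, 60, 90] ms
        acq = AcqParams(n_frames=3)
        s = build_spiral_schedule(acq, 1000.0, rng=None)
        assert np.array_equal(s.t_lci[0, 0], [15.0, 45.0, 75.0])
        assert np.array_equal(s.t_lci[1, 0], [30.0, 60.0, 90.0])

    def test_combined_and_interpolated_frame_times(self):
        acq = AcqParams(n_frames=4, interpolate_frames=True)
        s = build_spiral_schedule(acq, 1000.0, rng=None)
        assert np.array_equal(s.frame_times, 22.5 + 30.0 * np.arange(4))
        assert np.array_equal(s.interp_frame_times, 37.5 + 30.0 * np.arange(3))

    def test_times_satisfy_timing_law_exactly(self):
        acq = AcqParams()
        rng = np.random.default_rng(0)
        s = build_spiral_schedule(acq, 1100.0, rng=rng)
        for l in (1, 2):
            for c in (1, 2):
                expected = 15.0 + s.jitter[c - 1] + 30.0 * (l - 1) / 2 + 30.0 * np.arange(s.n_frames)
                assert np.array_equal(s.t_lci[l - 1, c - 1], expected)
        assert np.abs(s.jitter).max() <= 5.0

    def test_frame_count_fills_cardiac_cycle(self):
        acq = AcqParams()
        assert build_spiral_schedule(acq, 825.0).n_frames in (26, 27)
        assert build_spiral_schedule(acq, 1200.0).n_frames in (39, 40)

    def test_overlong_schedule_truncated_with_warning(self):
        acq = AcqParams(n_frames=50)
        with pytest.warns(UserWarning, match="truncat"):
            s = build_spiral_schedule(acq, 900.0)
        assert s.t_lci.max() <= 900.0

    def test_coverage_start_shifts_imaging_train(self):
        # prospective triggering: a 60 ms offset delays every frame
        from densesim.acquisition import DenseSimulator
        from densesim.anatomy import generate_annulus, polar_geometry
        from densesim.motion import DeformationModel, MotionParams

        lm = generate_annulus(80, 2.4, 22, 36)
        geo = polar_geometry(lm)
        p = MotionParams(rr_interval=900.0, peak_ecc_scale=0.12, coverage_start=60.0)
        model = DeformationModel(lm, geo, p)
        acq = AcqParams(N1=80, N2=40, Nf=48, n_frames=4, sampling="cartesian")
        series = DenseSimulator(lm, geo, model, acq).run()
        assert series.frame_times[0] == pytest.approx(15.0 + 60.0 + 7.5)

    def test_interpolation_doubles_temporal_resolution(self):
        a0 = AcqParams(n_frames=10)
        a1 = AcqParams(n_frames=10, interpolate_frames=True)
        s0 = build_spiral_schedule(a0, 1000.0)
        s1 = build_spiral_schedule(a1, 1000.0)
        n0 = len(s0.frame_times)
        assert len(s1.frame_times) + len(s1.interp_frame_times) == 2 * n0 - 1

    def test_interpolated_frames_encode_motion_at_their_nominal_times(self):
        # reconstructed phase of an interpolated frame tracks the Eulerian
        # displacement at 37.5 + 30 i ms within a few percent
        from scipy import ndimage

        from densesim.acquisition import DenseSimulator
        from densesim.anatomy import generate_annulus, polar_geometry
        from densesim.fourier import grid_coords
        from densesim.motion import DeformationModel, MotionParams

        lm = generate_annulus(80, 2.4, 22, 36)
        geo = polar_geometry(lm)
        model = DeformationModel(lm, geo, MotionParams(rr_interval=900.0,
                                                       peak_ecc_scale=0.14,
                                                       peak_rotation=0.1))
        acq = AcqParams(N1=80, N2=40, Nf=48, n_frames=6, interpolate_frames=True)
        series = DenseSimulator(lm, geo, model, acq,
                                rng=np.random.default_rng(0)).run()
        assert len(series.frame_times) == 11
        assert series.frame_times[1] == pytest.approx(37.5)
        f = 3  # interpolated frame at 67.5 ms
        t = series.frame_times[f]
        mask = ndimage.binary_erosion(model.deformed_mask(t, 48, lm.fov / 48))
        ax = grid_coords(48, lm.fov)
        X, Y = np.meshgrid(ax, ax)
        u = model.eulerian_displacement(np.stack([X, Y], -1).reshape(-1, 2),
                                        t).reshape(48, 48, 2)
        ux = series.phase_x[f] / (2 * np.pi * acq.ke)
        rel = (np.sqrt(np.mean((ux - u[..., 0])[mask] ** 2))
               / np.sqrt(np.mean(u[mask, 0] ** 2)))
        assert rel < 0.1


# ---------------------------------------------------------------------------
# tissue properties and signal model
# ---------------------------------------------------------------------------


class TestTissues:
    def test_rasters_carry_table_values(self, small_annulus):
        lm, _ = small_annulus
        props = assign_tissue_properties(lm, DEFAULT_TISSUES)
        assert set(np.unique(props["t1"][lm.myocardium])) == {1200.0}
        assert set(np.unique(props["t1"][lm.blood])) == {1900.0}

    def test_missing_label_rejected(self, small_annulus):
        lm, _ = small_annulus
        with pytest.raises(ConfigError):
            assign_tissue_properties(lm, {0: DEFAULT_TISSUES[0], 1: DEFAULT_TISSUES[1]})

    def test_unphysical_relaxation_rejected(self):
        with pytest.raises(ConfigError):
            TissueProperty(t1=50.0, t2=100.0, m0=1.0)

    def test_dark_blood_decays_rapidly(self):
        # blood stimulated-echo amplitude at frame 5 under 10% of frame 1
        acq = AcqParams()
        t = 22.5 + 30.0 * np.arange(6)
        flips = flip_angle_schedule(6, acq.dt, DEFAULT_TISSUES[1].t1, acq.flip_final)
        blood = DEFAULT_TISSUES[2]

        def amp(i):
            return (stimulated_echo_amplitude(flips, i) * np.exp(-t[i] / blood.t1)
                    * np.exp(-t[i] / blood.washout))

        assert amp(5) < 0.1 * amp(0)


class TestFlipSchedule:
    def test_equalizes_stimulated_echo_amplitude(self):
        t1 = 1200.0
        dt = 30.0
        flips = flip_angle_schedule(20, dt, t1, 15.0)
        t = 15.0 + dt * np.arange(20)
        amps = [stimulated_echo_amplitude(flips, i) * np.exp(-t[i] / t1) for i in range(20)]
        assert np.ptp(amps) / np.mean(amps) < 1e-9
        assert flips[-1] == pytest.approx(np.deg2rad(15.0))


def _single_pixel_field(disp, times):
    ref = np.zeros((1, 2))
    d = np.tile(np.asarray(disp, dtype=float), (len(times), 1, 1))
    d[0] = 0.0
    return MotionField(ref, np.asarray(times, dtype=float), d,
                       (np.array([0]), np.array([0])), (1, 1), 1.0)


class TestSignalModel:
    props = {"t1": np.array([1200.0]), "t2": np.array([50.0]),
             "m0": np.array([1.0]), "washout": np.array([np.inf])}

    def test_displacement_phase_is_2pi_ke_u(self):
        # 2 mm along x at ke = 0.1 -> phase 0.4 pi
        field = _single_pixel_field([[2.0, 0.0]], [0.0, 100.0])
        ste, _, _ = simulate_dense_signal(field, self.props, AcqParams(), 0, "x")
        assert np.angle(ste[1, 0]) == pytest.approx(0.4 * np.pi, abs=1e-12)

    def test_reference_encoding_has_zero_phase(self):
        field = _single_pixel_field([[3.0, -2.0]], [0.0, 100.0])
        ste, _, _ = simulate_dense_signal(field, self.props, AcqParams(), 0, "none")
        assert np.abs(np.angle(ste)).max() < 1e-12

    def test_two_point_cycling_cancels_recovery_algebraically(self):
        field = _single_pixel_field([[1.0, 0.5]], [0.0, 60.0, 120.0])
        acq = AcqParams()
        sigs = []
        for p in range(2):
            ste, rec, _ = simulate_dense_signal(field, self.props, acq, p, "x")
            sigs.append(ste + rec)
        combined = combine_phase_cycles(sigs)
        ste0, rec0, _ = simulate_dense_signal(field, self.props, acq, 0, "x")
        assert np.abs(combined - ste0).max() < 1e-12 * np.abs(rec0).max()

    def test_phase_cycle_out_of_range(self):
        field = _single_pixel_field([[0.0, 0.0]], [0.0])
        with pytest.raises(ConfigError):
            simulate_dense_signal(field, self.props, AcqParams(), 5, "x")


# ---------------------------------------------------------------------------
# gridding and windowing
# ---------------------------------------------------------------------------


class TestGridding:
    def test_intravoxel_dephasing_cancels_opposed_phases(self):
        acq = AcqParams(N1=120, N2=60)
        # opposed-phase isochromats sharing one N2 voxel (3.2 mm): their
        # coherent sum vanishes; a finite offset leaves only the band-limited
        # dipole residual
        pos = np.array([[0.3, 0.0], [0.3, 0.0]])
        img_pair = grid_isochromats([1.0, np.exp(1j * np.pi)], pos, acq, FOV)
        img_single = grid_isochromats([1.0], pos[:1], acq, FOV)
        assert np.abs(img_pair).max() < 1e-6 * np.abs(img_single).max()

    def test_partial_cancellation_for_offset_opposed_pair(self):
        acq = AcqParams(N1=120, N2=60)
        pos = np.array([[0.0, 0.0], [0.8, 0.0]])
        img_pair = grid_isochromats([1.0, -1.0], pos, acq, FOV)
        img_sum = grid_isochromats([1.0, 1.0], pos, acq, FOV)
        assert np.abs(img_pair).max() < 0.5 * np.abs(img_sum).max()

    def test_outside_fov_excluded_with_warning(self):
        acq = AcqParams(N1=120, N2=60)
        with pytest.warns(UserWarning, match="outside"):
            img = grid_isochromats([1.0, 1.0], [[0.0, 0.0], [500.0, 0.0]], acq, FOV)
        ref = grid_isochromats([1.0], [[0.0, 0.0]], acq, FOV)
        assert np.abs(img - ref).max() < 1e-12


class TestSampleAndReconstruct:
    def _static_setup(self, t2star=40.0):
        from densesim.acquisition import sample_and_reconstruct
        from densesim.anatomy import generate_annulus

        acq = AcqParams(N1=120, N2=40, Nf=48, n_frames=1, t2star=t2star)
        schedule = build_spiral_schedule(acq, 900.0)
        lm = generate_annulus(120, 1.6, 37.5, 60)
        x, y = lm.coordinates()
        myo = lm.myocardium
        pos = np.stack([x[myo], y[myo]], axis=-1)
        sig = np.ones(len(pos), dtype=complex)
        img = apply_excitation_window(grid_isochromats(sig, pos, acq, FOV), FOV)
        frames = {(l, c, 0): img for l in (1, 2) for c in (1, 2)}
        return sample_and_reconstruct, frames, schedule, acq, img

    def test_static_noiseless_recon_matches_cartesian_reference(self):
        from densesim.fourier import image_from_kspace, kspace_on_grid

        fn, frames, schedule, acq, img = self._static_setup(t2star=np.inf)
        rec = fn(frames, schedule, acq, FOV)
        ref = image_from_kspace(kspace_on_grid(img, FOV), acq.Nf, FOV)
        m = np.abs(ref) > 0.1 * np.abs(ref).max()
        nrmse = np.sqrt(np.mean(np.abs(rec[0] - ref)[m] ** 2)
                        / np.mean(np.abs(ref)[m] ** 2))
        assert nrmse < 0.05

    def test_long_t2star_converges_to_undecayed_case(self):
        fn, frames, schedule, acq, _ = self._static_setup(t2star=40.0)
        rec_decayed = fn(frames, schedule, acq, FOV)
        rec_mid = fn(frames, schedule, AcqParams(N1=120, N2=40, Nf=48, n_frames=1,
                                                 t2star=4000.0), FOV)
        rec_inf = fn(frames, schedule, AcqParams(N1=120, N2=40, Nf=48, n_frames=1,
                                                 t2star=np.inf), FOV)
        d_mid = np.abs(rec_mid - rec_inf).max()
        d_short = np.abs(rec_decayed - rec_inf).max()
        assert d_mid < 0.02 * d_short  # ~two orders closer to the undecayed case

    def test_missing_interleaf_rejected(self):
        from densesim.acquisition import ConfigError, sample_and_reconstruct

        fn, frames, schedule, acq, _ = self._static_setup()
        del frames[(2, 2, 0)]
        with pytest.raises(ConfigError):
            sample_and_reconstruct(frames, schedule, acq, FOV)


class TestWindow:
    def test_center_gain_is_unity(self):
        assert excitation_window_profile(0.0, FOV) == pytest.approx(1.0)

    def test_half_maximum_at_03_width(self):
        assert excitation_window_profile(0.3 * FOV, FOV) == pytest.approx(0.5, rel=0.01)

    def test_corner_floor(self):
        corner = excitation_window_profile(np.hypot(FOV / 2, FOV / 2), FOV)
        assert corner <= 0.08

    def test_window_applies_radially(self):
        img = np.ones((64, 64))
        out = apply_excitation_window(img, FOV)
        assert out[32, 32] > 0.99
        assert np.abs(out - out.T).max() < 1e-12  # radial symmetry


# ---------------------------------------------------------------------------
# combination and SNR
# ---------------------------------------------------------------------------


class TestCombination:
    def test_identical_cycles_degenerate_to_scaling(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        out = combine_phase_cycles([f, f])
        # opposite weights on identical data: pure scaling, no echo survives
        assert np.abs(out).max() < 1e-12

    def test_single_cycle_passthrough(self):
        f = np.ones((4, 4), dtype=complex)
        assert np.array_equal(combine_phase_cycles([f]), f)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            combine_phase_cycles([np.zeros((4, 4)), np.zeros((5, 5))])

    def test_magnitude_average_idempotent(self):
        m = np.random.default_rng(1).random((6, 6))
        mag, px, py = combine_encodings(m, m, m * 0, m * 0, m * 0)
        assert np.array_equal(mag, m)

    def test_reference_subtraction_and_wrap(self):
        z = np.zeros((2, 2))
        mag, px, _ = combine_encodings(z + 1, z + 1, z + 3.0, z, z - 3.0)
        assert np.all(px <= np.pi) and np.all(px > -np.pi)
        assert px[0, 0] == pytest.approx(6.0 - 2 * np.pi)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_encodings(np.zeros((4, 4)), np.zeros((5, 5)),
                              np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)))


class TestSNR:
    def test_constant_plus_noise_estimates_ratio(self):
        rng = np.random.default_rng(2)
        img = 10.0 + rng.normal(0, 1.0, (40, 40))
        assert measure_snr(img, np.ones((40, 40), bool)) == pytest.approx(10.0, rel=0.1)

    def test_constant_region_gives_infinity(self):
        assert measure_snr(np.full((8, 8), 3.0), np.ones((8, 8), bool)) == np.inf

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        img = 5.0 + rng.normal(0, 0.5, (30, 30))
        m = np.ones((30, 30), bool)
        assert measure_snr(img, m) == pytest.approx(measure_snr(10 * img, m))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            measure_snr(np.ones((8, 8)), np.zeros((8, 8), bool))

    def test_calibration_requires_positive_target(self):
        with pytest.raises(ValueError):
            calibrate_noise(np.ones((8, 8)), np.ones((8, 8)), np.ones((8, 8), bool),
                            -1.0, np.random.default_rng(0), 1.0)
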