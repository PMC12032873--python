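"""Bloch-simulation cine DENSE image generation.

Simulates a 2D spiral cine DENSE acquisition from ground-truth Lagrangian
displacements: stimulated-echo displacement encoding (k_e cycles/mm) with
n-point phase cycling and a variable flip-angle readout train, isochromat
gridding with intravoxel dephasing (N1 -> N2 Fourier interpolation), a
radial Hamming excitation window, interleaved spiral sampling across two
cardiac cycles with ECG-trigger jitter and T2* readout decay, calibrated
complex k-space noise, and density-compensated adjoint reconstruction onto
an Nf x Nf grid. x/y/0-encodings are combined into magnitude and
reference-subtracted phase images.

Signal model per isochromat (two-term):

* stimulated echo — amplitude 0.5 * M0 * sin(a_i) * prod_{j<i} cos(a_j)
  * exp(-t/T1), phase 2 pi k_e (x(t) - x(0)).e + phase-cycling offset;
  blood additionally decays with a washout time constant (dark blood);
* T1-recovery echo — amplitude M0 * (1 - exp(-t/T1)) * sin(a_i), phase
  2 pi k_e x(t).e (position-encoded, not displacement-encoded), no cycling
  offset; n-point cycling is designed to cancel it.

The variable flip angles a_i follow the standard constant-stimulated-echo
backward recursion tan(a_i) = sin(a_{i+1}) exp(-dt/T1_myo) ending at
``flip_final``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .anatomy import LabelMap, PolarGeometry
from .fourier import (
    SpiralTrajectory,
    grid_coords,
    image_from_kspace,
    isochromat_kspace,
    kgrid,
    kspace_on_grid,
)
from .motion import DeformationModel, MotionField

__all__ = [
    "AcqParams",
    "TissueProperty",
    "TissueProperties",
    "SpiralSchedule",
    "DenseSeries",
    "ConfigError",
    "DEFAULT_TISSUES",
    "assign_tissue_properties",
    "flip_angle_schedule",
    "stimulated_echo_amplitude",
    "simulate_dense_signal",
    "grid_isochromats",
    "apply_excitation_window",
    "excitation_window_profile",
    "build_spiral_schedule",
    "sample_and_reconstruct",
    "combine_phase_cycles",
    "combine_encodings",
    "measure_snr",
    "calibrate_noise",
    "simulate_case",
    "DenseSimulator",
]


class ConfigError(ValueError):
    """Invalid acquisition/tissue configuration."""


# ---------------------------------------------------------------------------
# parameters and tissue properties
# ---------------------------------------------------------------------------


@dataclass
class AcqParams:
    """DENSE acquisition parameters (defaults follow a typical 2D spiral
    cine DENSE protocol: k_e = 0.1 cycles/mm, first imaging pulse at 15 ms,
    30 ms inter-frame spacing, +/-5 ms trigger jitter, T2* = 40 ms)."""

    ke: float = 0.1  # cycles/mm, encoding strength
    t_start: float = 15.0  # ms, first imaging RF pulse
    dt: float = 30.0  # ms, inter-frame spacing
    jitter_bound: float = 5.0  # ms, ECG trigger uncertainty per cycle
    t2star: float = 40.0  # ms, readout decay
    N1: int = 240  # ground-truth grid (set from the label map when simulating)
    N2: int = 60  # gridding size (intravoxel dephasing)
    Nf: int = 128  # reconstruction size
    n_phase_cycles: int = 2
    interpolate_frames: bool = False
    target_snr: float | None = None  # None = noiseless
    flip_final: float = 15.0  # deg, final readout flip angle
    readout_duration: float = 11.0  # ms, spiral readout length
    n_frames: int | None = None  # None = fill the cardiac cycle
    n_interleaves: int = 4
    sampling: str = "spiral"  # "spiral" | "cartesian"
    sample_density: float = 1.2  # spiral samples vs Nyquist arc length

    def __post_init__(self):
        if self.ke <= 0:
            raise ConfigError("ke must be > 0")
        if not self.N2 < self.N1:
            raise ConfigError("require N2 < N1")
        if self.Nf < self.N2:
            raise ConfigError("require Nf >= N2")
        if self.n_phase_cycles < 1:
            raise ConfigError("n_phase_cycles must be >= 1")
        if self.sampling not in ("spiral", "cartesian"):
            raise ConfigError(f"unknown sampling '{self.sampling}'")


@dataclass
class TissueProperty:
    """Relaxation/equilibrium parameters of one tissue label (3T values)."""

    t1: float  # ms
    t2: float  # ms
    m0: float  # a.u.
    washout: float | None = None  # ms; finite = dark-blood decay

    def __post_init__(self):
        if not (self.t1 > self.t2 > 0):
            raise ConfigError("require T1 > T2 > 0")
        if self.m0 < 0:
            raise ConfigError("require M0 >= 0")


TissueProperties = dict  # label -> TissueProperty

# literature-based 3T values, empirically scaled M0; blood carries the
# dark-blood washout decay
DEFAULT_TISSUES: TissueProperties = {
    0: TissueProperty(t1=1000.0, t2=100.0, m0=0.0),
    1: TissueProperty(t1=1200.0, t2=50.0, m0=1.0),
    2: TissueProperty(t1=1900.0, t2=250.0, m0=1.2, washout=25.0),
}


def assign_tissue_properties(labelmap: LabelMap, table: TissueProperties):
    """Per-pixel T1/T2/M0/washout rasters from a label->property table."""
    labels = labelmap.labels
    present = np.unique(labels)
    missing = [int(v) for v in present if int(v) not in table]
    if missing:
        raise ConfigError(f"no tissue properties for labels {missing}")
    shape = labels.shape
    out = {
        "t1": np.zeros(shape),
        "t2": np.zeros(shape),
        "m0": np.zeros(shape),
        "washout": np.full(shape, np.inf),
    }
    for lab in present:
        p = table[int(lab)]
        sel = labels == lab
        out["t1"][sel] = p.t1
        out["t2"][sel] = p.t2
        out["m0"][sel] = p.m0
        out["washout"][sel] = p.washout if p.washout is not None else np.inf
    return out


# ---------------------------------------------------------------------------
# spiral schedule
# ---------------------------------------------------------------------------


@dataclass
class SpiralSchedule:
    """Interleaf acquisition times of a 4-interleaf / 2-cycle spiral DENSE
    protocol: t_lci = t_start + eps_c + dt (l-1)/2 + dt i."""

    t_lci: np.ndarray  # (2, 2, T): [l-1, c-1, i]
    frame_times: np.ndarray  # (T,) nominal combined times t_start + dt/4 + dt i
    interp_frame_times: np.ndarray  # (T-1,) or empty
    interleaf_rotations: np.ndarray  # (4,) rad, one per (l, c)
    jitter: np.ndarray  # (2,) eps_c in ms

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


def build_spiral_schedule(acq: AcqParams, rr_interval: float,
                          rng: np.random.Generator | None = None) -> SpiralSchedule:
    """Interleaf/frame timing with per-cardiac-cycle ECG-trigger jitter."""
    eps = np.zeros(2) if rng is None else rng.uniform(-acq.jitter_bound, acq.jitter_bound, 2)
    max_t = int(np.floor((rr_interval - acq.t_start - acq.jitter_bound - acq.dt / 2) / acq.dt)) + 1
    T = acq.n_frames if acq.n_frames is not None else max_t
    if T > max_t:
        warnings.warn(f"schedule exceeds R-R interval; truncating {T} -> {max_t} frames")
        T = max_t
    if T < 1:
        raise ConfigError("R-R interval too short for a single frame")
    i = np.arange(T)
    l = np.array([1, 2])[:, None, None]
    c = np.arange(2)[None, :, None]
    t_lci = acq.t_start + eps[c] + acq.dt * (l - 1) / 2 + acq.dt * i
    frame_times = acq.t_start + acq.dt / 4 + acq.dt * i
    interp = acq.t_start + 3 * acq.dt / 4 + acq.dt * np.arange(T - 1) \
        if acq.interpolate_frames else np.array([])
    rotations = np.pi / 2 * np.arange(4)  # interleaf (l, c) -> index (l-1) + 2(c-1)
    return SpiralSchedule(t_lci, frame_times, interp, rotations, eps)


def interleaf_rotation_index(l: int, c: int) -> int:
    """Spiral rotation index of interleaf l in cardiac cycle c (1-based)."""
    return (l - 1) + 2 * (c - 1)


# ---------------------------------------------------------------------------
# signal model
# ---------------------------------------------------------------------------


def flip_angle_schedule(n_frames: int, dt: float, t1: float, flip_final_deg: float) -> np.ndarray:
    """Variable flip angles (rad) equalizing stimulated-echo amplitude.

    Backward recursion tan(a_i) = sin(a_{i+1}) exp(-dt/T1), a_{T-1} = final.
    """
    a = np.empty(n_frames)
    a[-1] = np.deg2rad(flip_final_deg)
    decay = np.exp(-dt / t1)
    for i in range(n_frames - 2, -1, -1):
        a[i] = np.arctan(np.sin(a[i + 1]) * decay)
    return a


def stimulated_echo_amplitude(flips: np.ndarray, frame: int) -> float:
    """sin(a_i) * prod_{j<i} cos(a_j): readout of the stored magnetization."""
    return float(np.sin(flips[frame]) * np.prod(np.cos(flips[:frame])))


def simulate_dense_signal(
    field: MotionField,
    props: dict,
    acq: AcqParams,
    phase_cycle: int,
    encoding: str,
    flips: np.ndarray | None = None,
    frame_indices=None,
):
    """Two-term complex isochromat signals at each frame of ``field``.

    ``props`` are flat per-isochromat arrays (keys t1, t2, m0, washout) or
    rasters, matched to the field's pixels. Returns ``(ste, rec, positions)``
    where ``ste``/``rec`` are (T, P) stimulated-echo and T1-recovery terms
    (the phase-cycling offset of cycle ``phase_cycle`` is applied to the
    stimulated echo) and ``positions`` (T, P, 2) the deformed positions.
    """
    if phase_cycle >= acq.n_phase_cycles:
        raise ConfigError("phase_cycle index out of range")
    enc = _encoding_vector(encoding)
    times = field.frame_times
    T, P = len(times), len(field.ref_positions)
    if frame_indices is None:
        frame_indices = np.arange(T)
    if flips is None:
        flips = flip_angle_schedule(int(np.max(frame_indices)) + 1, acq.dt,
                                    DEFAULT_TISSUES[1].t1, acq.flip_final)
    pr = {k: (v[field.pixel_index] if np.ndim(v) == 2 else np.asarray(v)) for k, v in props.items()}
    theta = 2 * np.pi * phase_cycle / acq.n_phase_cycles

    ste = np.empty((T, P), dtype=complex)
    rec = np.empty((T, P), dtype=complex)
    positions = np.empty((T, P, 2))
    for f, t in enumerate(times):
        i = int(frame_indices[f])
        pos = field.deformed_positions(f)
        positions[f] = pos
        readout = stimulated_echo_amplitude(flips, i)
        amp = 0.5 * pr["m0"] * readout * np.exp(-t / pr["t1"])
        amp = amp * np.exp(-t / pr["washout"])
        if enc is None:
            ph = np.zeros(P)
            ph_rec = np.zeros(P)
        else:
            u = field.displacements[f]
            ph = 2 * np.pi * acq.ke * (u @ enc)
            ph_rec = 2 * np.pi * acq.ke * (pos @ enc)
        ste[f] = amp * np.exp(1j * (ph + theta))
        rec[f] = pr["m0"] * (1 - np.exp(-t / pr["t1"])) * np.sin(flips[i]) * np.exp(1j * ph_rec)
    return ste, rec, positions


def _encoding_vector(encoding: str):
    if encoding in ("none", "0", None):
        return None
    if encoding == "x":
        return np.array([1.0, 0.0])
    if encoding == "y":
        return np.array([0.0, 1.0])
    raise ConfigError(f"unknown encoding '{encoding}'")


# ---------------------------------------------------------------------------
# gridding, windowing, reconstruction
# ---------------------------------------------------------------------------


def grid_isochromats(signals, positions, acq: AcqParams, fov: float,
                     warn_outside: bool = True) -> np.ndarray:
    """Band-limited (Fourier-interpolation) gridding onto the N2 image.

    Gridding through a truncated k-space sums isochromats within each
    resolution cell coherently, which is what produces intravoxel dephasing
    of the displacement-encoded phase.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    s = np.asarray(signals, dtype=complex).ravel()
    inside = np.all(np.abs(pos) <= fov / 2, axis=1)
    if not inside.all():
        if warn_outside:
            warnings.warn(f"{np.count_nonzero(~inside)} isochromats outside the FOV; excluded")
        pos, s = pos[inside], s[inside]
    K = isochromat_kspace(s, pos, acq.N2, fov)
    return image_from_kspace(K, acq.N2, fov)


def excitation_window_profile(radius, width: float):
    """Radial Hamming gain: 1 at the center, 0.5 at radius 0.3 * width
    (half-maximum diameter 0.6 * width), 0.08 floor outside the taper."""
    # solve 0.54 + 0.46 cos(pi d/D) = 0.5 at d = 0.3 width
    D = 0.3 * width / (np.arccos(-0.04 / 0.46) / np.pi)
    r = np.asarray(radius, dtype=float)
    w = 0.54 + 0.46 * np.cos(np.pi * np.clip(r / D, 0.0, 1.0))
    return np.where(r <= D, w, 0.08)


def apply_excitation_window(image: np.ndarray, fov: float) -> np.ndarray:
    """Multiply an image by the radial Hamming excitation profile."""
    n = image.shape[0]
    x = grid_coords(n, fov)
    r = np.hypot(*np.meshgrid(x, x))
    return image * excitation_window_profile(r, fov)


def combine_phase_cycles(frames_per_cycle, offsets=None):
    """Cycle-weighted complex sum cancelling the non-displacement echo.

    For cycling offsets theta_p the weights are exp(-i theta_p)/n (for
    2-point cycling this is the half-difference of the 0- and pi-offset
    acquisitions); n = 1 passes through.
    """
    frames = [np.asarray(f, dtype=complex) for f in frames_per_cycle]
    n = len(frames)
    if any(f.shape != frames[0].shape for f in frames):
        raise ValueError("mismatched frame shapes across phase cycles")
    if offsets is None:
        offsets = 2 * np.pi * np.arange(n) / n
    out = np.zeros_like(frames[0])
    for f, th in zip(frames, offsets):
        out += np.exp(-1j * th) * f / n
    return out


def combine_encodings(mag_x, mag_y, phase_x, phase_y, phase_ref):
    """Average x/y magnitudes; subtract the 0-encoded reference phase."""
    arrs = [np.asarray(a) for a in (mag_x, mag_y, phase_x, phase_y, phase_ref)]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("shape mismatch between encodings")
    magnitude = 0.5 * (arrs[0] + arrs[1])
    px = _wrap(arrs[2] - arrs[4])
    py = _wrap(arrs[3] - arrs[4])
    return magnitude, px, py


def _wrap(phase):
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phase), 2 * np.pi)


def measure_snr(magnitude_frame: np.ndarray, myo_mask: np.ndarray) -> float:
    """Mean over std of the magnitude signal inside the myocardial ROI."""
    vals = np.asarray(magnitude_frame)[np.asarray(myo_mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty myocardial mask")
    sd = vals.std()
    if sd == 0:
        return np.inf
    return float(vals.mean() / sd)


def calibrate_noise(
    noiseless_mag_x: np.ndarray,
    noiseless_mag_y: np.ndarray,
    myo_mask: np.ndarray,
    target_snr: float,
    rng: np.random.Generator,
    noise_gain: float,
    n_draws: int = 256,
) -> float:
    """Per-sample k-space noise std matching a target myocardial SNR.

    Two-pass calibration: the noiseless end-systolic x/y magnitude values in
    the ROI are perturbed by complex Gaussian noise of image-domain std g
    (Monte Carlo with common random numbers), and g is root-found so the
    measured SNR (mean/std of the combined magnitude) hits ``target_snr``.
    ``noise_gain`` converts a unit per-sample k-space std into image-domain
    std (it depends only on the reconstruction weights). Returns the
    per-sample std; 0 with a warning if the target exceeds the noiseless
    heterogeneity SNR.
    """
    from scipy.optimize import brentq

    if target_snr <= 0:
        raise ValueError("target_snr must be > 0")
    mask = np.asarray(myo_mask, dtype=bool)
    mx = np.asarray(noiseless_mag_x)[mask]
    my = np.asarray(noiseless_mag_y)[mask]
    if mx.size == 0:
        raise ValueError("empty myocardial mask")
    eta = rng.standard_normal((2, 2, n_draws, mx.size))  # (enc, re/im, draw, pixel)

    def snr_at(g):
        magx = np.hypot(mx + g * eta[0, 0], g * eta[0, 1])
        magy = np.hypot(my + g * eta[1, 0], g * eta[1, 1])
        m = 0.5 * (magx + magy)
        return float(np.mean(m.mean(axis=1) / m.std(axis=1)))

    s0 = 0.5 * (mx + my)
    if snr_at(0.0) <= target_snr:
        warnings.warn("target SNR above the noiseless heterogeneity SNR; returning sigma = 0")
        return 0.0
    g_hi = 5.0 * s0.mean() / target_snr
    g = brentq(lambda g: snr_at(g) - target_snr, 1e-12 * s0.mean(), g_hi, xtol=1e-6 * s0.mean())
    return float(g / noise_gain)


def _inband_mask(traj: SpiralTrajectory, rotation: int, n2: int, fov: float) -> np.ndarray:
    """Spiral samples inside the N2 spectral support.

    The simulated object is band-limited by the N2 gridding stage, so its
    spectrum vanishes outside |kx|, |ky| <= N2/(2 FOV); samples beyond
    carry no signal (receiver noise is still added to every sample).
    """
    kb = n2 / (2.0 * fov)
    return (np.abs(traj.kx[rotation]) <= kb) & (np.abs(traj.ky[rotation]) <= kb)


def sample_and_reconstruct(
    cartesian_frames: dict,
    schedule: SpiralSchedule,
    acq: AcqParams,
    fov: float,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    trajectory: SpiralTrajectory | None = None,
) -> np.ndarray:
    """Spiral-sample per-interleaf Cartesian images and reconstruct frames.

    ``cartesian_frames`` maps ``(l, c, frame)`` to the windowed N2 x N2
    complex image evaluated at that interleaf's own acquisition time. Each
    interleaf is sampled along its rotated spiral arm, weighted by the
    exp(-tau/T2*) readout decay, perturbed by complex white noise of std
    ``noise_sigma`` per sample, and the four interleaves of each frame are
    reconstructed together by the density-compensated adjoint onto Nf x Nf.
    """
    from .fourier import adjoint_image, sample_kspace

    traj = trajectory or SpiralTrajectory.build(
        acq.Nf, fov, acq.n_interleaves, acq.readout_duration, acq.sample_density
    )
    decay = np.exp(-traj.tau / acq.t2star)
    if noise_sigma > 0 and rng is None:
        rng = np.random.default_rng()
    out = np.empty((schedule.n_frames, acq.Nf, acq.Nf), dtype=complex)
    for i in range(schedule.n_frames):
        samples, kx, ky, w = [], [], [], []
        for l, c in _INTERLEAF_ORDER:
            if (l, c, i) not in cartesian_frames:
                raise ConfigError(f"missing Cartesian source for interleaf {(l, c, i)}")
            rot = interleaf_rotation_index(l, c)
            s = sample_kspace(cartesian_frames[(l, c, i)], traj.kx[rot],
                              traj.ky[rot], fov) * decay
            s = s * _inband_mask(traj, rot, acq.N2, fov)
            if noise_sigma > 0:
                eta = rng.standard_normal((2, s.size))
                s = s + noise_sigma * (eta[0] + 1j * eta[1])
            samples.append(s)
            kx.append(traj.kx[rot])
            ky.append(traj.ky[rot])
            w.append(traj.weights[rot])
        out[i] = adjoint_image(np.concatenate(samples), np.concatenate(kx),
                               np.concatenate(ky), np.concatenate(w), acq.Nf, fov)
    return out


# ---------------------------------------------------------------------------
# end-to-end simulation
# ---------------------------------------------------------------------------


@dataclass
class DenseSeries:
    """Combined cine DENSE output on the Nf grid.

    ``phase_x``/``phase_y`` are displacement-encoded, reference-subtracted
    phases in (-pi, pi]; ``snr`` is the measured per-frame myocardial SNR.
    """

    frame_times: np.ndarray  # (T,) ms
    magnitude: np.ndarray  # (T, Nf, Nf)
    phase_x: np.ndarray  # (T, Nf, Nf) rad
    phase_y: np.ndarray
    snr: np.ndarray  # (T,)
    es_index: int
    meta: dict


_INTERLEAF_ORDER = [(1, 1), (2, 1), (1, 2), (2, 2)]  # (l, c)

_ENCODINGS = ("x", "y", "none")


class DenseSimulator:
    """Runs the full DENSE acquisition for one anatomy + deformation.

    The expensive Bloch/gridding stage is computed once per interleaf time
    as separate stimulated-echo and T1-recovery spiral sample vectors; phase
    cycling, noise injection and reconstruction then operate on these.
    """

    def __init__(
        self,
        labelmap: LabelMap,
        geometry: PolarGeometry,
        model: DeformationModel,
        acq: AcqParams | None = None,
        tissues: TissueProperties | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.labelmap = labelmap
        self.geometry = geometry
        self.model = model
        self.acq = acq or AcqParams()
        self.tissues = tissues or DEFAULT_TISSUES
        self.rng = rng or np.random.default_rng()
        self.fov = labelmap.fov
        self.props = assign_tissue_properties(labelmap, self.tissues)

    # -- helpers -----------------------------------------------------------
    def _static_pixels(self):
        """Non-myocardial isochromats with signal (e.g. blood pool)."""
        sel = (~self.labelmap.myocardium) & (self.props["m0"] > 0)
        rows, cols = np.nonzero(sel)
        x, y = self.labelmap.coordinates()
        pos = np.stack([x[sel], y[sel]], axis=-1)
        return rows, cols, pos

    def _myo_field(self, times) -> MotionField:
        from .motion import generate_displacement_field

        return generate_displacement_field(
            self.labelmap, self.geometry, self.model.params, times, model=self.model
        )

    def _frame_masks(self, frame_times):
        nf, fov = self.acq.Nf, self.fov
        masks = np.stack(
            [self.model.deformed_mask(t, nf, fov / nf) for t in frame_times]
        )
        return masks

    def es_frame_index(self, frame_times) -> int:
        return int(np.argmin(np.abs(np.asarray(frame_times) - self.model.params.t_es)))

    def _acq_with_coverage(self) -> AcqParams:
        """Shift the imaging train by the motion model's prospective-trigger
        offset (partial-cycle coverage: early-diastolic data missing)."""
        offset = getattr(self.model.params, "coverage_start", 0.0)
        if not offset:
            return self.acq
        from dataclasses import replace

        return replace(self.acq, t_start=self.acq.t_start + offset)

    # -- main entry --------------------------------------------------------
    def run(self) -> DenseSeries:
        if self.acq.sampling == "cartesian":
            return self._run_cartesian()
        return self._run_spiral()

    # -- spiral path -------------------------------------------------------
    def prepare_spiral(self):
        """Schedule, trajectory, noiseless sample vectors and recon operator.

        Cached on the instance; the expensive Bloch/gridding stage runs
        once, after which noise realizations and reconstructions are cheap.
        """
        if getattr(self, "_ctx", None) is not None:
            return self._ctx
        acq, fov = self.acq, self.fov
        schedule = build_spiral_schedule(self._acq_with_coverage(),
                                         self.model.params.rr_interval, self.rng)
        traj = SpiralTrajectory.build(
            acq.Nf, fov, acq.n_interleaves, acq.readout_duration, acq.sample_density
        )
        samples = self._acquire_samples(schedule, traj)
        out_times, sample_sets = self._frame_sample_sets(schedule, samples)

        # reconstruction operators (fixed per case)
        x_f = grid_coords(acq.Nf, fov)
        kx_all = np.concatenate([traj.kx[interleaf_rotation_index(l, c)] for l, c in _INTERLEAF_ORDER])
        ky_all = np.concatenate([traj.ky[interleaf_rotation_index(l, c)] for l, c in _INTERLEAF_ORDER])
        w_all = np.concatenate([traj.weights[interleaf_rotation_index(l, c)] for l, c in _INTERLEAF_ORDER])
        ex = np.exp(2j * np.pi * np.outer(x_f, kx_all))
        ey = np.exp(2j * np.pi * np.outer(x_f, ky_all))

        def recon(sample_vec):
            return (ey * (sample_vec * w_all)) @ ex.T

        es = self.es_frame_index(out_times)
        masks = self._frame_masks(out_times)
        roi = ndimage.binary_erosion(masks[es])
        if not roi.any():
            roi = masks[es]
        noise_gain = float(np.sqrt(np.sum(w_all**2) / acq.n_phase_cycles))
        self._ctx = {
            "schedule": schedule, "trajectory": traj, "sample_sets": sample_sets,
            "frame_times": out_times, "recon": recon, "es": es, "masks": masks,
            "roi": roi, "noise_gain": noise_gain,
        }
        return self._ctx

    def noiseless_es_magnitudes(self):
        """Noiseless combined x/y magnitude images at end-systole."""
        ctx = self.prepare_spiral()
        return {
            e: np.abs(ctx["recon"](combine_phase_cycles(self._cycle_samples(
                ctx["sample_sets"][ctx["es"]][e]))))
            for e in ("x", "y")
        }

    def calibrate(self, target_snr: float, roi: np.ndarray | None = None) -> float:
        ctx = self.prepare_spiral()
        mag0 = self.noiseless_es_magnitudes()
        roi = ctx["roi"] if roi is None else roi
        return calibrate_noise(mag0["x"], mag0["y"], roi, target_snr,
                               self.rng, ctx["noise_gain"])

    def es_snr_realizations(self, sigma: float, n_realizations: int,
                            rng: np.random.Generator | None = None,
                            roi: np.ndarray | None = None) -> np.ndarray:
        """Measured ES myocardial SNR over independent noise realizations
        at fixed per-sample noise std (for calibration verification)."""
        ctx = self.prepare_spiral()
        rng = rng or self.rng
        roi = ctx["roi"] if roi is None else roi
        out = np.empty(n_realizations)
        es = ctx["es"]
        for r in range(n_realizations):
            imgs = {}
            for e in ("x", "y"):
                cyc = self._cycle_samples(ctx["sample_sets"][es][e], sigma, rng)
                imgs[e] = combine_phase_cycles([ctx["recon"](s) for s in cyc])
            mag = 0.5 * (np.abs(imgs["x"]) + np.abs(imgs["y"]))
            out[r] = measure_snr(mag, ctx["roi"])
        return out

    def _run_spiral(self) -> DenseSeries:
        acq = self.acq
        ctx = self.prepare_spiral()
        sigma = 0.0
        if acq.target_snr is not None and np.isfinite(acq.target_snr):
            sigma = self.calibrate(acq.target_snr)
        mag, px, py, snr = self._reconstruct_series(
            ctx["sample_sets"], ctx["recon"], sigma, ctx["masks"]
        )
        return DenseSeries(
            np.asarray(ctx["frame_times"]), mag, px, py, snr, ctx["es"],
            meta=self._meta(schedule=ctx["schedule"], sigma=sigma),
        )

    def _acquire_samples(self, schedule: SpiralSchedule, traj: SpiralTrajectory):
        """Stimulated-echo / recovery spiral samples per (l, c, frame, enc).

        Ground-truth motion is evaluated at the jittered interleaf times;
        T2* decay is applied along the readout.
        """
        acq, fov = self.acq, self.fov
        T = schedule.n_frames
        flips = flip_angle_schedule(2 * T, acq.dt / 2, self.tissues[1].t1, acq.flip_final)
        decay = np.exp(-traj.tau / acq.t2star)
        n2 = acq.N2
        from .fourier import phase_vander

        x2 = grid_coords(n2, fov)
        k2 = kgrid(n2, fov)
        e_img = np.exp(2j * np.pi * np.outer(x2, k2))  # k-space -> N2 image
        win = excitation_window_profile(np.hypot(*np.meshgrid(x2, x2)), fov)
        fwd_x = [np.exp(-2j * np.pi * np.outer(x2, traj.kx[j])) for j in range(4)]
        fwd_y = [np.exp(-2j * np.pi * np.outer(x2, traj.ky[j])) for j in range(4)]
        inband = [_inband_mask(traj, j, n2, fov) for j in range(4)]
        ps2 = (fov / n2) ** 2

        # static (blood) isochromats: fixed positions -> fixed gridding ops
        _, _, static_pos = self._static_pixels()
        has_static = len(static_pos) > 0
        if has_static:
            sax = phase_vander(static_pos[:, 0], n2, fov)
            say = phase_vander(static_pos[:, 1], n2, fov)
            sprops = {k: self.props[k][(~self.labelmap.myocardium) & (self.props["m0"] > 0)]
                      for k in self.props}

        myo_props = {k: self.props[k][self.labelmap.myocardium] for k in self.props}

        samples = {}
        for l, c in _INTERLEAF_ORDER:
            times = schedule.t_lci[l - 1, c - 1]
            pulse_idx = 2 * np.arange(T) + (l - 1)
            field = self._myo_field(times)
            rot = interleaf_rotation_index(l, c)
            for enc in _ENCODINGS:
                ste, rec, pos = simulate_dense_signal(
                    field, myo_props, acq, 0, enc, flips=flips, frame_indices=pulse_idx
                )
                if has_static:
                    sste, srec = _static_signals(
                        static_pos, sprops, acq, enc, flips, pulse_idx, times
                    )
                for f in range(T):
                    ax = phase_vander(pos[f, :, 0], n2, fov)
                    ay = phase_vander(pos[f, :, 1], n2, fov)
                    k_ste = (ay * ste[f]) @ ax.T
                    k_rec = (ay * rec[f]) @ ax.T
                    if has_static:
                        k_ste = k_ste + (say * sste[f]) @ sax.T
                        k_rec = k_rec + (say * srec[f]) @ sax.T
                    out = []
                    for K in (k_ste, k_rec):
                        img = (e_img @ K.T @ e_img.T).T / fov**2
                        img = img * win
                        s = np.einsum("rj,rc,cj->j", fwd_y[rot], img, fwd_x[rot]) * ps2
                        out.append(s * decay * inband[rot])
                    samples[(l, c, f, enc)] = tuple(out)
        return samples

    def _frame_sample_sets(self, schedule: SpiralSchedule, samples):
        """Group interleaf samples into output frames (with optional
        interpolated frames doubling the temporal resolution)."""
        T = schedule.n_frames
        sets = []
        times = []
        for i in range(T):
            times.append(schedule.frame_times[i])
            sets.append({e: [samples[(l, c, i, e)] for l, c in _INTERLEAF_ORDER]
                         for e in _ENCODINGS})
        if self.acq.interpolate_frames:
            for i in range(T - 1):
                times.append(schedule.interp_frame_times[i])
                sets.append({e: [samples[(1, 1, i + 1, e)], samples[(2, 1, i, e)],
                                 samples[(1, 2, i + 1, e)], samples[(2, 2, i, e)]]
                             for e in _ENCODINGS})
            order = np.argsort(times, kind="stable")
            times = [times[j] for j in order]
            sets = [sets[j] for j in order]
        return times, sets

    def _cycle_samples(self, interleaf_samples, sigma: float = 0.0,
                       rng: np.random.Generator | None = None):
        """Per-phase-cycle concatenated sample vectors for one frame/enc."""
        ste = np.concatenate([s[0] for s in interleaf_samples])
        rec = np.concatenate([s[1] for s in interleaf_samples])
        out = []
        for p in range(self.acq.n_phase_cycles):
            theta = 2 * np.pi * p / self.acq.n_phase_cycles
            s = np.exp(1j * theta) * ste + rec
            if sigma > 0:
                noise = rng.standard_normal((2, s.size))
                s = s + sigma * (noise[0] + 1j * noise[1])
            out.append(s)
        return out

    def _reconstruct_series(self, sample_sets, recon, sigma, masks):
        acq = self.acq
        T = len(sample_sets)
        nf = acq.Nf
        mag = np.empty((T, nf, nf))
        px = np.empty((T, nf, nf))
        py = np.empty((T, nf, nf))
        snr = np.empty(T)
        for f in range(T):
            imgs = {}
            for e in _ENCODINGS:
                cyc = self._cycle_samples(sample_sets[f][e], sigma, self.rng)
                imgs[e] = combine_phase_cycles([recon(s) for s in cyc])
            mag[f], px[f], py[f] = combine_encodings(
                np.abs(imgs["x"]), np.abs(imgs["y"]),
                np.angle(imgs["x"]), np.angle(imgs["y"]), np.angle(imgs["none"]),
            )
            roi = ndimage.binary_erosion(masks[f])
            snr[f] = measure_snr(mag[f], roi if roi.any() else masks[f])
        return mag, px, py, snr

    # -- Cartesian (idealized) path ---------------------------------------
    def _run_cartesian(self) -> DenseSeries:
        """Fully sampled Cartesian reference: each frame evaluated at its
        nominal combined time, reconstructed by Fourier zero-padding."""
        acq, fov = self.acq, self.fov
        schedule = build_spiral_schedule(self._acq_with_coverage(),
                                         self.model.params.rr_interval, None)
        times = schedule.frame_times
        if acq.interpolate_frames:
            times = np.sort(np.concatenate([times, schedule.interp_frame_times]))
        T = len(times)
        flips = flip_angle_schedule(T, acq.dt / 2 if acq.interpolate_frames else acq.dt,
                                    self.tissues[1].t1, acq.flip_final)
        field = self._myo_field(times)
        myo_props = {k: self.props[k][self.labelmap.myocardium] for k in self.props}
        _, _, static_pos = self._static_pixels()
        has_static = len(static_pos) > 0
        if has_static:
            sprops = {k: self.props[k][(~self.labelmap.myocardium) & (self.props["m0"] > 0)]
                      for k in self.props}

        masks = self._frame_masks(times)
        es = self.es_frame_index(times)
        sigma = 0.0
        noise_gain = acq.N2 / fov**2 / np.sqrt(acq.n_phase_cycles)

        frames_k = {e: [] for e in _ENCODINGS}  # (K_ste, K_rec) per frame
        for e in _ENCODINGS:
            ste, rec, pos = simulate_dense_signal(
                field, myo_props, acq, 0, e, flips=flips, frame_indices=np.arange(T)
            )
            if has_static:
                sste, srec = _static_signals(static_pos, sprops, acq, e, flips,
                                             np.arange(T), times)
            for f in range(T):
                sig_ste, sig_rec = ste[f], rec[f]
                p = pos[f]
                if has_static:
                    sig_ste = np.concatenate([sig_ste, sste[f]])
                    sig_rec = np.concatenate([sig_rec, srec[f]])
                    p = np.concatenate([p, static_pos])
                k_ste = kspace_on_grid(
                    apply_excitation_window(grid_isochromats(sig_ste, p, acq, fov), fov), fov)
                k_rec = kspace_on_grid(
                    apply_excitation_window(grid_isochromats(sig_rec, p, acq, fov), fov), fov)
                frames_k[e].append((k_ste, k_rec))

        if acq.target_snr is not None and np.isfinite(acq.target_snr):
            roi = ndimage.binary_erosion(masks[es])
            mag0 = {}
            for e in ("x", "y"):
                k_ste, _ = frames_k[e][es]
                mag0[e] = np.abs(image_from_kspace(k_ste, acq.Nf, fov))
            sigma = calibrate_noise(mag0["x"], mag0["y"], roi if roi.any() else masks[es],
                                    acq.target_snr, self.rng, noise_gain)

        nf = acq.Nf
        mag = np.empty((T, nf, nf))
        px = np.empty((T, nf, nf))
        py = np.empty((T, nf, nf))
        snr = np.empty(T)
        for f in range(T):
            imgs = {}
            for e in _ENCODINGS:
                k_ste, k_rec = frames_k[e][f]
                cyc = []
                for pcyc in range(acq.n_phase_cycles):
                    theta = 2 * np.pi * pcyc / acq.n_phase_cycles
                    K = np.exp(1j * theta) * k_ste + k_rec
                    if sigma > 0:
                        eta = self.rng.standard_normal((2,) + K.shape)
                        K = K + sigma * (eta[0] + 1j * eta[1])
                    cyc.append(image_from_kspace(K, nf, fov))
                imgs[e] = combine_phase_cycles(cyc)
            mag[f], px[f], py[f] = combine_encodings(
                np.abs(imgs["x"]), np.abs(imgs["y"]),
                np.angle(imgs["x"]), np.angle(imgs["y"]), np.angle(imgs["none"]),
            )
            roi = ndimage.binary_erosion(masks[f])
            snr[f] = measure_snr(mag[f], roi if roi.any() else masks[f])
        return DenseSeries(np.asarray(times), mag, px, py, snr, es,
                           meta=self._meta(schedule=schedule, sigma=sigma))

    def _meta(self, schedule: SpiralSchedule, sigma: float) -> dict:
        return {
            "acq": asdict(self.acq),
            "sigma": float(sigma),
            "jitter": schedule.jitter.tolist(),
            "rr_interval": self.model.params.rr_interval,
            "t_es": self.model.params.t_es,
        }


def _static_signals(positions, props, acq: AcqParams, encoding, flips, pulse_idx, times):
    """Two-term signals of static isochromats (no displacement encoding of
    the stimulated echo; recovery phase follows the fixed position)."""
    enc = _encoding_vector(encoding)
    T, P = len(times), len(positions)
    ste = np.empty((T, P), dtype=complex)
    rec = np.empty((T, P), dtype=complex)
    ph_rec = np.zeros(P) if enc is None else 2 * np.pi * acq.ke * (positions @ enc)
    for f, t in enumerate(times):
        i = int(pulse_idx[f])
        readout = stimulated_echo_amplitude(flips, i)
        amp = 0.5 * props["m0"] * readout * np.exp(-t / props["t1"]) * np.exp(-t / props["washout"])
        ste[f] = amp  # zero displacement -> no encoding phase
        rec[f] = props["m0"] * (1 - np.exp(-t / props["t1"])) * np.sin(flips[i]) * np.exp(1j * ph_rec)
    return ste, rec


def simulate_case(
    labelmap: LabelMap,
    geometry: PolarGeometry,
    model: DeformationModel,
    acq: AcqParams | None = None,
    tissues: TissueProperties | None = None,
    rng: np.random.Generator | None = None,
) -> DenseSeries:
    """Convenience wrapper: run the full DENSE simulation for one case."""
    return DenseSimulator(labelmap, geometry, model, acq, tissues, rng).run()
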