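"""Direct discrete Fourier evaluation between arbitrary sample sets.

All k-space operations in the acquisition module (isochromat gridding,
spiral sampling, adjoint reconstruction) are exact direct DFT evaluations,
written in separable form so each reduces to two small dense matrix
products. At the matrix sizes used here (grids <= 128, ~1-4k samples per
interleaf) this is fast and free of gridding/interpolation error.

Conventions: positions in mm relative to the raster center, k in cycles/mm.
Forward transform uses exp(-2*pi*i*k.x) with pixel-area weighting; inverse
uses exp(+2*pi*i*k.x) with k-space cell-area (density) weighting, so both
approximate the continuous Fourier pair and round trips preserve scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "kgrid",
    "grid_coords",
    "phase_vander",
    "isochromat_kspace",
    "image_from_kspace",
    "kspace_on_grid",
    "sample_kspace",
    "adjoint_image",
    "SpiralTrajectory",
]


def kgrid(n: int, fov: float) -> np.ndarray:
    """Centered Cartesian k-space coordinates (cycles/mm), spacing 1/FOV."""
    return (np.arange(n) - n // 2) / fov


def grid_coords(n: int, fov: float) -> np.ndarray:
    """Physical pixel-center coordinates of an n-point axis, centered on 0."""
    return (np.arange(n) + 0.5 - n / 2.0) * (fov / n)


def phase_vander(coords, n_k: int, fov: float, sign: int = -1) -> np.ndarray:
    """exp(sign * 2 pi i * k_n * x) on the centered integer k grid, (n_k, M).

    Built by the multiplicative recurrence over k rows (two exp evaluations
    total), exact to ~n_k machine-epsilon round-off.
    """
    x = np.asarray(coords, dtype=float).ravel()
    base = np.exp(sign * 2j * np.pi * x / fov)
    out = np.empty((n_k, x.size), dtype=complex)
    out[0] = np.exp(sign * 2j * np.pi * (-(n_k // 2)) * x / fov)
    for i in range(1, n_k):
        out[i] = out[i - 1] * base
    return out


def isochromat_kspace(signals, positions, n: int, fov: float) -> np.ndarray:
    """Type-1 NUDFT: scattered isochromats -> centered n x n k-space grid.

    K[ky, kx] = sum_m s_m exp(-2 pi i (kx x_m + ky y_m)). The DC sample
    equals the plain sum of the signals (total signal conservation).
    """
    s = np.asarray(signals, dtype=complex).ravel()
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    ax = phase_vander(pos[:, 0], n, fov)
    ay = phase_vander(pos[:, 1], n, fov)
    return (ay * s) @ ax.T  # rows: ky, cols: kx


def image_from_kspace(K: np.ndarray, n_out: int, fov: float) -> np.ndarray:
    """Inverse transform of a centered k-space grid onto an n_out pixel grid.

    img(x) = (1/FOV^2) sum_k K(k) exp(+2 pi i k.x); evaluating on a finer
    grid than K implements Fourier (zero-padding) interpolation.
    """
    K = np.asarray(K)
    n_k = K.shape[0]
    k = kgrid(n_k, fov)
    x = grid_coords(n_out, fov)
    ex = np.exp(2j * np.pi * np.outer(x, k))  # (n_out, n_k)
    return (ex @ K.T @ ex.T).T / fov**2


def kspace_on_grid(image: np.ndarray, fov: float) -> np.ndarray:
    """Forward transform of a pixel image onto its own centered k grid."""
    n = image.shape[0]
    k = kgrid(n, fov)
    x = grid_coords(n, fov)
    e = np.exp(-2j * np.pi * np.outer(k, x))  # (n_k, n_x)
    ps = fov / n
    return (e @ image.T @ e.T).T * ps**2


def sample_kspace(image: np.ndarray, kx, ky, fov: float) -> np.ndarray:
    """Type-2 NUDFT: pixel image -> arbitrary k-space sample locations."""
    n = image.shape[0]
    x = grid_coords(n, fov)
    ps = fov / n
    ax = np.exp(-2j * np.pi * np.outer(x, kx))  # (n, M)
    ay = np.exp(-2j * np.pi * np.outer(x, ky))
    return np.einsum("rj,rc,cj->j", ay, image, ax) * ps**2


def adjoint_image(samples, kx, ky, weights, n_out: int, fov: float) -> np.ndarray:
    """Density-compensated adjoint: scattered k samples -> n_out pixel image.

    img(x) = sum_j w_j S_j exp(+2 pi i k_j.x) with w_j the k-space area
    element of sample j, approximating the continuous inverse transform.
    """
    s = np.asarray(samples, dtype=complex) * np.asarray(weights)
    x = grid_coords(n_out, fov)
    ex = np.exp(2j * np.pi * np.outer(x, kx))  # (n_out, M)
    ey = np.exp(2j * np.pi * np.outer(x, ky))
    return (ey * s) @ ex.T  # rows: y, cols: x


@dataclass
class SpiralTrajectory:
    """Uniform-density Archimedean spiral interleaves.

    Each of ``n_interleaves`` arms runs r(t) = k_max * t, phi(t) = 2 pi
    n_turns t + rotation, t in (0, 1], with uniform temporal sample spacing
    over ``readout_duration``. Density-compensation weights are the analytic
    k-space area per sample, 2 pi k_max |k| / (n_interleaves * M), so the
    full set of interleaves tiles the k_max disc.
    """

    kx: np.ndarray  # (n_interleaves, M)
    ky: np.ndarray
    tau: np.ndarray  # (M,) ms since readout start
    weights: np.ndarray  # (n_interleaves, M)
    rotations: np.ndarray  # (n_interleaves,)
    k_max: float

    @classmethod
    def build(
        cls,
        n_recon: int,
        fov: float,
        n_interleaves: int = 4,
        readout_duration: float = 11.0,
        sample_density: float = 1.2,
    ) -> "SpiralTrajectory":
        k_max = n_recon / (2.0 * fov)
        n_turns = int(np.ceil(k_max * fov / n_interleaves))
        m = int(np.ceil(sample_density * np.pi * k_max * fov * n_turns))
        t = (np.arange(m) + 0.5) / m
        rotations = 2 * np.pi * np.arange(n_interleaves) / n_interleaves
        r = k_max * t
        phi = 2 * np.pi * n_turns * t
        kx = r * np.cos(phi[None, :] + rotations[:, None])
        ky = r * np.sin(phi[None, :] + rotations[:, None])
        tau = t * readout_duration
        w = 2 * np.pi * k_max * r / (n_interleaves * m)
        weights = np.broadcast_to(w, (n_interleaves, m)).copy()
        return cls(kx, ky, tau, weights, rotations, k_max)

    @property
    def n_interleaves(self) -> int:
        return self.kx.shape[0]

    @property
    def samples_per_interleaf(self) -> int:
        return self.kx.shape[1]
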