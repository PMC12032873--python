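"""End-diastolic anatomy generation and polar geometry.

Builds 2D short-axis label maps (background / myocardium / blood pool) either
from a parametric annulus or from an imported binary myocardial mask, and
derives the per-pixel polar geometry (transmural coordinate, radial and
circumferential unit vectors) used to project strain tensors.

Coordinate convention (shared by all modules): pixel centers sit at
``(index + 0.5) * pixel_size`` with 0-based row/column indexing; physical
coordinates are expressed relative to the raster center, ``x`` along columns
and ``y`` along rows (y increases with row index). Positions are ``(x, y)``
pairs in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LabelMap",
    "PolarGeometry",
    "InvalidGeometryError",
    "LABEL_BACKGROUND",
    "LABEL_MYOCARDIUM",
    "LABEL_BLOOD",
    "pixel_coordinates",
    "generate_annulus",
    "upsample_and_dilate_mask",
    "polar_geometry",
    "load_mask",
    "save_labelmap",
]

LABEL_BACKGROUND = 0
LABEL_MYOCARDIUM = 1
LABEL_BLOOD = 2


class InvalidGeometryError(ValueError):
    """Raised for degenerate or non-annular anatomies."""


def pixel_coordinates(n: int, pixel_size: float, origin=(0.0, 0.0)):
    """Physical (x, y) coordinates of pixel centers of an ``n x n`` raster.

    Returns two ``(n, n)`` arrays (x for columns, y for rows), centered on
    ``origin`` which is the physical coordinate of the raster center.
    """
    c = (np.arange(n) + 0.5 - n / 2.0) * pixel_size
    x = origin[0] + np.broadcast_to(c, (n, n))
    y = origin[1] + np.broadcast_to(c[:, None], (n, n))
    return x, y


@dataclass
class LabelMap:
    """Integer tissue-label raster at ground-truth resolution.

    Label codes: 0 background, 1 myocardium, 2 blood pool (>=3 free for other
    tissues). ``origin`` is the physical coordinate of the raster center (mm).
    """

    labels: np.ndarray
    pixel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 2 or self.labels.shape[0] != self.labels.shape[1]:
            raise InvalidGeometryError("label raster must be square")
        if self.pixel_size <= 0:
            raise InvalidGeometryError("pixel_size must be > 0")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def fov(self) -> float:
        """Physical field of view (mm)."""
        return self.n * self.pixel_size

    @property
    def myocardium(self) -> np.ndarray:
        return self.labels == LABEL_MYOCARDIUM

    @property
    def blood(self) -> np.ndarray:
        return self.labels == LABEL_BLOOD

    def coordinates(self):
        return pixel_coordinates(self.n, self.pixel_size, self.origin)


@dataclass
class PolarGeometry:
    """Per-pixel polar geometry of a left-ventricular short-axis slice.

    ``transmural`` is the normalized endocardium->epicardium coordinate in
    [0, 1] (NaN outside the myocardium). ``radial_unit`` / ``circ_unit`` are
    ``(n, n, 2)`` rasters of orthonormal direction vectors; radial points
    outward from ``center``, circumferential is its +90 deg rotation.
    """

    center: np.ndarray
    transmural: np.ndarray
    radial_unit: np.ndarray
    circ_unit: np.ndarray
    pixel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def units_at(self, points: np.ndarray):
        """Radial/circumferential unit vectors at arbitrary physical points."""
        d = np.asarray(points, dtype=float) - self.center
        r = np.linalg.norm(d, axis=-1, keepdims=True)
        rad = d / np.where(r > 0, r, 1.0)
        circ = np.stack([-rad[..., 1], rad[..., 0]], axis=-1)
        return rad, circ

    def transmural_at(self, points: np.ndarray) -> np.ndarray:
        """Transmural coordinate interpolated at arbitrary physical points."""
        pts = np.asarray(points, dtype=float)
        n = self.transmural.shape[0]
        col = (pts[..., 0] - self.origin[0]) / self.pixel_size + n / 2.0 - 0.5
        row = (pts[..., 1] - self.origin[1]) / self.pixel_size + n / 2.0 - 0.5
        filled = _fill_nan_nearest(self.transmural)
        out = ndimage.map_coordinates(
            filled, np.stack([row.ravel(), col.ravel()]), order=1, mode="nearest"
        )
        return out.reshape(pts.shape[:-1])


def _fill_nan_nearest(a: np.ndarray) -> np.ndarray:
    if not np.isnan(a).any():
        return a
    mask = np.isnan(a)
    idx = ndimage.distance_transform_edt(mask, return_distances=False, return_indices=True)
    return a[tuple(idx)]


def generate_annulus(
    matrix_size: int,
    pixel_size: float,
    endo_diameter: float,
    epi_diameter: float,
) -> LabelMap:
    """Rasterize a centered annular phantom.

    Diameters are in pixels. Pixels whose center radius lies in
    ``(endo/2, epi/2]`` are myocardium, radius ``<= endo/2`` blood pool, the
    rest background.
    """
    if not (0 < endo_diameter < epi_diameter <= matrix_size):
        raise InvalidGeometryError(
            f"require 0 < endo ({endo_diameter}) < epi ({epi_diameter}) <= matrix ({matrix_size})"
        )
    x, y = pixel_coordinates(matrix_size, 1.0)  # radius in pixel units
    r = np.hypot(x, y)
    labels = np.zeros((matrix_size, matrix_size), dtype=np.int8)
    labels[r <= endo_diameter / 2.0] = LABEL_BLOOD
    labels[(r > endo_diameter / 2.0) & (r <= epi_diameter / 2.0)] = LABEL_MYOCARDIUM
    return LabelMap(labels, pixel_size)


def upsample_and_dilate_mask(
    mask: np.ndarray,
    target_size: int,
    dilation: int = 0,
    pixel_size: float = 0.8,
    sigma: float = 1.0,
) -> LabelMap:
    """Turn a coarse binary myocardial mask into a high-resolution label map.

    The mask is Gaussian-smoothed (``sigma`` in input pixels), spline
    interpolated to ``target_size``, binarized at 0.5, then morphologically
    dilated by ``dilation`` pixels (manual contours tend to be thinner than
    the true wall). The blood pool is inferred by filling the enclosed hole.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if not mask.any():
        raise ValueError("empty mask")
    if not (0 <= dilation <= 6):
        raise ValueError("dilation must be in [0, 6] pixels")
    smooth = ndimage.gaussian_filter(mask.astype(float), sigma, mode="nearest")
    up = ndimage.zoom(smooth, (target_size / mask.shape[0], target_size / mask.shape[1]),
                      order=3, mode="nearest", grid_mode=True)
    myo = up >= 0.5
    if dilation > 0:
        myo = ndimage.binary_dilation(myo, structure=_disk(dilation))
    filled = ndimage.binary_fill_holes(myo)
    blood = filled & ~myo
    labels = np.zeros(myo.shape, dtype=np.int8)
    labels[myo] = LABEL_MYOCARDIUM
    labels[blood] = LABEL_BLOOD
    return LabelMap(labels, pixel_size)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return x * x + y * y <= r * r


def polar_geometry(labelmap: LabelMap) -> PolarGeometry:
    """Derive the polar geometry of an annular label map.

    The LV center is the centroid of blood pool + myocardium; the transmural
    coordinate is built from the two Euclidean distance transforms
    ``d_endo / (d_endo + d_epi)`` (half-pixel corrected so border pixels sit
    near 0 and 1); unit vectors follow the outward ray through each pixel.
    """
    myo = labelmap.myocardium
    _check_annular(labelmap)
    x, y = labelmap.coordinates()
    cavity = labelmap.blood | myo
    center = np.array([x[cavity].mean(), y[cavity].mean()])

    # distance (pixels) from each myocardial pixel to the nearest blood /
    # background pixel; 0.5 px offset puts the tissue interface at 0 and 1
    d_endo = ndimage.distance_transform_edt(~labelmap.blood) - 0.5
    d_epi = ndimage.distance_transform_edt(labelmap.labels != LABEL_BACKGROUND) - 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.clip(d_endo / (d_endo + d_epi), 0.0, 1.0)
    trans[~myo] = np.nan

    dx = x - center[0]
    dy = y - center[1]
    r = np.hypot(dx, dy)
    r = np.where(r > 0, r, 1.0)
    radial = np.stack([dx / r, dy / r], axis=-1)
    circ = np.stack([-radial[..., 1], radial[..., 0]], axis=-1)
    return PolarGeometry(center, trans, radial, circ, labelmap.pixel_size, labelmap.origin)


def _check_annular(labelmap: LabelMap) -> None:
    myo = labelmap.myocardium
    if not myo.any():
        raise InvalidGeometryError("no myocardial pixels")
    _, n_comp = ndimage.label(myo)
    if n_comp != 1:
        raise InvalidGeometryError(f"myocardium has {n_comp} components, expected 1")
    filled = ndimage.binary_fill_holes(myo)
    if not (filled & ~myo).any():
        raise InvalidGeometryError("myocardium does not enclose a cavity")


def load_mask(path) -> np.ndarray:
    """Read a binary myocardial mask from NIfTI (.nii/.nii.gz) or PNG."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(path).dataobj)
        return np.squeeze(data) > 0
    from PIL import Image

    return np.asarray(Image.open(path).convert("L")) > 0


def save_labelmap(labelmap: LabelMap, path) -> None:
    """Write a label map as an integer NIfTI with pixel size in the affine."""
    import nibabel as nib

    affine = np.diag([labelmap.pixel_size, labelmap.pixel_size, 1.0, 1.0])
    img = nib.Nifti1Image(labelmap.labels.astype(np.int16), affine)
    nib.save(img, str(path))
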