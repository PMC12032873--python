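"""HDF5 / NIfTI serialization of simulated cases and strain results."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .acquisition import DenseSeries
from .motion import MotionField, MotionParams, StrainMap

__all__ = [
    "save_series",
    "load_series",
    "save_case",
    "load_case",
    "save_motion_field",
    "load_motion_field",
    "save_strain_map",
    "load_strain_map",
    "strain_to_nifti",
]


def save_series(group: h5py.Group, series: DenseSeries) -> None:
    for name in ("frame_times", "magnitude", "phase_x", "phase_y", "snr"):
        group.create_dataset(name, data=getattr(series, name))
    group.attrs["es_index"] = series.es_index
    group.attrs["meta"] = json.dumps(series.meta)


def load_series(group: h5py.Group) -> DenseSeries:
    return DenseSeries(
        frame_times=group["frame_times"][()],
        magnitude=group["magnitude"][()],
        phase_x=group["phase_x"][()],
        phase_y=group["phase_y"][()],
        snr=group["snr"][()],
        es_index=int(group.attrs["es_index"]),
        meta=json.loads(group.attrs["meta"]),
    )


def save_case(path, case) -> None:
    """Write one cohort case (series + provenance to rebuild ground truth)."""
    with h5py.File(path, "w") as f:
        save_series(f.create_group("series"), case.series)
        f.attrs["provenance"] = json.dumps({
            "seed": case.seed,
            "index": case.index,
            "stratum": case.stratum,
            "target_snr": case.target_snr,
            "matrix_size": case.labelmap.n,
            "pixel_size": case.labelmap.pixel_size,
            "motion_params": asdict(case.params),
        })
        f.create_dataset("labels", data=case.labelmap.labels)


def load_case(path):
    """Rebuild a saved case, including its analytic deformation model."""
    from .anatomy import LabelMap, polar_geometry
    from .cohort import Case
    from .motion import DeformationModel

    with h5py.File(path, "r") as f:
        series = load_series(f["series"])
        prov = json.loads(f.attrs["provenance"])
        labels = f["labels"][()]
    labelmap = LabelMap(labels, prov["pixel_size"])
    geometry = polar_geometry(labelmap)
    params = MotionParams(**prov["motion_params"])
    model = DeformationModel(labelmap, geometry, params)
    return Case(prov["index"], prov["seed"], prov["stratum"], prov["target_snr"],
                labelmap, geometry, params, model, series)


def save_motion_field(path, field: MotionField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("ref_positions", data=field.ref_positions)
        f.create_dataset("frame_times", data=field.frame_times)
        f.create_dataset("displacements", data=field.displacements)
        f.create_dataset("rows", data=field.pixel_index[0])
        f.create_dataset("cols", data=field.pixel_index[1])
        f.attrs["shape"] = field.shape
        f.attrs["spacing"] = field.spacing


def load_motion_field(path) -> MotionField:
    with h5py.File(path, "r") as f:
        return MotionField(
            f["ref_positions"][()], f["frame_times"][()], f["displacements"][()],
            (f["rows"][()], f["cols"][()]), tuple(f.attrs["shape"]),
            float(f.attrs["spacing"]),
        )


def save_strain_map(path, sm: StrainMap) -> None:
    with h5py.File(path, "w") as f:
        for name in ("frame_times", "E_tensor", "err", "ecc"):
            f.create_dataset(name, data=getattr(sm, name))
        f.create_dataset("valid", data=sm.valid.astype(np.uint8))
        if sm.transmural is not None:
            f.create_dataset("transmural", data=sm.transmural)


def load_strain_map(path) -> StrainMap:
    with h5py.File(path, "r") as f:
        trans = f["transmural"][()] if "transmural" in f else None
        return StrainMap(f["frame_times"][()], f["E_tensor"][()], f["err"][()],
                         f["ecc"][()], f["valid"][()].astype(bool), trans)


def strain_to_nifti(path, sm: StrainMap, component: str = "err",
                    pixel_size: float = 1.0) -> None:
    """Export one strain component as a multi-frame NIfTI volume."""
    import nibabel as nib

    data = np.moveaxis(getattr(sm, component), 0, -1)  # (H, W, T)
    affine = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.nan_to_num(data).astype(np.float32), affine), str(path))
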