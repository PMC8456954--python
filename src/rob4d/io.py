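"""NIfTI and JSON input/output for images, masks, displacement fields.

Images are written as NIfTI with a diagonal voxel-to-world affine; the
axis convention throughout the package is LPS (x left, y posterior,
z superior).  Displacement fields are 4-D NIfTI volumes whose last axis
holds the (x, y, z) components in mm.  Doses are stored in Gy (RBE).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import Grid, Volume
from .phantom4d import (
    PHASE_LABELS,
    REFERENCE_LABEL,
    MotionTruth,
    PhantomSpec,
    Series4D,
    build_phantom,
)
from .structures import StructureSet
from .warp import DVF


def _nifti(data: np.ndarray, grid: Grid) -> nib.Nifti1Image:
    img = nib.Nifti1Image(data, grid.affine())
    img.header.set_zooms((*grid.spacing_mm,) + ((1.0,) if data.ndim == 4 else ()))
    return img


def _grid_from(img: nib.Nifti1Image) -> Grid:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI grids are supported")
    spacing = tuple(float(v) for v in np.diag(aff[:3, :3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    shape = img.shape[:3]
    return Grid(shape, spacing, origin)


def save_volume(volume: Volume, path) -> None:
    _nifti(np.asarray(volume.values, dtype=np.float32), volume.grid).to_filename(str(path))


def load_volume(path) -> Volume:
    img = nib.load(str(path))
    return Volume(np.asarray(img.get_fdata(), dtype=float), _grid_from(img))


def save_mask(mask: np.ndarray, grid: Grid, path) -> None:
    _nifti(np.asarray(mask, dtype=np.uint8), grid).to_filename(str(path))


def load_mask(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5, _grid_from(img)


def save_dvf(dvf: DVF, path) -> None:
    _nifti(np.asarray(dvf.displacement_mm, dtype=np.float32), dvf.grid).to_filename(str(path))


def load_dvf(path) -> DVF:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError("a DVF NIfTI must have three components on the last axis")
    return DVF(data, _grid_from(img))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    kwargs = dict(d)
    for k in ("grid_shape", "spacing_mm", "tumor_center_mm"):
        if k in kwargs and kwargs[k] is not None:
            kwargs[k] = tuple(kwargs[k])
    return PhantomSpec(**kwargs)


def write_phantom_bundle(out_dir, series: Series4D,
                         structures_by_phase: dict[str, StructureSet],
                         truth: MotionTruth, spec: PhantomSpec) -> Path:
    """Write the phantom as NIfTI files plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "phase_labels": list(PHASE_LABELS),
        "reference_label": series.reference_label,
        "spec": spec_to_dict(spec),
        "motion": {
            "axis": truth.axis,
            "amplitude_mm": truth.amplitude_mm,
            "extreme_phases": list(truth.extreme_phases),
            "phase_offsets_mm": {k: list(v) for k, v in truth.phase_offsets_mm.items()},
        },
        "images": {},
        "dvfs": {},
        "structures": {},
    }
    for lab in series.phase_labels:
        name = f"density_{lab}.nii.gz"
        save_volume(series.images[lab], out / name)
        manifest["images"][lab] = name
        if lab != series.reference_label:
            dname = f"dvf_{lab}_to_{series.reference_label}.nii.gz"
            save_dvf(series.dvfs_to_reference[lab], out / dname)
            manifest["dvfs"][lab] = dname
        sset = structures_by_phase[lab]
        manifest["structures"][lab] = {}
        for sname in sorted(sset.names()):
            fname = f"mask_{lab}_{sname}.nii.gz"
            save_mask(sset[sname], sset.grid, out / fname)
            manifest["structures"][lab][sname] = fname
    path = out / "manifest.json"
    write_json(manifest, path)
    return path


def load_phantom_bundle(bundle_dir):
    """Load a phantom bundle back into (series, structures_by_phase, manifest)."""
    bundle = Path(bundle_dir)
    manifest = json.loads((bundle / "manifest.json").read_text())
    ref = manifest["reference_label"]
    images, dvfs = {}, {}
    for lab, fname in manifest["images"].items():
        images[lab] = load_volume(bundle / fname)
    grid = images[ref].grid
    for lab in manifest["phase_labels"]:
        if lab == ref:
            dvfs[lab] = DVF.zero(grid)
        else:
            dvfs[lab] = load_dvf(bundle / manifest["dvfs"][lab])
    series = Series4D(tuple(manifest["phase_labels"]), images, ref, dvfs)
    structures_by_phase = {}
    for lab, entries in manifest["structures"].items():
        masks = {}
        for sname, fname in entries.items():
            masks[sname], _ = load_mask(bundle / fname)
        structures_by_phase[lab] = StructureSet(grid, masks)
    return series, structures_by_phase, manifest


def phantom_from_config(config: dict | PhantomSpec):
    """Build a phantom from a spec mapping or PhantomSpec instance."""
    spec = config if isinstance(config, PhantomSpec) else spec_from_dict(config)
    series, structures_by_phase, truth = build_phantom(spec)
    return spec, series, structures_by_phase, truth
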