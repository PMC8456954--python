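"""Deformable mapping of dose grids and masks between breathing phases.

A displacement vector field (DVF) is defined on the reference-phase grid
and uses the pull-back convention: a reference-grid point ``x`` corresponds
to the point ``x + u(x)`` (mm, LPS) in the source phase.  Warping a phase
quantity onto the reference grid therefore samples the phase volume at
``x + u(x)`` with trilinear interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import Grid, Volume

log = logging.getLogger(__name__)


@dataclass
class DVF:
    """Displacement field in mm on the reference grid, shape ``(*grid.shape, 3)``."""

    displacement_mm: np.ndarray
    grid: Grid = field(repr=False)

    def __post_init__(self):
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if self.displacement_mm.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"DVF shape {self.displacement_mm.shape} != {(*self.grid.shape, 3)}"
            )
        if not np.isfinite(self.displacement_mm).all():
            raise ValueError("DVF contains non-finite displacements")

    @classmethod
    def zero(cls, grid: Grid) -> "DVF":
        return cls(np.zeros((*grid.shape, 3)), grid)

    def is_zero(self) -> bool:
        return not self.displacement_mm.any()

    def max_displacement_mm(self) -> float:
        return float(np.linalg.norm(self.displacement_mm, axis=-1).max())


def _sample_coordinates(dvf: DVF) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-index sampling coordinates ``idx + u/spacing`` and an in-grid mask."""
    grid = dvf.grid
    idx = np.indices(grid.shape, dtype=float)
    coords = np.empty_like(idx)
    for a in range(3):
        coords[a] = idx[a] + dvf.displacement_mm[..., a] / grid.spacing_mm[a]
    inside = np.ones(grid.shape, dtype=bool)
    for a in range(3):
        inside &= (coords[a] >= 0) & (coords[a] <= grid.shape[a] - 1)
    return coords, inside


def warp_scalar(values: np.ndarray, dvf: DVF) -> tuple[np.ndarray, int]:
    """Pull a scalar field from the source phase onto the reference grid.

    Returns the warped field and the number of voxels whose sample point
    fell outside the source grid (those are set to 0).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != dvf.grid.shape:
        raise ValueError("field and DVF grids are incompatible")
    if dvf.is_zero():
        # identity warp must be exact, not interpolated
        return values.copy(), 0
    coords, inside = _sample_coordinates(dvf)
    out = ndimage.map_coordinates(values, coords, order=1, mode="constant", cval=0.0)
    n_outside = int((~inside).sum())
    return out, n_outside


def warp_dose(dose_on_phase: Volume, dvf: DVF) -> Volume:
    """Warp a phase dose grid to the reference phase (trilinear pull-back).

    Out-of-grid samples are set to 0 Gy and their count is logged.
    """
    if not dose_on_phase.grid.same_geometry(dvf.grid):
        raise ValueError("dose and DVF grids are incompatible")
    warped, n_outside = warp_scalar(dose_on_phase.values, dvf)
    if n_outside:
        log.info("warp_dose: %d voxels sampled outside the source grid (set to 0)", n_outside)
    return Volume(warped, dvf.grid)


def warp_mask(mask_on_phase: np.ndarray, dvf: DVF) -> np.ndarray:
    """Warp a binary mask as a scalar field and re-threshold at 0.5."""
    mask = np.asarray(mask_on_phase)
    if mask.shape != dvf.grid.shape:
        raise ValueError("mask and DVF grids are incompatible")
    warped, _ = warp_scalar(mask.astype(float), dvf)
    return warped >= 0.5


def invert_dvf(dvf: DVF, n_iter: int = 30, tol_mm: float = 1e-3) -> DVF:
    """Numerically invert a DVF by fixed-point iteration.

    Solves ``v(x) = -u(x + v(x))``; converges for displacement fields whose
    gradient magnitude is below 1 (guaranteed by the phantom invariants).
    """
    grid = dvf.grid
    v = np.zeros_like(dvf.displacement_mm)
    for _ in range(n_iter):
        shifted = DVF(v, grid)
        coords, _ = _sample_coordinates(shifted)
        u_at = np.stack(
            [
                ndimage.map_coordinates(
                    dvf.displacement_mm[..., a], coords, order=1, mode="nearest"
                )
                for a in range(3)
            ],
            axis=-1,
        )
        v_new = -u_at
        delta = np.linalg.norm(v_new - v, axis=-1).max()
        v = v_new
        if delta < tol_mm:
            break
    return DVF(v, grid)


def compose_residual_mm(dvf: DVF, inverse: DVF) -> np.ndarray:
    """Residual |x - (x + v + u(x+v))| of composing a DVF with its inverse."""
    grid = dvf.grid
    coords, _ = _sample_coordinates(inverse)
    u_at = np.stack(
        [
            ndimage.map_coordinates(dvf.displacement_mm[..., a], coords, order=1, mode="nearest")
            for a in range(3)
        ],
        axis=-1,
    )
    total = inverse.displacement_mm + u_at
    return np.linalg.norm(total, axis=-1)
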