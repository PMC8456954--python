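"""Target-volume geometry: margins, ITV construction, motion summary, Dice.

The planning chain implemented here follows standard free-breathing proton
practice for moving lung tumors: the gross tumor volume (GTV) is expanded
isotropically to the clinical target volume (CTV), the internal target
volume (ITV) is the union of the per-phase CTVs over the breathing cycle,
and the robust-optimization target is the ITV plus a small safety margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import AXIS_NAMES, Grid, Volume, require_same_grid

log = logging.getLogger(__name__)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid.

    Typical roles: GTVp, CTVp, ITVp, ITVp_02, heart, esophagus,
    spinal_cord, lungs, lung_contra, MedEnv_05.
    """

    grid: Grid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name, m in list(self.masks.items()):
            self.masks[name] = self._check(name, m)

    def _check(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.shape != self.grid.shape:
            raise ValueError(f"mask {name!r} shape {mask.shape} != grid {self.grid.shape}")
        return mask.astype(bool)

    def add(self, name: str, mask: np.ndarray) -> None:
        if name in self.masks:
            raise ValueError(f"structure {name!r} already present")
        self.masks[name] = self._check(name, mask)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)

    def volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_cc


@dataclass(frozen=True)
class MotionSummary:
    """Peak-to-peak tumor excursion along one anatomical axis.

    ``amplitude_mm`` is the largest per-axis difference between the
    bounding-box midpoints of the tumor mask over any two phases; the two
    phases realizing it are the extreme phases.
    """

    amplitude_mm: float
    axis: str
    extreme_phase_pair: tuple[str, str]


def expand_isotropic(mask: np.ndarray, margin_mm: float, grid: Grid) -> np.ndarray:
    """Expand a binary mask by a Euclidean margin (anisotropic spacing respected).

    The output contains exactly the voxels whose center lies within
    ``margin_mm`` of some voxel center of the input mask.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    if not mask.any():
        log.warning("expand_isotropic: empty input mask")
        return mask.copy()
    if margin_mm == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing_mm)
    return dist <= margin_mm + 1e-9


def build_itv(ctv_masks: list[np.ndarray], grid: Grid | None = None) -> np.ndarray:
    """Voxel-wise union of per-phase CTV masks on a common grid."""
    if len(ctv_masks) == 0:
        raise ValueError("need at least one mask")
    shape = np.asarray(ctv_masks[0]).shape
    out = np.zeros(shape, dtype=bool)
    for m in ctv_masks:
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError("grid mismatch between phase masks")
        out |= m.astype(bool)
    return out


def _bbox_midpoint_mm(mask: np.ndarray, grid: Grid) -> np.ndarray:
    """Axis-aligned bounding-box center of a mask, in world mm."""
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    mid = np.empty(3)
    for a in range(3):
        proj = mask.any(axis=tuple(ax for ax in range(3) if ax != a))
        idx = np.nonzero(proj)[0]
        center_idx = (idx[0] + idx[-1]) / 2.0
        mid[a] = grid.origin_mm[a] + center_idx * grid.spacing_mm[a]
    return mid


def tumor_amplitude(gtv_masks: dict[str, np.ndarray], grid: Grid) -> MotionSummary:
    """Largest per-axis bounding-box-midpoint distance over all phase pairs.

    Returns the amplitude, the direction of largest movement and the pair
    of extreme phases.
    """
    if len(gtv_masks) < 2:
        raise ValueError("need at least two phases")
    labels = list(gtv_masks)
    mids = {}
    for lab, m in gtv_masks.items():
        m = np.asarray(m).astype(bool)
        if m.shape != grid.shape:
            raise ValueError(f"mask {lab!r} does not match grid")
        if not m.any():
            raise ValueError(f"empty tumor mask in phase {lab!r}")
        mids[lab] = _bbox_midpoint_mm(m, grid)
    best = (0.0, 0, (labels[0], labels[1]))
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            diff = np.abs(mids[la] - mids[lb])
            a = int(np.argmax(diff))
            if diff[a] > best[0]:
                best = (float(diff[a]), a, (la, lb))
    amplitude, axis, pair = best
    if amplitude == 0.0:
        pair = (labels[0], labels[0])
    return MotionSummary(amplitude_mm=amplitude, axis=AXIS_NAMES[axis], extreme_phase_pair=pair)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def average_ct(series) -> Volume:
    """Voxel-wise arithmetic mean of all phase images (the avgCT)."""
    images = [series.images[lab] for lab in series.phase_labels]
    grid = require_same_grid(*[im.grid for im in images])
    stack = np.stack([im.values for im in images])
    return Volume(stack.mean(axis=0), grid)
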