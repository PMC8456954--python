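"""Regular image grids and scalar volumes.

All geometry is expressed in patient LPS coordinates: the first array axis
runs to the patient's left (+x), the second posterior (+y), the third
superior (+z).  A :class:`Grid` is an axis-aligned regular lattice; voxel
``(i, j, k)`` has world position ``origin_mm + (i, j, k) * spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_NAMES = ("LR", "AP", "SI")  # world axis 0, 1, 2


def axis_index(name: str) -> int:
    """Map an anatomical axis name (LR/AP/SI) to its array axis."""
    try:
        return AXIS_NAMES.index(name)
    except ValueError:
        raise ValueError(f"unknown axis {name!r}; expected one of {AXIS_NAMES}") from None


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular voxel lattice (shape, spacing and origin in mm)."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense world-coordinate arrays (X, Y, Z), each of ``shape``."""
        axes = [
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal; axes are LPS by convention)."""
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def same_geometry(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )


def centered_grid(shape, spacing_mm) -> Grid:
    """Grid whose world origin sits at the lattice center."""
    shape = tuple(int(n) for n in shape)
    spacing_mm = tuple(float(s) for s in spacing_mm)
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing_mm))
    return Grid(shape, spacing_mm, origin)


@dataclass
class Volume:
    """A scalar field on a :class:`Grid` (density images, dose grids)."""

    values: np.ndarray
    grid: Grid = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"array shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.grid)


def require_same_grid(*grids: Grid) -> Grid:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise ValueError("grid geometry mismatch between volumes")
    return first
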