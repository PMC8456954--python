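"""Analytic broad-beam proton dose engine on stopping-power grids.

This is a deliberately simple stand-in for a clinical Monte Carlo engine:
each beam is a broad field whose depth dose is a spread-out Bragg peak
(SOBP) in water-equivalent depth and whose lateral profile is the target
silhouette expanded by an aperture margin and blurred with a Gaussian
penumbra.  What matters for the evaluation strategies built on top is not
spot-level realism but the engine's faithful sensitivity to the two error
axes of robust evaluation: rigid setup shifts (the aperture and SOBP stay
fixed in the room while the patient moves) and range errors (a global
density rescaling shifts every water-equivalent depth).

The plan is fitted once on the planning CT (SOBP bounds from the target
WEPL span, lateral aperture from the target silhouette, one normalization
constant) and is never re-fitted per scenario or phase: setup and range
errors are systematic, so every scenario perturbs the delivery of the
same fixed plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import Grid, Volume
from .scenarios import NOMINAL, Scenario
from .structures import StructureSet

#: A dose grid is a scalar volume in Gy (RBE).
DoseGrid = Volume

DEFAULT_FALLOFF_MM = 5.0  # 80-20 % distal falloff width in WEPL
DEFAULT_ENTRY_FACTOR = 0.85  # relative dose at zero depth (proximal sub-plateau)


@dataclass(frozen=True)
class BeamSpec:
    """One broad beam.

    ``direction`` is the propagation direction in LPS; the analytic engine
    supports the six axis-aligned directions.  ``lateral_margin_mm`` is the
    aperture margin around the target silhouette, given either as a scalar
    or per world axis (the margin used is the one of each lateral axis,
    allowing a tighter margin along an axis the target already encloses
    motion in).  ``sobp_margin_mm`` pads the SOBP proximally and distally
    in water-equivalent depth; ``penumbra_sigma_mm`` is the lateral
    Gaussian blur.
    """

    direction: tuple[float, float, float]
    sobp_margin_mm: float = 12.0
    lateral_margin_mm: float | tuple[float, float, float] = 12.0
    penumbra_sigma_mm: float = 4.0
    name: str = ""

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("beam direction must be nonzero")
        d = d / n
        object.__setattr__(self, "direction", tuple(d))
        if self.sobp_margin_mm < 0 or self.penumbra_sigma_mm < 0:
            raise ValueError("margins must be >= 0")
        margins = self.margin_per_axis()
        if any(m < 0 for m in margins):
            raise ValueError("margins must be >= 0")

    def margin_per_axis(self) -> tuple[float, float, float]:
        m = self.lateral_margin_mm
        if np.isscalar(m):
            return (float(m),) * 3
        m = tuple(float(v) for v in m)
        if len(m) != 3:
            raise ValueError("lateral_margin_mm must be a scalar or a 3-tuple")
        return m

    def axis_and_sign(self) -> tuple[int, int]:
        """Propagation axis and sign; rejects non-axis-aligned directions."""
        d = np.asarray(self.direction)
        axis = int(np.argmax(np.abs(d)))
        if not np.isclose(np.abs(d[axis]), 1.0, atol=1e-9):
            raise ValueError(
                "the analytic broad-beam engine supports axis-aligned beams only"
            )
        return axis, (1 if d[axis] > 0 else -1)


@dataclass(frozen=True)
class PlanSpec:
    """Prescription-level plan parameters (60 Gy RBE in 30 fractions by default)."""

    beams: tuple[BeamSpec, ...]
    target_name: str = "ITVp_02"
    prescription_gy: float = 60.0
    n_fractions: int = 30
    rbe_factor: float = 1.1
    dose_grid_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self):
        object.__setattr__(self, "beams", tuple(self.beams))
        if not self.beams:
            raise ValueError("plan needs at least one beam")
        if self.prescription_gy <= 0:
            raise ValueError("prescription_gy must be positive")


def default_beams() -> tuple[BeamSpec, ...]:
    """Anterior, posterior and ipsilateral beams for the left-lung phantom.

    Margins are anisotropic: 12 mm in the axial plane, 10 mm along SI where
    the ITV-based target already encloses the breathing excursion.
    """
    m = (12.0, 12.0, 10.0)
    return (
        BeamSpec((0, 1, 0), lateral_margin_mm=m, name="ANT"),
        BeamSpec((0, -1, 0), lateral_margin_mm=m, name="POST"),
        BeamSpec((-1, 0, 0), lateral_margin_mm=m, name="LAT"),
    )


def wepl_map(density: np.ndarray, axis: int, sign: int, spacing_mm: float) -> np.ndarray:
    """Cumulative water-equivalent depth at every voxel center along a beam axis.

    Midpoint rule: the WEPL at a voxel center includes half of that voxel's
    own water-equivalent thickness.
    """
    rho = np.asarray(density, dtype=float)
    if sign < 0:
        rho = np.flip(rho, axis=axis)
    w = (np.cumsum(rho, axis=axis) - 0.5 * rho) * spacing_mm
    if sign < 0:
        w = np.flip(w, axis=axis)
    return w


def wepl_profile(density: Volume, entry_point_mm, direction, step_mm: float):
    """Cumulative WEPL along an arbitrary ray through a density image.

    Returns ``(depths_mm, wepl_mm)`` sampled every ``step_mm`` from the
    entry point until the ray leaves the grid; both are empty if the ray
    misses the grid entirely.  Trapezoidal accumulation of density times
    geometric step.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be nonzero")
    d = d / n
    grid = density.grid
    if step_mm > min(grid.spacing_mm) + 1e-12:
        raise ValueError("step_mm must not exceed the smallest voxel spacing")
    p0 = np.asarray(entry_point_mm, dtype=float)
    # march far enough to cross the whole grid from any entry point
    extent = np.linalg.norm([s * (n_ - 1) for s, n_ in zip(grid.spacing_mm, grid.shape)])
    n_steps = int(np.ceil(2.0 * extent / step_mm)) + 1
    depths = step_mm * np.arange(n_steps)
    pts = p0[None, :] + depths[:, None] * d[None, :]
    vox = (pts - np.asarray(grid.origin_mm)) / np.asarray(grid.spacing_mm)
    inside = np.all((vox >= 0) & (vox <= np.asarray(grid.shape) - 1), axis=1)
    if not inside.any():
        return np.empty(0), np.empty(0)
    last = int(np.nonzero(inside)[0][-1])
    first = int(np.nonzero(inside)[0][0])
    vox = vox[first:last + 1]
    depths = depths[first:last + 1]
    rho = ndimage.map_coordinates(
        np.asarray(density.values, dtype=float), vox.T, order=1, mode="constant", cval=0.0
    )
    wepl = np.zeros_like(rho)
    if rho.size > 1:
        wepl[1:] = np.cumsum(0.5 * (rho[1:] + rho[:-1]) * step_mm)
    return depths - depths[0], wepl


def sobp_depth_dose(depth_wepl, proximal_mm: float, distal_mm: float,
                    falloff_mm: float = DEFAULT_FALLOFF_MM,
                    entry_factor: float = DEFAULT_ENTRY_FACTOR) -> np.ndarray:
    """Relative SOBP depth dose as a function of water-equivalent depth.

    Unity plateau on [proximal, distal]; a reduced proximal plateau ramps
    from ``entry_factor`` at zero depth; beyond the distal edge the dose
    falls off along a Gaussian shoulder with an 80-20 % width of
    ``falloff_mm``.
    """
    if proximal_mm >= distal_mm:
        raise ValueError("proximal_mm must be smaller than distal_mm")
    if falloff_mm <= 0:
        raise ValueError("falloff_mm must be positive")
    w = np.asarray(depth_wepl, dtype=float)
    out = np.ones_like(w)
    if proximal_mm > 0:
        pre = w < proximal_mm
        out[pre] = entry_factor + (1.0 - entry_factor) * w[pre] / proximal_mm
    post = w > distal_mm
    # Gaussian shoulder: k chosen so the 80 % and 20 % depths are falloff_mm apart
    k = (np.sqrt(np.log(5.0)) - np.sqrt(np.log(1.25))) / falloff_mm
    out[post] = np.exp(-((k * (w[post] - distal_mm)) ** 2))
    return out


@dataclass
class FittedBeam:
    """Per-beam quantities frozen at plan time (room frame)."""

    spec: BeamSpec
    axis: int
    sign: int
    proximal_mm: float
    distal_mm: float
    lateral_map: np.ndarray = field(repr=False)  # 2-D over the non-beam axes


@dataclass
class Plan:
    """A fitted plan: fixed SOBP bounds, apertures and one normalization."""

    spec: PlanSpec
    grid: Grid = field(repr=False)
    beams: list[FittedBeam] = field(repr=False)
    norm: float = 1.0

    @property
    def prescription_gy(self) -> float:
        return self.spec.prescription_gy


def _fit_beam(beam: BeamSpec, density: np.ndarray, target: np.ndarray,
              grid: Grid) -> FittedBeam:
    axis, sign = beam.axis_and_sign()
    w = wepl_map(density, axis, sign, grid.spacing_mm[axis])
    tw = w[target]
    proximal = max(0.0, float(tw.min()) - beam.sobp_margin_mm)
    distal = float(tw.max()) + beam.sobp_margin_mm
    lat_axes = tuple(a for a in range(3) if a != axis)
    sil = target.any(axis=axis)
    if not sil.any():
        raise ValueError(f"beam {beam.name or beam.direction} misses the target")
    margins = beam.margin_per_axis()
    # elliptical dilation: distance normalized per lateral axis by its margin
    sampling = tuple(
        grid.spacing_mm[a] / max(margins[a], 1e-9) for a in lat_axes
    )
    dist = ndimage.distance_transform_edt(~sil, sampling=sampling)
    aperture = (dist <= 1.0 + 1e-9).astype(float)
    sigma_vox = tuple(beam.penumbra_sigma_mm / grid.spacing_mm[a] for a in lat_axes)
    lateral = ndimage.gaussian_filter(aperture, sigma=sigma_vox, mode="constant")
    return FittedBeam(beam, axis, sign, proximal, distal, lateral)


def _raw_dose(plan: Plan, density: np.ndarray) -> np.ndarray:
    out = np.zeros(plan.grid.shape)
    w_beam = 1.0 / len(plan.beams)
    for fb in plan.beams:
        w = wepl_map(density, fb.axis, fb.sign, plan.grid.spacing_mm[fb.axis])
        depth = sobp_depth_dose(w, fb.proximal_mm, fb.distal_mm)
        lat = np.expand_dims(fb.lateral_map, axis=fb.axis)
        out += w_beam * depth * lat
    return out


def make_plan(spec: PlanSpec, planning_ct: Volume, structures: StructureSet) -> Plan:
    """Fit SOBP bounds and apertures on the planning CT and normalize.

    The normalization constant maps the median nominal dose over the target
    to the prescription (Gy RBE); the same constant is reused for every
    scenario and phase of this plan.
    """
    if spec.target_name not in structures:
        raise ValueError(f"target structure {spec.target_name!r} missing")
    target = structures[spec.target_name]
    if not target.any():
        raise ValueError("target structure is empty")
    grid = planning_ct.grid
    if not grid.same_geometry(structures.grid):
        raise ValueError("planning CT and structures grids differ")
    density = np.asarray(planning_ct.values, dtype=float)
    beams = [_fit_beam(b, density, target, grid) for b in spec.beams]
    plan = Plan(spec, grid, beams, norm=1.0)
    raw = _raw_dose(plan, density)
    med = float(np.median(raw[target]))
    if med <= 0:
        raise ValueError("plan delivers no dose to the target")
    plan.norm = spec.prescription_gy / med
    return plan


def translate(values: np.ndarray, offset_mm, grid: Grid) -> np.ndarray:
    """Rigidly translate a field by ``offset_mm``: output(x) = input(x - offset).

    Voxel-multiple offsets use exact integer rolling (with zero fill);
    anything else falls back to trilinear resampling.
    """
    offset_vox = np.asarray(offset_mm, dtype=float) / np.asarray(grid.spacing_mm)
    if not offset_vox.any():
        return np.asarray(values, dtype=float).copy()
    rounded = np.round(offset_vox)
    if np.allclose(offset_vox, rounded, atol=1e-9):
        out = np.asarray(values, dtype=float)
        for a, n in enumerate(rounded.astype(int)):
            if n == 0:
                continue
            out = np.roll(out, n, axis=a)
            sl = [slice(None)] * 3
            sl[a] = slice(0, n) if n > 0 else slice(n, None)
            out = out.copy()
            out[tuple(sl)] = 0.0
        return out
    return ndimage.shift(
        np.asarray(values, dtype=float), offset_vox, order=1, mode="constant", cval=0.0
    )


def compute_dose(plan: Plan, density_image: Volume,
                 scenario: Scenario = NOMINAL) -> DoseGrid:
    """Dose (Gy RBE) for one error scenario on one density image.

    The scenario moves the patient by ``-shift_mm`` relative to the fixed
    beams and rescales all stopping powers before ray casting; the
    resulting dose is translated back so it lives on the patient grid and
    can be evaluated against unshifted contours.
    """
    if not density_image.grid.same_geometry(plan.grid):
        raise ValueError("density grid differs from the plan grid")
    rho = np.asarray(density_image.values, dtype=float)
    shift = np.asarray(scenario.shift_mm, dtype=float)
    if shift.any():
        rho = translate(rho, -shift, plan.grid)
    if scenario.density_scale != 1.0:
        rho = rho * scenario.density_scale
    dose = _raw_dose(plan, rho) * plan.norm
    if shift.any():
        dose = translate(dose, shift, plan.grid)
    np.clip(dose, 0.0, None, out=dose)
    return DoseGrid(dose, plan.grid)
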