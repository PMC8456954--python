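"""Synthetic 8-phase 4DCT phantom with analytically known tumor motion.

The phantom emulates an amplitude-binned free-breathing 4DCT of the thorax:
a water-equivalent body cylinder, two low-density lung compartments
separated by a mediastinal column, and a spherical tumor that translates
rigidly along one anatomical axis through the lung.  Voxel values are
relative proton stopping powers (water = 1), which the analytic dose
engine consumes directly.

Phase naming follows the amplitude-binned convention: five amplitude
levels (0/25/50/75/100 % of peak-to-peak) with the intermediate levels
split into an inhale and an exhale branch, giving the eight phases
CT0in ... CT100in ... CT25ex.  CT50ex is the reference phase.  Every
non-reference phase carries an analytic displacement field to the
reference grid, so dose warping can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, Volume, axis_index, centered_grid
from .structures import StructureSet, build_itv, expand_isotropic
from .warp import DVF

PHASE_LABELS = (
    "CT0in", "CT25in", "CT50in", "CT75in",
    "CT100in", "CT75ex", "CT50ex", "CT25ex",
)
REFERENCE_LABEL = "CT50ex"

#: Amplitude level of each phase as a fraction of the peak-to-peak amplitude.
AMPLITUDE_LEVELS = {
    "CT0in": 0.0, "CT25in": 0.25, "CT50in": 0.5, "CT75in": 0.75,
    "CT100in": 1.0, "CT75ex": 0.75, "CT50ex": 0.5, "CT25ex": 0.25,
}

#: Amplitude-bin edges as fractions of the peak-to-peak amplitude; the five
#: levels own the bins delimited by the midpoints between adjacent levels.
BIN_EDGES = (0.125, 0.375, 0.625, 0.875)

WEIGHT_PATTERNS = ("equal", "cos", "cos4")

# Fixed thorax geometry (mm); the tumor is configurable, the torso is not.
BODY_RADIUS_MM = 80.0
LUNG_RADIUS_MM = 62.0
MEDIASTINUM_HALFWIDTH_MM = 18.0
AIR_DENSITY = 0.0

# Rigid core of the motion field extends this far beyond the GTV surface so
# that the CTV moves rigidly with the tumor.
RIGID_CORE_PAD_MM = 8.0


@dataclass(frozen=True)
class WeightScheme:
    """Per-phase nonnegative time weights summing to 1, keyed by phase label."""

    weights: dict[str, float]
    pattern_name: str

    def __post_init__(self):
        w = {k: float(v) for k, v in self.weights.items()}
        object.__setattr__(self, "weights", w)
        if set(w) != set(PHASE_LABELS):
            raise ValueError("weights must be keyed by the eight phase labels")
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be nonnegative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {sum(w.values())!r}, expected 1")

    def as_array(self, labels=PHASE_LABELS) -> np.ndarray:
        return np.array([self.weights[lab] for lab in labels])


def phase_displacements(amplitude_mm: float, n_phases: int = 8,
                        pattern: str = "equal") -> dict[str, float]:
    """Scalar displacement of each phase along the motion axis.

    With amplitude binning the displacement of a phase is fixed by its
    amplitude level alone -- CT0in sits at full exhale (0), CT100in at full
    inhale (``amplitude_mm``) -- regardless of the breathing waveform.  The
    waveform only changes how much *time* is spent per phase (see
    :func:`breathing_weights`), which is why ``pattern`` is validated but
    does not alter the returned displacements.
    """
    if pattern not in WEIGHT_PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {WEIGHT_PATTERNS}")
    if n_phases != 8:
        raise ValueError("amplitude-binned phantom supports exactly 8 phases")
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    return {lab: AMPLITUDE_LEVELS[lab] * amplitude_mm for lab in PHASE_LABELS}


def weights_from_signal(amplitude_samples: np.ndarray,
                        inhale: np.ndarray,
                        pattern_name: str = "sampled") -> WeightScheme:
    """Time weights from a densely sampled periodic breathing signal.

    ``amplitude_samples`` are signal values over one period (any units),
    ``inhale`` marks samples on the inhale branch.  Samples are binned into
    the five amplitude levels at the midpoint bin edges; the extreme bins
    belong to CT0in / CT100in, intermediate bins are split by branch.
    """
    a = np.asarray(amplitude_samples, dtype=float)
    inhale = np.asarray(inhale, dtype=bool)
    if a.shape != inhale.shape or a.ndim != 1 or a.size < 8:
        raise ValueError("need matching 1-D sample arrays")
    peak, trough = a.max(), a.min()
    if peak - trough <= 0:
        raise ValueError("degenerate breathing signal: zero amplitude")
    frac = (a - trough) / (peak - trough)
    level = np.digitize(frac, BIN_EDGES)  # 0..4
    counts = {lab: 0 for lab in PHASE_LABELS}
    counts["CT0in"] = int((level == 0).sum())
    counts["CT100in"] = int((level == 4).sum())
    for lev, name in ((1, "25"), (2, "50"), (3, "75")):
        sel = level == lev
        counts[f"CT{name}in"] = int((sel & inhale).sum())
        counts[f"CT{name}ex"] = int((sel & ~inhale).sum())
    total = a.size
    return WeightScheme({lab: counts[lab] / total for lab in PHASE_LABELS}, pattern_name)


def breathing_weights(pattern: str, n_samples: int = 400_000) -> WeightScheme:
    """Per-phase time weights for a breathing-pattern assumption.

    ``equal`` assigns w = 1/8 to every phase.  ``cos`` assumes the
    breathing signal x(t) = A (1 - cos 2πt/T) / 2 (t = 0 at full exhale);
    ``cos4`` uses the same expression raised to the fourth power, which
    spends most of the cycle near exhale.  For the sampled patterns the
    weight of a phase is the fraction of one period spent in its
    amplitude bin.
    """
    if pattern not in WEIGHT_PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {WEIGHT_PATTERNS}")
    if pattern == "equal":
        return WeightScheme({lab: 1.0 / 8.0 for lab in PHASE_LABELS}, "equal")
    if n_samples < 10**5:
        raise ValueError("need at least 1e5 samples for a stable time fraction")
    t = (np.arange(n_samples) + 0.5) / n_samples
    base = (1.0 - np.cos(2.0 * np.pi * t)) / 2.0
    signal = base if pattern == "cos" else base**4
    inhale = t < 0.5  # signal rises monotonically on the first half-period
    return weights_from_signal(signal, inhale, pattern)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic 4D phantom.

    Densities are relative proton stopping powers.  ``tumor_center_mm`` is
    the tumor position in the reference phase (CT50ex, the 50 % amplitude
    level); the programmed motion spans ``amplitude_mm`` peak-to-peak along
    ``motion_axis``.  ``transition_shell_mm`` is the width over which the
    displacement field decays linearly to zero outside the rigid tumor
    core; it must exceed half the amplitude so the deformation stays
    invertible (displacement-gradient magnitude < 1).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    lung_density: float = 0.26
    body_density: float = 1.0
    tumor_density: float = 1.0
    tumor_radius_mm: float = 12.0
    tumor_center_mm: tuple[float, float, float] = (40.0, 0.0, 0.0)
    amplitude_mm: float = 20.0
    motion_axis: str = "SI"
    transition_shell_mm: float | None = None
    n_phases: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be >= 0")
        if self.n_phases != 8:
            raise ValueError("the amplitude-binned phantom has exactly 8 phases")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor_radius_mm must be > 0")
        axis_index(self.motion_axis)  # validates the name
        if self.transition_shell_mm is None:
            shell = max(12.0, 0.75 * self.amplitude_mm)
            object.__setattr__(self, "transition_shell_mm", shell)
        if self.transition_shell_mm <= self.amplitude_mm / 2.0:
            raise ValueError(
                "transition_shell_mm must exceed amplitude_mm/2 for an "
                "invertible deformation"
            )

    @property
    def grid(self) -> Grid:
        return centered_grid(self.grid_shape, self.spacing_mm)


@dataclass
class Series4D:
    """Ordered phase density images with per-phase DVFs to the reference."""

    phase_labels: tuple[str, ...]
    images: dict[str, Volume]
    reference_label: str
    dvfs_to_reference: dict[str, DVF]

    def __post_init__(self):
        if tuple(self.phase_labels) != PHASE_LABELS:
            raise ValueError(f"phase labels must be {PHASE_LABELS}")
        if self.reference_label not in self.phase_labels:
            raise ValueError("reference label must be one of the phases")
        grid = self.grid
        for lab in self.phase_labels:
            if not self.images[lab].grid.same_geometry(grid):
                raise ValueError(f"phase {lab!r} image grid differs from reference")
            if not self.dvfs_to_reference[lab].grid.same_geometry(grid):
                raise ValueError(f"phase {lab!r} DVF grid differs from reference")
        if not self.dvfs_to_reference[self.reference_label].is_zero():
            raise ValueError("reference-phase DVF must be identically zero")

    @property
    def grid(self) -> Grid:
        return self.images[self.reference_label].grid

    @property
    def reference_image(self) -> Volume:
        return self.images[self.reference_label]


@dataclass(frozen=True)
class MotionTruth:
    """Programmed ground-truth motion of the phantom tumor."""

    phase_offsets_mm: dict[str, np.ndarray]  # rigid tumor offset vs reference
    axis: str
    amplitude_mm: float
    extreme_phases: tuple[str, str]
    rigid_core_radius_mm: float
    transition_shell_mm: float


def _thorax_regions(grid: Grid):
    x, y, z = grid.world_coordinates()
    r_xy = np.hypot(x, y)
    body = r_xy <= BODY_RADIUS_MM
    inner = r_xy <= LUNG_RADIUS_MM
    mediastinum = inner & (np.abs(x) <= MEDIASTINUM_HALFWIDTH_MM)
    lung = inner & ~mediastinum
    return (x, y, z), body, mediastinum, lung


def _sphere(coords, center, radius) -> np.ndarray:
    x, y, z = coords
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2


def build_phantom(spec: PhantomSpec):
    """Render the phantom: density series, per-phase structures, motion truth.

    Returns ``(series, structures_by_phase, truth)``.  Tumor masks are
    analytic spheres translated by the programmed per-phase displacement;
    densities use binary assignment (no partial volume).  The DVF of each
    phase maps a reference point x to x + d_phase * g(x), with g = 1 inside
    the rigid tumor core and decaying linearly to 0 across the transition
    shell.
    """
    grid = spec.grid
    coords, body, mediastinum, lung = _thorax_regions(grid)
    axis = axis_index(spec.motion_axis)
    unit = np.zeros(3)
    unit[axis] = 1.0

    displacements = phase_displacements(spec.amplitude_mm)
    center_ref = np.asarray(spec.tumor_center_mm, dtype=float)
    offsets = {
        lab: (displacements[lab] - displacements[REFERENCE_LABEL]) * unit
        for lab in PHASE_LABELS
    }

    base = np.full(grid.shape, AIR_DENSITY)
    base[body] = spec.body_density
    base[lung] = spec.lung_density

    # static OARs
    x, y, z = coords
    heart = _sphere(coords, (-25.0, -15.0, -20.0), 25.0)
    esophagus = (np.hypot(x - 0.0, y - 25.0) <= 4.0) & body
    cord = (np.hypot(x - 0.0, y - 45.0) <= 5.0) & body
    medenv = expand_isotropic(mediastinum, 5.0, grid)
    lungs_mask = lung
    contra_side = np.sign(center_ref[0]) or 1.0
    lung_contra = lung & (np.sign(x) != contra_side) & (np.abs(x) > MEDIASTINUM_HALFWIDTH_MM)

    # the tumor sphere plus its full excursion must stay inside the lung
    # compartment and the grid
    half_extent = [(n - 1) * s / 2.0 for n, s in zip(grid.shape, grid.spacing_mm)]
    r = spec.tumor_radius_mm
    for lab in PHASE_LABELS:
        c = center_ref + offsets[lab]
        radial = float(np.hypot(c[0], c[1]))
        if (radial + r > LUNG_RADIUS_MM or abs(c[0]) - r < MEDIASTINUM_HALFWIDTH_MM
                or any(abs(c[a]) + r > half_extent[a] for a in range(3))):
            raise ValueError(
                "tumor sphere leaves the lung compartment during the breathing "
                "cycle; reduce amplitude or move the tumor center"
            )

    ctv_margin = 5.0
    images: dict[str, Volume] = {}
    gtv_by_phase: dict[str, np.ndarray] = {}
    ctv_by_phase: dict[str, np.ndarray] = {}
    for lab in PHASE_LABELS:
        c = center_ref + offsets[lab]
        gtv = _sphere(coords, c, spec.tumor_radius_mm)
        if (gtv & ~lung).any():
            raise ValueError(
                "tumor sphere leaves the lung compartment during the breathing "
                "cycle; reduce amplitude or move the tumor center"
            )
        ctv = _sphere(coords, c, spec.tumor_radius_mm + ctv_margin)
        dens = base.copy()
        dens[gtv] = spec.tumor_density
        images[lab] = Volume(dens, grid)
        gtv_by_phase[lab] = gtv
        ctv_by_phase[lab] = ctv

    itv = build_itv([ctv_by_phase[lab] for lab in PHASE_LABELS])
    itv_02 = expand_isotropic(itv, 2.0, grid)

    # displacement fields: rigid core + linear decay shell
    core_r = spec.tumor_radius_mm + RIGID_CORE_PAD_MM
    dist_core = np.sqrt(
        (x - center_ref[0]) ** 2 + (y - center_ref[1]) ** 2 + (z - center_ref[2]) ** 2
    ) - core_r
    g = np.clip(1.0 - np.maximum(dist_core, 0.0) / spec.transition_shell_mm, 0.0, 1.0)
    dvfs = {}
    for lab in PHASE_LABELS:
        if lab == REFERENCE_LABEL:
            dvfs[lab] = DVF.zero(grid)
        else:
            disp = g[..., None] * offsets[lab][None, None, None, :]
            dvfs[lab] = DVF(disp, grid)

    series = Series4D(PHASE_LABELS, images, REFERENCE_LABEL, dvfs)

    structures_by_phase = {}
    for lab in PHASE_LABELS:
        structures_by_phase[lab] = StructureSet(
            grid,
            {
                "GTVp": gtv_by_phase[lab],
                "CTVp": ctv_by_phase[lab],
                "ITVp": itv,
                "ITVp_02": itv_02,
                "heart": heart,
                "esophagus": esophagus,
                "spinal_cord": cord,
                "lungs": lungs_mask,
                "lung_contra": lung_contra,
                "MedEnv_05": medenv,
            },
        )

    truth = MotionTruth(
        phase_offsets_mm={lab: offsets[lab].copy() for lab in PHASE_LABELS},
        axis=spec.motion_axis,
        amplitude_mm=spec.amplitude_mm,
        extreme_phases=("CT0in", "CT100in"),
        rigid_core_radius_mm=core_r,
        transition_shell_mm=spec.transition_shell_mm,
    )
    return series, structures_by_phase, truth
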