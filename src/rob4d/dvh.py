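"""Dose-volume histogram metrics and clinical-goal checking.

All metrics use a deterministic voxel-count convention with no sub-voxel
interpolation: Dx% is the dose of the voxel at rank ceil(x/100*N) of the
descending-sorted structure doses, VxGy counts voxels at or above the
threshold, and D0.03cc walks the sorted voxels until their cumulative
volume reaches 0.03 cm3.  Clinical goals follow the standard robust
reading: target coverage is judged on the voxel-wise minimum dose, OAR
near-maximum doses on the voxel-wise maximum, and mean-dose goals on the
nominal dose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .grid import Grid
from .structures import StructureSet

log = logging.getLogger(__name__)


def _structure_doses(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.asarray(dose).shape:
        raise ValueError("dose and mask must share one grid")
    if not mask.any():
        raise ValueError("empty structure mask")
    return np.asarray(dose, dtype=float)[mask]


def dose_at_volume(dose: np.ndarray, mask: np.ndarray, volume_pct: float) -> float:
    """Dx%: the largest dose received by at least x% of the structure volume."""
    if not (0.0 < volume_pct <= 100.0):
        raise ValueError("volume_pct must be in (0, 100]")
    vals = np.sort(_structure_doses(dose, mask))[::-1]
    idx = math.ceil(volume_pct / 100.0 * vals.size) - 1
    return float(vals[idx])


def volume_at_dose(dose: np.ndarray, mask: np.ndarray, threshold_gy: float) -> float:
    """VxGy: percent of the structure volume receiving at least the threshold."""
    vals = _structure_doses(dose, mask)
    return 100.0 * float((vals >= threshold_gy).sum()) / vals.size


def near_max(dose: np.ndarray, mask: np.ndarray, grid: Grid, cc: float = 0.03) -> float:
    """D_cc: dose of the voxel at which cumulative hottest volume reaches ``cc``.

    If the structure is smaller than ``cc`` the minimum structure dose is
    returned with a warning.
    """
    vals = np.sort(_structure_doses(dose, mask))[::-1]
    vox_cc = grid.voxel_volume_cc
    if vals.size * vox_cc < cc:
        log.warning("near_max: structure volume %.4f cc below requested %.4f cc",
                    vals.size * vox_cc, cc)
        return float(vals[-1])
    n = math.ceil(cc / vox_cc)
    return float(vals[n - 1])


def mean_dose(dose: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean dose over the structure voxels."""
    return float(_structure_doses(dose, mask).mean())


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= each bin dose."""

    dose_bins_gy: np.ndarray
    cumulative_volume_fraction: np.ndarray


def dvh_curve(dose: np.ndarray, mask: np.ndarray, bin_gy: float = 0.1,
              max_gy: float | None = None) -> DVHCurve:
    vals = _structure_doses(dose, mask)
    top = float(vals.max()) if max_gy is None else max_gy
    bins = np.arange(0.0, top + 2 * bin_gy, bin_gy)
    frac = (vals[None, :] >= bins[:, None]).mean(axis=1)
    return DVHCurve(bins, frac)


# ---------------------------------------------------------------------------
# DVH parameters and clinical goals


@dataclass(frozen=True)
class DVHParam:
    """One reportable DVH parameter of one structure.

    ``kind``: "dx" (Dx%, value = x), "vgy" (VxGy, value = threshold in Gy),
    "dcc" (D_cc, value = cc) or "mean".  ``role`` decides both the dose
    distribution the parameter is read from in a robust evaluation
    ("target" -> VWmin, "oar_max" -> VWmax, "oar_mean" -> nominal) and the
    worst-value sense (targets: lower is worse; OARs: higher is worse).
    """

    structure: str
    kind: str
    value: float | None
    role: str
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("dx", "vgy", "dcc", "mean"):
            raise ValueError(f"unknown DVH parameter kind {self.kind!r}")
        if self.role not in ("target", "oar_max", "oar_mean"):
            raise ValueError(f"unknown role {self.role!r}")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.kind == "dx":
            return f"D{self.value:g}%"
        if self.kind == "vgy":
            return f"V{self.value:g}Gy"
        if self.kind == "dcc":
            return f"D{self.value:g}cc"
        return "Dmean"

    @property
    def distribution(self) -> str:
        return {"target": "vwmin", "oar_max": "vwmax", "oar_mean": "nominal"}[self.role]

    @property
    def higher_is_better(self) -> bool:
        return self.role == "target"

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure, self.label)


def resolve_mask(structures: StructureSet, name: str) -> np.ndarray | None:
    """Resolve a structure name, deriving ``lungs_ex_gtv`` = lungs minus GTVp."""
    if name in structures:
        return structures[name]
    if name == "lungs_ex_gtv" and "lungs" in structures and "GTVp" in structures:
        return structures["lungs"] & ~structures["GTVp"]
    return None


def evaluate_param(dose: np.ndarray, structures: StructureSet, param: DVHParam) -> float:
    mask = resolve_mask(structures, param.structure)
    if mask is None:
        raise KeyError(f"structure {param.structure!r} not available")
    if param.kind == "dx":
        return dose_at_volume(dose, mask, param.value)
    if param.kind == "vgy":
        return volume_at_dose(dose, mask, param.value)
    if param.kind == "dcc":
        return near_max(dose, mask, structures.grid, param.value)
    return mean_dose(dose, mask)


def default_params(d_pres: float = 60.0) -> list[DVHParam]:
    """The standard reporting set for the lung phantom."""
    v95 = 0.95 * d_pres
    params = [
        DVHParam("CTVp", "dx", 95.0, "target"),
        DVHParam("CTVp", "vgy", v95, "target", label="V95%"),
        DVHParam("ITVp_02", "dx", 95.0, "target"),
        DVHParam("ITVp_02", "vgy", v95, "target", label="V95%"),
        DVHParam("heart", "dcc", 0.03, "oar_max"),
        DVHParam("esophagus", "dcc", 0.03, "oar_max"),
        DVHParam("MedEnv_05", "dcc", 0.03, "oar_max"),
        DVHParam("spinal_cord", "dcc", 0.03, "oar_max"),
        DVHParam("heart", "mean", None, "oar_mean"),
        DVHParam("esophagus", "mean", None, "oar_mean"),
        DVHParam("lungs_ex_gtv", "mean", None, "oar_mean"),
        DVHParam("lung_contra", "vgy", 5.0, "oar_mean", label="V5Gy"),
    ]
    return params


@dataclass(frozen=True)
class Goal:
    """One clinical constraint on a DVH parameter."""

    param: DVHParam
    limit: float
    comparator: str  # ">" or "<"
    hard: bool = True

    def __post_init__(self):
        if self.comparator not in (">", "<"):
            raise ValueError("comparator must be '>' or '<'")

    def check(self, value: float) -> bool:
        return value > self.limit if self.comparator == ">" else value < self.limit


@dataclass(frozen=True)
class GoalResult:
    """Outcome of one clinical goal on one robust dose."""

    structure: str
    parameter: str
    dose_distribution_used: str
    value: float | None
    limit: float
    comparator: str
    hard: bool
    passed: bool | None  # None when the structure is not available

    @property
    def evaluable(self) -> bool:
        return self.passed is not None


def default_goals(d_pres: float = 60.0,
                  target_names: tuple[str, ...] = ("ITVp_02",)) -> list[Goal]:
    """The clinical constraint set for proton lung plans.

    Targets: D95% > 95% of the prescription and V95% > 95% on VWmin.
    OARs: D0.03cc < 76 Gy for heart, esophagus and MedEnv_05 and < 54 Gy
    for spinal cord on VWmax; V5Gy < 60% for the contralateral lung and
    mean < 20 Gy for total lung minus GTV on the nominal dose; preferred
    (soft) mean-dose goals of 10 Gy for heart and 26 Gy for esophagus.
    """
    v95 = 0.95 * d_pres
    goals: list[Goal] = []
    for name in target_names:
        goals.append(Goal(DVHParam(name, "dx", 95.0, "target"), v95, ">"))
        goals.append(Goal(DVHParam(name, "vgy", v95, "target", label="V95%"), 95.0, ">"))
    for name in ("heart", "esophagus", "MedEnv_05"):
        goals.append(Goal(DVHParam(name, "dcc", 0.03, "oar_max"), 76.0, "<"))
    goals.append(Goal(DVHParam("spinal_cord", "dcc", 0.03, "oar_max"), 54.0, "<"))
    goals.append(Goal(DVHParam("lung_contra", "vgy", 5.0, "oar_mean", label="V5Gy"), 60.0, "<"))
    goals.append(Goal(DVHParam("lungs_ex_gtv", "mean", None, "oar_mean"), 20.0, "<"))
    goals.append(Goal(DVHParam("heart", "mean", None, "oar_mean"), 10.0, "<", hard=False))
    goals.append(Goal(DVHParam("esophagus", "mean", None, "oar_mean"), 26.0, "<", hard=False))
    return goals


def check_clinical_goals(robust, structures: StructureSet,
                         goals: list[Goal] | None = None,
                         d_pres: float = 60.0) -> list[GoalResult]:
    """Check every goal on the distribution its role dictates.

    ``robust`` is any object with ``nominal``, ``vwmin`` and ``vwmax``
    dose volumes.  A goal whose structure is missing is reported as
    not-evaluable (``passed is None``), never as a pass.
    """
    if goals is None:
        goals = default_goals(d_pres)
    dists = {
        "vwmin": robust.vwmin.values,
        "vwmax": robust.vwmax.values,
        "nominal": robust.nominal.values,
    }
    results = []
    for goal in goals:
        p = goal.param
        dose = dists[p.distribution]
        mask = resolve_mask(structures, p.structure)
        if mask is None or not mask.any():
            results.append(GoalResult(p.structure, p.label, p.distribution, None,
                                      goal.limit, goal.comparator, goal.hard, None))
            continue
        value = evaluate_param(dose, structures, p)
        results.append(GoalResult(p.structure, p.label, p.distribution, value,
                                  goal.limit, goal.comparator, goal.hard,
                                  goal.check(value)))
    return results


def hard_failures(results: list[GoalResult]) -> list[GoalResult]:
    return [r for r in results if r.hard and r.passed is False]
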