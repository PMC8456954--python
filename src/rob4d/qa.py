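"""Safety checks for deformable dose accumulation.

Two checks guard the phase-averaged robust evaluation:

* the dose-deformation DVH check compares DVH parameters extracted
  before warping (phase dose, phase contours) and after warping
  (warped dose, reference contours) for every scenario and every
  non-reference phase, flagging clinically relevant differences;
* the containment check verifies that the unadjusted per-phase CTV
  contours lie inside the expanded ITV, which must hold if the contour
  propagation underlying the ITV is sound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dvh import DVHParam, evaluate_param
from .structures import StructureSet

log = logging.getLogger(__name__)

DEFAULT_RELEVANCE_GY = 1.0  # dose differences above this are clinically relevant
DEFAULT_NOTIFY_FRACTION = 0.02  # user notification threshold, fraction of D_pres


def default_qa_params() -> list[DVHParam]:
    return [
        DVHParam("CTVp", "dx", 95.0, "target"),
        DVHParam("heart", "dcc", 0.03, "oar_max"),
        DVHParam("esophagus", "dcc", 0.03, "oar_max"),
        DVHParam("spinal_cord", "dcc", 0.03, "oar_max"),
    ]


@dataclass
class DeformationReport:
    """Per phase/scenario/parameter DVH differences before vs after warping."""

    table: pd.DataFrame = field(repr=False)
    relevance_gy: float
    notify_gy: float
    d_pres: float

    def __post_init__(self):
        if (self.table["diff"] < 0).any():
            raise ValueError("differences must be absolute values")

    @property
    def n_phases(self) -> int:
        return self.table["phase"].nunique()

    @property
    def n_scenarios(self) -> int:
        return self.table["scenario"].nunique()

    def per_phase_summary(self) -> pd.DataFrame:
        """Mean and max difference over scenarios, per phase and parameter."""
        return (
            self.table.groupby(["phase", "structure", "parameter"])["diff"]
            .agg(["mean", "max"])
            .reset_index()
        )

    def max_diff(self, structure: str | None = None, parameter: str | None = None) -> float:
        t = self.table
        if structure is not None:
            t = t[t["structure"] == structure]
        if parameter is not None:
            t = t[t["parameter"] == parameter]
        return float(t["diff"].max())

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flag_relevance"]]

    @property
    def notifications(self) -> pd.DataFrame:
        return self.table[self.table["notify"]]

    @property
    def notify_user(self) -> bool:
        """True when any CTV parameter differs by more than the 2%-of-D_pres bound."""
        return bool(self.table["notify"].any())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class DeformationAccumulator:
    """Collects before/after DVH values while an evaluation loop runs.

    ``add`` is called once per (non-reference phase, scenario) with the
    phase dose and its warped counterpart; ``report`` assembles the
    DeformationReport.  The notification flag applies to CTV structures
    only, mirroring the clinical rule.
    """

    def __init__(self, params: list[DVHParam],
                 structures_by_phase: dict[str, StructureSet],
                 reference_label: str,
                 d_pres: float,
                 relevance_gy: float = DEFAULT_RELEVANCE_GY,
                 notify_fraction: float = DEFAULT_NOTIFY_FRACTION):
        self.params = params
        self.structs = structures_by_phase
        self.ref = reference_label
        self.d_pres = d_pres
        self.relevance_gy = relevance_gy
        self.notify_gy = notify_fraction * d_pres
        self.rows: list[dict] = []

    def add(self, phase: str, scenario_label: str,
            dose_on_phase: np.ndarray, dose_warped: np.ndarray) -> None:
        if phase == self.ref:
            raise ValueError("the reference phase is not part of the deformation check")
        for p in self.params:
            before = evaluate_param(dose_on_phase, self.structs[phase], p)
            after = evaluate_param(dose_warped, self.structs[self.ref], p)
            diff = abs(before - after)
            self.rows.append(
                {
                    "phase": phase,
                    "scenario": scenario_label,
                    "structure": p.structure,
                    "parameter": p.label,
                    "before": before,
                    "after": after,
                    "diff": diff,
                    "flag_relevance": diff > self.relevance_gy,
                    "notify": p.structure.startswith("CTV") and diff > self.notify_gy,
                }
            )

    def report(self) -> DeformationReport:
        if not self.rows:
            raise ValueError("no deformation entries accumulated")
        return DeformationReport(pd.DataFrame(self.rows), self.relevance_gy,
                                 self.notify_gy, self.d_pres)


def deformation_dvh_check(doses_on_phase: dict[str, dict[str, np.ndarray]],
                          warped_doses: dict[str, dict[str, np.ndarray]],
                          contours_phase: dict[str, StructureSet],
                          contours_reference: StructureSet,
                          d_pres: float,
                          params: list[DVHParam] | None = None,
                          relevance_gy: float = DEFAULT_RELEVANCE_GY,
                          notify_fraction: float = DEFAULT_NOTIFY_FRACTION,
                          reference_label: str = "CT50ex") -> DeformationReport:
    """DVH consistency of dose deformation, from materialized dose sets.

    ``doses_on_phase[phase][scenario]`` holds the dose computed on that
    phase, ``warped_doses`` the same dose after warping to the reference;
    parameters are extracted with the phase contours before and with the
    reference contours after.
    """
    if params is None:
        params = default_qa_params()
    structs = dict(contours_phase)
    structs[reference_label] = contours_reference
    acc = DeformationAccumulator(params, structs, reference_label, d_pres,
                                 relevance_gy, notify_fraction)
    for phase, per_scen in doses_on_phase.items():
        for scen_label, dose in per_scen.items():
            try:
                warped = warped_doses[phase][scen_label]
            except KeyError:
                raise ValueError(f"missing warped dose for {phase}/{scen_label}") from None
            d0 = dose.values if hasattr(dose, "values") else np.asarray(dose)
            d1 = warped.values if hasattr(warped, "values") else np.asarray(warped)
            acc.add(phase, scen_label, d0, d1)
    return acc.report()


@dataclass(frozen=True)
class ContainmentResult:
    """Outcome of the CTV-within-expanded-ITV check."""

    contained: dict[str, bool]
    violating_voxels: dict[str, int]
    violating_indices: dict[str, np.ndarray] = field(repr=False, default=None)

    @property
    def all_contained(self) -> bool:
        return all(self.contained.values())


def containment_check(unadjusted_ctv_masks: dict[str, np.ndarray],
                      itv_02_mask: np.ndarray) -> ContainmentResult:
    """Verify every unadjusted per-phase CTV voxel lies inside the expanded ITV.

    Reports, per phase, whether containment holds and the count and
    indices of violating voxels.  An empty CTV is vacuously contained
    (with a warning).
    """
    itv = np.asarray(itv_02_mask, dtype=bool)
    contained, counts, indices = {}, {}, {}
    for phase, ctv in unadjusted_ctv_masks.items():
        ctv = np.asarray(ctv, dtype=bool)
        if ctv.shape != itv.shape:
            raise ValueError(f"phase {phase!r}: CTV and ITV grids differ")
        if not ctv.any():
            log.warning("containment_check: empty CTV on phase %s", phase)
        outside = ctv & ~itv
        n = int(outside.sum())
        contained[phase] = n == 0
        counts[phase] = n
        indices[phase] = np.argwhere(outside)
    return ContainmentResult(contained, counts, indices)
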