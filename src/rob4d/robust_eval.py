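"""Robust dose-evaluation strategies for moving targets.

Four strategies are implemented against one fixed plan:

* 3D robust evaluation: voxel-wise minimum/maximum (VWmin/VWmax) over the
  28 error scenarios computed on the planning (average) CT;
* 4DNom: the nominal dose recomputed on each breathing phase, reporting
  the worst per-phase value of each DVH parameter;
* 4DRobInd: an independent 3D robust evaluation per phase (eight VWmin
  and eight VWmax grids), reporting the phase mean of each parameter;
* 4DRobAvg: for every scenario the per-phase doses are warped to the
  reference phase and combined into a breathing-weighted sum; VWmin and
  VWmax are then taken over the 28 weighted sums.  Averaging over the
  breathing cycle *before* the voxel-wise extrema keeps systematic-error
  semantics (range and setup errors persist across one fraction while
  the tumor breathes through all phases) and avoids the over-conservatism
  of per-phase envelopes.

All strategies evaluate the same plan with one normalization; per-phase
DVH parameters use the contours of that phase, weighted sums use the
reference-phase contours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_engine import DoseGrid, Plan, compute_dose
from .dvh import DVHParam, default_params, evaluate_param
from .grid import Volume, require_same_grid
from .phantom4d import Series4D, WeightScheme
from .qa import DeformationAccumulator, DeformationReport, default_qa_params
from .scenarios import NOMINAL, Scenario
from .structures import StructureSet
from .warp import warp_dose

log = logging.getLogger(__name__)


@dataclass
class RobustDose:
    """Nominal dose plus the voxel-wise scenario envelope.

    The envelope is clamped to include the nominal member, so
    ``vwmin <= nominal <= vwmax`` holds voxel-wise by construction;
    ``scenario_count`` counts the error scenarios entering the envelope
    (the nominal case is not one of them).
    """

    nominal: DoseGrid
    vwmin: DoseGrid
    vwmax: DoseGrid
    scenario_count: int

    def __post_init__(self):
        require_same_grid(self.nominal.grid, self.vwmin.grid, self.vwmax.grid)
        np.minimum(self.vwmin.values, self.nominal.values, out=self.vwmin.values)
        np.maximum(self.vwmax.values, self.nominal.values, out=self.vwmax.values)


@dataclass
class EvalResult:
    """Outcome of one evaluation strategy.

    ``per_phase`` holds the raw per-phase parameter values (empty for the
    strategies that do not loop over phases), ``aggregated`` the reported
    value per (structure, parameter) with the strategy's aggregation rule
    (worst over phases for 4DNom, mean over phases for 4DRobInd, none
    otherwise).
    """

    strategy: str
    aggregation: str | None
    per_phase: pd.DataFrame = field(repr=False)
    aggregated: pd.DataFrame = field(repr=False)
    robust_dose: RobustDose | None = None
    robust_doses_by_phase: dict[str, RobustDose] | None = None
    nominal_doses_by_phase: dict[str, DoseGrid] | None = None
    qa_report: DeformationReport | None = None
    weight_scheme: str | None = None

    def value(self, structure: str, parameter: str) -> float:
        t = self.aggregated
        row = t[(t["structure"] == structure) & (t["parameter"] == parameter)]
        if len(row) != 1:
            raise KeyError(f"no unique aggregated value for {structure}/{parameter}")
        return float(row["value"].iloc[0])


def voxelwise_min_max(doses: list[DoseGrid]) -> tuple[Volume, Volume]:
    """Per-voxel minimum and maximum across a list of dose grids."""
    if not doses:
        raise ValueError("need at least one dose grid")
    grid = require_same_grid(*[d.grid for d in doses])
    stack_min = doses[0].values.copy()
    stack_max = doses[0].values.copy()
    for d in doses[1:]:
        np.minimum(stack_min, d.values, out=stack_min)
        np.maximum(stack_max, d.values, out=stack_max)
    return Volume(stack_min, grid), Volume(stack_max, grid)


def _scenario_envelope(plan: Plan, density: Volume,
                       scenario_set: list[Scenario]) -> tuple[Volume, Volume]:
    """Streamed VWmin/VWmax over a scenario set on one density image."""
    if not scenario_set:
        raise ValueError("empty scenario set")
    vmin = vmax = None
    for scen in scenario_set:
        d = compute_dose(plan, density, scen).values
        if vmin is None:
            vmin, vmax = d.copy(), d.copy()
        else:
            np.minimum(vmin, d, out=vmin)
            np.maximum(vmax, d, out=vmax)
    return Volume(vmin, density.grid), Volume(vmax, density.grid)


def eval_3d_robust(plan: Plan, planning_ct: Volume, structures: StructureSet,
                   scenario_set: list[Scenario]) -> RobustDose:
    """Robust evaluation on the planning CT: nominal plus scenario envelope."""
    nominal = compute_dose(plan, planning_ct, NOMINAL)
    vwmin, vwmax = _scenario_envelope(plan, planning_ct, scenario_set)
    return RobustDose(nominal, vwmin, vwmax, len(scenario_set))


def extract_params(robust: RobustDose, structures: StructureSet,
                   params: list[DVHParam]) -> pd.DataFrame:
    """Read each parameter from the distribution its role dictates."""
    dists = {"vwmin": robust.vwmin, "vwmax": robust.vwmax, "nominal": robust.nominal}
    rows = []
    for p in params:
        rows.append(
            {
                "structure": p.structure,
                "parameter": p.label,
                "distribution": p.distribution,
                "value": evaluate_param(dists[p.distribution].values, structures, p),
            }
        )
    return pd.DataFrame(rows)


def _aggregate(per_phase: pd.DataFrame, params: list[DVHParam], rule: str) -> pd.DataFrame:
    rows = []
    for p in params:
        sel = per_phase[
            (per_phase["structure"] == p.structure) & (per_phase["parameter"] == p.label)
        ]["value"]
        if rule == "worst":
            value = sel.min() if p.higher_is_better else sel.max()
        elif rule == "mean":
            value = sel.mean()
        else:
            raise ValueError(f"unknown aggregation rule {rule!r}")
        rows.append(
            {
                "structure": p.structure,
                "parameter": p.label,
                "value": float(value),
                "rule": rule,
            }
        )
    return pd.DataFrame(rows)


def eval_4d_nom(plan: Plan, series: Series4D,
                structures_by_phase: dict[str, StructureSet],
                params: list[DVHParam] | None = None) -> EvalResult:
    """4D nominal evaluation: recompute the nominal dose on every phase.

    Each parameter is read from the nominal phase dose with that phase's
    contours; the reported value is the worst over the eight phases
    (lowest target dose, highest OAR dose).
    """
    if params is None:
        params = default_params(plan.prescription_gy)
    rows = []
    doses = {}
    for lab in series.phase_labels:
        dose = compute_dose(plan, series.images[lab], NOMINAL)
        doses[lab] = dose
        for p in params:
            rows.append(
                {
                    "phase": lab,
                    "structure": p.structure,
                    "parameter": p.label,
                    "distribution": "nominal",
                    "value": evaluate_param(dose.values, structures_by_phase[lab], p),
                }
            )
    per_phase = pd.DataFrame(rows)
    return EvalResult(
        strategy="4dnom",
        aggregation="worst",
        per_phase=per_phase,
        aggregated=_aggregate(per_phase, params, "worst"),
        nominal_doses_by_phase=doses,
    )


def eval_4d_rob_ind(plan: Plan, series: Series4D,
                    structures_by_phase: dict[str, StructureSet],
                    scenario_set: list[Scenario],
                    params: list[DVHParam] | None = None) -> EvalResult:
    """4D robust individual-phase evaluation.

    A full 3D robust evaluation per phase (eight VWmin and eight VWmax
    grids); the reported value of each parameter is the arithmetic mean
    over the eight per-phase values.
    """
    if params is None:
        params = default_params(plan.prescription_gy)
    rows = []
    robust_by_phase = {}
    for lab in series.phase_labels:
        robust = eval_3d_robust(plan, series.images[lab], structures_by_phase[lab],
                                scenario_set)
        robust_by_phase[lab] = robust
        t = extract_params(robust, structures_by_phase[lab], params)
        t.insert(0, "phase", lab)
        rows.append(t)
    per_phase = pd.concat(rows, ignore_index=True)
    return EvalResult(
        strategy="4drobind",
        aggregation="mean",
        per_phase=per_phase,
        aggregated=_aggregate(per_phase, params, "mean"),
        robust_doses_by_phase=robust_by_phase,
    )


def _weighted_sum_eval(plan: Plan, series: Series4D,
                       structures_by_phase: dict[str, StructureSet],
                       scenario_set: list[Scenario],
                       schemes: dict[str, WeightScheme],
                       params: list[DVHParam],
                       qa_params: list[DVHParam] | None,
                       qa_relevance_gy: float,
                       qa_notify_fraction: float) -> dict[str, EvalResult]:
    """Shared phase-averaged evaluation loop for one or more weight schemes.

    For every scenario (and the nominal case) the dose is computed on each
    phase, warped to the reference and accumulated into one weighted sum
    per scheme; the scenario envelope is then streamed per scheme.  The
    optional deformation QA accumulates before/after DVH parameters for
    the 28 + 1 scenarios on each non-reference phase while the loop runs.
    """
    labels = series.phase_labels
    ref = series.reference_label
    grid = series.grid
    weights = {name: ws.as_array(labels) for name, ws in schemes.items()}

    acc = None
    if qa_params is not None:
        acc = DeformationAccumulator(qa_params, structures_by_phase, ref,
                                     plan.prescription_gy, qa_relevance_gy,
                                     qa_notify_fraction)

    def weighted_sums(scenario: Scenario) -> dict[str, np.ndarray]:
        sums = {name: np.zeros(grid.shape) for name in schemes}
        for i, lab in enumerate(labels):
            dose = compute_dose(plan, series.images[lab], scenario)
            warped = warp_dose(dose, series.dvfs_to_reference[lab])
            if acc is not None and lab != ref:
                acc.add(lab, scenario.label, dose.values, warped.values)
            for name, w in weights.items():
                if w[i] != 0.0:
                    sums[name] += w[i] * warped.values
        return sums

    nominal_sums = weighted_sums(NOMINAL)
    vmin = {name: None for name in schemes}
    vmax = {name: None for name in schemes}
    for scen in scenario_set:
        sums = weighted_sums(scen)
        for name, s in sums.items():
            if vmin[name] is None:
                vmin[name], vmax[name] = s.copy(), s.copy()
            else:
                np.minimum(vmin[name], s, out=vmin[name])
                np.maximum(vmax[name], s, out=vmax[name])

    results = {}
    ref_structs = structures_by_phase[ref]
    for name in schemes:
        robust = RobustDose(
            Volume(nominal_sums[name], grid),
            Volume(vmin[name], grid),
            Volume(vmax[name], grid),
            len(scenario_set),
        )
        table = extract_params(robust, ref_structs, params)
        results[name] = EvalResult(
            strategy="4drobavg",
            aggregation=None,
            per_phase=pd.DataFrame(),
            aggregated=table.rename(columns={}).assign(rule="weighted_sum"),
            robust_dose=robust,
            qa_report=acc.report() if acc is not None else None,
            weight_scheme=name,
        )
    return results


def eval_4d_rob_avg(plan: Plan, series: Series4D,
                    structures_by_phase: dict[str, StructureSet],
                    scenario_set: list[Scenario],
                    weights: WeightScheme,
                    params: list[DVHParam] | None = None,
                    qa: bool = False,
                    qa_params: list[DVHParam] | None = None,
                    qa_relevance_gy: float = 1.0,
                    qa_notify_fraction: float = 0.02) -> EvalResult:
    """4D robust phase-averaged evaluation.

    Per scenario: compute the dose on each phase, warp it to the reference
    phase and form the breathing-weighted sum; then take VWmin/VWmax over
    the weighted scenario sums.  Together with the weighted nominal sum
    the strategy outputs exactly three dose distributions.  DVH parameters
    are extracted with the reference-phase contours.  With ``qa=True`` the
    dose-deformation DVH check runs inline over all 29 cases (28 scenarios
    plus nominal) on the seven non-reference phases.
    """
    if params is None:
        params = default_params(plan.prescription_gy)
    missing = [lab for lab in series.phase_labels
               if lab not in series.dvfs_to_reference]
    if missing:
        raise ValueError(f"missing DVFs for phases {missing}")
    if set(weights.weights) != set(series.phase_labels):
        raise ValueError("weight scheme does not match the series phase labels")
    if qa and qa_params is None:
        qa_params = default_qa_params()
    results = _weighted_sum_eval(
        plan, series, structures_by_phase, scenario_set,
        {weights.pattern_name: weights}, params,
        qa_params if qa else None, qa_relevance_gy, qa_notify_fraction,
    )
    return results[weights.pattern_name]


def compare_weight_schemes(plan: Plan, series: Series4D,
                           structures_by_phase: dict[str, StructureSet],
                           scenario_set: list[Scenario],
                           schemes: list[WeightScheme],
                           params: list[DVHParam] | None = None) -> pd.DataFrame:
    """DVH-parameter differences between the equal scheme and alternatives.

    Runs the phase-averaged evaluation once per scheme (sharing the
    per-phase dose computations and warps) and tabulates, per structure
    and parameter, the difference alternative minus equal.
    """
    if params is None:
        params = default_params(plan.prescription_gy)
    by_name = {ws.pattern_name: ws for ws in schemes}
    if "equal" not in by_name:
        raise ValueError("the comparison requires the equal-weight scheme")
    if len(by_name) < 2:
        raise ValueError("need at least two weight schemes")
    results = _weighted_sum_eval(plan, series, structures_by_phase, scenario_set,
                                 by_name, params, None, 1.0, 0.02)
    base = results["equal"].aggregated.set_index(["structure", "parameter"])["value"]
    rows = []
    for name, res in results.items():
        if name == "equal":
            continue
        alt = res.aggregated.set_index(["structure", "parameter"])["value"]
        for (structure, parameter), v in alt.items():
            rows.append(
                {
                    "scheme": name,
                    "structure": structure,
                    "parameter": parameter,
                    "equal": float(base.loc[(structure, parameter)]),
                    "alternative": float(v),
                    "delta": float(v - base.loc[(structure, parameter)]),
                }
            )
    return pd.DataFrame(rows)
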