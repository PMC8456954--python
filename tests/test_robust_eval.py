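"""Evaluation strategies: envelopes, aggregation rules, strategy relations."""

import numpy as np
import pandas as pd
import pytest

from rob4d import (
    PHASE_LABELS,
    PhantomSpec,
    PlanSpec,
    Volume,
    WeightScheme,
    average_ct,
    breathing_weights,
    build_phantom,
    compare_weight_schemes,
    default_beams,
    eval_3d_robust,
    eval_4d_rob_avg,
    make_plan,
    voxelwise_min_max,
    warp_dose,
)
from rob4d.dvh import DVHParam
from rob4d.robust_eval import _aggregate
from rob4d.scenarios import NOMINAL, Scenario

from . import oracles
from .fixtures import make_fixture


class TestVoxelwiseMinMax:
    def test_single_dose(self, rng):
        fx = make_fixture("two_constant_doses")
        d = fx.inputs["doses"][0]
        vmin, vmax = voxelwise_min_max([d])
        assert np.array_equal(vmin.values, d.values)
        assert np.array_equal(vmax.values, d.values)

    def test_constant_fields(self):
        fx = make_fixture("two_constant_doses")
        vmin, vmax = voxelwise_min_max(fx.inputs["doses"])
        assert (vmin.values == fx.expected["vwmin"]).all()
        assert (vmax.values == fx.expected["vwmax"]).all()

    def test_28_random_grids_match_brute_force(self, rng):
        from rob4d import centered_grid

        grid = centered_grid((7, 6, 5), (2.0, 2.0, 2.0))
        doses = [Volume(rng.random(grid.shape), grid) for _ in range(28)]
        vmin, vmax = voxelwise_min_max(doses)
        bmin, bmax = oracles.brute_voxelwise_min_max([d.values for d in doses])
        assert np.array_equal(vmin.values, bmin)
        assert np.array_equal(vmax.values, bmax)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            voxelwise_min_max([])


class TestEval3dRobust:
    def test_scenario_count_recorded(self, robust3d_moving):
        assert robust3d_moving.scenario_count == 28

    def test_degenerate_scenarios_collapse_to_nominal(self, coarse_case):
        zeros = [Scenario((0.0, 0.0, 0.0), 1.0, f"z{i}") for i in range(3)]
        robust = eval_3d_robust(coarse_case.plan, coarse_case.avg_ct,
                                coarse_case.structs[coarse_case.ref], zeros)
        assert np.array_equal(robust.vwmin.values, robust.nominal.values)
        assert np.array_equal(robust.vwmax.values, robust.nominal.values)

    def test_acceptable_plan_meets_target_constraint_on_vwmin(self, robust3d_moving,
                                                              moving_case):
        from rob4d.dvh import dose_at_volume

        target = moving_case.structs[moving_case.ref]["ITVp_02"]
        assert dose_at_volume(robust3d_moving.vwmin.values, target, 95.0) >= 57.0

    def test_envelope_brackets_nominal(self, robust3d_moving):
        assert (robust3d_moving.vwmin.values <= robust3d_moving.nominal.values).all()
        assert (robust3d_moving.nominal.values <= robust3d_moving.vwmax.values).all()


class TestEval4dNom:
    def test_static_phase_doses_equal_reference_nominal(self, static_case):
        from rob4d import eval_4d_nom
        from rob4d.dose_engine import compute_dose

        res = eval_4d_nom(static_case.plan, static_case.series, static_case.structs)
        ref_dose = compute_dose(static_case.plan,
                                static_case.series.images[static_case.ref], NOMINAL)
        for lab in PHASE_LABELS:
            assert np.abs(res.nominal_doses_by_phase[lab].values
                          - ref_dose.values).max() < 1e-9

    def test_worst_value_rule(self, nom4d_moving):
        per = nom4d_moving.per_phase
        d95 = per[(per.structure == "CTVp") & (per.parameter == "D95%")]["value"]
        assert nom4d_moving.value("CTVp", "D95%") == pytest.approx(d95.min())
        hmax = per[(per.structure == "heart") & (per.parameter == "D0.03cc")]["value"]
        assert nom4d_moving.value("heart", "D0.03cc") == pytest.approx(hmax.max())

    def test_constructed_underdosed_phase_sets_the_report(self):
        params = [DVHParam("CTVp", "dx", 95.0, "target")]
        rows = [{"phase": f"p{i}", "structure": "CTVp", "parameter": "D95%",
                 "value": 60.0 - (5.0 if i == 3 else 0.0)} for i in range(8)]
        agg = _aggregate(pd.DataFrame(rows), params, "worst")
        assert agg["value"].iloc[0] == 55.0


class TestEval4dRobInd:
    def test_eight_vwmin_and_eight_vwmax_grids(self, robind_moving):
        assert len(robind_moving.robust_doses_by_phase) == 8
        for rd in robind_moving.robust_doses_by_phase.values():
            assert rd.vwmin is not None and rd.vwmax is not None

    def test_mean_value_rule(self, robind_moving):
        per = robind_moving.per_phase
        sel = per[(per.structure == "CTVp") & (per.parameter == "D95%")]["value"]
        assert robind_moving.value("CTVp", "D95%") == pytest.approx(sel.mean())

    def test_static_per_phase_equals_3d_robust(self, static_case, robust3d_static,
                                               scens28):
        from rob4d import eval_4d_rob_ind

        res = eval_4d_rob_ind(static_case.plan, static_case.series,
                              static_case.structs, scens28)
        for rd in res.robust_doses_by_phase.values():
            assert np.abs(rd.vwmin.values - robust3d_static.vwmin.values).max() < 1e-9


class TestEval4dRobAvg:
    def test_static_equals_3d_robust_voxelwise(self, robavg_static, robust3d_static):
        rd = robavg_static.robust_dose
        assert np.abs(rd.nominal.values - robust3d_static.nominal.values).max() < 1e-9
        assert np.abs(rd.vwmin.values - robust3d_static.vwmin.values).max() < 1e-9
        assert np.abs(rd.vwmax.values - robust3d_static.vwmax.values).max() < 1e-9

    def test_weights_concentrated_on_reference_reproduce_its_3d_eval(self, moving_case,
                                                                     scens28):
        one_hot = {lab: (1.0 if lab == moving_case.ref else 0.0) for lab in PHASE_LABELS}
        res = eval_4d_rob_avg(moving_case.plan, moving_case.series, moving_case.structs,
                              scens28, WeightScheme(one_hot, "ref_only"))
        direct = eval_3d_robust(moving_case.plan,
                                moving_case.series.images[moving_case.ref],
                                moving_case.structs[moving_case.ref], scens28)
        assert np.abs(res.robust_dose.vwmin.values - direct.vwmin.values).max() < 1e-12

    def test_phase_averaging_dominates_phase_envelope_average(self, robavg_moving,
                                                              robind_moving,
                                                              moving_case):
        """min over scenarios of the weighted sum >= weighted sum of per-phase minima."""
        w = breathing_weights("equal").as_array(PHASE_LABELS)
        acc = np.zeros(moving_case.series.grid.shape)
        for wi, lab in zip(w, PHASE_LABELS):
            warped = warp_dose(robind_moving.robust_doses_by_phase[lab].vwmin,
                               moving_case.series.dvfs_to_reference[lab])
            acc += wi * warped.values
        assert (robavg_moving.robust_dose.vwmin.values >= acc - 1e-9).all()

    def test_exactly_three_output_distributions(self, robavg_moving):
        rd = robavg_moving.robust_dose
        assert rd.nominal is not None and rd.vwmin is not None and rd.vwmax is not None
        assert robavg_moving.robust_doses_by_phase is None

    def test_mismatched_weights_rejected(self, coarse_case, scens28):
        bad = WeightScheme({lab: 0.125 for lab in PHASE_LABELS}, "equal")
        object.__setattr__(bad, "weights", {"wrong": 1.0})
        with pytest.raises(ValueError, match="phase labels"):
            eval_4d_rob_avg(coarse_case.plan, coarse_case.series, coarse_case.structs,
                            scens28, bad)


class TestCompareWeightSchemes:
    def test_identical_schemes_give_zero_deltas(self, coarse_case, scens28):
        equal = breathing_weights("equal")
        clone = WeightScheme(dict(equal.weights), "equal_clone")
        table = compare_weight_schemes(coarse_case.plan, coarse_case.series,
                                       coarse_case.structs, scens28, [equal, clone])
        assert np.allclose(table["delta"], 0.0, atol=1e-9)

    def test_zero_motion_gives_zero_deltas(self, scens28):
        spec = PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(4.0, 4.0, 4.0),
                           amplitude_mm=0.0)
        series, structs, _ = build_phantom(spec)
        ref = series.reference_label
        avg = average_ct(series)
        plan = make_plan(PlanSpec(default_beams()), avg, structs[ref])
        table = compare_weight_schemes(plan, series, structs, scens28,
                                       [breathing_weights("equal"),
                                        breathing_weights("cos4")])
        assert np.allclose(table["delta"], 0.0, atol=1e-9)

    def test_cos4_delta_grows_with_amplitude(self, scens28):
        deltas = []
        for amp in (8.0, 16.0, 24.0):
            spec = PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(4.0, 4.0, 4.0),
                               amplitude_mm=amp)
            series, structs, _ = build_phantom(spec)
            ref = series.reference_label
            plan = make_plan(PlanSpec(default_beams()), average_ct(series), structs[ref])
            table = compare_weight_schemes(plan, series, structs, scens28,
                                           [breathing_weights("equal"),
                                            breathing_weights("cos4")])
            row = table[(table.structure == "CTVp") & (table.parameter == "D95%")]
            deltas.append(abs(float(row["delta"].iloc[0])))
        assert deltas[-1] > deltas[0]
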