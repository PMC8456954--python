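"""DVH metrics against brute-force oracles; clinical-goal logic."""

from types import SimpleNamespace

import numpy as np
import pytest

from rob4d import (
    DVHParam,
    Goal,
    StructureSet,
    Volume,
    centered_grid,
    check_clinical_goals,
    dose_at_volume,
    mean_dose,
    near_max,
    volume_at_dose,
)
from rob4d.dvh import default_goals, dvh_curve, hard_failures

from . import oracles
from .fixtures import make_fixture


@pytest.fixture()
def grid3mm():
    return centered_grid((10, 10, 10), (3.0, 3.0, 3.0))


class TestDoseAtVolume:
    def test_uniform_dose(self, grid3mm):
        mask = np.ones(grid3mm.shape, bool)
        assert dose_at_volume(np.full(grid3mm.shape, 60.0), mask, 95.0) == 60.0

    def test_hand_sorted_split(self):
        dose = np.concatenate([np.full(95, 60.0), np.full(5, 30.0)]).reshape(10, 10, 1)
        mask = np.ones_like(dose, bool)
        assert dose_at_volume(dose, mask, 95.0) == 60.0
        assert dose_at_volume(dose, mask, 96.0) == 30.0

    def test_d100_is_the_minimum(self, rng):
        dose = rng.random((6, 6, 6)) * 70
        mask = rng.random((6, 6, 6)) < 0.5
        mask.flat[0] = True
        assert dose_at_volume(dose, mask, 100.0) == dose[mask].min()

    def test_nonincreasing_in_volume_fraction(self, rng):
        dose = rng.random((8, 8, 8)) * 70
        mask = np.ones((8, 8, 8), bool)
        vals = [dose_at_volume(dose, mask, p) for p in (5, 25, 50, 75, 95, 100)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dose_at_volume(np.ones((2, 2, 2)), np.ones((2, 2, 2), bool), 0.0)
        with pytest.raises(ValueError, match="empty"):
            dose_at_volume(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), 95.0)


class TestVolumeAtDose:
    def test_uniform_and_zero_threshold(self):
        dose = np.full((4, 4, 4), 60.0)
        mask = np.ones_like(dose, bool)
        assert volume_at_dose(dose, mask, 57.0) == 100.0
        assert volume_at_dose(dose, mask, 0.0) == 100.0

    def test_half_and_half(self):
        dose = np.concatenate([np.full(32, 10.0), np.zeros(32)]).reshape(4, 4, 4)
        mask = np.ones_like(dose, bool)
        assert volume_at_dose(dose, mask, 5.0) == 50.0

    def test_nonincreasing_in_threshold(self, rng):
        dose = rng.random((6, 6, 6)) * 70
        mask = np.ones((6, 6, 6), bool)
        vals = [volume_at_dose(dose, mask, t) for t in (0, 10, 30, 50, 69)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))


class TestNearMax:
    def test_hand_accumulation_3mm_voxels(self, grid3mm):
        # voxel volume 0.027 cc: the cumulative volume reaches 0.03 cc at
        # the second-hottest voxel
        dose = np.zeros(grid3mm.shape)
        dose[0, 0, 0], dose[0, 0, 1] = 70.0, 65.0
        mask = np.ones(grid3mm.shape, bool)
        assert near_max(dose, mask, grid3mm, cc=0.03) == 65.0

    def test_uniform_dose(self, grid3mm):
        mask = np.ones(grid3mm.shape, bool)
        assert near_max(np.full(grid3mm.shape, 48.0), mask, grid3mm) == 48.0

    def test_small_structure_warns_and_returns_minimum(self, grid3mm, caplog):
        dose = np.arange(1000.0).reshape(grid3mm.shape)
        mask = np.zeros(grid3mm.shape, bool)
        mask[0, 0, 0] = True
        with caplog.at_level("WARNING"):
            assert near_max(dose, mask, grid3mm, cc=0.05) == dose[0, 0, 0]
        assert "below requested" in caplog.text


class TestMeanDose:
    def test_two_voxel_average_and_scaling(self):
        dose = np.zeros((2, 2, 2))
        dose[0, 0, 0], dose[0, 0, 1] = 10.0, 20.0
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, :] = True
        assert mean_dose(dose, mask) == 15.0
        assert mean_dose(3.0 * dose, mask) == 45.0


@pytest.mark.parametrize("seed", range(10))
def test_all_metrics_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    grid = centered_grid((12, 12, 12), (3.0, 3.0, 3.0))
    dose = rng.uniform(0, 70, grid.shape)
    mask = rng.random(grid.shape) < 0.4
    mask.flat[0] = True
    pct = float(rng.uniform(5, 100))
    thr = float(rng.uniform(0, 70))
    assert dose_at_volume(dose, mask, pct) == oracles.brute_dose_at_volume(dose, mask, pct)
    assert volume_at_dose(dose, mask, thr) == oracles.brute_volume_at_dose(dose, mask, thr)
    assert near_max(dose, mask, grid, 0.03) == oracles.brute_near_max(dose, mask, grid, 0.03)
    assert mean_dose(dose, mask) == pytest.approx(float(dose[mask].mean()))


def test_frozen_random_field_fixture():
    fx = make_fixture("random_dose_field")
    dose, mask, grid = fx.inputs["dose"], fx.inputs["mask"], fx.inputs["grid"]
    assert dose_at_volume(dose, mask, 95.0) == fx.expected["d95"]
    assert volume_at_dose(dose, mask, 30.0) == fx.expected["v30"]
    assert near_max(dose, mask, grid, 0.03) == fx.expected["d003cc"]
    assert mean_dose(dose, mask) == pytest.approx(fx.expected["mean"])


def test_dvh_curve_monotone_and_dominated(rng):
    grid = centered_grid((8, 8, 8), (3.0, 3.0, 3.0))
    mask = np.ones(grid.shape, bool)
    low = rng.uniform(0, 40, grid.shape)
    high = low + rng.uniform(0, 20, grid.shape)
    c_low = dvh_curve(low, mask, max_gy=70.0)
    c_high = dvh_curve(high, mask, max_gy=70.0)
    assert (np.diff(c_low.cumulative_volume_fraction) <= 1e-12).all()
    assert (c_low.cumulative_volume_fraction <= c_high.cumulative_volume_fraction + 1e-12).all()


class TestClinicalGoals:
    def _robust(self, grid, nominal, vwmin, vwmax):
        return SimpleNamespace(nominal=Volume(nominal, grid),
                               vwmin=Volume(vwmin, grid),
                               vwmax=Volume(vwmax, grid))

    def test_target_underdose_fails_on_vwmin(self, grid3mm):
        target = np.zeros(grid3mm.shape, bool)
        target[3:7, 3:7, 3:7] = True
        structs = StructureSet(grid3mm, {"ITVp_02": target})
        robust = self._robust(grid3mm, np.full(grid3mm.shape, 60.0),
                              np.full(grid3mm.shape, 56.0),
                              np.full(grid3mm.shape, 62.0))
        goals = [Goal(DVHParam("ITVp_02", "dx", 95.0, "target"), 57.0, ">")]
        res = check_clinical_goals(robust, structs, goals)
        assert res[0].passed is False and res[0].value == 56.0
        assert res[0].dose_distribution_used == "vwmin"
        assert len(hard_failures(res)) == 1

    def test_distribution_rule_flips_asymmetric_case(self, grid3mm):
        """Targets read VWmin, OAR near-max goals read VWmax."""
        target = np.zeros(grid3mm.shape, bool)
        target[2:8, 2:8, 2:8] = True
        structs = StructureSet(grid3mm, {"ITVp_02": target, "heart": target.copy()})
        robust = self._robust(grid3mm, np.full(grid3mm.shape, 60.0),
                              np.full(grid3mm.shape, 50.0),
                              np.full(grid3mm.shape, 80.0))
        goals = [
            Goal(DVHParam("ITVp_02", "dx", 95.0, "target"), 57.0, ">"),
            Goal(DVHParam("heart", "dcc", 0.03, "oar_max"), 76.0, "<"),
        ]
        res = check_clinical_goals(robust, structs, goals)
        assert res[0].value == 50.0 and res[0].passed is False
        assert res[1].value == 80.0 and res[1].passed is False
        # swapping the distributions would have passed both
        assert 80.0 > 57.0 and 50.0 < 76.0

    def test_missing_structure_is_not_evaluable(self, grid3mm):
        structs = StructureSet(grid3mm, {})
        robust = self._robust(grid3mm, np.zeros(grid3mm.shape),
                              np.zeros(grid3mm.shape), np.zeros(grid3mm.shape))
        res = check_clinical_goals(robust, structs, default_goals(60.0))
        assert all(r.passed is None for r in res)
        assert not hard_failures(res)

    def test_phantom_oars_far_from_beams_pass(self, robust3d_moving, moving_case):
        structs = moving_case.structs[moving_case.ref]
        res = check_clinical_goals(robust3d_moving, structs, default_goals(60.0))
        oar = [r for r in res if r.structure != "ITVp_02"]
        assert oar and all(r.passed for r in oar)
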