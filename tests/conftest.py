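"""Shared fixtures: phantoms, plans and the heavy end-to-end evaluations.

The expensive evaluation runs (scenario loops over all phases) are
session-scoped so the acceptance tests and the unit tests share one
computation of each strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from rob4d import (
    PhantomSpec,
    PlanSpec,
    Series4D,
    average_ct,
    breathing_weights,
    build_phantom,
    default_beams,
    eval_3d_robust,
    eval_4d_nom,
    eval_4d_rob_avg,
    eval_4d_rob_ind,
    evaluation_scenarios,
    make_plan,
)
from rob4d.warp import DVF


@dataclass
class PhantomCase:
    spec: PhantomSpec
    series: Series4D
    structs: dict
    truth: object
    avg_ct: object
    plan: object

    @property
    def ref(self) -> str:
        return self.series.reference_label


def _build_case(spec: PhantomSpec) -> PhantomCase:
    series, structs, truth = build_phantom(spec)
    avg = average_ct(series)
    plan = make_plan(PlanSpec(default_beams()), avg, structs[series.reference_label])
    return PhantomCase(spec, series, structs, truth, avg, plan)


@pytest.fixture(scope="session")
def scens28():
    return evaluation_scenarios()


@pytest.fixture(scope="session")
def moving_case() -> PhantomCase:
    """The default moving phantom: 20 mm SI amplitude on a 64^3, 3 mm grid."""
    return _build_case(PhantomSpec())


@pytest.fixture(scope="session")
def static_case() -> PhantomCase:
    """Zero-amplitude phantom: all phases identical, all DVFs zero."""
    return _build_case(PhantomSpec(amplitude_mm=0.0))


@pytest.fixture(scope="session")
def coarse_case() -> PhantomCase:
    """Smaller, coarser phantom for fast end-to-end runs (48^3, 4 mm)."""
    return _build_case(PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(4.0, 4.0, 4.0),
                                   amplitude_mm=16.0))


@pytest.fixture(scope="session")
def robust3d_moving(moving_case, scens28):
    return eval_3d_robust(moving_case.plan, moving_case.avg_ct,
                          moving_case.structs[moving_case.ref], scens28)


@pytest.fixture(scope="session")
def nom4d_moving(moving_case):
    return eval_4d_nom(moving_case.plan, moving_case.series, moving_case.structs)


@pytest.fixture(scope="session")
def robind_moving(moving_case, scens28):
    return eval_4d_rob_ind(moving_case.plan, moving_case.series, moving_case.structs,
                           scens28)


@pytest.fixture(scope="session")
def robavg_moving(moving_case, scens28):
    return eval_4d_rob_avg(moving_case.plan, moving_case.series, moving_case.structs,
                           scens28, breathing_weights("equal"), qa=True)


@pytest.fixture(scope="session")
def robavg_biased_dvf(moving_case, scens28):
    """Phase-averaged evaluation with DVFs corrupted by a 5 mm SI bias."""
    case = moving_case
    dvfs = {}
    for lab, dvf in case.series.dvfs_to_reference.items():
        if lab == case.ref:
            dvfs[lab] = dvf
        else:
            d = dvf.displacement_mm.copy()
            d[..., 2] += 5.0
            dvfs[lab] = DVF(d, dvf.grid)
    series = Series4D(case.series.phase_labels, case.series.images, case.ref, dvfs)
    return eval_4d_rob_avg(case.plan, series, case.structs, scens28,
                           breathing_weights("equal"), qa=True)


@pytest.fixture(scope="session")
def robust3d_static(static_case, scens28):
    return eval_3d_robust(static_case.plan, static_case.avg_ct,
                          static_case.structs[static_case.ref], scens28)


@pytest.fixture(scope="session")
def robavg_static(static_case, scens28):
    return eval_4d_rob_avg(static_case.plan, static_case.series, static_case.structs,
                           scens28, breathing_weights("equal"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
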