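"""Deterministic micro-fixtures with oracle-computed expectations.

Each fixture bundles tiny inputs with expected outputs; expectations
marked as derived are computed here by the brute-force oracles at build
time, never hard-coded separately from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from rob4d.grid import Grid, Volume, centered_grid

from . import oracles


@dataclass
class Fixture:
    name: str
    inputs: dict[str, Any] = field(default_factory=dict)
    expected: dict[str, Any] = field(default_factory=dict)


def _two_constant_doses() -> Fixture:
    grid = centered_grid((6, 6, 6), (2.0, 2.0, 2.0))
    d1 = Volume(np.full(grid.shape, 1.0), grid)
    d2 = Volume(np.full(grid.shape, 2.0), grid)
    return Fixture(
        "two_constant_doses",
        inputs={"doses": [d1, d2]},
        expected={"vwmin": 1.0, "vwmax": 2.0},
    )


def _cube_shift_dice() -> Fixture:
    shape = (20, 20, 20)
    a = np.zeros(shape, dtype=bool)
    b = np.zeros(shape, dtype=bool)
    a[2:12, 2:12, 2:12] = True
    b[7:17, 2:12, 2:12] = True  # 10-voxel cube shifted by half its edge
    inter = int((a & b).sum())
    expected = 2.0 * inter / (int(a.sum()) + int(b.sum()))
    return Fixture("cube_shift_dice", inputs={"a": a, "b": b}, expected={"dice": expected})


def _triangle_wave_weights() -> Fixture:
    x, inhale = oracles.triangle_signal()
    return Fixture(
        "triangle_wave_weights",
        inputs={"signal": x, "inhale": inhale},
        expected={"weights": {lab: 0.125 for lab in
                              ("CT0in", "CT25in", "CT50in", "CT75in",
                               "CT100in", "CT75ex", "CT50ex", "CT25ex")}},
    )


def _sphere_expansion() -> Fixture:
    grid = centered_grid((24, 24, 24), (2.0, 2.0, 2.0))
    x, y, z = grid.world_coordinates()
    sphere = x**2 + y**2 + z**2 <= 10.0**2
    expected = oracles.brute_expand(sphere, 5.0, grid)
    return Fixture(
        "sphere_expansion",
        inputs={"mask": sphere, "margin_mm": 5.0, "grid": grid},
        expected={"expanded": expected},
    )


def _random_dose_field(seed: int = 7) -> Fixture:
    rng = np.random.default_rng(seed)
    grid = Grid((20, 20, 20), (3.0, 3.0, 3.0))
    dose = rng.uniform(0.0, 70.0, grid.shape)
    mask = rng.random(grid.shape) < 0.4
    mask.flat[0] = True  # never empty
    return Fixture(
        "random_dose_field",
        inputs={"dose": dose, "mask": mask, "grid": grid},
        expected={
            "d95": oracles.brute_dose_at_volume(dose, mask, 95.0),
            "v30": oracles.brute_volume_at_dose(dose, mask, 30.0),
            "d003cc": oracles.brute_near_max(dose, mask, grid, 0.03),
            "mean": float(dose[mask].mean()),
        },
    )


_BUILDERS = {
    "two_constant_doses": _two_constant_doses,
    "cube_shift_dice": _cube_shift_dice,
    "triangle_wave_weights": _triangle_wave_weights,
    "sphere_expansion": _sphere_expansion,
    "random_dose_field": _random_dose_field,
}


def make_fixture(name: str) -> Fixture:
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}") from None


def fixture_names() -> list[str]:
    return sorted(_BUILDERS)
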