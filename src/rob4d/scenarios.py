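"""Systematic-error scenarios for robust optimization and evaluation.

A scenario combines a rigid setup shift (applied to the full dose
distribution, i.e. one translation of the patient common to all beams)
with a global multiplicative density scale representing proton range
uncertainty.  The evaluation set uses 14 shift directions (6 cube faces
plus 8 renormalized cube corners) crossed with the two density scales;
the optimization set is the standard 21-scenario minimax set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_SETUP_MM = 5.0
DEFAULT_DENSITY_PCT = 3.0


@dataclass(frozen=True)
class Scenario:
    """One robustness error case: setup shift (mm, LPS) + density scale."""

    shift_mm: tuple[float, float, float]
    density_scale: float
    label: str

    def __post_init__(self):
        object.__setattr__(self, "shift_mm", tuple(float(s) for s in self.shift_mm))
        if self.density_scale <= 0:
            raise ValueError("density_scale must be positive")

    @property
    def shift_norm_mm(self) -> float:
        return float(np.linalg.norm(self.shift_mm))

    @property
    def is_nominal(self) -> bool:
        return self.shift_norm_mm == 0.0 and self.density_scale == 1.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "shift_mm": list(self.shift_mm),
            "density_scale": self.density_scale,
        }


NOMINAL = Scenario((0.0, 0.0, 0.0), 1.0, "nominal")

_AXIS_TAGS = ("L", "P", "S")


def _axis_directions() -> list[tuple[np.ndarray, str]]:
    dirs = []
    for a in range(3):
        for sgn in (1.0, -1.0):
            v = np.zeros(3)
            v[a] = sgn
            tag = ("+" if sgn > 0 else "-") + _AXIS_TAGS[a]
            dirs.append((v, tag))
    return dirs


def _corner_directions() -> list[tuple[np.ndarray, str]]:
    dirs = []
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            for sz in (1.0, -1.0):
                v = np.array([sx, sy, sz]) / np.sqrt(3.0)
                tag = "".join(
                    ("+" if s > 0 else "-") + t
                    for s, t in zip((sx, sy, sz), _AXIS_TAGS)
                )
                dirs.append((v, tag))
    return dirs


def shift_directions_14() -> list[tuple[np.ndarray, str]]:
    """The 14 unit shift directions: 6 axis-aligned and 8 body diagonals."""
    return _axis_directions() + _corner_directions()


def evaluation_scenarios(setup_mm: float = DEFAULT_SETUP_MM,
                         density_pct: float = DEFAULT_DENSITY_PCT) -> list[Scenario]:
    """The 28 robust-evaluation scenarios: 14 shifts x 2 density scales.

    Every shift has Euclidean norm ``setup_mm``; the nominal case is not a
    member (it is evaluated separately).
    """
    if setup_mm <= 0 or density_pct <= 0:
        raise ValueError("setup_mm and density_pct must be positive")
    scales = (1.0 - density_pct / 100.0, 1.0 + density_pct / 100.0)
    out = []
    for v, tag in shift_directions_14():
        shift = tuple(v * setup_mm)
        for scale in scales:
            pct = (scale - 1.0) * 100.0
            out.append(Scenario(shift, scale, f"shift{tag}_rho{pct:+.0f}%"))
    return out


def optimization_scenarios(setup_mm: float = DEFAULT_SETUP_MM,
                           density_pct: float = DEFAULT_DENSITY_PCT) -> list[Scenario]:
    """The 21 minimax-optimization scenarios.

    One nominal, six axis-aligned setup shifts, two pure density scales,
    and the 12 combinations of axis shift and density scale.
    """
    if setup_mm <= 0 or density_pct <= 0:
        raise ValueError("setup_mm and density_pct must be positive")
    scales = (1.0 - density_pct / 100.0, 1.0 + density_pct / 100.0)
    out = [NOMINAL]
    for v, tag in _axis_directions():
        out.append(Scenario(tuple(v * setup_mm), 1.0, f"shift{tag}"))
    for scale in scales:
        pct = (scale - 1.0) * 100.0
        out.append(Scenario((0.0, 0.0, 0.0), scale, f"rho{pct:+.0f}%"))
    for v, tag in _axis_directions():
        for scale in scales:
            pct = (scale - 1.0) * 100.0
            out.append(Scenario(tuple(v * setup_mm), scale, f"shift{tag}_rho{pct:+.0f}%"))
    return out


def count_4d_scenarios(base_scenarios, n_phases: int) -> int:
    """Number of dose computations when every scenario runs on every phase."""
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    return len(base_scenarios) * n_phases
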