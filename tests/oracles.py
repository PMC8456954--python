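"""Independent brute-force oracles used to freeze expected test values.

These deliberately avoid the package's algorithms: margins are checked by
all-pairs Euclidean distance, DVH metrics by exhaustive candidate scans,
breathing weights by closed-form arc-cosine bin times, and envelopes by
per-voxel loops over stacked arrays.
"""

from __future__ import annotations

import math

import numpy as np

from rob4d.grid import Grid
from rob4d.phantom4d import BIN_EDGES, PHASE_LABELS


def brute_expand(mask: np.ndarray, margin_mm: float, grid: Grid) -> np.ndarray:
    """Margin expansion by exhaustive distance check per voxel."""
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask).astype(float) * np.asarray(grid.spacing_mm)
    if pts.size == 0:
        return mask.copy()
    out = np.zeros_like(mask)
    sp = np.asarray(grid.spacing_mm)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx, dtype=float) * sp
        d2 = ((pts - p) ** 2).sum(axis=1)
        out[idx] = d2.min() <= margin_mm**2 + 1e-6
    return out


def brute_voxelwise_min_max(arrays) -> tuple[np.ndarray, np.ndarray]:
    stack = np.stack([np.asarray(a) for a in arrays])
    vmin = np.empty(stack.shape[1:])
    vmax = np.empty(stack.shape[1:])
    for idx in np.ndindex(stack.shape[1:]):
        col = stack[(slice(None),) + idx]
        vmin[idx] = col.min()
        vmax[idx] = col.max()
    return vmin, vmax


def brute_dose_at_volume(dose: np.ndarray, mask: np.ndarray, pct: float) -> float:
    """Largest candidate dose d with at least pct % of voxels receiving >= d."""
    vals = np.asarray(dose, dtype=float)[np.asarray(mask, dtype=bool)]
    best = None
    for d in np.unique(vals):
        frac = 100.0 * (vals >= d).sum() / vals.size
        if frac >= pct and (best is None or d > best):
            best = d
    return float(best)


def brute_volume_at_dose(dose: np.ndarray, mask: np.ndarray, thr: float) -> float:
    vals = np.asarray(dose, dtype=float)[np.asarray(mask, dtype=bool)]
    return 100.0 * sum(1 for v in vals if v >= thr) / vals.size


def brute_near_max(dose: np.ndarray, mask: np.ndarray, grid: Grid, cc: float) -> float:
    """Largest candidate dose whose >=-volume reaches the requested cc."""
    vals = np.asarray(dose, dtype=float)[np.asarray(mask, dtype=bool)]
    vox_cc = grid.voxel_volume_cc
    if vals.size * vox_cc < cc:
        return float(vals.min())
    best = None
    for d in np.unique(vals):
        if (vals >= d).sum() * vox_cc >= cc and (best is None or d > best):
            best = d
    return float(best)


def brute_tumor_amplitude(masks: dict[str, np.ndarray], grid: Grid):
    """Exhaustive pairwise bounding-box-midpoint search over phases and axes."""
    mids = {}
    sp = np.asarray(grid.spacing_mm)
    org = np.asarray(grid.origin_mm)
    for lab, m in masks.items():
        idx = np.argwhere(np.asarray(m, dtype=bool))
        lo, hi = idx.min(axis=0), idx.max(axis=0)
        mids[lab] = org + sp * (lo + hi) / 2.0
    labels = list(masks)
    best = (0.0, 0, (labels[0], labels[1]))
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            for a in range(3):
                d = abs(mids[la][a] - mids[lb][a])
                if d > best[0]:
                    best = (float(d), a, (la, lb))
    return best


def _inhale_time_below(level: float, power: int) -> float:
    """Time (fraction of a period) the inhale branch spends below a signal level.

    The breathing signal is x(t) = ((1 - cos 2πt)/2)^power scaled to the
    peak amplitude; on the inhale branch t in [0, 1/2] it rises
    monotonically, so the crossing time follows from the arc cosine.
    """
    c = min(max(level, 0.0), 1.0) ** (1.0 / power)
    return math.acos(1.0 - 2.0 * c) / (2.0 * math.pi)


def closed_form_cos_weights(power: int = 1) -> dict[str, float]:
    """Analytic amplitude-bin time weights for the cos / cos^4 signals."""
    t = {edge: _inhale_time_below(edge, power) for edge in BIN_EDGES}
    w = {}
    w["CT0in"] = 2.0 * t[0.125]
    w["CT100in"] = 2.0 * (0.5 - t[0.875])
    for lo, hi, name in ((0.125, 0.375, "25"), (0.375, 0.625, "50"), (0.625, 0.875, "75")):
        half = t[hi] - t[lo]
        w[f"CT{name}in"] = half
        w[f"CT{name}ex"] = half  # the cosine cycle is time-symmetric
    assert set(w) == set(PHASE_LABELS)
    return w


def triangle_signal(n: int = 200_000) -> tuple[np.ndarray, np.ndarray]:
    """Constant-speed (triangular) breathing signal over one period."""
    t = (np.arange(n) + 0.5) / n
    x = np.where(t < 0.5, 2.0 * t, 2.0 * (1.0 - t))
    inhale = t < 0.5
    return x, inhale
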