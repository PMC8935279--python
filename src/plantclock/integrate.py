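"""Fixed-step RK4 stepping for piecewise-smooth forcing.

The light forcing is piecewise-constant, so within any segment between two
switch times the vector field is smooth and classical RK4 at a capped step
size is highly accurate (reaction rates are O(1) h^-1, so the local error at
the default 0.05 h cap is far below solver noise).  Segment boundaries are
never stepped over: every dawn, dusk and fluctuation breakpoint starts a
fresh step sequence.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["rk4_segment", "merge_boundaries"]


def rk4_segment(y: np.ndarray, f, a: float, b: float, dt_max: float) -> np.ndarray:
    """Advance ``y`` from time a to b with RK4 under an autonomous rhs ``f``.

    The state is projected onto the non-negative orthant after each step;
    this only acts within round-off of zero (degradation is proportional to
    the variable itself, so exact dynamics cannot cross zero).
    """
    n = max(1, math.ceil((b - a) / dt_max))
    h = (b - a) / n
    for _ in range(n):
        k1 = f(y)
        k2 = f(y + (0.5 * h) * k1)
        k3 = f(y + (0.5 * h) * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.maximum(y, 0.0, out=y)
    return y


def merge_boundaries(
    bounds: np.ndarray, record_times: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge segment boundaries with requested recording times.

    Returns ``(points, is_record, seg_index)`` where ``points`` is the sorted
    union, ``is_record[k]`` marks points at which the state should be stored,
    and ``seg_index[k]`` gives, for each interval (points[k], points[k+1]),
    the index of the original segment it falls in (last entry unused).
    """
    bounds = np.asarray(bounds, dtype=float)
    record_times = np.asarray(record_times, dtype=float)
    pts = np.concatenate([bounds, record_times])
    flags = np.concatenate(
        [np.zeros(len(bounds), bool), np.ones(len(record_times), bool)]
    )
    order = np.argsort(pts, kind="stable")
    pts, flags = pts[order], flags[order]
    # collapse duplicates within tolerance, OR-ing the record flags
    keep_pts, keep_flags = [pts[0]], [flags[0]]
    for p, fl in zip(pts[1:], flags[1:]):
        if p - keep_pts[-1] <= tol:
            keep_flags[-1] = keep_flags[-1] or fl
        else:
            keep_pts.append(p)
            keep_flags.append(fl)
    points = np.asarray(keep_pts)
    is_record = np.asarray(keep_flags)
    mids = 0.5 * (points[:-1] + points[1:])
    seg_index = np.clip(
        np.searchsorted(bounds, mids, side="right") - 1, 0, len(bounds) - 2
    )
    seg_index = np.concatenate([seg_index, [len(bounds) - 2]])
    return points, is_record, seg_index
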