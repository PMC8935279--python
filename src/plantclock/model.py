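"""Single-cell clock: state, light input, right-hand side, and simulation.

The model is a revised version of the compact De Caluwé et al. (2016)
Arabidopsis clock: 9 ODEs for four mRNA/protein pairs (CL, P97, P51, EL) and
the dark-accumulating protein P.  Revisions relative to the original network:
CL represses P97 transcription (instead of activating it), CL represses its
own transcription, P51 protein degradation is higher in the dark than in the
light, and every light-driven term is scaled by a cellular light sensitivity
``L_sens``.

Light enters the network in six places: acute activation of CL and P97
transcription at dawn via protein P, light-driven EL transcription, light-
boosted CL translation, light/dark switching of CL mRNA degradation, and
light/dark switching of the P97, P51 and EL protein degradation rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ClockParameters

__all__ = [
    "STATE_NAMES",
    "NSTATE",
    "ClockState",
    "LightInput",
    "clock_rhs",
    "rhs_vectorized",
    "simulate_cell",
    "CellTrajectory",
]

#: State component order used by every array-valued API in the package.
STATE_NAMES: tuple[str, ...] = (
    "cCLm", "cCLp", "cP97m", "cP97p", "cP51m", "cP51p", "cELm", "cELp", "P",
)
NSTATE = len(STATE_NAMES)

#: Map gene label -> (mRNA index, protein index).
GENE_INDEX: dict[str, tuple[int, int]] = {
    "CL": (0, 1),
    "P97": (2, 3),
    "P51": (4, 5),
    "EL": (6, 7),
}


@dataclass(frozen=True)
class ClockState:
    """One cell's state: 4 mRNAs, 4 proteins (arbitrary conc.), and P in [0,1]."""

    cCLm: float
    cCLp: float
    cP97m: float
    cP97p: float
    cP51m: float
    cP51p: float
    cELm: float
    cELp: float
    P: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ClockState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (NSTATE,):
            raise ValueError(f"expected shape ({NSTATE},), got {arr.shape}")
        return cls(*arr.tolist())

    @classmethod
    def default(cls, value: float = 0.1) -> "ClockState":
        """Default initial condition: every component at ``value``."""
        return cls(*([value] * NSTATE))


@dataclass(frozen=True)
class LightInput:
    """Instantaneous light environment of one cell.

    ``L`` is the light level (0 in dark, ~1 in day, in [0.5, 1.5] under noisy
    day light), ``D`` the dark indicator (1 iff L == 0), and ``L_sens`` the
    cellular light sensitivity multiplying every light-driven term.
    """

    L: float
    D: float
    L_sens: float = 1.0

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError(f"L must be >= 0, got {self.L}")
        if self.L_sens < 0:
            raise ValueError(f"L_sens must be >= 0, got {self.L_sens}")
        if self.D not in (0, 1, 0.0, 1.0):
            raise ValueError(f"D must be 0 or 1, got {self.D}")
        if (self.L == 0) != (self.D == 1):
            raise ValueError(
                f"dark signal inconsistent: D must be 1 iff L == 0 "
                f"(got L={self.L}, D={self.D})"
            )


def rhs_vectorized(y, L, D, L_sens, p) -> np.ndarray:
    """Time derivative of the 9 state variables, broadcast over cells.

    Parameters
    ----------
    y
        State array of shape (..., 9) in :data:`STATE_NAMES` order.
    L, D, L_sens
        Light level, dark indicator and light sensitivity; scalars or arrays
        broadcastable against ``y[..., 0]``.
    p
        Object exposing the parameter names as attributes; values may be
        scalars (one parameter set) or arrays (one set per cell/row).

    Returns
    -------
    Array with the shape of ``y``.
    """
    y = np.asarray(y, dtype=float)
    CLm, CLp = y[..., 0], y[..., 1]
    P97m, P97p = y[..., 2], y[..., 3]
    P51m, P51p = y[..., 4], y[..., 5]
    ELm, ELp = y[..., 6], y[..., 7]
    P = y[..., 8]

    lsl = L_sens * L  # effective light drive

    dy = np.empty_like(y)
    # CL: acute light activation via P; repressed by its own protein (K0),
    # P97 protein (K1) and P51 protein (K2); light-switched mRNA decay.
    dy[..., 0] = (p.v1 + p.v1L * lsl * P) / (
        1.0 + (CLp / p.K0) ** 2 + (P97p / p.K1) ** 2 + (P51p / p.K2) ** 2
    ) - (p.k1L * lsl + p.k1D * D) * CLm
    dy[..., 1] = (p.p1 + p.p1L * lsl) * CLm - p.d1 * CLp
    # P97: acute light activation plus basal transcription; repressed by P51
    # (K4), EL (K5) and CL (K5b) proteins.
    dy[..., 2] = (p.v2L * lsl * P + p.v2A) / (
        1.0 + (P51p / p.K4) ** 2 + (ELp / p.K5) ** 2 + (CLp / p.K5b) ** 2
    ) - p.k2 * P97m
    dy[..., 3] = p.p2 * P97m - (p.d2D * D + p.d2L * L) * P97p
    # P51: repressed by CL (K6) and itself (K7); dark-enhanced protein decay.
    dy[..., 4] = p.v3 / (1.0 + (CLp / p.K6) ** 2 + (P51p / p.K7) ** 2) - p.k3 * P51m
    dy[..., 5] = p.p3 * P51m - (p.d3D * D + p.d3L * L) * P51p
    # EL: transcription is strictly light-driven; repressed by CL (K8), P51
    # (K9) and itself (K10); light term of protein decay carries L_sens.
    dy[..., 6] = lsl * p.v4 / (
        1.0 + (CLp / p.K8) ** 2 + (P51p / p.K9) ** 2 + (ELp / p.K10) ** 2
    ) - p.k4 * ELm
    dy[..., 7] = p.p4 * ELm - (p.d4D * D + p.d4L * lsl) * ELp
    # Protein P: accumulates in the dark, degraded by light.
    dy[..., 8] = p.q * (1.0 - P) * D - lsl * P
    return dy


def clock_rhs(
    state: ClockState, light: LightInput, params: ClockParameters
) -> ClockState:
    """Derivative of a single cell's state under the given light input."""
    y = state.to_array()
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    dy = rhs_vectorized(y, light.L, light.D, light.L_sens, params)
    return ClockState.from_array(dy)


@dataclass(frozen=True)
class CellTrajectory:
    """Dense single-cell trajectory on a uniform output grid."""

    t: np.ndarray        # (T,) hours
    y: np.ndarray        # (T, 9) in STATE_NAMES order

    def variable(self, name: str) -> np.ndarray:
        return self.y[:, STATE_NAMES.index(name)]

    def to_frame(self):
        """Long-format table (time_h, variable, value)."""
        import pandas as pd

        frames = [
            pd.DataFrame(
                {"time_h": self.t, "variable": name, "value": self.y[:, i]}
            )
            for i, name in enumerate(STATE_NAMES)
        ]
        return pd.concat(frames, ignore_index=True)


def simulate_cell(
    params: ClockParameters,
    light_protocol,
    L_sens: float = 1.0,
    t_span: tuple[float, float] | None = None,
    initial_state: ClockState | None = None,
    output_dt: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> CellTrajectory:
    """Integrate one cell under a light protocol with an adaptive solver.

    The forcing L(t)/D(t) is piecewise-constant, so the integration is
    restarted at every light-switch time (dawn, dusk, fluctuation boundary);
    an adaptive solver stepping across a discontinuity would otherwise lose
    accuracy silently.

    Parameters
    ----------
    light_protocol
        Object exposing ``switch_times(t0, t1)`` and ``light_at(cell_id, t)``
        (see :mod:`plantclock.light`); cell_id 0 is used.
    t_span
        Time window in hours; defaults to the protocol's full span.
    output_dt
        Spacing of the returned uniform output grid (h).
    """
    from scipy.integrate import solve_ivp

    if t_span is None:
        t_span = (0.0, light_protocol.total_hours)
    t0, t1 = map(float, t_span)
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    y0 = (initial_state or ClockState.default()).to_array()
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")

    switches = [s for s in light_protocol.switch_times(t0, t1) if t0 < s < t1]
    bounds = np.concatenate(([t0], np.sort(np.asarray(switches, float)), [t1]))
    t_out = t0 + output_dt * np.arange(int(round((t1 - t0) / output_dt)) + 1)
    t_out = t_out[t_out <= t1 + 1e-9]

    ys = np.empty((len(t_out), NSTATE))
    if t_out[0] <= t0 + 1e-9:
        ys[0] = y0
        filled = 1
    else:
        filled = 0
    y = y0
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a <= 1e-12:
            continue
        li = light_protocol.light_at(0, 0.5 * (a + b))
        L, D, ls = li.L, li.D, L_sens

        def f(t, yy, L=L, D=D, ls=ls):
            return rhs_vectorized(yy, L, D, ls, params)

        n_seg = 0
        while filled + n_seg < len(t_out) and t_out[filled + n_seg] <= b + 1e-9:
            n_seg += 1
        grid = t_out[filled : filled + n_seg]
        t_eval = np.unique(np.concatenate([grid, [b]]))
        sol = solve_ivp(
            f, (a, b), y, method=method, rtol=rtol, atol=atol, t_eval=t_eval
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed in segment [{a:.4f}, {b:.4f}] h: {sol.message}"
            )
        if n_seg:
            ys[filled : filled + n_seg] = sol.y.T[:n_seg]
            filled += n_seg
        y = sol.y[:, -1]
    if filled != len(t_out):  # pragma: no cover - defensive
        raise RuntimeError("output grid not fully covered")
    return CellTrajectory(t=t_out, y=ys)
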