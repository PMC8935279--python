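"""Light protocols: LL, DD, idealized LD, and noisy LD with mixed fluctuations.

A protocol defines, per cell, a piecewise-constant light level L(t) and the
complementary dark indicator D(t) = 1 iff L(t) = 0.  Time 0 is dawn of day 0.

Noisy day light follows a telegraph-like fluctuation process: deviations last
exponentially distributed intervals (mean 2.4 h) and are uniform on
[-0.5, +0.5], so the instantaneous day intensity is uniform on [0.5, 1.5].
Each cell mixes a shared ("global") and a private ("individual") fluctuation
track,

    L(t) = 1 - [ lam * xi_global(t) + (1 - lam) * xi_individual(t) ],

with mixture ratio ``lam`` in [0, 1]: lam = 1 gives every cell the same noisy
cycle, lam = 0 gives fully independent cycles.  Fluctuations modify daytime
intensity only; night light is exactly 0 and dawn/dusk times are never
perturbed.  Tracks restart (are redrawn) at each dawn; the night-time value of
a track is never consumed, so this choice only fixes the correlation structure
across the night gap.

Every random draw descends from a single protocol seed through named
``numpy.random.SeedSequence`` streams keyed by (cell, day), making each
cell's light trace reproducible independently of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .model import LightInput

__all__ = [
    "FluctuationTrack",
    "LightProtocol",
    "LightField",
    "make_fluctuation_track",
]

Kind = Literal["LL", "DD", "LD_ideal", "LD_noisy"]

#: stream tags for seed derivation
_GLOBAL_STREAM = 0
_CELL_STREAM = 1


@dataclass(frozen=True)
class FluctuationTrack:
    """Piecewise-constant deviation track xi(t) on [edges[0], edges[-1]].

    ``edges`` has one more entry than ``values``; interval ``j`` spans
    ``[edges[j], edges[j+1])`` with deviation ``values[j]``.
    """

    edges: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.values) + 1:
            raise ValueError("edges must have len(values) + 1 entries")

    def value_at(self, t) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(self.edges, t, side="right") - 1,
            0,
            len(self.values) - 1,
        )
        return self.values[idx]

    @property
    def breakpoints(self) -> np.ndarray:
        """Interior switch times (excludes the track's own end points)."""
        return self.edges[1:-1]


def make_fluctuation_track(
    seed,
    t_max: float,
    mean_duration_h: float = 2.4,
    halfwidth: float = 0.5,
    t_start: float = 0.0,
) -> FluctuationTrack:
    """Draw a fluctuation track covering [t_start, t_start + t_max].

    Interval durations are i.i.d. exponential with the given mean; deviations
    are i.i.d. uniform on [-halfwidth, +halfwidth].  The same seed always
    produces the identical track.
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be > 0, got {t_max}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    durations = np.empty(0)
    # draw in deterministic batches until the span is covered
    while durations.sum() < t_max:
        n = max(8, int(1.5 * (t_max - durations.sum()) / mean_duration_h) + 1)
        durations = np.concatenate([durations, rng.exponential(mean_duration_h, n)])
    n_used = int(np.searchsorted(np.cumsum(durations), t_max)) + 1
    durations = durations[:n_used]
    edges = t_start + np.concatenate([[0.0], np.cumsum(durations)])
    values = rng.uniform(-halfwidth, halfwidth, n_used)
    return FluctuationTrack(edges=edges, values=values)


@dataclass(frozen=True)
class LightProtocol:
    """A named light regime over ``days`` simulated days.

    Parameters
    ----------
    kind
        "LL" (constant light), "DD" (constant dark), "LD_ideal"
        (clean square-wave cycles) or "LD_noisy" (fluctuating day light).
    day_length_h
        Photoperiod of the LD phase in hours (8, 12 or 16 in practice).
    entrain_days
        Number of LD days (for LL/DD kinds: total duration in days).
    release_kind, release_days
        Optional constant phase appended after entrainment ("LL", "DD" or
        "none").
    lam
        Global/individual fluctuation mixture ratio in [0, 1] (noisy LD only).
    seed
        Root seed for every fluctuation stream.
    """

    kind: Kind
    entrain_days: int
    day_length_h: float = 12.0
    release_kind: Literal["LL", "DD", "none"] = "none"
    release_days: int = 0
    lam: float = 0.0
    fluctuation_mean_h: float = 2.4
    intensity_halfwidth: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("LL", "DD", "LD_ideal", "LD_noisy"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if not 0 < self.day_length_h < 24:
            raise ValueError("day_length_h must lie in (0, 24)")
        if not 0 <= self.lam <= 1:
            raise ValueError("lam must lie in [0, 1]")
        if self.entrain_days < 0 or self.release_days < 0:
            raise ValueError("day counts must be >= 0")

    # -- timeline ---------------------------------------------------------
    @property
    def days(self) -> int:
        return self.entrain_days + self.release_days

    @property
    def total_hours(self) -> float:
        return 24.0 * self.days

    def phase_kind(self, day: int) -> str:
        """Effective regime ("LL" | "DD" | "LD_ideal" | "LD_noisy") on a day."""
        if self.kind in ("LL", "DD"):
            return self.kind
        if day >= self.entrain_days and self.release_kind != "none":
            return self.release_kind
        return self.kind

    # -- fluctuation streams ---------------------------------------------
    def _day_track(self, stream: int, cell_id: int, day: int) -> FluctuationTrack:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed), stream, int(cell_id), int(day)])
        )
        return make_fluctuation_track(
            rng,
            self.day_length_h,
            self.fluctuation_mean_h,
            self.intensity_halfwidth,
            t_start=24.0 * day,
        )

    def global_track(self, day: int) -> FluctuationTrack:
        return self._day_track(_GLOBAL_STREAM, 0, day)

    def cell_track(self, cell_id: int, day: int) -> FluctuationTrack:
        return self._day_track(_CELL_STREAM, cell_id, day)

    # -- evaluation -------------------------------------------------------
    def light_at(self, cell_id: int, t: float) -> LightInput:
        """L and D for one cell at one time (D = 1 iff L = 0)."""
        if cell_id < 0:
            raise ValueError(f"unknown cell_id {cell_id}")
        if not 0 <= t <= self.total_hours + 1e-9:
            raise ValueError(f"t={t} outside protocol span [0, {self.total_hours}]")
        day = min(int(t // 24.0), self.days - 1)
        phase = self.phase_kind(day)
        if phase == "LL":
            return LightInput(L=1.0, D=0.0)
        if phase == "DD":
            return LightInput(L=0.0, D=1.0)
        hour = t - 24.0 * day
        if hour >= self.day_length_h:  # night
            return LightInput(L=0.0, D=1.0)
        if phase == "LD_ideal":
            return LightInput(L=1.0, D=0.0)
        dev = 0.0
        if self.lam > 0:
            dev += self.lam * float(self.global_track(day).value_at(t))
        if self.lam < 1:
            dev += (1.0 - self.lam) * float(self.cell_track(cell_id, day).value_at(t))
        return LightInput(L=1.0 - dev, D=0.0)

    def switch_times(self, t0: float, t1: float, cell_id: int = 0) -> np.ndarray:
        """All light discontinuities for one cell in [t0, t1].

        Includes dawn/dusk transitions and, for noisy LD, every fluctuation
        breakpoint of the cell's mixed track.  Integrators must restart at
        each of these times.
        """
        times: list[float] = []
        for day in range(int(t0 // 24.0), min(int(np.ceil(t1 / 24.0)), self.days)):
            phase = self.phase_kind(day)
            if phase in ("LL", "DD"):
                if day * 24.0 != 0:
                    times.append(day * 24.0)  # possible phase boundary
                continue
            times.extend([24.0 * day, 24.0 * day + self.day_length_h])
            if phase == "LD_noisy":
                if self.lam > 0:
                    times.extend(self.global_track(day).breakpoints)
                if self.lam < 1:
                    times.extend(self.cell_track(cell_id, day).breakpoints)
        arr = np.asarray(sorted(set(times)), dtype=float)
        return arr[(arr >= t0) & (arr <= t1)]

    def track_frame(self, cell_id: int = 0):
        """Piecewise-constant light trace of one cell as a tidy table.

        Columns (t_start, t_end, L); suitable for CSV export and audit.
        """
        import pandas as pd

        rows = []
        for day in range(self.days):
            start, end = 24.0 * day, 24.0 * (day + 1)
            pts = self.switch_times(start, end, cell_id)
            edges = np.unique(np.concatenate([[start], pts, [end]]))
            for a, b in zip(edges[:-1], edges[1:]):
                if b - a > 1e-12:
                    rows.append((a, b, self.light_at(cell_id, 0.5 * (a + b)).L))
        return pd.DataFrame(rows, columns=["t_start", "t_end", "L"])


class LightField:
    """Per-day, per-cell piecewise-constant light for the lattice integrator.

    For a given day it returns the merged segment boundaries of all cells'
    light traces together with an (n_segments, n_cells) matrix of light
    levels, so the multicellular stepper can hold light constant within each
    segment and restart exactly at every switch time.
    """

    def __init__(self, protocol: LightProtocol):
        self.protocol = protocol

    def day_segments(self, day: int, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
        pr = self.protocol
        start, end = 24.0 * day, 24.0 * (day + 1)
        phase = pr.phase_kind(day)
        if phase == "LL":
            return np.array([start, end]), np.ones((1, n_cells))
        if phase == "DD":
            return np.array([start, end]), np.zeros((1, n_cells))
        dusk = start + pr.day_length_h
        if phase == "LD_ideal":
            bounds = np.array([start, dusk, end])
            L = np.zeros((2, n_cells))
            L[0] = 1.0
            return bounds, L

        # noisy LD: merge the global track and every cell's private track
        gtrack = pr.global_track(day) if pr.lam > 0 else None
        ctracks = (
            [pr.cell_track(c, day) for c in range(n_cells)] if pr.lam < 1 else None
        )
        pieces = [np.array([start, dusk, end])]
        if gtrack is not None:
            pieces.append(gtrack.breakpoints)
        if ctracks is not None:
            pieces.extend(tr.breakpoints for tr in ctracks)
        bounds = np.unique(np.concatenate(pieces))
        bounds = bounds[(bounds >= start) & (bounds <= end)]
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        daytime = mids < dusk
        L = np.zeros((len(mids), n_cells))
        dev = np.zeros(int(daytime.sum()))
        day_mids = mids[daytime]
        if gtrack is not None:
            gdev = pr.lam * gtrack.value_at(day_mids)
        if ctracks is not None:
            for c, tr in enumerate(ctracks):
                dev = (1.0 - pr.lam) * tr.value_at(day_mids)
                if gtrack is not None:
                    dev = dev + gdev
                L[daytime, c] = 1.0 - dev
        else:
            L[daytime, :] = (1.0 - gdev)[:, None]
        return bounds, L
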