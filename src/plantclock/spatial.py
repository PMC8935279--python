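"""Coupled multicellular clock simulation on the seedling template.

Every cell runs the single-cell network with its own light sensitivity and
light trace; the full derivative of cell i is divided by its period-scaling
parameter tau_i (tau multiplies d/dt on the left of the coupled equations,
so it scales the coupling term too).  Two coupling routes are available:

* local: the coupled species' equation gains J_local * (cbar_i - c_i), where
  cbar_i is the mean over the cell's 4- or 8-neighbourhood (or over all cells
  for global coupling).  This emulates passive sharing of clock molecules
  through plasmodesmata.
* long-distance: the EL-protein (ELF4/LUX) equation of root-tip cells gains
  J_long * (cbar_EL_hypocotyl - c_ELp_i), emulating phloem transport of ELF4
  from the shoot to the phloem unloading zone at the root tip.

The state is one flat (N, 9) array; the rhs is fully vectorized over cells,
and growth (one new root-tip row per 24 h) stops and restarts the integrator
with an extended state vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .integrate import merge_boundaries, rk4_segment
from .light import LightField, LightProtocol
from .model import GENE_INDEX, NSTATE, STATE_NAMES, ClockState, rhs_vectorized
from .parameters import ClockParameters, DEFAULT_PARAMS
from .template import (
    GrowthEvent,
    RegionNoiseSpec,
    SeedlingTemplate,
    assign_tau,
    grow,
)

__all__ = ["CouplingConfig", "SimulationResult", "coupled_rhs", "run_protocol"]

_TAU_STREAM = 17  # sub-stream tag for tau draws under the run seed


@dataclass(frozen=True)
class CouplingConfig:
    """Coupling strengths, coupled species and neighbourhood rule.

    ``species`` is one of CL, P97, P51, EL and ``form`` selects its mRNA or
    protein; the local coupling term is appended to exactly that equation.
    Strengths are in h^-1; the reference grid is {0, 0.01, 0.1, 1, 2, 4}.
    """

    J_local: float = 0.0
    J_long: float = 0.0
    species: str = "CL"
    form: str = "mRNA"
    neighborhood: str = "4"

    def __post_init__(self) -> None:
        if self.J_local < 0 or self.J_long < 0:
            raise ValueError("coupling strengths must be >= 0")
        if not (np.isfinite(self.J_local) and np.isfinite(self.J_long)):
            raise ValueError("coupling strengths must be finite")
        if self.species not in GENE_INDEX:
            raise ValueError(f"unknown coupled species {self.species!r}")
        if self.form not in ("mRNA", "protein"):
            raise ValueError(f"form must be 'mRNA' or 'protein', got {self.form!r}")
        if self.neighborhood not in ("4", "8", "global"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")

    @property
    def coupled_index(self) -> int:
        m, p = GENE_INDEX[self.species]
        return m if self.form == "mRNA" else p


_ELP = STATE_NAMES.index("cELp")


def _lattice_rhs_factory(template: SeedlingTemplate, coupling: CouplingConfig,
                         params: ClockParameters):
    """Precompute per-day constants and return f(y, L, D) -> dy."""
    lsens = template.L_sens
    inv_tau = (1.0 / template.tau)[:, None]
    J_loc, J_long = coupling.J_local, coupling.J_long
    ci = coupling.coupled_index
    A = template.averaging_matrix(coupling.neighborhood) if J_loc > 0 else None
    tip = template.root_tip_cells if J_long > 0 else None
    hypo = template.hypocotyl_cells if J_long > 0 else None
    if J_long > 0 and len(hypo) == 0:
        raise ValueError("long-distance coupling requires hypocotyl cells")

    def f(y: np.ndarray, L, D) -> np.ndarray:
        dy = rhs_vectorized(y, L, D, lsens, params)
        if J_loc > 0:
            c = y[:, ci]
            dy[:, ci] += J_loc * (A.dot(c) - c)
        if J_long > 0:
            elp = y[:, _ELP]
            dy[tip, _ELP] += J_long * (elp[hypo].mean() - elp[tip])
        dy *= inv_tau
        return dy

    return f


def coupled_rhs(
    all_states: np.ndarray,
    t: float,
    template: SeedlingTemplate,
    coupling: CouplingConfig,
    light_env: LightProtocol,
    params: ClockParameters = DEFAULT_PARAMS,
) -> np.ndarray:
    """Derivative of the full lattice state at time t.

    ``all_states`` has shape (N, 9) in :data:`STATE_NAMES` order.  This is
    the reference (single-evaluation) entry point; the simulation loop uses
    the same factory with light held constant per segment.
    """
    all_states = np.asarray(all_states, dtype=float)
    if all_states.shape != (template.n_cells, NSTATE):
        raise ValueError(
            f"state shape {all_states.shape} does not match template "
            f"({template.n_cells}, {NSTATE})"
        )
    L = np.empty(template.n_cells)
    D = np.empty(template.n_cells)
    for i in range(template.n_cells):
        li = light_env.light_at(i, t)
        L[i], D[i] = li.L, li.D
    return _lattice_rhs_factory(template, coupling, params)(all_states, L, D)


@dataclass
class SimulationResult:
    """Trajectories of selected variables for every cell, plus provenance.

    ``data[var]`` has shape (T, N_final); cells created by growth hold NaN
    before their birth time.  ``template`` is the final (grown) template;
    ``initial_template`` the starting one; ``growth_log`` records each event.
    """

    t: np.ndarray
    data: dict[str, np.ndarray]
    template: SeedlingTemplate
    initial_template: SeedlingTemplate
    growth_log: list[tuple[float, GrowthEvent]]
    protocol: LightProtocol
    coupling: CouplingConfig
    params: ClockParameters
    seed: int
    noise_spec: RegionNoiseSpec | None

    @property
    def n_cells(self) -> int:
        return self.template.n_cells

    def series(self, var: str) -> np.ndarray:
        if var not in self.data:
            raise KeyError(
                f"variable {var!r} was not recorded (have {sorted(self.data)})"
            )
        return self.data[var]

    def mean_series(self, var: str) -> np.ndarray:
        """Whole-template mean at each time (ignoring unborn cells)."""
        return np.nanmean(self.series(var), axis=1)

    def region_mean_series(self, var: str, region: str) -> np.ndarray:
        mask = self.template.region_mask(region)
        return np.nanmean(self.series(var)[:, mask], axis=1)


def run_protocol(
    template: SeedlingTemplate,
    coupling: CouplingConfig,
    protocol: LightProtocol,
    params: ClockParameters = DEFAULT_PARAMS,
    seed: int = 0,
    noise_spec: RegionNoiseSpec | None = RegionNoiseSpec(),
    initial_state: ClockState | None = None,
    output_dt: float = 0.1,
    dt_max: float = 0.1,
    record: Sequence[str] | None = None,
    growth: bool = True,
) -> SimulationResult:
    """Integrate the coupled lattice over the full light protocol.

    Parameters
    ----------
    seed
        Run seed; it drives the tau field (and growth-time tau draws) via a
        dedicated sub-stream.  Light fluctuations are seeded separately by
        ``protocol.seed``, so replicates match tau fields across protocols by
        sharing the run seed.
    noise_spec
        Region tau SDs; ``None`` keeps the tau values already present on the
        template, ``RegionNoiseSpec.zero()`` disables cell-to-cell
        variability.
    record
        Variable names to store (default: all nine).
    growth
        Append one root-tip row every 24 h (the template's growth rule).
    """
    record = tuple(record) if record is not None else STATE_NAMES
    unknown = set(record) - set(STATE_NAMES)
    if unknown:
        raise ValueError(f"unknown record variable(s): {sorted(unknown)}")

    rng_tau = np.random.default_rng(
        np.random.SeedSequence([int(seed), _TAU_STREAM])
    )
    if noise_spec is not None:
        tpl = assign_tau(template, noise_spec, rng_tau)
    else:
        tpl = template.copy()
    tpl0 = tpl.copy()

    y = np.tile((initial_state or ClockState.default()).to_array(), (tpl.n_cells, 1))
    lightfield = LightField(protocol)
    n_days = protocol.days
    total = protocol.total_hours
    n_out = int(round(total / output_dt)) + 1
    t_grid = output_dt * np.arange(n_out)

    growth_log: list[tuple[float, GrowthEvent]] = []
    day_chunks: list[tuple[np.ndarray, dict[str, np.ndarray]]] = []
    rec_idx = [STATE_NAMES.index(v) for v in record]

    # record t = 0
    day_chunks.append(
        (np.array([0.0]), {v: y[None, :, STATE_NAMES.index(v)].copy() for v in record})
    )

    for day in range(n_days):
        if day > 0 and growth:
            tpl, ev = grow(tpl, noise_spec or RegionNoiseSpec.zero(), rng_tau)
            y = np.vstack([y, y[ev.source_cell_ids]])
            growth_log.append((24.0 * day, ev))
        f = _lattice_rhs_factory(tpl, coupling, params)
        start, end = 24.0 * day, min(24.0 * (day + 1), total)
        bounds, Lmat = lightfield.day_segments(day, tpl.n_cells)
        rec_times = t_grid[(t_grid > start + 1e-9) & (t_grid <= end + 1e-9)]
        points, is_rec, seg_idx = merge_boundaries(bounds, rec_times)
        times_out = []
        vals_out: dict[str, list[np.ndarray]] = {v: [] for v in record}
        for k in range(len(points) - 1):
            a, b = points[k], points[k + 1]
            L = Lmat[seg_idx[k]]
            D = (L == 0.0).astype(float)
            y = rk4_segment(y, lambda yy: f(yy, L, D), a, b, dt_max)
            if is_rec[k + 1]:
                times_out.append(points[k + 1])
                for v, i in zip(record, rec_idx):
                    vals_out[v].append(y[:, i].copy())
        day_chunks.append(
            (
                np.asarray(times_out),
                {v: np.asarray(vals_out[v]) for v in record},
            )
        )

    n_final = tpl.n_cells
    data: dict[str, np.ndarray] = {}
    for v in record:
        rows = []
        for times, chunk in day_chunks:
            arr = chunk[v]
            if arr.size == 0:
                continue
            if arr.shape[1] < n_final:
                pad = np.full((arr.shape[0], n_final - arr.shape[1]), np.nan)
                arr = np.hstack([arr, pad])
            rows.append(arr)
        data[v] = np.vstack(rows)
    t = np.concatenate([times for times, _ in day_chunks if len(times)])
    if len(t) != n_out:  # pragma: no cover - defensive
        raise RuntimeError(f"output grid mismatch: {len(t)} vs {n_out}")

    return SimulationResult(
        t=t_grid,  # canonical uniform grid (recorded times match to ~1e-9)
        data=data,
        template=tpl,
        initial_template=tpl0,
        growth_log=growth_log,
        protocol=protocol,
        coupling=coupling,
        params=params,
        seed=int(seed),
        noise_spec=noise_spec,
    )
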