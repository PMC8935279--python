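"""Seedling cell lattice: regions, light sensitivities, tau fields, growth.

Cells live on an integer 2-D grid (col, row); the primary axis of the
seedling runs along increasing row, from the cotyledons (top) down to the
root tip.  Every cell belongs to exactly one of four regions -- cotyledon,
hypocotyl, root, root_tip -- which fixes its light sensitivity ``L_sens``
and the distribution of its period-scaling parameter tau.

The default geometry places two 10x15 cotyledon blocks either side of a
5-cell-wide hypocotyl column (5x20), continued by a 5x70 root column and a
5x10 root tip: 800 cells, with the 5-wide columns matching the 1x5
cross-sections used by the space-time analysis.

Growth appends one new row of cells at the root tip every 24 simulated
hours; the root-tip region keeps a constant size, so its uppermost row is
relabelled to root (its light sensitivity drops to the root value; its tau
is retained, since the cell itself persists).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "REGIONS",
    "DEFAULT_L_SENS",
    "RegionNoiseSpec",
    "TemplateGeometry",
    "SeedlingTemplate",
    "GrowthEvent",
    "build_template",
    "assign_tau",
    "grow",
]

REGIONS: tuple[str, ...] = ("cotyledon", "hypocotyl", "root", "root_tip")

#: Region light sensitivities of the reference simulations.
DEFAULT_L_SENS: dict[str, float] = {
    "cotyledon": 1.6,
    "hypocotyl": 1.0,
    "root": 0.65,
    "root_tip": 0.95,
}


@dataclass(frozen=True)
class RegionNoiseSpec:
    """Per-region SD of the cell period-scaling parameter tau (mean 1).

    Defaults come from the between-cell period variability measured in
    single-cell imaging of each organ.  ``floor`` truncates draws at a small
    positive value (the distributions make non-positive draws astronomically
    unlikely, but tau must stay > 0).
    """

    cotyledon: float = 0.059
    hypocotyl: float = 0.028
    root: float = 0.073
    root_tip: float = 0.089
    floor: float = 0.05

    def __post_init__(self) -> None:
        for r in REGIONS:
            if getattr(self, r) < 0:
                raise ValueError(f"tau SD for {r} must be >= 0")

    def sd(self, region: str) -> float:
        return getattr(self, region)

    @classmethod
    def zero(cls) -> "RegionNoiseSpec":
        """No cell-to-cell variability: every tau = 1."""
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TemplateGeometry:
    """Block dimensions of the default seedling layout (cells)."""

    cotyledon_w: int = 10
    cotyledon_h: int = 15
    hypocotyl_w: int = 5
    hypocotyl_h: int = 20
    root_h: int = 70
    root_tip_h: int = 10

    def __post_init__(self) -> None:
        for f in ("cotyledon_w", "cotyledon_h", "hypocotyl_w", "hypocotyl_h",
                  "root_h", "root_tip_h"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.cotyledon_h > self.hypocotyl_h + self.root_h:
            raise ValueError("cotyledon blocks must attach along the hypocotyl")


@dataclass
class SeedlingTemplate:
    """Cell lattice with region labels, light sensitivities and tau values.

    Arrays are indexed by stable cell id (creation order; growth appends).
    """

    col: np.ndarray           # (N,) int
    row: np.ndarray           # (N,) int
    region: np.ndarray        # (N,) unicode, one of REGIONS
    L_sens: np.ndarray        # (N,) float
    tau: np.ndarray           # (N,) float, 1.0 until assigned
    geometry: TemplateGeometry = field(default_factory=TemplateGeometry)

    # -- basic views ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.col)

    def region_mask(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return self.region == region

    @property
    def hypocotyl_cells(self) -> np.ndarray:
        """Cell ids of the long-distance coupling source set R."""
        return np.flatnonzero(self.region_mask("hypocotyl"))

    @property
    def root_tip_cells(self) -> np.ndarray:
        return np.flatnonzero(self.region_mask("root_tip"))

    # -- neighbourhoods ---------------------------------------------------
    def neighbor_lists(self, mode: Literal["4", "8", "global"] = "4") -> list[np.ndarray]:
        """Neighbour ids per cell; mode "global" returns all cells (incl. self)."""
        n = self.n_cells
        if mode == "global":
            everyone = np.arange(n)
            return [everyone] * n
        if mode == "4":
            offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        elif mode == "8":
            offsets = [(-1, 0), (1, 0), (0, -1), (0, 1),
                       (-1, -1), (-1, 1), (1, -1), (1, 1)]
        else:
            raise ValueError(f"unknown neighborhood mode {mode!r}")
        index = {(c, r): i for i, (c, r) in enumerate(zip(self.col, self.row))}
        out = []
        for c, r in zip(self.col, self.row):
            ids = [index[(c + dc, r + dr)] for dc, dr in offsets
                   if (c + dc, r + dr) in index]
            out.append(np.asarray(ids, dtype=int))
        return out

    def averaging_matrix(self, mode: Literal["4", "8", "global"] = "4"):
        """Sparse matrix A with A @ x = neighbour-mean of x.

        Boundary cells average over their existing neighbours only; in
        "global" mode the mean runs over all N cells including self.
        """
        from scipy import sparse

        nbrs = self.neighbor_lists(mode)
        rows, cols, vals = [], [], []
        for i, ids in enumerate(nbrs):
            if len(ids) == 0:
                continue
            rows.extend([i] * len(ids))
            cols.extend(ids.tolist())
            vals.extend([1.0 / len(ids)] * len(ids))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_cells, self.n_cells)
        )

    # -- serialization ----------------------------------------------------
    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "col": self.col,
                "row": self.row,
                "region": self.region,
                "L_sens": self.L_sens,
                "tau": self.tau,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeedlingTemplate":
        import pandas as pd

        df = pd.read_csv(path).sort_values("cell_id")
        return cls(
            col=df["col"].to_numpy(int),
            row=df["row"].to_numpy(int),
            region=df["region"].to_numpy(str),
            L_sens=df["L_sens"].to_numpy(float),
            tau=df["tau"].to_numpy(float),
        )

    def copy(self) -> "SeedlingTemplate":
        return SeedlingTemplate(
            col=self.col.copy(), row=self.row.copy(), region=self.region.copy(),
            L_sens=self.L_sens.copy(), tau=self.tau.copy(), geometry=self.geometry,
        )


def build_template(
    geometry: TemplateGeometry | None = None,
    l_sens: dict[str, float] | None = None,
) -> SeedlingTemplate:
    """Construct the seedling lattice with region labels and L_sens values.

    Raises if the configured blocks do not form a 4-connected lattice.
    """
    g = geometry or TemplateGeometry()
    ls = dict(DEFAULT_L_SENS)
    if l_sens:
        unknown = set(l_sens) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region(s) in l_sens: {sorted(unknown)}")
        ls.update(l_sens)

    cols, rows, regions = [], [], []

    def block(c0, c1, r0, r1, region):
        for r in range(r0, r1):
            for c in range(c0, c1):
                cols.append(c)
                rows.append(r)
                regions.append(region)

    cw, hw = g.cotyledon_w, g.hypocotyl_w
    block(cw, cw + hw, 0, g.hypocotyl_h, "hypocotyl")
    block(0, cw, 0, g.cotyledon_h, "cotyledon")                    # left
    block(cw + hw, 2 * cw + hw, 0, g.cotyledon_h, "cotyledon")     # right
    r0 = g.hypocotyl_h
    block(cw, cw + hw, r0, r0 + g.root_h, "root")
    block(cw, cw + hw, r0 + g.root_h, r0 + g.root_h + g.root_tip_h, "root_tip")

    region = np.asarray(regions)
    tpl = SeedlingTemplate(
        col=np.asarray(cols, dtype=int),
        row=np.asarray(rows, dtype=int),
        region=region,
        L_sens=np.array([ls[r] for r in regions]),
        tau=np.ones(len(cols)),
        geometry=g,
    )
    _check_contiguous(tpl)
    return tpl


def _check_contiguous(tpl: SeedlingTemplate) -> None:
    nbrs = tpl.neighbor_lists("4")
    seen = np.zeros(tpl.n_cells, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in nbrs[i]:
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    if not seen.all():
        raise ValueError("template geometry is not 4-connected")


def assign_tau(
    template: SeedlingTemplate,
    noise_spec: RegionNoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> SeedlingTemplate:
    """Draw one tau per cell from its region's N(1, SD), held fixed thereafter.

    A zero-SD spec (``RegionNoiseSpec.zero()``) gives tau = 1 everywhere.
    """
    spec = noise_spec or RegionNoiseSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = template.copy()
    tau = np.ones(out.n_cells)
    for region in REGIONS:  # fixed order keeps draws order-independent
        mask = out.region_mask(region)
        sd = spec.sd(region)
        if sd > 0:
            tau[mask] = rng.normal(1.0, sd, int(mask.sum()))
        else:
            tau[mask] = 1.0
    out.tau = np.maximum(tau, spec.floor)
    return out


@dataclass(frozen=True)
class GrowthEvent:
    """Bookkeeping of one 24-h growth step."""

    new_cell_ids: np.ndarray       # ids of the appended root-tip row
    source_cell_ids: np.ndarray    # adjacent interior cells whose state seeds them
    relabeled_cell_ids: np.ndarray # former uppermost root-tip row, now root


def grow(
    template: SeedlingTemplate,
    noise_spec: RegionNoiseSpec | None = None,
    rng: np.random.Generator | int = 0,
    root_l_sens: float | None = None,
    tip_l_sens: float | None = None,
) -> tuple[SeedlingTemplate, GrowthEvent]:
    """Append one row of root-tip cells and relabel the uppermost tip row.

    New cells draw fresh tau values from the root-tip distribution; the
    relabelled cells keep their tau (only their region and light sensitivity
    change).  Returns the grown template and the bookkeeping event.
    """
    spec = noise_spec or RegionNoiseSpec()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tip = template.root_tip_cells
    if len(tip) == 0:
        raise ValueError("template has no root-tip cells")
    tip_rows = template.row[tip]
    top_row, bottom_row = tip_rows.min(), tip_rows.max()
    relabeled = tip[tip_rows == top_row]
    source = np.flatnonzero(template.row == bottom_row)
    source = source[np.argsort(template.col[source])]

    if root_l_sens is None:
        root_mask = template.region_mask("root")
        root_l_sens = (
            float(template.L_sens[root_mask][0]) if root_mask.any()
            else DEFAULT_L_SENS["root"]
        )
    if tip_l_sens is None:
        tip_l_sens = float(template.L_sens[tip[0]])

    n_new = len(source)
    new_ids = template.n_cells + np.arange(n_new)
    sd = spec.sd("root_tip")
    new_tau = (
        np.maximum(rng.normal(1.0, sd, n_new), spec.floor) if sd > 0
        else np.ones(n_new)
    )

    out = SeedlingTemplate(
        col=np.concatenate([template.col, template.col[source]]),
        row=np.concatenate([template.row, np.full(n_new, bottom_row + 1)]),
        region=np.concatenate([template.region, np.full(n_new, "root_tip")]),
        L_sens=np.concatenate([template.L_sens, np.full(n_new, tip_l_sens)]),
        tau=np.concatenate([template.tau, new_tau]),
        geometry=template.geometry,
    )
    out.region[relabeled] = "root"
    out.L_sens[relabeled] = root_l_sens
    return out, GrowthEvent(
        new_cell_ids=new_ids,
        source_cell_ids=source,
        relabeled_cell_ids=relabeled,
    )
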