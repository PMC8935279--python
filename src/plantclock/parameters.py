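"""Parameter table for the compact Arabidopsis clock network.

The network lumps the core clock genes into four mRNA/protein pairs --
CL (CCA1/LHY), P97 (PRR9/PRR7), P51 (PRR5/TOC1), EL (ELF4/LUX) -- plus the
hypothetical dark-accumulating protein P that mediates acute light activation
at dawn.  The table holds the network's 34 named reaction rates and
repression scaling constants plus the protein-P rate constant ``q``, which is
structurally fixed at 0.3 h^-1 (it appears as a literal in the P equation and
is never a free fitting parameter; sensitivity analyses perturb the 34 named
constants only).

Naming convention (units):

* ``v*``  transcription rates (conc. h^-1)
* ``k*``  mRNA degradation rates (h^-1); ``k1L``/``k1D`` are the light/dark
  CL-mRNA rates
* ``p*``  translation rates (h^-1)
* ``d*``  protein degradation rates (h^-1); ``*L``/``*D`` suffixes select the
  light/dark rate
* ``K*``  repression scaling constants (conc.)
* ``q``   protein-P production/decay rate constant (h^-1), fixed at 0.3
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "ClockParameters",
    "PARAM_NAMES",
    "DE_CALUWE_2016",
    "DEFAULT_PARAMS",
    "load_parameters",
    "save_parameters",
]


@dataclass(frozen=True)
class ClockParameters:
    """The 34 rate and scaling constants of the clock network.

    All values must be strictly positive and finite, and the dark degradation
    rate of the P51 (PRR5/TOC1) protein must exceed its light rate
    (``d3D > d3L``): degradation of both PRR5 and TOC1 is higher in darkness.
    """

    # transcription
    v1: float
    v1L: float
    v2A: float
    v2L: float
    v3: float
    v4: float
    # mRNA degradation
    k1L: float
    k1D: float
    k2: float
    k3: float
    k4: float
    # translation
    p1: float
    p1L: float
    p2: float
    p3: float
    p4: float
    # protein degradation
    d1: float
    d2D: float
    d2L: float
    d3D: float
    d3L: float
    d4D: float
    d4L: float
    # repression scaling constants
    K0: float
    K1: float
    K2: float
    K4: float
    K5: float
    K5b: float
    K6: float
    K7: float
    K8: float
    K9: float
    K10: float
    # protein-P rate constant: structurally fixed, carried for sensitivity work
    q: float = 0.3

    def __post_init__(self) -> None:
        import math

        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v!r}")
        if not self.d3L < self.d3D:
            raise ValueError(
                f"d3L must be < d3D (dark-enhanced P51 degradation); "
                f"got d3L={self.d3L}, d3D={self.d3D}"
            )

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def with_updates(self, **kwargs: float) -> "ClockParameters":
        return replace(self, **kwargs)

    def to_array(self) -> "list[float]":
        return [getattr(self, n) for n in PARAM_NAMES]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ClockParameters":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ClockParameters))


#: Base values of the original compact clock model (De Caluwé et al., 2016,
#: Front. Plant Sci. 7:74).  In the original network CL *activates* P97 and CL
#: does not repress itself, so K0 and K5b do not exist there; they are seeded
#: at neutral magnitudes here.  The packaged default table re-derives K0, K4,
#: K5, K5b, d3L and the P51-loop constants K6, K7, k3 by calibrating against
#: the revised model's reference single-cell behaviour (see
#: :func:`plantclock.fitting.calibrate_reference`).
DE_CALUWE_2016: ClockParameters = ClockParameters(
    v1=4.58, v1L=3.0, v2A=1.27, v2L=5.0, v3=1.0, v4=1.47,
    k1L=0.53, k1D=0.21, k2=0.35, k3=0.56, k4=0.57,
    p1=0.76, p1L=0.42, p2=1.01, p3=0.64, p4=1.01,
    d1=0.68, d2D=0.5, d2L=0.29, d3D=0.48, d3L=0.38, d4D=1.21, d4L=0.38,
    K0=1.0, K1=0.16, K2=1.18, K4=0.28, K5=0.57, K5b=1.0,
    K6=0.46, K7=2.0, K8=0.36, K9=1.9, K10=1.9,
)


def load_parameters(path: str | Path) -> ClockParameters:
    """Read a parameter table from a flat JSON or CSV key-value file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
    else:
        data = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(",")
            if key.strip().lower() in {"name", "parameter"}:
                continue  # header row
            data[key.strip()] = float(value)
    return ClockParameters.from_mapping(data)


def save_parameters(params: ClockParameters, path: str | Path) -> None:
    """Write a parameter table as flat JSON or CSV, chosen by file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(params.as_dict(), indent=1) + "\n")
    else:
        lines = ["name,value"] + [f"{k},{v!r}" for k, v in params]
        path.write_text("\n".join(lines) + "\n")


def _load_default() -> ClockParameters:
    """The packaged default: base table plus the five re-derived constants."""
    table = Path(__file__).with_name("data") / "default_parameters.json"
    if table.exists():
        return load_parameters(table)
    return DE_CALUWE_2016


DEFAULT_PARAMS: ClockParameters = _load_default()
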