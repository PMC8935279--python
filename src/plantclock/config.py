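"""Run configuration: a serializable description of one simulation setup.

A config file (YAML or JSON) has up to six sections -- ``geometry``,
``l_sens``, ``noise``, ``coupling``, ``protocol`` and ``run`` -- each holding
flat key-value pairs.  Missing sections and keys fall back to the reference
defaults (the 800-cell template, region light sensitivities 1.6 / 1.0 /
0.65 / 0.95, region tau SDs, CL-mRNA coupling with J_local = 2, and a
4-day 12:12 LD entrainment followed by 6 days of LL); unknown keys are
rejected by name.  ``load_config(dump_config(cfg)) == cfg`` round-trips.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .light import LightProtocol
from .model import STATE_NAMES
from .spatial import CouplingConfig
from .template import DEFAULT_L_SENS, RegionNoiseSpec, TemplateGeometry

__all__ = ["RunConfig", "load_config", "dump_config"]


def _default_protocol() -> LightProtocol:
    return LightProtocol(
        "LD_ideal", entrain_days=4, release_kind="LL", release_days=6
    )


@dataclass(frozen=True)
class RunConfig:
    geometry: TemplateGeometry = field(default_factory=TemplateGeometry)
    l_sens: tuple[tuple[str, float], ...] = tuple(sorted(DEFAULT_L_SENS.items()))
    noise: RegionNoiseSpec = field(default_factory=RegionNoiseSpec)
    coupling: CouplingConfig = field(default_factory=lambda: CouplingConfig(J_local=2.0))
    protocol: LightProtocol = field(default_factory=_default_protocol)
    output_dt: float = 0.1
    dt_max: float = 0.1
    seed: int = 0
    replicates: int = 9
    record: tuple[str, ...] = ("cP97m",)
    growth: bool = True

    @property
    def l_sens_map(self) -> dict[str, float]:
        return dict(self.l_sens)


_RUN_KEYS = ("output_dt", "dt_max", "seed", "replicates", "record", "growth")


def _build(section: str, cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    return cls(**data)


def _from_dict(data: dict) -> RunConfig:
    unknown = set(data) - {"geometry", "l_sens", "noise", "coupling",
                           "protocol", "run"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kw: dict = {}
    if "geometry" in data:
        kw["geometry"] = _build("geometry", TemplateGeometry, data["geometry"])
    if "l_sens" in data:
        ls = dict(DEFAULT_L_SENS)
        unknown_r = set(data["l_sens"]) - set(ls)
        if unknown_r:
            raise ValueError(
                f"unknown region(s) in section 'l_sens': {sorted(unknown_r)}"
            )
        ls.update({k: float(v) for k, v in data["l_sens"].items()})
        kw["l_sens"] = tuple(sorted(ls.items()))
    if "noise" in data:
        kw["noise"] = _build("noise", RegionNoiseSpec, data["noise"])
    if "coupling" in data:
        kw["coupling"] = _build("coupling", CouplingConfig, data["coupling"])
    if "protocol" in data:
        kw["protocol"] = _build("protocol", LightProtocol, data["protocol"])
    run = data.get("run", {})
    unknown_k = set(run) - set(_RUN_KEYS)
    if unknown_k:
        raise ValueError(f"unknown key(s) in section 'run': {sorted(unknown_k)}")
    for k in _RUN_KEYS:
        if k in run:
            kw[k] = tuple(run[k]) if k == "record" else run[k]
    if "record" in kw:
        bad = set(kw["record"]) - set(STATE_NAMES)
        if bad:
            raise ValueError(f"unknown record variable(s): {sorted(bad)}")
    return RunConfig(**kw)


def load_config(path_or_dict) -> RunConfig:
    """Read a RunConfig from YAML/JSON (by suffix) or from a plain dict.

    An empty file or empty dict yields the full reference default run.
    """
    if isinstance(path_or_dict, dict):
        return _from_dict(path_or_dict)
    path = Path(path_or_dict)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text) or {}
    else:
        data = json.loads(text) if text.strip() else {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping of sections")
    return _from_dict(data)


def dump_config(config: RunConfig, path: str | Path | None = None) -> dict:
    """Resolved config as a plain dict; optionally written to YAML/JSON."""
    data = {
        "geometry": dataclasses.asdict(config.geometry),
        "l_sens": config.l_sens_map,
        "noise": dataclasses.asdict(config.noise),
        "coupling": dataclasses.asdict(config.coupling),
        "protocol": dataclasses.asdict(config.protocol),
        "run": {
            "output_dt": config.output_dt,
            "dt_max": config.dt_max,
            "seed": config.seed,
            "replicates": config.replicates,
            "record": list(config.record),
            "growth": config.growth,
        },
    }
    if path is not None:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=1) + "\n")
    return data
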