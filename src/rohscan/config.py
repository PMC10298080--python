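"""Run configuration: every pipeline knob in one serializable object.

Round-trips losslessly through TOML; command-line flags override file
values.
"""

from __future__ import annotations

import dataclasses
import os
import tomllib
from dataclasses import dataclass, field

from .caller import CallerParams


@dataclass
class RunConfig:
    vcf: str | None = None
    samples: str | None = None
    autosomes: str | None = None
    genes: str | None = None
    out_dir: str = "rohscan_out"
    chroms: list[str] = field(default_factory=list)
    population: str | None = None
    caller: CallerParams = field(default_factory=CallerParams)
    top_fraction: float = 0.01
    merge_gap_bp: int = 1_000_000
    coverage_method: str = "mean"
    scientific_floats: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        caller = d.pop("caller", {})
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.caller = CallerParams(**caller)
        return cfg

    @classmethod
    def from_toml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(_dump_toml(self.to_dict()))

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with non-None keyword values replacing fields
        (caller parameters addressed as ``caller__<name>``)."""
        cfg = dataclasses.replace(self)
        caller_kwargs = {}
        for key, value in kwargs.items():
            if value is None:
                continue
            if key.startswith("caller__"):
                caller_kwargs[key[len("caller__"):]] = value
            else:
                setattr(cfg, key, value)
        if caller_kwargs:
            cfg.caller = dataclasses.replace(cfg.caller, **caller_kwargs)
        return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def _dump_toml(d: dict) -> str:
    lines: list[str] = []
    tables: list[tuple[str, dict]] = []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        elif v is not None:
            lines.append(f"{k} = {_toml_value(v)}")
    for name, sub in tables:
        lines.append("")
        lines.append(f"[{name}]")
        for k, v in sub.items():
            if v is not None:
                lines.append(f"{k} = {_toml_value(v)}")
    return "\n".join(lines) + "\n"
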