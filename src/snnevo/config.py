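"""Flat plain-text run configuration.

A run is fully described by a flat ``key = value`` text file (one pair per
line, ``#`` comments allowed), in the style of classic EA parameter files.
Unknown keys are errors and are reported with their line number, so typos
cannot silently fall back to defaults.  A run can be reconstructed from its
saved resolved config alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

from .evolution import EAConfig
from .experiment import ProtocolConfig
from .network import PARAM_RANGES
from .simulator import SimConfig
from .stimulus import GratingConfig

__all__ = ["RunConfig", "ConfigError", "parse_config", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Malformed configuration text."""


@dataclass(frozen=True)
class RunConfig:
    """Merged EA + protocol + simulation settings for one tuning run."""

    grid_size: int = 8
    seed: int = 0
    preset: str = "full"  # one of: full, desk, micro (protocol preset)
    ea: EAConfig = EAConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    sim: SimConfig = SimConfig()
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(PARAM_RANGES))


_PRESETS = {
    "full": ProtocolConfig,
    "desk": ProtocolConfig.desk,
    "micro": ProtocolConfig.micro,
}

# key -> (section object name, field name, type)
_INT = int
_FLOAT = float


def _schema() -> dict[str, tuple[str, str, type]]:
    table: dict[str, tuple[str, str, type]] = {
        "grid_size": ("", "grid_size", _INT),
        "seed": ("", "seed", _INT),
        "preset": ("", "preset", str),
    }
    for f in fields(EAConfig):
        typ = _FLOAT if f.type == "float" else _INT
        table[f"ea.{f.name}"] = ("ea", f.name, typ)
    for f in fields(ProtocolConfig):
        if f.name == "grating":
            continue
        typ = _FLOAT if f.type == "float" else _INT
        table[f"protocol.{f.name}"] = ("protocol", f.name, typ)
    for f in fields(GratingConfig):
        table[f"grating.{f.name}"] = ("grating", f.name, _FLOAT)
    for f in fields(SimConfig):
        typ = _INT if f.type == "int" else _FLOAT
        table[f"sim.{f.name}"] = ("sim", f.name, typ)
    for name in PARAM_RANGES:
        table[f"range.{name}"] = ("ranges", name, str)
    return table


def parse_config(text: str, base: RunConfig | None = None) -> RunConfig:
    """Parse ``key = value`` text into a RunConfig over defaults.

    Raises :class:`ConfigError` naming the offending line for unknown keys,
    missing '=' separators, or unparsable values.
    """
    schema = _schema()
    cfg = base or RunConfig()
    scalars: dict[str, object] = {}
    sections: dict[str, dict[str, object]] = {"ea": {}, "protocol": {}, "grating": {}, "sim": {}}
    ranges = dict(cfg.ranges)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key not in schema:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        section, name, typ = schema[key]
        try:
            if section == "ranges":
                lo, hi = (float(v) for v in value.split(","))
                if hi < lo:
                    raise ValueError("upper bound below lower bound")
                ranges[name] = (lo, hi)
            elif typ is str:
                scalars[name] = value
            else:
                parsed = typ(value)
                (scalars if section == "" else sections[section])[name] = parsed
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"line {lineno}: bad value for {key!r}: {exc}") from exc

    preset = scalars.get("preset", cfg.preset)
    if preset not in _PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    protocol = _PRESETS[preset]() if "preset" in scalars else cfg.protocol
    if sections["protocol"]:
        protocol = replace(protocol, **sections["protocol"])
    if sections["grating"]:
        protocol = replace(protocol, grating=replace(protocol.grating, **sections["grating"]))
    ea = replace(cfg.ea, **sections["ea"]) if sections["ea"] else cfg.ea
    sim = replace(cfg.sim, **sections["sim"]) if sections["sim"] else cfg.sim
    if "seed" in scalars:
        ea = replace(ea, seed=int(scalars["seed"]))
    return RunConfig(
        grid_size=int(scalars.get("grid_size", cfg.grid_size)),
        seed=int(scalars.get("seed", cfg.seed)),
        preset=str(preset),
        ea=ea,
        protocol=protocol,
        sim=sim,
        ranges=ranges,
    )


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return parse_config(fh.read())


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to the flat text form (round-trips)."""
    lines = [
        f"grid_size = {cfg.grid_size}",
        f"seed = {cfg.seed}",
        f"preset = {cfg.preset}",
    ]
    for f in fields(EAConfig):
        lines.append(f"ea.{f.name} = {getattr(cfg.ea, f.name)}")
    for f in fields(ProtocolConfig):
        if f.name == "grating":
            continue
        lines.append(f"protocol.{f.name} = {getattr(cfg.protocol, f.name)}")
    for f in fields(GratingConfig):
        lines.append(f"grating.{f.name} = {getattr(cfg.protocol.grating, f.name)}")
    for f in fields(SimConfig):
        lines.append(f"sim.{f.name} = {getattr(cfg.sim, f.name)}")
    for name, (lo, hi) in cfg.ranges.items():
        lines.append(f"range.{name} = {lo},{hi}")
    return "\n".join(lines) + "\n"
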