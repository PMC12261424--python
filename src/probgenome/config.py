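"""Flat dotted-key run configuration: defaults <- file <- flags.

The config file format is plain text, one ``section.key = value`` per
line, ``#`` comments allowed. Every resolved value is echoed to the log
before execution and unknown keys are rejected, so typos fail loudly
instead of silently using a default.
"""

from __future__ import annotations

import logging
from dataclasses import fields
from pathlib import Path
from typing import Any

from .downstream import FinetuneConfig
from .masking import MaskingPolicy
from .model.encoder import ModelConfig, RopeConfig
from .simulate import SimConfig
from .train import TrainConfig

log = logging.getLogger(__name__)

_SECTIONS = {
    "model": ModelConfig,
    "rope": RopeConfig,
    "masking": MaskingPolicy,
    "train": TrainConfig,
    "finetune": FinetuneConfig,
    "sim": SimConfig,
}


def default_config() -> dict[str, Any]:
    """All tunable keys with their package defaults, as dotted names."""
    out: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        instance = cls()
        for f in fields(cls):
            out[f"{section}.{f.name}"] = getattr(instance, f.name)
    return out


def _coerce(raw: str, template: Any) -> Any:
    raw = raw.strip()
    if isinstance(template, bool):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    if isinstance(template, int) and not isinstance(template, bool):
        return int(raw)
    if isinstance(template, float):
        return float(raw)
    if isinstance(template, tuple) or template is None and "," in raw:
        parts = [p.strip() for p in raw.split(",") if p.strip()]
        if isinstance(template, tuple) and template and isinstance(
                template[0], float):
            return tuple(float(p) for p in parts)
        if isinstance(template, tuple) and template and isinstance(
                template[0], int):
            return tuple(int(p) for p in parts)
        return tuple(parts)
    if template is None:
        # optional numeric fields (e.g. warmup override)
        try:
            return int(raw)
        except ValueError:
            try:
                return float(raw)
            except ValueError:
                return raw
    return raw


def parse_config_file(path: str | Path) -> dict[str, str]:
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = stripped.split("=", 1)
        values[key.strip()] = raw.strip()
    return values


def resolve_config(config_file: str | Path | None = None,
                   overrides: dict[str, str] | None = None
                   ) -> dict[str, Any]:
    """Merge defaults, an optional config file, and flag overrides, in
    that precedence order; reject unknown keys; echo the result."""
    resolved = default_config()
    layers: list[dict[str, str]] = []
    if config_file is not None:
        layers.append(parse_config_file(config_file))
    if overrides:
        layers.append(dict(overrides))
    for layer in layers:
        for key, raw in layer.items():
            if key not in resolved:
                raise KeyError(f"unknown config key: {key}")
            resolved[key] = _coerce(str(raw), resolved[key])
    for key in sorted(resolved):
        log.info("config %s = %r", key, resolved[key])
    return resolved


def section(resolved: dict[str, Any], name: str):
    """Instantiate one section's dataclass from a resolved config."""
    cls = _SECTIONS[name]
    prefix = name + "."
    kwargs = {k[len(prefix):]: v for k, v in resolved.items()
              if k.startswith(prefix)}
    return cls(**kwargs)


def dump_defaults() -> str:
    lines = []
    for key, value in default_config().items():
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"
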