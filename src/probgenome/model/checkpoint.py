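"""Checkpoint container: config + weights + optional training state.

Layout: a NumPy .npz archive holding a JSON header (model and rotary
config, format version, step counter) plus one array per named parameter
and, when saved mid-training, the optimizer moments. Resumption restores
bit-identical training state on the same thread count.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from ..exceptions import FormatVersionError
from .encoder import ModelConfig, ProbEncoder, RopeConfig
from .optim import AdamW

_VERSION = 1


def save_checkpoint(path: str | Path, model: ProbEncoder,
                    optimizer: AdamW | None = None, step: int = 0) -> None:
    header = {
        "format": "probgenome-checkpoint",
        "version": _VERSION,
        "step": step,
        "model_config": asdict(model.config),
        "rope_config": asdict(model.rope),
    }
    arrays = {f"param/{name}": p.value
              for name, p in model.named_parameters().items()}
    if optimizer is not None:
        state = optimizer.state_dict()
        header["optimizer_t"] = state["t"]
        for i, (m, v) in enumerate(zip(state["m"], state["v"])):
            arrays[f"opt_m/{i}"] = m
            arrays[f"opt_v/{i}"] = v
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path,
                    optimizer: AdamW | None = None
                    ) -> tuple[ProbEncoder, int]:
    """Rebuild the model (and optionally refill an optimizer's state);
    returns (model, step)."""
    with np.load(path) as data:
        if "header" not in data:
            raise FormatVersionError(f"{path} is not a checkpoint")
        header = json.loads(bytes(data["header"]).decode())
        if header.get("format") != "probgenome-checkpoint":
            raise FormatVersionError(f"{path} is not a checkpoint")
        if header.get("version") != _VERSION:
            raise FormatVersionError(
                f"unsupported checkpoint version {header.get('version')}")
        model = ProbEncoder(ModelConfig(**header["model_config"]),
                            RopeConfig(**header["rope_config"]))
        named = model.named_parameters()
        for key in data.files:
            if key.startswith("param/"):
                name = key[len("param/"):]
                if name not in named:
                    raise FormatVersionError(
                        f"checkpoint parameter {name!r} not in model")
                named[name].value[...] = data[key]
        if optimizer is not None and "optimizer_t" in header:
            n = len(optimizer.params)
            optimizer.load_state_dict({
                "t": header["optimizer_t"],
                "m": [data[f"opt_m/{i}"] for i in range(n)],
                "v": [data[f"opt_v/{i}"] for i in range(n)],
            })
        return model, int(header["step"])
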