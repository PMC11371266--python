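"""Image/array I/O, run configuration and checkpoint serialization.

Conventions: images are row-major with the origin at the top-left; loaded
integer images are scaled to floats in [0, 1] (8-bit by 255, 16-bit by
65535); solvers and metrics run in double precision throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import yaml

from .masks import MMRMaskGenerator, SAFIMaskGenerator
from .operators import ConvOperator

__all__ = [
    "load_image",
    "save_image",
    "load_npz",
    "save_npz",
    "load_config",
    "RunConfig",
    "save_checkpoint",
    "load_checkpoint",
    "write_run_log",
]


def load_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF/NPY image as floats in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        return np.asarray(np.load(path), dtype=np.float64)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    raise ValueError(f"unsupported bit depth: {arr.dtype}")


def save_image(path, x: np.ndarray) -> None:
    """Write an image; PNG as rounded 8-bit, NPY/TIFF as float64."""
    path = Path(path)
    x = np.asarray(x, dtype=np.float64)
    if path.suffix.lower() == ".npy":
        np.save(path, x)
        return
    if path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, x.astype(np.float32))
        return
    iio.imwrite(path, np.round(np.clip(x, 0.0, 1.0) * 255.0).astype(np.uint8))


def load_npz(path) -> dict:
    with np.load(path, allow_pickle=False) as f:
        return {k: f[k] for k in f.files}


def save_npz(path, **arrays) -> None:
    np.savez(path, **arrays)


@dataclass
class RunConfig:
    """Validated reconstruction-run configuration."""

    scheme: str = "mmr"                 # mmr | safi | l1
    checkpoint: Optional[str] = None
    forward_model: dict = field(default_factory=lambda: {"kind": "identity"})
    lam: Optional[float] = None         # override the checkpoint value
    K_out: int = 10
    eps_out: float = 1e-6
    tolerance_mode: Optional[str] = None
    output: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        for key in data:
            if key not in known:
                raise ValueError(f"unknown configuration key: {key!r}")
        cfg = cls(**data)
        if cfg.scheme not in ("mmr", "safi", "l1"):
            raise ValueError(f"invalid value for key 'scheme': {cfg.scheme!r}")
        if cfg.checkpoint is not None and not Path(cfg.checkpoint).exists():
            raise ValueError(f"invalid value for key 'checkpoint': file not found")
        if not isinstance(cfg.forward_model, dict) or "kind" not in cfg.forward_model:
            raise ValueError("invalid value for key 'forward_model': needs a 'kind'")
        return cfg


def load_config(path) -> RunConfig:
    """Read a YAML/JSON run configuration, validating every key."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# model checkpoints (NPZ archive + JSON metadata block)
# ---------------------------------------------------------------------------

def _conv_meta(op: ConvOperator) -> dict:
    return {"in_channels": op.in_channels, "out_channels": op.out_channels,
            "groups": op.groups, "constraint": op.constraint, "padding": op.padding,
            "n_layers": op.n_layers}


def save_checkpoint(path, gen, metadata: Optional[dict] = None) -> None:
    """Serialize a mask generator (MMR or SAFI) with its lam and metadata."""
    from ._ad import val

    arrays: dict = {"lam": np.asarray(float(val(gen.lam)))}
    meta = {"scheme": gen.scheme, "convs": {}, "extra": metadata or {}}
    conv_names = (("W", "B") if gen.scheme == "mmr" else ("W", "Wt", "Bt", "Bh"))
    for name in conv_names:
        op: ConvOperator = getattr(gen, name)
        meta["convs"][name] = _conv_meta(op)
        for i, k in enumerate(op.kernels):
            arrays[f"{name}_k{i}"] = np.asarray(val(k))
    if gen.scheme == "mmr":
        arrays["sigma_knots"] = np.asarray(val(gen.sigma_knots))
        arrays["r"] = np.asarray(val(gen.r))
        meta["delta"] = gen.delta
    else:
        for name in ("phi1", "phi2", "phi3"):
            arrays[name] = np.asarray(val(getattr(gen, name)))
        meta["M"] = gen.M
        meta["delta"] = gen.delta
    arrays["metadata_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _load_conv(arrays: dict, name: str, meta: dict) -> ConvOperator:
    m = meta["convs"][name]
    kernels = [arrays[f"{name}_k{i}"] for i in range(m["n_layers"])]
    return ConvOperator(kernels, m["in_channels"], m["out_channels"],
                        m["groups"], m["constraint"], m["padding"])


def load_checkpoint(path):
    """Load a generator checkpoint; constraints are re-projected on load."""
    arrays = load_npz(path)
    meta = json.loads(bytes(arrays["metadata_json"]).decode())
    lam = float(arrays["lam"])
    if meta["scheme"] == "mmr":
        gen = MMRMaskGenerator(_load_conv(arrays, "W", meta), _load_conv(arrays, "B", meta),
                               arrays["sigma_knots"], arrays["r"],
                               delta=float(meta["delta"]), lam=lam)
    else:
        gen = SAFIMaskGenerator(_load_conv(arrays, "W", meta), _load_conv(arrays, "Wt", meta),
                                _load_conv(arrays, "Bt", meta), _load_conv(arrays, "Bh", meta),
                                arrays["phi1"], arrays["phi2"], arrays["phi3"],
                                M=int(meta["M"]), delta=float(meta["delta"]), lam=lam)
    gen.project()
    return gen, meta["extra"]


def write_run_log(path, config: dict, seed: int, trace=None, metrics: Optional[dict] = None) -> None:
    """JSON log with the resolved configuration, seed, trace and metrics."""
    log = {"config": config, "seed": seed}
    if trace is not None:
        log["trace"] = trace.as_dict() if hasattr(trace, "as_dict") else trace
    if metrics:
        log["metrics"] = {k: (float(v) if np.isscalar(v) else v) for k, v in metrics.items()}
    Path(path).write_text(json.dumps(log, indent=2, allow_nan=True))
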