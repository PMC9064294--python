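"""TIFF/CSV input-output, run configuration, and reproducibility scaffolding.

Images travel as multi-page TIFF with a YAML sidecar carrying the physical
metadata (pixel size, frame interval, seed) that TIFF itself does not store
reliably; tables travel as CSV. A run is described by a single flat config
mapping; all distances in configs are physical (µm) and converted through
the pixel size, so results are magnification-independent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .preprocess import ImageStack

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "validate_config",
    "config_hash",
    "KNOWN_CONFIG_KEYS",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_image_stack(stack: ImageStack, path, seed: int | None = None
                      ) -> Path:
    """Write a stack as multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "pixel_size_um": float(stack.pixel_size),
        "frame_interval_s": float(stack.frame_interval),
        "z_step_um": None if stack.z_step is None else float(stack.z_step),
        "channel_name": stack.channel_name,
        "seed": seed,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_image_stack(path, metadata_overrides: dict | None = None
                     ) -> ImageStack:
    """Read a TIFF stack; metadata comes from the sidecar unless overridden.

    Pixel values are preserved exactly. A missing pixel size (no sidecar and
    no override) is an error rather than a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    overrides = dict(metadata_overrides or {})
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    pixel_size = overrides.get("pixel_size", meta.get("pixel_size_um"))
    if pixel_size is None:
        raise ValueError(
            f"{path}: pixel size unknown; provide metadata_overrides="
            "{'pixel_size': ...} or a sidecar file")
    frame_interval = overrides.get("frame_interval",
                                   meta.get("frame_interval_s", 0.0))
    return ImageStack(data=np.asarray(data, dtype=float),
                      pixel_size=float(pixel_size),
                      frame_interval=float(frame_interval or 0.0),
                      z_step=overrides.get("z_step", meta.get("z_step_um")),
                      channel_name=overrides.get(
                          "channel_name", meta.get("channel_name", "") or ""))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

KNOWN_CONFIG_KEYS = {
    "movie_path": str,
    "reference_path": str,
    "pixel_size": float,          # µm/px
    "frame_interval": float,      # s
    "output_dir": str,
    "rng_seed": int,
    "rolling_ball_radius_px": float,
    "bleach_correct": bool,
    "simulate": dict,             # SimulationConfig field overrides
    "patches": dict,              # detection/tracking parameters
    "frap": dict,                 # FRAP protocol parameters
}

_POSITIVE_KEYS = ("pixel_size", "frame_interval", "rolling_ball_radius_px")


def validate_config(config: dict) -> list[str]:
    """Validate a run config, returning *all* violations (empty when valid)."""
    errors: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    for key in config:
        if key not in KNOWN_CONFIG_KEYS:
            errors.append(f"unknown key: {key}")
    for key, value in config.items():
        expected = KNOWN_CONFIG_KEYS.get(key)
        if expected is None:
            continue
        if expected in (float, int) and isinstance(value, bool):
            errors.append(f"{key}: expected {expected.__name__}, got bool")
        elif expected is float and not isinstance(value, (int, float)):
            errors.append(f"{key}: expected a number")
        elif expected in (str, dict, bool, int) and not isinstance(value, expected):
            errors.append(f"{key}: expected {expected.__name__}")
    for key in _POSITIVE_KEYS:
        v = config.get(key)
        if isinstance(v, (int, float)) and not isinstance(v, bool) and v <= 0:
            errors.append(f"{key} must be positive")
    for key in ("movie_path", "reference_path"):
        p = config.get(key)
        if isinstance(p, str) and not Path(p).exists():
            errors.append(f"{key}: file not found: {p}")
    if "movie_path" not in config and "simulate" not in config:
        errors.append("config needs either movie_path or a simulate block")
    return errors


def config_hash(config: dict) -> str:
    """Stable short hash of a config, recorded with every output artifact."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
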