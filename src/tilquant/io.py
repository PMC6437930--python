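"""File-format plumbing: multichannel TIFF cores and YAML/JSON configs.

Cores are written as one single-file multichannel TIFF per core (one page
per channel) with the channel names and pixel scale stored as JSON in the
image description, so a directory of cores plus a core→patient CSV is a
complete dataset.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from tilquant.errors import ConfigError
from tilquant.syndata import CohortSpec, CoreImage, ImageSpec


def write_core_tiff(image: CoreImage, path) -> None:
    names = list(image.channels)
    stack = np.stack([image.channels[c] for c in names])
    meta = json.dumps({"channels": names, "um_per_px": image.um_per_px,
                       "core_id": image.core_id})
    tifffile.imwrite(path, stack, description=meta, photometric="minisblack")


def read_core_tiff(path, channel_names=None, um_per_px=None) -> CoreImage:
    """Read a multichannel core; falls back to caller-supplied channel order
    when the file carries no metadata."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    try:
        meta = json.loads(desc)
    except (TypeError, ValueError):
        pass
    names = meta.get("channels", channel_names)
    if names is None or len(names) != stack.shape[0]:
        raise ConfigError(
            f"{path.name}: no channel names in metadata and no matching "
            f"channel_names given ({stack.shape[0]} pages)"
        )
    scale = meta.get("um_per_px", um_per_px)
    if scale is None:
        raise ConfigError(f"{path.name}: pixel scale unknown")
    core_id = meta.get("core_id", path.stem)
    return CoreImage(
        core_id=core_id,
        channels={n: stack[i].astype(np.float32) for i, n in enumerate(names)},
        um_per_px=float(scale),
    )


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _tupled(mapping: dict) -> dict:
    return {tuple(k.split("+")) if isinstance(k, str) else tuple(k): v
            for k, v in (mapping or {}).items()}


def image_spec_from_config(cfg: dict) -> ImageSpec:
    cfg = dict(cfg)
    if "coexpression" in cfg:
        cfg["coexpression"] = _tupled(cfg["coexpression"])
    for key in ("cell_radius_range_um", "intensity_fg", "intensity_bg",
                "hole_count_range", "hole_radius_range_um", "cores_per_patient"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    return ImageSpec(**cfg)


def cohort_spec_from_config(cfg: dict) -> CohortSpec:
    cfg = dict(cfg)
    if "planted_effects" in cfg:
        cfg["planted_effects"] = _tupled(cfg["planted_effects"])
    if "cores_per_patient" in cfg and isinstance(cfg["cores_per_patient"], list):
        cfg["cores_per_patient"] = tuple(cfg["cores_per_patient"])
    return CohortSpec(**cfg)
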