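"""File I/O: multi-channel TIFF with pixel-size metadata, localization CSV,
per-image cell-count CSV, trace-endpoint CSV, and YAML run configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simgen import CHANNELS, GroundTruthScene, SceneParams, StormParams

__all__ = [
    "write_channels_tiff",
    "read_channels_tiff",
    "write_scene_json",
    "read_scene_json",
    "write_localizations_csv",
    "read_localizations_csv",
    "read_cell_counts_csv",
    "read_trace_endpoints_csv",
    "load_config",
]

LOC_HEADER = ["id", "x_nm", "y_nm", "z_nm", "photons", "frame", "cluster_id"]


def write_channels_tiff(path, channels: dict[str, np.ndarray],
                        pixel_size_um: float, dtype: str = "float32") -> None:
    """Write channels as a multi-page TIFF with resolution metadata.

    Pages follow the canonical channel order; channel names are stored in
    the ImageDescription JSON.  ``dtype`` may be float32 or uint16 (uint16
    clips negatives and rounds).
    """
    names = [c for c in CHANNELS if c in channels] + \
        sorted(set(channels) - set(CHANNELS))
    stack = np.stack([channels[n] for n in names])
    if dtype == "uint16":
        stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        stack = stack.astype(np.float32)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    px_cm = 1e4 / pixel_size_um  # pixels per cm
    tifffile.imwrite(
        path, stack, photometric="minisblack",
        resolution=(px_cm, px_cm), resolutionunit="CENTIMETER",
        description=json.dumps({"channels": names,
                                "pixel_size_um": pixel_size_um}))


def read_channels_tiff(path, pixel_size_um: float | None = None,
                       ) -> tuple[dict[str, np.ndarray], float]:
    """Read a multi-page TIFF back into named channels and pixel size.

    Pixel size is taken from the ImageDescription JSON, then the TIFF
    resolution tags; an explicit ``pixel_size_um`` overrides both.
    """
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        page = tf.pages[0]
        names = None
        ps = None
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                names = meta.get("channels")
                ps = meta.get("pixel_size_um")
            except (json.JSONDecodeError, TypeError):
                pass
        if ps is None:
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is not None and getattr(unit, "value", None) is not None:
                num, den = xres.value
                per_unit = num / den
                unit_cm = {2: 2.54, 3: 1.0}.get(int(unit.value))
                if unit_cm and per_unit > 0:
                    ps = 1e4 * unit_cm / per_unit
    if stack.ndim == 2:
        stack = stack[None]
    if names is None:
        names = [f"channel{i}" for i in range(len(stack))]
    if pixel_size_um is not None:
        ps = pixel_size_um
    if ps is None:
        raise ValueError("pixel size not found in metadata; pass it explicitly")
    return {n: stack[i].astype(float) for i, n in enumerate(names)}, float(ps)


def write_scene_json(path, scene: GroundTruthScene) -> None:
    Path(path).write_text(scene.to_json())


def read_scene_json(path) -> GroundTruthScene:
    return GroundTruthScene.from_json(Path(path).read_text())


def write_localizations_csv(path, locs: pd.DataFrame) -> None:
    cols = [c for c in LOC_HEADER if c in locs.columns]
    locs.to_csv(path, index=False, columns=cols)


def read_localizations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LOC_HEADER[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"localization CSV missing columns: {sorted(missing)}")
    return df


def read_cell_counts_csv(path) -> dict[str, int]:
    """CSV ``image_id,n_cells`` -> mapping."""
    df = pd.read_csv(path)
    if not {"image_id", "n_cells"} <= set(df.columns):
        raise ValueError("cell-count CSV needs columns image_id,n_cells")
    return dict(zip(df["image_id"].astype(str), df["n_cells"].astype(int)))


def read_trace_endpoints_csv(path) -> pd.DataFrame:
    """CSV ``trace_id,cell_id,class,x0_um,y0_um,x1_um,y1_um``."""
    df = pd.read_csv(path)
    need = {"trace_id", "cell_id", "class", "x0_um", "y0_um", "x1_um", "y1_um"}
    if not need <= set(df.columns):
        raise ValueError(f"trace CSV needs columns {sorted(need)}")
    return df


def load_config(path) -> dict:
    """Load a YAML run configuration; scene/storm sections mirror the
    SceneParams/StormParams field names exactly."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out = dict(doc)
    if "scene" in doc:
        out["scene"] = SceneParams.from_dict(doc["scene"])
    if "storm" in doc:
        out["storm"] = StormParams.from_dict(doc["storm"])
    return out
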