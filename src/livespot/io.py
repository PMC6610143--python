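"""Movie and table I/O: multi-page TIFF with a JSON metadata sidecar, CSV tables.

Movies are written as plain multi-page TIFF in ``(T, C, Z, Y, X)`` order
with calibration carried in a ``<name>.json`` sidecar
(``{pixel_size_um, frame_interval_s, channel_names, axes}``); tables go
out as CSV with a fixed column order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from livespot.movie import Movie

__all__ = ["read_movie", "write_movie", "write_table", "read_table", "sidecar_path"]


def sidecar_path(tiff_path: str | Path) -> Path:
    p = Path(tiff_path)
    return p.with_suffix(p.suffix + ".json")


def write_movie(path: str | Path, movie: Movie) -> Path:
    """Write a movie as multi-page TIFF plus JSON sidecar metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.data.astype(np.float32), metadata={"axes": "TCZYX"})
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        "channel_names": movie.channel_names,
        "axes": "TCZYX",
        "shape": list(movie.data.shape),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_movie(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> Movie:
    """Read a TIFF movie; calibration from the sidecar or explicit overrides.

    Dimension order is normalized to ``(T, C, Z, Y, X)``; a plain 2-D TIFF
    becomes a single-frame single-channel movie.  Missing calibration with
    no sidecar is rejected with a hint to pass it explicitly.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    meta: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise ValueError(
            f"no calibration for {path.name}: write a sidecar JSON or pass "
            "pixel_size_um= and frame_interval_s= explicitly"
        )
    if "shape" in meta and tuple(meta["shape"]) != arr.shape:
        arr = arr.reshape(meta["shape"])  # tifffile squeezes singleton axes
    return Movie(
        arr.astype(float),
        pixel_size_um=float(px),
        frame_interval_s=float(dt),
        channel_names=list(meta.get("channel_names", [])),
    )


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
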