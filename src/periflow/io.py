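"""File formats: multi-page TIFF movies and kymographs with JSON
sidecars, ROI label images with metadata, and CSV tables.

Every image file ``foo.tif`` travels with a sidecar ``foo.json`` holding
the acquisition metadata the arrays cannot carry (frame rate, line
period, pixel size, orientation, channel order). Readers validate the
sidecar and fail with the offending path in the message.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .calcium import FluorescenceMovie, ROIMeta, ROISet
from .linescan import Kymograph

__all__ = [
    "read_movie", "write_movie",
    "read_kymograph", "write_kymograph",
    "read_roiset", "write_roiset",
    "write_table", "read_table",
    "config_hash",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sc} for {path}")
    with open(sc) as fh:
        return json.load(fh)


def write_movie(path: str | Path, movie: FluorescenceMovie) -> Path:
    """Write a movie as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data)
    meta = {
        "frame_rate": movie.frame_rate,
        "channel_names": list(movie.channel_names),
        "n_frames": movie.n_frames,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path: str | Path) -> FluorescenceMovie:
    """Read a 1–2 channel multi-page TIFF movie and its sidecar."""
    path = Path(path)
    meta = _load_sidecar(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    fr = float(meta.get("frame_rate", 0))
    if fr <= 0:
        raise ValueError(f"invalid frame_rate in sidecar for {path}")
    names = tuple(meta.get("channel_names", ("calcium",)))
    n_ch = 1 if data.ndim == 3 else data.shape[-1]
    if n_ch > 2:
        raise ValueError(f"{path}: {n_ch}-channel movies unsupported (max 2)")
    if "n_frames" in meta and int(meta["n_frames"]) != data.shape[0]:
        raise ValueError(f"{path}: page count {data.shape[0]} does not match "
                         f"sidecar n_frames={meta['n_frames']}")
    return FluorescenceMovie(data=data, frame_rate=fr, channel_names=names[:n_ch])


def write_kymograph(path: str | Path, kym: Kymograph) -> Path:
    """Write a kymograph as TIFF (or CSV matrix by extension) + sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, kym.data, delimiter=",")
    else:
        tifffile.imwrite(path, np.asarray(kym.data, dtype=np.float32))
    meta = {"line_period": kym.line_period, "pixel_size": kym.pixel_size,
            "orientation": kym.orientation}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    meta = _load_sidecar(path)
    if path.suffix.lower() == ".csv":
        data = np.loadtxt(path, delimiter=",")
    else:
        data = tifffile.imread(path)
    try:
        return Kymograph(data=data, line_period=float(meta["line_period"]),
                         pixel_size=float(meta["pixel_size"]),
                         orientation=str(meta["orientation"]))
    except (KeyError, ValueError) as exc:
        raise ValueError(f"invalid kymograph metadata for {path}: {exc}") from exc


def write_roiset(path: str | Path, rois: ROISet) -> Path:
    """ROI label image as TIFF, metadata (and vessel mask) in the sidecar."""
    path = Path(path)
    tifffile.imwrite(path, rois.label_image.astype(np.int32))
    meta = {
        "rois": {str(lbl): vars(m) for lbl, m in rois.meta.items()},
        "vessel_mask": (rois.vessel_mask.astype(int).tolist()
                        if rois.vessel_mask is not None else None),
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_roiset(path: str | Path) -> ROISet:
    path = Path(path)
    meta = _load_sidecar(path)
    labels = tifffile.imread(path)
    rois = {int(k): ROIMeta(**v) for k, v in meta.get("rois", {}).items()}
    vm = meta.get("vessel_mask")
    vessel = np.asarray(vm, dtype=bool) if vm is not None else None
    return ROISet(label_image=labels, meta=rois, vessel_mask=vessel)


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                header_lines: Optional[list[str]] = None) -> Path:
    """CSV with optional ``#``-prefixed header comment lines.

    Floats are written with a fixed general format so identical inputs
    produce byte-identical files.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
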