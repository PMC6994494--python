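"""TIFF / sidecar / CSV plumbing.

Movies travel as multi-page grayscale TIFF (16-bit unsigned for
Poisson-noise data, 32-bit float otherwise) with a JSON sidecar carrying
the physical calibration, per-frame timestamps, the generating seed and a
full configuration echo -- enough to re-run the acquisition from scratch.
Moment maps are written as 32-bit float TIFFs, masks as 8-bit TIFFs,
tables as CSV with units in the column names.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .core import AcquisitionConfig, Movie
from .errors import err
from .moments import MomentSeries

SCHEMA_VERSION = 1


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".tif" else path.with_suffix(".json")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_movie(
    movie: Movie,
    path: str | Path,
    seed: int | None = None,
    config_echo: dict | None = None,
) -> Path:
    """Write a movie as multi-page grayscale TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = movie.frames
    if np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.uint16)
    else:
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "n_frames": movie.n_frames,
        "frame_shape": list(movie.frame_shape),
        "frame_time_s": movie.acquisition.frame_time,
        "pixel_size_um": movie.acquisition.pixel_size,
        "timestamps_s": movie.times().tolist(),
        "seed": seed,
        "config_echo": _jsonable(config_echo) if config_echo else None,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_movie(path: str | Path) -> Movie:
    """Read a multi-page grayscale TIFF movie and its sidecar.

    Without a sidecar, the default frame time and pixel size are assumed
    with a warning.  A sidecar whose timestamp count disagrees with the
    page count is an error.
    """
    path = Path(path)
    if not path.exists():
        raise err("not_found", str(path))
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise err("unsupported_tiff", "expected a single-channel multi-page TIFF")
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sc = json.loads(sc_path.read_text())
        ts = np.asarray(sc["timestamps_s"], dtype=float)
        if len(ts) != frames.shape[0]:
            raise err("metadata_mismatch", "sidecar timestamps do not match page count")
        acq = AcquisitionConfig(
            n_frames=frames.shape[0],
            frame_shape=frames.shape[1:],
            frame_time=float(sc["frame_time_s"]),
            pixel_size=float(sc["pixel_size_um"]),
        )
        uniform = len(ts) < 2 or np.allclose(np.diff(ts), acq.frame_time)
        return Movie(frames, acq, timestamps=None if uniform else ts)
    warnings.warn(f"no sidecar next to {path}: assuming default calibration", stacklevel=2)
    acq = AcquisitionConfig(n_frames=frames.shape[0], frame_shape=frames.shape[1:])
    return Movie(frames, acq)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)), photometric="minisblack")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise err("not_found", str(path))
    return tifffile.imread(path) > 0


def write_moment_series(series: MomentSeries, outdir: str | Path) -> Path:
    """Per-segment mean/variance/ratio maps as 32-bit float TIFF stacks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, attr in (("mean", "mean_img"), ("variance", "var_img"), ("ratio", "ratio_img")):
        stack = np.stack([getattr(m, attr) for m in series]).astype(np.float32)
        tifffile.imwrite(outdir / f"moment_{name}.tif", stack, photometric="minisblack")
    return outdir
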