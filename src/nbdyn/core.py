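"""Core containers: acquisition calibration and the movie (image stack) type.

Conventions used throughout the package
---------------------------------------
* Pixel indices are 0-based ``(row, col)``; the physical axes are
  ``x = col``, ``y = row``; a pixel's center sits at ``(index + 0.5) *
  pixel_size`` micrometres.
* A movie is a ``T x H x W`` stack of non-negative intensity counts with a
  physical calibration (seconds/frame, micrometres/pixel).  Non-uniform
  frame spacing (as in a photobleaching protocol) is carried by an explicit
  timestamp vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import err

#: Default confocal raster calibration: 1000 frames of 64 x 64 pixels over a
#: 13.5 um field of view, 121 ms per frame (64 lines x 1.89 ms line time).
DEFAULT_N_FRAMES = 1000
DEFAULT_FRAME_SHAPE = (64, 64)
DEFAULT_LINE_TIME = 1.89e-3  # s per scanned line
DEFAULT_FIELD_OF_VIEW = 13.5  # um
DEFAULT_FRAME_TIME = 0.121  # s, printed instrument value (64 * 1.89 ms rounded)
DEFAULT_PIXEL_SIZE = DEFAULT_FIELD_OF_VIEW / 64  # um/px


def frame_time_from_line_scan(n_lines: int = 64, line_time: float = DEFAULT_LINE_TIME) -> float:
    """Frame time (s) implied by a line-scanned raster: ``n_lines * line_time``."""
    if n_lines < 1 or line_time <= 0:
        raise err("invalid_config", "n_lines >= 1 and line_time > 0 required")
    return n_lines * line_time


@dataclass(frozen=True)
class AcquisitionConfig:
    """Physical calibration of a confocal time-series acquisition.

    Attributes
    ----------
    n_frames:
        Number of frames in the acquisition (>= 1).
    frame_shape:
        (rows, cols) of each frame in pixels.
    frame_time:
        Seconds per frame (uniform raster scanning).
    pixel_size:
        Micrometres per pixel.
    """

    n_frames: int = DEFAULT_N_FRAMES
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE
    frame_time: float = DEFAULT_FRAME_TIME
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self):
        if self.n_frames < 1:
            raise err("invalid_config", "n_frames must be >= 1")
        if self.frame_time <= 0:
            raise err("invalid_config", "frame_time must be > 0")
        if self.pixel_size <= 0:
            raise err("invalid_config", "pixel_size must be > 0")
        r, c = self.frame_shape
        if r < 1 or c < 1:
            raise err("invalid_config", "frame_shape must be positive")

    @property
    def field_of_view(self) -> tuple[float, float]:
        """(height, width) of the imaged field in micrometres."""
        r, c = self.frame_shape
        return (r * self.pixel_size, c * self.pixel_size)

    @property
    def frame_time_ms(self) -> float:
        """Frame time in milliseconds, rounded to the nearest ms as printed
        by the instrument software."""
        return round(self.frame_time * 1000)

    def segment_duration(self, segment_len: int) -> float:
        """Duration (s) of a contiguous segment of ``segment_len`` frames."""
        return segment_len * self.frame_time

    def validate_field_of_view(self, field_of_view: float, atol: float = 1e-9) -> None:
        """Check a stated square field of view against shape x pixel_size."""
        h, w = self.field_of_view
        if abs(h - field_of_view) > atol or abs(w - field_of_view) > atol:
            raise err(
                "invalid_config",
                f"field of view {field_of_view} um inconsistent with "
                f"{self.frame_shape} x {self.pixel_size} um/px",
            )


@dataclass
class Movie:
    """A calibrated intensity time series.

    ``frames`` holds non-negative counts (integer-valued when the detector
    noise model is Poisson).  ``timestamps`` is ``None`` for uniformly
    spaced acquisitions; protocols with variable spacing (pre-bleach vs
    recovery frames) set it explicitly.
    """

    frames: np.ndarray
    acquisition: AcquisitionConfig
    timestamps: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise err("invalid_config", "frames must be a T x H x W stack")
        if self.frames.shape[0] != self.acquisition.n_frames:
            raise err(
                "invalid_config",
                f"{self.frames.shape[0]} frames but acquisition declares "
                f"{self.acquisition.n_frames}",
            )
        if tuple(self.frames.shape[1:]) != tuple(self.acquisition.frame_shape):
            raise err("invalid_config", "frame shape mismatch with acquisition")
        if np.any(self.frames < 0):
            raise err("invalid_config", "negative intensity counts")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.n_frames,):
                raise err("metadata_mismatch", "timestamps length != frame count")
            if np.any(np.diff(self.timestamps) <= 0):
                raise err("metadata_mismatch", "timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        """Per-frame acquisition times in seconds (uniform grid if no
        explicit timestamps were recorded)."""
        if self.timestamps is not None:
            return self.timestamps
        return np.arange(self.n_frames) * self.acquisition.frame_time
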