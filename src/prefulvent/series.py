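"""Core in-memory containers: a dynamic 2D+t series and a lung mask.

The raster convention is (row, column) with 0-based indices; the frame axis
is the last axis of the signal array. Masks and derived maps share the
series raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

MIN_FRAMES = 50
MIN_LUNG_AREA = 100
_SPACING_TOL = 1e-6


@dataclass
class DynamicSeries:
    """A single-slice dynamic proton-MRI series acquired during tidal breathing.

    Parameters
    ----------
    signal
        Intensity array of shape ``(ny, nx, n_frames)``; arbitrary units,
        finite and non-negative.
    frame_times
        Acquisition time of each frame in seconds; strictly increasing with
        uniform spacing.
    pixel_spacing
        In-plane pixel size in millimetres (metadata only).
    """

    signal: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: tuple[float, float] = (3.9, 3.9)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.signal.ndim != 3:
            raise InvalidParameterError(
                f"signal must be (ny, nx, n_frames); got shape {self.signal.shape}"
            )
        if self.signal.shape[2] != self.frame_times.size:
            raise InvalidParameterError(
                f"{self.signal.shape[2]} frames but {self.frame_times.size} frame times"
            )
        if self.n_frames < MIN_FRAMES:
            raise InvalidParameterError(
                f"need at least {MIN_FRAMES} frames, got {self.n_frames}"
            )
        dt = np.diff(self.frame_times)
        if np.any(dt <= 0) or np.ptp(dt) > _SPACING_TOL:
            raise InvalidParameterError("frame times must increase uniformly")
        if not np.all(np.isfinite(self.signal)):
            raise InvalidParameterError("signal contains non-finite values")
        if np.any(self.signal < 0):
            raise InvalidParameterError("signal contains negative intensities")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[2]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.signal.shape[:2]

    @property
    def frame_interval(self) -> float:
        return float(np.mean(np.diff(self.frame_times)))

    @property
    def sampling_rate(self) -> float:
        """Frame rate in Hz."""
        return 1.0 / self.frame_interval

    def mean_signal(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Spatial-mean signal per frame, optionally restricted to a mask."""
        if mask is None:
            return self.signal.mean(axis=(0, 1))
        return self.signal[np.asarray(mask, bool)].mean(axis=0)

    def with_signal(self, signal: np.ndarray) -> "DynamicSeries":
        return DynamicSeries(signal, self.frame_times.copy(), self.pixel_spacing)


@dataclass
class LungMask:
    """Binary analysis region on the series raster."""

    lung: np.ndarray
    vessels_removed: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lung = np.asarray(self.lung, dtype=bool)
        if self.lung.ndim != 2:
            raise InvalidParameterError("lung mask must be 2D")
        if self.area < MIN_LUNG_AREA:
            raise InvalidParameterError(
                f"lung mask has {self.area} pixels; need at least {MIN_LUNG_AREA}"
            )

    @property
    def area(self) -> int:
        return int(self.lung.sum())
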