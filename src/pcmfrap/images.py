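"""In-memory carriers for calibrated images, movies and bleach events.

All lengths are micrometres, all times seconds, all intensities camera counts.
Pixel (i, j) of a 2D image is centred at ``((j + 0.5) * pixel_size,
(i + 0.5) * pixel_size)`` in (x, y) coordinates with the origin at the image
corner; x runs along columns and y along rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["ImageStack", "BleachEvent", "FrapMovie"]


@dataclass
class ImageStack:
    """A 2D image or a 3D (z, y, x) stack with physical calibration."""

    pixels: np.ndarray
    pixel_size: float
    frame_time: float | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be a 2D image or a 3D (z, y, x) stack")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape_um(self) -> tuple[float, float]:
        """Physical (width, height) of the field in micrometres."""
        ny, nx = self.pixels.shape[-2:]
        return nx * self.pixel_size, ny * self.pixel_size

    def with_pixels(self, pixels: np.ndarray, pixel_size: float | None = None) -> "ImageStack":
        return replace(self, pixels=pixels,
                       pixel_size=self.pixel_size if pixel_size is None else pixel_size)


@dataclass(frozen=True)
class BleachEvent:
    """An instantaneous photobleach of a circular ROI.

    ``efficiency`` is the bleached fraction of the fluorescent pool inside the
    ROI: 1.0 erases it completely, 0.0 is a no-op.
    """

    time: float
    center: tuple[float, float]
    radius: float
    efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("bleach efficiency must lie in [0, 1]")
        if not self.radius > 0:
            raise ValueError("bleach radius must be positive")


@dataclass
class FrapMovie:
    """A time-lapse of a single field with bleach-event annotations.

    ``frames`` is a (T, ny, nx) array of camera counts; ``times`` gives the
    acquisition time of each frame.  ``centrosomes`` lists the seed positions
    (x, y) around which quantification is performed.
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_size: float
    bleach_events: tuple[BleachEvent, ...] = ()
    centrosomes: tuple[tuple[float, float], ...] = ()
    channel: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, ny, nx) array")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("one time stamp per frame is required")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame time stamps must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        lo, hi = self.times[0], self.times[-1]
        for ev in self.bleach_events:
            if not lo <= ev.time <= hi:
                raise ValueError(
                    f"bleach at t={ev.time} s lies outside the movie span [{lo}, {hi}]")
        self.bleach_events = tuple(sorted(self.bleach_events, key=lambda e: e.time))
        self.centrosomes = tuple((float(x), float(y)) for x, y in self.centrosomes)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def bleach_times(self) -> np.ndarray:
        """Distinct bleach times, sorted; simultaneous events (e.g. one per
        centrosome) count as one bleach."""
        return np.unique([ev.time for ev in self.bleach_events])

    def frame(self, i: int) -> ImageStack:
        return ImageStack(self.frames[i], self.pixel_size,
                          frame_time=float(self.times[i]), channel=self.channel)

    def prebleach_index(self) -> int:
        """Index of the last frame acquired strictly before the first bleach."""
        if not self.bleach_events:
            raise ValueError("movie has no bleach events")
        idx = np.flatnonzero(self.times < self.bleach_events[0].time)
        if idx.size == 0:
            raise ValueError("movie has no pre-bleach frame")
        return int(idx[-1])
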