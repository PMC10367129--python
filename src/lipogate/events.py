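"""Core in-memory containers for single-event image data.

An *event* is one detected object on an imaging flow cytometer: a small
aligned stack of per-channel image tiles plus acquisition metadata. All
downstream feature computation operates on an event together with a boolean
pixel *mask* delimiting the object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageEvent", "Mask"]


@dataclass
class ImageEvent:
    """One detected object: aligned per-channel tiles + metadata.

    Parameters
    ----------
    event_id : str
        Unique identifier within an event set.
    channels : dict of str -> 2D ndarray
        Channel name (e.g. ``"membrane"``, ``"reporter"``) to intensity
        raster in arbitrary units. All rasters must share one shape and
        contain finite, non-negative values.
    pixel_size : float
        Physical pixel pitch in micrometres per pixel.
    """

    event_id: str
    channels: dict[str, np.ndarray]
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.channels:
            raise ValueError("event must carry at least one channel")
        shapes = {np.asarray(img).shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be 2D rasters")
        for name, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} has non-finite pixels")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative pixels")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"event {self.event_id!r} has no channel {name!r}; "
                f"available: {sorted(self.channels)}"
            ) from None


@dataclass
class Mask:
    """Boolean pixel region over which features are computed."""

    region: np.ndarray
    source_channel: str

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        if self.region.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def n_pixels(self) -> int:
        return int(self.region.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.region.any())
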