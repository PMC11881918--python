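"""Shared containers for image stacks, displacement fields, traces and ROIs.

Conventions used throughout the package:

* image orientation: row index = y, increasing downward; column index = x,
  increasing rightward; displacement vectors are reported as ``(x, y)`` in
  pixels and follow the same sign convention;
* time: seconds from the start of the recording, frame ``i`` sits at
  ``t0 + i / frame_rate``; frame indices are 0-based;
* displacement fields are always *target relative to reference*, i.e. the
  vector at a block tells where that piece of tissue moved to between the
  reference frame and the target frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["Trace", "ImageStack", "Roi", "DisplacementField"]


@dataclass
class Trace:
    """A named, uniformly sampled 1-D time series.

    Parameters
    ----------
    values : array-like
        Sample values, arbitrary units.
    dt : float
        Sampling interval in seconds (must be positive).
    t0 : float
        Time of the first sample in seconds.
    name : str
        Human-readable label, carried through derived traces.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("Trace values must be finite")
        if self.dt <= 0:
            raise ValueError("Trace dt must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) * self.dt

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) * self.dt

    def with_values(self, values: np.ndarray, name: Optional[str] = None) -> "Trace":
        """Return a copy holding new values on the same time base."""
        return replace(self, values=np.asarray(values, dtype=float),
                       name=self.name if name is None else name)


@dataclass
class ImageStack:
    """Ordered grayscale frames plus frame-rate metadata."""

    frames: np.ndarray  # (T, m, n) float array
    frame_rate: float = 2.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("ImageStack frames must be a (T, m, n) array")
        if self.frames.shape[0] < 2:
            raise ValueError("ImageStack needs at least two frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class Roi:
    """A rectangular or mask region of interest inside an m x n frame.

    Either ``rect = (row0, col0, height, width)`` or a boolean ``mask``
    must be given.  ``mask_for(shape)`` materializes the boolean mask.
    """

    label: str = "roi"
    rect: Optional[tuple] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.rect is None and self.mask is None:
            raise ValueError("Roi needs a rect or a mask")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise ValueError("Roi mask is empty")
        if self.rect is not None:
            r0, c0, h, w = self.rect
            if h <= 0 or w <= 0 or r0 < 0 or c0 < 0:
                raise ValueError("Roi rect must be (row0, col0, height, width) with positive size")

    @classmethod
    def full_frame(cls, shape: tuple, label: str = "full") -> "Roi":
        return cls(label=label, rect=(0, 0, shape[0], shape[1]))

    def mask_for(self, shape: tuple) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise ValueError("Roi mask shape does not match frame shape")
            return self.mask
        r0, c0, h, w = self.rect
        if r0 + h > shape[0] or c0 + w > shape[1]:
            raise ValueError("Roi rect exceeds frame bounds")
        m = np.zeros(shape, dtype=bool)
        m[r0:r0 + h, c0:c0 + w] = True
        return m


@dataclass
class DisplacementField:
    """Block-resolution displacement of a target frame relative to frame 0.

    ``vx``/``vy`` are (rows, cols) grids of per-block displacements in
    pixels; ``centers_r``/``centers_c`` give the pixel coordinates of block
    centers so the field can be intersected with pixel-space ROIs.
    ``confident`` is False where a block had too little texture to match
    (displacement then reported as zero).
    """

    vx: np.ndarray
    vy: np.ndarray
    centers_r: np.ndarray
    centers_c: np.ndarray
    block_size: int
    search_radius: int
    reference_index: int = 0
    target_index: int = 0
    confident: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape:
            raise ValueError("vx and vy grids must share shape")
        if not (np.isfinite(self.vx).all() and np.isfinite(self.vy).all()):
            raise ValueError("displacement entries must be finite")
        if self.confident is None:
            self.confident = np.ones(self.vx.shape, dtype=bool)

    @property
    def norm(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def block_mask(self, roi: Roi, frame_shape: tuple) -> np.ndarray:
        """Boolean grid of blocks whose centers fall inside the ROI."""
        pixel_mask = roi.mask_for(frame_shape)
        rr = np.clip(np.round(self.centers_r).astype(int), 0, frame_shape[0] - 1)
        cc = np.clip(np.round(self.centers_c).astype(int), 0, frame_shape[1] - 1)
        return pixel_mask[rr[:, None], cc[None, :]]
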