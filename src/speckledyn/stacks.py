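"""The FrameStack container: time-ordered detector images plus metadata.

This is the raw I(Q, t) carrier for everything downstream — a stack of
photon-count frames, their timestamps, the detector geometry, a pixel
validity mask and the experimental metadata (temperature, incident flux
density, sample provenance, and — for synthetic stacks — the generator's
ground-truth parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import ConfigError
from .geometry import DetectorGeometry


@dataclass
class FrameStack:
    images: np.ndarray            # counts, shape (n_frames, n_rows, n_cols)
    timestamps: np.ndarray        # seconds, strictly increasing
    geometry: DetectorGeometry
    mask: np.ndarray              # bool, True = valid pixel
    temperature_k: Optional[float] = None
    flux_density: Optional[float] = None     # (ph/s)/um^2
    meta: dict = field(default_factory=dict)  # sample id, hydration h, seed, truth

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.images.ndim != 3:
            raise ConfigError("images must be a (frames, rows, cols) array")
        if np.issubdtype(self.images.dtype, np.floating):
            if np.any(self.images < 0):
                raise ConfigError("photon counts must be non-negative")
        if len(self.timestamps) != self.images.shape[0]:
            raise ConfigError("one timestamp per frame required")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ConfigError("timestamps must be strictly increasing")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.images.shape[1:]:
            raise ConfigError("mask shape must match image shape")
        if tuple(self.geometry.shape) != self.images.shape[1:]:
            raise ConfigError("geometry shape must match image shape")

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]

    @property
    def frame_interval(self) -> float:
        """Median frame spacing in seconds."""
        if self.n_frames < 2:
            return float("nan")
        return float(np.median(np.diff(self.timestamps)))

    def with_mask(self, mask: np.ndarray) -> "FrameStack":
        return replace(self, mask=np.asarray(mask, dtype=bool))

    def pixel_series(self, sel: np.ndarray) -> np.ndarray:
        """Time series of the pixels selected by boolean map ``sel``,
        intersected with the stack mask; shape (n_frames, n_pixels), float64."""
        sel = np.asarray(sel, dtype=bool) & self.mask
        return self.images[:, sel].astype(np.float64)
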