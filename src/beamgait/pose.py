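"""Time-indexed feature-point coordinate sequences."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .skeleton import FeaturePointConfig, default_config

__all__ = ["PoseSequence"]


@dataclass
class PoseSequence:
    """Per-frame coordinates of all feature points, 2D or 3D.

    ``coords`` has shape ``(frames, n_points, dims)``.  Coordinates are in
    pixels (raw tracking) or centimetres (after geometric processing).  The
    pixel convention is image-style: origin top-left, y pointing down,
    0-based frame indices.  Missing/low-confidence entries are stored as NaN
    until filled by :func:`beamgait.pose_io.fill_gaps`.
    """

    coords: np.ndarray
    fps: float
    units: str = "px"
    config: FeaturePointConfig = field(default_factory=default_config)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must have shape (frames, n_points, dims)")
        if self.coords.shape[1] != self.config.n_points:
            raise ValueError(
                f"coords has {self.coords.shape[1]} points, "
                f"config expects {self.config.n_points}"
            )
        if self.coords.shape[2] not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.units not in ("px", "cm"):
            raise ValueError("units must be 'px' or 'cm'")

    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dims(self) -> int:
        return self.coords.shape[2]

    def has_gaps(self) -> bool:
        return bool(np.isnan(self.coords).any())

    def flat(self) -> np.ndarray:
        """Coordinates in the stacked (x1, y1[, z1], x2, ...) layout."""
        return self.coords.reshape(self.frames, -1)

    def single_frame(self, t: int = 0) -> np.ndarray:
        """One posture as an ``(n_points, dims)`` array."""
        return self.coords[t].copy()

    def copy(self) -> "PoseSequence":
        return replace(self, coords=self.coords.copy())
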