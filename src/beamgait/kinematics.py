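"""Per-frame speed vectors and culling of non-walking intervals.

The speed of the tracked posture is the backward finite difference of the
stacked coordinate vector,

    V(t) = X(t) - X(t - dt),

evaluated per video frame, so the natural unit is coordinate units *per
frame*.  All cycle-extraction and correlation analysis downstream operates
on this per-frame displacement; conversion to physical units per second is
an explicit, separate step (divide by the frame interval ``1/fps``).

For the default 18-point skeleton the stacked vector has 36 components for
2D coordinates and 54 for 3D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .pose import PoseSequence
from .skeleton import FeaturePointConfig, default_config

__all__ = [
    "SpeedSeries",
    "CullingPlan",
    "compute_speed",
    "frame_interval",
    "cull",
    "auto_cull_plan",
]


@dataclass
class SpeedSeries:
    """Stacked per-component displacement per frame.

    ``values`` has shape ``(frames, n_components)`` with component order
    ``(x1, y1[, z1], x2, ...)`` matching the flattened pose layout.  Entry
    ``values[t]`` is ``X(t+1) - X(t)`` of the source pose, so a pose with F
    frames yields F - 1 speed frames.  ``frame_index`` maps each row back to
    its original speed-timeline index (identity until culling).
    """

    values: np.ndarray
    fps: float
    dims: int
    units: str = "px"
    per_second: bool = False
    config: FeaturePointConfig = field(default_factory=default_config)
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (frames, components)")
        if self.values.shape[1] != self.config.n_points * self.dims:
            raise ValueError(
                f"expected {self.config.n_points * self.dims} components, "
                f"got {self.values.shape[1]}"
            )
        if self.frame_index is None:
            self.frame_index = np.arange(self.values.shape[0])
        else:
            self.frame_index = np.asarray(self.frame_index, dtype=int)
            if self.frame_index.shape != (self.values.shape[0],):
                raise ValueError("frame_index length mismatch")

    @property
    def frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def component_names(self) -> list[str]:
        return self.config.component_names(self.dims)

    def copy(self) -> "SpeedSeries":
        return replace(self, values=self.values.copy(),
                       frame_index=self.frame_index.copy())


def frame_interval(fps: float) -> float:
    """Time between two video frames in seconds (1/30 s = 0.0333 s at 30 fps)."""
    if not fps > 0:
        raise ValueError("fps must be positive")
    return 1.0 / fps


def compute_speed(pose: PoseSequence, per_second: bool = False) -> SpeedSeries:
    """Backward finite difference of the stacked coordinate vector.

    Parameters
    ----------
    pose
        Gap-free pose sequence with at least 2 frames.
    per_second
        If True, divide by the frame interval to obtain physical speeds
        (units/second); default is displacement per frame.
    """
    if pose.frames < 2:
        raise ValueError("need at least 2 frames to compute speed")
    if pose.has_gaps():
        raise ValueError("pose has unfilled gaps; run fill_gaps first")
    values = np.diff(pose.flat(), axis=0)
    if per_second:
        values = values / frame_interval(pose.fps)
    return SpeedSeries(values=values, fps=pose.fps, dims=pose.dims,
                       units=pose.units, per_second=per_second,
                       config=pose.config)


@dataclass
class CullingPlan:
    """Sorted, disjoint ``[start, end)`` intervals to keep on the speed timeline."""

    keep: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.keep = [(int(s), int(e)) for s, e in self.keep]
        prev_end = None
        for s, e in self.keep:
            if s < 0 or e <= s:
                raise ValueError(f"invalid interval [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = e

    def n_kept(self) -> int:
        return sum(e - s for s, e in self.keep)


def cull(speed: SpeedSeries, plan: CullingPlan) -> SpeedSeries:
    """Concatenate kept intervals; original frame indices retained in metadata."""
    if plan.keep and plan.keep[-1][1] > speed.frames:
        raise ValueError("culling plan exceeds series length")
    if plan.n_kept() == 0:
        raise ValueError("culling plan keeps no frames")
    idx = np.concatenate([np.arange(s, e) for s, e in plan.keep])
    return replace(speed, values=speed.values[idx],
                   frame_index=speed.frame_index[idx])


def auto_cull_plan(speed: SpeedSeries, epsilon: float,
                   min_len: int = 5) -> CullingPlan:
    """Plan removing stationary stretches based on foot movement.

    Maximal runs of at least ``min_len`` frames where the RMS of the
    foot-group speed components stays below ``epsilon`` are dropped;
    everything else is kept.  The paper culls such stop/hesitation
    intervals manually, so this is an optional convenience.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    feet = speed.config.component_indices("feet", speed.dims)
    rms = np.sqrt(np.mean(speed.values[:, feet] ** 2, axis=1))
    low = rms < epsilon
    keep: list[tuple[int, int]] = []
    t = 0
    n = speed.frames
    while t < n:
        if low[t]:
            run = t
            while run < n and low[run]:
                run += 1
            if run - t < min_len:  # short lull: keep it
                keep.append((t, run))
            t = run
        else:
            run = t
            while run < n and not low[run]:
                run += 1
            keep.append((t, run))
            t = run
    # merge adjacent keeps
    merged: list[tuple[int, int]] = []
    for s, e in keep:
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    if not merged:
        warnings.warn("auto-cull removed every frame (no foot movement above "
                      "threshold)", stacklevel=2)
    return CullingPlan(keep=[tuple(i) for i in merged])
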