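"""Drift-free synthetic walk animation from an SWC.

An SWC averaged from real cycles rarely closes: the per-component speed
sums over one period differ between points, so naive integration makes the
posture smear apart.  Normalisation enforces that every point advances by
the same net displacement per period — the largest per-point displacement
along the beam (x) direction — with zero net y/z drift, by adding a small
per-component constant (the smallest change that preserves the waveform
shape, in particular zero-speed stance phases).  The animation is then the
Forward-Euler cumulative sum of the periodically tiled normalised SWC from
an initial posture X0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pose import PoseSequence
from .swc import StandardWalkCycle

__all__ = ["NormalizedSWC", "WalkAnimation", "cycle_displacement",
           "normalize_swc", "generate_walk"]


def cycle_displacement(swc: StandardWalkCycle) -> np.ndarray:
    """Per-component net displacement over one period (plain frame sum)."""
    return swc.values.sum(axis=0)


@dataclass
class NormalizedSWC:
    """SWC whose per-period displacement is (V_x, 0[, 0]) for every point."""

    values: np.ndarray
    net_displacement: np.ndarray  # length-dims vector (V_x, 0[, 0])
    fps: float
    dims: int

    @property
    def tau(self) -> int:
        return self.values.shape[0]


def normalize_swc(swc: StandardWalkCycle) -> NormalizedSWC:
    """Enforce a common per-period displacement by per-component offsets.

    The target forward displacement V_x is the maximum net x-displacement
    over all points; y (and z) targets are zero.  Each component is shifted
    by ``(target - current_sum) / tau``.  Raises if no point has positive
    net x-displacement (walking direction undefined).
    """
    dims = swc.dims
    sums = cycle_displacement(swc)
    x_sums = sums[0::dims]
    vx = float(np.max(x_sums))
    if vx <= 0:
        raise ValueError("no point advances along the beam; cannot normalize")
    target = np.zeros_like(sums)
    target[0::dims] = vx
    values = swc.values + (target - sums) / swc.tau
    net = np.zeros(dims)
    net[0] = vx
    return NormalizedSWC(values=values, net_displacement=net,
                         fps=swc.fps, dims=dims)


@dataclass
class WalkAnimation:
    """Synthetic posture trajectory; frame 0 is exactly X0."""

    pose: PoseSequence
    x0: np.ndarray


def generate_walk(nswc: NormalizedSWC, x0, n_frames: int) -> WalkAnimation:
    """Forward-Euler integration of the tiled normalised SWC from posture X0.

    ``x0`` is a single posture, either an ``(n_points, dims)`` array or a
    one-frame :class:`PoseSequence`.  A 2D SWC may animate a 3D posture:
    the 2D in-plane axes map to beam (x) and vertical (z), and the lateral
    (y) axis simply carries no movement.
    """
    if isinstance(x0, PoseSequence):
        config = x0.config
        units = x0.units
        x0 = x0.single_frame(0)
    else:
        config = None
        units = "cm"
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim != 2 or x0.shape[1] not in (2, 3):
        raise ValueError("x0 must be (n_points, 2 or 3)")
    n_points, out_dims = x0.shape
    if nswc.values.shape[1] != n_points * nswc.dims:
        raise ValueError(f"SWC has {nswc.values.shape[1]} components; "
                         f"x0 has {n_points} points")
    if n_frames < 1:
        raise ValueError("need at least one frame")

    tau = nswc.tau
    step = nswc.values.reshape(tau, n_points, nswc.dims)
    if nswc.dims == 2 and out_dims == 3:
        # 2D (beam, vertical) into 3D (beam, lateral, vertical): no lateral motion
        full = np.zeros((tau, n_points, 3))
        full[:, :, 0] = step[:, :, 0]
        full[:, :, 2] = step[:, :, 1]
        step = full
    elif nswc.dims != out_dims:
        raise ValueError(f"cannot animate a {nswc.dims}D SWC on a "
                         f"{out_dims}D posture")

    coords = np.empty((n_frames, n_points, out_dims))
    coords[0] = x0
    for t in range(1, n_frames):
        coords[t] = coords[t - 1] + step[(t - 1) % tau]
    if config is None:
        from .skeleton import FeaturePointConfig, default_config
        config = default_config()
        if config.n_points != n_points:
            config = FeaturePointConfig(
                groups={"points": tuple(f"p{i}" for i in range(n_points))})
    pose = PoseSequence(coords=coords, fps=nswc.fps, units=units, config=config)
    return WalkAnimation(pose=pose, x0=x0.copy())
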