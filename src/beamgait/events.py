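"""Event abstraction: cycle-to-SWC correlations and variance of correlation.

For each segmented walk cycle and each coordinate component, the cycle's
speed (rescaled to the SWC length) is correlated with the SWC and
normalised by the SWC component's autocorrelation (self-inner-product).
On that scale 0 means no movement, 1 an exact match to the SWC, values
above 1 the same movement at higher speed, and negative values movement
opposite to the SWC.

The variance of correlation (VoC) condenses this matrix per body-part
group: the population variance of the group's component correlations
within each cycle.  VoC is non-negative, near zero when the animal either
follows the SWC or holds still coherently, and rises when components of a
group deviate from the SWC inconsistently — slips, jumps, head raises and
similar events appear as VoC peaks.  Following the original analysis, only
x/y components enter the VoC by default when 3D data are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import SpeedSeries
from .skeleton import FeaturePointConfig
from .swc import CycleSegmentation, StandardWalkCycle, rescale_cycle

__all__ = ["CorrelationMatrix", "VoCSeries", "EventFlag",
           "correlation_matrix", "voc", "flag_events", "plot_voc"]


@dataclass
class CorrelationMatrix:
    """Normalised correlation per cycle (rows) and component (columns).

    ``zero_norm`` marks components whose SWC autocorrelation is zero; their
    correlations are reported as 0.
    """

    values: np.ndarray
    zero_norm: np.ndarray
    starts: np.ndarray
    periods: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0]


def correlation_matrix(speed: SpeedSeries, swc: StandardWalkCycle,
                       seg: CycleSegmentation) -> CorrelationMatrix:
    """Normalised cycle-vs-SWC correlation for every cycle and component."""
    if seg.n_cycles == 0:
        raise ValueError("empty segmentation")
    if speed.values.shape[1] != swc.n_components:
        raise ValueError("component count mismatch between series and SWC")
    norms = np.sum(swc.values ** 2, axis=0)
    zero = norms == 0.0
    safe = np.where(zero, 1.0, norms)
    rows = np.empty((seg.n_cycles, swc.n_components))
    for i, (s, tau) in enumerate(zip(seg.starts, seg.periods)):
        cyc = rescale_cycle(speed.values[s:s + tau], swc.tau)
        rows[i] = np.sum(cyc * swc.values, axis=0) / safe
    rows[:, zero] = 0.0
    return CorrelationMatrix(values=rows, zero_norm=zero,
                             starts=seg.starts.copy(), periods=seg.periods.copy())


@dataclass
class VoCSeries:
    """Per-group, per-cycle variance of the normalised correlations."""

    values: np.ndarray  # (n_groups, n_cycles)
    groups: tuple[str, ...]
    starts: np.ndarray
    periods: np.ndarray
    axes: str = "xy"

    def group(self, name: str) -> np.ndarray:
        return self.values[self.groups.index(name)]

    def stepwise(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Expand a group's VoC to a per-frame step function of time.

        Returns ``(frame_indices, values)`` covering the segmented span;
        each cycle's VoC is held constant over its ``[t_i, t_i + tau_i)``.
        """
        g = self.group(name)
        n = int(self.starts[-1] + self.periods[-1])
        t = np.arange(self.starts[0], n)
        v = np.repeat(g, self.periods)
        return t, v


def voc(corr: CorrelationMatrix, config: FeaturePointConfig, dims: int,
        axes: str | None = None) -> VoCSeries:
    """Variance of correlation per body-part group and cycle.

    ``axes`` selects which coordinate axes enter the variance; by default
    x and y only (also for 3D data, mirroring the original analysis; pass
    ``"xyz"`` to include vertical components).  The variance is the
    population second central moment (divisor = component count).
    """
    if axes is None:
        axes = "xy"
    out = np.empty((len(config.group_names), corr.n_cycles))
    for gi, g in enumerate(config.group_names):
        comp = config.component_indices(g, dims, axes=axes)
        if len(comp) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 components "
                             f"for axes {axes!r}")
        sub = corr.values[:, comp]
        out[gi] = sub.var(axis=1)  # population variance
    return VoCSeries(values=out, groups=config.group_names,
                     starts=corr.starts.copy(), periods=corr.periods.copy(),
                     axes=axes)


@dataclass
class EventFlag:
    """A contiguous run of cycles whose VoC exceeds the threshold.

    ``label`` is a free annotation (slip/jump/stop/hesitation...); the
    interpretation of a peak is left to the user.
    """

    group: str
    cycle_start: int
    cycle_end: int  # exclusive
    frame_start: int
    frame_end: int
    peak_voc: float
    peak_cycle: int
    label: str = ""


def flag_events(voc_series: VoCSeries, threshold: float) -> list[EventFlag]:
    """Flag cycles with VoC above ``threshold``, merged into contiguous events."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    flags: list[EventFlag] = []
    for gi, g in enumerate(voc_series.groups):
        v = voc_series.values[gi]
        above = v > threshold
        i = 0
        while i < len(v):
            if above[i]:
                j = i
                while j < len(v) and above[j]:
                    j += 1
                peak = i + int(np.argmax(v[i:j]))
                flags.append(EventFlag(
                    group=g, cycle_start=i, cycle_end=j,
                    frame_start=int(voc_series.starts[i]),
                    frame_end=int(voc_series.starts[j - 1]
                                  + voc_series.periods[j - 1]),
                    peak_voc=float(v[peak]), peak_cycle=peak))
                i = j
            else:
                i += 1
    return flags


def plot_voc(voc_series: VoCSeries, flags: list[EventFlag] | None = None,
             fps: float | None = None, path: str | None = None):
    """Step plot of VoC against time per group, with optional event markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(voc_series.groups)
    fig, axes = plt.subplots(n, 1, sharex=True, figsize=(8, 2 * n))
    axes = np.atleast_1d(axes)
    for ax, g in zip(axes, voc_series.groups):
        t, v = voc_series.stepwise(g)
        tt = t / fps if fps else t
        ax.step(tt, v, where="post")
        ax.set_ylabel(f"VoC {g}")
        if flags:
            for f in flags:
                if f.group == g:
                    s = f.frame_start / fps if fps else f.frame_start
                    e = f.frame_end / fps if fps else f.frame_end
                    ax.axvspan(s, e, color="red", alpha=0.2)
    axes[-1].set_xlabel("time (s)" if fps else "speed frame")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
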