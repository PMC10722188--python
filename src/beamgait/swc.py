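"""Standard walk cycle (SWC) extraction by template-matched segmentation.

The SWC is a single-cycle speed waveform (one row per frame, one column per
coordinate component) representing an animal's typical gait.  It is obtained
by (1) choosing an initial cycle template from the culled speed series,
(2) segmenting the series into contiguous cycles whose periods may range
from half to double the template length, each cycle chosen to maximise its
correlation with the rescaled template, and (3) averaging the rescaled
cycles weighted by their correlation scores.  The cumulative weight is kept
so that further videos can refine the SWC as a running weighted mean.

Correlation here is the non-centred inner product between template and data
segment summed over components; the per-cycle weight Cmax is that inner
product normalised by the template's self-inner-product, so a template-like
cycle weighs ~1, a stationary one 0 and opposite movement negatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .kinematics import SpeedSeries
from .skeleton import FeaturePointConfig, default_config

__all__ = [
    "CycleTemplate",
    "CycleSegmentation",
    "StandardWalkCycle",
    "select_template",
    "suggest_template",
    "segment_cycles",
    "compute_swc",
    "refine_swc",
    "extract_swc",
    "rescale_cycle",
]


def rescale_cycle(values: np.ndarray, new_len: int) -> np.ndarray:
    """Linearly interpolate a (frames, components) block to ``new_len`` frames."""
    values = np.asarray(values, dtype=float)
    old_len = values.shape[0]
    if new_len == old_len:
        return values.copy()
    xi = np.linspace(0.0, old_len - 1.0, new_len)
    x = np.arange(old_len, dtype=float)
    out = np.empty((new_len, values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.interp(xi, x, values[:, j])
    return out


@dataclass
class CycleTemplate:
    """Initial walk-cycle template SWC0: ``tau0`` frames x components."""

    values: np.ndarray
    fps: float
    dims: int
    source: tuple[int, int] | None = None
    config: FeaturePointConfig = field(default_factory=default_config)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 4:
            raise ValueError("template needs at least 4 frames")
        if not np.isfinite(self.values).all():
            raise ValueError("template contains non-finite values")
        if float(np.sum(self.values ** 2)) == 0.0:
            raise ValueError("zero-norm template")

    @property
    def tau0(self) -> int:
        return self.values.shape[0]


@dataclass
class CycleSegmentation:
    """Contiguous cycle decomposition of a speed series.

    ``starts[i]`` is the first speed frame of cycle i and equals the sum of
    the preceding periods; ``periods[i]`` its length; ``scores[i]`` the
    normalised correlation weight Cmax.  The discarded tail (shorter than
    the minimum period) starts at ``tail_start``.
    """

    starts: np.ndarray
    periods: np.ndarray
    scores: np.ndarray
    template_len: int
    tail_start: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)
        self.periods = np.asarray(self.periods, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.starts) == len(self.periods) == len(self.scores)):
            raise ValueError("starts/periods/scores length mismatch")
        if len(self.starts):
            expected = np.concatenate([[self.starts[0]],
                                       self.starts[0] + np.cumsum(self.periods[:-1])])
            if not np.array_equal(self.starts, expected):
                raise ValueError("cycles must be contiguous")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite scores")

    @property
    def n_cycles(self) -> int:
        return len(self.starts)


@dataclass
class StandardWalkCycle:
    """The SWC: one cycle of speeds plus the cumulative correlation weight."""

    values: np.ndarray
    weight: float
    fps: float
    dims: int
    config_hash: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("SWC values must be 2D")
        if not self.weight > 0:
            raise ValueError("cumulative weight must be positive")

    @property
    def tau(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


def select_template(speed: SpeedSeries, t_start: int, t_end: int) -> CycleTemplate:
    """Copy the interval ``[t_start, t_end)`` of the culled series as SWC0."""
    if not (0 <= t_start < t_end <= speed.frames):
        raise ValueError(f"interval [{t_start}, {t_end}) out of range "
                         f"for {speed.frames} frames")
    if t_end - t_start < 4:
        raise ValueError("template interval must span at least 4 frames")
    return CycleTemplate(values=speed.values[t_start:t_end].copy(),
                         fps=speed.fps, dims=speed.dims,
                         source=(t_start, t_end), config=speed.config)


def suggest_template(speed: SpeedSeries, min_period: int = 4,
                     min_autocorr: float = 0.3) -> tuple[int, int]:
    """Suggest a template interval from foot-movement periodicity.

    The dominant period is the first prominent peak of the autocorrelation
    of the summed foot-group x-speed energy; the interval is the
    highest-energy window of that length.  Raises if no periodic structure
    is present (flat autocorrelation).
    """
    feet_x = speed.config.component_indices("feet", speed.dims, axes="x")
    n = speed.frames
    if n < 3 * min_period:
        raise ValueError("series too short to detect periodicity")
    # autocorrelate each foot's x-speed separately and average: each foot
    # swings once per stride, so the average peaks at the stride period
    # (the *summed* footfall energy would alias at the sub-phase rhythm)
    acs = []
    for j in feet_x:
        e = speed.values[:, j] - speed.values[:, j].mean()
        denom = float(np.dot(e, e))
        if denom > 0.0:
            acs.append(np.correlate(e, e, mode="full")[n - 1:] / denom)
    if not acs:
        raise ValueError("no periodic foot movement detected "
                         "(constant foot speed)")
    ac = np.mean(acs, axis=0)
    peaks, props = find_peaks(ac[min_period:], height=min_autocorr)
    if len(peaks) == 0:
        raise ValueError("no periodic foot movement detected "
                         "(flat autocorrelation)")
    period = int(peaks[np.argmax(props["peak_heights"])]) + min_period
    if period > n // 3:
        raise ValueError("detected period leaves fewer than 3 cycles")
    energy = np.sum(speed.values[:, feet_x] ** 2, axis=1)
    # highest-energy window of one period, then shift its start to the
    # quietest frame inside it so cycle boundaries sit in the support
    # phase rather than mid-swing
    csum = np.concatenate([[0.0], np.cumsum(energy)])
    win = csum[period:] - csum[:-period]
    t_star = int(np.argmax(win))
    local = energy[t_star:t_star + period]
    t0 = t_star + int(np.argmin(local))
    if t0 + period > n:
        t0 = n - period
    return t0, t0 + period


def _correlation(template_tau: np.ndarray, segment: np.ndarray) -> float:
    """Non-centred inner product summed over components."""
    return float(np.sum(template_tau * segment))


def segment_cycles(speed: SpeedSeries, template: CycleTemplate,
                   ratio_bounds: tuple[float, float] = (0.5, 2.0),
                   mode: str = "dp") -> CycleSegmentation:
    """Segment a culled speed series into contiguous template-matched cycles.

    Candidate periods are the integers between ``ceil(tau0*lo)`` and
    ``floor(tau0*hi)``; for each the template is rescaled to that length by
    linear interpolation and correlated (non-centred inner product summed
    over components) with the data window.

    ``mode='dp'`` (default) maximises the total correlation sum over *all*
    contiguous segmentations by dynamic programming — the full search over
    the finite grid of candidate segmentations.  Because each cycle's
    correlation is a sum over its own frames, constant components are
    segmentation-neutral and the discarded tail earns nothing, so
    boundaries are located by the informative periodic components.
    ``mode='greedy'`` walks left to right choosing, at each start, the
    period with the highest normalised correlation (cosine); it is faster
    on long series but a noisy boundary can ripple into the next period.
    Ties go to the smaller period.

    The recorded per-cycle score is the weight Cmax: the correlation sum
    normalised by the rescaled template's self-inner-product, so a
    template-like cycle scores ~1, a stationary one 0, opposite movement
    negatively.
    """
    tau0 = template.tau0
    lo = max(2, int(np.ceil(tau0 * ratio_bounds[0])))
    hi = max(lo, int(np.floor(tau0 * ratio_bounds[1])))
    n = speed.frames
    if n < lo:
        raise ValueError(f"series ({n} frames) shorter than one minimal "
                         f"period ({lo})")
    if speed.values.shape[1] != template.values.shape[1]:
        raise ValueError("component count mismatch between series and template")

    taus = range(lo, hi + 1)
    rescaled = {tau: rescale_cycle(template.values, tau) for tau in taus}
    norms = {tau: float(np.sum(r * r)) for tau, r in rescaled.items()}
    V = speed.values

    def inner(t: int, tau: int) -> float:
        return _correlation(rescaled[tau], V[t:t + tau])

    starts: list[int] = []
    periods: list[int] = []
    scores: list[float] = []

    if mode == "greedy":
        t = 0
        while t + lo <= n:
            best_cos, best_tau, best_cmax = -np.inf, lo, 0.0
            for tau in taus:
                if t + tau > n:
                    break
                ip = inner(t, tau)
                seg_norm = float(np.sum(V[t:t + tau] ** 2))
                cos = ip / np.sqrt(norms[tau] * seg_norm) if seg_norm else 0.0
                if cos > best_cos + 1e-12:
                    best_cos, best_tau, best_cmax = cos, tau, ip / norms[tau]
            starts.append(t)
            periods.append(best_tau)
            scores.append(best_cmax)
            t += best_tau
        tail_start = t
    elif mode == "dp":
        best = np.zeros(n + 1)
        choice = np.zeros(n + 1, dtype=int)
        for t in range(n - lo, -1, -1):
            for tau in taus:
                if t + tau > n:
                    break
                cand = inner(t, tau) + best[t + tau]
                if cand > best[t] + 1e-12:
                    best[t] = cand
                    choice[t] = tau
        t = 0
        while t <= n - lo and choice[t] > 0:
            tau = int(choice[t])
            starts.append(t)
            periods.append(tau)
            scores.append(inner(t, tau) / norms[tau])
            t += tau
        tail_start = t
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if not starts:
        raise ValueError("no cycles found (no positively correlated window)")
    return CycleSegmentation(starts=np.array(starts), periods=np.array(periods),
                             scores=np.array(scores), template_len=tau0,
                             tail_start=tail_start)


def compute_swc(speed: SpeedSeries, seg: CycleSegmentation,
                target_len: int | None = None,
                config_hash: str = "") -> StandardWalkCycle:
    """Correlation-weighted average of the rescaled cycles.

    Each cycle is rescaled to ``target_len`` (default: the template length)
    and averaged with its Cmax weight.  Cycles with non-positive weight are
    excluded with a warning; they contribute to neither the average nor the
    cumulative weight.
    """
    if seg.n_cycles == 0:
        raise ValueError("empty segmentation")
    if target_len is None:
        target_len = seg.template_len
    pos = seg.scores > 0
    if not pos.any():
        raise ValueError("all cycle scores are non-positive")
    if not pos.all():
        warnings.warn(f"dropping {int((~pos).sum())} cycle(s) with "
                      "non-positive correlation weight", stacklevel=2)
    acc = np.zeros((target_len, speed.values.shape[1]))
    total = 0.0
    for s, tau, w in zip(seg.starts[pos], seg.periods[pos], seg.scores[pos]):
        cyc = rescale_cycle(speed.values[s:s + tau], target_len)
        acc += w * cyc
        total += w
    return StandardWalkCycle(values=acc / total, weight=total, fps=speed.fps,
                             dims=speed.dims,
                             config_hash=config_hash or speed.config.config_hash())


def refine_swc(prev: StandardWalkCycle, new_speed: SpeedSeries,
               ratio_bounds: tuple[float, float] = (0.5, 2.0),
               mode: str = "greedy") -> StandardWalkCycle:
    """Fold a new video into an existing SWC as a running weighted mean.

    The previous SWC serves as the matching template for the new series;
    the result combines previous and new values with their cumulative
    weights, so sequential refinement equals batch extraction over the
    concatenated data (up to segmentation boundary effects).
    """
    if new_speed.values.shape[1] != prev.n_components:
        raise ValueError("component count mismatch between SWC and new series")
    if new_speed.dims != prev.dims:
        raise ValueError("dimensionality mismatch between SWC and new series")
    template = CycleTemplate(values=prev.values, fps=prev.fps, dims=prev.dims,
                             config=new_speed.config)
    seg = segment_cycles(new_speed, template, ratio_bounds, mode=mode)
    new = compute_swc(new_speed, seg, target_len=prev.tau,
                      config_hash=prev.config_hash)
    total = prev.weight + new.weight
    values = (prev.weight * prev.values + new.weight * new.values) / total
    return StandardWalkCycle(values=values, weight=total, fps=prev.fps,
                             dims=prev.dims, config_hash=prev.config_hash)


def extract_swc(speed: SpeedSeries,
                template_interval: tuple[int, int] | None = None,
                ratio_bounds: tuple[float, float] = (0.5, 2.0),
                mode: str = "greedy",
                ) -> tuple[StandardWalkCycle, CycleSegmentation]:
    """Convenience pipeline: template (auto if not given) -> segment -> average."""
    if template_interval is None:
        template_interval = suggest_template(speed)
    template = select_template(speed, *template_interval)
    seg = segment_cycles(speed, template, ratio_bounds, mode=mode)
    swc = compute_swc(speed, seg)
    return swc, seg
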