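import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beamgait as bg
from beamgait.events import correlation_matrix, flag_events, voc
from beamgait.skeleton import default_config
from beamgait.swc import CycleSegmentation, StandardWalkCycle

from conftest import NOISE_SD


def _series_of_cycles(cycles):
    """Stack cycle blocks into a SpeedSeries plus its segmentation."""
    values = np.concatenate(cycles)
    periods = np.array([len(c) for c in cycles])
    starts = np.concatenate([[0], np.cumsum(periods[:-1])])
    sp = bg.SpeedSeries(values=values, fps=30, dims=3)
    seg = CycleSegmentation(starts=starts, periods=periods,
                            scores=np.ones(len(cycles)),
                            template_len=periods[0],
                            tail_start=int(periods.sum()))
    return sp, seg


@pytest.fixture(scope="module")
def base_cycle():
    rng = np.random.default_rng(0)
    return rng.normal(size=(20, 54))


class TestCorrelationSemantics:
    def test_scaled_cycles_score_by_factor(self, base_cycle):
        """A matching cycle scores 1 per component; doubled 2; negated -1;
        a stationary cycle 0."""
        swc = StandardWalkCycle(values=base_cycle, weight=1.0, fps=30,
                                dims=3)
        sp, seg = _series_of_cycles([base_cycle, 2 * base_cycle,
                                     -base_cycle, np.zeros_like(base_cycle)])
        corr = correlation_matrix(sp, swc, seg)
        assert np.allclose(corr.values[0], 1.0, atol=1e-9)
        assert np.allclose(corr.values[1], 2.0, atol=1e-9)
        assert np.allclose(corr.values[2], -1.0, atol=1e-9)
        assert np.allclose(corr.values[3], 0.0, atol=1e-9)

    def test_zero_norm_component_flagged(self, base_cycle):
        values = base_cycle.copy()
        values[:, 11] = 0.0
        swc = StandardWalkCycle(values=values, weight=1.0, fps=30, dims=3)
        sp, seg = _series_of_cycles([values])
        corr = correlation_matrix(sp, swc, seg)
        assert corr.zero_norm[11]
        assert corr.values[0, 11] == 0.0

    def test_rescaled_cycle_lengths(self):
        """A smooth cycle played at a different tempo still scores ~1."""
        from beamgait.swc import rescale_cycle
        t = np.arange(20) / 20
        smooth = np.stack([np.sin(2 * np.pi * (t + k / 54.0))
                           for k in range(54)], axis=1)
        swc = StandardWalkCycle(values=smooth, weight=1.0, fps=30, dims=3)
        stretched = rescale_cycle(smooth, 30)
        sp, seg = _series_of_cycles([stretched])
        corr = correlation_matrix(sp, swc, seg)
        # 20 -> 30 -> 20 resampling is not exact, but close to a match
        assert np.abs(corr.values[0] - 1.0).mean() < 0.05

    def test_empty_segmentation_rejected(self, base_cycle):
        swc = StandardWalkCycle(values=base_cycle, weight=1.0, fps=30,
                                dims=3)
        sp, _ = _series_of_cycles([base_cycle])
        seg = CycleSegmentation(starts=np.array([], dtype=int),
                                periods=np.array([], dtype=int),
                                scores=np.array([]), template_len=20,
                                tail_start=0)
        with pytest.raises(ValueError):
            correlation_matrix(sp, swc, seg)


class TestVoC:
    def _voc_of(self, rows):
        cfg = default_config()
        from beamgait.events import CorrelationMatrix
        n = len(rows)
        corr = CorrelationMatrix(values=np.asarray(rows, dtype=float),
                                 zero_norm=np.zeros(54, dtype=bool),
                                 starts=np.arange(n) * 20,
                                 periods=np.full(n, 20))
        return voc(corr, cfg, dims=3)

    def test_uniform_correlations_give_zero(self):
        v = self._voc_of([np.full(54, 0.7)])
        assert np.allclose(v.values, 0.0)

    def test_population_variance_arithmetic(self):
        """Group correlations {0, 2, 0, 2, ...} have population variance 1."""
        row = np.zeros(54)
        cfg = default_config()
        feet_xy = cfg.component_indices("feet", 3, axes="xy")
        row[feet_xy] = [0, 2, 0, 2, 0, 2, 0, 2]
        v = self._voc_of([row])
        assert v.group("feet")[0] == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_nonnegative_on_random_matrices(self, seed):
        rows = np.random.default_rng(seed).normal(
            size=(3, 54)) * 5
        v = self._voc_of(list(rows))
        assert np.all(v.values >= 0)

    def test_scaling_anti_symmetry(self, base_cycle):
        """Scaling a cycle by c scales its correlation row by c and its
        VoC by c^2."""
        swc = StandardWalkCycle(values=base_cycle, weight=1.0, fps=30,
                                dims=3)
        c = 3.0
        sp, seg = _series_of_cycles([base_cycle, c * base_cycle])
        corr = correlation_matrix(sp, swc, seg)
        assert np.allclose(corr.values[1], c * corr.values[0], atol=1e-9)
        v = voc(corr, default_config(), dims=3)
        # row 0 is uniform (all ones) so compare against a structured row
        rng = np.random.default_rng(1)
        cyc = base_cycle * rng.uniform(0.5, 1.5, size=54)
        sp2, seg2 = _series_of_cycles([cyc, c * cyc])
        v2 = voc(correlation_matrix(sp2, swc, seg2), default_config(),
                 dims=3)
        assert np.allclose(v2.values[:, 1], c ** 2 * v2.values[:, 0],
                           rtol=1e-9)

    def test_small_group_rejected(self):
        from beamgait.events import CorrelationMatrix
        from beamgait.skeleton import FeaturePointConfig
        cfg = FeaturePointConfig(groups={"a": ("p1",), "b": ("p2", "p3")})
        corr = CorrelationMatrix(values=np.ones((1, 9)),
                                 zero_norm=np.zeros(9, dtype=bool),
                                 starts=np.array([0]),
                                 periods=np.array([20]))
        with pytest.raises(ValueError, match="fewer than 2"):
            voc(corr, cfg, dims=3, axes="x")

    def test_stepwise_expansion(self):
        v = self._voc_of([np.zeros(54), np.arange(54.0)])
        t, vals = v.stepwise("head")
        assert len(t) == 40
        assert np.allclose(vals[:20], v.group("head")[0])
        assert np.allclose(vals[20:], v.group("head")[1])


class TestEventFlags:
    def test_zero_voc_gives_no_flags(self):
        from beamgait.events import VoCSeries
        v = VoCSeries(values=np.zeros((4, 5)),
                      groups=("head", "body", "tail", "feet"),
                      starts=np.arange(5) * 20, periods=np.full(5, 20))
        assert flag_events(v, threshold=0.1) == []

    def test_threshold_zero_flags_every_positive_cycle(self):
        from beamgait.events import VoCSeries
        values = np.zeros((4, 5))
        values[3, 1] = 0.2
        values[3, 3] = 0.4
        v = VoCSeries(values=values,
                      groups=("head", "body", "tail", "feet"),
                      starts=np.arange(5) * 20, periods=np.full(5, 20))
        flags = flag_events(v, threshold=0.0)
        assert [(f.group, f.cycle_start) for f in flags] == [
            ("feet", 1), ("feet", 3)]

    def test_contiguous_cycles_merge_into_one_event(self):
        from beamgait.events import VoCSeries
        values = np.zeros((1, 6))
        values[0, 2:5] = [0.3, 0.6, 0.2]
        v = VoCSeries(values=values, groups=("feet",),
                      starts=np.arange(6) * 10, periods=np.full(6, 10))
        flags = flag_events(v, threshold=0.1)
        assert len(flags) == 1
        f = flags[0]
        assert (f.cycle_start, f.cycle_end) == (2, 5)
        assert f.peak_cycle == 3 and f.peak_voc == pytest.approx(0.6)
        assert (f.frame_start, f.frame_end) == (20, 50)


class TestAnomalyLocalization:
    def test_slip_peaks_feet_voc_at_true_cycle(self):
        from beamgait.simulate import Anomaly
        spec = bg.GaitSpec(noise_sd_cm=NOISE_SD, seed=2,
                           anomalies=(Anomaly(cycle=6, kind="slip",
                                              magnitude=1.5,
                                              foot="rear-left"),))
        pose, truth = bg.simulate_gait(spec)
        sp = bg.compute_speed(pose)
        template = bg.select_template(sp, 0, 20)
        seg = bg.segment_cycles(sp, template)
        swc = bg.compute_swc(sp, seg)
        v = voc(correlation_matrix(sp, swc, seg), pose.config, dims=3)
        assert int(np.argmax(v.group("feet"))) == 6

    def test_jump_flags_feet_group(self):
        from beamgait.simulate import Anomaly
        spec = bg.GaitSpec(noise_sd_cm=NOISE_SD, seed=3,
                           anomalies=(Anomaly(cycle=5, kind="jump"),))
        pose, truth = bg.simulate_gait(spec)
        sp = bg.compute_speed(pose)
        template = bg.select_template(sp, 0, 20)
        seg = bg.segment_cycles(sp, template)
        swc = bg.compute_swc(sp, seg)
        v = voc(correlation_matrix(sp, swc, seg), pose.config, dims=3)
        flags = flag_events(v, threshold=0.05)
        feet_flags = [f for f in flags if f.group == "feet"]
        assert len(feet_flags) == 1
        assert feet_flags[0].cycle_start <= 5 < feet_flags[0].cycle_end


def test_plot_voc_writes_png(tmp_path):
    from beamgait.events import VoCSeries, plot_voc
    v = VoCSeries(values=np.array([[0.0, 0.3, 0.0]]), groups=("feet",),
                  starts=np.arange(3) * 20, periods=np.full(3, 20))
    flags = flag_events(v, threshold=0.1)
    out = tmp_path / "voc.png"
    plot_voc(v, flags, fps=30.0, path=str(out))
    assert out.exists() and out.stat().st_size > 0
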