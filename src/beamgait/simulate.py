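"""Ground-truthed synthetic beam-walking gait data.

The generator emulates the structure of quadruped locomotion on a balance
beam: feet alternate stance (stationary on the beam) and swing (a smooth
raised-cosine forward bump) following a repeating 2-3-3 support pattern —
one sub-phase with two diagonal feet swinging together, then two sub-phases
with a single swinging foot — while head, torso and tail points advance at
the stride rate with small periodic oscillations.  Per-cycle period jitter,
Gaussian tracking noise on positions, and injectable anomalies (stop, jump,
slip, phase shift) provide controlled deviations.  A pinhole stereo rig at
45 or 90 degrees projects the 3D scene together with the three calibration
line pairs (beam edges, box outer edges, box entrance edges).

Everything is reproducible from the spec's seed, and the returned ground
truth (true cycle boundaries, single-cycle waveform, camera matrices, 3D
lines) lets every pipeline stage be checked against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pose import PoseSequence
from .pose_io import CalibrationLineSet
from .skeleton import FOOT_LABELS, FeaturePointConfig, default_config

__all__ = ["GaitSpec", "Anomaly", "StereoRigSpec", "GroundTruth",
           "StereoProjection", "simulate_gait", "inject_anomaly",
           "project_stereo", "write_fixture",
           "DEFAULT_SUPPORT_PATTERN"]

# Support sets per sub-phase (feet ON the beam): 2-3-3, with front-left and
# rear-right swinging together in the first sub-phase (the "mouse M" pattern;
# mirror=True swaps left/right to get the "mouse F" variant).
DEFAULT_SUPPORT_PATTERN = (
    ("front-right", "rear-left"),
    ("front-left", "rear-left", "rear-right"),
    ("front-left", "front-right", "rear-right"),
)


@dataclass(frozen=True)
class Anomaly:
    """One injected gait anomaly.

    ``kind`` is one of ``stop`` (insert ``magnitude`` zero-speed frames at
    the cycle boundary), ``jump`` (both rear feet swing together in the
    cycle), ``slip`` (the target foot's z dips below the beam and recovers
    within its stance, with a small fore-aft slide; ``magnitude`` in cm),
    and ``phase_shift`` (the target foot's waveform is shifted by
    ``magnitude`` frames from the cycle onward).
    """

    cycle: int
    kind: str
    magnitude: float = 1.0
    foot: str = "rear-left"


@dataclass(frozen=True)
class GaitSpec:
    """Parameters of the synthetic gait (defaults mirror the study scale:
    18 points, 30 fps, 60 cm beam, ~20-frame stride period)."""

    period: int = 20
    n_cycles: int = 10
    fps: float = 30.0
    stride_cm: float = 5.0
    beam_length_cm: float = 60.0
    support_pattern: tuple[tuple[str, ...], ...] = DEFAULT_SUPPORT_PATTERN
    phase_fractions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    head_amp_cm: float = 0.6
    body_amp_cm: float = 0.6
    tail_amp_cm: float = 1.0
    foot_lift_cm: float = 1.0
    foot_sway_cm: float = 0.8
    noise_sd_cm: float = 0.0
    period_jitter: int = 0
    mirror: bool = False
    anomalies: tuple[Anomaly, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period < 8:
            raise ValueError("period must be at least 8 frames")
        for a in (self.head_amp_cm, self.body_amp_cm, self.tail_amp_cm,
                  self.foot_lift_cm, self.foot_sway_cm, self.noise_sd_cm):
            if a < 0:
                raise ValueError("amplitudes must be non-negative")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")
        if len(self.phase_fractions) != len(self.support_pattern):
            raise ValueError("one phase fraction per support sub-phase")
        for a in self.anomalies:
            if not 0 <= a.cycle < self.n_cycles:
                raise ValueError(f"anomaly cycle {a.cycle} out of range")
        self._swing_windows()  # validates the pattern

    def _support_pattern(self) -> tuple[tuple[str, ...], ...]:
        if not self.mirror:
            return self.support_pattern
        swap = {"front-left": "front-right", "front-right": "front-left",
                "rear-left": "rear-right", "rear-right": "rear-left"}
        return tuple(tuple(sorted(swap[f] for f in s))
                     for s in self.support_pattern)

    def _swing_windows(self) -> dict[str, tuple[float, float]]:
        """Phase-fraction interval (a, b) of each foot's swing."""
        bounds = np.concatenate([[0.0], np.cumsum(self.phase_fractions)])
        windows: dict[str, tuple[float, float]] = {}
        for k, support in enumerate(self._support_pattern()):
            for f in support:
                if f not in FOOT_LABELS:
                    raise ValueError(f"unknown foot label {f!r}")
            swing = [f for f in FOOT_LABELS if f not in support]
            for f in swing:
                if f in windows:
                    raise ValueError(
                        f"foot {f!r} swings in more than one sub-phase")
                windows[f] = (float(bounds[k]), float(bounds[k + 1]))
        if set(windows) != set(FOOT_LABELS):
            missing = set(FOOT_LABELS) - set(windows)
            raise ValueError(f"feet never swing: {sorted(missing)}")
        return windows


@dataclass
class GroundTruth:
    """Construction-level truth accompanying a simulated gait."""

    pose_clean: PoseSequence              # noiseless 3D positions (cm)
    boundaries: list[tuple[int, int]]     # (t_i, tau_i) on the speed timeline
    cycle_waveform: np.ndarray            # nominal single-cycle speed (period x 54)
    cycle_lengths: np.ndarray
    spec: GaitSpec
    anomaly_spans: list[tuple[Anomaly, int, int]] = field(default_factory=list)


# -- posture geometry -------------------------------------------------------

def _base_posture(config: FeaturePointConfig) -> np.ndarray:
    """Resting 18-point posture (cm) with beam top at z=0, nose toward +x."""
    pos = {
        "left-ear-tip": (3.0, -1.0, 4.0),
        "right-ear-tip": (3.0, 1.0, 4.0),
        "nose-tip": (4.2, 0.0, 3.2),
        "body-1": (2.2, 0.0, 3.4),
        "body-2": (1.4, 0.0, 3.6),
        "body-3": (0.6, 0.0, 3.5),
        "body-4": (-0.2, 0.0, 3.2),
        "front-left": (2.4, -0.8, 0.0),
        "front-right": (2.4, 0.8, 0.0),
        "rear-left": (0.2, -0.9, 0.0),
        "rear-right": (0.2, 0.9, 0.0),
    }
    for i in range(7):
        pos[f"tail-{i + 1}"] = (-1.0 - 0.9 * i, 0.0, 2.8 - 0.25 * i)
    return np.array([pos[p] for p in config.point_names])


def _swing_profile(u: np.ndarray) -> np.ndarray:
    """Normalized forward progress within a swing, smooth 0->1 (raised cosine)."""
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


class _GaitModel:
    """Evaluates noiseless point positions at arbitrary gait phases."""

    def __init__(self, spec: GaitSpec, config: FeaturePointConfig):
        self.spec = spec
        self.config = config
        self.x0 = _base_posture(config)
        self.windows = spec._swing_windows()
        self.names = config.point_names
        amp = {"head": spec.head_amp_cm, "body": spec.body_amp_cm,
               "tail": spec.tail_amp_cm, "feet": 0.0}
        self.amps = np.array([amp[config.group_of(p)] for p in self.names])
        # per-point phase offsets stagger the oscillations along the body
        self.osc_phase = np.array([0.37 * i for i in range(len(self.names))])

    def positions(self, phi: np.ndarray,
                  cycle_lengths: np.ndarray | None = None,
                  foot_windows: dict[str, dict[int, tuple[float, float]]] | None = None,
                  foot_phase_shift: dict[str, tuple[int, float]] | None = None,
                  ) -> np.ndarray:
        """Positions (len(phi), n_points, 3) at absolute gait phases ``phi``.

        Swing sub-phase boundaries are snapped to frame boundaries of the
        nominal period, so the support pattern is exact at the sampled
        frames of unjittered cycles and jittered cycles are exact time
        warps of the nominal waveform.  ``foot_windows`` optionally overrides one
        foot's swing window in specific cycles; ``foot_phase_shift``
        applies ``(from_cycle, delta)`` phase offsets to a foot (delta in
        cycle units).
        """
        spec = self.spec
        phi = np.asarray(phi, dtype=float)
        if cycle_lengths is None:
            cycle_lengths = np.array([spec.period])
        cycle_lengths = np.asarray(cycle_lengths, dtype=float)
        out = np.empty((len(phi), len(self.names), 3))
        two_pi = 2 * np.pi

        def snap(frac: np.ndarray, tau: np.ndarray) -> np.ndarray:
            return np.round(frac * tau) / tau

        for i, name in enumerate(self.names):
            base = self.x0[i]
            if name in FOOT_LABELS:
                p = phi.copy()
                if foot_phase_shift and name in foot_phase_shift:
                    c0, delta = foot_phase_shift[name]
                    p = np.where(p >= c0, p - delta, p)
                cyc = np.floor(p).astype(int)
                u = p - cyc
                per = float(self.spec.period)
                wa, wb = self.windows[name]
                a = snap(np.full_like(u, wa), per)
                b = snap(np.full_like(u, wb), per)
                if foot_windows and name in foot_windows:
                    for c, (oa, ob) in foot_windows[name].items():
                        m = cyc == c
                        a[m] = snap(np.full(m.sum(), oa), per)
                        b[m] = snap(np.full(m.sum(), ob), per)
                b = np.maximum(b, a + 1.0 / per)
                ul = np.clip((u - a) / (b - a), 0.0, 1.0)
                prog = _swing_profile(ul)
                out[:, i, 0] = base[0] + spec.stride_cm * (cyc + prog)
                lift = spec.foot_lift_cm * 0.5 * (1 - np.cos(two_pi * ul))
                lift[(ul <= 0) | (ul >= 1)] = 0.0
                out[:, i, 2] = base[2] + lift
                sway_sign = -1.0 if name.endswith("left") else 1.0
                sway = spec.foot_sway_cm * np.sin(np.pi * ul) * sway_sign
                sway[(ul <= 0) | (ul >= 1)] = 0.0
                out[:, i, 1] = base[1] + sway
            else:
                amp = self.amps[i]
                ph = self.osc_phase[i]
                out[:, i, 0] = (base[0] + spec.stride_cm * phi
                                + amp * np.sin(two_pi * phi + ph))
                out[:, i, 1] = base[1] + amp * np.sin(two_pi * phi + ph + 1.1)
                out[:, i, 2] = base[2] + amp * np.sin(two_pi * phi + ph + 2.3)
        return out


def _phases(cycle_lengths: np.ndarray) -> np.ndarray:
    """Absolute gait phase of every position frame (sum(tau)+1 frames)."""
    starts = np.concatenate([[0], np.cumsum(cycle_lengths)])
    total = int(starts[-1])
    phi = np.empty(total + 1)
    for c, tau in enumerate(cycle_lengths):
        t0 = int(starts[c])
        phi[t0:t0 + tau] = c + np.arange(tau) / tau
    phi[total] = len(cycle_lengths)
    return phi


def simulate_gait(spec: GaitSpec,
                  config: FeaturePointConfig | None = None,
                  ) -> tuple[PoseSequence, GroundTruth]:
    """Generate a synthetic 3D beam walk and its ground truth.

    Returns the (possibly noisy) pose sequence in cm with the beam along x,
    and a :class:`GroundTruth` with the noiseless pose, true cycle
    boundaries on the speed timeline, the nominal single-cycle speed
    waveform, and resolved anomaly spans.
    """
    config = config or default_config()
    rng = np.random.default_rng(spec.seed)
    if spec.period_jitter > 0:
        jit = rng.integers(-spec.period_jitter, spec.period_jitter + 1,
                           size=spec.n_cycles)
    else:
        jit = np.zeros(spec.n_cycles, dtype=int)
    cycle_lengths = spec.period + jit
    model = _GaitModel(spec, config)
    coords = model.positions(_phases(cycle_lengths), cycle_lengths)

    starts = np.concatenate([[0], np.cumsum(cycle_lengths)])
    boundaries = [(int(starts[c]), int(cycle_lengths[c]))
                  for c in range(spec.n_cycles)]

    # nominal single-cycle speed waveform (no jitter)
    nominal = model.positions(np.arange(spec.period + 1) / spec.period)
    waveform = np.diff(nominal.reshape(spec.period + 1, -1), axis=0)

    pose = PoseSequence(coords=coords, fps=spec.fps, units="cm", config=config)
    truth = GroundTruth(pose_clean=pose.copy(), boundaries=boundaries,
                        cycle_waveform=waveform, cycle_lengths=cycle_lengths,
                        spec=spec)
    for anomaly in spec.anomalies:
        pose, truth = inject_anomaly(pose, truth, anomaly)
    if spec.noise_sd_cm > 0:
        pose.coords = pose.coords + rng.normal(0.0, spec.noise_sd_cm,
                                               pose.coords.shape)
    return pose, truth


def inject_anomaly(pose: PoseSequence, truth: GroundTruth,
                   anomaly: Anomaly) -> tuple[PoseSequence, GroundTruth]:
    """Apply one anomaly to a simulated pose, updating the ground truth.

    Re-timing anomalies (jump, phase shift) are applied as the difference
    between a re-generated and the baseline noiseless trajectory, so only
    the targeted foot's coordinates change.
    """
    spec = truth.spec
    config = pose.config
    model = _GaitModel(spec, config)
    phi = _phases(truth.cycle_lengths)
    starts = np.concatenate([[0], np.cumsum(truth.cycle_lengths)])
    c = anomaly.cycle
    t0, tau = int(starts[c]), int(truth.cycle_lengths[c])
    coords = pose.coords.copy()
    clean = truth.pose_clean.coords.copy()
    spans = list(truth.anomaly_spans)

    if anomaly.kind == "stop":
        k = int(round(anomaly.magnitude))
        if k < 0:
            raise ValueError("stop duration must be non-negative")
        if k > 0:
            block = np.repeat(coords[t0:t0 + 1], k, axis=0)
            coords = np.concatenate([coords[:t0], block, coords[t0:]])
            block_c = np.repeat(clean[t0:t0 + 1], k, axis=0)
            clean = np.concatenate([clean[:t0], block_c, clean[t0:]])
            truth.boundaries = [(t + k, tt) if t >= t0 else (t, tt)
                                for t, tt in truth.boundaries]
            spans = [(a, s + k, e + k) if s >= t0 else (a, s, e)
                     for a, s, e in spans]
        spans.append((anomaly, t0, t0 + k))
    elif anomaly.kind in ("jump", "slip", "phase_shift"):
        foot = anomaly.foot
        if foot not in FOOT_LABELS:
            raise ValueError(f"unknown foot {anomaly.foot!r}")
        fi = config.point_names.index(foot)
        base = model.positions(phi, truth.cycle_lengths)
        if anomaly.kind == "jump":
            # both rear feet swing together: move the other rear foot's
            # swing into this foot's partner window for one cycle
            other = "rear-right" if foot == "rear-left" else "rear-left"
            oi = config.point_names.index(other)
            win = {other: {c: model.windows[foot]}}
            mod = model.positions(phi, truth.cycle_lengths, foot_windows=win)
            delta = anomaly.magnitude * (mod[:, oi] - base[:, oi])
            coords[:, oi] += delta
            clean[:, oi] += delta
        elif anomaly.kind == "phase_shift":
            delta_phase = anomaly.magnitude / spec.period
            mod = model.positions(
                phi, truth.cycle_lengths,
                foot_phase_shift={foot: (c, delta_phase)})
            delta = mod[:, fi] - base[:, fi]
            coords[:, fi] += delta
            clean[:, fi] += delta
        else:  # slip: z dip during stance + a compressed catch-step swing
            wa, wb = model.windows[foot]
            m = anomaly.magnitude
            # the recovering foot swings faster (compressed swing window),
            # which is what the cycle-to-SWC correlation reacts to
            frac = 1.0 - min(0.8, 0.5 * m)
            win = {foot: {c: (wa, wa + (wb - wa) * frac)}}
            mod = model.positions(phi, truth.cycle_lengths, foot_windows=win)
            delta = mod[:, fi] - base[:, fi]
            coords[:, fi] += delta
            clean[:, fi] += delta
            # visible z dip below the beam during the stance stretch
            u = phi - c
            lo, hi = (wb, 1.0) if wb < 1.0 - 1e-9 else (0.0, wa)
            mask = (u >= lo) & (u < hi)
            v = (u[mask] - lo) / (hi - lo)
            dip = m * 0.5 * (1 - np.cos(2 * np.pi * v))
            coords[mask, fi, 2] -= dip
            clean[mask, fi, 2] -= dip
        spans.append((anomaly, t0, t0 + tau))
    else:
        raise ValueError(f"unknown anomaly kind {anomaly.kind!r}")

    new_pose = replace(pose, coords=coords)
    new_truth = replace(truth,
                        pose_clean=replace(truth.pose_clean, coords=clean),
                        anomaly_spans=spans)
    return new_pose, new_truth


# -- stereo projection ------------------------------------------------------

@dataclass(frozen=True)
class StereoRigSpec:
    """Two-camera pinhole rig, 45-degree stereo or 90-degree opposed."""

    configuration: str = "45"          # "45" or "90"
    distance_cm: float = 80.0
    height_cm: float = 12.0
    focal_px: float = 900.0
    image_size: tuple[int, int] = (1280, 720)
    beam_length_cm: float = 60.0
    incline_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.configuration not in ("45", "90"):
            raise ValueError("configuration must be '45' or '90'")


def _look_at(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World->camera rotation with optical axis toward target, image y down."""
    z = target - position
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    x = np.cross(z, up)
    if np.linalg.norm(x) < 1e-12:
        raise ValueError("camera looking straight up/down")
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)  # points downward-ish: pixel y grows downward
    return np.stack([x, y, z])


def _camera_matrices(rig: StereoRigSpec) -> tuple[np.ndarray, np.ndarray]:
    L = rig.beam_length_cm
    target = np.array([L / 2, 0.0, 2.0])
    d = rig.distance_cm
    h = rig.height_cm
    if rig.configuration == "45":
        c = d / np.sqrt(2.0)
        posL = np.array([L / 2 - c, -c, h])
        posR = np.array([L / 2 - c, c, h])
    else:
        posL = np.array([L / 2, -d, h])
        posR = np.array([L / 2, d, h])
    w, hh = rig.image_size
    K = np.array([[rig.focal_px, 0, w / 2],
                  [0, rig.focal_px, hh / 2],
                  [0, 0, 1.0]])
    Ps = []
    for pos in (posL, posR):
        R = _look_at(pos, target)
        t = -R @ pos
        Ps.append(K @ np.hstack([R, t[:, None]]))
    return Ps[0], Ps[1]


def _calibration_lines_3d(rig: StereoRigSpec) -> dict[str, np.ndarray]:
    """Ground-truth 3D calibration segments in beam-aligned coordinates.

    Beam edges run along x; box outer edges along y; box entrance edges are
    vertical in the gravity frame, i.e. tilted by -incline in beam
    coordinates when the beam is inclined.
    """
    L = rig.beam_length_cm
    th = np.deg2rad(rig.incline_deg)
    zdir = np.array([-np.sin(th), 0.0, np.cos(th)])
    ent = lambda y: np.stack([np.array([L + 2, y, -2.0]),
                              np.array([L + 2, y, -2.0]) + 10.0 * zdir])
    return {
        "beam": np.array([[[0.0, 0.0, 0.0], [L, 0.0, 0.0]],
                          [[0.0, 0.0, -2.54], [L, 0.0, -2.54]]]),
        "box_y": np.array([[[L + 2, -5.0, 8.0], [L + 2, 5.0, 8.0]],
                           [[L + 14, -5.0, 8.0], [L + 14, 5.0, 8.0]]]),
        "box_z": np.array([ent(-5.0), ent(5.0)]),
    }


def _project(P: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Pinhole projection of (..., 3) world points to (..., 2) pixels."""
    shape = pts.shape[:-1]
    h = np.concatenate([pts.reshape(-1, 3), np.ones((pts.size // 3, 1))],
                       axis=1)
    proj = (P @ h.T).T
    if np.any(proj[:, 2] <= 1e-9):
        raise ValueError("point behind camera")
    return (proj[:, :2] / proj[:, 2:3]).reshape(*shape, 2)


@dataclass
class StereoProjection:
    """Projected views with the rig's construction-level truth."""

    pose_left: PoseSequence
    pose_right: PoseSequence
    lines: CalibrationLineSet
    P_left: np.ndarray
    P_right: np.ndarray
    lines_3d: dict[str, np.ndarray]


def project_stereo(pose3d: PoseSequence, rig: StereoRigSpec,
                   pixel_noise_sd: float = 0.0,
                   seed: int = 0) -> StereoProjection:
    """Project a 3D gait and the calibration lines through a stereo rig."""
    if pose3d.dims != 3:
        raise ValueError("need a 3D pose sequence")
    PL, PR = _camera_matrices(rig)
    lines3d = _calibration_lines_3d(rig)
    rng = np.random.default_rng(seed)
    views = {}
    poses = []
    for name, P in (("left", PL), ("right", PR)):
        pix = _project(P, pose3d.coords)
        segs = {}
        for label, seg in lines3d.items():
            pts = _project(P, seg.reshape(-1, 3)).reshape(2, 2, 2)
            if pixel_noise_sd > 0:
                pts = pts + rng.normal(0, pixel_noise_sd, pts.shape)
            segs[label] = pts
        if pixel_noise_sd > 0:
            pix = pix + rng.normal(0, pixel_noise_sd, pix.shape)
        poses.append(PoseSequence(coords=pix, fps=pose3d.fps, units="px",
                                  config=pose3d.config))
        views[name] = segs
    lines = CalibrationLineSet(views=views)
    return StereoProjection(pose_left=poses[0], pose_right=poses[1],
                            lines=lines, P_left=PL, P_right=PR,
                            lines_3d=lines3d)


def write_fixture(out_dir, spec: GaitSpec,
                  rig: StereoRigSpec | None = None,
                  pixel_noise_sd: float = 0.0) -> dict[str, str]:
    """Emit a complete on-disk fixture: tracking tables for both views,
    calibration-line file, run config, and a ground-truth sidecar (JSON).

    Returns the mapping of artifact names to file paths.
    """
    import json
    from pathlib import Path

    from . import pose_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rig = rig or StereoRigSpec(beam_length_cm=spec.beam_length_cm)
    pose, truth = simulate_gait(spec)
    proj = project_stereo(pose, rig, pixel_noise_sd=pixel_noise_sd,
                          seed=spec.seed + 1)
    paths = {}
    for name, p in (("left", proj.pose_left), ("right", proj.pose_right)):
        path = out / f"tracking_{name}.csv"
        pose_io.write_tracking_table(path, p)
        paths[f"tracking_{name}"] = str(path)
    lines_path = out / "calibration_lines.yaml"
    pose_io.write_calibration_lines(lines_path, proj.lines)
    paths["lines"] = str(lines_path)
    cfg_path = out / "config.yaml"
    pose_io.write_run_config(cfg_path, fps=spec.fps,
                             beam_length_cm=spec.beam_length_cm,
                             incline_deg=rig.incline_deg,
                             config=pose.config)
    paths["config"] = str(cfg_path)
    truth_path = out / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump({
            "boundaries": [[int(t), int(tau)] for t, tau in truth.boundaries],
            "cycle_waveform": truth.cycle_waveform.tolist(),
            "anomalies": [
                {"kind": a.kind, "cycle": a.cycle, "foot": a.foot,
                 "magnitude": a.magnitude, "span": [int(s), int(e)]}
                for a, s, e in truth.anomaly_spans],
            "seed": spec.seed,
            "rig": rig.configuration,
        }, fh)
    paths["ground_truth"] = str(truth_path)
    pose3d_path = out / "pose3d_true.csv"
    pose_io.write_pose_csv(pose3d_path, truth.pose_clean)
    paths["pose3d_true"] = str(pose3d_path)
    return paths
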