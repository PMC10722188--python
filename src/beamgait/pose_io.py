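"""Readers and writers for tracking tables, calibration lines, configs and
the persistent SWC file.

Tracking tables use the DeepLabCut convention: a table whose columns form a
scorer / bodyparts / coords hierarchy with an ``x``, ``y`` (and optional
``likelihood``) column per body part, one row per frame.  Both the CSV and
HDF5 dialects are accepted, auto-detected by file extension.  Entries whose
likelihood falls below a threshold are treated as gaps (NaN) to be filled
by linear interpolation — a stand-in for the manual curation the original
workflow performs.

The SWC file is a self-describing versioned text format (header lines
starting with ``#`` followed by a numeric block) so that extracted cycles
diff cleanly under version control; values and the cumulative weight
round-trip bit-exactly via 17-significant-digit decimal encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import SpeedSeries
from .pose import PoseSequence
from .skeleton import FeaturePointConfig, default_config
from .swc import StandardWalkCycle

__all__ = [
    "CalibrationLineSet",
    "read_tracking_table", "write_tracking_table", "fill_gaps",
    "read_swc", "write_swc",
    "read_calibration_lines", "write_calibration_lines",
    "read_run_config", "write_run_config", "RunConfig",
    "write_pose_csv", "read_pose_csv",
    "write_speed_csv", "read_speed_csv",
]

SWC_FORMAT_VERSION = 1
REQUIRED_LINE_LABELS = ("beam", "box_y", "box_z")


# -- calibration lines ------------------------------------------------------

@dataclass
class CalibrationLineSet:
    """Three labeled pairs of parallel segments traced in each view.

    ``views`` maps view name -> {label -> array (2 segments, 2 endpoints,
    2 coords in px)}.  The labels are ``beam`` (upper/lower beam edges,
    defining the x direction), ``box_y`` (outer goal-box edges, y) and
    ``box_z`` (goal-box entrance edges, z).
    """

    views: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.views) != 2:
            raise ValueError("calibration needs exactly two views")
        labelsets = []
        for view, segs in self.views.items():
            labelsets.append(tuple(sorted(segs)))
            for label in REQUIRED_LINE_LABELS:
                if label not in segs:
                    raise ValueError(f"view {view!r} missing line pair "
                                     f"{label!r}")
            for label, arr in segs.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (2, 2, 2):
                    raise ValueError(
                        f"{view}/{label}: expected 2 segments x 2 endpoints "
                        f"x 2 coords, got {arr.shape}")
                for s in range(2):
                    if np.linalg.norm(arr[s, 1] - arr[s, 0]) <= 0:
                        raise ValueError(f"{view}/{label}: zero-length "
                                         "segment")
                if np.allclose(arr[0], arr[1]):
                    raise ValueError(f"{view}/{label}: identical segments")
                segs[label] = arr
        if labelsets[0] != labelsets[1]:
            raise ValueError("views carry different line labels")

    def view_names(self) -> tuple[str, str]:
        return tuple(self.views)

    def correspondences(self) -> tuple[np.ndarray, np.ndarray]:
        """The 12 corresponding line endpoints per view, as (12, 2) arrays."""
        vn = self.view_names()
        out = []
        for v in vn:
            pts = [self.views[v][label].reshape(-1, 2)
                   for label in REQUIRED_LINE_LABELS]
            out.append(np.concatenate(pts))
        return out[0], out[1]


def write_calibration_lines(path, lines: CalibrationLineSet) -> None:
    doc = {"views": {
        v: {label: np.asarray(arr, dtype=float).tolist()
            for label, arr in segs.items()}
        for v, segs in lines.views.items()}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_calibration_lines(path) -> CalibrationLineSet:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "views" not in doc:
        raise ValueError(f"{path}: not a calibration-line file")
    views = {v: {label: np.asarray(arr, dtype=float)
                 for label, arr in segs.items()}
             for v, segs in doc["views"].items()}
    return CalibrationLineSet(views=views)


# -- tracking tables --------------------------------------------------------

def write_tracking_table(path, pose: PoseSequence, scorer: str = "beamgait",
                         likelihood: np.ndarray | None = None) -> None:
    """Write a pose sequence in the scorer/bodyparts/coords layout.

    ``likelihood`` is an optional (frames, n_points) confidence array; if
    omitted, a likelihood of 1.0 is written for present coordinates and 0.0
    for NaN gaps.
    """
    path = Path(path)
    names = pose.config.point_names
    if likelihood is None:
        likelihood = np.where(np.isnan(pose.coords).any(axis=2), 0.0, 1.0)
    cols = []
    data = []
    axes = ("x", "y") if pose.dims == 2 else ("x", "y", "z")
    for i, name in enumerate(names):
        for a_idx, a in enumerate(axes):
            cols.append((scorer, name, a))
            data.append(pose.coords[:, i, a_idx])
        cols.append((scorer, name, "likelihood"))
        data.append(likelihood[:, i])
    df = pd.DataFrame(
        np.column_stack(data),
        columns=pd.MultiIndex.from_tuples(
            cols, names=["scorer", "bodyparts", "coords"]))
    if path.suffix in (".h5", ".hdf5"):
        df.to_hdf(path, key="df_with_missing", mode="w")
    else:
        df.to_csv(path)


def read_tracking_table(path, config: FeaturePointConfig | None = None,
                        fps: float = 30.0,
                        likelihood_threshold: float = 0.9) -> PoseSequence:
    """Read a DLC-style tracking table into a PoseSequence.

    Coordinates are reordered to the configuration's point order; entries
    with likelihood below ``likelihood_threshold`` become NaN gaps.  Raises
    a named error listing any configured point absent from the table.
    """
    path = Path(path)
    config = config or default_config()
    if path.suffix in (".h5", ".hdf5"):
        df = pd.read_hdf(path)
    else:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    if df.columns.nlevels != 3:
        raise ValueError(f"{path}: expected a scorer/bodyparts/coords "
                         "column hierarchy")
    present = set(df.columns.get_level_values(1))
    missing = [p for p in config.point_names if p not in present]
    if missing:
        raise ValueError(f"{path}: tracking table is missing body parts: "
                         f"{missing}")
    scorer = df.columns.get_level_values(0)[0]
    first = df[scorer][config.point_names[0]]
    dims = 3 if "z" in first.columns else 2
    axes = ("x", "y") if dims == 2 else ("x", "y", "z")
    frames = len(df)
    coords = np.empty((frames, config.n_points, dims))
    for i, name in enumerate(config.point_names):
        block = df[scorer][name]
        for a_idx, a in enumerate(axes):
            if a not in block.columns:
                raise ValueError(f"{path}: body part {name!r} lacks "
                                 f"coordinate {a!r}")
            col = block[a].to_numpy(dtype=float)
            if len(col) != frames:
                raise ValueError(f"{path}: ragged frame count for {name!r}")
            coords[:, i, a_idx] = col
        if "likelihood" in block.columns:
            bad = block["likelihood"].to_numpy(dtype=float) < likelihood_threshold
            coords[bad, i, :] = np.nan
    return PoseSequence(coords=coords, fps=fps, units="px", config=config)


def fill_gaps(pose: PoseSequence, max_gap: int = 5) -> PoseSequence:
    """Linearly interpolate interior NaN gaps of up to ``max_gap`` frames.

    Gaps longer than ``max_gap`` or touching the sequence boundary raise,
    since extrapolated coordinates would silently corrupt the kinematics.
    """
    coords = pose.coords.copy()
    frames = pose.frames
    t = np.arange(frames)
    for i in range(coords.shape[1]):
        gap = np.isnan(coords[:, i, :]).any(axis=1)
        if not gap.any():
            continue
        if gap[0] or gap[-1]:
            raise ValueError(
                f"point {pose.config.point_names[i]!r}: gap at sequence "
                "boundary cannot be interpolated")
        runs = np.flatnonzero(np.diff(np.concatenate([[0], gap.view(np.int8),
                                                      [0]])))
        for s, e in zip(runs[::2], runs[1::2]):
            if e - s > max_gap:
                raise ValueError(
                    f"point {pose.config.point_names[i]!r}: gap of "
                    f"{e - s} frames at {s} exceeds max_gap={max_gap}")
        ok = ~gap
        for d in range(coords.shape[2]):
            coords[gap, i, d] = np.interp(t[gap], t[ok], coords[ok, i, d])
    out = pose.copy()
    out.coords = coords
    return out


# -- SWC file ---------------------------------------------------------------

def write_swc(path, swc: StandardWalkCycle) -> None:
    """Write the versioned text SWC format (values + cumulative weight)."""
    path = Path(path)
    lines = [
        f"# beamgait-swc v{SWC_FORMAT_VERSION}",
        f"# tau={swc.tau} ncomp={swc.n_components} dims={swc.dims}",
        f"# fps={float(swc.fps)!r} weight={float(swc.weight)!r}",
        f"# config_hash={swc.config_hash}",
    ]
    body = "\n".join(" ".join(repr(float(v)) for v in row)
                     for row in swc.values)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_swc(path, expect_config_hash: str | None = None) -> StandardWalkCycle:
    """Read an SWC file; raises on version or configuration-hash mismatch."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty SWC file")
    lines = text.splitlines()
    if not lines[0].startswith("# beamgait-swc v"):
        raise ValueError(f"{path}: not an SWC file")
    version = int(lines[0].rsplit("v", 1)[1])
    if version != SWC_FORMAT_VERSION:
        raise ValueError(f"{path}: SWC format version {version} "
                         f"(expected {SWC_FORMAT_VERSION})")
    meta: dict[str, str] = {}
    body_start = 0
    for k, ln in enumerate(lines[1:], start=1):
        if not ln.startswith("#"):
            body_start = k
            break
        for tok in ln[1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = val
    tau, ncomp = int(meta["tau"]), int(meta["ncomp"])
    values = np.array([[float(v) for v in ln.split()]
                       for ln in lines[body_start:]])
    if values.shape != (tau, ncomp):
        raise ValueError(f"{path}: numeric block {values.shape} does not "
                         f"match header ({tau}, {ncomp})")
    config_hash = meta.get("config_hash", "")
    if expect_config_hash is not None and config_hash != expect_config_hash:
        raise ValueError(f"{path}: SWC was built for configuration "
                         f"{config_hash!r}, expected {expect_config_hash!r}")
    return StandardWalkCycle(values=values, weight=float(meta["weight"]),
                             fps=float(meta["fps"]), dims=int(meta["dims"]),
                             config_hash=config_hash)


# -- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis-wide settings loaded from the YAML config file."""

    fps: float = 30.0
    beam_length_cm: float = 60.0
    incline_deg: float = 0.0
    likelihood_threshold: float = 0.9
    max_gap: int = 5
    cull_intervals: list[tuple[int, int]] = field(default_factory=list)
    ratio_bounds: tuple[float, float] = (0.5, 2.0)
    voc_threshold: float = 0.05
    config: FeaturePointConfig = field(default_factory=default_config)

    def __post_init__(self) -> None:
        if not self.beam_length_cm > 0:
            raise ValueError("beam_length_cm must be positive")
        if not 0 <= self.incline_deg < 90:
            raise ValueError("incline_deg must be in [0, 90)")


def write_run_config(path, fps: float = 30.0, beam_length_cm: float = 60.0,
                     incline_deg: float = 0.0,
                     config: FeaturePointConfig | None = None,
                     **extra) -> None:
    config = config or default_config()
    doc = {
        "fps": fps,
        "beam_length_cm": beam_length_cm,
        "incline_deg": incline_deg,
        "groups": {g: list(p) for g, p in config.groups.items()},
        **extra,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_run_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: not a config file")
    kwargs = {}
    for key in ("fps", "beam_length_cm", "incline_deg",
                "likelihood_threshold", "max_gap", "voc_threshold"):
        if key in doc:
            kwargs[key] = doc[key]
    if "cull_intervals" in doc:
        kwargs["cull_intervals"] = [tuple(iv) for iv in doc["cull_intervals"]]
    if "ratio_bounds" in doc:
        kwargs["ratio_bounds"] = tuple(doc["ratio_bounds"])
    if "groups" in doc:
        kwargs["config"] = FeaturePointConfig(
            groups={g: tuple(p) for g, p in doc["groups"].items()})
    return RunConfig(**kwargs)


# -- plain CSV pose / speed tables -----------------------------------------

def write_pose_csv(path, pose: PoseSequence) -> None:
    """Flat CSV of a pose sequence with ``point_axis`` column names."""
    df = pd.DataFrame(pose.flat(),
                      columns=pose.config.component_names(pose.dims))
    header = (f"# beamgait-pose fps={pose.fps!r} dims={pose.dims} "
              f"units={pose.units}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index_label="frame")


def read_pose_csv(path, config: FeaturePointConfig | None = None) -> PoseSequence:
    config = config or default_config()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# beamgait-pose"):
            raise ValueError(f"{path}: not a beamgait pose CSV")
        meta = dict(tok.split("=") for tok in header.split()[2:])
        df = pd.read_csv(fh, index_col=0)
    dims = int(meta["dims"])
    coords = df.to_numpy(dtype=float).reshape(len(df), -1, dims)
    return PoseSequence(coords=coords, fps=float(meta["fps"]),
                        units=meta.get("units", "cm"), config=config)


def write_speed_csv(path, speed: SpeedSeries) -> None:
    df = pd.DataFrame(speed.values, columns=speed.component_names(),
                      index=speed.frame_index)
    header = (f"# beamgait-speed fps={speed.fps!r} dims={speed.dims} "
              f"units={speed.units} per_second={int(speed.per_second)}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index_label="frame")


def read_speed_csv(path, config: FeaturePointConfig | None = None) -> SpeedSeries:
    config = config or default_config()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# beamgait-speed"):
            raise ValueError(f"{path}: not a beamgait speed CSV")
        meta = dict(tok.split("=") for tok in header.split()[2:])
        df = pd.read_csv(fh, index_col=0)
    return SpeedSeries(values=df.to_numpy(dtype=float),
                       fps=float(meta["fps"]), dims=int(meta["dims"]),
                       units=meta.get("units", "px"),
                       per_second=bool(int(meta.get("per_second", "0"))),
                       config=config,
                       frame_index=df.index.to_numpy(dtype=int))
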