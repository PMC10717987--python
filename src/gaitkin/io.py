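"""Marker-trajectory container and TRC / CSV readers and writers.

TRC is the tab-separated ASCII trajectory format used throughout optical
motion capture: a 5-line header (file type, field names, rates/counts/units,
marker-name row, per-marker X/Y/Z row) followed by one row per frame of
``Frame# Time X1 Y1 Z1 X2 ...``.  Blank coordinate cells denote occluded
markers, never zero positions.  Coordinates are stored in the lab frame
defined in :mod:`gaitkin.kinematic_model` (X forward, Z up, mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import GaitKinError, TRCParseError

_TIME_UNIFORMITY_TOL = 1e-6  # s


@dataclass
class MarkerTrajectorySet:
    """Time-stamped labelled 3-D marker positions with an occlusion mask.

    Attributes
    ----------
    marker_names : ordered marker labels
    times : (T,) seconds, strictly increasing and uniformly spaced
    positions : (T, M, 3) mm; meaningful only where ``visible``
    visible : (T, M) bool, False = occluded in that frame
    sample_rate : Hz
    """

    marker_names: tuple[str, ...]
    times: np.ndarray
    positions: np.ndarray
    visible: np.ndarray = None
    sample_rate: float = None

    def __post_init__(self):
        self.marker_names = tuple(self.marker_names)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        T, M = len(self.times), len(self.marker_names)
        if self.positions.shape != (T, M, 3):
            raise GaitKinError(
                f"positions shape {self.positions.shape} != ({T}, {M}, 3)")
        if self.visible is None:
            self.visible = np.all(np.isfinite(self.positions), axis=2)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.visible.shape != (T, M):
            raise GaitKinError(f"visibility mask shape {self.visible.shape} != ({T}, {M})")
        if T > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise GaitKinError("times must be strictly increasing")
            if np.ptp(dt) > _TIME_UNIFORMITY_TOL:
                raise GaitKinError("times must be uniformly spaced")
            if self.sample_rate is None:
                self.sample_rate = 1.0 / float(np.mean(dt))
        elif self.sample_rate is None:
            self.sample_rate = 100.0
        if not np.all(np.isfinite(self.positions[self.visible])):
            raise GaitKinError("non-finite position marked visible")

    # -- queries ----------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(name) from None

    def trajectory(self, name: str) -> np.ndarray:
        """(T, 3) positions of one marker (NaN where occluded)."""
        j = self.index(name)
        out = self.positions[:, j].copy()
        out[~self.visible[:, j]] = np.nan
        return out

    def select(self, names) -> "MarkerTrajectorySet":
        """Subset of markers, positions bit-identical for retained names."""
        idx = [self.index(n) for n in names]
        return MarkerTrajectorySet(tuple(names), self.times,
                                   self.positions[:, idx],
                                   self.visible[:, idx], self.sample_rate)

    def frame(self, t_index: int) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """(positions dict for visible markers, visibility row) at one frame."""
        vis = self.visible[t_index]
        pos = {n: self.positions[t_index, j]
               for j, n in enumerate(self.marker_names) if vis[j]}
        return pos, vis

    def mean_positions(self) -> dict[str, np.ndarray]:
        """Per-marker time-average over visible frames."""
        out = {}
        for j, n in enumerate(self.marker_names):
            vis = self.visible[:, j]
            if not vis.any():
                continue
            out[n] = self.positions[vis, j].mean(axis=0)
        return out


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(data: MarkerTrajectorySet, path) -> None:
    """Write a trajectory set as a standard TRC file (mm)."""
    if data.n_frames == 0 or len(data.marker_names) == 0:
        raise GaitKinError("cannot write an empty trajectory set")
    path = Path(path)
    rate = data.sample_rate
    T, M = data.n_frames, len(data.marker_names)
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{T}\t{M}\tmm\t{rate:g}\t1\t{T}",
        "Frame#\tTime\t" + "\t\t\t".join(data.marker_names) + "\t\t",
        "\t\t" + "\t".join(f"X{j + 1}\tY{j + 1}\tZ{j + 1}" for j in range(M)),
        "",
    ]
    for t in range(T):
        cells = [str(t + 1), f"{data.times[t]:.6f}"]
        for j in range(M):
            if data.visible[t, j]:
                cells += [f"{v:.6f}" for v in data.positions[t, j]]
            else:
                cells += ["", "", ""]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_trc(path) -> MarkerTrajectorySet:
    """Read a TRC file; blank cells become occlusions, units normalized to mm."""
    raw = Path(path).read_text().splitlines()
    if len(raw) < 6:
        raise TRCParseError("file too short for a TRC header", line=len(raw))
    if not raw[0].startswith("PathFileType"):
        raise TRCParseError("expected PathFileType header", line=1)
    meta_keys = raw[1].split("\t")
    meta_vals = raw[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    try:
        rate = float(meta["DataRate"])
        n_frames = int(meta["NumFrames"])
        n_markers = int(meta["NumMarkers"])
        units = meta["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise TRCParseError(f"malformed metadata row ({exc})", line=3) from None
    if units not in ("mm", "m"):
        raise TRCParseError(f"unsupported units {units!r} (expected mm or m)", line=3)
    scale = 1000.0 if units == "m" else 1.0

    names = [c for c in raw[3].split("\t")[2:] if c.strip()]
    if len(names) != n_markers:
        raise TRCParseError(
            f"header declares {n_markers} markers but {len(names)} names found", line=4)

    data_lines = [(i + 1, ln) for i, ln in enumerate(raw) if i >= 5 and ln.strip()]
    if len(data_lines) != n_frames:
        raise TRCParseError(
            f"header declares {n_frames} frames but {len(data_lines)} data rows found",
            line=len(raw))

    times = np.empty(n_frames)
    pos = np.full((n_frames, n_markers, 3), np.nan)
    vis = np.zeros((n_frames, n_markers), dtype=bool)
    width = 2 + 3 * n_markers
    for t, (lineno, ln) in enumerate(data_lines):
        cells = ln.split("\t")
        if len(cells) < width:
            cells += [""] * (width - len(cells))
        elif len(cells) > width and any(c.strip() for c in cells[width:]):
            raise TRCParseError(
                f"row has more than the expected {width} columns", line=lineno)
        try:
            times[t] = float(cells[1])
        except ValueError:
            raise TRCParseError(f"bad time value {cells[1]!r}", line=lineno) from None
        for j in range(n_markers):
            triplet = cells[2 + 3 * j: 5 + 3 * j]
            if all(c.strip() for c in triplet):
                try:
                    pos[t, j] = [float(c) * scale for c in triplet]
                except ValueError:
                    raise TRCParseError(
                        f"bad coordinate in marker {names[j]!r}", line=lineno) from None
                vis[t, j] = True
            elif any(c.strip() for c in triplet):
                raise TRCParseError(
                    f"partial coordinate triplet for marker {names[j]!r}", line=lineno)
    return MarkerTrajectorySet(tuple(names), times, pos, vis, rate)


# ---------------------------------------------------------------------------
# CSV helpers (angles, normalized curves, events)
# ---------------------------------------------------------------------------

def write_angles_csv(path, times, q_matrix, residual_rms=None, q_names=None) -> None:
    """One row per frame: time, the 22 pose entries (deg/mm), residual RMS."""
    from .kinematic_model import Q_NAMES
    q_names = list(q_names or Q_NAMES)
    df = pd.DataFrame(np.asarray(q_matrix), columns=q_names)
    df.insert(0, "time_s", np.asarray(times))
    if residual_rms is not None:
        df["residual_rms_mm"] = np.asarray(residual_rms)
    df.to_csv(path, index=False)


def read_angles_csv(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Inverse of :func:`write_angles_csv`; returns (times, q_matrix, names)."""
    df = pd.read_csv(path)
    times = df.pop("time_s").to_numpy()
    if "residual_rms_mm" in df.columns:
        df = df.drop(columns=["residual_rms_mm"])
    return times, df.to_numpy(), list(df.columns)


def write_curves_csv(path, curves: dict[str, np.ndarray]) -> None:
    """Normalized gait curves: 102 columns (angle name + 101 cycle points)."""
    rows = []
    for name, values in curves.items():
        values = np.asarray(values, dtype=float)
        if values.shape != (101,):
            raise GaitKinError(f"curve {name!r} must have 101 points, got {values.shape}")
        rows.append([name, *values])
    pd.DataFrame(rows, columns=["angle", *[f"p{k}" for k in range(101)]]).to_csv(
        path, index=False)


def read_curves_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {row["angle"]: row.iloc[1:].to_numpy(dtype=float) for _, row in df.iterrows()}


def write_events_csv(path, times, label="right_heel_strike") -> None:
    pd.DataFrame({"time_s": np.asarray(times), "label": label}).to_csv(path, index=False)


def read_events_csv(path, label=None) -> np.ndarray:
    df = pd.read_csv(path)
    if label is not None:
        df = df[df["label"] == label]
    return df["time_s"].to_numpy(dtype=float)
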