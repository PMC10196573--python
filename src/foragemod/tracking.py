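"""Trajectory ingestion, coordinate alignment, kinematics and zone annotation.

The tracking dialect is a CSV with header ``frame,t,x,y`` (0-based frame
index, seconds, cm). A permissive importer accepts extra columns and
common aliases. Rows with unparseable coordinates are flagged missing;
gaps of up to ``max_gap_frames`` are linearly interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    ArenaGeometry,
    CENTER,
    IN_TUNNEL,
    INTERMEDIATE,
    OUT_OF_BOUNDS,
    POT_ZONES,
    TUNNEL_ENTRY,
    TUNNEL_ZONE,
    WALL,
    ZONE_NAMES,
)

__all__ = [
    "Trajectory",
    "KinematicsConfig",
    "VelocityBout",
    "TrackingFormatError",
    "TrackingValidationError",
    "AlignmentError",
    "KinematicsError",
    "read_tracking_table",
    "write_tracking_table",
    "procrustes_align",
    "compute_kinematics",
    "annotate_zones",
    "validate_trajectory",
]

SLOW, MEDIUM, FAST = 0, 1, 2
VCLASS_NAMES = {SLOW: "slow", MEDIUM: "medium", FAST: "fast"}


class TrackingFormatError(ValueError):
    pass


class TrackingValidationError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class KinematicsError(ValueError):
    pass


@dataclass
class KinematicsConfig:
    """Velocity-class boundaries and bout rules.

    Classes are closed on the stated boundaries: slow v <= slow_max,
    medium slow_max < v <= medium_max, fast v > medium_max (cm/s).
    Runs of a single class longer than ``min_bout_frames`` frames count
    as one velocity bout.
    """

    slow_max: float = 5.0
    medium_max: float = 15.0
    min_bout_frames: int = 3
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.slow_max < self.medium_max):
            raise ValueError("require 0 < slow_max < medium_max")
        if self.min_bout_frames < 1:
            raise ValueError("min_bout_frames must be >= 1")


@dataclass
class VelocityBout:
    vclass: int
    start: int  # frame index, inclusive
    end: int    # frame index, exclusive

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class Trajectory:
    """One mouse-phase trial: per-frame time and position plus derived channels."""

    mouse_id: str
    phase: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = 30.0
    sex: str = "?"
    genotype: str = "?"
    age: str = "adult"
    missing: np.ndarray | None = None
    velocity: np.ndarray | None = None
    vclass: np.ndarray | None = None
    zone: np.ndarray | None = None
    landmarks: np.ndarray | None = None  # per-trial tunnel + pot centers (5 x 2)
    bouts: list[VelocityBout] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def copy(self) -> "Trajectory":
        return Trajectory(
            mouse_id=self.mouse_id,
            phase=self.phase,
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            frame_rate=self.frame_rate,
            sex=self.sex,
            genotype=self.genotype,
            age=self.age,
            missing=None if self.missing is None else self.missing.copy(),
            velocity=None if self.velocity is None else self.velocity.copy(),
            vclass=None if self.vclass is None else self.vclass.copy(),
            zone=None if self.zone is None else self.zone.copy(),
            landmarks=None if self.landmarks is None else self.landmarks.copy(),
            bouts=list(self.bouts),
        )

    def zone_names(self) -> np.ndarray:
        if self.zone is None:
            raise TrackingValidationError("zones not annotated")
        return np.array([ZONE_NAMES[z] for z in self.zone])


def validate_trajectory(traj: Trajectory, geometry: ArenaGeometry | None = None) -> None:
    """Schema, monotone time, and (optionally) in-arena coordinate checks."""
    if traj.n_frames == 0:
        raise TrackingValidationError("empty trajectory")
    if not (len(traj.t) == len(traj.x) == len(traj.y)):
        raise TrackingValidationError("t/x/y length mismatch")
    if np.any(np.diff(traj.t) <= 0):
        raise TrackingValidationError("time must be strictly increasing")
    if geometry is not None:
        ok = ~(traj.missing if traj.missing is not None else np.zeros(traj.n_frames, bool))
        cx, cy = geometry.arena_center
        r = np.hypot(traj.x[ok] - cx, traj.y[ok] - cy)
        slack = geometry.in_tunnel_offset + geometry.in_tunnel_radius
        if np.any(r > geometry.arena_radius + slack + 1e-6):
            raise TrackingValidationError("coordinates outside arena bounds")


_ALIASES = {"frame": ("frame", "frame_idx"), "t": ("t", "time", "time_s"),
            "x": ("x", "x_cm"), "y": ("y", "y_cm")}


def read_tracking_table(path: str | Path, frame_rate: float = 30.0,
                        max_gap_frames: int = 10, **meta) -> Trajectory:
    """Read a tracking CSV into a validated :class:`Trajectory`.

    Unparseable coordinates become missing; gaps up to ``max_gap_frames``
    frames are linearly interpolated, longer gaps stay flagged missing.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    cols = {}
    for key, aliases in _ALIASES.items():
        found = next((a for a in aliases if a in df.columns), None)
        if found is None:
            raise TrackingFormatError(f"missing required column {key!r} in {path}")
        cols[key] = found
    t = pd.to_numeric(df[cols["t"]], errors="coerce").to_numpy(float)
    x = pd.to_numeric(df[cols["x"]], errors="coerce").to_numpy(float)
    y = pd.to_numeric(df[cols["y"]], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(t)):
        raise TrackingFormatError("unparseable time values")
    if np.any(np.diff(t) <= 0):
        raise TrackingValidationError("time must be strictly increasing")
    missing = ~(np.isfinite(x) & np.isfinite(y))
    x, y, missing = _fill_gaps(x, y, missing, max_gap_frames)
    traj = Trajectory(
        mouse_id=str(meta.pop("mouse_id", Path(path).stem)),
        phase=str(meta.pop("phase", "?")),
        t=t, x=x, y=y, frame_rate=frame_rate, missing=missing, **meta,
    )
    validate_trajectory(traj)
    return traj


def write_tracking_table(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "t": traj.t,
        "x": np.where(traj.missing, np.nan, traj.x) if traj.missing is not None else traj.x,
        "y": np.where(traj.missing, np.nan, traj.y) if traj.missing is not None else traj.y,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def _fill_gaps(x: np.ndarray, y: np.ndarray, missing: np.ndarray,
               max_gap: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not missing.any():
        return x, y, missing
    idx = np.arange(len(x))
    good = ~missing
    if good.sum() < 2:
        return x, y, missing
    xf = x.copy()
    yf = y.copy()
    xf[missing] = np.interp(idx[missing], idx[good], x[good])
    yf[missing] = np.interp(idx[missing], idx[good], y[good])
    # keep long gaps flagged missing
    still = missing.copy()
    runs = _runs(missing)
    for s, e in runs:
        if e - s <= max_gap and s > 0 and e < len(x):
            still[s:e] = False
    return xf, yf, still


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


# -- Procrustes alignment -------------------------------------------------

def procrustes_transform(source: np.ndarray, target: np.ndarray
                         ) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Similarity transform (scale, rotation, translation; no reflection)
    minimizing RMSD of ``source`` landmarks onto ``target``.

    Returns ``(s, R, b, rmsd)`` such that ``p -> s * p @ R.T + b``.
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    if src.shape != tgt.shape or src.shape[0] < 3:
        raise AlignmentError("need >= 3 paired landmark points")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    A = src - mu_s
    B = tgt - mu_t
    norm_a = np.linalg.norm(A)
    if norm_a < 1e-12 or np.linalg.norm(B) < 1e-12:
        raise AlignmentError("degenerate landmarks (zero extent)")
    if np.linalg.matrix_rank(A, tol=1e-9 * norm_a) < 2:
        raise AlignmentError("collinear landmarks")
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    s = np.trace(D @ np.diag(S)) / (norm_a ** 2)
    b = mu_t - s * mu_s @ R.T
    resid = s * src @ R.T + b - tgt
    rmsd = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return float(s), R, b, rmsd


def procrustes_align(traj: Trajectory, reference: ArenaGeometry) -> Trajectory:
    """Map a trial into the canonical arena frame (tunnel center at origin).

    Uses the trial's recorded landmarks (tunnel + pot centers); a trial
    without recorded landmarks is assumed to be in the reference frame
    already and is only re-zeroed to the tunnel center.
    """
    out = traj.copy()
    target = reference.landmarks()
    if traj.landmarks is None:
        return out
    s, R, b, _ = procrustes_transform(np.asarray(traj.landmarks, float), target)
    pts = s * out.xy @ R.T + b
    out.x, out.y = pts[:, 0], pts[:, 1]
    out.landmarks = s * np.asarray(traj.landmarks, float) @ R.T + b
    return out


# -- kinematics -----------------------------------------------------------

def compute_kinematics(traj: Trajectory, cfg: KinematicsConfig | None = None
                       ) -> Trajectory:
    """Per-frame velocity (cm/s), velocity classes, and velocity bouts.

    Velocity is inter-frame displacement times frame rate, median-smoothed
    over ``cfg.smoothing_window`` frames; the first frame repeats the
    second's value so every frame carries a class. Frames flagged missing
    propagate NaN velocity and are excluded from bouts.
    """
    cfg = cfg or KinematicsConfig()
    if traj.n_frames < 2:
        raise KinematicsError("need at least 2 frames for kinematics")
    out = traj.copy()
    dx = np.diff(out.x)
    dy = np.diff(out.y)
    v = np.hypot(dx, dy) * out.frame_rate
    v = np.concatenate([[v[0]], v])
    if out.missing is not None and out.missing.any():
        bad = out.missing.copy()
        bad[1:] |= out.missing[:-1]
        v[bad] = np.nan
    if cfg.smoothing_window and cfg.smoothing_window > 1:
        v = (pd.Series(v)
             .rolling(cfg.smoothing_window, center=True, min_periods=1)
             .median()
             .to_numpy())
    vclass = np.full(len(v), -1, dtype=np.int8)
    ok = np.isfinite(v)
    vclass[ok & (v <= cfg.slow_max)] = SLOW
    vclass[ok & (v > cfg.slow_max) & (v <= cfg.medium_max)] = MEDIUM
    vclass[ok & (v > cfg.medium_max)] = FAST
    out.velocity = v
    out.vclass = vclass
    out.bouts = extract_bouts(vclass, cfg.min_bout_frames)
    return out


def extract_bouts(vclass: np.ndarray, min_bout_frames: int = 3) -> list[VelocityBout]:
    """Maximal same-class runs strictly longer than ``min_bout_frames``."""
    bouts: list[VelocityBout] = []
    n = len(vclass)
    i = 0
    while i < n:
        if vclass[i] < 0:
            i += 1
            continue
        j = i
        while j < n and vclass[j] == vclass[i]:
            j += 1
        if j - i > min_bout_frames:
            bouts.append(VelocityBout(int(vclass[i]), i, j))
        i = j
    return bouts


# -- zone annotation ------------------------------------------------------

def annotate_zones(traj: Trajectory, geometry: ArenaGeometry) -> Trajectory:
    """Assign exactly one zone per frame.

    Precedence: InTunnel > TunnelEntry > pot zones > TunnelZone > Center >
    Intermediate > Wall; positions beyond the arena (and outside the
    tunnel region) are flagged OutOfBounds but kept.
    """
    out = traj.copy()
    x, y = out.x, out.y
    zone = np.full(out.n_frames, OUT_OF_BOUNDS, dtype=np.int8)

    cx, cy = geometry.arena_center
    r_arena = np.hypot(x - cx, y - cy)
    zone[r_arena <= geometry.arena_radius] = WALL
    zone[r_arena <= geometry.intermediate_outer_radius] = INTERMEDIATE
    zone[r_arena <= geometry.center_radius] = CENTER

    tx, ty = geometry.tunnel_center
    r_tun = np.hypot(x - tx, y - ty)
    zone[r_tun <= geometry.tunnel_zone_radius] = TUNNEL_ZONE

    for pot, code in zip(range(1, 5), POT_ZONES):
        px, py = geometry.pot_center(pot)
        m = np.hypot(x - px, y - py) <= geometry.pot_zone_radius
        zone[m] = code

    zone[r_tun <= geometry.pot_radius] = TUNNEL_ENTRY
    ix, iy = geometry.in_tunnel_point
    zone[np.hypot(x - ix, y - iy) <= geometry.in_tunnel_radius] = IN_TUNNEL

    out.zone = zone
    return out
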