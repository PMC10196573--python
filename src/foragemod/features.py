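"""The 57-measure excursion description and the scaled feature matrix.

Each round-trip excursion is summarized by a fixed, versioned catalog of 57
scalar measures covering where the animal went (zone dwell fractions, visit
counts, first-visit latencies), the shape of its path (length, displacement,
tortuosity, turning statistics), and how it moved (velocity summaries and
per-class velocity bouts). Dwell times are normalized by the excursion's
time in the arena so they are fractions in [0, 1]; latencies are measured
from the excursion's arena entry (the trip-level analogue of subtracting
the latency to enter the platform) and censored at the excursion duration
when a zone is never visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (CENTER, INTERMEDIATE, POT1, POT2, POT3, POT4,
                       TUNNEL_ENTRY, TUNNEL_ZONE, WALL, ZONE_NAMES)
from .tracking import FAST, MEDIUM, SLOW, KinematicsConfig
from .excursions import Excursion

__all__ = ["CATALOG_VERSION", "FEATURE_NAMES", "NormalizationContext",
           "FeatureMatrix", "IntegrityError", "extract_features",
           "build_feature_matrix", "scale_features", "catalog_schema"]

CATALOG_VERSION = "fm57-1"

_FEATURE_ZONES = [POT1, POT2, POT3, POT4, TUNNEL_ZONE, TUNNEL_ENTRY,
                  CENTER, INTERMEDIATE, WALL]
_ZONE_TAGS = [ZONE_NAMES[z] for z in _FEATURE_ZONES]
_VTAGS = ["slow", "medium", "fast"]

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"frac_time_{z}" for z in _ZONE_TAGS]
    + [f"n_visits_{z}" for z in _ZONE_TAGS]
    + [f"latency_{z}_s" for z in _ZONE_TAGS]
    + [
        "duration_s",
        "path_length_cm",
        "max_dist_from_tunnel_cm",
        "mean_dist_from_tunnel_cm",
        "mean_dist_from_wall_cm",
        "tortuosity",
        "straightness",
        "sd_turning_angle_deg",
        "mean_abs_turning_angle_deg",
        "x_sd_cm",
        "y_sd_cm",
        "xy_corr",
        "radial_sd_cm",
        "mean_velocity_cms",
        "max_velocity_cms",
        "sd_velocity_cms",
    ]
    + [f"n_bouts_{v}" for v in _VTAGS]
    + [f"frac_time_{v}" for v in _VTAGS]
    + [f"mean_bout_s_{v}" for v in _VTAGS]
    + [
        "exit_speed_cms",
        "entry_speed_cms",
        "latency_leave_tunnel_zone_s",
        "n_pot_zone_entries",
        "n_distinct_pots_visited",
    ]
)
assert len(FEATURE_NAMES) == 57


class IntegrityError(ValueError):
    pass


@dataclass
class NormalizationContext:
    """Trial-level normalizers.

    TTA is the total time in the arena for the trial (dwell-time divisor);
    LEP is the latency to enter the platform (subtracted from trial-level
    latencies). ``tta_per_bin`` holds the per-time-bin TTA used when
    normalizing binned dwell values.
    """

    tta: float
    lep: float = 0.0
    tta_per_bin: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tta <= 0:
            raise ValueError("TTA must be positive for a trial with excursions")
        if self.lep < 0:
            raise ValueError("LEP must be >= 0")

    def normalize_time(self, x: float, bin_index: int | None = None) -> float:
        if bin_index is not None and self.tta_per_bin is not None:
            denom = self.tta_per_bin[bin_index]
            return x / denom if denom > 0 else 0.0
        return x / self.tta

    def normalize_latency(self, x: float) -> float:
        return x - self.lep


def extract_features(exc: Excursion, geometry, ctx: NormalizationContext | None = None,
                     cfg: KinematicsConfig | None = None) -> np.ndarray:
    """Compute the 57-measure vector for one excursion.

    Requires the parent trial to be zone-annotated and kinematics-computed.
    ``ctx`` and ``cfg`` are accepted for interface completeness; excursion
    dwell fractions always use the excursion's own arena time as TTA.
    """
    traj = exc.traj
    if traj.zone is None or traj.velocity is None:
        raise IntegrityError("excursion trial needs zones and kinematics")
    cfg = cfg or KinematicsConfig()
    zone = exc.slice(traj.zone)
    v = exc.slice(traj.velocity)
    vclass = exc.slice(traj.vclass)
    x = exc.slice(traj.x)
    y = exc.slice(traj.y)
    n = len(zone)
    fr = traj.frame_rate
    dur = n / fr

    vals: list[float] = []
    counts = np.bincount(zone, minlength=11)
    for z in _FEATURE_ZONES:
        vals.append(counts[z] / n)
    changed = np.empty(n, dtype=bool)
    changed[0] = True
    changed[1:] = zone[1:] != zone[:-1]
    visit_counts = np.bincount(zone[changed], minlength=11)
    for z in _FEATURE_ZONES:
        vals.append(float(visit_counts[z]))
    first = np.full(11, n)
    np.minimum.at(first, zone, np.arange(n))
    for z in _FEATURE_ZONES:
        vals.append(first[z] / fr if first[z] < n else dur)

    tx, ty = geometry.tunnel_center
    cx, cy = geometry.arena_center
    d_tun = np.hypot(x - tx, y - ty)
    d_wall = np.clip(geometry.arena_radius - np.hypot(x - cx, y - cy), 0.0, None)
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    path_len = float(step.sum())
    max_d = float(d_tun.max())
    headings = np.arctan2(dy, dx)
    # turning statistics over locomotion steps only: tracking jitter at a
    # standstill produces random headings that would swamp the turn signal
    moving = step > 0.15
    h = headings[moving]
    if len(h) >= 2:
        turn = np.degrees(np.angle(np.exp(1j * np.diff(h))))
    else:
        turn = np.zeros(1)
    r = np.hypot(x - cx, y - cy)
    finite_v = v[np.isfinite(v)]
    vals += [
        dur,
        path_len,
        max_d,
        float(d_tun.mean()),
        float(d_wall.mean()),
        path_len / (2 * max_d) if max_d > 1e-9 else 0.0,
        # straightness: mean cosine of the turning angle (1 = straight line);
        # unlike a signed mean it is invariant to the arbitrary sign of
        # out-and-back reversals
        float(np.cos(np.radians(turn)).mean()),
        float(turn.std()),
        float(np.abs(turn).mean()),
        float(x.std()),
        float(y.std()),
        float(np.corrcoef(x, y)[0, 1]) if x.std() > 1e-12 and y.std() > 1e-12 else 0.0,
        float(r.std()),
        float(finite_v.mean()) if finite_v.size else 0.0,
        float(finite_v.max()) if finite_v.size else 0.0,
        float(finite_v.std()) if finite_v.size else 0.0,
    ]

    # velocity bouts restricted to this excursion's span; bouts are sorted
    # by start frame, so binary search bounds the overlap scan
    bout_n = {SLOW: 0, MEDIUM: 0, FAST: 0}
    bout_frames = {SLOW: 0, MEDIUM: 0, FAST: 0}
    from bisect import bisect_left, bisect_right
    starts = getattr(traj, "_bout_starts", None)
    if starts is None or len(starts) != len(traj.bouts):
        starts = [b.start for b in traj.bouts]
        traj._bout_starts = starts
    ends = getattr(traj, "_bout_ends", None)
    if ends is None or len(ends) != len(traj.bouts):
        ends = [b.end for b in traj.bouts]
        traj._bout_ends = ends
    lo = bisect_right(ends, exc.start)
    hi = bisect_left(starts, exc.end)
    for b in traj.bouts[lo:hi]:
        s = max(b.start, exc.start)
        e = min(b.end, exc.end)
        if e - s > cfg.min_bout_frames:
            bout_n[b.vclass] += 1
            bout_frames[b.vclass] += e - s
    for k in (SLOW, MEDIUM, FAST):
        vals.append(float(bout_n[k]))
    cls_counts = np.bincount(vclass[vclass >= 0], minlength=3)
    for k in (SLOW, MEDIUM, FAST):
        vals.append(cls_counts[k] / n)
    for k in (SLOW, MEDIUM, FAST):
        vals.append((bout_frames[k] / bout_n[k] / fr) if bout_n[k] else 0.0)

    sec = max(1, int(round(fr)))
    v0 = v[:sec]
    v1 = v[-sec:]
    vals.append(float(np.nanmean(v0)) if np.isfinite(v0).any() else 0.0)
    vals.append(float(np.nanmean(v1)) if np.isfinite(v1).any() else 0.0)
    outside = np.flatnonzero(zone != TUNNEL_ZONE)
    vals.append(outside[0] / fr if outside.size else dur)
    pot_mask = (zone >= POT1) & (zone <= POT4)
    entries = np.sum(changed & pot_mask)
    vals.append(float(entries))
    vals.append(float(len(set(zone[pot_mask].tolist()))))

    vec = np.asarray(vals, dtype=float)
    vec[~np.isfinite(vec)] = 0.0
    assert vec.shape == (57,)
    return vec


@dataclass
class FeatureMatrix:
    """Excursions x measures, CIMAR-keyed; ``scaled`` marks z-scored columns."""

    data: pd.DataFrame
    scaled: bool = False
    constant_columns: tuple[str, ...] = field(default_factory=tuple)
    catalog_version: str = CATALOG_VERSION

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def cimars(self) -> list[str]:
        return list(self.data.index)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="cimar")


def scale_features(df: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Column-wise z-score (ddof=1); constant columns are zeroed, not dropped."""
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    const = tuple(df.columns[(sd < 1e-12) | sd.isna()])
    sd_safe = sd.replace(0.0, 1.0).fillna(1.0)
    out = (df - mu) / sd_safe
    out[list(const)] = 0.0
    return out, const


def build_feature_matrix(vectors: list[np.ndarray] | np.ndarray,
                         cimars: list[str]) -> FeatureMatrix:
    """Assemble and scale the excursion x 57 matrix."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_NAMES):
        raise IntegrityError(f"expected n x {len(FEATURE_NAMES)} matrix")
    if arr.shape[0] < 2:
        raise IntegrityError("need at least 2 excursions to scale")
    if len(set(cimars)) != len(cimars):
        raise IntegrityError("duplicate CIMAR keys")
    df = pd.DataFrame(arr, index=list(cimars), columns=list(FEATURE_NAMES))
    scaled, const = scale_features(df)
    return FeatureMatrix(scaled, scaled=True, constant_columns=const)


def catalog_schema() -> dict:
    """Machine-readable catalog: name, group and unit per measure."""
    def group(name: str) -> str:
        if name.startswith("frac_time_") and name.split("_")[-1] in _VTAGS:
            return "velocity_bouts"
        if name.startswith(("frac_time_", "n_visits_", "latency_")):
            return "zones"
        if name.startswith(("n_bouts_", "mean_bout_")):
            return "velocity_bouts"
        if "velocity" in name or "speed" in name:
            return "velocity"
        return "path_shape"

    def unit(name: str) -> str:
        if name.endswith("_cm"):
            return "cm"
        if name.endswith("_s"):
            return "s"
        if name.endswith("_cms"):
            return "cm/s"
        if name.endswith("_deg"):
            return "deg"
        return "dimensionless"

    return {
        "version": CATALOG_VERSION,
        "n_measures": len(FEATURE_NAMES),
        "measures": [
            {"index": i, "name": n, "group": group(n), "unit": unit(n)}
            for i, n in enumerate(FEATURE_NAMES)
        ],
    }
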