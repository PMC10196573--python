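"""Synthetic tracking cohorts with planted module structure.

The generator emulates the study conditions of a two-phase naturalistic
foraging assay: 15 mice per genotype x sex cell (WT/KO, M/F), 30-minute
trials tracked at 30 frames/s in a 35 cm five-hole arena. Round-trip
excursions are built from six stereotyped archetypes (direct darts to the
food pot, brief home-darts, former-food-patch checks, wall patrols, center
exploration, and two-pot tours) plus diffuse noise excursions with random
waypoints. Archetype rates differ by genotype and are modulated per
minute-window, which plants epoch-structured waves of former-food-patch
(Pot2) occupancy; every generated excursion carries a ground-truth label
so downstream module discovery has an acceptance surface.

Trajectories are waypoint paths with Gaussian positional jitter (sd 0.3 cm)
and per-leg speed jitter — the simplest generative model that exercises
zone logic, velocity classes, and path-shape features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ArenaGeometry
from .tracking import Trajectory

__all__ = ["ArchetypeSpec", "SimConfig", "PlantedTruth", "ConfigurationError",
           "EmptyCohortError", "default_archetypes", "default_config",
           "epoch_benchmark_config", "generate_excursion_trajectory",
           "generate_cohort", "export_truth", "load_truth", "write_cohort"]

POSITION_JITTER_SD = 0.3  # cm
HOME_JITTER_SD = 0.05     # cm, while parked in the tunnel
NOISE_LABEL = "noise"


class ConfigurationError(ValueError):
    pass


class EmptyCohortError(ValueError):
    pass


@dataclass
class ArchetypeSpec:
    """A stereotyped excursion blueprint.

    Waypoints are arena landmarks: ``("tunnel",)``, ``("pot", i)``,
    ``("wall", angle_deg)``, ``("center",)`` or ``("mid", i)`` (the
    retreat point between pot i and the arena center, outside the pot
    zone). ``dwell_times`` gives (mean_s, jitter_sd_s) per waypoint;
    ``speed_profile`` the mean speed (cm/s) per leg. ``repeat_loops``
    replays the interior waypoints that many times, producing separated
    revisits of the looped landmarks.
    """

    name: str
    waypoints: list[tuple]
    dwell_times: list[tuple[float, float]]
    speed_profile: list[float]
    repeat_loops: int = 1

    def __post_init__(self) -> None:
        if len(self.waypoints) < 2:
            raise ConfigurationError("need at least 2 waypoints")
        if self.waypoints[0][0] != "tunnel" or self.waypoints[-1][0] != "tunnel":
            raise ConfigurationError("first and last waypoint must be the tunnel")
        if len(self.dwell_times) != len(self.waypoints):
            raise ConfigurationError("one dwell per waypoint required")
        if any(m < 0 for m, _ in self.dwell_times):
            raise ConfigurationError("dwell times must be >= 0")
        if len(self.speed_profile) != len(self.waypoints) - 1:
            raise ConfigurationError("one speed per leg required")
        if self.repeat_loops < 1:
            raise ConfigurationError("repeat_loops must be >= 1")

    def expanded_waypoints(self) -> tuple[list[tuple], list[tuple[float, float]], list[float]]:
        """Waypoint/dwell/speed sequences with interior loops unrolled."""
        if self.repeat_loops == 1 or len(self.waypoints) <= 2:
            return list(self.waypoints), list(self.dwell_times), list(self.speed_profile)
        wp = [self.waypoints[0]]
        dw = [self.dwell_times[0]]
        sp: list[float] = []
        interior_wp = self.waypoints[1:-1]
        interior_dw = self.dwell_times[1:-1]
        leg_sp = self.speed_profile
        for loop in range(self.repeat_loops):
            for j, (w, d) in enumerate(zip(interior_wp, interior_dw)):
                sp.append(leg_sp[min(j, len(leg_sp) - 2)] if len(leg_sp) > 1 else leg_sp[0])
                wp.append(w)
                dw.append(d)
        sp.append(leg_sp[-1])
        wp.append(self.waypoints[-1])
        dw.append(self.dwell_times[-1])
        return wp, dw, sp


def _smooth_jitter(n: int, sd: float, rng: np.random.Generator,
                   frame_rate: float) -> np.ndarray:
    """Autocorrelated 2D jitter with stationary positional sd ``sd``."""
    w = max(1, int(round(0.5 * frame_rate)))
    white = rng.normal(0.0, 1.0, (n + w, 2))
    kernel = np.ones(w) / w
    sm = np.column_stack([np.convolve(white[:, j], kernel, mode="valid")
                          for j in range(2)])[:n]
    return sm * (sd * np.sqrt(w))


def _landmark_xy(token: tuple, geometry: ArenaGeometry) -> np.ndarray:
    kind = token[0]
    cx, cy = geometry.arena_center
    if kind == "tunnel":
        return geometry.in_tunnel_point
    if kind == "pot":
        return geometry.pot_center(int(token[1]))
    if kind == "wall":
        ang = np.deg2rad(float(token[1]))
        r = geometry.arena_radius - 0.6
        return np.array([cx + r * np.cos(ang), cy + r * np.sin(ang)])
    if kind == "center":
        return np.array([cx, cy], float)
    if kind == "mid":
        p = geometry.pot_center(int(token[1]))
        return (p + np.array([cx, cy])) / 2.0
    raise ConfigurationError(f"unknown waypoint token: {token!r}")


def generate_excursion_trajectory(spec: ArchetypeSpec, geometry: ArenaGeometry,
                                  seed: int | np.random.Generator,
                                  frame_rate: float = 30.0) -> np.ndarray:
    """Frames (n x 2, cm) of one excursion; starts and ends In-Tunnel.

    Frames are equally spaced at 1/frame_rate; the same spec and seed give
    bit-identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wps, dwells, speeds = spec.expanded_waypoints()
    pts = [_landmark_xy(w, geometry) for w in wps]
    segs: list[np.ndarray] = []
    # anchor frame inside the In-Tunnel zone
    segs.append(pts[0][None, :])
    for i in range(len(pts) - 1):
        p, q = pts[i], pts[i + 1]
        speed = max(1.0, speeds[i] * rng.normal(1.0, 0.07))
        dist = float(np.linalg.norm(q - p))
        n_leg = max(2, int(round(dist / speed * frame_rate)))
        frac = np.linspace(0.0, 1.0, n_leg, endpoint=False)[1:, None]
        segs.append(p[None, :] + frac * (q - p)[None, :])
        mean_d, sd_d = dwells[i + 1]
        dwell_s = max(0.0, rng.normal(mean_d, sd_d)) if mean_d > 0 else 0.0
        n_dwell = int(round(dwell_s * frame_rate))
        if i == len(pts) - 2:
            n_dwell = max(n_dwell, 1)  # guarantee a closing In-Tunnel frame
        if n_dwell:
            segs.append(np.repeat(q[None, :], n_dwell, axis=0))
    xy = np.vstack(segs)
    # temporally correlated positional jitter: white noise smoothed over
    # ~0.5 s, rescaled to POSITION_JITTER_SD, so apparent frame-to-frame
    # velocity noise stays small (tracking error is autocorrelated)
    xy = xy + _smooth_jitter(len(xy), POSITION_JITTER_SD, rng, frame_rate)
    # clamp inside the arena wall
    cx, cy = geometry.arena_center
    d = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
    rmax = geometry.arena_radius - 0.05
    over = d > rmax
    if over.any():
        scale = rmax / d[over]
        xy[over, 0] = cx + (xy[over, 0] - cx) * scale
        xy[over, 1] = cy + (xy[over, 1] - cy) * scale
    # pin the endpoints into the In-Tunnel disc
    home = geometry.in_tunnel_point
    for k in (0, -1):
        if np.linalg.norm(xy[k] - home) > geometry.in_tunnel_radius * 0.9:
            xy[k] = home
    _push_out_tunnel_dips(xy, geometry)
    return xy


def _push_out_tunnel_dips(xy: np.ndarray, geometry: ArenaGeometry) -> None:
    """Displace mid-excursion frames out of the In-Tunnel disc, in place.

    A path leg that grazes the tunnel hole would otherwise split one round
    trip into two at segmentation time. Frames in the contiguous entry/exit
    runs at either end of the segment legitimately sit in the disc.
    """
    home = geometry.in_tunnel_point
    r = geometry.in_tunnel_radius
    d = np.hypot(xy[:, 0] - home[0], xy[:, 1] - home[1])
    inside = d <= r  # must match the zone-annotation radius exactly
    n = len(xy)
    lead = 0
    while lead < n and inside[lead]:
        lead += 1
    tail = n
    while tail > 0 and inside[tail - 1]:
        tail -= 1
    mid = np.flatnonzero(inside[lead:tail]) + lead
    if mid.size == 0:
        return
    vec = xy[mid] - home[None, :]
    norm = np.hypot(vec[:, 0], vec[:, 1])
    norm[norm < 1e-9] = 1e-9
    xy[mid] = home[None, :] + vec / norm[:, None] * (r * 1.3)


def default_archetypes() -> list[ArchetypeSpec]:
    """The six planted archetypes of the default cohort."""
    t = ("tunnel",)
    return [
        ArchetypeSpec("dart_pot4", [t, ("pot", 4), t],
                      [(0, 0), (4.0, 0.25), (0, 0)], [28.0, 28.0]),
        ArchetypeSpec("dart_home", [t, ("mid", 4), t],
                      [(0, 0), (0.6, 0.1), (0, 0)], [24.0, 24.0]),
        ArchetypeSpec("check_pot2", [t, ("pot", 2), ("mid", 2), t],
                      [(0, 0), (6.5, 0.5), (0.5, 0.1), (0, 0)],
                      [16.0, 10.0, 16.0], repeat_loops=2),
        ArchetypeSpec("patrol_wall", [t, ("wall", 250), ("wall", 170),
                                      ("wall", 90), ("wall", 10), t],
                      [(0, 0), (1.0, 0.15), (1.0, 0.15), (1.0, 0.15), (1.0, 0.15), (0, 0)],
                      [12.0, 11.0, 11.0, 11.0, 12.0]),
        ArchetypeSpec("center_explore", [t, ("center",), ("pot", 1), ("center",), t],
                      [(0, 0), (5.0, 0.7), (3.0, 0.5), (2.0, 0.4), (0, 0)],
                      [6.0, 5.0, 5.0, 7.0]),
        ArchetypeSpec("pot2_pot4_tour", [t, ("pot", 2), ("pot", 4), t],
                      [(0, 0), (2.5, 0.4), (7.0, 0.7), (0, 0)],
                      [18.0, 14.0, 18.0]),
    ]


def _noise_spec(rng: np.random.Generator) -> ArchetypeSpec:
    """A diffuse, idiosyncratic excursion: 3-7 random waypoints.

    Waypoint kinds are mixed within each trip so noise excursions form a
    diffuse continuum in feature space rather than kind-specific clumps.
    """
    t = ("tunnel",)
    n_wp = 4
    wps: list[tuple] = [t]
    dwells: list[tuple[float, float]] = [(0, 0)]
    for _ in range(n_wp):
        kind = rng.choice(["wall", "center", "mid", "pot"])
        if kind == "wall":
            wps.append(("wall", float(rng.uniform(0, 360))))
        elif kind == "center":
            wps.append(("center",))
        elif kind == "mid":
            wps.append(("mid", int(rng.integers(1, 5))))
        else:
            wps.append(("pot", int(rng.integers(1, 5))))
        dwells.append((float(rng.uniform(0.5, 2.5)), 0.3))
    wps.append(t)
    dwells.append((0, 0))
    speeds = [float(rng.uniform(8.0, 20.0)) for _ in range(len(wps) - 1)]
    return ArchetypeSpec(NOISE_LABEL, wps, dwells, speeds)


@dataclass
class SimConfig:
    """Cohort-level study conditions.

    ``archetype_rates[name][genotype]`` is a per-minute expected-excursion
    vector over the trial; ``noise_rate`` is the per-minute rate of
    non-modular excursions. ``pot2_wave_windows`` documents the planted
    minute-windows of elevated former-food-patch occupancy per genotype
    (the rate vectors implement them).
    """

    n_per_group: int = 15
    genotypes: tuple[str, ...] = ("WT", "KO")
    sexes: tuple[str, ...] = ("M", "F")
    phases: tuple[str, ...] = ("Exploration", "Foraging")
    trial_min: float = 30.0
    frame_rate: float = 30.0
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    archetype_rates: dict = field(default_factory=dict)
    noise_rate: float = 0.08  # per minute
    pot2_wave_windows: dict = field(default_factory=dict)
    home_dwell_mean_s: float = 20.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.trial_min <= 0:
            raise ConfigurationError("frame_rate and trial_min must be positive")
        if self.noise_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        n_min = int(self.trial_min)
        for name, per_geno in self.archetype_rates.items():
            for g, vec in per_geno.items():
                v = np.asarray(vec, float)
                if v.ndim != 1 or len(v) != n_min:
                    raise ConfigurationError(
                        f"rate vector for {name}/{g} must have {n_min} entries")
                if np.any(v < 0):
                    raise ConfigurationError("rates must be >= 0")
        for g, windows in self.pot2_wave_windows.items():
            for a, b in windows:
                if not (0 <= a < b <= self.trial_min):
                    raise ConfigurationError("wave windows must lie in the trial")

    @property
    def n_minutes(self) -> int:
        return int(self.trial_min)

    def archetype(self, name: str) -> ArchetypeSpec:
        for a in self.archetypes:
            if a.name == name:
                return a
        raise ConfigurationError(f"unknown archetype {name!r}")

    def expected_total_excursions(self) -> float:
        total = 0.0
        n_trials_per_geno = self.n_per_group * len(self.sexes) * len(self.phases)
        for per_geno in self.archetype_rates.values():
            for g in self.genotypes:
                total += float(np.sum(per_geno[g])) * n_trials_per_geno
        total += (self.noise_rate * self.trial_min
                  * n_trials_per_geno * len(self.genotypes))
        return total


def _flat(rate_per_trial: float, n_min: int) -> np.ndarray:
    return np.full(n_min, rate_per_trial / n_min)


def _wave_vector(base: float, wave_rate: float, windows: list[tuple[int, int]],
                 n_min: int) -> np.ndarray:
    v = np.full(n_min, base, float)
    for a, b in windows:
        v[a:b] = wave_rate
    return v


def default_config() -> SimConfig:
    """The default cohort: 60 mice, two phases, ~1,600 excursions.

    WT mice carry three planted waves of Pot2 checking (minutes 0-10,
    12-17, 19-30); KO mice only the first, with the checking archetype
    largely replaced by direct food-pot darts — the planted genotype
    contrast for the expression and transition statistics.
    """
    n_min = 30
    wt_waves = [(0, 10), (12, 17), (19, 30)]
    ko_waves = [(0, 10)]
    rates = {
        "dart_pot4": {"WT": _flat(2.1, n_min), "KO": _flat(3.4, n_min)},
        "dart_home": {"WT": _flat(1.5, n_min), "KO": _flat(2.2, n_min)},
        "check_pot2": {"WT": _wave_vector(0.0, 3.8 / 25.0, wt_waves, n_min),
                       "KO": _wave_vector(0.0, 1.2 / 10.0, ko_waves, n_min)},
        "patrol_wall": {"WT": _flat(1.7, n_min), "KO": _flat(1.7, n_min)},
        "center_explore": {"WT": _flat(1.9, n_min), "KO": _flat(1.9, n_min)},
        "pot2_pot4_tour": {"WT": _flat(1.35, n_min), "KO": _flat(1.35, n_min)},
    }
    return SimConfig(
        archetype_rates=rates,
        noise_rate=1.0 / n_min,
        pot2_wave_windows={"WT": wt_waves, "KO": ko_waves},
    )


def epoch_benchmark_config(wave_windows: list[tuple[int, int]] | None = None,
                           wave_rate: float = 1.2) -> SimConfig:
    """Single-genotype, Foraging-only cohort with strong planted Pot2 waves.

    Used to benchmark the sliding-window epoch analysis: within the wave
    windows the checking archetype runs at ``wave_rate`` excursions/min
    with long Pot2 dwells; outside them Pot2 and Pot1 occupancy are both
    near zero and balanced.
    """
    n_min = 30
    waves = wave_windows or [(0, 10), (12, 17), (19, 30)]
    rates = {
        "dart_pot4": {"WT": _flat(1.5, n_min)},
        "check_pot2": {"WT": _wave_vector(0.0, wave_rate, waves, n_min)},
        "center_explore": {"WT": _flat(1.5, n_min)},
    }
    cfg = SimConfig(
        genotypes=("WT",),
        phases=("Foraging",),
        archetype_rates=rates,
        noise_rate=0.04,
        pot2_wave_windows={"WT": waves},
    )
    # long, low-variance Pot2 dwells for per-window power
    cfg.archetypes = [a for a in default_archetypes()
                      if a.name in ("dart_pot4", "check_pot2", "center_explore")]
    for a in cfg.archetypes:
        if a.name == "check_pot2":
            a.dwell_times[1] = (7.0, 1.0)
            a.repeat_loops = 1
    return cfg


@dataclass
class PlantedTruth:
    """Ground truth for one generated cohort."""

    labels: dict[str, str] = field(default_factory=dict)  # cimar -> archetype/noise
    per_mouse_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    expected_pot_occupancy: dict = field(default_factory=dict)

    def archetype_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    @property
    def n_excursions(self) -> int:
        return len(self.labels)


def export_truth(truth: PlantedTruth, path: str | Path) -> None:
    d = {
        "labels": truth.labels,
        "per_mouse_counts": truth.per_mouse_counts,
        "expected_pot_occupancy": truth.expected_pot_occupancy,
    }
    Path(path).write_text(json.dumps(d, indent=2))


def load_truth(path: str | Path) -> PlantedTruth:
    d = json.loads(Path(path).read_text())
    return PlantedTruth(labels=d["labels"],
                        per_mouse_counts=d["per_mouse_counts"],
                        expected_pot_occupancy=d["expected_pot_occupancy"])


def generate_cohort(config: SimConfig, geometry: ArenaGeometry | None = None,
                    seed: int = 0) -> tuple[list[Trajectory], pd.DataFrame, PlantedTruth]:
    """Generate one tracking table per mouse per phase, plus truth labels.

    Excursion counts per archetype and minute are Poisson with the
    configured rates; excursions are laid out in time with exponential
    inter-excursion home dwells (mean ``home_dwell_mean_s``).
    """
    geometry = geometry or ArenaGeometry()
    total_rate = sum(float(np.sum(v)) for per_g in config.archetype_rates.values()
                     for v in per_g.values()) + config.noise_rate
    if total_rate <= 0:
        raise EmptyCohortError("all archetype and noise rates are zero")
    rng = np.random.default_rng(seed)
    fr = config.frame_rate
    n_frames = int(round(config.trial_min * 60 * fr))
    trajectories: list[Trajectory] = []
    manifest_rows = []
    truth = PlantedTruth()

    mouse_id = 0
    for genotype in config.genotypes:
        for sex in config.sexes:
            for _ in range(config.n_per_group):
                mouse_id += 1
                mkey = f"m{mouse_id:03d}"
                truth.per_mouse_counts.setdefault(mkey, {})
                # idiosyncratic per-mouse repertoire: noise excursions are
                # mouse-specific templates, not a shared distribution, so
                # they do not reproduce across held-out mice
                noise_templates = [_noise_spec(rng)
                                   for _ in range(int(rng.integers(1, 4)))]
                for phase in config.phases:
                    traj, labels = _generate_trial(
                        config, geometry, rng, mouse_id, sex, genotype, phase,
                        n_frames, noise_templates)
                    trajectories.append(traj)
                    manifest_rows.append({"mouse_id": mouse_id, "sex": sex,
                                          "genotype": genotype, "phase": phase})
                    for cimar, lab in labels.items():
                        truth.labels[cimar] = lab
                        pm = truth.per_mouse_counts[mkey]
                        pm[lab] = pm.get(lab, 0) + 1
    truth.expected_pot_occupancy = _expected_occupancy(config)
    manifest = pd.DataFrame(manifest_rows)
    return trajectories, manifest, truth


def _expected_occupancy(config: SimConfig) -> dict:
    """Per-genotype, per-minute expected Pot2/Pot1 dwell seconds."""
    out: dict = {}
    for g in config.genotypes:
        pot2 = np.zeros(config.n_minutes)
        pot1 = np.zeros(config.n_minutes)
        for name, per_geno in config.archetype_rates.items():
            if g not in per_geno:
                continue
            spec = config.archetype(name)
            wps, dwells, _ = spec.expanded_waypoints()
            d2 = sum(d[0] for w, d in zip(wps, dwells) if w == ("pot", 2))
            d1 = sum(d[0] for w, d in zip(wps, dwells) if w == ("pot", 1))
            pot2 += np.asarray(per_geno[g]) * d2
            pot1 += np.asarray(per_geno[g]) * d1
        out[g] = {"pot2_s": pot2.tolist(), "pot1_s": pot1.tolist()}
    return out


def _generate_trial(config: SimConfig, geometry: ArenaGeometry,
                    rng: np.random.Generator, mouse_id: int, sex: str,
                    genotype: str, phase: str, n_frames: int,
                    noise_templates: list[ArchetypeSpec] | None = None
                    ) -> tuple[Trajectory, dict[str, str]]:
    from .excursions import CimarKey, format_cimar

    fr = config.frame_rate
    events: list[tuple[float, str]] = []
    for name, per_geno in config.archetype_rates.items():
        if genotype not in per_geno:
            continue
        vec = np.asarray(per_geno[genotype], float)
        counts = rng.poisson(vec)
        for minute, c in enumerate(counts):
            for _ in range(int(c)):
                events.append((minute * 60 + rng.uniform(0, 60), name))
    n_noise = rng.poisson(config.noise_rate * config.trial_min)
    for _ in range(int(n_noise)):
        events.append((rng.uniform(0, config.trial_min * 60), NOISE_LABEL))
    events.sort(key=lambda e: e[0])

    home = geometry.in_tunnel_point
    chunks: list[np.ndarray] = []
    labels: dict[str, str] = {}
    cursor = 0  # frames laid out so far
    exc_num = 0
    first_dwell = min(rng.exponential(config.home_dwell_mean_s), 30.0)
    cursor = _append_home(chunks, home, rng, int(round(first_dwell * fr)), cursor)
    gap = max(2, int(round(0.5 * fr)))  # home frames separating excursions
    for t_intended, name in events:
        start = max(cursor + gap, int(round(t_intended * fr)))
        if start >= n_frames - int(2 * fr):
            break
        cursor = _append_home(chunks, home, rng, start - cursor, cursor)
        if name != NOISE_LABEL:
            spec = config.archetype(name)
        elif noise_templates:
            spec = noise_templates[int(rng.integers(0, len(noise_templates)))]
        else:
            spec = _noise_spec(rng)
        xy = generate_excursion_trajectory(spec, geometry, rng, frame_rate=fr)
        if cursor + len(xy) > n_frames:
            xy = xy[: n_frames - cursor]
            if len(xy) < 2:
                break
        exc_num += 1
        key = CimarKey(mouse_id, exc_num, sex, "adult", genotype, phase)
        labels[format_cimar(key)] = name
        chunks.append(xy)
        cursor += len(xy)
    cursor = _append_home(chunks, home, rng, n_frames - cursor, cursor)
    xy = np.vstack(chunks)
    t = np.arange(len(xy)) / fr
    traj = Trajectory(mouse_id=f"m{mouse_id:03d}", phase=phase,
                      t=t, x=xy[:, 0], y=xy[:, 1], frame_rate=fr,
                      sex=sex, genotype=genotype)
    return traj, labels


def _append_home(chunks: list[np.ndarray], home: np.ndarray,
                 rng: np.random.Generator, n: int, cursor: int) -> int:
    if n <= 0:
        return cursor
    block = np.repeat(home[None, :], n, axis=0) + rng.normal(0, HOME_JITTER_SD, (n, 2))
    chunks.append(block)
    return cursor + n


def write_cohort(trajectories: list[Trajectory], manifest: pd.DataFrame,
                 truth: PlantedTruth, outdir: str | Path) -> pd.DataFrame:
    """Write tracking CSVs, a manifest CSV, and the truth JSON."""
    from .tracking import write_tracking_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for traj in trajectories:
        fname = f"{traj.mouse_id}_{traj.phase}.csv"
        write_tracking_table(traj, outdir / fname)
        files.append(fname)
    manifest = manifest.copy()
    manifest["file"] = files
    manifest.to_csv(outdir / "manifest.csv", index=False)
    export_truth(truth, outdir / "truth.json")
    return manifest
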