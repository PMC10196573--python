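"""Round-trip excursion segmentation and CIMAR addressing.

An excursion begins when the mouse leaves the In-Tunnel zone and ends when
it next returns to it: one round trip into the arena. Each excursion gets a
CIMAR key — a unique string carrying mouse number, excursion number, sex,
age, genotype and phase — used to address rows of the feature matrix and
every downstream table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import IN_TUNNEL
from .tracking import Trajectory

__all__ = ["CimarKey", "Excursion", "SegmentationError", "CimarParseError",
           "segment_excursions", "format_cimar", "parse_cimar",
           "export_excursion_index"]


class SegmentationError(ValueError):
    pass


class CimarParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class CimarKey:
    mouse_number: int
    excursion_number: int
    sex: str = "?"
    age: str = "adult"
    genotype: str = "?"
    phase: str = "?"

    def __str__(self) -> str:
        return format_cimar(self)


_CIMAR_RE = re.compile(
    r"^m(?P<mouse>\d+)\.e(?P<exc>\d+)\.(?P<sex>[^.]+)\.(?P<age>[^.]+)"
    r"\.(?P<geno>[^.]+)\.(?P<phase>[^.]+)$"
)


def format_cimar(key: CimarKey) -> str:
    return (f"m{key.mouse_number:03d}.e{key.excursion_number:03d}."
            f"{key.sex}.{key.age}.{key.genotype}.{key.phase}")


def parse_cimar(s: str) -> CimarKey:
    m = _CIMAR_RE.match(s.strip())
    if m is None:
        raise CimarParseError(f"malformed CIMAR key: {s!r}")
    return CimarKey(
        mouse_number=int(m.group("mouse")),
        excursion_number=int(m.group("exc")),
        sex=m.group("sex"),
        age=m.group("age"),
        genotype=m.group("geno"),
        phase=m.group("phase"),
    )


@dataclass
class Excursion:
    """One round trip; ``span`` is a half-open frame interval [start, end)."""

    key: CimarKey
    start: int
    end: int
    traj: Trajectory  # the parent trial (excursions hold views, not copies)
    open_ended: bool = False

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    @property
    def duration(self) -> float:
        return self.n_frames / self.traj.frame_rate

    @property
    def start_time(self) -> float:
        return float(self.traj.t[self.start])

    def slice(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.start:self.end]

    @property
    def cimar(self) -> str:
        return format_cimar(self.key)


def segment_excursions(traj: Trajectory, analysis_window_min: float | None = 25.0,
                       mouse_number: int | None = None,
                       min_frames: int = 2) -> list[Excursion]:
    """Split a zone-annotated trial into ordered, non-overlapping excursions.

    Excursions straddling the analysis window end are truncated there; a
    trailing trip that never returns to the tunnel is kept and flagged
    ``open_ended``. Single-frame zone flickers (< ``min_frames``) are
    discarded as tracking jitter.
    """
    if traj.zone is None:
        raise SegmentationError("trajectory must be zone-annotated first")
    zone = traj.zone
    in_tunnel = zone == IN_TUNNEL
    if not in_tunnel.any():
        raise SegmentationError("trajectory has no InTunnel frames")
    if mouse_number is None:
        digits = re.findall(r"\d+", traj.mouse_id)
        mouse_number = int(digits[0]) if digits else 0

    n = len(zone)
    if analysis_window_min is None:
        n_window = n
    else:
        t0 = traj.t[0]
        n_window = int(np.searchsorted(traj.t, t0 + analysis_window_min * 60.0,
                                       side="left"))
    first_in = int(np.argmax(in_tunnel))
    out = ~in_tunnel
    excursions: list[Excursion] = []
    i = first_in
    num = 0
    while i < n_window:
        if not out[i]:
            i += 1
            continue
        j = i
        while j < n and out[j]:
            j += 1
        open_ended = j >= n
        end = min(j, n_window)
        if end - i >= min_frames:
            num += 1
            key = CimarKey(mouse_number, num, traj.sex, traj.age,
                           traj.genotype, traj.phase)
            excursions.append(Excursion(key, i, end, traj,
                                        open_ended=open_ended))
        i = j
    return excursions


def export_excursion_index(excursions: list[Excursion], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame({
        "cimar": [e.cimar for e in excursions],
        "start_frame": [e.start for e in excursions],
        "end_frame": [e.end for e in excursions],
        "start_time_s": [e.start_time for e in excursions],
        "duration_s": [e.duration for e in excursions],
        "open_ended": [e.open_ended for e in excursions],
    })
    df.to_csv(path, index=False)
    return df
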