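"""Arena geometry: the circular 5-hole foraging platform and its tracking zones.

The arena is a 35 cm diameter circular platform reached from the home cage
through a tunnel that enters via one of five equally spaced holes; the other
four holes hold sand pots (Pot1..Pot4). Concentric zones (Center,
Intermediate, Wall) and per-feature zones (pot zones at 1.7x pot radius,
tunnel-entry and tunnel zones) partition the platform for behavioral scoring.

Coordinates are in cm. After alignment the tunnel center sits at the origin
and the arena center on the +y axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

# Zone codes, in annotation precedence order (lower code wins on overlap,
# except OUT_OF_BOUNDS which is a fallback flag).
IN_TUNNEL = 0
TUNNEL_ENTRY = 1
POT1 = 2
POT2 = 3
POT3 = 4
POT4 = 5
TUNNEL_ZONE = 6
CENTER = 7
INTERMEDIATE = 8
WALL = 9
OUT_OF_BOUNDS = 10

ZONE_NAMES = {
    IN_TUNNEL: "InTunnel",
    TUNNEL_ENTRY: "TunnelEntry",
    POT1: "Pot1",
    POT2: "Pot2",
    POT3: "Pot3",
    POT4: "Pot4",
    TUNNEL_ZONE: "TunnelZone",
    CENTER: "Center",
    INTERMEDIATE: "Intermediate",
    WALL: "Wall",
    OUT_OF_BOUNDS: "OutOfBounds",
}
ZONE_CODES = {v: k for k, v in ZONE_NAMES.items()}
POT_ZONES = (POT1, POT2, POT3, POT4)


class GeometryError(ValueError):
    """Raised for inconsistent arena configurations."""


@dataclass
class ArenaGeometry:
    """Canonical arena layout.

    The five holes sit on the circle through the pot centers (the outer
    radius of the Intermediate zone); the tunnel hole is placed at the
    bottom of that circle and Pots 1-4 follow counter-clockwise at 72
    degree steps. The Center zone radius is half the Intermediate radius
    and pot zones extend ``pot_zone_factor`` times the pot radius.
    """

    arena_diameter: float = 35.0
    pot_radius: float = 2.75
    pot_zone_factor: float = 1.7
    intermediate_outer_radius: float = 12.0
    tunnel_center: tuple[float, float] = (0.0, 0.0)
    in_tunnel_offset: float = 1.5
    in_tunnel_radius: float = 1.0

    # derived fields
    arena_center: tuple[float, float] = field(init=False)
    pot_centers: np.ndarray = field(init=False, repr=False)
    sector_boundaries: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.arena_diameter <= 0 or self.pot_radius <= 0:
            raise GeometryError("arena diameter and pot radius must be positive")
        if self.intermediate_outer_radius + self.pot_radius > self.arena_radius:
            raise GeometryError("pots must lie inside the arena")
        tx, ty = self.tunnel_center
        self.arena_center = (tx, ty + self.intermediate_outer_radius)
        # hole angles measured at the arena center; tunnel hole at -90 deg
        angles = -math.pi / 2 + 2 * math.pi / 5 * np.arange(1, 5)
        cx, cy = self.arena_center
        r = self.intermediate_outer_radius
        self.pot_centers = np.column_stack(
            [cx + r * np.cos(angles), cy + r * np.sin(angles)]
        )
        hole_angles = -math.pi / 2 + 2 * math.pi / 5 * np.arange(5)
        self.sector_boundaries = hole_angles + math.pi / 5

    @property
    def arena_radius(self) -> float:
        return self.arena_diameter / 2.0

    @property
    def pot_zone_radius(self) -> float:
        return self.pot_zone_factor * self.pot_radius

    @property
    def tunnel_zone_radius(self) -> float:
        # the tunnel zone shares the pot-zone radius
        return self.pot_zone_radius

    @property
    def center_radius(self) -> float:
        return self.intermediate_outer_radius / 2.0

    @property
    def in_tunnel_point(self) -> np.ndarray:
        """Center of the In-Tunnel zone (peripheral edge of the entry hole).

        The tracker pins the mouse here whenever it is in the tunnel or cage.
        """
        tx, ty = self.tunnel_center
        cx, cy = self.arena_center
        v = np.array([tx - cx, ty - cy], dtype=float)
        v /= np.linalg.norm(v)
        return np.array([tx, ty], dtype=float) + self.in_tunnel_offset * v

    def landmarks(self) -> np.ndarray:
        """Tunnel center followed by the four pot centers (5 x 2)."""
        return np.vstack([np.asarray(self.tunnel_center), self.pot_centers])

    def pot_center(self, pot: int) -> np.ndarray:
        """Center of Pot ``pot`` (1-based)."""
        if pot not in (1, 2, 3, 4):
            raise GeometryError(f"no such pot: {pot}")
        return self.pot_centers[pot - 1]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("arena_center")
        d.pop("pot_centers")
        d.pop("sector_boundaries")
        d["tunnel_center"] = list(self.tunnel_center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        d = dict(d)
        if "tunnel_center" in d:
            d["tunnel_center"] = tuple(d["tunnel_center"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ArenaGeometry":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)
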