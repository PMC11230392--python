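"""Arena geometry: coordinate frame and zone definitions.

The assay arena is a square open field connected to a home cage through a
short tunnel.  Four circular food pots sit in the arena; one of them carries
food during the Exploration phase (Pot2) and a different one during the
Foraging phase (Pot4, buried).  All downstream computation — excursion
segmentation, location measures, second-guessing series — is defined in
terms of these zones.

Coordinates are in centimetres, origin at the arena's lower-left corner,
x to the right, y up.  The home cage and tunnel sit below the arena at
negative y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: canonical zone labels in annotation precedence order
ZONE_HOME = "home"
ZONE_TUNNEL = "tunnel"
POT_LABELS = ("Pot1", "Pot2", "Pot3", "Pot4")
ZONE_CENTER = "center"
ZONE_PERIMETER = "perimeter"
ZONE_OOB = "out_of_bounds"

#: food pot per assay phase
PHASE_FOOD_POT = {"Exploration": "Pot2", "Foraging": "Pot4"}
PHASES = ("Exploration", "Foraging")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1] × [y0, y1] in cm."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle {self}")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)


@dataclass(frozen=True)
class ArenaGeometry:
    """Zone layout of the foraging assay.

    Defaults describe a 60 × 60 cm arena with the home cage attached below
    through a 8-cm tunnel and the four pots placed symmetrically near the
    corners.  Pot2 (top-left) holds food during Exploration; Pot4
    (bottom-right) during Foraging.
    """

    arena_bounds: Rect = Rect(0.0, 0.0, 60.0, 60.0)
    home_zone: Rect = Rect(24.0, -20.0, 36.0, -8.0)
    tunnel_zone: Rect = Rect(27.0, -8.0, 33.0, 0.0)
    pot_centers: dict = field(
        default_factory=lambda: {
            "Pot1": (12.0, 12.0),
            "Pot2": (12.0, 48.0),
            "Pot3": (48.0, 48.0),
            "Pot4": (48.0, 12.0),
        }
    )
    pot_radius_cm: float = 5.0
    center_fraction: float = 1.0 / 3.0  # side fraction of the centred center zone

    def __post_init__(self) -> None:
        if set(self.pot_centers) != set(POT_LABELS):
            raise ValueError(f"pot_centers must define exactly {POT_LABELS}")
        if self.pot_radius_cm <= 0:
            raise ValueError("pot_radius_cm must be positive")
        if not (0 < self.center_fraction < 1):
            raise ValueError("center_fraction must be in (0, 1)")
        # pots pairwise disjoint and inside the arena
        pts = [np.asarray(self.pot_centers[p]) for p in POT_LABELS]
        for i in range(4):
            if not bool(self.arena_bounds.contains(*pts[i])):
                raise ValueError(f"{POT_LABELS[i]} centre outside arena bounds")
            for j in range(i + 1, 4):
                if np.linalg.norm(pts[i] - pts[j]) < 2 * self.pot_radius_cm:
                    raise ValueError(
                        f"pot zones {POT_LABELS[i]} and {POT_LABELS[j]} overlap"
                    )
        # home and tunnel must not intrude into the arena
        if self.tunnel_zone.y1 > self.arena_bounds.y0 + 1e-9:
            raise ValueError("tunnel must end at the arena boundary")
        if self.home_zone.y1 > self.tunnel_zone.y0 + 1e-9:
            raise ValueError("home zone overlaps tunnel")

    # -- derived landmarks ------------------------------------------------

    @property
    def center_zone(self) -> Rect:
        b = self.arena_bounds
        w = (b.x1 - b.x0) * self.center_fraction
        h = (b.y1 - b.y0) * self.center_fraction
        cx, cy = b.center
        return Rect(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    @property
    def entry_point(self) -> tuple[float, float]:
        """Point where the tunnel opens into the arena (tunnel exit)."""
        return ((self.tunnel_zone.x0 + self.tunnel_zone.x1) / 2.0, self.arena_bounds.y0)

    @property
    def arena_centroid(self) -> tuple[float, float]:
        return self.arena_bounds.center

    # -- zone annotation --------------------------------------------------

    def annotate(self, x, y) -> np.ndarray:
        """Label each (x, y) sample with its primary zone.

        Precedence: home > tunnel > pots > center > perimeter; anything
        outside all zones is ``out_of_bounds``.  Vectorised; idempotent by
        construction (a pure function of position).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, ZONE_OOB, dtype=object)
        in_arena = self.arena_bounds.contains(x, y)
        out[in_arena] = ZONE_PERIMETER
        cz = self.center_zone
        out[in_arena & cz.contains(x, y)] = ZONE_CENTER
        for pot in POT_LABELS:
            px, py = self.pot_centers[pot]
            d2 = (x - px) ** 2 + (y - py) ** 2
            out[in_arena & (d2 <= self.pot_radius_cm**2)] = pot
        out[self.tunnel_zone.contains(x, y)] = ZONE_TUNNEL
        out[self.home_zone.contains(x, y)] = ZONE_HOME
        return out.astype(str)

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "arena_bounds": [self.arena_bounds.x0, self.arena_bounds.y0,
                             self.arena_bounds.x1, self.arena_bounds.y1],
            "home_zone": [self.home_zone.x0, self.home_zone.y0,
                          self.home_zone.x1, self.home_zone.y1],
            "tunnel_zone": [self.tunnel_zone.x0, self.tunnel_zone.y0,
                            self.tunnel_zone.x1, self.tunnel_zone.y1],
            "pot_centers": {k: list(v) for k, v in self.pot_centers.items()},
            "pot_radius_cm": self.pot_radius_cm,
            "center_fraction": self.center_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        kw = {}
        for key in ("arena_bounds", "home_zone", "tunnel_zone"):
            if key in d:
                kw[key] = Rect(*map(float, d[key]))
        if "pot_centers" in d:
            kw["pot_centers"] = {k: tuple(map(float, v)) for k, v in d["pot_centers"].items()}
        for key in ("pot_radius_cm", "center_fraction"):
            if key in d:
                kw[key] = float(d[key])
        return cls(**kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "ArenaGeometry":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
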