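"""Synthetic foraging cohorts with planted ground truth.

Generates seeded cohorts for the two-phase home-base foraging assay: each
mouse gets a 30-minute Exploration phase (food at Pot2) and a 30-minute
Foraging phase (food moved to Pot4 and buried).  Trajectories are built
from round-trip excursions drawn from a mixture of *excursion archetypes*
whose mixture weights can be shifted per genotype × sex × age × phase
group, plus a temporally localised "second-guessing" signal: scheduled
revisits of the former food patch (Pot2) during the Foraging phase whose
per-minute dwell follows a configured baseline/peak profile.

Every planted quantity (archetype of each excursion, group mixtures,
second-guess profiles, gross-measure shifts) is returned as ground truth
so downstream recovery can be tested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    ArenaGeometry,
    PHASES,
    POT_LABELS,
    ZONE_CENTER,
    ZONE_HOME,
)

GENOTYPES = ("KO", "WT")
SEXES = ("M", "F")
AGES = ("young", "aged")

#: reserved ground-truth label for scheduled second-guess Pot2 checks
SG_ARCHETYPE = "_sg_pot2"

#: fixed order of group cells (genotype, sex, age)
GROUP_CELLS = tuple(product(GENOTYPES, SEXES, AGES))


def group_key(genotype: str, sex: str, age: str, phase: str | None = None) -> str:
    parts = [genotype, sex, age] + ([phase] if phase else [])
    return "|".join(parts)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExcursionArchetype:
    """A stereotyped round-trip excursion template.

    ``target_sequence`` is the ordered list of zones visited, starting and
    ending at home.  ``tortuosity_level`` scales Ornstein–Uhlenbeck heading
    noise while in the arena; ``center_bias`` in [-1, 1] routes legs through
    the arena centre (positive) or along the walls (negative).
    """

    label: str
    target_sequence: tuple
    duration_mean_s: float
    duration_sd_s: float
    speed_mean_cm_s: float
    speed_sd_cm_s: float
    tortuosity_level: float = 0.5
    dig_probability: float = 0.0
    center_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_mean_s <= 0:
            raise ValueError("duration mean must be positive")
        if self.speed_mean_cm_s <= 0:
            raise ValueError("speed mean must be positive")
        if not (0 <= self.dig_probability <= 1):
            raise ValueError("dig_probability must be in [0,1]")
        seq = tuple(self.target_sequence)
        if len(seq) < 2 or seq[0] != ZONE_HOME or seq[-1] != ZONE_HOME:
            raise ValueError("target_sequence must start and end at home")


@dataclass(frozen=True)
class SecondGuessSpec:
    """Planted Pot2-revisit profile for the Foraging phase.

    Dwell per 1-minute bin is ``baseline_s_per_min`` for every mouse, plus
    ``peak_amplitude_s_per_min`` inside ``peak_window_min`` for mice in
    ``affected_groups`` (cells given as "genotype|sex|age" keys).
    """

    affected_groups: tuple = ()
    peak_window_min: tuple = (5, 12)
    peak_amplitude_s_per_min: float = 10.0
    baseline_s_per_min: float = 2.0
    noise_sd_s: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.peak_window_min
        if not (0 <= lo <= hi <= 30):
            raise ValueError("peak window must lie within [0, 30] minutes")
        if self.peak_amplitude_s_per_min < 0 or self.baseline_s_per_min < 0:
            raise ValueError("amplitudes must be nonnegative")

    def expected_bin_dwell(self, cell_key: str) -> np.ndarray:
        """Expected dwell (s) in bins 1..30 for a group cell."""
        bins = np.arange(1, 31)
        prof = np.full(30, float(self.baseline_s_per_min))
        lo, hi = self.peak_window_min
        if cell_key in self.affected_groups:
            # bin b covers minutes [b-1, b); window (5,12) → bins 6..12
            prof[(bins > lo) & (bins <= hi)] += self.peak_amplitude_s_per_min
        return prof


@dataclass
class SimConfig:
    """Full cohort simulation configuration (see module docstring)."""

    n_per_group: dict            # (genotype, sex, age) -> int
    archetypes: list             # list[ExcursionArchetype]
    base_logits: dict            # phase -> array of len(archetypes)
    mixture_logits: dict = field(default_factory=dict)  # "g|s|a|phase" -> array
    secondguess: SecondGuessSpec = field(default_factory=SecondGuessSpec)
    gross_effects: dict = field(default_factory=dict)
    phases: tuple = PHASES
    phase_duration_s: float = 1800.0
    sample_rate_hz: float = 5.0
    home_dwell_mean_s: float = 35.0
    seed: int = 0
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)

    def __post_init__(self) -> None:
        if self.phase_duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("phase duration and sample rate must be positive")
        for cell, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{cell}] must be >= 1")
        k = len(self.archetypes)
        labels = [a.label for a in self.archetypes]
        if len(set(labels)) != k:
            raise ValueError("archetype labels must be unique")
        for ph in self.phases:
            if len(np.atleast_1d(self.base_logits[ph])) != k:
                raise ValueError(f"base_logits[{ph}] length != {k}")

    def group_weights(self, genotype: str, sex: str, age: str, phase: str) -> np.ndarray:
        """Archetype mixture for one group cell in one phase (softmax simplex)."""
        logits = np.asarray(self.base_logits[phase], dtype=float).copy()
        shift = self.mixture_logits.get(group_key(genotype, sex, age, phase))
        if shift is not None:
            logits = logits + np.asarray(shift, dtype=float)
        w = np.exp(logits - logits.max())
        return w / w.sum()


@dataclass
class GroundTruth:
    """Planted truth for a simulated cohort."""

    excursions: pd.DataFrame     # mouse_id, phase, index, archetype
    mixtures: dict               # "g|s|a|phase" -> {archetype: weight}
    secondguess_profiles: dict   # "g|s|a" -> list of 30 expected dwell (s)
    effects: dict                # planted gross shifts etc.

    def to_json(self, path: str | Path) -> None:
        payload = {
            "excursions": self.excursions.to_dict(orient="list"),
            "mixtures": self.mixtures,
            "secondguess_profiles": {k: list(map(float, v))
                                     for k, v in self.secondguess_profiles.items()},
            "effects": self.effects,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _default_archetypes() -> list:
    # each archetype gets a distinctive kinematic signature (route ×
    # duration × speed × tortuosity × digging) so that stereotyped types
    # are separable in feature space, as in real foraging ethograms
    A = ExcursionArchetype
    return [
        A("dart", (ZONE_HOME, "perimeter", ZONE_HOME), 6, 1.5, 20, 2, 0.2, 0.0, -0.5),
        A("pot2_visit", (ZONE_HOME, "Pot2", ZONE_HOME), 25, 5, 14, 1.5, 0.4, 0.85, -0.2),
        A("pot4_visit", (ZONE_HOME, "Pot4", ZONE_HOME), 25, 5, 14, 1.5, 0.4, 0.85, -0.2),
        A("pot2_pot4", (ZONE_HOME, "Pot2", "Pot4", ZONE_HOME), 45, 6, 16, 1.5, 0.3, 0.5, 0.0),
        A("wall_patrol", (ZONE_HOME, "Pot1", "Pot3", ZONE_HOME), 50, 8, 10, 1, 0.3, 0.05, -0.9),
        A("center_explore", (ZONE_HOME, ZONE_CENTER, ZONE_HOME), 30, 5, 7, 1, 2.2, 0.0, 0.8),
        A("grand_tour", (ZONE_HOME, "Pot1", "Pot2", "Pot3", "Pot4", ZONE_HOME), 80, 10, 13, 1.5, 0.8, 0.3, 0.0),
        A("pot1_visit", (ZONE_HOME, "Pot1", ZONE_HOME), 15, 3, 18, 2, 0.3, 0.5, -0.3),
        A("pot3_visit", (ZONE_HOME, "Pot3", ZONE_HOME), 35, 5, 8, 1, 1.2, 0.6, 0.2),
        A("long_meander", (ZONE_HOME, ZONE_CENTER, "Pot3", ZONE_CENTER, ZONE_HOME), 90, 15, 5, 0.8, 2.8, 0.0, 0.5),
    ]


def make_default_config(preset: str, seed: int = 0) -> SimConfig:
    """Build one of the documented study-condition presets.

    ``paper_like``
        2 phases × 2 genotypes × 2 sexes × 2 ages; n=24/cell young and
        12/cell aged (144 mice); 10 archetypes; phase-shifted mixtures with
        genotype effects concentrated in aged mice in the Foraging phase;
        second-guessing peak (bins 6–12) in aged +/+ (WT) females; an
        age-related drop in food consumption.
    ``null``
        Same archetypes, all group effects zero, second-guess amplitudes
        equal across groups (no affected groups); n=8/cell.
    ``two_archetype_toy``
        Exactly two well-separated archetypes (darts vs long Pot2 visits),
        no planted effects, no second-guess signal; n=4/cell.
    """
    presets = ("paper_like", "null", "two_archetype_toy")
    if preset not in presets:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {presets}")

    if preset == "two_archetype_toy":
        arche = [
            ExcursionArchetype("pot4_fast", (ZONE_HOME, "Pot4", ZONE_HOME),
                               15, 2.0, 16, 1.5, 0.3, 0.0, -0.3),
            ExcursionArchetype("pot2_slow_dig", (ZONE_HOME, "Pot2", ZONE_HOME),
                               50, 6.0, 6, 0.8, 2.0, 1.0, 0.3),
        ]
        base = np.log(np.array([0.8, 0.2]))
        return SimConfig(
            n_per_group={c: 4 for c in GROUP_CELLS},
            archetypes=arche,
            base_logits={ph: base for ph in PHASES},
            secondguess=SecondGuessSpec(affected_groups=(),
                                        peak_amplitude_s_per_min=0.0,
                                        baseline_s_per_min=0.0, noise_sd_s=0.0),
            seed=seed,
        )

    arche = _default_archetypes()
    k = len(arche)
    idx = {a.label: i for i, a in enumerate(arche)}
    base_expl = np.zeros(k)
    base_expl[idx["pot2_visit"]] = 1.0      # food at Pot2 in Exploration
    base_expl[idx["center_explore"]] = 0.4
    base_expl[idx["pot4_visit"]] = -8.0     # nothing buried at Pot4 yet
    base_expl[idx["pot2_pot4"]] = -8.0
    base_forag = np.zeros(k)
    base_forag[idx["pot4_visit"]] = 1.0     # food moved to Pot4 and buried
    base_forag[idx["pot2_pot4"]] = 0.5
    base_forag[idx["center_explore"]] = -8.0  # novelty-driven, Exploration only
    base_forag[idx["long_meander"]] = -8.0

    if preset == "null":
        return SimConfig(
            n_per_group={c: 8 for c in GROUP_CELLS},
            archetypes=arche,
            base_logits={"Exploration": base_expl, "Foraging": base_forag},
            secondguess=SecondGuessSpec(affected_groups=(),
                                        peak_amplitude_s_per_min=0.0,
                                        baseline_s_per_min=2.0),
            seed=seed,
        )

    # paper_like: genotype effects mostly in aged mice, Foraging phase
    mixture = {}
    for sex in SEXES:
        shift = np.zeros(k)
        shift[idx["dart"]] = 1.0
        shift[idx["grand_tour"]] = -1.2
        shift[idx["pot4_visit"]] = 0.7
        mixture[group_key("KO", sex, "aged", "Foraging")] = shift
        shift2 = np.zeros(k)
        shift2[idx["long_meander"]] = -0.8
        mixture[group_key("KO", sex, "aged", "Exploration")] = shift2
    # male KO repertoire narrowing at both ages (diversity effect)
    for age in AGES:
        for ph in PHASES:
            key = group_key("KO", "M", age, ph)
            shift = mixture.get(key, np.zeros(k)).copy()
            shift[idx["pot2_visit" if ph == "Exploration" else "pot4_visit"]] += 0.9
            mixture[key] = shift

    n = {}
    for cell in GROUP_CELLS:
        n[cell] = 24 if cell[2] == "young" else 12

    return SimConfig(
        n_per_group=n,
        archetypes=arche,
        base_logits={"Exploration": base_expl, "Foraging": base_forag},
        mixture_logits=mixture,
        home_dwell_mean_s=90.0,  # ≈14 excursions/phase → ~4,000 cohort-wide
        secondguess=SecondGuessSpec(
            affected_groups=(group_key("WT", "F", "aged"),),
            peak_window_min=(5, 12),
            peak_amplitude_s_per_min=10.0,
            baseline_s_per_min=2.0,
        ),
        gross_effects={"food_g": {"base_mean": 0.6, "base_sd": 0.12,
                                  "aged_shift": -0.2},
                       "sand_g": {"base_mean": 5.0, "base_sd": 1.2}},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# excursion path generation
# ---------------------------------------------------------------------------

_ARRIVE_CM = 2.5       # waypoint capture radius
_OU_KAPPA = 2.0        # heading-noise mean reversion (1/s)


def _zone_waypoint(zone: str, geom: ArenaGeometry) -> np.ndarray:
    if zone in POT_LABELS:
        return np.array(geom.pot_centers[zone], dtype=float)
    if zone == ZONE_CENTER:
        return np.array(geom.arena_centroid, dtype=float)
    if zone == "perimeter":
        ex, ey = geom.entry_point
        return np.array([ex, ey + 9.0], dtype=float)
    if zone == ZONE_HOME:
        return np.array(geom.home_zone.center, dtype=float)
    raise ValueError(f"archetype target zone {zone!r} not present in geometry")


def _route_waypoints(seq, geom: ArenaGeometry, center_bias: float) -> list:
    """Expand a zone sequence into a polyline of waypoints through the tunnel."""
    entry = np.array(geom.entry_point, dtype=float)
    tun = np.array(geom.tunnel_zone.center, dtype=float)
    home = np.array(geom.home_zone.center, dtype=float)
    inner = [_zone_waypoint(z, geom) for z in seq[1:-1]]
    pts = [home, tun, entry]
    centroid = np.array(geom.arena_centroid, dtype=float)
    prev = entry
    for p in inner:
        mid = 0.5 * (prev + p)
        via = mid + 0.6 * center_bias * (centroid - mid)
        b = geom.arena_bounds
        via = np.clip(via, [b.x0 + 2, b.y0 + 2], [b.x1 - 2, b.y1 - 2])
        if np.linalg.norm(p - prev) > 12:   # only bend long legs
            pts.append(via)
        pts.append(p)
        prev = p
    pts += [entry, tun, home]
    # dig-eligible waypoint indices = pots in the inner sequence
    pot_idx = [i for i, p in enumerate(pts)
               if any(np.allclose(p, geom.pot_centers[q]) for q in POT_LABELS)]
    return pts, pot_idx


def simulate_excursion(archetype: ExcursionArchetype, geometry: ArenaGeometry,
                       rng: np.random.Generator, sample_rate_hz: float = 5.0,
                       pot_dwell_s: float | None = None) -> np.ndarray:
    """Simulate one round-trip excursion; returns an (n, 2) position array.

    The route home → targets → home is traversed at a drawn speed with
    OU heading noise scaled by ``tortuosity_level`` while in the arena.
    If the realised travel time falls short of the drawn duration and the
    archetype digs (or ``pot_dwell_s`` is given), the mouse dwells at the
    last pot to make up the difference.  First and last samples lie in the
    home zone.
    """
    dt = 1.0 / sample_rate_hz
    for z in archetype.target_sequence:
        _zone_waypoint(z, geometry)  # raises for unknown zones
    speed = max(1.0, rng.normal(archetype.speed_mean_cm_s, archetype.speed_sd_cm_s))
    duration = max(dt, rng.normal(archetype.duration_mean_s, archetype.duration_sd_s))
    waypoints, pot_idx = _route_waypoints(archetype.target_sequence, geometry,
                                          archetype.center_bias)

    b = geometry.arena_bounds
    pos = waypoints[0].copy()
    pts = [pos.copy()]
    theta = 0.0
    sigma = 1.2 * archetype.tortuosity_level
    pot_arrivals = {}  # waypoint index -> sample index of arrival
    arrivals = {}      # every waypoint index -> sample index of arrival
    for wi in range(1, len(waypoints)):
        wp = waypoints[wi]
        seg_budget = int(4 * np.linalg.norm(wp - pos) / (speed * dt)) + 40
        steps = 0
        arrive = max(_ARRIVE_CM, 1.2 * speed * dt)  # avoid overshoot oscillation
        while np.linalg.norm(wp - pos) > arrive:
            steps += 1
            vec = wp - pos
            ideal = math.atan2(vec[1], vec[0])
            in_arena = pos[1] > b.y0 + 0.5 and wp[1] > b.y0 - 0.5
            if in_arena and steps <= seg_budget:
                theta += -_OU_KAPPA * theta * dt + sigma * math.sqrt(dt) * rng.normal()
            else:
                theta = 0.0
            h = ideal + theta
            step = min(speed * dt, np.linalg.norm(vec))
            pos = pos + step * np.array([math.cos(h), math.sin(h)])
            if in_arena:
                pos = np.clip(pos, [b.x0 + 0.3, b.y0 + 0.3], [b.x1 - 0.3, b.y1 - 0.3])
            pts.append(pos.copy())
        arrivals[wi] = len(pts) - 1
        if wi in pot_idx:
            pot_arrivals[wi] = len(pts) - 1
    if np.linalg.norm(pos - waypoints[-1]) > 1e-9:
        pts.append(waypoints[-1].copy())  # close the round trip exactly
    xy = np.array(pts)

    # dwell to realise the drawn duration: dig at a pot when the archetype
    # digs (or an explicit pot dwell is requested), otherwise linger at the
    # waypoint farthest from home
    travel_s = (len(xy) - 1) * dt
    dwell_i = None
    jitter_sd = 0.35
    if pot_dwell_s is not None and pot_arrivals:
        dwell_n = int(round(pot_dwell_s / dt))
        dwell_i = pot_arrivals[max(pot_arrivals)]
    else:
        dwell_n = int(round(max(0.0, duration - travel_s) / dt))
        if dwell_n > 0:
            if pot_arrivals and rng.random() < archetype.dig_probability:
                dwell_i = pot_arrivals[max(pot_arrivals)]
            else:
                home = waypoints[0]
                far = max((wi for wi in arrivals if 0 < wi < len(waypoints) - 1),
                          key=lambda wi: np.linalg.norm(waypoints[wi] - home),
                          default=None)
                if far is not None:
                    dwell_i = arrivals[far]
                    jitter_sd = 0.6
    if dwell_n > 0 and dwell_i is not None:
        centre = xy[dwell_i]
        jit = rng.normal(0.0, jitter_sd, size=(dwell_n, 2))
        block = centre + np.clip(jit, -1.8, 1.8)
        xy = np.vstack([xy[: dwell_i + 1], block, xy[dwell_i + 1:]])

    # guarantee closure inside the home zone
    hz = geometry.home_zone
    for k in (0, -1):
        if not bool(hz.contains(*xy[k])):
            xy[k] = geometry.home_zone.center
    return xy


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _home_dwell_block(n: int, geom: ArenaGeometry, rng: np.random.Generator) -> np.ndarray:
    cx, cy = geom.home_zone.center
    hz = geom.home_zone
    xy = np.column_stack([
        np.clip(cx + rng.normal(0, 1.0, n), hz.x0 + 0.5, hz.x1 - 0.5),
        np.clip(cy + rng.normal(0, 1.0, n), hz.y0 + 0.5, hz.y1 - 0.5),
    ])
    return xy


def _simulate_phase(config: SimConfig, cell, phase: str, mouse_idx: int,
                    rng: np.random.Generator):
    """One mouse-phase timeline; returns (xy array, excursion labels)."""
    geom = config.geometry
    rate = config.sample_rate_hz
    dt = 1.0 / rate
    n_total = int(round(config.phase_duration_s * rate))
    weights = config.group_weights(*cell, phase)
    k = len(config.archetypes)

    # second-guess schedule (Foraging phase only); low-rate baseline dwell
    # is delivered as occasional longer checks (chunk ~8 s) rather than a
    # visit every minute, preserving the expected dwell per bin while
    # keeping revisit counts realistic
    sg_sched = []  # (scheduled time s, dwell s)
    if phase == "Foraging":
        sg = config.secondguess
        chunk = 8.0
        prof = sg.expected_bin_dwell(group_key(*cell))
        for b in range(1, 31):
            target = prof[b - 1]
            if target <= 0.25:
                continue
            if target < chunk and rng.random() > target / chunk:
                continue
            d = max(0.0, rng.normal(max(target, chunk), sg.noise_sd_s))
            d = min(d, 45.0)
            if d > 0.25:
                sg_sched.append(((b - 1) * 60.0 + rng.uniform(1.0, 6.0), d))

    blocks = []
    labels = []
    i = 0  # samples emitted
    sg_ptr = 0
    sg_arche = ExcursionArchetype(SG_ARCHETYPE, (ZONE_HOME, "Pot2", ZONE_HOME),
                                  10, 0, 15, 1, 0.2, 1.0, -0.2)
    blocks.append(_home_dwell_block(1, geom, rng))
    i += 1
    while i < n_total:
        t = i * dt
        # pending second-guess check?
        if sg_ptr < len(sg_sched) and t >= sg_sched[sg_ptr][0]:
            dwell = sg_sched[sg_ptr][1]
            sg_ptr += 1
            xy = simulate_excursion(sg_arche, geom, rng, rate, pot_dwell_s=dwell)
            if i + len(xy) + 2 <= n_total:
                blocks.append(xy)
                labels.append(SG_ARCHETYPE)
                i += len(xy)
            continue
        # home dwell until next event
        dwell_s = max(1.0, rng.exponential(config.home_dwell_mean_s))
        if sg_ptr < len(sg_sched):
            dwell_s = min(dwell_s, max(0.4, sg_sched[sg_ptr][0] - t))
        nd = min(int(round(dwell_s * rate)), n_total - i)
        if nd > 0:
            blocks.append(_home_dwell_block(nd, geom, rng))
            i += nd
        if i >= n_total:
            break
        # regular excursion; an overrun past a scheduled Pot2 check only
        # delays the check (it fires on the next return home), which keeps
        # archetype frequencies unbiased across phases
        ai = int(rng.choice(k, p=weights))
        arche = config.archetypes[ai]
        xy = simulate_excursion(arche, geom, rng, rate)
        if i + len(xy) + 2 > n_total:
            # would be cut by phase end: stay home instead
            nd = n_total - i
            blocks.append(_home_dwell_block(nd, geom, rng))
            i += nd
            break
        blocks.append(xy)
        labels.append(arche.label)
        i += len(xy)
    xy = np.vstack(blocks)[:n_total]
    return xy, labels


def simulate_cohort(config: SimConfig):
    """Simulate the full cohort.

    Returns ``(trajectories, metadata, gross, truth)``: a long trajectory
    table (mouse_id, phase, t_s, x_cm, y_cm), per-mouse metadata with the
    externally measured scalars (food_g, sand_g), the gross scalar table,
    and a :class:`GroundTruth`.  Identical ``config.seed`` gives identical
    outputs.
    """
    geom = config.geometry
    dt = 1.0 / config.sample_rate_hz
    n_total = int(round(config.phase_duration_s * config.sample_rate_hz))
    t_grid = np.arange(n_total) * dt

    mice = []
    mouse_idx = 0
    for cell in GROUP_CELLS:
        for _ in range(config.n_per_group.get(cell, 0)):
            mouse_idx += 1
            mice.append((f"M{mouse_idx:03d}", cell))

    traj_parts = []
    gt_rows = []
    meta_rows = []
    fx = config.gross_effects.get("food_g", {"base_mean": 0.6, "base_sd": 0.12})
    sx = config.gross_effects.get("sand_g", {"base_mean": 5.0, "base_sd": 1.2})
    for mi, (mid, cell) in enumerate(mice):
        for pi, phase in enumerate(config.phases):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, mi, pi]))
            xy, labels = _simulate_phase(config, cell, phase, mi, rng)
            traj_parts.append(pd.DataFrame({
                "mouse_id": mid, "phase": phase, "t_s": t_grid,
                "x_cm": xy[:, 0], "y_cm": xy[:, 1],
            }))
            for j, lab in enumerate(labels, start=1):
                gt_rows.append((mid, phase, j, lab))
        g = np.random.default_rng(np.random.SeedSequence([config.seed, mi, 97]))
        genotype, sex, age = cell
        food = fx["base_mean"] + (fx.get("aged_shift", 0.0) if age == "aged" else 0.0)
        food += fx.get(f"{genotype}_shift", 0.0)
        food_g = max(0.0, g.normal(food, fx["base_sd"]))
        sand_g = max(0.0, g.normal(sx["base_mean"] + sx.get(f"{genotype}_shift", 0.0),
                                   sx["base_sd"]))
        meta_rows.append((mid, genotype, sex, age, food_g, sand_g))

    traj = pd.concat(traj_parts, ignore_index=True)
    meta = pd.DataFrame(meta_rows, columns=["mouse_id", "genotype", "sex",
                                            "age", "food_g", "sand_g"])
    gross = meta[["mouse_id", "food_g", "sand_g"]].copy()

    mixtures = {}
    arch_labels = [a.label for a in config.archetypes]
    for cell in GROUP_CELLS:
        for phase in config.phases:
            w = config.group_weights(*cell, phase)
            mixtures[group_key(*cell, phase)] = dict(zip(arch_labels, map(float, w)))
    sg_prof = {group_key(*cell): config.secondguess.expected_bin_dwell(group_key(*cell))
               for cell in GROUP_CELLS}
    truth = GroundTruth(
        excursions=pd.DataFrame(gt_rows, columns=["mouse_id", "phase", "index", "archetype"]),
        mixtures=mixtures,
        secondguess_profiles=sg_prof,
        effects={"gross": config.gross_effects,
                 "mixture_logits": {kk: list(map(float, vv))
                                    for kk, vv in config.mixture_logits.items()},
                 "secondguess_affected": list(config.secondguess.affected_groups)},
    )
    return traj, meta, gross, truth


def write_cohort(outdir: str | Path, traj: pd.DataFrame, meta: pd.DataFrame,
                 truth: GroundTruth) -> dict:
    """Write trajectory/metadata CSVs and ground-truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectories": outdir / "trajectories.csv",
        "metadata": outdir / "metadata.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    traj.to_csv(paths["trajectories"], index=False, float_format="%.3f")
    meta.to_csv(paths["metadata"], index=False, float_format="%.4f")
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}


# fast, trajectory-free generators used by the statistical power/FDR batteries
# ---------------------------------------------------------------------------

def simulate_secondguess_series(spec: SecondGuessSpec, metadata: pd.DataFrame,
                                rng: np.random.Generator,
                                noise_sd_s: float = 5.0) -> pd.DataFrame:
    """Draw per-mouse 30-bin Pot2 dwell series directly from a profile.

    Used by the model-level simulation batteries, where generating full
    trajectories would only add Monte-Carlo noise around the same planted
    profile.  Returns long form (mouse_id, bin, dwell_s).
    """
    rows = []
    for _, m in metadata.iterrows():
        prof = spec.expected_bin_dwell(group_key(m.genotype, m.sex, m.age))
        vals = np.clip(prof + rng.normal(0, noise_sd_s, 30), 0, 60)
        for b in range(30):
            rows.append((m.mouse_id, b + 1, vals[b]))
    return pd.DataFrame(rows, columns=["mouse_id", "bin", "dwell_s"])


def simulate_module_expression(metadata: pd.DataFrame, n_modules: int,
                               rng: np.random.Generator,
                               fold_changes: dict | None = None,
                               base_weights: np.ndarray | None = None,
                               phase: str = "Foraging",
                               mean_total: int = 45,
                               concentration: float = 600.0) -> pd.DataFrame:
    """Draw per-mouse module expression counts directly (no trajectories).

    Each mouse's counts are multinomial over ``n_modules`` with weights
    drawn from a Dirichlet around ``base_weights`` (uniform if omitted;
    ``concentration`` controls between-mouse overdispersion) after applying
    per-group multiplicative ``fold_changes`` ("genotype|sex|age" →
    length-m array).  Totals are Poisson(``mean_total``), floored at 1.
    Returns the long expression form used by the module-wise tests.
    """
    base = (np.full(n_modules, 1.0 / n_modules) if base_weights is None
            else np.asarray(base_weights, dtype=float))
    rows = []
    for _, m in metadata.iterrows():
        w = base.copy()
        if fold_changes:
            fc = fold_changes.get(group_key(m.genotype, m.sex, m.age))
            if fc is not None:
                w = w * np.asarray(fc, dtype=float)
        w = w / w.sum()
        w = rng.dirichlet(w * concentration)
        total = max(1, int(rng.poisson(mean_total)))
        counts = rng.multinomial(total, w)
        for mod in np.nonzero(counts)[0]:
            rows.append((m.mouse_id, phase, mod + 1, int(counts[mod]), total,
                         counts[mod] / total, m.genotype, m.sex, m.age))
    return pd.DataFrame(rows, columns=["mouse_id", "phase", "module", "count",
                                       "total", "freq", "genotype", "sex", "age"])


def fdr_battery_design(n_modules: int = 40, n_planted: int = 5):
    """Base weights and KO fold-changes for the module-FDR battery.

    Five planted 3-fold frequency shifts (three rare modules up ×3 at base
    weight 0.02, two common ones down ÷3 at 0.09) chosen so total planted
    mass is conserved — the 35 unplanted modules keep their expected
    frequencies exactly, making them a genuine null for FDR evaluation
    under the compositional (multinomial) model.
    """
    if n_modules != 40 or n_planted != 5:
        raise ValueError("the balanced design is defined for 40 modules / 5 planted")
    base = np.full(n_modules, 0.76 / 35)
    base[:3] = 0.02
    base[3:5] = 0.09
    fold = np.ones(n_modules)
    fold[:3] = 3.0
    fold[3:5] = 1 / 3.0
    assert np.isclose((base * fold).sum(), 1.0)
    return base, fold


def make_group_metadata(n_per_cell: int, cells=GROUP_CELLS) -> pd.DataFrame:
    """Balanced metadata frame with ``n_per_cell`` mice per group cell."""
    rows = []
    i = 0
    for cell in cells:
        for _ in range(n_per_cell):
            i += 1
            rows.append((f"M{i:03d}",) + cell)
    return pd.DataFrame(rows, columns=["mouse_id", "genotype", "sex", "age"])
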