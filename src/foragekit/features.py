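"""The 52-measure excursion featurization.

Each round-trip excursion is described by 52 measures in four families —
velocity (8), gait dynamics (12), trajectory geometry (16) and location
(16).  Speeds come from central differences of position; headings from
consecutive displacement vectors; a "stop" is speed < 2 cm/s sustained for
at least 1 s.  Spatial-occupancy measures use a square grid whose cell
side equals the geometry's pot radius (5 cm by default) anchored at the
arena's lower-left corner, so the measures move and scale with the
geometry.  Tortuosity (path length ÷ max displacement from the tunnel
exit) is capped at 50 when the displacement is under 1 cm.

Standardization is per-column z-scoring with the population SD (divide by
n) or a robust median/MAD variant; zero-variance columns are dropped and
recorded so held-out excursions can be projected with the same parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .geometry import ArenaGeometry, PHASE_FOOD_POT, POT_LABELS, ZONE_CENTER, ZONE_PERIMETER, ZONE_TUNNEL

MOBILE_SPEED_CM_S = 2.0     # mobile/stop threshold
STOP_MIN_S = 1.0
DIG_SPEED_CM_S = 1.0
TORTUOSITY_CAP = 50.0
MIN_DISPLACEMENT_CM = 1.0

CATEGORIES = ("velocity", "gait_dynamics", "trajectory_geometry", "location")


@dataclass(frozen=True)
class MeasureDefinition:
    name: str
    category: str
    units: str
    higher_is: str = "n/a"   # more_movement | more_dwell | n/a


def measure_catalog() -> list[MeasureDefinition]:
    """The 52 measure definitions, in feature-matrix column order."""
    M = MeasureDefinition
    velocity = [
        M("speed_mean", "velocity", "cm/s", "more_movement"),
        M("speed_median", "velocity", "cm/s", "more_movement"),
        M("speed_max", "velocity", "cm/s", "more_movement"),
        M("speed_sd", "velocity", "cm/s"),
        M("accel_mean", "velocity", "cm/s^2", "more_movement"),
        M("accel_max", "velocity", "cm/s^2", "more_movement"),
        M("entry_speed", "velocity", "cm/s", "more_movement"),
        M("exit_speed", "velocity", "cm/s", "more_movement"),
    ]
    gait = [
        M("fraction_mobile", "gait_dynamics", "fraction", "more_movement"),
        M("stop_count", "gait_dynamics", "count", "more_dwell"),
        M("stop_mean_s", "gait_dynamics", "s", "more_dwell"),
        M("stop_longest_s", "gait_dynamics", "s", "more_dwell"),
        M("speed_lag1_autocorr", "gait_dynamics", "unitless"),
        M("speed_osc_period_s", "gait_dynamics", "s"),
        M("burst_count", "gait_dynamics", "count", "more_movement"),
        M("burst_mean_s", "gait_dynamics", "s", "more_movement"),
        M("jerk_rms", "gait_dynamics", "cm/s^3"),
        M("movebout_count", "gait_dynamics", "count", "more_movement"),
        M("movebout_mean_s", "gait_dynamics", "s", "more_movement"),
        M("speed_entropy", "gait_dynamics", "nats"),
    ]
    geometry = [
        M("duration_s", "trajectory_geometry", "s"),
        M("path_length_cm", "trajectory_geometry", "cm", "more_movement"),
        M("max_displacement_cm", "trajectory_geometry", "cm", "more_movement"),
        M("tortuosity", "trajectory_geometry", "unitless"),
        M("total_turning_rad", "trajectory_geometry", "rad"),
        M("angular_speed_mean", "trajectory_geometry", "rad/s"),
        M("turns_gt90_count", "trajectory_geometry", "count"),
        M("meander_rad_per_cm", "trajectory_geometry", "rad/cm"),
        M("heading_circ_var", "trajectory_geometry", "unitless"),
        M("clockwise_fraction", "trajectory_geometry", "fraction"),
        M("grid_cells_visited", "trajectory_geometry", "count", "more_movement"),
        M("revisit_index", "trajectory_geometry", "fraction", "more_dwell"),
        M("straightness_1s_mean", "trajectory_geometry", "fraction"),
        M("net_bearing_rad", "trajectory_geometry", "rad"),
        M("hull_area_cm2", "trajectory_geometry", "cm^2", "more_movement"),
        M("grid_max_dwell_s", "trajectory_geometry", "s", "more_dwell"),
    ]
    location = (
        [M(f"{p.lower()}_time_s", "location", "s", "more_dwell") for p in POT_LABELS]
        + [M(f"{p.lower()}_visits", "location", "count") for p in POT_LABELS]
        + [
            M("pot_latency_s", "location", "s"),
            M("first_pot_index", "location", "index"),
            M("center_time_s", "location", "s", "more_dwell"),
            M("perimeter_time_s", "location", "s", "more_dwell"),
            M("wall_dist_mean_cm", "location", "cm"),
            M("food_pot_min_dist_cm", "location", "cm"),
            M("dig_time_s", "location", "s", "more_dwell"),
            M("arena_time_fraction", "location", "fraction"),
        ]
    )
    catalog = velocity + gait + geometry + location
    assert len(catalog) == 52 and len({m.name for m in catalog}) == 52
    return catalog


MEASURE_NAMES = tuple(m.name for m in measure_catalog())


def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return [(s, e - s + 1) for s, e in zip(starts, ends)]


def compute_features(samples: pd.DataFrame, geometry: ArenaGeometry,
                     phase: str, t_start_s: float | None = None,
                     t_end_s: float | None = None) -> dict:
    """Compute the 52 measures for one excursion.

    ``samples`` holds the excursion's rows (t_s, x_cm, y_cm, zone) in time
    order.  ``phase`` selects the current food pot (Pot2 in Exploration,
    Pot4 in Foraging) for the goal-distance measure.
    """
    n = len(samples)
    if n < 3:
        raise ValueError("excursion has fewer than 3 samples; "
                         "derivatives are undefined")
    t = samples["t_s"].to_numpy(dtype=float)
    x = samples["x_cm"].to_numpy(dtype=float)
    y = samples["y_cm"].to_numpy(dtype=float)
    zone = samples["zone"].to_numpy()
    dt = float(np.median(np.diff(t)))
    duration = (t_end_s - t_start_s) if (t_start_s is not None and t_end_s is not None) \
        else float(t[-1] - t[0] + dt)

    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    ax = np.gradient(vx, t)
    ay = np.gradient(vy, t)
    accel = np.hypot(ax, ay)
    jx = np.gradient(ax, t)
    jy = np.gradient(ay, t)

    f: dict[str, float] = {}
    # --- velocity ---------------------------------------------------------
    f["speed_mean"] = float(speed.mean())
    f["speed_median"] = float(np.median(speed))
    f["speed_max"] = float(speed.max())
    f["speed_sd"] = float(speed.std())
    f["accel_mean"] = float(accel.mean())
    f["accel_max"] = float(accel.max())
    first_s = t <= t[0] + 1.0
    last_s = t >= t[-1] - 1.0
    f["entry_speed"] = float(speed[first_s].mean())
    f["exit_speed"] = float(speed[last_s].mean())

    # --- gait dynamics ----------------------------------------------------
    mobile = speed > MOBILE_SPEED_CM_S
    f["fraction_mobile"] = float(mobile.mean())
    stops = [(s, ln) for s, ln in _runs(~mobile) if ln * dt >= STOP_MIN_S]
    f["stop_count"] = float(len(stops))
    f["stop_mean_s"] = float(np.mean([ln for _, ln in stops]) * dt) if stops else 0.0
    f["stop_longest_s"] = float(max((ln for _, ln in stops), default=0) * dt)
    if speed.std() > 1e-12:
        f["speed_lag1_autocorr"] = float(np.corrcoef(speed[:-1], speed[1:])[0, 1])
    else:
        f["speed_lag1_autocorr"] = 0.0
    dev = speed - speed.mean()
    if np.abs(dev).max() > 1e-12 and n >= 4:
        power = np.abs(np.fft.rfft(dev)) ** 2
        freqs = np.fft.rfftfreq(n, d=dt)
        kk = int(np.argmax(power[1:]) + 1)
        f["speed_osc_period_s"] = float(1.0 / freqs[kk]) if freqs[kk] > 0 else duration
    else:
        f["speed_osc_period_s"] = duration
    bursts = _runs(speed > 1.5 * speed.mean()) if speed.mean() > 0 else []
    f["burst_count"] = float(len(bursts))
    f["burst_mean_s"] = float(np.mean([ln for _, ln in bursts]) * dt) if bursts else 0.0
    f["jerk_rms"] = float(np.sqrt(np.mean(jx ** 2 + jy ** 2)))
    bouts = _runs(mobile)
    f["movebout_count"] = float(len(bouts))
    f["movebout_mean_s"] = float(np.mean([ln for _, ln in bouts]) * dt) if bouts else 0.0
    smax = speed.max()
    if smax > 1e-12:
        hist, _ = np.histogram(speed / smax, bins=10, range=(0, 1))
        p = hist / hist.sum()
        p = p[p > 0]
        f["speed_entropy"] = float(-(p * np.log(p)).sum())
    else:
        f["speed_entropy"] = 0.0

    # --- trajectory geometry ----------------------------------------------
    steps = np.column_stack([np.diff(x), np.diff(y)])
    step_len = np.hypot(steps[:, 0], steps[:, 1])
    path_len = float(step_len.sum())
    ex, ey = geometry.entry_point
    disp = np.hypot(x - ex, y - ey)
    max_disp = float(disp.max())
    f["duration_s"] = duration
    f["path_length_cm"] = path_len
    f["max_displacement_cm"] = max_disp
    if max_disp < MIN_DISPLACEMENT_CM:
        f["tortuosity"] = TORTUOSITY_CAP
    else:
        f["tortuosity"] = min(TORTUOSITY_CAP, path_len / max_disp)
    moving = step_len > 1e-9
    headings = np.arctan2(steps[moving, 1], steps[moving, 0])
    if headings.size >= 2:
        dh = np.diff(headings)
        dh = (dh + np.pi) % (2 * np.pi) - np.pi
    else:
        dh = np.array([])
    total_turn = float(np.abs(dh).sum())
    f["total_turning_rad"] = total_turn
    f["angular_speed_mean"] = total_turn / duration if duration > 0 else 0.0
    f["turns_gt90_count"] = float((np.abs(dh) > np.pi / 2).sum())
    f["meander_rad_per_cm"] = total_turn / path_len if path_len > 1e-9 else 0.0
    if headings.size:
        R = float(np.hypot(np.cos(headings).mean(), np.sin(headings).mean()))
        f["heading_circ_var"] = 1.0 - R
    else:
        f["heading_circ_var"] = 0.0
    signif = np.abs(dh) > 1e-6
    f["clockwise_fraction"] = float((dh[signif] < 0).mean()) if signif.any() else 0.5
    cell = geometry.pot_radius_cm
    b = geometry.arena_bounds
    cx = np.floor((x - b.x0) / cell).astype(int)
    cy = np.floor((y - b.y0) / cell).astype(int)
    cells = cx * 100003 + cy
    uniq, counts = np.unique(cells, return_counts=True)
    f["grid_cells_visited"] = float(len(uniq))
    # a "visit" to a cell = maximal run of consecutive samples in it
    change = np.nonzero(np.diff(cells) != 0)[0]
    run_cells = cells[np.concatenate([[0], change + 1])]
    vis_uniq, vis_counts = np.unique(run_cells, return_counts=True)
    f["revisit_index"] = float((vis_counts >= 2).sum() / len(vis_uniq))
    f["grid_max_dwell_s"] = float(counts.max() * dt)
    # straightness over consecutive 1-s windows
    w = max(2, int(round(1.0 / dt)))
    ratios = []
    for s0 in range(0, n - 1, w):
        seg = slice(s0, min(s0 + w + 1, n))
        pl = float(np.hypot(np.diff(x[seg]), np.diff(y[seg])).sum())
        if pl > 1e-9:
            net = float(np.hypot(x[seg][-1] - x[seg][0], y[seg][-1] - y[seg][0]))
            ratios.append(net / pl)
    f["straightness_1s_mean"] = float(np.mean(ratios)) if ratios else 1.0
    far = int(np.argmax(disp))
    f["net_bearing_rad"] = float(np.arctan2(y[far] - y[0], x[far] - x[0]))
    pts = np.unique(np.column_stack([x, y]), axis=0)
    if len(pts) >= 3:
        try:
            f["hull_area_cm2"] = float(ConvexHull(pts).volume)
        except QhullError:
            f["hull_area_cm2"] = 0.0
    else:
        f["hull_area_cm2"] = 0.0

    # --- location ----------------------------------------------------------
    for p in POT_LABELS:
        in_pot = zone == p
        f[f"{p.lower()}_time_s"] = float(in_pot.sum() * dt)
        f[f"{p.lower()}_visits"] = float(len(_runs(in_pot)))
    in_any_pot = np.isin(zone, POT_LABELS)
    if in_any_pot.any():
        first = int(np.argmax(in_any_pot))
        f["pot_latency_s"] = float(t[first] - t[0])
        f["first_pot_index"] = float(POT_LABELS.index(zone[first]) + 1)
    else:
        f["pot_latency_s"] = duration     # censored at excursion duration
        f["first_pot_index"] = 0.0
    f["center_time_s"] = float((zone == ZONE_CENTER).sum() * dt)
    f["perimeter_time_s"] = float((zone == ZONE_PERIMETER).sum() * dt)
    in_arena = in_any_pot | (zone == ZONE_CENTER) | (zone == ZONE_PERIMETER)
    if in_arena.any():
        wd = np.minimum.reduce([x[in_arena] - b.x0, b.x1 - x[in_arena],
                                y[in_arena] - b.y0, b.y1 - y[in_arena]])
        f["wall_dist_mean_cm"] = float(wd.mean())
    else:
        f["wall_dist_mean_cm"] = 0.0
    fp = geometry.pot_centers[PHASE_FOOD_POT.get(phase, "Pot2")]
    f["food_pot_min_dist_cm"] = float(np.hypot(x - fp[0], y - fp[1]).min())
    near_pot = np.zeros(n, dtype=bool)
    for p in POT_LABELS:
        pcx, pcy = geometry.pot_centers[p]
        near_pot |= np.hypot(x - pcx, y - pcy) <= geometry.pot_radius_cm
    f["dig_time_s"] = float((near_pot & (speed < DIG_SPEED_CM_S)).sum() * dt)
    arena_n = int(in_arena.sum())
    tunnel_n = int((zone == ZONE_TUNNEL).sum())
    f["arena_time_fraction"] = arena_n / (arena_n + tunnel_n) if arena_n + tunnel_n else 0.0

    out = {name: f[name] for name in MEASURE_NAMES}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite measures: {bad}")
    return out


def feature_matrix(excursions: pd.DataFrame, annotated: pd.DataFrame,
                   geometry: ArenaGeometry) -> pd.DataFrame:
    """52-measure row for every valid excursion.

    Returns a frame keyed by (mouse_id, phase, index) followed by the 52
    measure columns in catalog order.
    """
    rows = []
    valid = excursions[excursions["valid"]]
    for rec in valid.itertuples(index=False):
        sl = annotated.iloc[rec.i_start: rec.i_end + 1]
        feats = compute_features(sl, geometry, rec.phase,
                                 t_start_s=rec.t_start_s, t_end_s=rec.t_end_s)
        rows.append({"mouse_id": rec.mouse_id, "phase": rec.phase,
                     "index": rec.index, **feats})
    cols = ["mouse_id", "phase", "index"] + list(MEASURE_NAMES)
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass
class StandardizationRecord:
    method: str
    center: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"method": self.method, "center": self.center,
                "scale": self.scale, "dropped": self.dropped}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationRecord":
        return cls(**d)


def standardize(values: pd.DataFrame, method: str = "zscore"):
    """Standardize feature columns; returns (standardized frame, record).

    zscore: (x − mean) / population SD.  robust: (x − median) / (1.4826·MAD).
    Zero-variance (or zero-MAD) columns are dropped and listed in the
    record.  Raises if nothing remains.
    """
    if method not in ("zscore", "robust"):
        raise ValueError("method must be 'zscore' or 'robust'")
    if len(values) < 2:
        raise ValueError("need at least 2 rows to standardize")
    X = values.astype(float)
    if method == "zscore":
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
    else:
        center = X.median(axis=0)
        scale = 1.4826 * (X - center).abs().median(axis=0)
    keep = scale > 1e-12
    dropped = list(scale.index[~keep])
    if not keep.any():
        raise ValueError("all feature columns are constant; nothing to standardize")
    rec = StandardizationRecord(
        method=method,
        center={c: float(center[c]) for c in scale.index[keep]},
        scale={c: float(scale[c]) for c in scale.index[keep]},
        dropped=dropped,
    )
    return apply_standardization(values, rec), rec


def apply_standardization(values: pd.DataFrame, record: StandardizationRecord) -> pd.DataFrame:
    cols = list(record.center)
    missing = [c for c in cols if c not in values.columns]
    if missing:
        raise ValueError(f"feature columns missing: {missing}")
    X = values[cols].astype(float)
    return (X - pd.Series(record.center)) / pd.Series(record.scale)
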