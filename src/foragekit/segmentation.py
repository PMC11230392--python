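"""Trajectory I/O, zone annotation, and round-trip excursion segmentation.

An *excursion* is one round trip from the home cage into the arena and
back: it spans from the first sample after the mouse leaves the home zone
to the last sample before it re-enters.  Tunnel samples count as neither
home nor arena; boundaries are defined by home-zone membership only.
Excursions shorter than ``min_duration_s`` or penetrating less than
``min_penetration_cm`` into the arena (distance from the tunnel exit) are
flagged rather than silently dropped, and excluded from downstream counts.
All intervals are half-open [t_start, t_end).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    ArenaGeometry,
    POT_LABELS,
    ZONE_CENTER,
    ZONE_HOME,
    ZONE_OOB,
    ZONE_PERIMETER,
    ZONE_TUNNEL,
)

TRAJ_COLUMNS = ("mouse_id", "phase", "t_s", "x_cm", "y_cm")
ARENA_ZONES = frozenset(POT_LABELS) | {ZONE_CENTER, ZONE_PERIMETER}


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


def load_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV, validate it, and sort by (mouse, phase, t)."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory file missing columns: {missing}")
    df = df[list(TRAJ_COLUMNS)].copy()
    for c in ("t_s", "x_cm", "y_cm"):
        df[c] = pd.to_numeric(df[c], errors="raise")
    if not np.isfinite(df[["t_s", "x_cm", "y_cm"]].to_numpy()).all():
        raise SchemaError("non-finite values in trajectory table")
    df = df.sort_values(["mouse_id", "phase", "t_s"], kind="mergesort",
                        ignore_index=True)
    for (mid, ph), g in df.groupby(["mouse_id", "phase"], sort=False):
        t = g["t_s"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise SchemaError(
                f"non-increasing time for mouse {mid}, phase {ph} at t={t[bad[0] + 1]}")
    return df


def annotate_zones(traj: pd.DataFrame, geometry: ArenaGeometry) -> pd.DataFrame:
    """Add a ``zone`` column (one primary label per sample) and QC counts.

    Idempotent: the zone is a pure function of position and geometry.
    Out-of-bounds samples are labelled rather than rejected; their count is
    available via :func:`qc_report`.
    """
    out = traj.copy()
    out["zone"] = geometry.annotate(out["x_cm"].to_numpy(), out["y_cm"].to_numpy())
    return out


def qc_report(annotated: pd.DataFrame) -> dict:
    n = len(annotated)
    oob = int((annotated["zone"] == ZONE_OOB).sum())
    return {"n_samples": n, "n_out_of_bounds": oob,
            "fraction_out_of_bounds": (oob / n) if n else 0.0}


def _segment_one(t: np.ndarray, x: np.ndarray, y: np.ndarray, zone: np.ndarray,
                 geometry: ArenaGeometry, min_duration_s: float,
                 min_penetration_cm: float, phase_end_s: float) -> list[dict]:
    """Segment a single (mouse, phase) series; vectorised run detection."""
    home = zone == ZONE_HOME
    if not home.any():
        raise ValueError("trajectory never enters the home zone; "
                         "cannot establish a home base")
    away = ~home
    # maximal runs of non-home samples
    d = np.diff(away.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0]  # inclusive end index of the run
    if away[0]:
        starts = np.concatenate([[0], starts])
    open_end = away[-1]
    ex, ey = geometry.entry_point
    out = []
    for k, s in enumerate(starts):
        if k < len(ends):
            e = ends[k]
            unterminated = False
        else:
            e = len(t) - 1
            unterminated = True
        t_start = float(t[s])
        # half-open [t_start, t_end): t_end = time of first home sample after run
        t_end = float(t[e + 1]) if e + 1 < len(t) else float(phase_end_s)
        in_arena = np.isin(zone[s:e + 1], list(ARENA_ZONES))
        if in_arena.any():
            dx = x[s:e + 1][in_arena] - ex
            dy = y[s:e + 1][in_arena] - ey
            penetration = float(np.sqrt(dx * dx + dy * dy).max())
        else:
            penetration = 0.0
        flags = []
        if unterminated or (s == 0):  # never returned / started outside home
            flags.append("unterminated")
        if t_end - t_start < min_duration_s:
            flags.append("too_short")
        if penetration < min_penetration_cm:
            flags.append("shallow")
        out.append({"t_start_s": t_start, "t_end_s": t_end,
                    "i_start": int(s), "i_end": int(e),
                    "max_penetration_cm": penetration,
                    "flags": ";".join(flags)})
    return out


def segment_excursions(annotated: pd.DataFrame, geometry: ArenaGeometry,
                       min_duration_s: float = 2.0,
                       min_penetration_cm: float = 5.0) -> pd.DataFrame:
    """Segment every (mouse, phase) series into round-trip excursions.

    Returns one row per excursion with 1-based ``index`` within its
    (mouse, phase), boundary times, global sample-span row positions
    (``i_start``..``i_end`` inclusive) into the sorted annotated table,
    penetration depth, a ``flags`` string
    (empty for valid excursions) and a ``valid`` boolean.
    """
    if "zone" not in annotated.columns:
        raise ValueError("trajectory must be zone-annotated first")
    rows = []
    for (mid, ph), g in annotated.groupby(["mouse_id", "phase"], sort=False):
        t = g["t_s"].to_numpy()
        phase_end = float(t[-1] + (t[-1] - t[-2] if len(t) > 1 else 0.0))
        segs = _segment_one(t, g["x_cm"].to_numpy(), g["y_cm"].to_numpy(),
                            g["zone"].to_numpy(), geometry,
                            min_duration_s, min_penetration_cm, phase_end)
        offset = int(g.index[0])  # groups are contiguous in the sorted table
        for j, seg in enumerate(segs, start=1):
            seg["i_start"] += offset
            seg["i_end"] += offset
            rows.append({"mouse_id": mid, "phase": ph, "index": j, **seg})
    cols = ["mouse_id", "phase", "index", "t_start_s", "t_end_s",
            "i_start", "i_end", "max_penetration_cm", "flags"]
    df = pd.DataFrame(rows, columns=cols)
    df["valid"] = df["flags"] == ""
    return df


def gross_latency_and_counts(excursions: pd.DataFrame, annotated: pd.DataFrame,
                             geometry: ArenaGeometry,
                             phase_duration_s: float = 1800.0) -> pd.DataFrame:
    """Per mouse-phase gross measures.

    number_of_excursions: valid excursions only.
    latency_to_enter_arena_s: t_start of the first valid excursion, or the
    phase duration if none.  distance_traveled_cm: polyline length of the
    whole phase.  relative_time_in_center: dt-weighted seconds in the
    center zone divided by seconds anywhere in the arena (0 if never).
    """
    rows = []
    exc_g = dict(tuple(excursions.groupby(["mouse_id", "phase"], sort=False)))
    for (mid, ph), g in annotated.groupby(["mouse_id", "phase"], sort=False):
        t = g["t_s"].to_numpy()
        x = g["x_cm"].to_numpy()
        y = g["y_cm"].to_numpy()
        zone = g["zone"].to_numpy()
        dist = float(np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2).sum())
        # dt weight of each sample = interval to next sample (last gets median dt)
        dt = np.diff(t)
        w = np.append(dt, np.median(dt) if dt.size else 0.0)
        in_arena = np.isin(zone, list(ARENA_ZONES))
        arena_s = float(w[in_arena].sum())
        center_s = float(w[zone == ZONE_CENTER].sum())
        exc = exc_g.get((mid, ph))
        valid = exc[exc["valid"]] if exc is not None else None
        n_exc = 0 if valid is None else int(len(valid))
        latency = (float(valid["t_start_s"].iloc[0])
                   if n_exc else float(phase_duration_s))
        rows.append({
            "mouse_id": mid, "phase": ph,
            "number_of_excursions": n_exc,
            "latency_to_enter_arena_s": latency,
            "distance_traveled_cm": dist,
            "relative_time_in_center": (center_s / arena_s) if arena_s > 0 else 0.0,
        })
    return pd.DataFrame(rows)


def write_excursions(path: str | Path, excursions: pd.DataFrame) -> None:
    excursions.to_csv(path, index=False, float_format="%.3f")


def write_qc(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=1), encoding="utf-8")
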