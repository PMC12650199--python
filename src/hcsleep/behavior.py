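"""Behavioral readouts: object-location discrimination index and zone-based
zero-maze summaries from labeled position tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class ExplorationTrial:
    animal_id: str
    group: str
    t_displaced_s: float
    t_stationary_s: float

    def __post_init__(self) -> None:
        if self.t_displaced_s < 0 or self.t_stationary_s < 0:
            raise ValidationError("exploration times must be >= 0")


def discrimination_index(t_displaced_s: float, t_stationary_s: float) -> float:
    """DI = (displaced - stationary) / total exploration * 100, in [-100, 100].

    Antisymmetric under swapping the two times; the bounds are attained
    only when one time is zero.
    """
    total = t_displaced_s + t_stationary_s
    if t_displaced_s < 0 or t_stationary_s < 0:
        raise ValidationError("exploration times must be >= 0")
    if total <= 0:
        raise ValidationError("DI undefined: both exploration times are zero")
    return (t_displaced_s - t_stationary_s) / total * 100.0


def zone_summary(track: pd.DataFrame) -> dict[str, float]:
    """Open-arm time and per-zone path lengths from a labeled track.

    ``track`` columns: t_s, x_cm, y_cm, zone (OPEN | CLOSED), with t_s
    strictly increasing.  Each inter-sample interval (time and Euclidean
    step) is attributed to the zone of its starting sample, so
    zone-crossing steps deterministically belong to the zone being left.
    """
    for col in ("t_s", "x_cm", "y_cm", "zone"):
        if col not in track.columns:
            raise ValidationError(f"track missing column {col!r}")
    if len(track) < 2:
        raise ValidationError("track needs at least 2 samples")
    t = track["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("track time must be strictly increasing")
    x = track["x_cm"].to_numpy(dtype=float)
    y = track["y_cm"].to_numpy(dtype=float)
    zone = track["zone"].to_numpy()
    bad = set(zone) - {"OPEN", "CLOSED"}
    if bad:
        raise ValidationError(f"unknown zone labels: {sorted(bad)}")
    dt = np.diff(t)
    step = np.hypot(np.diff(x), np.diff(y))
    start_zone = zone[:-1]
    is_open = start_zone == "OPEN"
    return {
        "open_time_s": float(dt[is_open].sum()),
        "closed_time_s": float(dt[~is_open].sum()),
        "open_distance_cm": float(step[is_open].sum()),
        "closed_distance_cm": float(step[~is_open].sum()),
    }


def group_table(
    trials: pd.DataFrame | list[ExplorationTrial],
) -> pd.DataFrame:
    """Tidy per-animal DI table; one row per animal, group labels preserved."""
    if isinstance(trials, list):
        df = pd.DataFrame(
            {
                "animal_id": [t.animal_id for t in trials],
                "group": [t.group for t in trials],
                "t_displaced_s": [t.t_displaced_s for t in trials],
                "t_stationary_s": [t.t_stationary_s for t in trials],
            }
        )
    else:
        df = trials.copy()
    for col in ("animal_id", "group", "t_displaced_s", "t_stationary_s"):
        if col not in df.columns:
            raise ValidationError(f"trial table missing column {col!r}")
    dup = df.duplicated(subset=["group", "animal_id"])
    if dup.any():
        raise ValidationError(
            f"duplicate animal_id within group: "
            f"{df.loc[dup, 'animal_id'].tolist()}"
        )
    df["di"] = [
        discrimination_index(d, s)
        for d, s in zip(df["t_displaced_s"], df["t_stationary_s"])
    ]
    return df.reset_index(drop=True)
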