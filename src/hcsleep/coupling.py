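"""Cross-regional event coupling: D–S, R–D and R–D–S sequences.

A spindle is coupled to a delta wave when its peak follows the delta peak
by a lag in the (0.1, 1.3] s window; a delta is coupled to a ripple when
its peak follows the ripple peak by a lag in (0.05, 0.25] s.  An R–D–S
sequence is the conjunction of both through a shared delta wave.  Lag
windows are half-open: a lag exactly equal to the lower edge is NOT
coupled, one exactly equal to the upper edge IS.

Under GREEDY_ONE_TO_ONE pairing (default), leaders are scanned in time
order and each takes the earliest still-unassigned in-window follower, so
every event participates in at most one pair and a count reflects discrete
joint occurrences.  ALL_PAIRS returns every in-window combination and is
kept for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CouplingParams
from .core import EventKind, EventTable, Hypnogram, Stage
from .detection import restrict_to_sleep
from .errors import ValidationError


@dataclass
class CouplingResult:
    """Counts and per-minute rates of coupled sequences in one session window."""

    session_id: str
    phase: str  # PRE | POST
    counts: dict[str, int]
    sleep_minutes: float
    rates_per_min: dict[str, float]
    extras: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _check_sorted(table: EventTable, name: str) -> np.ndarray:
    peaks = table.peaks
    if len(peaks) > 1 and np.any(np.diff(peaks) < 0):
        raise ValidationError(f"{name} table not sorted by peak_s")
    return peaks


def pair_events(
    leaders: EventTable,
    followers: EventTable,
    window: tuple[float, float],
    pairing: str = "GREEDY_ONE_TO_ONE",
) -> list[tuple[int, int, float]]:
    """Pairs (leader_index, follower_index, lag_s) with lag in (lo, hi].

    Indices refer to row positions in the (peak-sorted) input tables.
    """
    lo, hi = window
    if not (0 < lo < hi):
        raise ValidationError(f"window ({lo}, {hi}) must satisfy 0 < lo < hi")
    lp = _check_sorted(leaders, "leader")
    fp = _check_sorted(followers, "follower")
    pairs: list[tuple[int, int, float]] = []
    if pairing == "ALL_PAIRS":
        for i, t in enumerate(lp):
            j0 = int(np.searchsorted(fp, t + lo, side="right"))
            j1 = int(np.searchsorted(fp, t + hi, side="right"))
            for j in range(j0, j1):
                pairs.append((i, j, float(fp[j] - t)))
        return pairs
    if pairing != "GREEDY_ONE_TO_ONE":
        raise ValidationError(f"unknown pairing mode {pairing!r}")
    used = np.zeros(len(fp), dtype=bool)
    for i, t in enumerate(lp):
        j0 = int(np.searchsorted(fp, t + lo, side="right"))
        j1 = int(np.searchsorted(fp, t + hi, side="right"))
        for j in range(j0, j1):
            if not used[j]:
                used[j] = True
                pairs.append((i, j, float(fp[j] - t)))
                break
    return pairs


def triple_sequences(
    ripples: EventTable,
    deltas: EventTable,
    spindles: EventTable,
    params: CouplingParams | None = None,
) -> list[tuple[int, int, int]]:
    """R–D–S triples: R–D pairs whose delta also leads a D–S pair.

    Both constituent pairings use the same mode; under GREEDY_ONE_TO_ONE
    each event therefore appears in at most one triple.
    """
    params = params or CouplingParams()
    rd = pair_events(ripples, deltas, params.rd_window_s, params.pairing)
    ds = pair_events(deltas, spindles, params.ds_window_s, params.pairing)
    ds_by_delta: dict[int, list[int]] = {}
    for d, s, _ in ds:
        ds_by_delta.setdefault(d, []).append(s)
    triples: list[tuple[int, int, int]] = []
    for r, d, _ in rd:
        for s in ds_by_delta.get(d, []):
            triples.append((r, d, s))
            if params.pairing == "GREEDY_ONE_TO_ONE":
                break
    return triples


def coupling_rates(
    events: EventTable,
    hypnogram: Hypnogram,
    params: CouplingParams | None = None,
    phase: str = "PRE",
    session_id: str | None = None,
) -> CouplingResult:
    """Count D–S, R–D and R–D–S sequences during sleep and normalize.

    Events are first restricted to the configured stages; rates are counts
    per minute of time in those stages.  ``extras`` additionally reports
    counts per minute of total recording and per leader event, since the
    normalization denominator of a joint occurrence rate is a reporting
    choice.
    """
    params = params or CouplingParams()
    stages = {Stage(s) for s in params.stages}
    minutes = hypnogram.minutes_in(stages)
    if minutes <= 0:
        raise ZeroDivisionError(
            f"no time in stages {[s.value for s in stages]}; cannot form rates"
        )
    inside = restrict_to_sleep(events, hypnogram, stages)
    ripples = inside.select(kind=EventKind.RIPPLE)
    deltas = inside.select(kind=EventKind.DELTA)
    spindles = inside.select(kind=EventKind.SPINDLE)

    ds = pair_events(deltas, spindles, params.ds_window_s, params.pairing)
    rd = pair_events(ripples, deltas, params.rd_window_s, params.pairing)
    rds = triple_sequences(ripples, deltas, spindles, params)

    counts = {"ds": len(ds), "rd": len(rd), "rds": len(rds)}
    rates = {k: v / minutes for k, v in counts.items()}
    total_minutes = hypnogram.duration_s / 60.0
    extras = {
        "rates_per_recording_min": {k: v / total_minutes for k, v in counts.items()},
        "per_leader": {
            "ds": counts["ds"] / len(deltas) if len(deltas) else float("nan"),
            "rd": counts["rd"] / len(ripples) if len(ripples) else float("nan"),
            "rds": counts["rds"] / len(ripples) if len(ripples) else float("nan"),
        },
        "event_counts": {
            "ripple": len(ripples),
            "delta": len(deltas),
            "spindle": len(spindles),
        },
    }
    sid = session_id or (
        str(inside.df["session_id"].iloc[0]) if len(inside) else "session"
    )
    return CouplingResult(
        session_id=sid,
        phase=phase,
        counts=counts,
        sleep_minutes=minutes,
        rates_per_min=rates,
        extras=extras,
        params={
            "ds_window_s": list(params.ds_window_s),
            "rd_window_s": list(params.rd_window_s),
            "pairing": params.pairing,
            "stages": [s.value for s in stages],
        },
    )


def compare_phases(
    pre: list[CouplingResult],
    post: list[CouplingResult],
    n_bootstrap: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Post-minus-pre rate change per sequence type across replicates.

    Replicates are paired by list position (one animal's pre and post
    windows).  Returns a tidy table with the per-replicate differences
    summarized as mean and a seeded bootstrap percentile CI; with a single
    replicate the CI is flagged undefined (NaN).
    """
    if not pre or not post:
        raise ValidationError("need at least one replicate per phase")
    if len(pre) != len(post):
        raise ValidationError("pre and post replicate lists must be paired")
    rng = np.random.default_rng(seed)
    rows = []
    alpha = (1.0 - ci) / 2.0
    for seq in ("ds", "rd", "rds"):
        diffs = np.array(
            [po.rates_per_min[seq] - pr.rates_per_min[seq] for pr, po in zip(pre, post)]
        )
        if len(diffs) > 1:
            idx = rng.integers(0, len(diffs), size=(n_bootstrap, len(diffs)))
            boot = diffs[idx].mean(axis=1)
            lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
        else:
            lo, hi = float("nan"), float("nan")
        rows.append(
            {
                "sequence": seq.upper(),
                "n": len(diffs),
                "mean_diff_per_min": float(diffs.mean()),
                "ci_lo": float(lo),
                "ci_hi": float(hi),
                "ci_level": ci,
            }
        )
    return pd.DataFrame(rows)
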