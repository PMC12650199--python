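"""Scoring detectors and pipelines against synthetic ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CouplingParams, DeltaParams, RippleParams, SimulationParams, SpindleParams
from .core import EventKind, EventTable, Region, SignalRecord, Stage
from .coupling import CouplingResult, coupling_rates
from .detection import detect_delta, detect_ripples, detect_spindles, restrict_to_sleep
from .synthetic import SyntheticGroundTruth, sample_event_times, sample_state_sequence

#: peak-matching tolerance per event kind (seconds)
MATCH_TOL_S = {EventKind.RIPPLE: 0.015, EventKind.DELTA: 0.050, EventKind.SPINDLE: 0.050}


def match_counts(
    true_peaks: np.ndarray, detected_peaks: np.ndarray, tol_s: float
) -> int:
    """Greedy one-to-one matching: each truth event claims its nearest
    unclaimed detection within tolerance."""
    used: set[int] = set()
    tp = 0
    order = np.argsort(detected_peaks)
    det = np.asarray(detected_peaks)[order]
    for t in true_peaks:
        lo = np.searchsorted(det, t - tol_s)
        hi = np.searchsorted(det, t + tol_s, side="right")
        best, best_d = None, tol_s + 1e-12
        for j in range(lo, hi):
            if j not in used and abs(det[j] - t) <= best_d:
                best, best_d = j, abs(det[j] - t)
        if best is not None:
            used.add(best)
            tp += 1
    return tp


def detector_scores(
    record: SignalRecord,
    truth: SyntheticGroundTruth,
    ripple_params: RippleParams | None = None,
    delta_params: DeltaParams | None = None,
    spindle_params: SpindleParams | None = None,
) -> pd.DataFrame:
    """Per-kind true-positive / truth / detection counts for one session.

    Detections are restricted to NREM (where ground-truth events live)
    before matching.
    """
    hyp = truth.hypnogram
    ca1 = record.get(region=Region.CA1)
    mpfc = record.get(region=Region.MPFC)
    detected = {
        EventKind.RIPPLE: restrict_to_sleep(detect_ripples(ca1, ripple_params), hyp),
        EventKind.DELTA: restrict_to_sleep(detect_delta(mpfc, delta_params), hyp),
        EventKind.SPINDLE: restrict_to_sleep(detect_spindles(mpfc, spindle_params), hyp),
    }
    rows = []
    for kind, det in detected.items():
        true_peaks = truth.true_events.select(kind=kind).peaks
        tp = match_counts(true_peaks, det.peaks, MATCH_TOL_S[kind])
        rows.append(
            {
                "kind": kind.value,
                "tp": tp,
                "n_true": len(true_peaks),
                "n_detected": len(det),
            }
        )
    return pd.DataFrame(rows)


def pooled_scores(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Micro-averaged recall/precision over a set of sessions."""
    total = pd.concat(frames).groupby("kind", sort=False).sum().reset_index()
    total["recall"] = total["tp"] / total["n_true"]
    total["precision"] = total["tp"] / total["n_detected"]
    return total


def simulate_coupling_cohort(
    n_animals: int,
    pre_prob_ds: float,
    post_prob_ds: float,
    seed: int,
    duration_s: float = 1800.0,
) -> tuple[list[CouplingResult], list[CouplingResult]]:
    """Event-level pre/post coupling cohort (no LFP synthesis).

    Each animal gets its own state sequence and ground-truth event tables
    for both phases; coupling rates use the GREEDY pairing on NREM time.
    """
    pre, post = [], []
    params = CouplingParams()
    for a in range(n_animals):
        for phase, prob, bucket in (
            ("PRE", pre_prob_ds, pre),
            ("POST", post_prob_ds, post),
        ):
            s = (seed * 1000 + a * 10 + (0 if phase == "PRE" else 1)) % (2**31)
            sim = SimulationParams(
                duration_s=duration_s, seed=s, coupling_prob_ds=prob
            )
            hyp = sample_state_sequence(sim, s)
            events = sample_event_times(sim, hyp, s, session_id=f"animal{a}")
            bucket.append(
                coupling_rates(events, hyp, params, phase=phase,
                               session_id=f"animal{a}")
            )
    return pre, post
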