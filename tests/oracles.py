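"""Independent brute-force references used to cross-check the fast paths.

These deliberately use naive per-sample / per-pair loops over the documented
definitions, so they stay independent of the vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def scan_threshold_events(
    z: np.ndarray,
    fs: float,
    boundary: float,
    peak: float,
    min_dur_ms: float,
    max_dur_ms: float,
    min_inclusive: bool,
) -> list[tuple[float, float, float, float]]:
    """Sample-by-sample scan for envelope threshold events.

    Returns (start_s, peak_s, end_s, peak_z) per kept run; runs touching
    either end of the trace are ignored (no crossing on one side).
    """
    events = []
    n = len(z)
    i = 0
    while i < n:
        if z[i] >= boundary:
            j = i
            while j + 1 < n and z[j + 1] >= boundary:
                j += 1
            if i > 0 and j < n - 1:
                dur_ms = (j + 1 - i) / fs * 1000.0
                ok_min = dur_ms >= min_dur_ms if min_inclusive else dur_ms > min_dur_ms
                if ok_min and dur_ms <= max_dur_ms:
                    best = i
                    for k in range(i, j + 1):
                        if z[k] > z[best]:
                            best = k
                    if z[best] >= peak:
                        events.append(
                            (i / fs, (best + 0.5) / fs, (j + 1) / fs, float(z[best]))
                        )
            i = j + 1
        else:
            i += 1
    return events


def scan_halfwave_events(
    z: np.ndarray,
    fs: float,
    threshold: float,
    min_dur_ms: float,
    max_dur_ms: float,
    polarity: str = "BOTH",
) -> list[tuple[float, float, float, float]]:
    """Zero-crossing-delimited half-waves with |extremum| strictly above
    threshold and duration inside the bounds (inclusive)."""
    events = []
    n = len(z)
    for sign in (1, -1):
        if polarity == "POS" and sign < 0:
            continue
        if polarity == "NEG" and sign > 0:
            continue
        i = 0
        while i < n:
            if sign * z[i] > 0:
                j = i
                while j + 1 < n and sign * z[j + 1] > 0:
                    j += 1
                if i > 0 and j < n - 1:
                    dur_ms = (j + 1 - i) / fs * 1000.0
                    if min_dur_ms <= dur_ms <= max_dur_ms:
                        best = i
                        for k in range(i, j + 1):
                            if sign * z[k] > sign * z[best]:
                                best = k
                        if sign * z[best] > threshold:
                            events.append(
                                (i / fs, (best + 0.5) / fs, (j + 1) / fs,
                                 float(abs(z[best])))
                            )
                i = j + 1
            else:
                i += 1
    events.sort(key=lambda e: e[1])
    return events


def enumerate_pairs(
    leader_peaks: np.ndarray,
    follower_peaks: np.ndarray,
    lo: float,
    hi: float,
    pairing: str,
) -> list[tuple[int, int]]:
    """Exhaustive pair enumeration with (lo, hi] lag windows."""
    if pairing == "ALL_PAIRS":
        return [
            (i, j)
            for i in range(len(leader_peaks))
            for j in range(len(follower_peaks))
            if lo < follower_peaks[j] - leader_peaks[i] <= hi
        ]
    pairs = []
    used = set()
    order = np.argsort(leader_peaks, kind="stable")
    for i in order:
        candidates = [
            j
            for j in range(len(follower_peaks))
            if j not in used and lo < follower_peaks[j] - leader_peaks[i] <= hi
        ]
        if candidates:
            j = min(candidates, key=lambda j: follower_peaks[j])
            used.add(j)
            pairs.append((int(i), j))
    return pairs


def match_events(
    true_peaks: np.ndarray, detected_peaks: np.ndarray, tol_s: float
) -> int:
    """Greedy one-to-one matching count between truth and detections."""
    used: set[int] = set()
    tp = 0
    for t in true_peaks:
        best, best_d = None, tol_s
        for j, d in enumerate(detected_peaks):
            if j in used:
                continue
            if abs(d - t) <= best_d:
                best, best_d = j, abs(d - t)
        if best is not None:
            used.add(best)
            tp += 1
    return tp
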