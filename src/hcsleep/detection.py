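"""Oscillatory event detectors: hippocampal ripples, cortical delta waves
and sleep spindles.

All three follow the filter → envelope → z-score → threshold/duration scheme
common to rodent LFP work.  Normalization statistics (mean and SD) are taken
over *all* samples of the transformed trace, so amplitudes are expressed in
SD units of the whole recording.  Filtering is zero-phase, which keeps event
peak times unbiased for downstream coupling-lag analysis.

Sample ``i`` covers the time interval ``[i/fs, (i+1)/fs)``; run boundaries
are reported at the enclosing sample edges and peaks at sample centers, so a
peak is always strictly interior to its event.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .config import DeltaParams, RippleParams, SpindleParams
from .core import (
    ChannelTrace,
    EventKind,
    EventTable,
    Hypnogram,
    Region,
    Stage,
)
from .errors import DegenerateInputError, EmptyStageError, ValidationError


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValidationError(
            f"band ({lo}, {hi}) Hz must lie strictly inside (0, {nyq}) Hz"
        )
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_zero_phase(
    trace: ChannelTrace, band: tuple[float, float], order: int = 4
) -> ChannelTrace:
    """Zero-phase Butterworth bandpass (forward-backward filtering)."""
    sos = _bandpass_sos(band, trace.sampling_rate_hz, order)
    out = signal.sosfiltfilt(sos, trace.samples)
    return ChannelTrace(
        name=trace.name,
        modality=trace.modality,
        region=trace.region,
        sampling_rate_hz=trace.sampling_rate_hz,
        samples=out,
    )


def _zscore_all(x: np.ndarray) -> np.ndarray:
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateInputError("transformed trace has zero variance")
    return (x - float(np.mean(x))) / sd


def _raw_envelope(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    method: str,
    smoothing: float,
    order: int = 4,
) -> np.ndarray:
    """Un-normalized envelope: bandpass, square, then smooth."""
    sos = _bandpass_sos(band, fs, order)
    filt = signal.sosfiltfilt(sos, x)
    sq = filt * filt
    if method == "lowpass":
        lp = signal.butter(4, smoothing, btype="lowpass", fs=fs, output="sos")
        env = signal.sosfiltfilt(lp, sq)
    elif method == "gaussian":
        sigma_samples = smoothing * fs  # smoothing given in seconds
        env = ndimage.gaussian_filter1d(sq, sigma_samples)
    else:
        raise ValidationError(f"unknown envelope method {method!r}")
    return env


def normalized_envelope(
    trace: ChannelTrace,
    band: tuple[float, float],
    method: str = "lowpass",
    smoothing: float = 20.0,
) -> np.ndarray:
    """Z-scored squared-and-smoothed envelope, same length as the input.

    ``method='lowpass'`` (ripples) smooths the squared signal with a
    Butterworth lowpass at ``smoothing`` Hz; ``method='gaussian'``
    (spindles) uses a Gaussian kernel with sigma ``smoothing`` seconds.
    Normalization uses mean and SD over all samples.
    """
    env = _raw_envelope(
        trace.samples, trace.sampling_rate_hz, band, method, smoothing
    )
    return _zscore_all(env)


def _threshold_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) sample indices, edges excluded.

    Runs touching the first or last sample have no threshold crossing on
    one side and are discarded.
    """
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    runs = []
    n = len(above)
    for s, e in zip(starts, ends):
        if s == 0 or e == n - 1:
            continue
        runs.append((int(s), int(e)))
    return runs


def _runs_to_events(
    runs: list[tuple[int, int]],
    z: np.ndarray,
    fs: float,
    kind: EventKind,
    region: Region,
    peak_min: float,
    dur_bounds_ms: tuple[float, float],
    min_inclusive: bool,
    session_id: str,
    peak_time: str = "ARGMAX",
) -> pd.DataFrame:
    rows = []
    lo_ms, hi_ms = dur_bounds_ms
    eps = 1e-9
    for s, e in runs:
        dur_ms = (e + 1 - s) / fs * 1000.0
        if min_inclusive:
            if dur_ms < lo_ms - eps:
                continue
        else:
            if dur_ms <= lo_ms + eps:
                continue
        if dur_ms > hi_ms + eps:
            continue
        seg = z[s : e + 1]
        ip = s + int(np.argmax(seg))
        if seg.max() < peak_min:
            continue
        if peak_time == "MIDPOINT":
            peak_s = (s + e + 1) / 2.0 / fs
        else:
            peak_s = (ip + 0.5) / fs
        rows.append(
            {
                "session_id": session_id,
                "region": region.value,
                "kind": kind.value,
                "start_s": s / fs,
                "peak_s": peak_s,
                "end_s": (e + 1) / fs,
                "peak_z": float(z[ip]),
            }
        )
    return pd.DataFrame(rows)


def detect_ripples(
    lfp: ChannelTrace, params: RippleParams | None = None
) -> EventTable:
    """Detect 100–250 Hz sharp-wave ripples on a hippocampal LFP trace.

    A candidate is a maximal run where the normalized envelope stays at or
    above the boundary threshold; it is kept if its envelope maximum
    reaches the peak threshold and its duration lies within the configured
    bounds (boundaries inclusive).
    """
    params = params or RippleParams()
    if lfp.sampling_rate_hz < 2 * params.band[1]:
        raise ValidationError(
            f"sampling rate {lfp.sampling_rate_hz} Hz too low for "
            f"{params.band[1]} Hz ripple band"
        )
    z = normalized_envelope(
        lfp, params.band, method="lowpass", smoothing=params.envelope_lowpass_hz
    )
    runs = _threshold_runs(z >= params.boundary_threshold_sd)
    df = _runs_to_events(
        runs,
        z,
        lfp.sampling_rate_hz,
        EventKind.RIPPLE,
        lfp.region,
        params.peak_threshold_sd,
        (params.min_dur_ms, params.max_dur_ms),
        True,
        "session",
    )
    return EventTable(df, provenance={"ripple": params.__dict__.copy()})


def detect_delta(
    lfp: ChannelTrace, params: DeltaParams | None = None
) -> EventTable:
    """Detect delta waves as zero-crossing-delimited half-waves.

    The trace is bandpass filtered (0.1–5 Hz by default) and z-scored over
    all points; each half-wave (maximal same-sign run of the filtered
    trace, polarity per config) is kept if its extremum exceeds the
    threshold in absolute value and its duration lies within the bounds
    (inclusive).
    """
    params = params or DeltaParams()
    sos = _bandpass_sos(params.band, lfp.sampling_rate_hz, order=2)
    filt = signal.sosfiltfilt(sos, lfp.samples)
    z = _zscore_all(filt)
    fs = lfp.sampling_rate_hz
    rows = []
    eps = 1e-9
    for sign_wanted in (1, -1):
        if params.polarity == "POS" and sign_wanted < 0:
            continue
        if params.polarity == "NEG" and sign_wanted > 0:
            continue
        runs = _threshold_runs(sign_wanted * z > 0)
        for s, e in runs:
            dur_ms = (e + 1 - s) / fs * 1000.0
            if dur_ms < params.min_dur_ms - eps or dur_ms > params.max_dur_ms + eps:
                continue
            seg = sign_wanted * z[s : e + 1]
            ip = s + int(np.argmax(seg))
            if seg.max() <= params.peak_threshold_sd:
                continue
            rows.append(
                {
                    "session_id": "session",
                    "region": lfp.region.value,
                    "kind": EventKind.DELTA.value,
                    "start_s": s / fs,
                    "peak_s": (ip + 0.5) / fs,
                    "end_s": (e + 1) / fs,
                    "peak_z": float(abs(z[ip])),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("peak_s").reset_index(drop=True)
    return EventTable(df, provenance={"delta": params.__dict__.copy()})


def detect_spindles(
    lfp: ChannelTrace, params: SpindleParams | None = None
) -> EventTable:
    """Detect sleep spindles (9–17 Hz) on a cortical LFP trace.

    A candidate is a maximal run of the smoothed normalized envelope at or
    above the sustain threshold; it is kept if it lasts strictly more than
    ``min_dur_ms``, at most the max-duration cap, and its envelope maximum
    reaches the peak threshold.
    """
    params = params or SpindleParams()
    z = normalized_envelope(
        lfp,
        params.band,
        method="gaussian",
        smoothing=params.smoothing_ms / 1000.0,
    )
    runs = _threshold_runs(z >= params.sustain_threshold_sd)
    df = _runs_to_events(
        runs,
        z,
        lfp.sampling_rate_hz,
        EventKind.SPINDLE,
        lfp.region,
        params.peak_threshold_sd,
        (params.min_dur_ms, params.max_dur_ms),
        False,
        "session",
        peak_time=params.peak_time,
    )
    return EventTable(df, provenance={"spindle": params.__dict__.copy()})


def restrict_to_sleep(
    events: EventTable,
    hypnogram: Hypnogram,
    stages: set[Stage | str] | None = None,
) -> EventTable:
    """Keep events whose peak falls in an epoch of the given stage set."""
    stages = {Stage(s) for s in (stages or {Stage.NREM})}
    if not len(events):
        return events
    peaks = events.peaks
    if peaks.min() < hypnogram.start_s or peaks.max() >= hypnogram.end_s:
        raise ValidationError("event peak outside hypnogram span")
    keep = np.array(
        [hypnogram.stage_at(t) in stages for t in peaks], dtype=bool
    )
    return EventTable(
        events.df[keep].reset_index(drop=True), provenance=events.provenance
    )


def event_rates(
    events: EventTable,
    hypnogram: Hypnogram,
    stages: set[Stage | str] | None = None,
) -> pd.DataFrame:
    """Per-kind incidence (events/min of stage time), mean normalized
    amplitude (SD units) and density (fraction of all events in the
    restricted set).  Empty kinds get incidence 0 and NaN amplitude.
    """
    stages = {Stage(s) for s in (stages or {Stage.NREM})}
    minutes = hypnogram.minutes_in(stages)
    if minutes <= 0:
        raise ZeroDivisionError(
            f"no time in stages {[s.value for s in stages]}; "
            "cannot normalize incidence"
        )
    inside = restrict_to_sleep(events, hypnogram, stages)
    total = len(inside)
    rows = []
    for kind in EventKind:
        sub = inside.select(kind=kind)
        n = len(sub)
        rows.append(
            {
                "kind": kind.value,
                "count": n,
                "incidence_per_min": n / minutes,
                "mean_peak_z": float(sub.df["peak_z"].mean()) if n else float("nan"),
                "density_fraction": (n / total) if total else float("nan"),
                "minutes": minutes,
            }
        )
    return pd.DataFrame(rows)
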