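"""Synthetic EEG/EMG/LFP sessions with known sleep states and embedded,
optionally coupled ripple/delta/spindle events.

The generator provides ground truth for every downstream stage:

* a semi-Markov WAKE/NREM/REM bout sequence (exponential bout durations,
  REM entered only from NREM),
* 1/f^alpha background with stage-dependent rhythms — NREM boosts 0.5–4 Hz
  power (three times the wake delta amplitude), REM adds 6–9 Hz theta, and
  EMG tone is high awake, low in NREM, minimal in REM (muscle atonia) —
  cross-faded over 0.5 s at stage boundaries,
* ripple (Gaussian-windowed 150 Hz bursts, CA1), delta (half-sine
  deflections, mPFC) and spindle (waxing-waning 12 Hz bursts, mPFC) events
  placed in NREM, with ripple→delta and delta→spindle children scheduled at
  lags drawn inside the coupling-analysis windows.

Event amplitudes are specified in SD units of the corresponding detector
envelope and calibrated in two passes against the actual background, so
detector tests are self-calibrating.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .config import DeltaParams, RippleParams, SimulationParams, SpindleParams
from .core import (
    ChannelTrace,
    EventKind,
    EventTable,
    Hypnogram,
    Modality,
    Region,
    SignalRecord,
    Stage,
)
from .detection import _bandpass_sos, _raw_envelope
from .errors import PlacementError, ValidationError

RIPPLE_CARRIER_HZ = 150.0
SPINDLE_CARRIER_HZ = 12.0


@dataclass
class SyntheticGroundTruth:
    """True state sequence and true event table with coupling lineage."""

    hypnogram: Hypnogram
    true_events: EventTable


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-purpose generator derived from one session seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# state sequence


def sample_state_sequence(
    params: SimulationParams, seed: int | None = None
) -> Hypnogram:
    """Semi-Markov bout sequence discretized to fixed epochs.

    Bout durations are exponential with the configured per-stage means.
    Transitions: WAKE→NREM always; NREM→REM with ``rem_entry_prob`` else
    back to WAKE; REM→NREM with ``rem_to_nrem_prob`` else WAKE.  A direct
    WAKE→REM transition never occurs.  Each epoch takes the state active
    at its midpoint.
    """
    rng = _child_rng(params.seed if seed is None else seed, "states")
    means = {
        Stage.WAKE: params.bout_mean_wake_s,
        Stage.NREM: params.bout_mean_nrem_s,
        Stage.REM: params.bout_mean_rem_s,
    }
    n_epochs = int(np.floor(params.duration_s / params.epoch_length_s))
    if n_epochs < 1:
        raise ValidationError("duration shorter than one epoch")
    bounds: list[float] = [0.0]
    states: list[Stage] = [Stage.WAKE]
    t = float(rng.exponential(means[Stage.WAKE]))
    bounds.append(t)
    while t < params.duration_s:
        prev = states[-1]
        if prev is Stage.WAKE:
            nxt = Stage.NREM
        elif prev is Stage.NREM:
            nxt = Stage.REM if rng.random() < params.rem_entry_prob else Stage.WAKE
        else:  # REM
            nxt = Stage.NREM if rng.random() < params.rem_to_nrem_prob else Stage.WAKE
        states.append(nxt)
        t += float(rng.exponential(means[nxt]))
        bounds.append(t)
    bounds_arr = np.asarray(bounds)
    mids = (np.arange(n_epochs) + 0.5) * params.epoch_length_s
    idx = np.searchsorted(bounds_arr, mids, side="right") - 1
    stages = [states[i] for i in idx]
    return Hypnogram(stages=stages, epoch_length_s=params.epoch_length_s)


# ---------------------------------------------------------------------------
# background synthesis

# stage-dependent component amplitudes (arbitrary microvolt scales; the
# detectors z-normalize, so only the ratios matter).  The EEG channel
# carries the full staging rhythms; LFP backgrounds are only mildly
# stage-modulated because cortical delta-band power is supposed to come
# from the discrete injected delta waves, not from a continuous rhythm.
_DELTA_AMP_EEG = {Stage.WAKE: 8.0, Stage.NREM: 24.0, Stage.REM: 6.0}
_THETA_AMP_EEG = {Stage.WAKE: 6.0, Stage.NREM: 3.0, Stage.REM: 22.0}
_DELTA_AMP_LFP = {Stage.WAKE: 3.0, Stage.NREM: 4.0, Stage.REM: 2.5}
_THETA_AMP_LFP = {Stage.WAKE: 2.0, Stage.NREM: 1.5, Stage.REM: 6.0}
_EMG_SD = {Stage.WAKE: 30.0, Stage.NREM: 8.0, Stage.REM: 3.0}
_BROADBAND_UV = 12.0  # RMS of the 1/f background


def _powerlaw_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """1/f^alpha Gaussian noise with unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    # flatten below 0.1 Hz so the variance does not blow up at DC
    shaping[nz] = np.maximum(freqs[nz], 0.1) ** (-alpha / 2.0)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n=n)
    return out / np.std(out)


def _stage_gain(
    hypnogram: Hypnogram, amp: dict[Stage, float], n: int, fs: float, crossfade_s: float
) -> np.ndarray:
    per_epoch = np.array([amp[s] for s in hypnogram.stages])
    spe = hypnogram.epoch_length_s * fs
    idx = np.minimum((np.arange(n) / spe).astype(int), len(per_epoch) - 1)
    gain = per_epoch[idx]
    size = max(int(round(crossfade_s * fs)), 1)
    return ndimage.uniform_filter1d(gain, size=size, mode="nearest")


def _narrowband(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = _bandpass_sos(band, fs, order=2)
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


def synthesize_background(
    hypnogram: Hypnogram,
    name: str,
    modality: Modality | str,
    region: Region | str,
    rate_hz: float,
    params: SimulationParams,
    seed: int | None = None,
) -> ChannelTrace:
    """One background channel for the given hypnogram.

    EEG/LFP: 1/f^alpha noise plus stage-gated delta (0.5–4 Hz) and theta
    (6–9 Hz) components.  EMG: white noise with stage-dependent variance.
    Stage transitions are cross-faded over ``params.crossfade_s``.
    """
    modality = Modality(modality)
    rng = _child_rng(params.seed if seed is None else seed, f"bg:{name}")
    n = int(round(hypnogram.duration_s * rate_hz))
    if modality is Modality.EMG:
        sd = _stage_gain(hypnogram, _EMG_SD, n, rate_hz, params.crossfade_s)
        samples = sd * rng.standard_normal(n)
    else:
        base = _BROADBAND_UV * _powerlaw_noise(rng, n, rate_hz, params.spectral_exponent)
        delta = _narrowband(rng, n, rate_hz, (0.5, 4.0))
        theta = _narrowband(rng, n, rate_hz, (6.0, 9.0))
        d_amp = _DELTA_AMP_EEG if modality is Modality.EEG else _DELTA_AMP_LFP
        t_amp = _THETA_AMP_EEG if modality is Modality.EEG else _THETA_AMP_LFP
        g_delta = _stage_gain(hypnogram, d_amp, n, rate_hz, params.crossfade_s)
        g_theta = _stage_gain(hypnogram, t_amp, n, rate_hz, params.crossfade_s)
        samples = base + g_delta * delta + g_theta * theta
    return ChannelTrace(
        name=name,
        modality=modality,
        region=Region(region),
        sampling_rate_hz=rate_hz,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# event templates


def ripple_template(duration_s: float, fs: float) -> np.ndarray:
    """Unit-amplitude Gaussian-windowed ripple-band burst."""
    n = max(int(round(duration_s * fs)), 3)
    t = (np.arange(n) - (n - 1) / 2) / fs
    window = np.exp(-0.5 * (t / (duration_s / 4.0)) ** 2)
    return window * np.sin(2 * np.pi * RIPPLE_CARRIER_HZ * t)


def delta_template(duration_s: float, fs: float) -> np.ndarray:
    """Unit-amplitude biphasic delta deflection.

    A raised-cosine main lobe (``duration_s`` wide) flanked by small
    opposite-polarity lobes, mimicking the multiphasic shape of cortical
    slow waves.  The smooth edges keep spectral leakage out of the spindle
    band of the same trace, and the undershoots pin the zero crossings of
    the band-filtered trace to the main-lobe edges, so the detected
    half-wave duration tracks the nominal event duration.
    """
    n = max(int(round(duration_s * fs)), 3)
    # slow side lobes: their spectral content stays below the spindle band
    lobe = max(int(round(0.8 * duration_s * fs)), 2)
    side = -0.18 * np.hanning(lobe)
    tpl = np.concatenate([side, np.hanning(n), side])
    # final smoothing wipes any residual spindle-band (9-17 Hz) leakage so
    # a large delta wave cannot distort a nearby spindle's envelope
    return ndimage.gaussian_filter1d(tpl, max(0.025 * fs, 1.0))


def spindle_template(duration_s: float, fs: float) -> np.ndarray:
    """Unit-amplitude waxing-waning 12 Hz burst.

    The amplitude envelope is a sustained plateau (Tukey window) carrying
    a sharper central maximum, so the burst both stays above the sustain
    threshold for most of its nominal duration and has an unambiguous
    envelope peak at the event's center.
    """
    n = max(int(round(duration_s * fs)), 3)
    t = (np.arange(n) - (n - 1) / 2) / fs
    env = 0.65 * signal.windows.tukey(n, 0.5) + 0.35 * np.exp(
        -0.5 * (t / (duration_s / 16.0)) ** 2
    )
    env /= env.max()
    return env * np.sin(2 * np.pi * SPINDLE_CARRIER_HZ * t)


_TEMPLATES = {
    EventKind.RIPPLE: ripple_template,
    EventKind.DELTA: delta_template,
    EventKind.SPINDLE: spindle_template,
}


# ---------------------------------------------------------------------------
# event placement (times only)


def _nrem_windows(
    hypnogram: Hypnogram, stages: tuple[str, ...], margin_s: float
) -> list[tuple[float, float]]:
    wanted = [Stage(s) for s in stages]
    intervals: list[tuple[float, float]] = []
    for st in wanted:
        intervals.extend(hypnogram.intervals(st))
    out = []
    for lo, hi in sorted(intervals):
        if hi - lo > 2 * margin_s:
            out.append((lo + margin_s, hi - margin_s))
    return out


def _draw_time(
    rng: np.random.Generator, windows: list[tuple[float, float]], widths: np.ndarray
) -> float:
    cum = np.cumsum(widths)
    u = rng.random() * cum[-1]
    k = min(int(np.searchsorted(cum, u, side="right")), len(windows) - 1)
    lo, _ = windows[k]
    offset = u - (cum[k] - widths[k])
    return lo + offset


def _no_conflict(
    peak: float, half: float, gap: float, placed: list[tuple[float, float]]
) -> bool:
    for s, e in placed:
        if peak - half < e + gap and peak + half > s - gap:
            return False
    return True


def _in_windows(peak: float, half: float, windows: list[tuple[float, float]]) -> bool:
    return any(lo <= peak - half and peak + half <= hi for lo, hi in windows)


def sample_event_times(
    params: SimulationParams,
    hypnogram: Hypnogram,
    seed: int | None = None,
    session_id: str = "synthetic",
) -> EventTable:
    """Draw ground-truth event times (no waveforms) for a hypnogram.

    Ripples and uncoupled delta/spindle events arrive as Poisson processes
    at the configured per-NREM-minute densities; with ``coupling_prob_rd``
    each ripple additionally schedules a delta child at lag U[rd_lag], and
    with ``coupling_prob_ds`` each delta schedules a spindle child at lag
    U[ds_lag].  Same-kind events keep a refractory gap; children whose
    scheduled time falls outside NREM or would overlap are dropped.

    Returns an EventTable with extra columns ``event_id``,
    ``parent_event_id`` and ``injected_amplitude_sd``.
    """
    rng = _child_rng(params.seed if seed is None else seed, "events")
    spec = {
        EventKind.RIPPLE: (params.ripple_per_min, params.ripple_dur_s,
                           params.ripple_gap_s, params.ripple_amplitude_sd,
                           Region.CA1),
        EventKind.DELTA: (params.delta_per_min, params.delta_dur_s,
                          params.delta_gap_s, params.delta_amplitude_sd,
                          Region.MPFC),
        EventKind.SPINDLE: (params.spindle_per_min, params.spindle_dur_s,
                            params.spindle_gap_s, params.spindle_amplitude_sd,
                            Region.MPFC),
    }
    placed: dict[EventKind, list[tuple[float, float]]] = {k: [] for k in spec}
    rows: list[dict] = []
    counters = {k: 0 for k in spec}
    prefix = {EventKind.RIPPLE: "R", EventKind.DELTA: "D", EventKind.SPINDLE: "S"}

    def add_event(kind: EventKind, peak: float, parent: str) -> str | None:
        density, dur_rng, gap, amp, region = spec[kind]
        dur = float(rng.uniform(*dur_rng))
        half = dur / 2.0
        margin = half + 0.25
        windows = _nrem_windows(hypnogram, params.event_stages, margin)
        if not windows:
            return None
        if not _in_windows(peak, half, windows):
            return None
        if not _no_conflict(peak, half, gap, placed[kind]):
            return None
        placed[kind].append((peak - half, peak + half))
        counters[kind] += 1
        eid = f"{prefix[kind]}{counters[kind]:05d}"
        rows.append(
            {
                "session_id": session_id,
                "region": region.value,
                "kind": kind.value,
                "start_s": peak - half,
                "peak_s": peak,
                "end_s": peak + half,
                "peak_z": amp,
                "event_id": eid,
                "parent_event_id": parent,
                "injected_amplitude_sd": amp,
            }
        )
        return eid

    def place_poisson(kind: EventKind) -> list[str]:
        density, dur_rng, gap, amp, region = spec[kind]
        margin = dur_rng[1] / 2.0 + 0.25
        windows = _nrem_windows(hypnogram, params.event_stages, margin)
        ids: list[str] = []
        if not windows or density <= 0:
            return ids
        widths = np.array([hi - lo for lo, hi in windows])
        minutes = widths.sum() / 60.0
        n_target = rng.poisson(density * minutes)
        attempts = 0
        n_done = 0
        while n_done < n_target:
            attempts += 1
            if attempts > 200 * max(n_target, 1):
                raise PlacementError(
                    f"cannot place {n_target} {kind.value} events without "
                    f"overlap (placed {n_done})"
                )
            peak = _draw_time(rng, windows, widths)
            eid = add_event(kind, peak, "")
            if eid is not None:
                ids.append(eid)
                n_done += 1
        return ids

    ripple_ids = place_poisson(EventKind.RIPPLE)

    # coupled deltas: children of ripples
    delta_ids: list[str] = []
    ripple_rows = {r["event_id"]: r for r in rows if r["kind"] == "RIPPLE"}
    for rid in ripple_ids:
        if rng.random() < params.coupling_prob_rd:
            for _ in range(10):  # retry lags that collide
                lag = float(rng.uniform(*params.rd_lag_s))
                eid = add_event(
                    EventKind.DELTA, ripple_rows[rid]["peak_s"] + lag, rid
                )
                if eid is not None:
                    delta_ids.append(eid)
                    break
    delta_ids.extend(place_poisson(EventKind.DELTA))

    # coupled spindles: children of deltas
    delta_rows = {r["event_id"]: r for r in rows if r["kind"] == "DELTA"}
    for did in delta_ids:
        if rng.random() < params.coupling_prob_ds:
            for _ in range(10):
                lag = float(rng.uniform(*params.ds_lag_s))
                eid = add_event(
                    EventKind.SPINDLE, delta_rows[did]["peak_s"] + lag, did
                )
                if eid is not None:
                    break
    place_poisson(EventKind.SPINDLE)

    df = pd.DataFrame(
        rows,
        columns=[
            "session_id", "region", "kind", "start_s", "peak_s", "end_s",
            "peak_z", "event_id", "parent_event_id", "injected_amplitude_sd",
        ],
    )
    if len(df):
        df["duration_ms"] = (df["end_s"] - df["start_s"]) * 1000.0
    return EventTable(df)


# ---------------------------------------------------------------------------
# amplitude-calibrated injection


def _envelope_for_kind(kind: EventKind, x: np.ndarray, fs: float) -> np.ndarray:
    """Raw (un-normalized) detector-matched envelope transform."""
    if kind is EventKind.RIPPLE:
        p = RippleParams()
        return _raw_envelope(x, fs, p.band, "lowpass", p.envelope_lowpass_hz)
    if kind is EventKind.SPINDLE:
        p = SpindleParams()
        return _raw_envelope(x, fs, p.band, "gaussian", p.smoothing_ms / 1000.0)
    p = DeltaParams()
    sos = _bandpass_sos(p.band, fs, order=2)
    return signal.sosfiltfilt(sos, x)  # delta "envelope" is the filtered trace


def _template_gain(kind: EventKind, duration_s: float, fs: float) -> float:
    """Peak envelope response of a unit-amplitude template in isolation."""
    tpl = _TEMPLATES[kind](duration_s, fs)
    pad = int(round(4.0 * fs))
    x = np.zeros(2 * pad + tpl.size)
    x[pad : pad + tpl.size] = tpl
    env = _envelope_for_kind(kind, x, fs)
    return float(np.max(np.abs(env)))


def _add_events_to_trace(
    samples: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    amplitudes: dict[str, float],
) -> np.ndarray:
    out = samples.copy()
    n = out.size
    for _, ev in events.iterrows():
        kind = EventKind(ev["kind"])
        dur = ev["end_s"] - ev["start_s"]
        tpl = _TEMPLATES[kind](dur, fs) * amplitudes[ev["event_id"]]
        # templates are symmetric about the event peak (they may extend
        # past [start, end], e.g. biphasic delta side lobes)
        i0 = int(round(ev["peak_s"] * fs)) - tpl.size // 2
        j0 = max(i0, 0)
        j1 = min(i0 + tpl.size, n)
        if j0 >= j1:
            continue
        out[j0:j1] += tpl[j0 - i0 : j1 - i0]
    return out


def _measured_peak_z(
    z: np.ndarray, fs: float, peaks: np.ndarray, window_s: float
) -> np.ndarray:
    """Local maximum of a z-scored envelope around each peak time."""
    n = z.size
    out = np.empty(len(peaks))
    for k, t in enumerate(peaks):
        i0 = max(int((t - window_s) * fs), 0)
        i1 = min(int((t + window_s) * fs) + 1, n)
        out[k] = z[i0:i1].max()
    return out


def _calibrate_amplitudes(
    bg: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    kinds: tuple[EventKind, ...],
    max_iter: int = 6,
    rel_tol: float = 0.02,
) -> dict[str, float]:
    """Iterative amplitude calibration against the actual background.

    Injection inflates the normalization SD (the z-score is taken over the
    whole trace, events included), so the mapping from waveform amplitude
    to measured envelope SD is implicit.  Starting from amplitudes scaled
    to the background-only envelope statistics, each iteration injects the
    current amplitudes, measures the mean achieved peak z over all events
    of the kind, and applies a global multiplicative correction (linear for
    the delta half-wave criterion, square-root for the quadratic envelopes)
    until the achieved mean is within ``rel_tol`` of the target.
    """
    amplitudes: dict[str, float] = {}
    for kind in kinds:
        sub = events[events["kind"] == kind.value]
        if not len(sub):
            continue
        if amplitudes:
            # calibrate against the trace with previously calibrated kinds
            # already present (e.g. spindles see the injected delta waves)
            done = events[events["event_id"].isin(amplitudes)]
            bg_kind = _add_events_to_trace(bg, fs, done, amplitudes)
        else:
            bg_kind = bg
        quadratic = kind is not EventKind.DELTA
        window_s = 0.03 if kind is EventKind.RIPPLE else 0.15
        env_bg = _envelope_for_kind(kind, bg_kind, fs)
        mu = float(np.mean(env_bg)) if quadratic else 0.0
        sd = float(np.std(env_bg))
        gains = {
            eid: _template_gain(kind, dur, fs)
            for eid, dur in zip(sub["event_id"], sub["end_s"] - sub["start_s"])
        }
        target = float(sub["injected_amplitude_sd"].mean())
        amps = {}
        for _, ev in sub.iterrows():
            g = gains[ev["event_id"]]
            t = ev["injected_amplitude_sd"]
            amps[ev["event_id"]] = (
                float(np.sqrt(max(t * sd, 0.0) / g)) if quadratic else t * sd / g
            )
        peaks = sub["peak_s"].to_numpy(dtype=float)
        for _ in range(max_iter):
            injected = _add_events_to_trace(bg_kind, fs, sub, amps)
            env = _envelope_for_kind(kind, injected, fs)
            z = (env - np.mean(env)) / np.std(env)
            if not quadratic:
                z = np.abs(z)
            achieved = float(np.mean(_measured_peak_z(z, fs, peaks, window_s)))
            if achieved <= 0:
                factor = 2.0
            else:
                factor = target / achieved
            if abs(factor - 1.0) <= rel_tol:
                break
            if quadratic:
                factor = float(np.sqrt(factor))
            amps = {eid: a * factor for eid, a in amps.items()}
        amplitudes.update(amps)
    return amplitudes


def inject_events(
    record: SignalRecord,
    hypnogram: Hypnogram,
    params: SimulationParams,
    seed: int | None = None,
) -> tuple[SignalRecord, SyntheticGroundTruth]:
    """Embed calibrated ripple/delta/spindle waveforms into the LFP channels.

    Requires a CA1 LFP and an mPFC LFP channel in ``record``.  Returns a
    new SignalRecord plus ground truth with coupling lineage.
    """
    truth = sample_event_times(params, hypnogram, seed, record.session_id)
    ca1 = record.get(modality=Modality.LFP, region=Region.CA1)
    mpfc = record.get(modality=Modality.LFP, region=Region.MPFC)
    df = truth.df

    amps_ca1 = _calibrate_amplitudes(
        ca1.samples, ca1.sampling_rate_hz, df, (EventKind.RIPPLE,)
    )
    amps_mpfc = _calibrate_amplitudes(
        mpfc.samples, mpfc.sampling_rate_hz, df, (EventKind.DELTA, EventKind.SPINDLE)
    )

    new_channels = []
    for ch in record.channels:
        if ch is ca1:
            samples = _add_events_to_trace(
                ch.samples, ch.sampling_rate_hz, df[df["kind"] == "RIPPLE"], amps_ca1
            )
        elif ch is mpfc:
            samples = _add_events_to_trace(
                ch.samples,
                ch.sampling_rate_hz,
                df[df["kind"].isin(["DELTA", "SPINDLE"])],
                amps_mpfc,
            )
        else:
            samples = ch.samples
        new_channels.append(
            ChannelTrace(
                name=ch.name,
                modality=ch.modality,
                region=ch.region,
                sampling_rate_hz=ch.sampling_rate_hz,
                samples=samples,
            )
        )
    out = SignalRecord(
        channels=new_channels,
        session_id=record.session_id,
        start_offset=record.start_offset,
    )
    return out, SyntheticGroundTruth(hypnogram=hypnogram, true_events=truth)


# ---------------------------------------------------------------------------
# full session


DEFAULT_CHANNELS = (
    ("EEG_parietal", Modality.EEG, Region.PARIETAL, "eeg_rate_hz"),
    ("EMG_neck", Modality.EMG, Region.NECK, "emg_rate_hz"),
    ("LFP_CA1", Modality.LFP, Region.CA1, "lfp_rate_hz"),
    ("LFP_mPFC", Modality.LFP, Region.MPFC, "lfp_rate_hz"),
)


def generate_session(
    params: SimulationParams,
    seed: int | None = None,
    session_id: str = "synthetic",
) -> tuple[SignalRecord, SyntheticGroundTruth]:
    """Full synthetic session: states, background, injected events."""
    seed = params.seed if seed is None else seed
    hypnogram = sample_state_sequence(params, seed)
    channels = [
        synthesize_background(
            hypnogram, name, modality, region, getattr(params, rate_attr), params, seed
        )
        for name, modality, region, rate_attr in DEFAULT_CHANNELS
    ]
    record = SignalRecord(channels=channels, session_id=session_id)
    return inject_events(record, hypnogram, params, seed)


# ---------------------------------------------------------------------------
# behavior tables


def generate_behavior_table(
    group_specs: list[dict],
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic object-exploration table feeding the discrimination index.

    Each group spec: ``{"group": str, "n": int, "preference_multiplier":
    float, "mean_exploration_s": float (default 12), "shape": float
    (default 4)}``.  Exploration times are gamma distributed; the displaced
    object's mean is scaled by the preference multiplier, so multiplier 1
    yields expected DI 0 and multiplier > 1 a positive DI.
    """
    rng = _child_rng(seed, "behavior")
    rows = []
    idx = 0
    for spec in group_specs:
        n = int(spec["n"])
        if n < 1:
            raise ValidationError("group size must be >= 1")
        mult = float(spec.get("preference_multiplier", 1.0))
        mean = float(spec.get("mean_exploration_s", 12.0))
        shape = float(spec.get("shape", 4.0))
        for _ in range(n):
            idx += 1
            t_stat = float(rng.gamma(shape, mean / shape))
            t_disp = float(rng.gamma(shape, mean * mult / shape))
            rows.append(
                {
                    "animal_id": f"m{idx:04d}",
                    "group": spec["group"],
                    "t_displaced_s": t_disp,
                    "t_stationary_s": t_stat,
                }
            )
    return pd.DataFrame(rows)
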