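"""Epoch-based sleep staging from EEG/EMG, stage-relative power spectra and
sleep-architecture summaries.

Staging is deterministic and rule-based: an epoch with high EMG tone
(robust z above threshold) is WAKE; otherwise a dominant theta/delta ratio
marks REM and everything else is NREM.  A majority-vote smoother and a
"REM entered only from sleep" correction follow.  Power spectra are
computed per epoch of a stage (Welch, Hann window spanning the epoch),
averaged, and expressed relative to the total power of the same stage over
the analysis band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import SpectraParams, StagingParams
from .core import ChannelTrace, Hypnogram, Stage
from .errors import EmptyStageError, ValidationError


@dataclass
class StageSpectrum:
    """Average relative power spectrum of one sleep stage."""

    stage: Stage
    frequencies: np.ndarray
    relative_power: np.ndarray
    n_epochs: int

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        total = float(np.sum(self.relative_power))
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"relative power sums to {total}, not 1")


def _epoch_view(x: np.ndarray, samples_per_epoch: int) -> np.ndarray:
    n_epochs = x.size // samples_per_epoch
    return x[: n_epochs * samples_per_epoch].reshape(n_epochs, samples_per_epoch)


def _emg_tone_z(rms: np.ndarray) -> tuple[np.ndarray, bool]:
    """Robust EMG-tone score against the sleep baseline.

    Epoch RMS in rodent recordings is bimodal (atonia/low sleep tone vs
    high wake tone).  Centering on the 20th percentile anchors the score
    to the sleep mode regardless of how much of the recording is wake —
    a median center drifts into the wake mode whenever wake occupies more
    than half the epochs.  The scale is the MAD of the lower half.  The
    second return value reports whether the RMS distribution carries any
    wake/sleep contrast at all; if not, staging falls back to EEG rules.
    """
    base = float(np.percentile(rms, 20))
    lower = rms[rms <= np.median(rms)]
    scale = 1.4826 * float(np.median(np.abs(lower - base)))
    # floor the scale at 10% of the sleep baseline: epoch-RMS jitter within
    # a stage is a few percent, wake tone is several-fold higher
    scale = max(scale, 0.1 * base, 1e-12)
    spread = float(np.percentile(rms, 95)) - base
    bimodal = spread > 0.2 * base
    return (rms - base) / scale, bimodal


def _band_fraction(psd: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    sel = (freqs >= band[0]) & (freqs < band[1])
    return psd[:, sel].sum(axis=1)


def score_sleep(
    eeg: ChannelTrace,
    emg: ChannelTrace,
    params: StagingParams | None = None,
) -> Hypnogram:
    """Score WAKE/NREM/REM per epoch from one EEG and one EMG channel.

    Rule order per epoch: EMG robust-z above ``emg_wake_z`` → WAKE; else
    theta/delta power ratio above ``theta_delta_rem_ratio`` → REM; else
    NREM.  Stages are then majority-smoothed over ``smoothing_epochs`` and
    REM epochs directly preceded by WAKE are relabeled NREM (REM is entered
    only from sleep).
    """
    params = params or StagingParams()
    if abs(eeg.duration_s - emg.duration_s) > 1.0 / min(
        eeg.sampling_rate_hz, emg.sampling_rate_hz
    ):
        raise ValidationError("EEG and EMG must cover the same duration")
    spe_eeg = int(round(params.epoch_length_s * eeg.sampling_rate_hz))
    spe_emg = int(round(params.epoch_length_s * emg.sampling_rate_hz))
    n_epochs = min(eeg.n_samples // spe_eeg, emg.n_samples // spe_emg)
    if n_epochs < 1:
        raise ValidationError("recording shorter than one epoch")

    emg_epochs = _epoch_view(emg.samples, spe_emg)[:n_epochs]
    emg_rms = np.sqrt(np.mean(emg_epochs**2, axis=1))
    emg_z, emg_bimodal = _emg_tone_z(emg_rms)

    eeg_epochs = _epoch_view(eeg.samples, spe_eeg)[:n_epochs]
    freqs, psd = signal.welch(
        eeg_epochs,
        fs=eeg.sampling_rate_hz,
        window="hann",
        nperseg=spe_eeg,
        axis=1,
    )
    total = _band_fraction(psd, freqs, (0.5, 30.0))
    delta = _band_fraction(psd, freqs, params.delta_band)
    theta = _band_fraction(psd, freqs, params.theta_band)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.inf)
        delta_share = np.where(total > 0, delta / total, 0.0)

    if emg_bimodal:
        wake = emg_z > params.emg_wake_z
    else:
        # EMG tone carries no wake/sleep contrast (e.g. an all-sleep or
        # all-wake recording): a delta-dominated EEG means sleep, a flat
        # or desynchronized EEG means wake
        wake = delta_share <= 0.35
    stages = np.where(
        wake,
        Stage.WAKE.value,
        np.where(ratio > params.theta_delta_rem_ratio, Stage.REM.value, Stage.NREM.value),
    )

    # majority smoothing
    half = params.smoothing_epochs // 2
    smoothed = stages.copy()
    if half > 0 and n_epochs > 1:
        order = [Stage.WAKE.value, Stage.NREM.value, Stage.REM.value]
        for i in range(n_epochs):
            lo, hi = max(0, i - half), min(n_epochs, i + half + 1)
            window = stages[lo:hi]
            counts = [int(np.sum(window == s)) for s in order]
            best = max(counts)
            # ties keep the epoch's own label
            winners = [s for s, c in zip(order, counts) if c == best]
            if stages[i] not in winners:
                smoothed[i] = winners[0]

    # REM entered only from sleep: REM directly after WAKE becomes NREM
    for i in range(n_epochs):
        if smoothed[i] == Stage.REM.value and (
            i == 0 or smoothed[i - 1] == Stage.WAKE.value
        ):
            smoothed[i] = Stage.NREM.value

    return Hypnogram(
        stages=[Stage(s) for s in smoothed],
        epoch_length_s=params.epoch_length_s,
    )


def stage_spectrum(
    eeg: ChannelTrace,
    hypnogram: Hypnogram,
    stage: Stage | str,
    band: tuple[float, float] = (0.5, 30.0),
) -> StageSpectrum:
    """Welch spectrum averaged over all epochs of a stage, normalized so the
    relative power sums to 1 over the analysis band."""
    stage = Stage(stage)
    spe = int(round(hypnogram.epoch_length_s * eeg.sampling_rate_hz))
    epochs = _epoch_view(eeg.samples, spe)
    n = min(len(hypnogram.stages), epochs.shape[0])
    sel = [i for i in range(n) if hypnogram.stages[i] is stage]
    if not sel:
        raise EmptyStageError(f"no {stage.value} epochs in hypnogram")
    freqs, psd = signal.welch(
        epochs[sel], fs=eeg.sampling_rate_hz, window="hann", nperseg=spe, axis=1
    )
    mean_psd = psd.mean(axis=0)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    rel = mean_psd[keep] / mean_psd[keep].sum()
    return StageSpectrum(
        stage=stage,
        frequencies=freqs[keep],
        relative_power=rel,
        n_epochs=len(sel),
    )


def band_power(
    spectrum: StageSpectrum,
    bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Sum relative power over named bands (bin centers in [lo, hi))."""
    bands = bands or SpectraParams().named_bands
    f = spectrum.frequencies
    rows = []
    for name, (lo, hi) in bands.items():
        if lo < f[0] - 1e-9 or hi > f[-1] + (f[1] - f[0]) + 1e-9:
            raise ValidationError(
                f"band {name} ({lo}, {hi}) outside spectrum grid "
                f"[{f[0]}, {f[-1]}]"
            )
        sel = (f >= lo) & (f < hi)
        rows.append(
            {
                "band": name,
                "lo_hz": lo,
                "hi_hz": hi,
                "relative_power": float(spectrum.relative_power[sel].sum()),
            }
        )
    return pd.DataFrame(rows)


def architecture_summary(
    hypnogram: Hypnogram,
    light_dark_boundary_s: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-stage totals (optionally split light/dark) and hourly time course.

    Minutes are conserved: per full hour the three stages sum to 60, and
    the phase totals sum to the recording length exactly.
    """
    epoch_min = hypnogram.epoch_length_s / 60.0
    starts = hypnogram.start_s + np.arange(len(hypnogram)) * hypnogram.epoch_length_s
    labels = np.array([s.value for s in hypnogram.stages])

    def totals(mask: np.ndarray) -> dict[str, float]:
        return {
            st.value: float(np.sum(mask & (labels == st.value)) * epoch_min)
            for st in Stage
        }

    phase_rows = []
    if light_dark_boundary_s is None:
        phase_rows.append({"phase": "all", **totals(np.ones_like(starts, bool))})
    else:
        light = starts < light_dark_boundary_s
        phase_rows.append({"phase": "light", **totals(light)})
        phase_rows.append({"phase": "dark", **totals(~light)})
    phases = pd.DataFrame(phase_rows)

    hour = (starts // 3600).astype(int)
    hourly_rows = []
    for h in np.unique(hour):
        mask = hour == h
        hourly_rows.append({"hour": int(h), **totals(mask)})
    hourly = pd.DataFrame(hourly_rows)
    return {"phases": phases, "hourly": hourly}
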