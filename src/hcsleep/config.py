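"""Parameter blocks for staging, detection, coupling, spectra and simulation.

Every block is a plain dataclass that round-trips losslessly through
``to_dict`` / ``from_dict`` and hence through YAML or JSON config files.
Defaults follow the detection conventions of the rodent sleep literature:
ripples 100–250 Hz with a 3 SD envelope threshold and 30–100 ms duration,
delta waves 0.1–5 Hz half-waves of 150–500 ms exceeding 2 SD, spindles
9–17 Hz sustained above 2.5 SD for more than 500 ms and peaking above 5 SD.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

from .errors import ConfigError, ValidationError


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class StagingParams:
    epoch_length_s: float = 4.0
    emg_wake_z: float = 1.0
    theta_delta_rem_ratio: float = 1.5
    delta_band: tuple[float, float] = (0.5, 4.0)
    theta_band: tuple[float, float] = (6.0, 9.0)
    smoothing_epochs: int = 3

    def __post_init__(self) -> None:
        _check(self.epoch_length_s > 0, "epoch_length_s must be > 0")
        for lo, hi in (self.delta_band, self.theta_band):
            _check(0 < lo < hi, f"band ({lo}, {hi}) must satisfy 0 < lo < hi")
        _check(
            self.smoothing_epochs >= 1 and self.smoothing_epochs % 2 == 1,
            "smoothing_epochs must be odd and >= 1",
        )


@dataclass
class SpectraParams:
    band: tuple[float, float] = (0.5, 30.0)
    named_bands: dict = field(
        default_factory=lambda: {
            "delta": (0.5, 4.0),
            "theta": (6.0, 9.0),
            "alpha": (9.0, 12.0),
            "beta": (12.0, 30.0),
        }
    )


@dataclass
class RippleParams:
    band: tuple[float, float] = (100.0, 250.0)
    peak_threshold_sd: float = 3.0
    boundary_threshold_sd: float = 3.0
    min_dur_ms: float = 30.0
    max_dur_ms: float = 100.0
    # 25 Hz keeps measured run durations faithful near the 30 ms floor; a
    # lower corner smears even a 20 ms burst into a >=30 ms run
    envelope_lowpass_hz: float = 25.0


@dataclass
class DeltaParams:
    band: tuple[float, float] = (0.1, 5.0)
    peak_threshold_sd: float = 2.0
    min_dur_ms: float = 150.0
    max_dur_ms: float = 500.0
    polarity: str = "BOTH"  # POS | NEG | BOTH

    def __post_init__(self) -> None:
        _check(self.polarity in ("POS", "NEG", "BOTH"), "polarity must be POS/NEG/BOTH")


@dataclass
class SpindleParams:
    band: tuple[float, float] = (9.0, 17.0)
    sustain_threshold_sd: float = 2.5
    peak_threshold_sd: float = 5.0
    min_dur_ms: float = 500.0
    max_dur_ms: float = 3000.0
    smoothing_ms: float = 100.0
    # peak-time convention: the midpoint of the suprathreshold run is a
    # stable timing estimator for plateau-shaped spindle envelopes, whose
    # smoothed argmax wanders under background interference
    peak_time: str = "MIDPOINT"  # MIDPOINT | ARGMAX

    def __post_init__(self) -> None:
        _check(self.peak_time in ("MIDPOINT", "ARGMAX"), "peak_time must be MIDPOINT/ARGMAX")


@dataclass
class CouplingParams:
    """Lag windows are half-open (lo, hi] in seconds; lags measured peak to peak."""

    ds_window_s: tuple[float, float] = (0.100, 1.300)
    rd_window_s: tuple[float, float] = (0.050, 0.250)
    pairing: str = "GREEDY_ONE_TO_ONE"  # or ALL_PAIRS
    stages: tuple[str, ...] = ("NREM",)

    def __post_init__(self) -> None:
        for lo, hi in (self.ds_window_s, self.rd_window_s):
            _check(0 < lo < hi, f"window ({lo}, {hi}) must satisfy 0 < lo < hi")
        _check(
            self.pairing in ("GREEDY_ONE_TO_ONE", "ALL_PAIRS"),
            "pairing must be GREEDY_ONE_TO_ONE or ALL_PAIRS",
        )


@dataclass
class SimulationParams:
    """Study conditions for the synthetic session generator.

    Event densities are per minute of NREM; amplitude targets are in SD
    units of each detector's normalized envelope.  Coupled-event lags are
    drawn uniformly inside the coupling analysis windows: delta follows
    ripple by U[0.05, 0.25] s, spindle follows delta by U[0.2, 0.8] s.
    """

    duration_s: float = 7200.0
    epoch_length_s: float = 4.0
    eeg_rate_hz: float = 250.0
    emg_rate_hz: float = 250.0
    lfp_rate_hz: float = 1000.0
    # semi-Markov bout means (s)
    bout_mean_wake_s: float = 200.0
    bout_mean_nrem_s: float = 120.0
    bout_mean_rem_s: float = 60.0
    rem_entry_prob: float = 0.3  # P(NREM -> REM); WAKE -> REM forbidden
    rem_to_nrem_prob: float = 0.5  # P(REM -> NREM), else REM -> WAKE
    # event populations (per minute of NREM)
    ripple_per_min: float = 12.0
    delta_per_min: float = 40.0
    spindle_per_min: float = 1.5
    # envelope-SD amplitude targets
    ripple_amplitude_sd: float = 12.0
    delta_amplitude_sd: float = 4.5
    spindle_amplitude_sd: float = 12.0
    # event durations drawn uniformly within these bounds (s)
    ripple_dur_s: tuple[float, float] = (0.075, 0.095)
    delta_dur_s: tuple[float, float] = (0.250, 0.400)
    spindle_dur_s: tuple[float, float] = (0.700, 1.000)
    # refractory gap between same-kind events (s)
    ripple_gap_s: float = 0.200
    delta_gap_s: float = 0.300
    spindle_gap_s: float = 1.000
    # cross-region coupling; post-encoding values default to the pre values
    coupling_prob_rd: float = 0.20
    coupling_prob_ds: float = 0.05
    post_coupling_prob_rd: float | None = None
    post_coupling_prob_ds: float | None = None
    rd_lag_s: tuple[float, float] = (0.05, 0.25)
    ds_lag_s: tuple[float, float] = (0.20, 0.80)
    # background
    spectral_exponent: float = 1.0
    crossfade_s: float = 0.5
    seed: int = 0
    event_stages: tuple[str, ...] = ("NREM",)

    def __post_init__(self) -> None:
        _check(self.duration_s > 0, "duration_s must be > 0")
        _check(self.duration_s >= self.epoch_length_s, "duration shorter than one epoch")
        for p in (
            self.coupling_prob_rd,
            self.coupling_prob_ds,
            self.rem_entry_prob,
            self.rem_to_nrem_prob,
        ):
            _check(0.0 <= p <= 1.0, f"probability {p} outside [0, 1]")
        for d in (self.ripple_per_min, self.delta_per_min, self.spindle_per_min):
            _check(d >= 0, "event densities must be >= 0")
        for m in (self.bout_mean_wake_s, self.bout_mean_nrem_s, self.bout_mean_rem_s):
            _check(m > 0, "bout means must be > 0")
        for lo, hi in (self.rd_lag_s, self.ds_lag_s, self.ripple_dur_s,
                       self.delta_dur_s, self.spindle_dur_s):
            _check(0 < lo <= hi, f"interval ({lo}, {hi}) must satisfy 0 < lo <= hi")


@dataclass
class PipelineConfig:
    """Full configuration for an end-to-end run."""

    staging: StagingParams = field(default_factory=StagingParams)
    spectra: SpectraParams = field(default_factory=SpectraParams)
    ripple: RippleParams = field(default_factory=RippleParams)
    delta: DeltaParams = field(default_factory=DeltaParams)
    spindle: SpindleParams = field(default_factory=SpindleParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    seed: int = 0


_LIST_TO_TUPLE_FIELDS = {"band", "delta_band", "theta_band", "ds_window_s",
                         "rd_window_s", "stages", "event_stages", "rd_lag_s",
                         "ds_lag_s", "ripple_dur_s", "delta_dur_s",
                         "spindle_dur_s"}


def _block_to_dict(obj) -> dict:
    out = {}
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, dict):
            v = {k: list(t) if isinstance(t, tuple) else t for k, t in v.items()}
        out[f.name] = v
    return out


def _block_from_dict(cls, d: dict):
    kwargs = {}
    valid = {f.name for f in fields(cls)}
    for k, v in d.items():
        if k not in valid:
            raise ConfigError(f"{cls.__name__}: unknown field {k!r}")
        if isinstance(v, list):
            v = tuple(v)
        elif isinstance(v, dict):
            v = {kk: tuple(t) if isinstance(t, list) else t for kk, t in v.items()}
        kwargs[k] = v
    return cls(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return {
        "seed": cfg.seed,
        "staging": _block_to_dict(cfg.staging),
        "spectra": _block_to_dict(cfg.spectra),
        "ripple": _block_to_dict(cfg.ripple),
        "delta": _block_to_dict(cfg.delta),
        "spindle": _block_to_dict(cfg.spindle),
        "coupling": _block_to_dict(cfg.coupling),
        "simulation": _block_to_dict(cfg.simulation),
    }


_BLOCKS = {
    "staging": StagingParams,
    "spectra": SpectraParams,
    "ripple": RippleParams,
    "delta": DeltaParams,
    "spindle": SpindleParams,
    "coupling": CouplingParams,
    "simulation": SimulationParams,
}


def config_from_dict(d: dict) -> PipelineConfig:
    if not isinstance(d, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(d) - set(_BLOCKS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        block = d.get(name)
        if block is None:
            kwargs[name] = cls()
        else:
            try:
                kwargs[name] = _block_from_dict(cls, block)
            except (TypeError, ValidationError) as exc:
                raise ConfigError(f"section {name!r}: {exc}") from exc
    return PipelineConfig(seed=int(d.get("seed", 0)), **kwargs)


def require_sections(d: dict, sections: tuple[str, ...] = ("ripple", "delta", "spindle")) -> None:
    """Strict validation used by the pipeline: detector blocks must be present."""
    missing = [s for s in sections if s not in d]
    if missing:
        raise ConfigError(f"config missing detector sections: {missing} (detectors)")
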