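"""Shared domain types: traces, records, hypnograms and event tables.

Time convention: all times are seconds from session start (float64).
Sample index ``i`` of a trace sampled at rate ``r`` maps to time ``i / r``;
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

EVENT_COLUMNS = [
    "session_id",
    "region",
    "kind",
    "start_s",
    "peak_s",
    "end_s",
    "peak_z",
    "duration_ms",
]


class Stage(str, Enum):
    WAKE = "WAKE"
    NREM = "NREM"
    REM = "REM"


class Modality(str, Enum):
    EEG = "EEG"
    EMG = "EMG"
    LFP = "LFP"
    OTHER = "OTHER"


class Region(str, Enum):
    CA1 = "CA1"
    MPFC = "MPFC"
    PARIETAL = "PARIETAL"
    CEREBELLUM = "CEREBELLUM"
    NECK = "NECK"
    OTHER = "OTHER"


class EventKind(str, Enum):
    RIPPLE = "RIPPLE"
    DELTA = "DELTA"
    SPINDLE = "SPINDLE"


@dataclass
class ChannelTrace:
    """One uniformly sampled channel, samples in microvolts."""

    name: str
    modality: Modality
    region: Region
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.region = Region(self.region)
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate_hz <= 0:
            raise ValidationError(
                f"channel {self.name!r}: sampling rate must be > 0, "
                f"got {self.sampling_rate_hz}"
            )
        if self.samples.ndim != 1:
            raise ValidationError(f"channel {self.name!r}: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"channel {self.name!r}: non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class SignalRecord:
    """A multi-channel session; channels may have different rates but one duration."""

    channels: list[ChannelTrace]
    session_id: str = "session"
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("SignalRecord needs at least one channel")
        d0 = self.channels[0].duration_s
        for ch in self.channels:
            # sample counts must equal round(duration * rate) per channel
            if abs(ch.n_samples - d0 * ch.sampling_rate_hz) > 0.5:
                raise ValidationError(
                    f"channel {ch.name!r} duration {ch.duration_s:.6f}s "
                    f"differs from record duration {d0:.6f}s"
                )

    @property
    def duration_s(self) -> float:
        return self.channels[0].duration_s

    def get(
        self,
        *,
        name: str | None = None,
        modality: Modality | str | None = None,
        region: Region | str | None = None,
    ) -> ChannelTrace:
        """Return the unique channel matching the given criteria."""
        hits = [
            ch
            for ch in self.channels
            if (name is None or ch.name == name)
            and (modality is None or ch.modality == Modality(modality))
            and (region is None or ch.region == Region(region))
        ]
        if len(hits) != 1:
            raise ValidationError(
                f"expected exactly one channel matching name={name} "
                f"modality={modality} region={region}; found {len(hits)}"
            )
        return hits[0]


@dataclass
class Hypnogram:
    """Fixed-epoch sleep-stage sequence (WAKE / NREM / REM)."""

    stages: list[Stage]
    epoch_length_s: float = 4.0
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.epoch_length_s <= 0:
            raise ValidationError("epoch_length_s must be > 0")
        self.stages = [Stage(s) for s in self.stages]
        if not self.stages:
            raise ValidationError("hypnogram must contain at least one epoch")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_length_s

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def epoch_of(self, t_s: float) -> int:
        """Index of the epoch containing time ``t_s`` ([start, end) per epoch)."""
        idx = int(np.floor((t_s - self.start_s) / self.epoch_length_s))
        if idx < 0 or idx >= len(self.stages):
            raise ValidationError(
                f"time {t_s} outside hypnogram span "
                f"[{self.start_s}, {self.end_s})"
            )
        return idx

    def stage_at(self, t_s: float) -> Stage:
        return self.stages[self.epoch_of(t_s)]

    def minutes_in(self, stages: Iterable[Stage | str]) -> float:
        wanted = {Stage(s) for s in stages}
        n = sum(1 for s in self.stages if s in wanted)
        return n * self.epoch_length_s / 60.0

    def intervals(self, stage: Stage | str) -> list[tuple[float, float]]:
        """Contiguous [start, end) intervals occupied by ``stage``."""
        stage = Stage(stage)
        out: list[tuple[float, float]] = []
        run_start: float | None = None
        for i, s in enumerate(self.stages):
            t = self.start_s + i * self.epoch_length_s
            if s is stage and run_start is None:
                run_start = t
            elif s is not stage and run_start is not None:
                out.append((run_start, t))
                run_start = None
        if run_start is not None:
            out.append((run_start, self.end_s))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(len(self.stages)),
                "start_s": self.start_s
                + np.arange(len(self.stages)) * self.epoch_length_s,
                "stage": [s.value for s in self.stages],
            }
        )


@dataclass
class DetectedEvent:
    """One oscillatory event; peak is strictly interior to [start, end]."""

    kind: EventKind
    region: Region
    start_s: float
    peak_s: float
    end_s: float
    peak_z: float
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        self.region = Region(self.region)
        if not (self.start_s < self.peak_s < self.end_s):
            raise ValidationError(
                f"event requires start < peak < end, got "
                f"({self.start_s}, {self.peak_s}, {self.end_s})"
            )

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


class EventTable:
    """Table of detected (or ground-truth) events, sorted by peak time.

    Backed by a pandas DataFrame with the canonical columns plus any
    extras (ground-truth tables add ``event_id``, ``parent_event_id`` and
    ``injected_amplitude_sd``).  Per (kind, region) the event intervals
    must be non-overlapping.
    """

    def __init__(
        self,
        events: pd.DataFrame | Sequence[DetectedEvent] | None = None,
        provenance: dict | None = None,
    ) -> None:
        if events is None:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        elif isinstance(events, pd.DataFrame):
            df = events.copy()
            if df.empty:
                for col in EVENT_COLUMNS:
                    if col not in df.columns:
                        df[col] = pd.Series(dtype=float)
        else:
            df = pd.DataFrame(
                {
                    "session_id": [e.session_id for e in events],
                    "region": [e.region.value for e in events],
                    "kind": [e.kind.value for e in events],
                    "start_s": [e.start_s for e in events],
                    "peak_s": [e.peak_s for e in events],
                    "end_s": [e.end_s for e in events],
                    "peak_z": [e.peak_z for e in events],
                }
            )
        if "duration_ms" not in df.columns and len(df):
            df["duration_ms"] = (df["end_s"] - df["start_s"]) * 1000.0
        elif "duration_ms" not in df.columns:
            df["duration_ms"] = pd.Series(dtype=float)
        self._validate(df)
        df = df.sort_values("peak_s", kind="mergesort").reset_index(drop=True)
        self.df = df
        self.provenance = dict(provenance or {})

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns: {missing}")
        if not len(df):
            return
        if (df["start_s"] > df["end_s"]).any():
            raise ValidationError("event with start_s > end_s")
        bad = ~(
            (df["start_s"] < df["peak_s"]) & (df["peak_s"] < df["end_s"])
        )
        if bad.any():
            raise ValidationError("event peak must lie strictly inside [start, end]")
        dur = (df["end_s"] - df["start_s"]) * 1000.0
        if (np.abs(dur - df["duration_ms"]) > 1e-6).any():
            raise ValidationError("duration_ms inconsistent with start/end")
        for (kind, region), grp in df.groupby(["kind", "region"], sort=False):
            g = grp.sort_values("start_s")
            if (g["start_s"].values[1:] < g["end_s"].values[:-1]).any():
                raise ValidationError(
                    f"overlapping {kind} events in region {region}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def select(
        self,
        kind: EventKind | str | None = None,
        region: Region | str | None = None,
    ) -> "EventTable":
        df = self.df
        if kind is not None:
            df = df[df["kind"] == EventKind(kind).value]
        if region is not None:
            df = df[df["region"] == Region(region).value]
        return EventTable(df.reset_index(drop=True), provenance=self.provenance)

    @property
    def peaks(self) -> np.ndarray:
        return self.df["peak_s"].to_numpy(dtype=float)

    def shifted(self, dt_s: float) -> "EventTable":
        df = self.df.copy()
        for col in ("start_s", "peak_s", "end_s"):
            df[col] = df[col] + dt_s
        return EventTable(df, provenance=self.provenance)


def concat_event_tables(tables: Iterable[EventTable]) -> EventTable:
    frames = [t.df for t in tables if len(t)]
    if not frames:
        return EventTable()
    return EventTable(pd.concat(frames, ignore_index=True))
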