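"""File I/O: EDF/EDF+ signals, TSV hypnograms and event tables, JSON/YAML config.

EDF is the de-facto interchange format for sleep EEG; its 16-bit integer
encoding means signal round trips are exact only up to one quantization
step of ``(phys_max - phys_min) / 65535`` per channel.  EDF labels are
free text, so channel modality/region come from a JSON sidecar map.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig, config_from_dict, config_to_dict
from .core import (
    EVENT_COLUMNS,
    ChannelTrace,
    EventTable,
    Hypnogram,
    Modality,
    Region,
    SignalRecord,
    Stage,
)
from .errors import FormatError, ValidationError

_EDF_HEADER = 256  # bytes, fixed part
_EDF_PER_SIGNAL = 256  # bytes of header per signal

# physical-dimension label -> microvolt multiplier
_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6, "": 1.0}


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _fmt_float(v: float) -> str:
    """Render a float into <= 8 ASCII chars, parseable back by float()."""
    for fmt in ("%.8g", "%.6g", "%.4g", "%.2g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    return "%.1g" % v


def write_signals(record: SignalRecord, path: str | Path) -> Path:
    """Write a SignalRecord as EDF+ (continuous).

    Record duration is fixed at 1 s, so every channel rate must be a
    positive integer and the session an integer number of seconds.
    Physical min/max per channel are chosen to cover the observed range.
    """
    path = Path(path)
    n_records = record.duration_s
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValidationError(
            f"EDF writer uses 1 s data records; duration {record.duration_s} s "
            "is not an integer number of seconds"
        )
    n_records = int(round(n_records))
    for ch in record.channels:
        if abs(ch.sampling_rate_hz - round(ch.sampling_rate_hz)) > 1e-9:
            raise ValidationError(
                f"channel {ch.name!r}: rate {ch.sampling_rate_hz} Hz is not an "
                "integer, cannot lay out 1 s EDF records"
            )
        if not np.all(np.isfinite(ch.samples)):
            raise ValidationError(f"channel {ch.name!r}: non-finite samples")

    ns = len(record.channels)
    header = bytearray()
    header += _pad("0", 8)  # version
    header += _pad(record.session_id, 80)  # patient id field carries session id
    header += _pad("Startdate 01-JAN-2000 X X X", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(_EDF_HEADER + ns * _EDF_PER_SIGNAL), 8)
    header += _pad("EDF+C", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)  # record duration, seconds
    header += _pad(str(ns), 4)

    phys_min, phys_max, scales = [], [], []
    dig_min, dig_max = -32768, 32767
    for ch in record.channels:
        lo = float(np.min(ch.samples)) if ch.n_samples else -1.0
        hi = float(np.max(ch.samples)) if ch.n_samples else 1.0
        if hi <= lo:
            hi = lo + 1.0
        # round-trip the header strings so read-back scaling matches exactly
        lo = float(_fmt_float(lo))
        hi = float(_fmt_float(hi))
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scales.append((hi - lo) / (dig_max - dig_min))

    for ch in record.channels:
        header += _pad(ch.name, 16)
    for _ in record.channels:
        header += _pad("", 80)  # transducer
    for _ in record.channels:
        header += _pad("uV", 8)
    for lo in phys_min:
        header += _pad(_fmt_float(lo), 8)
    for hi in phys_max:
        header += _pad(_fmt_float(hi), 8)
    for _ in record.channels:
        header += _pad(str(dig_min), 8)
    for _ in record.channels:
        header += _pad(str(dig_max), 8)
    for _ in record.channels:
        header += _pad("", 80)  # prefiltering
    for ch in record.channels:
        header += _pad(str(int(round(ch.sampling_rate_hz))), 8)
    for _ in record.channels:
        header += _pad("", 32)

    digitized = []
    for ch, lo, hi, sc in zip(record.channels, phys_min, phys_max, scales):
        d = np.round((ch.samples - lo) / sc + dig_min)
        d = np.clip(d, dig_min, dig_max).astype("<i2")
        digitized.append(d)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        spr = [int(round(ch.sampling_rate_hz)) for ch in record.channels]
        for rec in range(n_records):
            for d, n in zip(digitized, spr):
                fh.write(d[rec * n : (rec + 1) * n].tobytes())
    return path


def _read_header_field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset : offset + width].decode("ascii", errors="replace").strip()


def read_signals(
    path: str | Path,
    channel_map: dict[str, tuple[str, str]] | None = None,
) -> SignalRecord:
    """Read an EDF/EDF+ file into a SignalRecord (samples in microvolts).

    ``channel_map`` maps channel label -> (modality, region); unmapped
    channels get modality OTHER / region OTHER.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _EDF_HEADER:
        raise FormatError(f"{path}: file shorter than EDF header")
    try:
        header_bytes = int(_read_header_field(raw, 184, 8))
        n_records = int(_read_header_field(raw, 236, 8))
        record_dur = float(_read_header_field(raw, 244, 8))
        ns = int(_read_header_field(raw, 252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: corrupt EDF header ({exc})") from exc
    if ns <= 0:
        raise FormatError(f"{path}: EDF file declares zero signals")
    if header_bytes != _EDF_HEADER + ns * _EDF_PER_SIGNAL:
        raise FormatError(f"{path}: inconsistent EDF header size field")
    session_id = _read_header_field(raw, 8, 80) or path.stem

    sig = raw[_EDF_HEADER:header_bytes]

    def field(block: int, width: int, i: int) -> str:
        # signal header is stored field-major: all labels, all transducers, ...
        return (
            sig[block + i * width : block + (i + 1) * width]
            .decode("ascii", errors="replace")
            .strip()
        )

    off_label = 0
    off_transducer = off_label + ns * 16
    off_dim = off_transducer + ns * 80
    off_pmin = off_dim + ns * 8
    off_pmax = off_pmin + ns * 8
    off_dmin = off_pmax + ns * 8
    off_dmax = off_dmin + ns * 8
    off_prefilter = off_dmax + ns * 8
    off_spr = off_prefilter + ns * 80

    try:
        labels = [field(off_label, 16, i) for i in range(ns)]
        dims = [field(off_dim, 8, i) for i in range(ns)]
        pmin = [float(field(off_pmin, 8, i)) for i in range(ns)]
        pmax = [float(field(off_pmax, 8, i)) for i in range(ns)]
        dmin = [int(field(off_dmin, 8, i)) for i in range(ns)]
        dmax = [int(field(off_dmax, 8, i)) for i in range(ns)]
        spr = [int(field(off_spr, 8, i)) for i in range(ns)]
    except ValueError as exc:
        raise FormatError(f"{path}: corrupt EDF signal header ({exc})") from exc

    record_bytes = 2 * sum(spr)
    n_avail = (len(raw) - header_bytes) // record_bytes if record_bytes else 0
    if n_records == -1:
        n_records = n_avail
    if n_records != n_avail or (len(raw) - header_bytes) % record_bytes:
        raise FormatError(
            f"{path}: declared {n_records} data records but file holds {n_avail}"
        )

    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    data = data.reshape(n_records, record_bytes // 2)

    channels = []
    col = 0
    for i in range(ns):
        dig = data[:, col : col + spr[i]].reshape(-1).astype(np.float64)
        col += spr[i]
        if dmax[i] == dmin[i]:
            raise FormatError(f"{path}: signal {labels[i]!r} has zero digital range")
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (dig - dmin[i]) * scale + pmin[i]
        unit = _UNIT_TO_UV.get(dims[i], None)
        if unit is None:
            unit = 1.0  # unknown physical dimension: take values as-is
        modality, region = Modality.OTHER, Region.OTHER
        if channel_map and labels[i] in channel_map:
            m, r = channel_map[labels[i]]
            modality, region = Modality(m), Region(r)
        channels.append(
            ChannelTrace(
                name=labels[i],
                modality=modality,
                region=region,
                sampling_rate_hz=spr[i] / record_dur,
                samples=phys * unit,
            )
        )
    return SignalRecord(channels=channels, session_id=session_id)


# ---------------------------------------------------------------------------
# channel map sidecar


def read_channel_map(path: str | Path) -> dict[str, tuple[str, str]]:
    with open(path) as fh:
        d = json.load(fh)
    out = {}
    for name, mr in d.items():
        if isinstance(mr, dict):
            out[name] = (mr["modality"], mr["region"])
        else:
            out[name] = (mr[0], mr[1])
    return out


def write_channel_map(record: SignalRecord, path: str | Path) -> Path:
    path = Path(path)
    d = {
        ch.name: {"modality": ch.modality.value, "region": ch.region.value}
        for ch in record.channels
    }
    path.write_text(json.dumps(d, indent=2))
    return path


# ---------------------------------------------------------------------------
# hypnograms


def write_hypnogram(h: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# epoch_length_s={h.epoch_length_s!r}\n")
        fh.write("epoch_index\tstart_s\tstage\n")
        for i, s in enumerate(h.stages):
            fh.write(f"{i}\t{h.start_s + i * h.epoch_length_s!r}\t{s.value}\n")
    return path


def read_hypnogram(path: str | Path) -> Hypnogram:
    path = Path(path)
    epoch_length = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# epoch_length_s="):
            epoch_length = float(first.split("=", 1)[1])
            body = fh.read()
        else:
            body = first + fh.read()
    from io import StringIO

    try:
        df = pd.read_csv(StringIO(body), sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse hypnogram TSV ({exc})") from exc
    for col in ("epoch_index", "start_s", "stage"):
        if col not in df.columns:
            raise FormatError(f"{path}: hypnogram missing column {col!r}")
    idx = df["epoch_index"].to_numpy()
    if len(idx) == 0:
        raise FormatError(f"{path}: empty hypnogram")
    if not np.array_equal(idx, np.arange(len(idx))):
        raise FormatError(f"{path}: epoch_index must be contiguous from 0")
    try:
        stages = [Stage(s) for s in df["stage"]]
    except ValueError as exc:
        raise FormatError(f"{path}: unknown stage label ({exc})") from exc
    start = float(df["start_s"].iloc[0])
    if epoch_length is None:
        if len(df) > 1:
            epoch_length = float(df["start_s"].iloc[1]) - start
        else:
            epoch_length = 4.0
    starts = start + np.arange(len(df)) * epoch_length
    if not np.allclose(starts, df["start_s"].to_numpy(), atol=1e-6):
        raise FormatError(f"{path}: epoch start times are not contiguous")
    return Hypnogram(stages=stages, epoch_length_s=epoch_length, start_s=start)


# ---------------------------------------------------------------------------
# event tables


def write_events(table: EventTable, path: str | Path) -> Path:
    path = Path(path)
    df = table.df.copy()
    cols = EVENT_COLUMNS + [c for c in df.columns if c not in EVENT_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> EventTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse event TSV ({exc})") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: event table missing columns {missing}")
    if len(df) and (df["start_s"] > df["end_s"]).any():
        raise ValidationError(f"{path}: event with start_s > end_s")
    return EventTable(df)


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(fh)
        else:
            d = json.load(fh)
    return config_from_dict(d or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    d = config_to_dict(cfg)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(d, fh, sort_keys=False)
        else:
            json.dump(d, fh, indent=2)
    return path
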