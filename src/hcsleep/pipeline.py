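"""End-to-end orchestration: simulate → score → detect → couple → report.

Each stage writes its outputs under the run directory and records a SHA-256
digest, wall-clock time and output paths in a machine-readable manifest
(``manifest.json``).  Re-running with the same config and seed reproduces
byte-identical event tables and coupling reports; a stage whose outputs
already exist with matching digests is skipped.

The single config seed fans out to per-stage child seeds by stable hashing
of the stage name, so inserting a stage does not reshuffle the randomness
of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    PipelineConfig,
    SimulationParams,
    config_from_dict,
    config_to_dict,
    require_sections,
)
from .core import EventKind, Hypnogram, Modality, Region, SignalRecord, Stage
from .coupling import CouplingResult, coupling_rates
from .detection import detect_delta, detect_ripples, detect_spindles, event_rates
from .errors import ConfigError, DependencyError
from .signal_io import (
    load_config,
    read_events,
    read_hypnogram,
    write_channel_map,
    write_events,
    write_hypnogram,
    write_signals,
)
from .staging import architecture_summary, band_power, score_sleep, stage_spectrum
from .synthetic import generate_session
from .core import EventTable, concat_event_tables

log = logging.getLogger("hcsleep.pipeline")

PHASES = ("PRE", "POST")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31."""
    return (seed * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _phase_params(sim: SimulationParams, phase: str, seed: int) -> SimulationParams:
    kwargs = dataclasses.asdict(sim)
    kwargs["seed"] = stage_seed(seed, f"simulate:{phase}")
    if phase == "POST":
        if sim.post_coupling_prob_rd is not None:
            kwargs["coupling_prob_rd"] = sim.post_coupling_prob_rd
        if sim.post_coupling_prob_ds is not None:
            kwargs["coupling_prob_ds"] = sim.post_coupling_prob_ds
    kwargs["post_coupling_prob_rd"] = None
    kwargs["post_coupling_prob_ds"] = None
    # dataclasses.asdict leaves tuples intact but yaml round trips produce
    # lists; normalize defensively
    return SimulationParams(**kwargs)


def run_pipeline(
    config: PipelineConfig | str | Path | dict,
    out_dir: str | Path,
    skip_existing: bool = True,
) -> dict:
    """Run all stages for both phases and return the manifest dict."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    elif isinstance(config, dict):
        require_sections(config)
        cfg = config_from_dict(config)
    else:
        cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": config_to_dict(cfg),
        "stages": {},
    }
    manifest_path = out / "manifest.json"
    previous = {}
    if skip_existing and manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config") == manifest["config"]:
                previous = old.get("stages", {})
        except (json.JSONDecodeError, OSError):
            previous = {}

    def run_stage(name: str, outputs: list[Path], fn) -> None:
        prev = previous.get(name)
        if (
            prev
            and all(p.exists() for p in outputs)
            and [str(p) for p in outputs] == prev.get("outputs")
            and [_sha256(p) for p in outputs] == prev.get("digests")
        ):
            log.info("stage %s: outputs up to date, skipped", name)
            manifest["stages"][name] = prev
            return
        log.info("stage %s: start", name)
        t0 = time.perf_counter()
        fn()
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {
            "outputs": [str(p) for p in outputs],
            "digests": [_sha256(p) for p in outputs],
            "seconds": round(dt, 3),
        }
        log.info("stage %s: done in %.2f s", name, dt)

    records: dict[str, SignalRecord] = {}
    truths: dict[str, object] = {}

    # --- simulate -----------------------------------------------------------
    sim_outputs = []
    for phase in PHASES:
        sim_outputs += [
            out / f"{phase.lower()}_session.edf",
            out / f"{phase.lower()}_channels.json",
            out / f"{phase.lower()}_truth_events.tsv",
            out / f"{phase.lower()}_truth_hypnogram.tsv",
        ]

    def do_simulate() -> None:
        for phase in PHASES:
            params = _phase_params(cfg.simulation, phase, cfg.seed)
            record, truth = generate_session(
                params, session_id=f"synthetic_{phase.lower()}"
            )
            records[phase] = record
            truths[phase] = truth
            write_signals(record, out / f"{phase.lower()}_session.edf")
            write_channel_map(record, out / f"{phase.lower()}_channels.json")
            write_events(truth.true_events, out / f"{phase.lower()}_truth_events.tsv")
            write_hypnogram(
                truth.hypnogram, out / f"{phase.lower()}_truth_hypnogram.tsv"
            )

    run_stage("simulate", sim_outputs, do_simulate)
    if not records:  # stage was skipped; reload from disk
        from .signal_io import read_channel_map, read_signals

        for phase in PHASES:
            cmap = read_channel_map(out / f"{phase.lower()}_channels.json")
            records[phase] = read_signals(
                out / f"{phase.lower()}_session.edf", cmap
            )

    # --- score --------------------------------------------------------------
    score_outputs = [out / f"{p.lower()}_hypnogram.tsv" for p in PHASES] + [
        out / f"{p.lower()}_architecture.tsv" for p in PHASES
    ] + [out / f"{p.lower()}_band_power.tsv" for p in PHASES]

    hypnograms: dict[str, Hypnogram] = {}

    def do_score() -> None:
        for phase in PHASES:
            rec = records[phase]
            eeg = rec.get(modality=Modality.EEG)
            emg = rec.get(modality=Modality.EMG)
            h = score_sleep(eeg, emg, cfg.staging)
            hypnograms[phase] = h
            write_hypnogram(h, out / f"{phase.lower()}_hypnogram.tsv")
            arch = architecture_summary(h)
            arch["phases"].to_csv(
                out / f"{phase.lower()}_architecture.tsv", sep="\t", index=False
            )
            bp_rows = []
            for stage in Stage:
                try:
                    spec = stage_spectrum(eeg, h, stage, cfg.spectra.band)
                except Exception:
                    continue
                bp = band_power(spec, cfg.spectra.named_bands)
                bp["stage"] = stage.value
                bp_rows.append(bp)
            pd.concat(bp_rows, ignore_index=True).to_csv(
                out / f"{phase.lower()}_band_power.tsv", sep="\t", index=False
            )

    run_stage("score", score_outputs, do_score)
    for phase in PHASES:
        if phase not in hypnograms:
            hypnograms[phase] = read_hypnogram(out / f"{phase.lower()}_hypnogram.tsv")

    # --- detect -------------------------------------------------------------
    detect_outputs = [out / f"{p.lower()}_events.tsv" for p in PHASES] + [
        out / f"{p.lower()}_event_rates.tsv" for p in PHASES
    ]
    event_tables: dict[str, EventTable] = {}

    def do_detect() -> None:
        for phase in PHASES:
            rec = records[phase]
            ca1 = rec.get(modality=Modality.LFP, region=Region.CA1)
            mpfc = rec.get(modality=Modality.LFP, region=Region.MPFC)
            tables = [
                detect_ripples(ca1, cfg.ripple),
                detect_delta(mpfc, cfg.delta),
                detect_spindles(mpfc, cfg.spindle),
            ]
            merged = concat_event_tables(tables)
            df = merged.df.copy()
            df["session_id"] = rec.session_id
            merged = EventTable(df)
            event_tables[phase] = merged
            write_events(merged, out / f"{phase.lower()}_events.tsv")
            rates = event_rates(
                merged, hypnograms[phase], set(cfg.coupling.stages)
            )
            rates.to_csv(
                out / f"{phase.lower()}_event_rates.tsv", sep="\t", index=False
            )

    run_stage("detect", detect_outputs, do_detect)
    for phase in PHASES:
        if phase not in event_tables:
            event_tables[phase] = read_events(out / f"{phase.lower()}_events.tsv")

    # --- couple -------------------------------------------------------------
    couple_outputs = [out / "coupling.json"]

    def do_couple() -> None:
        report = {}
        for phase in PHASES:
            res = coupling_rates(
                event_tables[phase],
                hypnograms[phase],
                cfg.coupling,
                phase=phase,
            )
            report[phase] = {
                "session_id": res.session_id,
                "counts": res.counts,
                "sleep_minutes": res.sleep_minutes,
                "rates_per_min": res.rates_per_min,
                "extras": res.extras,
                "params": res.params,
            }
        report["seed"] = cfg.seed
        (out / "coupling.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    run_stage("couple", couple_outputs, do_couple)

    # --- report -------------------------------------------------------------
    report_outputs = [out / "report.html"]
    run_stage("report", report_outputs, lambda: render_report(manifest, out))

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def render_report(manifest: dict, out_dir: str | Path, plots: bool = False) -> Path:
    """Render a static HTML report from a completed run directory.

    All numbers shown are read back from the stage TSV/JSON outputs, so the
    report is traceable to files on disk.  With ``plots=True`` PNG figures
    (hypnogram time course, band powers) are written next to the report.
    """
    out = Path(out_dir)
    required = {
        "architecture": [out / f"{p.lower()}_architecture.tsv" for p in PHASES],
        "band_power": [out / f"{p.lower()}_band_power.tsv" for p in PHASES],
        "event_rates": [out / f"{p.lower()}_event_rates.tsv" for p in PHASES],
        "coupling": [out / "coupling.json"],
    }
    for kind, paths in required.items():
        for p in paths:
            if not p.exists():
                raise DependencyError(f"report needs {kind} output {p.name}")

    sections = ["<html><head><title>hcsleep run report</title></head><body>"]
    sections.append("<h1>Sleep / coupling pipeline report</h1>")
    for phase in PHASES:
        sections.append(f"<h2>Phase {phase}</h2>")
        for label, path in (
            ("Sleep architecture (min)", out / f"{phase.lower()}_architecture.tsv"),
            ("Relative band power", out / f"{phase.lower()}_band_power.tsv"),
            ("Event incidence/amplitude/density", out / f"{phase.lower()}_event_rates.tsv"),
        ):
            df = pd.read_csv(path, sep="\t")
            sections.append(f"<h3>{label}</h3>")
            sections.append(df.to_html(index=False))
    coupling = json.loads((out / "coupling.json").read_text())
    sections.append("<h2>Coupling rates (per NREM minute)</h2>")
    rows = []
    for phase in PHASES:
        r = coupling[phase]["rates_per_min"]
        rows.append({"phase": phase, **{k.upper(): v for k, v in r.items()}})
    sections.append(pd.DataFrame(rows).to_html(index=False))
    sections.append("</body></html>")

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for phase in PHASES:
            h = read_hypnogram(out / f"{phase.lower()}_hypnogram.tsv")
            codes = {"WAKE": 2, "NREM": 1, "REM": 0}
            y = [codes[s.value] for s in h.stages]
            fig, ax = plt.subplots(figsize=(10, 2))
            ax.step(
                h.start_s + np.arange(len(h)) * h.epoch_length_s, y, where="post"
            )
            ax.set_yticks([0, 1, 2], ["REM", "NREM", "WAKE"])
            ax.set_xlabel("time (s)")
            fig.tight_layout()
            fig.savefig(out / f"{phase.lower()}_hypnogram.png", dpi=100)
            plt.close(fig)

    path = out / "report.html"
    path.write_text("\n".join(sections))
    return path
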