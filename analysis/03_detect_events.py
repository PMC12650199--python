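#!/usr/bin/env python
"""Run the ripple/delta/spindle detectors on the simulated sessions and
score them against ground truth.

Writes ``results/detector_performance.tsv`` (per session and pooled) and
``results/event_rates.tsv`` (incidence, amplitude, density per session).
"""

from pathlib import Path

import pandas as pd

from hcsleep.core import EventTable, Stage
from hcsleep.detection import event_rates
from hcsleep.signal_io import read_channel_map, read_events, read_hypnogram, read_signals
from hcsleep.synthetic import SyntheticGroundTruth
from hcsleep.validation import detector_scores, pooled_scores

SESSIONS = Path("scratch/sessions")
RESULTS = Path("results")


def main() -> None:
    per_session, rate_rows, frames = [], [], []
    for edf in sorted(SESSIONS.glob("sess*.edf")):
        name = edf.stem
        record = read_signals(edf, read_channel_map(SESSIONS / f"{name}_channels.json"))
        hyp = read_hypnogram(SESSIONS / f"{name}_hypnogram.tsv")
        truth_events = read_events(SESSIONS / f"{name}_truth_events.tsv")
        truth = SyntheticGroundTruth(hypnogram=hyp, true_events=truth_events)

        scores = detector_scores(record, truth)
        frames.append(scores)
        s = scores.copy()
        s.insert(0, "session", name)
        s["recall"] = (s["tp"] / s["n_true"]).round(3)
        s["precision"] = (s["tp"] / s["n_detected"]).round(3)
        per_session.append(s)

        rates = event_rates(truth_events, hyp, {Stage.NREM})
        rates.insert(0, "session", name)
        rate_rows.append(rates)

    pooled = pooled_scores(frames)
    pooled.insert(0, "session", "POOLED")
    pooled["recall"] = pooled["recall"].round(3)
    pooled["precision"] = pooled["precision"].round(3)
    table = pd.concat(per_session + [pooled], ignore_index=True)
    table.to_csv(RESULTS / "detector_performance.tsv", sep="\t", index=False)
    pd.concat(rate_rows, ignore_index=True).to_csv(
        RESULTS / "event_rates.tsv", sep="\t", index=False
    )
    print("detector performance (peak-matched against ground truth):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
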