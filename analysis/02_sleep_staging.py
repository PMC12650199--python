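#!/usr/bin/env python
"""Score sleep stages on the simulated sessions, compare against ground
truth, and summarize architecture and band power.

Reads the EDF sessions written by 01_simulate_sessions.py, writes
``results/sleep_architecture.tsv``, ``results/band_power.tsv`` and
``results/staging_accuracy.tsv``.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hcsleep.core import Modality, Stage
from hcsleep.signal_io import read_channel_map, read_hypnogram, read_signals
from hcsleep.staging import architecture_summary, band_power, score_sleep, stage_spectrum

SESSIONS = Path("scratch/sessions")
RESULTS = Path("results")


def main() -> None:
    arch_rows, power_rows, acc_rows = [], [], []
    for edf in sorted(SESSIONS.glob("sess*.edf")):
        name = edf.stem
        cmap = read_channel_map(SESSIONS / f"{name}_channels.json")
        record = read_signals(edf, cmap)
        truth = read_hypnogram(SESSIONS / f"{name}_hypnogram.tsv")
        eeg = record.get(modality=Modality.EEG)
        scored = score_sleep(eeg, record.get(modality=Modality.EMG))

        n = min(len(scored), len(truth))
        acc = float(np.mean([scored.stages[i] is truth.stages[i] for i in range(n)]))
        acc_rows.append({"session": name, "epochs": n, "accuracy": round(acc, 4)})

        phases = architecture_summary(scored)["phases"]
        phases.insert(0, "session", name)
        arch_rows.append(phases)

        for stage in Stage:
            try:
                sp = stage_spectrum(eeg, scored, stage)
            except Exception:
                continue
            bp = band_power(sp)
            bp.insert(0, "session", name)
            bp.insert(1, "stage", stage.value)
            power_rows.append(bp)

    acc = pd.DataFrame(acc_rows)
    acc.to_csv(RESULTS / "staging_accuracy.tsv", sep="\t", index=False)
    pd.concat(arch_rows).to_csv(RESULTS / "sleep_architecture.tsv", sep="\t", index=False)
    pd.concat(power_rows).to_csv(RESULTS / "band_power.tsv", sep="\t", index=False)
    print("staging accuracy vs ground truth:")
    print(acc.to_string(index=False))
    print("mean accuracy: %.3f" % acc["accuracy"].mean())


if __name__ == "__main__":
    main()
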