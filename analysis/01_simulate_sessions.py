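#!/usr/bin/env python
"""Generate the synthetic pre/post recording sessions used by the later
analysis steps.

Writes EDF signals, channel maps and ground-truth tables under
``scratch/sessions/`` (binary/bulky) and a per-session summary under
``results/simulated_sessions.tsv``.
"""

from pathlib import Path

import pandas as pd

from hcsleep.config import SimulationParams
from hcsleep.core import Stage
from hcsleep.signal_io import (
    write_channel_map,
    write_events,
    write_hypnogram,
    write_signals,
)
from hcsleep.synthetic import generate_session

SESSION_SEEDS = [3, 4, 5]
DURATION_S = 1800.0

OUT = Path("scratch/sessions")
RESULTS = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for seed in SESSION_SEEDS:
        params = SimulationParams(duration_s=DURATION_S, seed=seed)
        record, truth = generate_session(params, seed=seed, session_id=f"sess{seed}")
        base = OUT / f"sess{seed}"
        write_signals(record, base.with_suffix(".edf"))
        write_channel_map(record, Path(str(base) + "_channels.json"))
        write_hypnogram(truth.hypnogram, Path(str(base) + "_hypnogram.tsv"))
        write_events(truth.true_events, Path(str(base) + "_truth_events.tsv"))
        counts = truth.true_events.df["kind"].value_counts().to_dict()
        rows.append(
            {
                "session": f"sess{seed}",
                "seed": seed,
                "duration_min": DURATION_S / 60,
                "nrem_min": round(truth.hypnogram.minutes_in({Stage.NREM}), 2),
                "rem_min": round(truth.hypnogram.minutes_in({Stage.REM}), 2),
                "n_ripples": counts.get("RIPPLE", 0),
                "n_deltas": counts.get("DELTA", 0),
                "n_spindles": counts.get("SPINDLE", 0),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "simulated_sessions.tsv", sep="\t", index=False)
    print(f"wrote {len(rows)} sessions to {OUT}/ ({DURATION_S/60:.0f} min each)")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
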