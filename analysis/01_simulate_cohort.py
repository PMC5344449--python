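#!/usr/bin/env python
"""Simulate the synthetic study cohort and write its shareable artifacts.

Generates the default 31-subject cohort (two runs per subject: gesture and
color Stroop) with the planted activation pattern: a gesture-task effect in
five contiguous right-temporal channels and two left-DLPFC channels, and an
incongruency effect in two right-DLPFC channels, each one noise-SD strong.

Writes (under results/cohort/):
  events_sub-01_{gesture,color}.tsv  example BIDS-style event tables
  behavior_trials.tsv                all behavioral trials, all subjects
  ground_truth.json                  planted per-channel amplitudes
and one example raw recording as SNIRF under scratch/ (binary, not a
deliverable).  The cohort itself is regenerated deterministically from the
seed by the downstream scripts, so no bulk raw data needs to be stored.
"""

import json
from pathlib import Path

import pandas as pd

from nirstroop.io import write_events_tsv, write_json, write_snirf
from nirstroop.simulate import (SimulationConfig, default_active_channels,
                                simulate_subject)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "cohort"
SCRATCH = ROOT / "scratch"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    config = SimulationConfig(seed=SEED,
                              active_channels=default_active_channels())

    behavior = []
    for s in range(config.n_subjects):
        sub = simulate_subject(config, s, with_recording=(s == 0))
        behavior.append(sub.behavior)
        if s == 0:
            for task in config.tasks:
                write_events_tsv(OUT / f"events_sub-01_{task}.tsv",
                                 sub.schedules[task],
                                 duration=config.trial_duration)
            write_snirf(SCRATCH / "sub-01_gesture.snirf",
                        sub.intensity["gesture"], config.sample_period,
                        [780.0, 805.0, 830.0], sub.layout)
            write_json(OUT / "ground_truth.json", {
                "seed": SEED,
                "noise_sd": config.noise_sd,
                "active_channels": {
                    str(ch): [[c, a] for c, a in specs]
                    for ch, specs in config.active_channels.items()},
                "design_names": {t: sub.designs[t].names
                                 for t in config.tasks},
            })

    trials = pd.concat(behavior, ignore_index=True)
    trials.to_csv(OUT / "behavior_trials.tsv", sep="\t", index=False)
    print(f"simulated {config.n_subjects} subjects "
          f"({len(trials)} behavioral trials) with seed {SEED}")
    print(f"planted channels: {sorted(config.active_channels)}")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
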