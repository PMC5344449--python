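#!/usr/bin/env python
"""Behavioral analysis: the Stroop interference effect in reaction times.

Reads the cohort's behavioral trials (written by 01_simulate_cohort.py),
aggregates subject-first, and reports group means with SEM, the one-tailed
paired t-tests (incongruent > congruent per task and combined; gesture >
color), and per-task accuracy.

Writes results/behavior/{rt_conditions.tsv, rt_tests.tsv,
subject_means.tsv, accuracy.tsv}.
"""

from pathlib import Path

import pandas as pd

from nirstroop.behavior import accuracy, rt_summary

ROOT = Path(__file__).resolve().parents[1]
TRIALS = ROOT / "results" / "cohort" / "behavior_trials.tsv"
OUT = ROOT / "results" / "behavior"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    trials = pd.read_csv(TRIALS, sep="\t")

    blocks = []
    tests = []
    for label, subset, grouping in [
        ("congruency_all", trials, "congruency"),
        ("task", trials, "task"),
        ("congruency_gesture", trials[trials.task == "gesture"], "congruency"),
        ("congruency_color", trials[trials.task == "color"], "congruency"),
    ]:
        stats = rt_summary(subset, grouping)
        blocks.append(stats.conditions.assign(analysis=label))
        tests.append(stats.tests.assign(analysis=label))
        for _, row in stats.conditions.iterrows():
            print(f"{label:20s} {row[grouping]:12s} "
                  f"{row['mean']:7.0f} ± {row['sem']:.0f} ms (SEM, n={row['n']})")
    conditions = pd.concat(blocks, ignore_index=True)
    test_table = pd.concat(tests, ignore_index=True)

    print("\none-tailed paired t-tests:")
    for _, row in test_table.iterrows():
        if row["greater"] in ("incongruent", "gesture"):
            print(f"  [{row['analysis']}] {row['greater']} > {row['lesser']}: "
                  f"t = {row['t']:.3f}, p = {row['p']:.2g}, df = {row['df']}")

    acc = accuracy(trials)
    print("\naccuracy: " + ", ".join(f"{task} {pct:.1f}%"
                                     for task, pct in acc.items()))

    conditions.to_csv(OUT / "rt_conditions.tsv", sep="\t", index=False)
    test_table.to_csv(OUT / "rt_tests.tsv", sep="\t", index=False)
    rt_summary(trials, "congruency").subject_means.to_csv(
        OUT / "subject_means.tsv", sep="\t", index=False)
    acc.reset_index().to_csv(OUT / "accuracy.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
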