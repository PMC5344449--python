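"""Behavioral analysis: gesture onsets, reaction times, accuracy, paired tests.

Reaction time is the interval from stimulus onset to button press.  For
gesture videos the stimulus onset is not the video start but the moment the
gesture becomes interpretable, estimated as the median of independent rater
annotations per video.  Group statistics aggregate subject-first: condition
means are computed per subject, then averaged across subjects, so the
reported SEM is the between-subject standard error and the congruency
comparison is a paired, one-tailed t-test (interference predicts slower
incongruent responses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RTStats",
    "gesture_onset",
    "rt_summary",
    "paired_t_one_tailed",
    "accuracy",
]


def gesture_onset(rater_times) -> float:
    """Median of the per-video rater annotations (s).

    With an even rater count (the study used four) this is the mean of the
    two central values.
    """
    values = np.asarray(list(rater_times), float)
    if values.size == 0:
        raise ValueError("no rater annotations for this video")
    return float(np.median(values))


@dataclass
class RTStats:
    """Group reaction-time summary.

    ``conditions`` has one row per condition with the group mean (ms), SEM
    across subjects (SD/sqrt(n); NaN at n=1), and n; ``subject_means`` is
    the tidy subject x condition table the group rows were computed from;
    ``tests`` holds the pairwise one-tailed paired t-tests.
    """

    conditions: pd.DataFrame
    subject_means: pd.DataFrame
    tests: pd.DataFrame


def rt_summary(
    trials: pd.DataFrame,
    grouping: str = "congruency",
    responded_only: bool = False,
    exclude_errors: bool = False,
) -> RTStats:
    """Subject-then-group reaction-time aggregation.

    ``trials`` needs columns subject, rt_ms, correct and the grouping
    column (e.g. congruency or task).  Error trials are kept by default;
    ``exclude_errors`` drops them.  Pairwise condition comparisons are
    one-tailed paired t-tests in both directions (a > b rows).
    """
    t = trials.copy()
    if exclude_errors:
        t = t[t["correct"].astype(bool)]
    if responded_only:
        t = t[t["rt_ms"].notna() & (t["rt_ms"] > 0)]
    if t.empty:
        raise ValueError("no trials left to summarize")

    per_subject = (t.groupby(["subject", grouping])["rt_ms"]
                   .mean().rename("mean_rt_ms").reset_index())
    counts = per_subject.groupby("subject").size()
    n_conditions = t[grouping].nunique()
    incomplete = counts[counts < n_conditions]
    if len(incomplete):
        raise ValueError(
            f"subjects missing a condition: {list(incomplete.index)}")

    group = (per_subject.groupby(grouping)["mean_rt_ms"]
             .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size")
             .reset_index())
    group["sem"] = group["sd"] / np.sqrt(group["n"])

    wide = per_subject.pivot(index="subject", columns=grouping,
                             values="mean_rt_ms")
    rows = []
    conds = list(wide.columns)
    for a in conds:
        for b in conds:
            if a == b:
                continue
            tval, p, df = paired_t_one_tailed(wide[a].to_numpy(),
                                              wide[b].to_numpy())
            rows.append({"greater": a, "lesser": b, "t": tval, "p": p,
                         "df": df})
    return RTStats(conditions=group, subject_means=per_subject,
                   tests=pd.DataFrame(rows))


def paired_t_one_tailed(a, b) -> tuple[float, float, int]:
    """One-tailed paired t-test of H1: mean(a) > mean(b).

    t = mean(d) / (SD(d)/sqrt(n)) with d = a - b and df = n - 1; p is the
    upper tail.  Raises if the pairing is broken or the differences have
    zero variance.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 paired values")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 0.5, len(d) - 1
        raise ValueError("zero variance of nonzero differences")
    n = len(d)
    t = float(d.mean() / (sd / np.sqrt(n)))
    return t, float(stats.t.sf(t, n - 1)), n - 1


def accuracy(trials: pd.DataFrame, by: str = "task") -> pd.Series:
    """Percent-correct per level of ``by`` (default task)."""
    if trials.empty:
        raise ValueError("no trials")
    return (trials.groupby(by)["correct"]
            .apply(lambda v: 100.0 * v.astype(bool).mean())
            .rename("percent_correct"))
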