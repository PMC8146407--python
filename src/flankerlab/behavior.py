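"""Per-trial response scoring and behavioral summaries.

A trial lasts 1000 ms; any key press within that window is a candidate
response, but only the first one counts.  A trial with no response is a
*missing* trial, not an error.  Accuracy is the percentage of correctly
answered trials; by default missing trials stay in the denominator
(they were presented) but are never counted as errors.  Mean response
times are computed over correct trials only, subject-level first, so the
group mean is the mean of subject means as the repeated-measures ANOVA
assumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .paradigm import CONGRUENT, INCONGRUENT, StimulusSchedule, TrialSpec
from .stats import StatResult, rm_anova

__all__ = [
    "ResponseEvent",
    "ScoredTrial",
    "BehavioralSummary",
    "score_trial",
    "score_log",
    "summarize_subject",
    "behavioral_anova",
    "write_behavior_log",
    "read_behavior_log",
]

TRIAL_WINDOW_MS = 1000.0

CORRECT = "correct"
ERROR = "error"
MISSING = "missing"


@dataclass(frozen=True)
class ResponseEvent:
    key: str  # "left" | "right"
    time: float  # ms from trial onset

    def __post_init__(self) -> None:
        if not 0.0 <= self.time <= TRIAL_WINDOW_MS:
            raise ValueError(f"response at {self.time} ms outside the trial window")
        if self.key not in ("left", "right"):
            raise ValueError(f"unknown response key {self.key!r}")


@dataclass(frozen=True)
class ScoredTrial:
    trial: TrialSpec
    outcome: str
    rt: float | None  # ms; time of the first response, absent when missing


@dataclass
class BehavioralSummary:
    subject: str
    group: str
    mean_rt: dict[str, float | None]  # per condition, correct trials only
    accuracy: dict[str, float]  # percent
    counts: dict[str, dict[str, int]]  # condition -> outcome -> n


def score_trial(trial: TrialSpec, responses: list[ResponseEvent]) -> ScoredTrial:
    """Score one trial: first response decides; no response -> missing."""
    if not responses:
        return ScoredTrial(trial, MISSING, None)
    first = min(responses, key=lambda r: r.time)
    outcome = CORRECT if first.key == trial.direction else ERROR
    return ScoredTrial(trial, outcome, first.time)


def score_log(schedule: StimulusSchedule,
              responses_by_trial: dict[int, list[ResponseEvent]]) -> list[ScoredTrial]:
    """Score every analyzed (non-training) trial of a session."""
    return [score_trial(tr, responses_by_trial.get(tr.index, []))
            for tr in schedule.trials]


def summarize_subject(scored: list[ScoredTrial], subject: str = "",
                      group: str = "", include_missing_in_denominator: bool = True
                      ) -> BehavioralSummary:
    """Condition-wise mean RT (correct trials) and accuracy (percent).

    A condition with zero correct trials gets ``mean_rt = None``.
    """
    conditions = (CONGRUENT, INCONGRUENT)
    counts = {c: {CORRECT: 0, ERROR: 0, MISSING: 0} for c in conditions}
    rts = {c: [] for c in conditions}
    for st in scored:
        c = st.trial.congruency
        counts[c][st.outcome] += 1
        if st.outcome == CORRECT:
            rts[c].append(st.rt)
    mean_rt: dict[str, float | None] = {}
    accuracy: dict[str, float] = {}
    for c in conditions:
        n_all = sum(counts[c].values())
        if n_all == 0:
            raise ValueError(f"no trials in condition {c}")
        denom = n_all if include_missing_in_denominator else n_all - counts[c][MISSING]
        accuracy[c] = 100.0 * counts[c][CORRECT] / denom if denom else 0.0
        mean_rt[c] = float(np.mean(rts[c])) if rts[c] else None
    return BehavioralSummary(subject, group, mean_rt, accuracy, counts)


def behavioral_anova(summaries: list[BehavioralSummary]) -> dict[str, list[StatResult]]:
    """Congruency x group mixed ANOVA per dependent variable (RT, accuracy).

    Subjects missing a condition mean (no correct trials in a cell) are
    dropped from the RT analysis; the dropped ids are returned under
    ``"dropped_rt"`` (as zero-length StatResult list placeholder is
    unhelpful, they are attached to the returned dict under a plain key).
    """
    out: dict[str, list] = {}
    rt_rows, rt_groups, dropped = [], [], []
    for s in summaries:
        if s.mean_rt[CONGRUENT] is None or s.mean_rt[INCONGRUENT] is None:
            dropped.append(s.subject)
            continue
        rt_rows.append([s.mean_rt[CONGRUENT], s.mean_rt[INCONGRUENT]])
        rt_groups.append(s.group)
    acc_rows = [[s.accuracy[CONGRUENT], s.accuracy[INCONGRUENT]] for s in summaries]
    acc_groups = [s.group for s in summaries]
    multi_group = len(set(rt_groups)) > 1
    out["rt"] = rm_anova(np.array(rt_rows), ("congruency",),
                         rt_groups if multi_group else None)
    out["accuracy"] = rm_anova(np.array(acc_rows), ("congruency",),
                               acc_groups if len(set(acc_groups)) > 1 else None)
    out["dropped_rt"] = dropped
    return out


def write_behavior_log(path, subject: str,
                       responses_by_trial: dict[int, list[ResponseEvent]]) -> None:
    """One row per response event: subject, trial_index, key, time_ms."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject", "trial_index", "key", "time_ms"])
        for idx in sorted(responses_by_trial):
            for ev in responses_by_trial[idx]:
                w.writerow([subject, idx, ev.key, f"{ev.time:.1f}"])


def read_behavior_log(path) -> dict[int, list[ResponseEvent]]:
    out: dict[int, list[ResponseEvent]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(int(row["trial_index"]), []).append(
                ResponseEvent(row["key"], float(row["time_ms"])))
    for evs in out.values():
        evs.sort(key=lambda e: e.time)
    return out
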