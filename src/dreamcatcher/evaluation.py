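"""Scoring of blinded classifications and the statistical evaluation suite.

Each step is scored at its own decision granularity — 54 case calls, 27 pair
calls (twice), 9 participant-group calls, and one final binary call — with an
exact two-tailed binomial test against chance at every step.  A Monte-Carlo
power analysis for the paired design (one-sample t on n paired Gaussian
differences) quantifies what effect sizes the 9-participant design could
have detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .labeling import DREAMFUL, DREAMLESS

__all__ = ["StepResult", "binomial_two_tailed", "score_step", "mc_power",
           "table2_report", "STEP_DECISIONS", "STEP_INFO"]

STEP_DECISIONS = {1: 54, 2: 27, 3: 27, 4: 9, 5: 1}
STEP_INFO = {1: "Case", 2: "Pair", 3: "Subject", 4: "Subject-condition",
             5: "Condition"}


@dataclass
class StepResult:
    """One row of the performance summary."""

    step: int
    info: str
    n_decisions: int
    n_correct: int
    p_value: float

    def __post_init__(self) -> None:
        if self.n_decisions != STEP_DECISIONS[self.step]:
            raise ValueError(f"step {self.step} must have "
                             f"{STEP_DECISIONS[self.step]} decisions, "
                             f"got {self.n_decisions}")

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_correct / self.n_decisions


def binomial_two_tailed(n: int, k: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial p (point-probability method).

    For p0 = 0.5 this equals the doubled smaller tail capped at 1, and is
    symmetric in k and n - k.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    return float(stats.binomtest(k, n, p0).pvalue)


def _pair_of(truth: pd.DataFrame) -> pd.Series:
    if "pair" in truth.columns:
        return truth["pair"]
    return truth["participant"].astype(str) + "/" + truth["session"].astype(str)


def score_step(predictions, truth: pd.DataFrame, step: int) -> StepResult:
    """Score one step's condition calls against the truth table.

    ``predictions``: steps 1–3 take a case_id -> condition-name mapping;
    step 4 a participant_condition-group -> name mapping (needs the
    ``participant_condition`` column in ``truth``); step 5 a condition-group
    label -> name mapping (needs the ``condition_label`` column).  Steps 2–3
    count a pair correct only when its dreamful member is the one called
    dreamful.
    """
    if step not in STEP_DECISIONS:
        raise ValueError(f"step must be 1..5, got {step}")
    t = truth.set_index("case_id") if "case_id" in truth.columns else truth

    if step == 1:
        pred = pd.Series(dict(predictions))
        if set(pred.index) != set(t.index):
            raise ValueError("step 1 predictions must cover all 54 cases")
        correct = int((pred.reindex(t.index) == t["condition"]).sum())
    elif step in (2, 3):
        pred = pd.Series(dict(predictions))
        if set(pred.index) != set(t.index):
            raise ValueError(f"step {step} predictions must cover all 54 cases")
        correct = 0
        for _, grp in t.groupby(_pair_of(t)):
            ok = all(pred[cid] == grp.loc[cid, "condition"] for cid in grp.index)
            correct += int(ok)
    elif step == 4:
        if "participant_condition" not in t.columns:
            raise ValueError("step 4 scoring needs the participant_condition column")
        group_truth = (t.reset_index().groupby("participant_condition")["condition"]
                       .agg(lambda s: s.iloc[0]))
        pred = pd.Series(dict(predictions))
        if set(pred.index) != set(group_truth.index):
            raise ValueError("step 4 predictions must cover all 18 groups")
        correct = 0
        part_of = (t.reset_index().groupby("participant_condition")["participant"]
                   .agg(lambda s: s.iloc[0]))
        for _, gs in part_of.groupby(part_of):
            correct += int(all(pred[g] == group_truth[g] for g in gs.index))
    else:  # step 5
        if "condition_label" not in t.columns:
            raise ValueError("step 5 scoring needs the condition_label column")
        label_truth = (t.reset_index().groupby("condition_label")["condition"]
                       .agg(lambda s: s.iloc[0]))
        pred = pd.Series(dict(predictions))
        if set(pred.index) != set(label_truth.index):
            raise ValueError("step 5 predictions must cover both condition groups")
        correct = int((pred == label_truth.reindex(pred.index)).all())

    n = STEP_DECISIONS[step]
    return StepResult(step, STEP_INFO[step], n, correct, binomial_two_tailed(n, correct))


def mc_power(n_pairs: int, effect_d: float, alpha: float = 0.05, tails: int = 1,
             reps: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo power of a paired t-test at standardized effect size d.

    Paired differences are drawn as Normal(d, 1); each replicate runs a
    one-sample t-test on n_pairs differences and the power is the rejection
    fraction at level alpha with the stated tails.
    """
    if reps < 1000:
        raise ValueError("need reps >= 1000")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    rng = np.random.default_rng(seed)
    draws = rng.normal(effect_d, 1.0, size=(reps, n_pairs))
    t = draws.mean(axis=1) / (draws.std(axis=1, ddof=1) / np.sqrt(n_pairs))
    df = n_pairs - 1
    if tails == 1:
        crit = stats.t.ppf(1 - alpha, df)
        reject = t > crit
    else:
        crit = stats.t.ppf(1 - alpha / 2, df)
        reject = np.abs(t) > crit
    return float(reject.mean())


def table2_report(step_results: list[StepResult]) -> pd.DataFrame:
    """Performance summary table; the accuracy column is recomputed, not stored."""
    rows = [{
        "Step": r.step,
        "Information revealed": r.info,
        "Number of decisions": r.n_decisions,
        "Number correct": r.n_correct,
        "Accuracy (%)": round(100.0 * r.n_correct / r.n_decisions),
        "Binomial p": r.p_value,
    } for r in sorted(step_results, key=lambda r: r.step)]
    return pd.DataFrame(rows, columns=["Step", "Information revealed",
                                       "Number of decisions", "Number correct",
                                       "Accuracy (%)", "Binomial p"])
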