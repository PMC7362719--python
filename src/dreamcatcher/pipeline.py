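"""Orchestration of the five-step blinded classification workflow.

Each step sees only the grouping labels its reveal level discloses plus the
scored accuracies of earlier steps; the condition-name truth lives inside a
sealed scoring oracle that only ever returns accuracy numbers (the
data-team role).  Steps:

1. combination clustering of all 54 cases on the chosen feature set
   (fine-resolution log PSD by default), spectral labeling;
2. pair-difference hyperplane ensemble on the 50-feature composite set,
   average linkage, spectral labeling;
3. per-participant ICA cleanup, the four-way similarity ensemble, Ward
   linkage, spectral labeling;
4. adjusted ICA cleanup, participant-condition group difference vectors,
   hyperplane ensemble over the 18 group means, spectral + frontal-high
   labeling;
5. no clustering: group means of the literature-replication features decide
   the final binary call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .combination_clustering import (EnsembleConfig, extract_two_clusters,
                                     run_combination_clustering)
from .consistency_screen import screen_feature_sets
from .evaluation import StepResult, score_step, table2_report
from .features import extract_features, studentize
from .ica_cleanup import (fit_participant_ica, remove_and_recompose,
                          score_condition_relevance,
                          score_condition_relevance_groups)
from .labeling import ConditionCall, label_by_spectrum, label_step4, label_step5
from .paired_geometry import (pairwise_ensemble, step3_similarity,
                              step4_group_ensemble)
from .psg_data import BlindKey, PsgCase, reveal
from .synthetic_psg import CohortConfig, synth_cohort

__all__ = ["RunConfig", "ScoringOracle", "run_step", "run_experiment"]


class TruthLeakError(RuntimeError):
    """An analysis stage tried to read the sealed condition truth."""


class ScoringOracle:
    """The data-team role: scores predictions, never reveals the truth."""

    def __init__(self, truth: pd.DataFrame, key: BlindKey):
        merged = truth.merge(
            key.table.rename(columns={"participant": "participant_blind",
                                      "condition": "condition_label"}),
            on="case_id")
        object.__setattr__(self, "_sealed", merged)

    @property
    def truth(self):
        raise TruthLeakError("the condition truth is sealed; only scores are available")

    def __getattr__(self, name):
        if "truth" in name.lower() and not name.startswith("_"):
            raise TruthLeakError("the condition truth is sealed")
        raise AttributeError(name)

    def score(self, predictions, step: int) -> StepResult:
        return score_step(predictions, object.__getattribute__(self, "_sealed"), step)


@dataclass
class RunConfig:
    """Configuration of one full five-step run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    step1_feature_set: str = "PowerFine"
    run_screen: bool = False
    screen_sets: tuple[str, ...] = ("PowerBand", "PowerFine", "PermEn", "EmgRms")
    step1_ensemble: EnsembleConfig = field(
        default_factory=lambda: EnsembleConfig(combinations=500))
    pair_ensemble: EnsembleConfig = field(
        default_factory=lambda: EnsembleConfig(combinations=200))
    mc_reps: int = 1000
    ica_keep: float = 0.5
    seed: int = 0
    out_dir: str | None = None


def _predictions_from_labels(case_ids, labels, call: ConditionCall) -> dict:
    return {cid: call.mapping[int(lab)] for cid, lab in zip(case_ids, labels)}


def run_step(step: int, config: RunConfig, state: dict) -> dict:
    """Execute one step; ``state`` carries cases, key and prior artifacts.

    Returns a dict with the step's predictions, cluster labels, the
    condition call and supporting artifacts.  Only ``reveal(key, step)``
    is consulted for identity information.
    """
    cases: list[PsgCase] = state["cases"]
    key: BlindKey = state["key"]
    view = reveal(key, step)
    case_ids = [c.case_id for c in cases]
    log = {"step": step, "revealed_columns": [c for c in view.columns if c != "case_id"]}

    if step == 1:
        if config.run_screen:
            screen = screen_feature_sets(cases, list(config.screen_sets),
                                         replace(config.pair_ensemble,
                                                 seed=config.seed + 11),
                                         seed=config.seed)
            state["screen_report"] = screen
        fm = extract_features(cases, config.step1_feature_set)
        cfg = replace(config.step1_ensemble, linkage="average", seed=config.seed + 1)
        result, coassoc = run_combination_clustering(fm.values, cfg)
        call = label_by_spectrum(result.labels, fm.df)
        preds = _predictions_from_labels(fm.case_ids, result.labels, call)
        return {"predictions": preds, "labels": result.labels, "call": call,
                "coassoc": coassoc, "features": fm, "log": log,
                "screen": state.get("screen_report")}

    if step == 2:
        fm = extract_features(cases, "Step2_50")
        st = studentize(fm)
        cfg = replace(config.pair_ensemble, linkage="average", seed=config.seed + 2)
        coassoc = pairwise_ensemble(st.values, st.case_ids, view, cfg,
                                    mc_reps=config.mc_reps)
        result = extract_two_clusters(coassoc, "average")
        call = label_by_spectrum(result.labels, fm.df)
        preds = _predictions_from_labels(st.case_ids, result.labels, call)
        return {"predictions": preds, "labels": result.labels, "call": call,
                "coassoc": coassoc, "features": fm, "log": log}

    if step == 3:
        cleaned = []
        for part, grp in view.groupby("participant"):
            sub = [c for c in cases if c.case_id in set(grp["case_id"])]
            model = fit_participant_ica(sub, seed=config.seed + 3, participant=part)
            score_condition_relevance(model, grp)
            cleaned.extend(remove_and_recompose(model, keep=config.ica_keep))
        cleaned.sort(key=lambda c: c.case_id)
        state["cleaned_step3"] = cleaned
        fm = extract_features(cleaned, "Step2_50")
        st = studentize(fm)
        cfg = replace(config.pair_ensemble, seed=config.seed + 4)
        coassoc = step3_similarity(st, view, view, cfg, mc_reps=config.mc_reps)
        result = extract_two_clusters(coassoc, "ward")
        call = label_by_spectrum(result.labels, fm.df)
        preds = _predictions_from_labels(st.case_ids, result.labels, call)
        return {"predictions": preds, "labels": result.labels, "call": call,
                "coassoc": coassoc, "features": fm, "log": log}

    if step == 4:
        cleaned = []
        for part, grp in view.groupby("participant"):
            sub = [c for c in cases if c.case_id in set(grp["case_id"])]
            model = fit_participant_ica(sub, seed=config.seed + 5, participant=part)
            score_condition_relevance_groups(model, grp)
            cleaned.extend(remove_and_recompose(model, keep=config.ica_keep))
        cleaned.sort(key=lambda c: c.case_id)
        fm = extract_features(cleaned, "Step2_50")
        st = studentize(fm)
        cfg = replace(config.pair_ensemble, seed=config.seed + 6)
        coassoc, group_order = step4_group_ensemble(st, view, cfg,
                                                    mc_reps=config.mc_reps)
        result = extract_two_clusters(coassoc, "ward")
        group_features = fm.df.groupby(
            view.set_index("case_id")["participant_condition"]).mean()
        group_features = group_features.loc[group_order]
        call = label_step4(result.labels, group_features)
        preds = {g: call.mapping[int(lab)] for g, lab in zip(group_order, result.labels)}
        return {"predictions": preds, "labels": result.labels, "call": call,
                "coassoc": coassoc, "group_order": group_order,
                "features": fm, "log": log}

    if step == 5:
        fm = extract_features(cases, "Step5")
        idx = view.set_index("case_id")
        groups = idx.loc[fm.case_ids, "condition"]
        participants = idx.loc[fm.case_ids, "participant"]
        call = label_step5(fm.df, groups, participants)
        preds = dict(call.mapping)
        return {"predictions": preds, "call": call, "features": fm, "log": log}

    raise ValueError(f"step must be 1..5, got {step}")


def run_experiment(config: RunConfig) -> dict:
    """Generate (or accept) a cohort and run all five steps with scoring.

    Returns the per-step results, the final performance table, and all
    condition calls.  The synthetic truth table goes straight into the
    scoring oracle and is never placed into the analysis state.
    """
    cases, truth, key = synth_cohort(replace(config.cohort, seed=config.cohort.seed))
    oracle = ScoringOracle(truth, key)
    state: dict = {"cases": cases, "key": key}
    results, calls, artifacts, logs = [], {}, {}, []
    for step in range(1, 6):
        art = run_step(step, config, state)
        res = oracle.score(art["predictions"], step)
        results.append(res)
        calls[step] = art["call"]
        artifacts[step] = art
        logs.append({**art["log"], "accuracy": res.accuracy, "p": res.p_value})
        state[f"accuracy_step{step}"] = res.accuracy  # the data-team feedback loop
    table = table2_report(results)
    bundle = {"results": results, "table": table, "calls": calls,
              "artifacts": artifacts, "logs": logs, "config": config}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "performance.csv", index=False)
        with open(out / "calls.json", "w") as f:
            json.dump({s: json.loads(c.to_json()) for s, c in calls.items()}, f, indent=2)
        with open(out / "run_log.jsonl", "w") as f:
            for rec in logs:
                f.write(json.dumps(rec) + "\n")
        for step in (1, 2, 3, 4):
            np.savetxt(out / f"coassoc_step{step}.csv",
                       artifacts[step]["coassoc"].values, delimiter=",", fmt="%.4f")
    return bundle
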