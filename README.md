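# dreamcatcher

Blinded unsupervised classification of dreamful vs. dreamless NREM sleep
from 1-minute polysomnograms — a full re-implementation of the staged
blinded-analysis protocol, exercised end-to-end on synthetic cohorts.

## The problem

Several sleep studies report that dreaming during NREM sleep goes with
reduced low-frequency (delta) EEG power, mostly posteriorly, and sometimes
with elevated high-frequency power.  A stringent way to test such claims is
a blinded challenge: one team records 54 one-minute pre-awakening
polysomnograms (9 participants x 3 sessions x 2 report conditions), strips
all identity, and a second team must classify each case as dreamful or
dreamless from the signals alone.  Blindness is then lifted in five steps —
pair labels, participant labels, participant-condition groups, condition
groups — with only an accuracy score returned after each attempt.

This package is for researchers who want to run, probe or extend that
protocol: the cohort simulator, every feature set, the clustering ensemble,
the de-blinding machinery and the scoring are importable library code.

## The method in brief

* **Combination clustering** — an evidence-accumulation ensemble: thousands
  of 2-means runs on random feature subsets (|subset| ≤ 9), each weighted by
  its mean silhouette; the weighted co-association matrix is cut
  hierarchically at the level whose best single cluster is closest to n/2.
* **Temporal-consistency screening** — with no labels, feature sets are
  ranked by the agreement of independent per-15-s-segment clusterings,
  C = 2|π₁ − ½|, against a Monte-Carlo null.
* **Pair geometry** — once pairs are known, per-pair difference vectors
  (orientation only; polarity is blinded) are summarized by the unit vector
  v maximizing mean |cos(v, uᵢ)|, and cases are sub-clustered by the
  hyperplane normal to v: pair members never co-associate.
* **ICA cleanup** — per-participant FastICA removes condition-irrelevant
  components before the later steps.
* **Labeling and scoring** — clusters get condition names from spectral
  rules (dreamless: more low-, less high-frequency power; Cohen's
  d = (μ₁ − μ₂)/σ per bin), and every step is scored with an exact
  two-tailed binomial test at its own decision granularity.

The synthetic generator produces 1/f^α EEG with participant and case random
effects, spindles, slow-oscillation bursts, EOG/EMG activity, and a tunable
spectral condition effect (regionally weighted low-band increase for
dreamless, high-band increase for dreamful cases).

## Worked example

```python
import warnings
from dreamcatcher import CohortConfig, RunConfig, run_experiment
from dreamcatcher.combination_clustering import EnsembleConfig

cfg = RunConfig(
    cohort=CohortConfig(seed=5, rate=128, condition_delta_ratio=2.0,
                        condition_high_ratio=1.5),
    step1_ensemble=EnsembleConfig(combinations=100),
    pair_ensemble=EnsembleConfig(combinations=50),
    seed=5)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_experiment(cfg)
print(bundle["table"].to_string(index=False))
```

prints

```
 Step Information revealed  Number of decisions  Number correct  Accuracy (%)   Binomial p
    1                 Case                   54              30            56 4.966174e-01
    2                 Pair                   27              27           100 1.490116e-08
    3              Subject                   27              25            93 5.647540e-06
    4    Subject-condition                    9               9           100 3.906250e-03
    5            Condition                    1               1           100 1.000000e+00
```

Read: with a moderate injected effect hiding under the default participant
variability, Step 1 (no identity information) stays at chance — the
clustering grabs participant identity instead of dreamfulness.  As soon as
pair labels balance the participant effect away (Steps 2–5), the injected
contrast is recovered essentially perfectly.  The step-5 binomial p is 1.0
because a single binary decision can never be significant.  With the
condition ratios set to 1 (no effect), every step sits at chance — the
protocol has no way to manufacture signal.

The numbered drivers under `analysis/` tell the same story from the shell:

```bash
python analysis/01_simulate_cohort.py     # blinded EDF cohort -> scratch/
python analysis/02_screen_feature_sets.py # consistency screen -> results/
python analysis/03_run_blinded_steps.py   # five scored steps  -> results/
python analysis/04_power_analysis.py      # paired-design power -> results/
```

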