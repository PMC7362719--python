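"""Feature-set screening by temporal consistency of per-segment clusterings.

Each 60-s case is split into four 15-s segments; every segment is clustered
independently into two groups.  Because cluster identities are arbitrary,
agreement between two segments is measured through the two possible label
mappings: with pi1 the fraction of cases keeping co-membership under the
first mapping (and pi2 = 1 - pi1 under the second), the consistency is

    C = 2 * |pi1 - 0.5| = 2 * max(pi1, pi2) - 1  in [0, 1],

invariant to relabeling either clustering.  A Monte-Carlo null (random
labelings) gives the upper confidence bound used to flag feature sets whose
clusterings persist across time — the screening signal used to pick the
working feature set before any identity information is revealed.
"""

from __future__ import annotations

import math
from dataclasses import replace
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .combination_clustering import EnsembleConfig, run_combination_clustering
from .features import FeatureMatrix, extract_features
from .psg_data import PsgCase

__all__ = [
    "split_segments", "consistency", "consistency_binomial",
    "consistency_null", "trend_permutation_test", "screen_feature_sets",
]


def split_segments(case: PsgCase, n_segments: int = 4) -> list[PsgCase]:
    """Contiguous equal segments, ordered; the last one ends at awakening."""
    n = case.n_samples
    whole_seconds = abs(case.duration / n_segments
                        - round(case.duration / n_segments)) < 1e-9
    if n % n_segments or not whole_seconds:
        raise ValueError(f"case {case.case_id}: {case.duration:g}-s duration is not "
                         f"divisible into {n_segments} whole-second segments")
    seg_len = n // n_segments
    return [
        PsgCase(case.case_id, case.channels,
                case.samples[:, j * seg_len:(j + 1) * seg_len], case.rate)
        for j in range(n_segments)
    ]


def _align(labels_m, labels_n) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(labels_m, pd.Series) and isinstance(labels_n, pd.Series):
        if set(labels_m.index) != set(labels_n.index):
            raise ValueError("segment labelings cover different case sets")
        labels_n = labels_n.reindex(labels_m.index)
        return labels_m.to_numpy(), labels_n.to_numpy()
    a, b = np.asarray(labels_m), np.asarray(labels_n)
    if a.shape != b.shape:
        raise ValueError("segment labelings cover different case sets")
    return a, b


def consistency(labels_m, labels_n) -> float:
    """Temporal consistency C between two binary clusterings of the same cases."""
    a, b = _align(labels_m, labels_n)
    pi1 = float(np.mean(a == b))
    return 2.0 * abs(pi1 - 0.5)


def consistency_binomial(labels_m, labels_n) -> float:
    """Exact two-tailed binomial p on agreements under the better mapping."""
    a, b = _align(labels_m, labels_n)
    n = a.size
    agree = int(np.sum(a == b))
    k = max(agree, n - agree)
    return float(binomtest(k, n, 0.5).pvalue)


def consistency_null(n_cases: int, cluster_sizes: tuple[int, int] | None = None,
                     reps: int = 2000, alpha: float = 0.05,
                     n_comparisons: int = 1, seed: int = 0) -> float:
    """Upper 1 - alpha/n_comparisons quantile of C under random labelings.

    The null draws pairs of independent uniformly random labelings with the
    given cluster sizes (balanced by default); this stands in for the
    clusterer's own size profile, which is configuration-dependent.
    """
    if reps < 1000:
        raise ValueError("need reps >= 1000 for a stable null quantile")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if cluster_sizes is None:
        cluster_sizes = (n_cases // 2, n_cases - n_cases // 2)
    if sum(cluster_sizes) != n_cases:
        raise ValueError("cluster sizes must sum to n_cases")
    rng = np.random.default_rng(seed)
    base = np.repeat([0, 1], cluster_sizes)

    def draw() -> np.ndarray:
        u = rng.random((reps, n_cases))
        return base[np.argsort(u, axis=1)]

    pi1 = (draw() == draw()).mean(axis=1)
    c = 2.0 * np.abs(pi1 - 0.5)
    return float(np.quantile(c, 1.0 - alpha / n_comparisons))


def trend_permutation_test(c_values, n_perm: int = 10_000, seed: int = 0) -> float:
    """One-tailed permutation p for a late-minus-early rise in consistency.

    The statistic is mean(last half) - mean(first half) of the time-ordered C
    values.  All arrangements are enumerated when feasible (p = fraction of
    arrangements with a statistic >= observed); otherwise Monte-Carlo sampling
    with the add-one correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    c = np.asarray(c_values, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 consistency values")
    half = c.size // 2

    def stat(v: np.ndarray) -> float:
        return float(v[half:].mean() - v[:half].mean())

    observed = stat(c)
    total = math.factorial(c.size)
    if total <= n_perm:
        hits = sum(stat(np.array(p)) >= observed - 1e-12 for p in permutations(c))
        return hits / total
    rng = np.random.default_rng(seed)
    hits = sum(stat(rng.permutation(c)) >= observed - 1e-12 for _ in range(n_perm))
    return (1 + hits) / (1 + n_perm)


def _fit_config(config: EnsembleConfig, n_features: int) -> EnsembleConfig:
    sizes = tuple(k for k in config.subset_sizes if k <= n_features)
    if sizes != config.subset_sizes or n_features == 1:
        return replace(config, subset_sizes=sizes or (1,),
                       include_singletons=True)
    return config


def cluster_segments(cases: list[PsgCase], set_name: str,
                     config: EnsembleConfig, n_segments: int = 4,
                     ) -> list[pd.Series]:
    """Independent per-segment 2-clusterings of all cases for one feature set."""
    per_case_segments = [split_segments(c, n_segments) for c in cases]
    out = []
    for j in range(n_segments):
        seg_cases = [segs[j] for segs in per_case_segments]
        fm = extract_features(seg_cases, set_name)
        cfg = _fit_config(replace(config, seed=config.seed + j), fm.df.shape[1])
        result, _ = run_combination_clustering(fm.values, cfg)
        out.append(pd.Series(result.labels, index=fm.case_ids))
    return out


def screen_feature_sets(cases: list[PsgCase], set_names: list[str],
                        config: EnsembleConfig, n_segments: int = 4,
                        null_reps: int = 2000, alpha: float = 0.05,
                        seed: int = 0) -> pd.DataFrame:
    """Rank candidate feature sets by adjacent-segment clustering consistency.

    Reports, per set, the adjacent-pair consistencies (1v2, 2v3, 3v4), their
    exact binomial p-values, and the Bonferroni-corrected Monte-Carlo null
    bound shared by all comparisons.  The report ranks; the choice of the
    working set stays with the analyst.
    """
    if len(set_names) < 1:
        raise ValueError("need at least one feature set")
    n_pairs = n_segments - 1
    bound = consistency_null(len(cases), reps=null_reps, alpha=alpha,
                             n_comparisons=len(set_names) * n_pairs, seed=seed)
    rows = []
    for name in set_names:
        seg_labels = cluster_segments(cases, name, config, n_segments)
        row: dict = {"set": name}
        cs = []
        for j in range(n_pairs):
            c = consistency(seg_labels[j], seg_labels[j + 1])
            row[f"C{j + 1}{j + 2}"] = c
            row[f"p{j + 1}{j + 2}"] = consistency_binomial(seg_labels[j], seg_labels[j + 1])
            cs.append(c)
        row["mean_C"] = float(np.mean(cs))
        row["null_bound"] = bound
        row["significant"] = bool(np.all(np.array(cs) > bound))
        rows.append(row)
    return (pd.DataFrame(rows).sort_values("mean_C", ascending=False)
            .reset_index(drop=True))
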