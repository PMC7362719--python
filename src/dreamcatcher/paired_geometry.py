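"""Pair-difference geometry for the partially de-blinded steps.

Once cases are revealed as dreamful/dreamless *pairs*, each pair yields a
difference vector in feature space whose orientation — not direction, since
which member is which condition stays hidden — carries the condition
contrast.  The machinery here:

* canonical difference vectors (polarity fixed so the first non-zero
  coordinate is positive, unit length, centred at the pair midpoint);
* the mean orientation vector: the unit v maximizing mean |cos(v, u_i)|,
  found by alternating sign-assignment/averaging ascent (with an exhaustive
  sign-enumeration oracle for small sets);
* hyperplane sub-clustering: the hyperplane through the origin normal to v
  splits every pair, so pair members never co-associate;
* a Monte-Carlo normalization making mean-|cos| goodness values comparable
  across subspace dimensionalities;
* the four-way ensemble used when participant groups are known, and the
  participant-condition group differences used when those are known too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .combination_clustering import (CoAssocMatrix, EnsembleConfig,
                                     SubClustering, mean_silhouette,
                                     sample_combinations, two_means)

__all__ = [
    "DifferenceVectorSet", "OrientationVector",
    "pair_differences", "mean_orientation", "mean_orientation_exhaustive",
    "hyperplane_subcluster", "mc_normalize_goodness", "expected_random_goodness",
    "pairwise_ensemble", "step3_similarity", "step4_condition_differences",
    "pair_rows",
]


# ---------------------------------------------------------------------------
# difference vectors

def _canonicalize(vectors: np.ndarray) -> np.ndarray:
    """Unit length + canonical polarity (first non-zero coordinate >= 0)."""
    v = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    for row in v:
        nz = np.nonzero(np.abs(row) > 1e-12)[0]
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return v


@dataclass
class DifferenceVectorSet:
    """Canonical difference vectors, one per pair (or per participant)."""

    vectors: np.ndarray           # (m, d) canonical unit vectors
    raw: np.ndarray               # (m, d) raw differences, input member order
    members: list[tuple]          # (entity_a, entity_b) per vector
    source_labels: list           # pair / participant label per vector

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return self.vectors.shape[0]


def pair_rows(case_ids: list[str], pairs: pd.DataFrame) -> list[tuple[str, int, int]]:
    """(pair label, row_i, row_j) triples; every pair must have exactly 2 cases."""
    row_of = {cid: i for i, cid in enumerate(case_ids)}
    out = []
    for label, grp in pairs.groupby("pair"):
        ids = list(grp["case_id"])
        if len(ids) != 2:
            raise ValueError(f"pair {label} has {len(ids)} cases, expected 2")
        out.append((label, row_of[ids[0]], row_of[ids[1]]))
    return out


def pair_differences(matrix, pairs: pd.DataFrame) -> DifferenceVectorSet:
    """Per-pair studentized-feature differences as canonical unit vectors.

    ``matrix`` is a FeatureMatrix (expected Studentized) or DataFrame; pairs
    with a zero difference vector are excluded with a warning.
    """
    df = matrix.df if hasattr(matrix, "df") else matrix
    X = df.to_numpy(dtype=float)
    raws, members, labels = [], [], []
    for label, i, j in pair_rows(list(df.index), pairs):
        diff = X[i] - X[j]
        if np.linalg.norm(diff) == 0:
            warnings.warn(f"pair {label}: identical members, difference vector excluded")
            continue
        raws.append(diff)
        members.append((df.index[i], df.index[j]))
        labels.append(label)
    if not raws:
        raise ValueError("no non-zero difference vectors")
    raw = np.vstack(raws)
    return DifferenceVectorSet(_canonicalize(raw.copy()), raw, members, labels)


# ---------------------------------------------------------------------------
# mean orientation

@dataclass
class OrientationVector:
    vector: np.ndarray
    goodness: float                  # mean |cos| against the set
    normalized_goodness: float | None = None


def _goodness(v: np.ndarray, units: np.ndarray) -> float:
    return float(np.abs(units @ v).mean())


def _ascend(units: np.ndarray, v0: np.ndarray, max_iter: int = 200,
            ) -> tuple[np.ndarray, list[float]]:
    """Alternate sign assignment and averaging from v0; goodness is monotone."""
    v = v0 / np.linalg.norm(v0)
    history = [_goodness(v, units)]
    signs = None
    for _ in range(max_iter):
        new_signs = np.where(units @ v >= 0, 1.0, -1.0)
        if signs is not None and np.array_equal(new_signs, signs):
            break
        signs = new_signs
        s = signs @ units
        norm = np.linalg.norm(s)
        if norm == 0:
            break
        v = s / norm
        history.append(_goodness(v, units))
    return v, history


def _polish_signs(units: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    """Greedy single-sign-flip improvement of |sum(s_i u_i)| from v's signs."""
    signs = np.where(units @ v >= 0, 1.0, -1.0)
    s_sum = signs @ units
    best = np.linalg.norm(s_sum)
    improved = True
    while improved and best > 0:
        improved = False
        for i in range(units.shape[0]):
            cand = s_sum - 2 * signs[i] * units[i]
            norm = np.linalg.norm(cand)
            if norm > best + 1e-12:
                signs[i] *= -1.0
                s_sum, best = cand, norm
                improved = True
    if best == 0:
        return v, _goodness(v, units)
    v = s_sum / best
    return v, _goodness(v, units)


def mean_orientation(vectors: DifferenceVectorSet | np.ndarray,
                     n_restarts: int = 5, seed: int = 0,
                     return_history: bool = False):
    """Unit vector maximizing the mean absolute cosine similarity to the set.

    The |cos| objective is non-convex.  The ascent starts from the leading
    eigenvector of the vectors' outer-product sum, each input vector (for
    small sets), and ``n_restarts`` random unit starts; every ascent solution
    is then polished by greedy single-sign-flip moves over the sign pattern.
    For sets of up to 15 vectors this reliably attains the global optimum of
    the exhaustive sign enumeration.
    """
    units = vectors.vectors if isinstance(vectors, DifferenceVectorSet) else \
        _canonicalize(np.atleast_2d(np.asarray(vectors, dtype=float)).copy())
    if units.shape[0] == 0:
        raise ValueError("empty vector set")
    n, d = units.shape
    scatter = units.T @ units
    starts = [np.linalg.eigh(scatter)[1][:, -1]]
    if n <= 15:
        starts.extend(units)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        starts.append(rng.standard_normal(d))
    best_v, best_g, best_hist = None, -1.0, None
    for v0 in starts:
        v, hist = _ascend(units, v0)
        v2, g2 = _polish_signs(units, v)
        v_cand, g_cand = (v2, g2) if g2 >= hist[-1] else (v, hist[-1])
        if g_cand > best_g:
            best_v, best_g = v_cand, g_cand
            best_hist = hist + ([g2] if g2 > hist[-1] + 1e-15 else [])
    out = OrientationVector(best_v, best_g)
    return (out, best_hist) if return_history else out


def mean_orientation_exhaustive(units: np.ndarray) -> OrientationVector:
    """Global optimum by enumerating all sign patterns (oracle, n <= 15)."""
    units = np.atleast_2d(np.asarray(units, dtype=float))
    units = units / np.linalg.norm(units, axis=1, keepdims=True)
    n = units.shape[0]
    if n > 15:
        raise ValueError("exhaustive enumeration is limited to 15 vectors")
    best_v, best_g = None, -1.0
    for bits in range(2 ** (n - 1)):
        signs = np.ones(n)
        for i in range(n - 1):
            if bits >> i & 1:
                signs[i + 1] = -1.0
        s = signs @ units
        norm = np.linalg.norm(s)
        if norm == 0:
            continue
        v = s / norm
        g = _goodness(v, units)
        if g > best_g:
            best_v, best_g = v, g
    return OrientationVector(best_v, best_g)


# ---------------------------------------------------------------------------
# Monte-Carlo goodness normalization

@lru_cache(maxsize=None)
def expected_random_goodness(n_vectors: int, dim: int, reps: int = 1000,
                             seed: int = 0) -> float:
    """MC mean of the mean-orientation goodness for random directions.

    In one dimension (or for a single vector) the goodness is exactly 1, so
    no simulation is run.
    """
    if dim < 1 or n_vectors < 1:
        raise ValueError("dim and n_vectors must be >= 1")
    if dim == 1 or n_vectors == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for r in range(reps):
        u = rng.standard_normal((n_vectors, dim))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        vals[r] = mean_orientation(u, n_restarts=2,
                                   seed=int(rng.integers(2 ** 31))).goodness
    return float(vals.mean())


def mc_normalize_goodness(goodness: float, n_vectors: int, dim: int,
                          reps: int = 1000, seed: int = 0) -> float:
    """Goodness divided by its random-orientation expectation (same n, dim)."""
    if reps < 1000:
        raise ValueError("need reps >= 1000")
    return goodness / expected_random_goodness(n_vectors, dim, reps, seed)


# ---------------------------------------------------------------------------
# hyperplane sub-clustering

def hyperplane_subcluster(diffs: DifferenceVectorSet, orientation: np.ndarray,
                          n_entities: int | None = None,
                          entity_index: dict | None = None) -> SubClustering:
    """Split every pair by the hyperplane through the origin normal to v.

    Each member's side is the sign of (endpoint - pair midpoint) . v, which
    for a pair equals the sign of +-(raw difference) . v — so the two members
    of a pair always land on opposite sides and never co-associate.  An
    exactly-on-hyperplane projection puts the first member on the positive
    side (deterministic tie-break, logged as a warning).
    """
    v = np.asarray(orientation, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError("orientation must be unit-norm")
    if entity_index is None:
        entities = sorted({e for ab in diffs.members for e in ab})
        entity_index = {e: i for i, e in enumerate(entities)}
    if n_entities is None:
        n_entities = len(entity_index)
    labels = np.zeros(n_entities, dtype=int)
    proj = diffs.raw @ v
    ties = np.abs(proj) < 1e-12
    if ties.any():
        warnings.warn(f"{int(ties.sum())} pair(s) exactly on the hyperplane; "
                      "first member assigned to the positive side")
    side_first = np.where(proj >= 0, 1, 0)
    for (a, b), s in zip(diffs.members, side_first):
        labels[entity_index[a]] = s
        labels[entity_index[b]] = 1 - s
    return SubClustering(np.arange(diffs.dim), labels, 1.0)


# ---------------------------------------------------------------------------
# ensembles over feature subsets

def _subspace_diffs(X: np.ndarray, rows: list[tuple], subset: np.ndarray,
                    ) -> np.ndarray | None:
    """Raw difference vectors restricted to a feature subset; None if all zero."""
    raw = np.array([X[i, subset] - X[j, subset] for _, i, j in rows])
    norms = np.linalg.norm(raw, axis=1)
    if (norms == 0).all():
        return None
    return raw[norms > 0]


def _units(raw: np.ndarray) -> np.ndarray:
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def _tally(subclusterings: list[SubClustering], n: int,
           rescale: bool = True) -> np.ndarray:
    """Weighted co-association tally; weights min-max rescaled to [0, 1]."""
    weights = np.array([sc.weight for sc in subclusterings], dtype=float)
    if rescale and weights.size:
        lo, hi = weights.min(), weights.max()
        weights = np.ones_like(weights) if hi == lo else (weights - lo) / (hi - lo)
    acc = np.zeros((n, n))
    total = 0.0
    for sc, w in zip(subclusterings, weights):
        if w <= 0:
            continue
        acc += w * (sc.labels[:, None] == sc.labels[None, :])
        total += w
    if total <= 0:  # all weights degenerate: fall back to unweighted tally
        for sc in subclusterings:
            acc += sc.labels[:, None] == sc.labels[None, :]
            total += 1.0
    vals = acc / total
    np.fill_diagonal(vals, 1.0)
    return vals


def pairwise_ensemble(X: np.ndarray, case_ids: list[str], pairs: pd.DataFrame,
                      config: EnsembleConfig, participants: pd.DataFrame | None = None,
                      mc_reps: int = 1000) -> CoAssocMatrix:
    """Hyperplane sub-clustering over random feature subsets.

    For every subset, pair difference vectors are rebuilt in the subspace,
    the mean orientation estimated, and cases split by the normal
    hyperplane; each sub-clustering is weighted by its Monte-Carlo-normalized
    mean |cos| goodness.  With ``participants`` given, orientations are
    estimated within each participant's own pairs instead of globally.
    """
    n = len(case_ids)
    rows = pair_rows(case_ids, pairs)
    per_part: dict[str, list] = {}
    if participants is not None:
        part_of_case = dict(zip(participants["case_id"], participants["participant"]))
        for trip in rows:
            per_part.setdefault(part_of_case[case_ids[trip[1]]], []).append(trip)
    subsets = sample_combinations(X.shape[1], config)
    scs = []
    for subset in subsets:
        if participants is None:
            groups = [rows]
        else:
            groups = list(per_part.values())
        labels = np.zeros(n, dtype=int)
        weight_parts = []
        ok = True
        for grp in groups:
            raw = _subspace_diffs(X, grp, subset)
            if raw is None or raw.shape[0] < len(grp):
                ok = False  # a degenerate pair in this subspace: skip the subset
                break
            units = _units(raw)
            orient = mean_orientation(units, n_restarts=2, seed=config.seed)
            g = mc_normalize_goodness(orient.goodness, units.shape[0], units.shape[1],
                                      reps=mc_reps, seed=config.seed)
            weight_parts.append(g)
            side_first = (raw @ orient.vector >= 0).astype(int)
            for (_, i, j), s in zip(grp, side_first):
                labels[i], labels[j] = s, 1 - s
        if not ok:
            continue
        scs.append(SubClustering(subset, labels, float(np.mean(weight_parts))))
    if not scs:
        raise ValueError("no usable sub-clusterings (all difference vectors zero)")
    return CoAssocMatrix(_tally(scs, n))


def _kmeans_ensemble_tally(X: np.ndarray, config: EnsembleConfig,
                           rng: np.random.Generator,
                           groups: list[np.ndarray] | None = None) -> np.ndarray:
    """2-means sub-clusterings over subsets; optionally within case groups."""
    n = X.shape[0]
    scs = []
    for subset in sample_combinations(X.shape[1], config):
        if groups is None:
            sub = X[:, subset]
            if np.ptp(sub, axis=0).max() == 0:
                continue
            labels = two_means(sub, restarts=config.restarts, rng=rng)
            w = max(0.0, mean_silhouette(sub, labels))
            scs.append(SubClustering(subset, labels, w))
        else:
            labels = np.zeros(n, dtype=int)
            ws = []
            for g in groups:
                sub = X[np.ix_(g, subset)]
                if np.ptp(sub, axis=0).max() == 0:
                    ws.append(0.0)
                    continue
                gl = two_means(sub, restarts=config.restarts, rng=rng)
                labels[g] = gl
                ws.append(max(0.0, mean_silhouette(sub, gl)))
            scs.append(SubClustering(subset, labels, float(np.mean(ws))))
    if not scs:
        raise ValueError("no usable sub-clusterings")
    return _tally(scs, n)


def step3_similarity(matrix, pairs: pd.DataFrame, participants: pd.DataFrame,
                     config: EnsembleConfig, mc_reps: int = 1000) -> CoAssocMatrix:
    """Four-way ensemble once pair and participant labels are both known.

    Equal-weight average of four co-association matrices: (a) pairwise splits
    against the global mean orientation; (b) pairwise splits against each
    participant's own orientation; (c) 2-means sub-clusterings over all
    cases; (d) 2-means sub-clusterings within each participant's six cases,
    tallied globally.  Pairwise components carry MC-normalized |cos| weights,
    k-means components mean-silhouette weights; each family is min-max
    rescaled before tallying, so the two weight scales stay comparable.
    """
    df = matrix.df if hasattr(matrix, "df") else matrix
    X = df.to_numpy(dtype=float)
    case_ids = list(df.index)
    part_groups = [
        np.array([case_ids.index(c) for c in grp["case_id"]])
        for _, grp in participants.groupby("participant")
    ]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    a = pairwise_ensemble(X, case_ids, pairs, config, mc_reps=mc_reps).values
    b = pairwise_ensemble(X, case_ids, pairs, config, participants=participants,
                          mc_reps=mc_reps).values
    c = _kmeans_ensemble_tally(X, config, rng)
    d = _kmeans_ensemble_tally(X, config, rng, groups=part_groups)
    vals = (a + b + c + d) / 4.0
    np.fill_diagonal(vals, 1.0)
    return CoAssocMatrix(vals)


def step4_condition_differences(matrix, groups: pd.DataFrame) -> DifferenceVectorSet:
    """Per-participant difference of condition-group mean feature vectors.

    ``groups`` maps case_id -> participant, participant_condition.  Each
    participant contributes one canonical unit vector (the difference of the
    mean features of their two unlabeled groups of three cases); zero
    differences are excluded with a warning.
    """
    df = matrix.df if hasattr(matrix, "df") else matrix
    raws, members, labels = [], [], []
    for part, grp in groups.groupby("participant"):
        gl = sorted(grp["participant_condition"].unique())
        if len(gl) != 2:
            raise ValueError(f"participant {part} must have exactly 2 condition groups")
        means = []
        for g in gl:
            ids = grp.loc[grp["participant_condition"] == g, "case_id"]
            if len(ids) != 3:
                raise ValueError(f"group {g} has {len(ids)} cases, expected 3")
            means.append(df.loc[ids].to_numpy(dtype=float).mean(axis=0))
        diff = means[0] - means[1]
        if np.linalg.norm(diff) == 0:
            warnings.warn(f"participant {part}: zero group difference, excluded")
            continue
        raws.append(diff)
        members.append((gl[0], gl[1]))
        labels.append(part)
    if not raws:
        raise ValueError("no non-zero group difference vectors")
    raw = np.vstack(raws)
    return DifferenceVectorSet(_canonicalize(raw.copy()), raw, members, labels)


def step4_group_ensemble(matrix, groups: pd.DataFrame, config: EnsembleConfig,
                         mc_reps: int = 1000) -> tuple[CoAssocMatrix, list[str]]:
    """Hyperplane ensemble over the 18 participant-condition group means."""
    df = matrix.df if hasattr(matrix, "df") else matrix
    group_means = {}
    for g, grp in groups.groupby("participant_condition"):
        group_means[g] = df.loc[grp["case_id"]].to_numpy(dtype=float).mean(axis=0)
    labels_order = sorted(group_means)
    M = np.vstack([group_means[g] for g in labels_order])
    gdf = pd.DataFrame({
        "case_id": labels_order,
        "pair": [groups.loc[groups["participant_condition"] == g, "participant"].iloc[0]
                 for g in labels_order],
    })
    coassoc = pairwise_ensemble(M, labels_order, gdf, config, mc_reps=mc_reps)
    return coassoc, labels_order
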