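"""Rule-based labeling of unlabeled clusters as dreamful vs. dreamless.

The clustering stages produce two anonymous groups; these rules assign the
condition names using literature-derived spectral signatures: dreamless NREM
sleep shows higher low-frequency (1–12 Hz) and lower high-frequency
(18–50 Hz) EEG power.  Effect sizes use Cohen's d

    d = (mu1 - mu2) / sigma,   sigma = sqrt((SD1^2 + SD2^2) / 2)

(the equal-n pooled convention; raw unequal-n inputs fall back to the
standard pooled formula, which coincides for equal group sizes).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DREAMFUL = "dreamful"
DREAMLESS = "dreamless"

LOW_BAND = (1.0, 12.0)
HIGH_BAND = (18.0, 50.0)

logger = logging.getLogger(__name__)

__all__ = ["EffectSize", "ConditionCall", "cohens_d", "cohens_d_summary",
           "label_by_spectrum", "label_step4", "label_step5"]


@dataclass
class EffectSize:
    d: float
    mu1: float
    mu2: float
    sigma: float


@dataclass
class ConditionCall:
    """A cluster -> condition-name bijection plus the rule that produced it."""

    mapping: dict
    rule: str
    contrasts: dict = field(default_factory=dict)
    conflict: bool = False

    def __post_init__(self) -> None:
        if sorted(self.mapping.values()) != [DREAMFUL, DREAMLESS]:
            raise ValueError("mapping must be a bijection onto {dreamful, dreamless}")

    def to_json(self) -> str:
        return json.dumps({
            "mapping": {str(k): v for k, v in self.mapping.items()},
            "rule": self.rule,
            "contrasts": self.contrasts,
            "conflict": self.conflict,
        }, indent=2)


def cohens_d_summary(mu1: float, sd1: float, mu2: float, sd2: float) -> EffectSize:
    """Cohen's d from group summary statistics (equal-n pooled SD)."""
    sigma = float(np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0))
    if sigma == 0:
        raise ValueError("pooled SD is zero")
    return EffectSize(float((mu1 - mu2) / sigma), float(mu1), float(mu2), sigma)


def cohens_d(x1, x2) -> EffectSize:
    """Cohen's d from raw samples (standard pooled SD, antisymmetric in inputs)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    var_p = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    sigma = float(np.sqrt(var_p))
    if sigma == 0:
        raise ValueError("pooled SD is zero")
    return EffectSize(float((x1.mean() - x2.mean()) / sigma),
                      float(x1.mean()), float(x2.mean()), sigma)


# ---------------------------------------------------------------------------
# spectral labeling

_FREQ_RE = re.compile(r"/([\d.]+)(?:-([\d.]+))?Hz$")


def _bin_freqs(columns) -> np.ndarray:
    """Representative frequency per spectral feature name; NaN if not spectral."""
    freqs = np.full(len(columns), np.nan)
    for i, name in enumerate(columns):
        m = _FREQ_RE.search(name)
        if m:
            lo = float(m.group(1))
            hi = float(m.group(2)) if m.group(2) else lo
            freqs[i] = np.sqrt(lo * hi) if hi > lo else lo
    return freqs


def _band_mean_d(features: pd.DataFrame, labels: np.ndarray,
                 ) -> tuple[float, float, dict]:
    """Mean per-bin Cohen's d (cluster 1 minus cluster 2) over low/high bands."""
    freqs = _bin_freqs(features.columns)
    X = features.to_numpy(dtype=float)
    g1, g2 = X[labels == 1], X[labels == 2]
    d = np.full(freqs.size, np.nan)
    for j in range(freqs.size):
        if np.isnan(freqs[j]):
            continue
        s = np.sqrt((g1[:, j].std(ddof=1) ** 2 + g2[:, j].std(ddof=1) ** 2) / 2) \
            if min(len(g1), len(g2)) > 1 else 0.0
        d[j] = (g1[:, j].mean() - g2[:, j].mean()) / s if s > 0 else 0.0
    low = (freqs >= LOW_BAND[0]) & (freqs <= LOW_BAND[1])
    high = (freqs >= HIGH_BAND[0]) & (freqs <= HIGH_BAND[1])
    if not low.any() or not high.any():
        raise ValueError("features lack low-band or high-band spectral bins")
    d_low, d_high = float(np.nanmean(d[low])), float(np.nanmean(d[high]))
    return d_low, d_high, {"d_low": d_low, "d_high": d_high,
                           "n_low_bins": int(low.sum()), "n_high_bins": int(high.sum())}


def _call_from_band_d(d_low: float, d_high: float, contrasts: dict,
                      rule: str) -> ConditionCall:
    if d_low == 0 and d_high == 0:
        raise ValueError("no separable contrast: cluster spectra are identical")
    if np.sign(d_low) != np.sign(d_high) and d_low != 0 and d_high != 0:
        # consistent pattern: one cluster has more low AND less high power
        cluster1_dreamless = d_low > 0
        conflict = False
    else:
        conflict = True
        if abs(d_low) >= abs(d_high):
            cluster1_dreamless = d_low > 0
        else:
            cluster1_dreamless = d_high < 0
        logger.info("band contrasts agree in sign (d_low=%.3f, d_high=%.3f); "
                    "decided by the larger-|d| band", d_low, d_high)
    mapping = {1: DREAMLESS, 2: DREAMFUL} if cluster1_dreamless else \
        {1: DREAMFUL, 2: DREAMLESS}
    return ConditionCall(mapping, rule, contrasts, conflict)


def label_by_spectrum(labels, log_psd_features: pd.DataFrame) -> ConditionCall:
    """Assign dreamless to the cluster with higher low / lower high power.

    ``labels`` are 1/2 per case, row-aligned with the feature frame; spectral
    features are recognized by a trailing frequency tag in their names.  When
    the two band summaries conflict in sign pattern the larger-|d| band
    decides and the conflict is recorded.
    """
    labels = np.asarray(labels)
    d_low, d_high, contrasts = _band_mean_d(log_psd_features, labels)
    return _call_from_band_d(d_low, d_high, contrasts, rule="spectral low/high bands")


def label_step4(labels, step2_features: pd.DataFrame) -> ConditionCall:
    """Spectral rule first; frontal high-frequency power as the tiebreak.

    Prior reporting associates reduced frontal high-frequency activity with
    an absence of dream experience, so when the broadband spectral rule is
    inconclusive, the cluster with lower frontal high power is called
    dreamless.
    """
    labels = np.asarray(labels)
    d_low, d_high, contrasts = _band_mean_d(step2_features, labels)
    frontal_cols = [c for c in step2_features.columns if c.startswith("siclari/frontal/high")]
    if not frontal_cols:
        raise ValueError("missing frontal high-frequency features")
    X = step2_features[frontal_cols].to_numpy(dtype=float)
    fh1, fh2 = X[labels == 1].mean(), X[labels == 2].mean()
    contrasts["frontal_high_mean_1"] = float(fh1)
    contrasts["frontal_high_mean_2"] = float(fh2)
    if np.sign(d_low) != np.sign(d_high) and d_low != 0 and d_high != 0:
        call = _call_from_band_d(d_low, d_high, contrasts, rule="spectral rule")
        # consistency check against the frontal-high indication
        frontal_says_1_dreamless = fh1 < fh2
        spectral_says_1_dreamless = call.mapping[1] == DREAMLESS
        if frontal_says_1_dreamless != spectral_says_1_dreamless:
            call.conflict = True
            logger.info("frontal-high tiebreak disagrees with the spectral rule; "
                        "spectral rule takes precedence")
        return call
    if fh1 == fh2 and d_low == 0 and d_high == 0:
        raise ValueError("no separable contrast between clusters")
    mapping = {1: DREAMLESS, 2: DREAMFUL} if fh1 < fh2 else {1: DREAMFUL, 2: DREAMLESS}
    return ConditionCall(mapping, "frontal high-frequency tiebreak", contrasts, True)


def label_step5(features: pd.DataFrame, groups: pd.Series,
                participants: pd.Series) -> ConditionCall:
    """Classify the two fully-revealed condition groups from SBP/Scarpelli means.

    Each participant's mean is subtracted per feature first (the groups are
    perfectly balanced over participants, so this removes the participant
    random effect).  The group with lower SBP_low, higher SBP_high and lower
    Scarpelli wins the dreamful call by majority vote; a tied vote is an
    error, not a guess.
    """
    glabels = sorted(groups.unique())
    if len(glabels) != 2:
        raise ValueError("need exactly two condition groups")
    centered = features.copy().astype(float)
    for p, idx in features.groupby(participants).groups.items():
        centered.loc[idx] -= features.loc[idx].mean()
    means = centered.groupby(groups).mean()
    diff = means.loc[glabels[0]] - means.loc[glabels[1]]  # A - B
    votes_a_dreamful = 0
    contrasts = {}
    for feat, lower_is_dreamful in (("step5/SBP_low", True),
                                    ("step5/SBP_high", False),
                                    ("step5/Scarpelli", True)):
        v = float(diff[feat])
        contrasts[feat] = v
        if v == 0:
            continue
        a_dreamful = (v < 0) if lower_is_dreamful else (v > 0)
        votes_a_dreamful += 1 if a_dreamful else -1
    if votes_a_dreamful == 0:
        raise ValueError("tied vote: condition groups are not separable")
    a_is_dreamful = votes_a_dreamful > 0
    mapping = {glabels[0]: DREAMFUL if a_is_dreamful else DREAMLESS,
               glabels[1]: DREAMLESS if a_is_dreamful else DREAMFUL}
    return ConditionCall(mapping, "group means of SBP_low/SBP_high/Scarpelli",
                         contrasts)
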