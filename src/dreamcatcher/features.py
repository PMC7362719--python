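"""Candidate feature sets extracted from one polysomnogram case.

All spectral features derive from Welch power spectral density estimates
(2-s Hann windows, 80% overlap, hence 0.5-Hz native resolution) and are
log-transformed with the natural log, in ln(µV²/Hz).  The available sets:

``PowerFine``  99 log-PSD bins (0.5–49.5 Hz) x 25 EEG channels = 2475 features
``PowerBand``  log band power per EEG channel at the six classical bands
``AutoCorr``   per-channel autocorrelation summaries (1/e decay, first zero, lag-1)
``PermEn``     permutation entropy per EEG channel (order 3, delay 1)
``ApEn``       approximate entropy per EEG channel (m=2, r=0.2 SD, 64-Hz decimated)
``EogRms``     RMS per 15-s quarter per EOG channel
``EmgRms``     RMS per 15-s quarter per EMG channel
``Siclari``    11 hot-zone emulation features (regional band power, see below)
``Step2_50``   the 50-feature composite set (19 scalp PSD + 11 Siclari + 10 EMG + 10 EOG)
``Step5``      SBP_low / SBP_high / Scarpelli literature-replication features

The Siclari hot-zone list and the exact RMS variants are documented
emulations (the original supplementary definitions are configurable here,
not canonical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .psg_data import PsgCase, channels_at

__all__ = [
    "PsdEstimate", "FeatureMatrix", "FEATURE_SETS",
    "welch_log_psd", "extract_feature_set", "extract_features",
    "permutation_entropy", "approximate_entropy",
    "assemble_step2_features", "extract_step5_features", "studentize",
]

#: classical EEG bands, Hz (upper edge of the last band is inclusive)
POWER_BANDS = {
    "delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0),
    "sigma": (12.0, 15.0), "beta": (15.0, 30.0), "gamma": (30.0, 49.5),
}

#: hot-zone emulation electrode groups (names, not position tags)
HOT_ZONE_GROUPS = {
    "occipital": ("O1", "Oz", "O2"),
    "temporal": ("FT7", "FT8", "T7", "T8"),
    "posterior-temporal": ("P7", "P8"),
}
LATERAL_FRONTAL = ("F7", "F8")
LEFT_FRONTO_TEMPORAL = ("F7", "FT7", "T7")

SICLARI_LOW = (1.0, 12.0)
SICLARI_HIGH = (18.0, 50.0)


@dataclass
class PsdEstimate:
    """Per-channel Welch PSD: ``psd`` is (n_channels, n_bins) in µV²/Hz."""

    channel_names: list[str]
    freqs: np.ndarray
    psd: np.ndarray
    window_s: float
    overlap: float
    log: bool = False

    def take_log(self) -> "PsdEstimate":
        if self.log:
            return self
        return PsdEstimate(self.channel_names, self.freqs, np.log(self.psd),
                           self.window_s, self.overlap, log=True)


def _welch(x: np.ndarray, rate: float, window_s: float, overlap: float,
           ) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(window_s * rate))
    if nperseg < 2:
        raise ValueError("Welch window shorter than 2 samples")
    if x.shape[-1] < nperseg:
        raise ValueError("Welch window longer than the record")
    if not 0 < overlap < 1:
        raise ValueError("overlap must be in (0, 1)")
    return signal.welch(x, fs=rate, window="hann", nperseg=nperseg,
                        noverlap=int(round(overlap * nperseg)),
                        detrend="constant", scaling="density")


def welch_log_psd(case: PsgCase, window_s: float = 2.0, overlap: float = 0.8,
                  fmax: float | None = None) -> PsdEstimate:
    """Welch PSD of every channel; Parseval-consistent density scaling."""
    freqs, psd = _welch(case.samples, case.rate, window_s, overlap)
    if fmax is not None:
        keep = freqs <= fmax
        freqs, psd = freqs[keep], psd[:, keep]
    return PsdEstimate([c.name for c in case.channels], freqs, psd, window_s, overlap)


def _eeg_psd(case: PsgCase, window_s: float = 2.0, overlap: float = 0.8,
             tail_s: float | None = None) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(names, freqs, psd) over EEG channels, optionally on the final tail_s seconds."""
    idx = channels_at(case.channels, modality="EEG")
    x = case.samples[idx]
    if tail_s is not None:
        x = x[:, -int(round(tail_s * case.rate)):]
    freqs, psd = _welch(x, case.rate, window_s, overlap)
    return [case.channels[i].name for i in idx], freqs, psd


def _band_log_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float,
                    ) -> np.ndarray:
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ValueError(f"no PSD bins inside band {lo}-{hi} Hz")
    return np.log(psd[..., band].mean(axis=-1))


# ---------------------------------------------------------------------------
# entropies

def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Shannon entropy (nats) of the ordinal-pattern distribution.

    Ties are broken by order of occurrence (stable sort).  Ranges over
    [0, ln(order!)]; a monotone ramp gives 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < order * delay + 1:
        raise ValueError(f"need at least {order * delay + 1} samples for order={order}, "
                         f"delay={delay}")
    n_win = x.size - (order - 1) * delay
    idx = np.arange(n_win)[:, None] + delay * np.arange(order)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = patterns.dot(order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) = Phi_m - Phi_{m+1}, Chebyshev distance, self-matches included.

    ``r`` defaults to 0.2 x SD(x); a zero-variance input returns 0 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"need more than {m + 1} samples")
    sd = x.std()
    if r is None:
        r = 0.2 * sd
    if sd == 0 or r <= 0:
        return 0.0

    diff = np.abs(x[:, None] - x[None, :]).astype(np.float32)

    def phi(mm: int) -> float:
        n_t = x.size - mm + 1
        d = diff[:n_t, :n_t].copy()
        for k in range(1, mm):
            np.maximum(d, diff[k:k + n_t, k:k + n_t], out=d)
        counts = (d <= r).sum(axis=1)
        return float(np.mean(np.log(counts / n_t)))

    return phi(m) - phi(m + 1)


def _decimate_for_apen(x: np.ndarray, rate: float, target: float = 64.0) -> np.ndarray:
    q = int(round(rate / target))
    return signal.decimate(x, q, zero_phase=True) if q > 1 else x


# ---------------------------------------------------------------------------
# individual feature sets

def _powerfine(case: PsgCase) -> pd.Series:
    names, freqs, psd = _eeg_psd(case)
    keep = (freqs >= 0.5) & (freqs <= 49.5)
    fsel = freqs[keep]
    assert fsel.size == 99, f"PowerFine expects 99 bins, got {fsel.size}"
    vals = np.log(psd[:, keep])
    index = [f"powerfine/{ch}/{f:g}Hz" for ch in names for f in fsel]
    return pd.Series(vals.ravel(), index=index)


def _powerband(case: PsgCase) -> pd.Series:
    names, freqs, psd = _eeg_psd(case)
    out = {}
    for band, (lo, hi) in POWER_BANDS.items():
        sel = (freqs >= lo) & ((freqs < hi) if band != "gamma" else (freqs <= hi))
        vals = np.log(psd[:, sel].mean(axis=1))
        for ch, v in zip(names, vals):
            out[f"powerband/{ch}/{band}"] = v
    return pd.Series(out)


def _autocorr(case: PsgCase) -> pd.Series:
    out = {}
    for i in channels_at(case.channels, modality="EEG"):
        x = case.samples[i] - case.samples[i].mean()
        n = x.size
        acf = signal.fftconvolve(x, x[::-1], mode="full")[n - 1:]
        acf /= acf[0] if acf[0] > 0 else 1.0
        below = np.nonzero(acf < 1.0 / np.e)[0]
        decay = (below[0] if below.size else n) / case.rate
        zeros = np.nonzero(acf <= 0)[0]
        first_zero = (zeros[0] if zeros.size else n) / case.rate
        ch = case.channels[i].name
        out[f"autocorr/{ch}/decay_1e"] = decay
        out[f"autocorr/{ch}/first_zero"] = first_zero
        out[f"autocorr/{ch}/lag1"] = acf[1]
    return pd.Series(out)


def _permen(case: PsgCase) -> pd.Series:
    return pd.Series({
        f"permen/{case.channels[i].name}": permutation_entropy(case.samples[i], 3, 1)
        for i in channels_at(case.channels, modality="EEG")
    })


def _apen(case: PsgCase) -> pd.Series:
    return pd.Series({
        f"apen/{case.channels[i].name}":
            approximate_entropy(_decimate_for_apen(case.samples[i], case.rate))
        for i in channels_at(case.channels, modality="EEG")
    })


def _quarter_rms(case: PsgCase, modality: str) -> pd.Series:
    prefix = modality.lower() + "rms"
    out = {}
    for i in channels_at(case.channels, modality=modality):
        quarters = np.array_split(case.samples[i], 4)
        for q, seg in enumerate(quarters, start=1):
            out[f"{prefix}/{case.channels[i].name}/q{q}"] = float(np.sqrt((seg ** 2).mean()))
    return pd.Series(out)


def _siclari(case: PsgCase) -> pd.Series:
    """11 hot-zone emulation features: regional log band power over final windows."""
    out = {}
    for tail in (20.0, 40.0, 60.0):
        names, freqs, psd = _eeg_psd(case, tail_s=tail)
        name_idx = {n: j for j, n in enumerate(names)}
        po = [name_idx[case.channels[i].name]
              for i in channels_at(case.channels, position="parieto-occipital")]
        fr = [name_idx[case.channels[i].name]
              for i in channels_at(case.channels, position="frontal")]
        if tail == 20.0:
            out["siclari/whole/low/20s"] = float(
                _band_log_power(freqs, psd, *SICLARI_LOW).mean())
            out["siclari/whole/high/20s"] = float(
                _band_log_power(freqs, psd, *SICLARI_HIGH).mean())
            for zone, chs in HOT_ZONE_GROUPS.items():
                zi = [name_idx[c] for c in chs]
                out[f"siclari/{zone}/high/20s"] = float(
                    _band_log_power(freqs, psd[zi], *SICLARI_HIGH).mean())
        out[f"siclari/parieto-occipital/low/{tail:g}s"] = float(
            _band_log_power(freqs, psd[po], *SICLARI_LOW).mean())
        out[f"siclari/frontal/high/{tail:g}s"] = float(
            _band_log_power(freqs, psd[fr], *SICLARI_HIGH).mean())
    return pd.Series(out)


def _log_spaced_edges(n_fine: int = 99, n_bins: int = 19) -> np.ndarray:
    """Strictly increasing integer edges over fine-bin indices, near-geometric."""
    edges = np.round(np.geomspace(1, n_fine + 1, n_bins + 1)).astype(int)
    for i in range(1, edges.size):  # repair rounding collisions
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] + 1
    overflow = edges[-1] - (n_fine + 1)
    if overflow > 0:
        for i in range(edges.size - 1, 0, -1):
            edges[i] = min(edges[i], n_fine + 1 - (edges.size - 1 - i))
    return edges


def _scalp_log_bins(case: PsgCase) -> pd.Series:
    """19 log-spaced bins of the scalp-average log PSD (0.5–49.5 Hz)."""
    _, freqs, psd = _eeg_psd(case)
    keep = (freqs >= 0.5) & (freqs <= 49.5)
    scalp = np.log(psd[:, keep]).mean(axis=0)
    fsel = freqs[keep]
    edges = _log_spaced_edges(n_fine=scalp.size, n_bins=19)
    out = {}
    for b in range(19):
        lo, hi = edges[b] - 1, edges[b + 1] - 1
        out[f"scalp/bin{b + 1:02d}/{fsel[lo]:g}-{fsel[hi - 1]:g}Hz"] = float(
            scalp[lo:hi].mean())
    return pd.Series(out)


def _halfminute_rms_percentiles(case: PsgCase, modality: str) -> pd.Series:
    """Per 30-s segment: percentiles of consecutive 1-s RMS over both channels."""
    idx = channels_at(case.channels, modality=modality)
    if not idx:
        raise ValueError(f"case {case.case_id} lacks {modality} channels")
    x = case.samples[idx]
    spw = int(round(case.rate))
    n_windows = x.shape[1] // spw
    rms = np.sqrt((x[:, :n_windows * spw].reshape(len(idx), n_windows, spw) ** 2)
                  .mean(axis=(0, 2)))
    out = {}
    half = n_windows // 2
    for s, seg in enumerate((rms[:half], rms[half:]), start=1):
        for p in (0, 25, 50, 75, 100):
            out[f"{modality.lower()}/seg{s}/p{p}"] = float(np.percentile(seg, p))
    return pd.Series(out)


def assemble_step2_features(case: PsgCase) -> pd.Series:
    """The 50-feature composite set: 19 scalp PSD + 11 Siclari + 10 EMG + 10 EOG."""
    parts = [
        _scalp_log_bins(case),
        _siclari(case),
        _halfminute_rms_percentiles(case, "EMG"),
        _halfminute_rms_percentiles(case, "EOG"),
    ]
    vec = pd.concat(parts)
    assert vec.size == 50, f"Step-2 set must have 50 features, got {vec.size}"
    return vec


def extract_step5_features(case: PsgCase) -> pd.Series:
    """Literature-replication features: SBP_low, SBP_high, Scarpelli.

    SBP_low: mean log power 1–4 Hz over parieto-occipital electrodes (lower
    with dreaming); SBP_high: mean log power 20–50 Hz over parieto-occipital +
    lateral-frontal + temporal electrodes (higher with dreaming); Scarpelli:
    mean log power 0.50–4.75 Hz over left fronto-temporal electrodes (lower
    with dreaming).
    """
    names, freqs, psd = _eeg_psd(case)
    name_idx = {n: j for j, n in enumerate(names)}
    po = [name_idx[case.channels[i].name]
          for i in channels_at(case.channels, position="parieto-occipital")]
    temporal = [name_idx[case.channels[i].name]
                for i in channels_at(case.channels, position="temporal")]
    lf = [name_idx[c] for c in LATERAL_FRONTAL if c in name_idx]
    lft = [name_idx[c] for c in LEFT_FRONTO_TEMPORAL if c in name_idx]
    for grp, label in ((po, "parieto-occipital"), (lf, "lateral-frontal"),
                       (temporal, "temporal"), (lft, "left fronto-temporal")):
        if not grp:
            raise ValueError(f"montage lacks {label} electrodes")
    sbp_high_idx = sorted(set(po) | set(lf) | set(temporal))
    return pd.Series({
        "step5/SBP_low": float(_band_log_power(freqs, psd[po], 1.0, 4.0).mean()),
        "step5/SBP_high": float(_band_log_power(freqs, psd[sbp_high_idx], 20.0, 50.0).mean()),
        "step5/Scarpelli": float(_band_log_power(freqs, psd[lft], 0.50, 4.75).mean()),
    })


FEATURE_SETS = {
    "PowerFine": _powerfine,
    "PowerBand": _powerband,
    "AutoCorr": _autocorr,
    "PermEn": _permen,
    "ApEn": _apen,
    "EogRms": lambda c: _quarter_rms(c, "EOG"),
    "EmgRms": lambda c: _quarter_rms(c, "EMG"),
    "Siclari": _siclari,
    "Step2_50": assemble_step2_features,
    "Step5": extract_step5_features,
}


def extract_feature_set(case: PsgCase, name: str) -> pd.Series:
    """Named feature vector of one case; deterministic in the case contents."""
    try:
        fn = FEATURE_SETS[name]
    except KeyError:
        raise ValueError(f"unknown feature set {name!r}; "
                         f"choose from {sorted(FEATURE_SETS)}") from None
    return fn(case)


# ---------------------------------------------------------------------------
# feature matrices

@dataclass
class FeatureMatrix:
    """Cases x named features with transform provenance."""

    df: pd.DataFrame
    transforms: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.df.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def case_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()


def extract_features(cases, name: str) -> FeatureMatrix:
    rows = {c.case_id: extract_feature_set(c, name) for c in cases}
    df = pd.DataFrame(rows).T
    df.index.name = "case_id"
    transforms = frozenset({"log"}) if name not in ("EogRms", "EmgRms") else frozenset()
    return FeatureMatrix(df, transforms)


def studentize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Center and scale each feature to mean 0, sample SD 1 across cases.

    Idempotent; a zero-variance feature becomes all-zeros with a warning.
    """
    if len(matrix.df) < 2:
        raise ValueError("studentization needs at least 2 cases")
    vals = matrix.df.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance feature(s) set to zero "
                      "during studentization")
        sd = np.where(dead, 1.0, sd)
    out = (vals - mean) / sd
    out[:, dead] = 0.0
    df = pd.DataFrame(out, index=matrix.df.index, columns=matrix.df.columns)
    return FeatureMatrix(df, matrix.transforms | {"studentized"})
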