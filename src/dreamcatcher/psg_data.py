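"""Domain types and I/O for blinded 1-minute polysomnogram cases.

A *case* is a 60-s multichannel recording (EEG + EOG + EMG) handed to the
analysis stages under a blinded label.  The blinding key maps each case to
participant / condition / pair / participant-condition group labels that are
revealed incrementally, one layer per classification step; the mapping from
condition labels (C1/C2) to condition *names* (dreamful/dreamless) is never
part of the key and lives only in the truth table kept by the scoring oracle.

On-disk formats: EDF (16-bit quantized, the polysomnography standard; read
back through :mod:`mne`) and a lossless ``.npz`` + JSON-header fallback used
when tests need exact float round-trips.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelInfo",
    "PsgCase",
    "BlindKey",
    "CohortError",
    "STANDARD_EEG_MONTAGE",
    "standard_channels",
    "channels_at",
    "apply_blinding",
    "reveal",
    "REVEAL_SCHEDULE",
    "read_cohort",
    "write_cohort",
]

CASE_DURATION_S = 60.0

#: 25-channel 10-10 subset used for the standard cohort, with nominal scalp
#: position tags.  The regional feature groups (hot-zone emulation, lateral
#: frontal, left fronto-temporal) are derived from channel names, not tags.
STANDARD_EEG_MONTAGE: tuple[tuple[str, str], ...] = (
    ("Fp1", "frontal"), ("Fp2", "frontal"),
    ("F7", "frontal"), ("F3", "frontal"), ("Fz", "frontal"),
    ("F4", "frontal"), ("F8", "frontal"),
    ("FT7", "temporal"), ("FC3", "central"), ("FCz", "central"),
    ("FC4", "central"), ("FT8", "temporal"),
    ("T7", "temporal"), ("C3", "central"), ("Cz", "central"),
    ("C4", "central"), ("T8", "temporal"),
    ("P7", "temporal"), ("P3", "parieto-occipital"), ("Pz", "parieto-occipital"),
    ("P4", "parieto-occipital"), ("P8", "temporal"),
    ("O1", "parieto-occipital"), ("Oz", "parieto-occipital"), ("O2", "parieto-occipital"),
)

EOG_CHANNELS = ("EOG1", "EOG2")
EMG_CHANNELS = ("EMG1", "EMG2")


class CohortError(ValueError):
    """Invariant violation in a case, cohort or blinding key."""


@dataclass(frozen=True)
class ChannelInfo:
    """One recording channel: label, modality and nominal scalp position."""

    name: str
    modality: str  # "EEG" | "EOG" | "EMG"
    position: str | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("EEG", "EOG", "EMG"):
            raise CohortError(f"unknown modality {self.modality!r} for channel {self.name}")
        if self.modality == "EEG" and self.position is None:
            raise CohortError(f"EEG channel {self.name} lacks a position tag")


def standard_channels() -> list[ChannelInfo]:
    """The 29-channel standard montage: 25 EEG + 2 EOG + 2 EMG."""
    chans = [ChannelInfo(n, "EEG", pos) for n, pos in STANDARD_EEG_MONTAGE]
    chans += [ChannelInfo(n, "EOG") for n in EOG_CHANNELS]
    chans += [ChannelInfo(n, "EMG") for n in EMG_CHANNELS]
    return chans


def channels_at(channels: Sequence[ChannelInfo], *, modality: str | None = None,
                position: str | None = None, names: Iterable[str] | None = None) -> list[int]:
    """Indices of channels matching the given modality/position/name filters."""
    name_set = set(names) if names is not None else None
    out = []
    for i, ch in enumerate(channels):
        if modality is not None and ch.modality != modality:
            continue
        if position is not None and ch.position != position:
            continue
        if name_set is not None and ch.name not in name_set:
            continue
        out.append(i)
    return out


@dataclass
class PsgCase:
    """One blinded recording: ``samples`` is (n_channels, n_samples) in microvolts."""

    case_id: str
    channels: list[ChannelInfo]
    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise CohortError(
                f"case {self.case_id}: samples shape {self.samples.shape} does not "
                f"match {len(self.channels)} channels")
        if not np.isfinite(self.samples).all():
            raise CohortError(f"case {self.case_id}: non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def validate_standard(self) -> None:
        """Enforce the standard-cohort invariants: 60 s, 25 EEG + 2 EOG + 2 EMG."""
        counts = {m: sum(c.modality == m for c in self.channels) for m in ("EEG", "EOG", "EMG")}
        expected = {"EEG": 25, "EOG": 2, "EMG": 2}
        missing = {m for m, n in expected.items() if counts[m] != n}
        if missing:
            raise CohortError(
                f"case {self.case_id}: channel counts {counts} "
                f"(expected {expected}; off for {sorted(missing)})")
        if abs(self.duration - CASE_DURATION_S) > 1.0 / self.rate:
            raise CohortError(
                f"case {self.case_id}: duration {self.duration:.3f} s violates the "
                f"{CASE_DURATION_S:.0f}-s case invariant")

    def eeg(self) -> np.ndarray:
        return self.samples[channels_at(self.channels, modality="EEG")]


# ---------------------------------------------------------------------------
# Blinding key

#: Cumulative disclosure schedule: which key columns each step may see.
REVEAL_SCHEDULE: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("pair",),
    3: ("pair", "participant"),
    4: ("pair", "participant", "participant_condition"),
    5: ("pair", "participant", "participant_condition", "condition"),
}


class BlindKey:
    """Blinded grouping labels for the 54-case cohort.

    Holds only the neutral labels (S1–S9, C1–C2, G01–G18, P01–P27); the
    dreamful/dreamless name of C1/C2 is deliberately not representable here.
    """

    COLUMNS = ("case_id", "pair", "participant", "participant_condition", "condition")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise CohortError(f"blinding key missing columns {sorted(missing)}")
        self.table = table.loc[:, list(self.COLUMNS)].sort_values("case_id").reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        t = self.table
        card = {
            "case_id": 54, "participant": 9, "condition": 2,
            "participant_condition": 18, "pair": 27,
        }
        for col, n in card.items():
            got = t[col].nunique()
            if len(t) != 54:
                raise CohortError(f"blinding key has {len(t)} rows, expected 54")
            if got != n:
                raise CohortError(f"blinding key column {col!r} has {got} labels, expected {n}")
        for s, grp in t.groupby("participant"):
            if len(grp) != 6 or any(grp.groupby("condition").size() != 3):
                raise CohortError(f"participant {s} does not own 3 cases per condition")
        for p, grp in t.groupby("pair"):
            if len(grp) != 2 or grp["condition"].nunique() != 2 or grp["participant"].nunique() != 1:
                raise CohortError(f"pair {p} is not one case of each condition from one participant")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def case_ids(self) -> list[str]:
        return list(self.table["case_id"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BlindKey":
        return cls(pd.read_csv(path))


def reveal(key: BlindKey, step: int) -> pd.DataFrame:
    """The step-visible view of the key per the disclosure schedule.

    Returns a frame with ``case_id`` plus exactly the columns disclosed at
    ``step``.  No view at any step carries condition *names*.
    """
    if step not in REVEAL_SCHEDULE:
        raise CohortError(f"step must be 1..5, got {step}")
    cols = ["case_id", *REVEAL_SCHEDULE[step]]
    return key.table.loc[:, cols].copy()


def apply_blinding(true_metadata: pd.DataFrame, seed: int) -> tuple[BlindKey, pd.DataFrame]:
    """Randomly blind a balanced 9x3x2 cohort, emulating the labeling scheme.

    ``true_metadata`` needs columns ``recording`` (original identifier),
    ``participant``, ``session`` and ``condition`` (names, e.g.
    dreamful/dreamless).  Returns the blinding key and a truth table mapping
    each blinded ``case_id`` back to its real metadata; the truth table is for
    the scoring oracle only and must never reach an analysis stage.
    """
    t = true_metadata.reset_index(drop=True)
    needed = {"recording", "participant", "session", "condition"}
    if not needed <= set(t.columns):
        raise CohortError(f"true metadata must have columns {sorted(needed)}")
    parts = sorted(t["participant"].unique())
    conds = sorted(t["condition"].unique())
    sessions = sorted(t["session"].unique())
    if len(t) != 54 or len(parts) != 9 or len(conds) != 2 or len(sessions) != 3:
        raise CohortError(
            f"metadata is not a balanced 9 participants x 3 sessions x 2 conditions "
            f"design ({len(t)} rows, {len(parts)} participants, {len(sessions)} sessions, "
            f"{len(conds)} conditions)")
    sizes = t.groupby(["participant", "session", "condition"]).size()
    if len(sizes) != 54 or (sizes != 1).any():
        raise CohortError("metadata cells are not singletons: unbalanced design")

    rng = np.random.default_rng(seed)
    case_ids = [f"ID{i + 1:02d}" for i in range(54)]
    order = rng.permutation(54)
    s_map = dict(zip(rng.permutation(parts), [f"S{i + 1}" for i in range(9)]))
    c_map = dict(zip(rng.permutation(conds), ["C1", "C2"]))
    pc_cells = [(p, c) for p in parts for c in conds]
    g_map = dict(zip(map(tuple, rng.permutation(pc_cells)),
                     [f"G{i + 1:02d}" for i in range(18)]))
    pair_cells = [(p, s) for p in parts for s in sessions]
    p_map = dict(zip(map(tuple, rng.permutation(np.array(pair_cells, dtype=object))),
                     [f"P{i + 1:02d}" for i in range(27)]))

    rows, truth_rows = [], []
    for case_id, idx in zip(case_ids, order):
        rec = t.iloc[int(idx)]
        part, sess, cond = rec["participant"], rec["session"], rec["condition"]
        rows.append({
            "case_id": case_id,
            "pair": p_map[(part, sess)],
            "participant": s_map[part],
            "participant_condition": g_map[(part, cond)],
            "condition": c_map[cond],
        })
        truth_rows.append({
            "case_id": case_id, "recording": rec["recording"],
            "participant": part, "session": sess, "condition": cond,
        })
    key = BlindKey(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows).sort_values("case_id").reset_index(drop=True)
    return key, truth


# ---------------------------------------------------------------------------
# On-disk cohort I/O

_EDF_DIG_MAX = 32767


def _edf_label(ch: ChannelInfo) -> str:
    return f"{ch.modality} {ch.name}"


def write_case_edf(case: PsgCase, path: str | Path) -> None:
    """Write one case as EDF (one 1-s data record per second, 16-bit).

    Physical units are microvolts; each channel gets a symmetric physical
    range covering its extremes, so the quantization step is
    ``2*max|x| / 65535`` per channel.
    """
    path = Path(path)
    n_ch = len(case.channels)
    spr = int(round(case.rate))  # samples per 1-s record
    if abs(case.rate - spr) > 1e-9:
        raise CohortError(f"case {case.case_id}: EDF writer needs an integer rate, got {case.rate}")
    n_rec = case.n_samples // spr
    if n_rec * spr != case.n_samples:
        raise CohortError(f"case {case.case_id}: sample count not a whole number of seconds")

    phys_max = np.maximum(np.abs(case.samples).max(axis=1), 1e-6)
    scale = _EDF_DIG_MAX / phys_max
    digital = np.round(case.samples * scale[:, None]).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {case.case_id}", 80),
        pad(f"Startdate 01-JAN-2000 {case.case_id} X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8),
        pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = [
        [pad(_edf_label(ch), 16) for ch in case.channels],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{-m:.6g}"[:8], 8) for m in phys_max],
        [pad(f"{m:.6g}"[:8], 8) for m in phys_max],
        [pad(str(-_EDF_DIG_MAX), 8)] * n_ch,
        [pad(str(_EDF_DIG_MAX), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(spr), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as f:
        f.write(header)
        for fld in fields:
            f.writelines(fld)
        # records: per second, channel-major int16 blocks
        recs = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        f.write(np.ascontiguousarray(recs).tobytes())


def read_case_edf(path: str | Path) -> PsgCase:
    """Read one case from EDF via mne; samples returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    chans, rows = [], []
    for label in raw.ch_names:
        m = re.match(r"(EEG|EOG|EMG)\s+(\S+)", label)
        if not m:
            raise CohortError(f"{path}: channel label {label!r} does not parse into a modality")
        modality, name = m.groups()
        pos = dict(STANDARD_EEG_MONTAGE).get(name) if modality == "EEG" else None
        if modality == "EEG" and pos is None:
            raise CohortError(f"{path}: EEG channel {name!r} is not in the standard montage")
        chans.append(ChannelInfo(name, modality, pos))
        rows.append(raw.get_data(picks=[label])[0])
    case_id = Path(path).stem
    # mne rescales 'uV'-dimensioned channels to volts
    samples = np.vstack(rows) * 1e6
    return PsgCase(case_id, chans, samples, float(raw.info["sfreq"]))


def write_case_npz(case: PsgCase, path: str | Path) -> None:
    """Lossless fallback: float64 samples + JSON channel header."""
    header = {
        "case_id": case.case_id,
        "rate": case.rate,
        "channels": [
            {"name": c.name, "modality": c.modality, "position": c.position}
            for c in case.channels
        ],
    }
    np.savez_compressed(path, samples=case.samples,
                        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8))


def read_case_npz(path: str | Path) -> PsgCase:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        samples = z["samples"]
    chans = [ChannelInfo(c["name"], c["modality"], c["position"]) for c in header["channels"]]
    return PsgCase(header["case_id"], chans, samples, float(header["rate"]))


def write_cohort(cases: Sequence[PsgCase], key: BlindKey, path: str | Path,
                 fmt: str = "edf") -> None:
    """Write a 54-case cohort (one file per case) plus the blinding-key CSV."""
    if len(cases) != 54:
        raise CohortError(f"cohort has {len(cases)} cases, expected 54")
    if sorted(c.case_id for c in cases) != sorted(key.case_ids):
        raise CohortError("cohort case_ids do not match blinding key")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for case in cases:
        case.validate_standard()
        if fmt == "edf":
            write_case_edf(case, path / f"{case.case_id}.edf")
        elif fmt == "npz":
            write_case_npz(case, path / f"{case.case_id}.npz")
        else:
            raise CohortError(f"unknown cohort format {fmt!r}")
    key.to_csv(path / "blinding_key.csv")


def read_cohort(path: str | Path) -> list[PsgCase]:
    """Read all cases under ``path`` (EDF or npz), sorted by case_id.

    Every case is validated against the standard-cohort invariants; failures
    name the offending case and channel set.
    """
    path = Path(path)
    files = sorted(path.glob("*.edf")) + sorted(path.glob("*.npz"))
    if not files:
        raise CohortError(f"no case files under {path}")
    cases = []
    for f in files:
        case = read_case_edf(f) if f.suffix == ".edf" else read_case_npz(f)
        case.validate_standard()
        rates = {case.rate}
        if len(rates) != 1:
            raise CohortError(f"case {case.case_id}: inconsistent rates {rates}")
        cases.append(case)
    cases.sort(key=lambda c: c.case_id)
    return cases
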