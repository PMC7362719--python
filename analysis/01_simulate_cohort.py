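"""Generate and persist one blinded synthetic cohort.

Creates the 54-case cohort (9 participants x 3 sessions x 2 conditions)
under the default study conditions, blinds it, and writes:

  scratch/cohort/ID01.edf ... ID54.edf   the blinded recordings
  scratch/cohort/blinding_key.csv        the grouping labels (no condition names)
  scratch/cohort_truth.csv               the sealed truth (data-team only)
  results/cohort_summary.csv             per-case summary statistics

The truth file never enters the analysis scripts 02/03; it is read only by
the scoring oracle.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from dreamcatcher import CohortConfig, synth_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    cfg = CohortConfig(seed=seed, rate=128.0)
    print(f"simulating cohort: 9 participants x 3 sessions x 2 conditions, "
          f"rate {cfg.rate:g} Hz, seed {seed}")
    cases, truth, key = synth_cohort(cfg)

    out = ROOT / "scratch" / "cohort"
    write_cohort(cases, key, out, fmt="edf")
    truth.to_csv(ROOT / "scratch" / "cohort_truth.csv", index=False)

    summary = pd.DataFrame({
        "case_id": [c.case_id for c in cases],
        "eeg_rms_uv": [float(np.sqrt((c.eeg() ** 2).mean())) for c in cases],
        "duration_s": [c.duration for c in cases],
    })
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "cohort_summary.csv", index=False)
    print(f"wrote {len(cases)} blinded cases to {out}")
    print(f"EEG RMS across cases: {summary['eeg_rms_uv'].mean():.1f} "
          f"+- {summary['eeg_rms_uv'].std():.1f} uV")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
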