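import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dreamcatcher.psg_data import ChannelInfo, PsgCase, standard_channels
from dreamcatcher.synthetic_psg import CohortConfig, synth_cohort

# tests run at 128 Hz: cheapest rate that still carries the 50-Hz band with
# 0.5-Hz Welch resolution
RATE = 128.0


def make_case(samples=None, case_id="X", rate=RATE, duration=60.0, rng=None):
    """A standard-montage case; white-noise samples unless given."""
    chans = standard_channels()
    n = int(duration * rate)
    if samples is None:
        rng = rng or np.random.default_rng(0)
        samples = rng.standard_normal((len(chans), n))
    return PsgCase(case_id, chans, np.asarray(samples, dtype=float), rate)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort under the standard study conditions (reduced sampling rate)."""
    return synth_cohort(CohortConfig(seed=11, rate=RATE))
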