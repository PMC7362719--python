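"""Synthetic 54-case polysomnogram cohort generator.

Emulates the statistical structure the blinded analysis assumes rather than
sleep physiology: each EEG channel is 1/f^alpha colored noise with a
participant-specific amplitude offset and spectral exponent, plus sleep
spindles (12–15 Hz) and slow-oscillation bursts; EOG carries slow eye-movement
events and frontal EEG crosstalk; EMG is high-frequency-weighted noise.

The dreamful-vs-dreamless contrast is injected purely spectrally, as
multiplicative band-power factors (low band 0.5–4 Hz raised in dreamless
cases, high band 18–50 Hz raised in dreamful cases), weighted per scalp
region.  The factors are applied to the composite EEG signal in the frequency
domain, so a Welch band-power estimate recovers the configured log-ratio
directly.  The true effect size of NREM dreaming is unknown (the study this
emulates found none), so the effect here is a free parameter, not a claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .psg_data import (BlindKey, CohortError, PsgCase, apply_blinding,
                       channels_at, standard_channels)

__all__ = ["CohortConfig", "ParticipantState", "synth_case", "synth_cohort",
           "DREAMFUL", "DREAMLESS"]

DREAMFUL = "dreamful"
DREAMLESS = "dreamless"

LOW_BAND = (0.5, 4.0)    # Hz, raised in dreamless cases
HIGH_BAND = (18.0, 50.0)  # Hz, raised in dreamful cases


def _default_low_weights() -> dict[str, float]:
    # low-frequency (dreamless-elevated) effect, strongest parieto-occipitally
    return {"parieto-occipital": 1.0, "central": 0.6, "temporal": 0.6, "frontal": 0.4}


def _default_high_weights() -> dict[str, float]:
    # high-frequency (dreamful-elevated) effect, strongest frontally
    return {"frontal": 1.0, "parieto-occipital": 0.8, "temporal": 0.6, "central": 0.5}


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the standard study conditions.

    ``participant_effect_sd`` is the between-participant SD of the EEG
    log-power offset (natural-log µV²/Hz scale); at the default 0.5 the
    participant random effect dominates any modest condition effect, which is
    the regime the blinded analysis had to operate in.  The condition ratios
    are multiplicative band-power factors (>= 1; 1 means no effect).  With
    participant variability off, ``condition_delta_ratio = 1.4`` yields a
    per-case delta-band log-power Cohen's d near 1.5.
    """

    seed: int = 0
    rate: float = 256.0
    n_participants: int = 9
    sessions_per_condition: int = 3
    duration_s: float = 60.0
    rms_uv: float = 30.0                      # target background RMS, microvolts
    participant_effect_sd: float = 0.5        # log-power scale
    case_effect_sd: float = 0.2               # within-participant between-case SD
    spectral_exponent_mean: float = 2.0       # 1/f^alpha background
    spectral_exponent_sd: float = 0.2
    condition_delta_ratio: float = 1.4        # dreamless/dreamful low-band power, >= 1
    condition_high_ratio: float = 1.3         # dreamful/dreamless high-band power, >= 1
    low_region_weights: dict[str, float] = field(default_factory=_default_low_weights)
    high_region_weights: dict[str, float] = field(default_factory=_default_high_weights)
    spindle_density: float = 2.0              # events per minute
    so_burst_rate: float = 6.0                # slow-oscillation bursts per minute
    eog_event_rate: float = 3.0               # slow eye movements per minute
    emg_tonus_level: float = 3.0              # EMG RMS, microvolts
    noise_sd: float = 1.0                     # additive sensor noise, microvolts

    def validate(self) -> None:
        if self.condition_delta_ratio < 1 or self.condition_high_ratio < 1:
            raise CohortError("condition ratios must be >= 1")
        if min(self.participant_effect_sd, self.spectral_exponent_sd,
               self.noise_sd, self.emg_tonus_level) < 0:
            raise CohortError("SDs and levels must be >= 0")
        if self.rate <= 2 * HIGH_BAND[1]:
            raise CohortError(f"rate {self.rate} cannot carry the {HIGH_BAND[1]} Hz effect band")


@dataclass(frozen=True)
class ParticipantState:
    """Participant-level random effects, drawn once per participant."""

    participant: str
    amp_log_offset: float   # log-power offset
    exponent: float         # spectral exponent alpha


def draw_participant_states(config: CohortConfig, rng: np.random.Generator,
                            ) -> list[ParticipantState]:
    return [
        ParticipantState(
            participant=f"p{i + 1}",
            amp_log_offset=rng.normal(0.0, config.participant_effect_sd),
            exponent=rng.normal(config.spectral_exponent_mean, config.spectral_exponent_sd),
        )
        for i in range(config.n_participants)
    ]


def _colored_noise(n: int, rate: float, exponent: float, rms: float,
                   rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha noise by spectral shaping of white noise; zero-mean, given RMS."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    # flatten below 0.5 Hz so the DC end stays finite
    shape[nz] = np.maximum(freqs[nz], 0.5) ** (-exponent / 2.0)
    x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_gain(x: np.ndarray, rate: float, gains: list[tuple[float, float, float]],
               ) -> np.ndarray:
    """Multiply signal power by ``gain`` inside each (lo, hi) frequency band."""
    n = x.size
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    for lo, hi, gain in gains:
        if gain != 1.0:
            band = (freqs >= lo) & (freqs <= hi)
            X[band] *= np.sqrt(gain)
    return np.fft.irfft(X, n)


def _gauss_burst(n: int, rate: float, t0: float, dur: float, freq: float,
                 phase: float) -> np.ndarray:
    t = np.arange(n) / rate
    env = np.exp(-0.5 * ((t - t0) / (dur / 4.0)) ** 2)
    return env * np.sin(2 * np.pi * freq * t + phase)


def synth_case(config: CohortConfig, participant_state: ParticipantState,
               condition: str, session: int, rng: np.random.Generator) -> PsgCase:
    """Generate one 60-s case for the given participant/condition/session.

    Deterministic given the rng state.  The returned case carries no
    condition information in any metadata field.
    """
    config.validate()
    if condition not in (DREAMFUL, DREAMLESS):
        raise CohortError(f"unknown condition {condition!r}")
    rate = config.rate
    n = int(round(config.duration_s * rate))
    channels = standard_channels()
    # participant and case random effects on the log-power scale -> amplitude
    case_offset = rng.normal(0.0, config.case_effect_sd)
    amp = float(np.exp((participant_state.amp_log_offset + case_offset) / 2.0))
    samples = np.zeros((len(channels), n))

    eeg_idx = channels_at(channels, modality="EEG")

    # common oscillatory events (spindles, slow-oscillation bursts) with
    # per-channel gains, so channels are realistically correlated
    n_spindles = rng.poisson(config.spindle_density * config.duration_s / 60.0)
    spindles = [(rng.uniform(0, config.duration_s), rng.uniform(0.5, 1.5),
                 rng.uniform(12.0, 15.0), rng.uniform(0, 2 * np.pi),
                 rng.uniform(5.0, 12.0)) for _ in range(n_spindles)]
    n_so = rng.poisson(config.so_burst_rate * config.duration_s / 60.0)
    so_bursts = [(rng.uniform(0, config.duration_s), rng.uniform(1.0, 2.5),
                  rng.uniform(0.6, 1.2), rng.uniform(0, 2 * np.pi),
                  rng.uniform(15.0, 40.0)) for _ in range(n_so)]

    for i in eeg_idx:
        ch = channels[i]
        x = _colored_noise(n, rate, participant_state.exponent, config.rms_uv * amp, rng)
        central_gain = 1.0 if ch.position == "central" else 0.6
        for t0, dur, freq, phase, a in spindles:
            x += a * amp * central_gain * _gauss_burst(n, rate, t0, dur, freq, phase)
        frontal_gain = 1.0 if ch.position in ("frontal", "central") else 0.7
        for t0, dur, freq, phase, a in so_bursts:
            x += a * amp * frontal_gain * _gauss_burst(n, rate, t0, dur, freq, phase)
        # condition effect: pure band-power factors on the composite signal
        gains = []
        if condition == DREAMLESS and config.condition_delta_ratio > 1:
            w = config.low_region_weights.get(ch.position, 0.0)
            # the low-frequency elevation extends through DC so that the
            # quantified 0.5-4 Hz band is not diluted by sub-band leakage
            gains.append((0.0, LOW_BAND[1], config.condition_delta_ratio ** w))
        if condition == DREAMFUL and config.condition_high_ratio > 1:
            w = config.high_region_weights.get(ch.position, 0.0)
            gains.append((*HIGH_BAND, config.condition_high_ratio ** w))
        if gains:
            x = _band_gain(x, rate, gains)
        samples[i] = x

    # EOG: steep-spectrum noise + slow-movement events (mirrored between the
    # two channels) + frontal EEG crosstalk; condition-independent by default
    frontal = samples[channels_at(channels, position="frontal")].mean(axis=0)
    n_eog = rng.poisson(config.eog_event_rate * config.duration_s / 60.0)
    eog_events = np.zeros(n)
    t = np.arange(n) / rate
    for _ in range(n_eog):
        t0 = rng.uniform(0, config.duration_s)
        dur = rng.uniform(1.0, 3.0)
        a = rng.uniform(60.0, 150.0) * rng.choice([-1.0, 1.0])
        inside = (t >= t0) & (t <= t0 + dur)
        eog_events[inside] += a * np.sin(np.pi * (t[inside] - t0) / dur)
    for sign, i in zip((1.0, -1.0), channels_at(channels, modality="EOG")):
        samples[i] = (sign * eog_events
                      + _colored_noise(n, rate, 3.0, 10.0, rng)
                      + 0.1 * frontal)

    # EMG: high-frequency-weighted noise scaled by tonus level
    for i in channels_at(channels, modality="EMG"):
        freqs = np.fft.rfftfreq(n, 1.0 / rate)
        shape = freqs / (freqs + 20.0)
        x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * shape, n)
        samples[i] = x * (config.emg_tonus_level / x.std())

    if config.noise_sd > 0:
        samples += rng.normal(0.0, config.noise_sd, samples.shape)

    return PsgCase(f"{participant_state.participant}-s{session}-r", channels, samples, rate)


def synth_cohort(config: CohortConfig,
                 ) -> tuple[list[PsgCase], pd.DataFrame, BlindKey]:
    """Generate the full blinded cohort: 54 cases, truth table, blinding key.

    Returns cases renamed to their blinded IDs and sorted by ID.  The truth
    table (case_id -> participant/session/condition plus the injected
    participant effects) is for scoring only and is never an analysis input.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(root.spawn(1)[0])
    states = draw_participant_states(config, master)

    meta_rows, raw_cases = [], {}
    case_seeds = root.spawn(config.n_participants * 2 * config.sessions_per_condition)
    k = 0
    for st in states:
        for cond in (DREAMFUL, DREAMLESS):
            for sess in range(1, config.sessions_per_condition + 1):
                rec = f"{st.participant}-{cond}-s{sess}"
                case = synth_case(config, st, cond, sess,
                                  np.random.default_rng(case_seeds[k]))
                k += 1
                raw_cases[rec] = case
                meta_rows.append({
                    "recording": rec, "participant": st.participant,
                    "session": sess, "condition": cond,
                    "amp_log_offset": st.amp_log_offset, "exponent": st.exponent,
                })
    meta = pd.DataFrame(meta_rows)
    key, truth = apply_blinding(meta[["recording", "participant", "session", "condition"]],
                                seed=int(master.integers(2 ** 31)))
    truth = truth.merge(meta[["recording", "amp_log_offset", "exponent"]], on="recording")

    cases = []
    for _, row in truth.iterrows():
        case = raw_cases[row["recording"]]
        cases.append(PsgCase(row["case_id"], case.channels, case.samples, case.rate))
    cases.sort(key=lambda c: c.case_id)
    return cases, truth, key
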