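"""Feature-extraction oracles: Welch scaling, entropies, composite sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dreamcatcher.features import (FeatureMatrix, approximate_entropy,
                                   assemble_step2_features, extract_feature_set,
                                   extract_features, extract_step5_features,
                                   permutation_entropy, studentize,
                                   welch_log_psd)

from conftest import RATE, make_case


class TestWelch:
    def test_sine_power_concentrated_and_parseval(self):
        t = np.arange(int(60 * RATE)) / RATE
        case = make_case(np.zeros((29, t.size)))
        case.samples[0] = np.sin(2 * np.pi * 10 * t)
        est = welch_log_psd(case)
        # unit-amplitude sine has total power 1/2 uV^2
        total = est.psd[0].sum() * (est.freqs[1] - est.freqs[0])
        assert abs(total - 0.5) < 0.025
        assert est.freqs[np.argmax(est.psd[0])] == pytest.approx(10.0)

    def test_zero_channel_zero_spectrum(self):
        case = make_case(np.zeros((29, int(60 * RATE))))
        est = welch_log_psd(case)
        assert np.all(est.psd == 0)

    def test_white_noise_flat_level(self):
        sigma = 3.0
        rng = np.random.default_rng(2)
        case = make_case(rng.normal(0, sigma, (29, int(60 * RATE))))
        est = welch_log_psd(case)
        levels = est.psd[:, 1:].mean(axis=1)  # per-channel mean density
        expect = sigma ** 2 / (RATE / 2)
        se = levels.std(ddof=1) / np.sqrt(levels.size)
        assert abs(levels.mean() - expect) < 3 * se + 0.01 * expect

    def test_window_longer_than_record(self):
        case = make_case(duration=1.0)
        with pytest.raises(ValueError):
            welch_log_psd(case, window_s=2.0)


class TestPermutationEntropy:
    def test_hand_enumerated_example(self):
        # ordinal pairs of [4,7,9,10,6,11,3]: 4 up, 2 down
        x = [4, 7, 9, 10, 6, 11, 3]
        expect = -(4 / 6 * np.log(4 / 6) + 2 / 6 * np.log(2 / 6))
        assert permutation_entropy(x, order=2, delay=1) == pytest.approx(expect, abs=1e-12)

    def test_monotone_ramp_is_zero(self):
        assert permutation_entropy(np.arange(50), 3, 1) == pytest.approx(0.0, abs=1e-12)

    def test_constant_signal_is_zero(self):
        assert permutation_entropy(np.ones(100), 3, 1) == pytest.approx(0.0, abs=1e-12)

    def test_iid_uniform_approaches_log_factorial(self):
        x = np.random.default_rng(0).random(200_000)
        assert permutation_entropy(x, 3, 1) == pytest.approx(np.log(6), rel=0.02)

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=40, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_negation_symmetry_order2(self, xs):
        # tie-free inputs: ties break by order of occurrence, which is not
        # negation-symmetric by construction
        x = np.asarray(xs)
        assert permutation_entropy(x, 2, 1) == pytest.approx(
            permutation_entropy(-x, 2, 1), abs=1e-9)

    def test_too_short_input(self):
        with pytest.raises(ValueError):
            permutation_entropy([1.0, 2.0], order=3, delay=1)


def apen_bruteforce(x, m, r):
    """Direct template counting per the Pincus definition (oracle)."""
    x = np.asarray(x, dtype=float)

    def phi(mm):
        n_t = x.size - mm + 1
        temps = [x[i:i + mm] for i in range(n_t)]
        logs = []
        for t1 in temps:
            c = sum(np.max(np.abs(t1 - t2)) <= r for t2 in temps)
            logs.append(np.log(c / n_t))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


class TestApproximateEntropy:
    def test_constant_signal_zero(self):
        assert approximate_entropy(np.ones(200)) == 0.0

    def test_period_two_alternation_near_zero(self):
        x = np.tile([1.0, -1.0], 150)
        assert approximate_entropy(x, m=2, r=0.1) == pytest.approx(0.0, abs=1e-3)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            x = rng.standard_normal(80)
            r = 0.2 * x.std()
            assert approximate_entropy(x, 2, r) == pytest.approx(
                apen_bruteforce(x, 2, r), abs=1e-10)

    def test_noise_more_entropic_than_sine(self):
        rng = np.random.default_rng(5)
        t = np.arange(1000) / 100
        sine = np.sin(2 * np.pi * 2 * t)
        noise = rng.standard_normal(1000) * sine.std()
        assert approximate_entropy(noise, 2, 0.2 * sine.std()) > \
            approximate_entropy(sine, 2, 0.2 * sine.std())


class TestFeatureSets:
    @pytest.fixture(scope="class")
    def case(self):
        return make_case(rng=np.random.default_rng(10))

    def test_powerfine_has_2475_features(self, case):
        v = extract_feature_set(case, "PowerFine")
        assert v.size == 2475
        assert v.index[0].startswith("powerfine/")

    def test_powerfine_consistent_with_welch(self, case):
        v = extract_feature_set(case, "PowerFine")
        est = welch_log_psd(case).take_log()
        keep = (est.freqs >= 0.5) & (est.freqs <= 49.5)
        expect = est.psd[:25][:, keep].ravel()
        np.testing.assert_allclose(v.to_numpy(), expect, rtol=1e-12)

    def test_powerband_count(self, case):
        assert extract_feature_set(case, "PowerBand").size == 150  # 6 bands x 25

    def test_entropy_sets_one_value_per_channel(self, case):
        assert extract_feature_set(case, "PermEn").size == 25

    def test_rms_sets_quarters(self, case):
        v = extract_feature_set(case, "EmgRms")
        assert v.size == 8  # 2 channels x 4 quarters

    def test_unknown_set_rejected(self, case):
        with pytest.raises(ValueError, match="unknown feature set"):
            extract_feature_set(case, "Nope")

    def test_deterministic(self, case):
        a = extract_feature_set(case, "Siclari")
        b = extract_feature_set(case, "Siclari")
        pd.testing.assert_series_equal(a, b)


class TestStep2Set:
    def test_fifty_named_features(self):
        case = make_case(rng=np.random.default_rng(11))
        v = assemble_step2_features(case)
        assert v.size == 50
        groups = {n.split("/")[0] for n in v.index}
        assert groups == {"scalp", "siclari", "emg", "eog"}

    def test_constant_emg_percentiles(self):
        case = make_case(rng=np.random.default_rng(12))
        case.samples[-2:] = -2.5  # both EMG channels constant
        v = assemble_step2_features(case)
        emg = v[[n for n in v.index if n.startswith("emg/")]]
        assert np.allclose(emg.to_numpy(), 2.5)

    def test_doubling_eeg_shifts_scalp_bins_by_2ln2(self):
        case = make_case(rng=np.random.default_rng(13))
        louder = make_case(case.samples.copy())
        louder.samples[:25] *= 2.0
        a = assemble_step2_features(case)
        b = assemble_step2_features(louder)
        scalp = [n for n in a.index if n.startswith("scalp/")]
        np.testing.assert_allclose(b[scalp] - a[scalp], 2 * np.log(2), rtol=1e-9)
        emg = [n for n in a.index if n.startswith("emg/")]
        np.testing.assert_allclose(b[emg], a[emg])


class TestStep5Features:
    def test_delta_injection_separates_bands(self):
        rng = np.random.default_rng(14)
        case = make_case(rng=rng)
        t = np.arange(case.n_samples) / case.rate
        boosted = make_case(case.samples.copy())
        po_names = ("O1", "Oz", "O2", "Pz")
        for i, ch in enumerate(boosted.channels):
            if ch.name in po_names:
                boosted.samples[i] += 5.0 * np.sin(2 * np.pi * 2.0 * t)
        a = extract_step5_features(case)
        b = extract_step5_features(boosted)
        assert b["step5/SBP_low"] > a["step5/SBP_low"] + 0.5
        assert b["step5/SBP_high"] == pytest.approx(a["step5/SBP_high"], abs=1e-6)

    def test_left_right_mirror_changes_only_scarpelli(self):
        case = make_case(rng=np.random.default_rng(15))
        mirror_pairs = [("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"), ("FT7", "FT8"),
                        ("FC3", "FC4"), ("T7", "T8"), ("C3", "C4"), ("P7", "P8"),
                        ("P3", "P4"), ("O1", "O2")]
        name_idx = {c.name: i for i, c in enumerate(case.channels)}
        mirrored = make_case(case.samples.copy())
        for a, b in mirror_pairs:
            mirrored.samples[[name_idx[a], name_idx[b]]] = \
                case.samples[[name_idx[b], name_idx[a]]]
        fa = extract_step5_features(case)
        fb = extract_step5_features(mirrored)
        assert fb["step5/SBP_low"] == pytest.approx(fa["step5/SBP_low"], abs=1e-9)
        assert fb["step5/SBP_high"] == pytest.approx(fa["step5/SBP_high"], abs=1e-9)
        assert fb["step5/Scarpelli"] != pytest.approx(fa["step5/Scarpelli"], abs=1e-6)


class TestStudentize:
    def test_columns_centered_and_scaled(self):
        rng = np.random.default_rng(16)
        fm = FeatureMatrix(pd.DataFrame(rng.normal(3, 5, (20, 7)),
                                        index=[f"c{i}" for i in range(20)]))
        st_ = studentize(fm)
        assert np.abs(st_.values.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(st_.values.std(axis=0, ddof=1), 1.0)
        assert "studentized" in st_.transforms

    def test_idempotent(self):
        rng = np.random.default_rng(17)
        fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(10, 3))))
        once = studentize(fm)
        twice = studentize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = studentize(FeatureMatrix(df))
        assert np.all(out.df["b"] == 0.0)


def test_extract_features_matrix(default_cohort):
    cases, _, _ = default_cohort
    fm = extract_features(cases[:4], "PowerBand")
    assert fm.df.shape == (4, 150)
    assert fm.case_ids == [c.case_id for c in cases[:4]]
    assert "log" in fm.transforms
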