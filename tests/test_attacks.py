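"""Attack forging: median filter, AWGN calibration, MN_MF and injection."""

import statistics

import numpy as np
import pytest

from bcishield import attacks as ak, synthgen as sg
from bcishield.exceptions import DataError


def brute_force_median(x, n):
    """Independent sliding-median oracle with the shrinking-edge policy."""
    half = n // 2
    out = []
    for m in range(len(x)):
        lo, hi = max(0, m - half), min(len(x), m + half + 1)
        out.append(statistics.median(x[lo:hi]))
    return np.array(out)


class TestMedianFilter:
    def test_worked_example(self):
        np.testing.assert_allclose(
            ak.median_filter(np.array([1.0, 5, 2, 8, 3]), 3), [3, 2, 5, 3, 5.5]
        )

    def test_identity_cases(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_allclose(ak.median_filter(x, 1), x)
        np.testing.assert_allclose(ak.median_filter(np.full(9, 2.5), 7), 2.5)

    @pytest.mark.parametrize("n", [3, 9])
    def test_against_brute_force_oracle(self, n, rng):
        for _ in range(1000):
            x = rng.standard_normal(rng.integers(n, 30))
            np.testing.assert_allclose(
                ak.median_filter(x, n), brute_force_median(x, n), atol=1e-12
            )

    @pytest.mark.parametrize("n", [0, 2, 4, -3])
    def test_invalid_order_rejected(self, n):
        with pytest.raises(ValueError):
            ak.median_filter(np.zeros(10), n)

    def test_matrix_filtered_along_time(self, rng):
        x = rng.standard_normal((3, 20))
        out = ak.median_filter(x, 3)
        for ch in range(3):
            np.testing.assert_allclose(out[ch], ak.median_filter(x[ch], 3))


class TestAWGN:
    @pytest.mark.parametrize("snr_db", [20.0, 40.0])
    def test_realized_snr_within_half_db(self, snr_db):
        rng = np.random.default_rng(0)
        trial = sg.EEGTrial(
            data=10.0 * rng.standard_normal((1, 100_000)), fs=128.0, label="nonP300"
        )
        fake = ak.awgn_attack(trial, snr_db, seed=1, amplitude_bound=None)
        noise = fake.data - trial.data
        realized = 10 * np.log10(np.mean(trial.data**2) / np.mean(noise**2))
        assert realized == pytest.approx(snr_db, abs=0.5)

    def test_noise_variance_matches_snr_definition(self):
        # SNR 20 dB -> noise variance P/100, estimated over many samples
        rng = np.random.default_rng(3)
        trial = sg.EEGTrial(
            data=4.0 * rng.standard_normal((2, 50_000)), fs=128.0, label="P300"
        )
        fake = ak.awgn_attack(trial, 20.0, seed=2, amplitude_bound=None)
        p = np.mean(trial.data**2, axis=1)
        var = np.var(fake.data - trial.data, axis=1)
        np.testing.assert_allclose(var, p / 100.0, rtol=0.05)

    def test_vanishing_noise_limit(self, small_dataset):
        trial = small_dataset.trials[0]
        fake = ak.awgn_attack(trial, 300.0, seed=0)
        np.testing.assert_allclose(fake.data, trial.data, atol=1e-6)
        assert fake.label == trial.label
        assert fake.provenance == "fake"

    def test_respects_amplitude_bound(self):
        data = np.full((1, 1000), 99.0)
        trial = sg.EEGTrial(data=data, fs=128.0, label="nonP300")
        fake = ak.awgn_attack(trial, 10.0, seed=0)
        assert np.max(np.abs(fake.data)) <= sg.AMPLITUDE_BOUND_UV


class TestTemplates:
    def test_mean_of_identical_trials(self, default_profile):
        t = sg.synth_trial("P300", default_profile, seed=0)
        t2 = t.copy(label="nonP300")
        tmpl = ak.build_templates([t, t, t2], n=1)
        np.testing.assert_allclose(tmpl.mP3, t.data)
        # n=1 median filter is the identity
        np.testing.assert_allclose(tmpl.MF_mP3, tmpl.mP3)

    def test_missing_class_rejected(self, default_profile):
        t = sg.synth_trial("P300", default_profile, seed=0)
        with pytest.raises(DataError):
            ak.build_templates([t], n=3)

    def test_template_peak_in_p300_window(self, donor_trials):
        tmpl = ak.build_templates(donor_trials, n=9)
        wave = tmpl.MF_mP3.mean(axis=0)
        peak_ms = np.argmax(wave) / tmpl.fs * 1000.0
        assert 250.0 <= peak_ms <= 500.0


@pytest.fixture(scope="module")
def tmpl(donor_trials):
    return ak.build_templates(donor_trials, n=9)


@pytest.fixture(scope="module")
def victim_lims(small_dataset):
    return small_dataset.channel_limits()


class TestMNMF:
    def test_zero_alpha_gives_scaled_template(self, tmpl, victim_lims):
        fake = ak.mnmf_attack(tmpl, victim_lims, class_seed=0, noise_seed=1, alpha1=0.0)
        mf = tmpl.MF_mP3 if fake.label == "P300" else tmpl.MF_mNP3
        eeg_abs = np.max(np.abs(victim_lims), axis=1)
        k = np.minimum(1.0, eeg_abs / np.max(np.abs(mf), axis=1))
        np.testing.assert_allclose(fake.data, mf * k[:, None], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_winsorizing_safety(self, tmpl, victim_lims, seed):
        # per channel, |amplitude| never exceeds the victim's own limits
        fake = ak.mnmf_attack(tmpl, victim_lims, class_seed=seed, noise_seed=seed, alpha1=0.5)
        eeg_abs = np.max(np.abs(victim_lims), axis=1)
        assert np.all(np.max(np.abs(fake.data), axis=1) <= eeg_abs + 1e-12)

    def test_deterministic(self, tmpl, victim_lims):
        a = ak.mnmf_attack(tmpl, victim_lims, class_seed=3, noise_seed=4)
        b = ak.mnmf_attack(tmpl, victim_lims, class_seed=3, noise_seed=4)
        assert a.label == b.label
        np.testing.assert_array_equal(a.data, b.data)

    def test_degenerate_template_rejected(self, tmpl, victim_lims):
        import dataclasses

        zero = dataclasses.replace(
            tmpl, MF_mP3=np.zeros_like(tmpl.MF_mP3), MF_mNP3=np.zeros_like(tmpl.MF_mNP3)
        )
        with pytest.raises(DataError):
            ak.mnmf_attack(zero, victim_lims, class_seed=0, noise_seed=0)


class TestInject:
    def test_counts_and_provenance(self, small_dataset):
        hacked = ak.inject(small_dataset, "AWGN20", n_fake=40, selection_seed=4)
        assert len(hacked.substituted_indices) == 40
        subs = set(hacked.substituted_indices.tolist())
        for i, t in enumerate(hacked.trials):
            if i in subs:
                assert t.provenance == "fake"
                # same-slot substitution preserves the class composition
                assert t.label == small_dataset.trials[i].label
            else:
                assert t.provenance == "synthetic"
                np.testing.assert_array_equal(t.data, small_dataset.trials[i].data)
        assert hacked.dataset.counts == small_dataset.counts

    def test_empty_substitution_is_identity(self, small_dataset):
        hacked = ak.inject(small_dataset, "AWGN40", n_fake=0)
        assert len(hacked.substituted_indices) == 0
        for a, b in zip(hacked.trials, small_dataset.trials):
            np.testing.assert_array_equal(a.data, b.data)

    def test_selection_deterministic_per_seed(self, small_dataset):
        a = ak.inject(small_dataset, "AWGN20", n_fake=30, selection_seed=4)
        b = ak.inject(small_dataset, "AWGN20", n_fake=30, selection_seed=4)
        c = ak.inject(small_dataset, "AWGN20", n_fake=30, selection_seed=5)
        np.testing.assert_array_equal(a.substituted_indices, b.substituted_indices)
        assert not np.array_equal(a.substituted_indices, c.substituted_indices)

    def test_mnmf_preset_requires_matching_templates(self, small_dataset, donor_trials):
        with pytest.raises(ValueError):
            ak.inject(small_dataset, "MF9_001", templates=None, n_fake=10)
        tmpl3 = ak.build_templates(donor_trials, n=3)
        with pytest.raises(ValueError):
            ak.inject(small_dataset, "MF9_001", tmpl3, n_fake=10)
        hacked = ak.inject(small_dataset, "MF3_001", tmpl3, n_fake=10)
        assert hacked.attack_kind == "MF3_001"

    def test_oversize_request_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            ak.inject(small_dataset, "AWGN20", n_fake=len(small_dataset) + 1)
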