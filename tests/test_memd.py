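"""MEMD: completeness, filter-bank behaviour, reconstruction identities."""

import numpy as np
import pytest
from numpy.fft import rfft, rfftfreq
from scipy.signal import periodogram

from doamon import (EEGRecord, MEMDConfig, band_stop, eeg_filter,
                    generate_eog, generate_synthetic_eeg, memd_decompose,
                    mix_at_snr, na_memd_single, reconstruct)
from doamon.memd import is_imf, mean_zero_crossing_rates


@pytest.fixture(scope="module")
def two_tone_sets():
    fs = 125.0
    t = np.arange(1000) / fs
    x = np.column_stack([np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 40 * t),
                         np.cos(2 * np.pi * 2 * t) + 0.5 * np.sin(2 * np.pi * 40 * t)])
    return x, memd_decompose(x, MEMDConfig(seed=0), fs=fs)


@pytest.fixture(scope="module")
def na_sinusoid():
    fs = 125.0
    t = np.arange(1000) / fs
    rec = EEGRecord(np.sin(2 * np.pi * 1 * t) + np.sin(2 * np.pi * 30 * t), fs=fs)
    return rec, na_memd_single(rec, MEMDConfig(seed=1))


def dominant_freq(c, fs=125.0):
    p = np.abs(rfft(c)) ** 2
    return rfftfreq(c.size, 1 / fs)[np.argmax(p)]


class TestDecompose:
    def test_completeness_per_channel(self, two_tone_sets):
        x, sets = two_tone_sets
        for j, s in enumerate(sets):
            err = np.linalg.norm(s.reconstruct_all() - x[:, j]) \
                / np.linalg.norm(x[:, j])
            assert err < 1e-8

    def test_same_imf_count_across_channels(self, two_tone_sets):
        _, sets = two_tone_sets
        assert len({s.n_imfs for s in sets}) == 1

    def test_fast_tone_in_earlier_imf(self, two_tone_sets):
        _, sets = two_tone_sets
        s = sets[0]
        freqs = [dominant_freq(c) for c in s.imfs]
        i40 = min(i for i, f in enumerate(freqs) if abs(f - 40) < 5)
        i2 = min(i for i, f in enumerate(freqs) if abs(f - 2) < 1)
        assert i40 < i2

    def test_imf_acceptance_criterion(self, two_tone_sets):
        _, sets = two_tone_sets
        for s in sets:
            for c in s.imfs:
                assert is_imf(c)

    def test_zero_crossing_rate_ordering(self, two_tone_sets):
        _, sets = two_tone_sets
        zcr = mean_zero_crossing_rates(sets[0])
        assert np.all(np.diff(zcr) <= 1e-12)

    def test_white_noise_filter_bank_depth(self, rng):
        x = rng.standard_normal((1000, 2))
        sets = memd_decompose(x, MEMDConfig(seed=2))
        assert sets[0].n_imfs >= 5  # ~log2(N) dyadic bank

    def test_nonfinite_rejected(self):
        x = np.ones((100, 2))
        x[3, 0] = np.nan
        with pytest.raises(ValueError):
            memd_decompose(x)

    def test_too_few_channels(self, rng):
        with pytest.raises(ValueError):
            memd_decompose(rng.standard_normal((100, 1)))


class TestNoiseAssisted:
    def test_completeness(self, na_sinusoid):
        rec, s = na_sinusoid
        err = np.linalg.norm(s.reconstruct_all() - rec.samples) \
            / np.linalg.norm(rec.samples)
        assert err < 1e-8

    def test_tone_separation_cross_leakage(self, na_sinusoid):
        _, s = na_sinusoid
        fs = 125.0

        def band_energy(c, lo, hi):
            f = rfftfreq(c.size, 1 / fs)
            p = np.abs(rfft(c)) ** 2
            return p[(f >= lo) & (f <= hi)].sum()

        e30 = np.array([band_energy(c, 25, 35) for c in s.imfs])
        e1 = np.array([band_energy(c, 0.5, 1.5) for c in s.imfs])
        i30, i1 = int(np.argmax(e30)), int(np.argmax(e1))
        assert i30 != i1
        assert e1[i30] / (e30[i30] + e1[i30]) < 0.05
        assert e30[i1] / (e30[i1] + e1[i1]) < 0.05

    def test_bit_reproducible_under_seed(self, na_sinusoid):
        rec, s = na_sinusoid
        s2 = na_memd_single(rec, MEMDConfig(seed=1))
        assert np.array_equal(s.imfs, s2.imfs)
        assert np.array_equal(s.residue, s2.residue)

    def test_pure_band_preserved(self, na_sinusoid):
        # filtering introduces no noise: the matching band correlates > 0.99
        rec, s = na_sinusoid
        fs = 125.0
        t = np.arange(rec.n) / fs
        fast = np.sin(2 * np.pi * 30 * t)
        i30 = int(np.argmax([np.abs(np.corrcoef(c, fast)[0, 1]) for c in s.imfs]))
        assert abs(np.corrcoef(s.imfs[i30], fast)[0, 1]) > 0.99


class TestReconstruct:
    def test_full_band_plus_residue_is_identity(self, na_sinusoid):
        rec, s = na_sinusoid
        out = reconstruct(s, 1, s.n_imfs, include_residue=True)
        assert np.linalg.norm(out - rec.samples) / np.linalg.norm(rec.samples) < 1e-8

    def test_single_term(self, na_sinusoid):
        _, s = na_sinusoid
        assert np.array_equal(reconstruct(s, 1, 1), s.imfs[0])

    def test_band_is_elementwise_sum(self, na_sinusoid):
        _, s = na_sinusoid
        assert np.array_equal(reconstruct(s, 2, 3), s.imfs[1] + s.imfs[2])

    def test_out_of_range(self, na_sinusoid):
        _, s = na_sinusoid
        with pytest.raises(ValueError):
            reconstruct(s, 0, 2)
        with pytest.raises(ValueError):
            reconstruct(s, 3, 2)


class TestBandStop:
    def test_two_term_sum(self, na_sinusoid):
        _, s = na_sinusoid
        n = s.n_imfs
        assert np.array_equal(band_stop(s, n, 1), s.imfs[0] + s.imfs[-1])

    def test_partition_identity(self, na_sinusoid):
        rec, s = na_sinusoid
        k = 3
        out = band_stop(s, k + 1, k - 1) + s.imfs[k - 1] + s.residue
        assert np.linalg.norm(out - rec.samples) / np.linalg.norm(rec.samples) < 1e-8

    def test_equals_two_reconstructions(self, na_sinusoid):
        _, s = na_sinusoid
        n = s.n_imfs
        assert np.array_equal(band_stop(s, 4, 2),
                              reconstruct(s, 1, 2) + reconstruct(s, 4, n))

    def test_requires_gap(self, na_sinusoid):
        _, s = na_sinusoid
        with pytest.raises(ValueError):
            band_stop(s, 2, 2)


class TestEEGFilter:
    @pytest.fixture(scope="class")
    def corrupted(self):
        eeg = generate_synthetic_eeg(30, 125, "preoperation", seed=3)
        eog = generate_eog(30, 125, seed=4)
        return mix_at_snr(eeg, eog, -5.0)

    def test_suppresses_low_frequency_power(self, corrupted):
        filt = eeg_filter(corrupted, MEMDConfig(seed=5))

        def sub4(x):
            f, p = periodogram(x, 125)
            return p[f < 4].sum() / p.sum()

        assert sub4(filt.samples) < sub4(corrupted.samples)

    def test_sd_not_increased(self, corrupted):
        filt = eeg_filter(corrupted, MEMDConfig(seed=5))
        assert filt.samples.std() <= corrupted.samples.std()

    def test_full_selection_is_identity(self):
        rec = generate_synthetic_eeg(8, 125, "preoperation", seed=6)
        _, imfset = eeg_filter(rec, MEMDConfig(seed=7), imf_selection=(1,),
                               return_imfs=True)
        out = eeg_filter(rec, MEMDConfig(seed=7),
                         imf_selection=range(1, imfset.n_imfs + 1),
                         include_residue=True)
        err = np.linalg.norm(out.samples - rec.samples) / np.linalg.norm(rec.samples)
        assert err < 1e-8

    def test_too_few_imfs_diagnostic(self):
        rec = generate_synthetic_eeg(4, 125, "preoperation", seed=8)
        with pytest.raises(RuntimeError, match="IMFs"):
            eeg_filter(rec, MEMDConfig(seed=9), imf_selection=(40,))
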