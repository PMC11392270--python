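"""Feature extraction checked against independent brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ehgpreterm.bands import BANDS, Band, get_band
from ehgpreterm.errors import ParameterError, UndefinedValueError
from ehgpreterm.spectral_features import (
    ExtractionConfig,
    FeatureSpec,
    SEParams,
    bandpass_filter,
    extract_feature_vector,
    median_frequency,
    peak_amplitude_normalized,
    peak_frequency,
    power_spectrum,
    sample_entropy,
)

from conftest import make_record

FS = 20.0


def tone(freq, n=2000, amp=1.0, fs=FS, phase=0.3):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_spectrum(x, fs):
    """Direct DFT periodogram, independent of the implementation path."""
    n = len(x)
    X = np.array([np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n)) for k in range(n // 2 + 1)])
    p = np.abs(X) ** 2 / (fs * n)
    if n % 2 == 0:
        p[1:-1] *= 2
    else:
        p[1:] *= 2
    return p, fs / n


def oracle_band_indices(band, df, n_bins):
    lo = math.ceil(band.f_lo / df - 1e-9)
    hi = min(math.ceil(band.f_hi / df - 1e-9), n_bins)
    return lo, hi


def oracle_pf(power, df, band):
    lo, hi = oracle_band_indices(band, df, len(power))
    return (lo + int(np.argmax(power[lo:hi]))) * df


def oracle_mf(power, df, band):
    lo, hi = oracle_band_indices(band, df, len(power))
    p = power[lo:hi]
    half = p.sum() / 2.0
    acc = 0.0
    for j, v in enumerate(p):
        acc += v
        if acc >= half:
            return (lo + j) * df
    raise AssertionError


def oracle_se(x, m=3, r_frac=0.15):
    """O(N^2) sample entropy via explicit embedding matrices."""
    x = np.asarray(x, float)
    n = len(x)
    r = r_frac * np.std(x)
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)  # n-m+1 templates
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # n-m templates
    dm = squareform(pdist(emb_m, metric="chebyshev"))
    dm1 = squareform(pdist(emb_m1, metric="chebyshev"))
    cm = int((dm[np.triu_indices_from(dm, k=1)] <= r).sum())
    cm1 = int((dm1[np.triu_indices_from(dm1, k=1)] <= r).sum())
    if cm and cm1:
        return -np.log(cm1 / cm)
    return -np.log((n - m) / (n - m - 1))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestBands:
    def test_ten_canonical_bands(self):
        assert len(BANDS) == 10
        assert BANDS["B0"].f_lo == 0.08 and BANDS["B0"].f_hi == 1.0
        assert BANDS["B0Lp"].f_lo == 0.125 and BANDS["B0Lp"].f_hi == 0.575
        assert BANDS["B3"].f_lo == 3.5 and BANDS["B3"].f_hi == 5.0
        assert BANDS["B0Hp"].f_lo == 0.575 and BANDS["B0Hp"].f_hi == 1.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ParameterError):
            Band("bad", 2.0, 1.0)
        with pytest.raises(ParameterError):
            bandpass_filter(np.zeros(1000), Band("hi", 5.0, 15.0), FS)


class TestBandpassFilter:
    def test_in_band_tone_preserved(self):
        x = tone(0.3, 4000)
        y = bandpass_filter(x, "B0Lp", FS)
        mid = slice(1000, 3000)
        assert np.std(y[mid]) == pytest.approx(np.std(x[mid]), rel=0.05)

    def test_out_of_band_tone_attenuated_40db(self):
        x = tone(3.0, 4000)
        y = bandpass_filter(x, "B0Lp", FS)
        mid = slice(1000, 3000)
        assert np.std(y[mid]) < np.std(x[mid]) * 10 ** (-40 / 20)

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_filter(np.zeros(1000), "B1", FS), 0.0)


class TestPowerSpectrum:
    def test_single_tone_dominant_bin(self):
        sp = power_spectrum(tone(0.5), FS)
        assert np.argmax(sp.power) * sp.df == pytest.approx(0.5, abs=sp.df)

    def test_parseval(self, rng):
        x = rng.standard_normal(2048)
        sp = power_spectrum(x, FS)
        assert sp.power.sum() * sp.df == pytest.approx(np.mean(x**2), rel=0.05)

    def test_constant_signal_is_dc_only(self):
        sp = power_spectrum(np.full(1000, 3.0), FS)
        assert np.argmax(sp.power) == 0
        assert sp.power[5:].max() < 1e-12 * sp.power[0]


class TestPeakAndMedianFrequency:
    def test_larger_peak_wins(self):
        x = tone(0.2, amp=1.0) + tone(0.4, amp=2.0)
        sp = power_spectrum(x, FS)
        assert peak_frequency(sp, "B0Lp") == pytest.approx(0.4, abs=2 * sp.df)

    def test_single_tone_pf_mf(self):
        sp = power_spectrum(tone(0.3), FS)
        assert peak_frequency(sp, "B0") == pytest.approx(0.3, abs=sp.df)
        assert median_frequency(sp, "B0") == pytest.approx(0.3, abs=sp.df)

    def test_flat_spectrum_mf_near_midpoint(self):
        sp = power_spectrum(tone(0.3), FS)
        sp.power = np.ones_like(sp.power)
        band = get_band("B0Lp")
        mid = (band.f_lo + band.f_hi) / 2
        assert median_frequency(sp, band) == pytest.approx(mid, abs=2 * sp.df)

    def test_two_equal_tones_tie_rule(self):
        # MF lands on one of the two tone bins and agrees with the
        # brute-force cumulative-sum oracle under the same tie rule
        x = tone(0.2) + tone(0.4)
        sp = power_spectrum(x, FS)
        op, odf = oracle_spectrum(x, FS)
        mf = median_frequency(sp, "B0Lp")
        assert mf == pytest.approx(oracle_mf(op, odf, get_band("B0Lp")), abs=1e-12)
        assert min(abs(mf - 0.2), abs(mf - 0.4)) <= 2 * sp.df

    @pytest.mark.parametrize("band_name", ["B0", "B0Lp", "B3", "B0b"])
    def test_matches_bruteforce_oracle_on_noise(self, rng, band_name):
        x = rng.standard_normal(1500)
        sp = power_spectrum(x, FS)
        op, odf = oracle_spectrum(x, FS)
        band = get_band(band_name)
        assert sp.df == pytest.approx(odf, rel=1e-12)
        assert np.allclose(sp.power, op, rtol=1e-6, atol=1e-12)
        assert peak_frequency(sp, band) == pytest.approx(oracle_pf(op, odf, band), abs=1e-12)
        assert median_frequency(sp, band) == pytest.approx(oracle_mf(op, odf, band), abs=1e-12)

    def test_zero_power_band_raises(self):
        sp = power_spectrum(tone(0.3), FS)
        sp.power = np.zeros_like(sp.power)
        with pytest.raises(UndefinedValueError):
            median_frequency(sp, "B3")


class TestPeakAmplitude:
    def test_reference_band_is_identity(self, rng):
        # PA in the reference band itself equals 1 on arbitrary records
        for i in range(20):
            x = np.random.default_rng(i).standard_normal(1200)
            pa = peak_amplitude_normalized(x, "B0", FS, ExtractionConfig(trim_s=5.0))
            assert pa == pytest.approx(1.0, abs=1e-12)

    def test_quarter_power_ratio(self):
        # 0.3 Hz tone of power p and a 1.5 Hz tone of power p/4 -> PA(B1) ~ 0.25
        x = tone(0.3, n=12000, amp=1.0) + tone(1.5, n=12000, amp=0.5)
        pa = peak_amplitude_normalized(x, "B1", FS, ExtractionConfig(trim_s=10.0))
        assert pa == pytest.approx(0.25, rel=0.15)

    def test_zero_reference_raises(self):
        with pytest.raises(UndefinedValueError):
            peak_amplitude_normalized(np.zeros(2000), "B1", FS, ExtractionConfig(trim_s=5.0))


class TestSampleEntropy:
    def test_matches_bruteforce_oracle_exactly(self, rng):
        x = rng.standard_normal(2000)
        assert sample_entropy(x) == pytest.approx(oracle_se(x), abs=1e-12)

    def test_oracle_agreement_on_filtered_signal(self, rng):
        x = bandpass_filter(rng.standard_normal(1500), "B0b", FS)
        assert sample_entropy(x) == pytest.approx(oracle_se(x), abs=1e-12)

    def test_periodic_lower_than_shuffled(self, rng):
        saw = np.tile(np.linspace(-1, 1, 20), 50)
        shuffled = rng.permutation(saw)
        assert sample_entropy(saw) < sample_entropy(shuffled)

    def test_fallback_branch_printed_value(self):
        # length-3 zero templates match, but the extended templates end in
        # +1 vs -1, so c_{m+1} = 0 and the printed fallback applies
        x = np.array([0.0, 0, 0, 1, 0, 0, 0, -1])
        n, m = len(x), 3
        expected = -np.log((n - m) / (n - m - 1))
        assert sample_entropy(x) == pytest.approx(expected, abs=1e-15)
        assert expected < 0  # the printed fallback is negative as published
        flipped = sample_entropy(x, SEParams(sign_corrected_fallback=True))
        assert flipped == pytest.approx(-expected, abs=1e-15)

    def test_monotone_nonincreasing_in_tolerance(self, rng):
        x = rng.standard_normal(600)
        ses = [sample_entropy(x, SEParams(r_frac=r)) for r in (0.1, 0.15, 0.25, 0.5)]
        assert all(a >= b for a, b in zip(ses, ses[1:]))

    def test_too_short_raises(self):
        with pytest.raises(ParameterError):
            sample_entropy(np.zeros(3))


class TestScaleInvariance:
    def test_features_invariant_to_positive_scaling(self, rng):
        x = rng.standard_normal(3000) + tone(0.3, 3000)
        rec1 = make_record(x)
        rec2 = make_record(7.3 * x)
        specs = [
            FeatureSpec("PF", "S3", "B0Lp"),
            FeatureSpec("MF", "S2", "B3"),
            FeatureSpec("PA", "S3", "B0Lp"),
            FeatureSpec("SE", "S2", "B0b"),
        ]
        config = ExtractionConfig(trim_s=5.0)
        v1 = extract_feature_vector(rec1, specs, config)
        v2 = extract_feature_vector(rec2, specs, config)
        for name in v1:
            assert v1[name] == pytest.approx(v2[name], rel=1e-9)


class TestExtraction:
    def test_deterministic(self, rng):
        rec = make_record(rng.standard_normal(3000))
        specs = [FeatureSpec("PA", "S3", "B0Lp"), FeatureSpec("SE", "S2", "B3")]
        config = ExtractionConfig(trim_s=5.0)
        assert extract_feature_vector(rec, specs, config) == extract_feature_vector(
            rec, specs, config
        )

    def test_pa_disallowed_in_reference_bands(self):
        with pytest.raises(ParameterError):
            FeatureSpec("PA", "S3", "B0")
        with pytest.raises(ParameterError):
            FeatureSpec("PA", "S2", "B0b")
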