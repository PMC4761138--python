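"""Cross/auto-correlation estimators, peak selection, and the periodogram."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import nucfoot as nf
from nucfoot.correlation import (
    NoDominantPeriodError,
    NoEstimateError,
    smooth_running_window,
)


# --- running-window smoothing -----------------------------------------------

def test_smoothing_window_one_is_identity():
    v = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
    assert np.array_equal(smooth_running_window(v, 1), v)


def test_smoothing_preserves_constants():
    v = np.full(40, 2.5)
    assert np.allclose(smooth_running_window(v, 25), v)


def test_smoothing_hand_arithmetic():
    out = smooth_running_window(np.array([0.0, 0, 3, 0, 0]), 3)
    assert np.allclose(out, [0.0, 1, 1, 1, 0])


def test_smoothing_rejects_bad_window():
    with pytest.raises(ValueError):
        smooth_running_window(np.zeros(10), 0)


# --- cross-correlation ------------------------------------------------------

def test_cross_correlation_of_exact_shift_peaks_at_the_shift():
    rng = np.random.default_rng(0)
    plus = rng.poisson(1.0, 5000)
    minus = np.roll(plus, 49)
    tags = nf.TagSet(5000, True, plus, minus)
    prof = nf.strand_cross_correlation(tags, max_lag=200)
    assert prof.raw[49] == pytest.approx(1.0, abs=1e-9)
    assert int(np.argmax(prof.raw)) == 49


@given(st.integers(0, 2**31 - 1), st.integers(1, 50))
def test_cross_correlation_shift_invariance(seed, const):
    """Adding a constant to either strand leaves the Pearson profile unchanged."""
    rng = np.random.default_rng(seed)
    plus = rng.poisson(2.0, 400)
    minus = rng.poisson(2.0, 400)
    t1 = nf.TagSet(400, True, plus, minus)
    t2 = nf.TagSet(400, True, plus + const, minus)
    p1 = nf.strand_cross_correlation(t1, max_lag=50)
    p2 = nf.strand_cross_correlation(t2, max_lag=50)
    assert np.allclose(p1.raw, p2.raw, atol=1e-9)


def test_cross_correlation_reversal_and_strand_swap_invariance(nucleoid_tags):
    """Reversing the genome and swapping strand labels preserves the profile."""
    rev = nf.TagSet(nucleoid_tags.genome_length, True,
                    nucleoid_tags.counts_minus[::-1].copy(),
                    nucleoid_tags.counts_plus[::-1].copy())
    a = nf.strand_cross_correlation(nucleoid_tags, max_lag=200)
    b = nf.strand_cross_correlation(rev, max_lag=200)
    assert np.allclose(a.raw, b.raw, atol=1e-9)


def test_zero_variance_strand_is_an_error():
    tags = nf.TagSet(100, True, np.ones(100, dtype=int), np.ones(100, dtype=int))
    tags.counts_plus[0] = 1  # still constant
    with pytest.raises(ValueError):
        nf.strand_cross_correlation(tags, max_lag=10)


# --- auto-correlation -------------------------------------------------------

def test_autocorrelation_is_one_at_lag_zero(nucleoid_tags):
    prof = nf.strand_auto_correlation(nucleoid_tags, max_lag=10)
    assert prof.raw[0] == pytest.approx(1.0, abs=1e-12)


def test_impulse_comb_autocorrelation_peaks_at_multiples():
    L, period = 100_000, 93
    counts = np.zeros(L, dtype=np.int64)
    counts[::period] = 1
    tags = nf.TagSet(L, True, counts, counts.copy())
    prof = nf.strand_auto_correlation(tags, max_lag=300)
    for k in (93, 186, 279):
        assert prof.raw[k] > prof.raw[k - 2]
        assert prof.raw[k] > prof.raw[k + 2]
        assert prof.raw[k] > 0.5


def test_autocorrelation_matches_brute_force():
    rng = np.random.default_rng(1)
    plus = rng.poisson(3.0, 1000)
    minus = rng.poisson(3.0, 1000)
    tags = nf.TagSet(1000, True, plus, minus)
    prof = nf.strand_auto_correlation(tags, max_lag=100)
    for d in range(101):
        expected = 0.5 * (
            stats.pearsonr(plus, np.roll(plus, -d))[0]
            + stats.pearsonr(minus, np.roll(minus, -d))[0]
        )
        assert prof.raw[d] == pytest.approx(expected, abs=1e-10)


# --- fragment-size estimation ----------------------------------------------

def _bump(center, height, width=4.0, n=501):
    lags = np.arange(n)
    return height * np.exp(-0.5 * ((lags - center) / width) ** 2)


def test_fragment_size_skips_the_technical_peak():
    raw = _bump(36, 1.0) + _bump(50, 0.8)
    prof = nf.CorrelationProfile(np.arange(501), raw,
                                 smooth_running_window(raw, 5), 5, "cross")
    est = nf.estimate_fragment_size(prof, read_length=36)
    assert est.fragment_size == pytest.approx(50, abs=1)
    assert est.technical_peak_lag == pytest.approx(36, abs=1)


def test_only_a_technical_peak_gives_no_estimate():
    raw = _bump(36, 1.0)
    prof = nf.CorrelationProfile(np.arange(501), raw,
                                 smooth_running_window(raw, 5), 5, "cross")
    with pytest.raises(NoEstimateError):
        nf.estimate_fragment_size(prof, read_length=36)


def test_single_clean_peak_is_returned_verbatim():
    raw = _bump(80, 0.5)
    prof = nf.CorrelationProfile(np.arange(501), raw,
                                 smooth_running_window(raw, 5), 5, "cross")
    est = nf.estimate_fragment_size(prof, read_length=36)
    assert est.fragment_size == pytest.approx(80, abs=1)


def test_auto_profile_is_rejected_for_fragment_size(nucleoid_tags):
    prof = nf.strand_auto_correlation(nucleoid_tags, max_lag=100)
    with pytest.raises(ValueError):
        nf.estimate_fragment_size(prof)


# --- periodogram ------------------------------------------------------------

def test_pure_cosine_periodogram_recovers_the_period():
    lags = np.arange(1001)
    raw = np.cos(2 * np.pi * lags / 93.0)
    prof = nf.CorrelationProfile(lags, raw, raw, 25, "auto")
    pg = nf.periodogram(prof)
    assert pg.dominant_period == pytest.approx(93.0, abs=0.5)


def test_periodogram_power_equals_least_squares_fit():
    """At unpadded Fourier frequencies the power is the sinusoid's explained SS."""
    rng = np.random.default_rng(7)
    y = rng.standard_normal(201)
    prof = nf.CorrelationProfile(np.arange(201), y, y, 25, "auto")
    pg = nf.periodogram(prof, period_range=(2.5, 100.0), nfft=200)
    x = y[1:] - y[1:].mean()
    t = np.arange(len(x))
    for period, power in zip(pg.periods, pg.power):
        w = 2 * np.pi / period
        design = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones(len(t))])
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        fitted = design @ beta
        explained = float(((fitted - fitted.mean()) ** 2).sum())
        assert power == pytest.approx(explained, rel=0.01, abs=1e-9)


def test_constant_profile_has_no_dominant_period():
    raw = np.full(1001, 0.3)
    prof = nf.CorrelationProfile(np.arange(1001), raw, raw, 25, "auto")
    with pytest.raises(NoDominantPeriodError):
        nf.periodogram(prof)


# --- control sample behaviour ----------------------------------------------

def test_control_autocorrelation_declines_monotonically(control_tags):
    """Control digestion shows no periodicity: the profile decays to noise."""
    prof = nf.strand_auto_correlation(control_tags)
    sm = prof.smoothed
    assert int(np.argmax(sm)) <= 20
    assert sm[200:].max() < 0.2 * sm[1:50].max()
    assert abs(sm[500:].mean()) < 5e-4
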