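"""Strand correlation analyses: fragment size and spacing periodicity.

The characteristic protected-fragment size is estimated from the *strand
cross-correlation*: the Pearson correlation between the plus- and
minus-strand tag count vectors as a function of the shift applied to the
minus strand.  Fragments sequenced from both ends produce tag pairs on
opposite strands separated by roughly the fragment length, so the
cross-correlation peaks there.  A second, technical peak can occur at the
read length (a unique-alignment artifact) and is excluded from the estimate.

The characteristic spacing between protected fragments is estimated from the
*same-strand auto-correlation* and its discrete Fourier power spectrum: tags
from regularly spaced footprints make the auto-correlation a comb whose
dominant Fourier period is the spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger("nucfoot.correlation")

__all__ = [
    "CorrelationProfile",
    "FragmentSizeEstimate",
    "Periodogram",
    "NoEstimateError",
    "NoDominantPeriodError",
    "ZeroVarianceError",
    "smooth_running_window",
    "strand_cross_correlation",
    "strand_auto_correlation",
    "estimate_fragment_size",
    "periodogram",
]


class ZeroVarianceError(ValueError):
    """A count vector has zero variance; the correlation is undefined."""


class NoEstimateError(RuntimeError):
    """No fragment-size peak outside the technical band (control-like sample)."""


class NoDominantPeriodError(RuntimeError):
    """The profile is constant; the periodogram has no dominant period."""


@dataclass
class CorrelationProfile:
    lags: np.ndarray  # 0..max_lag, bp
    raw: np.ndarray  # Pearson correlation per lag, in [-1, 1]
    smoothed: np.ndarray  # running-window mean of raw
    window: int
    kind: str  # "cross" or "auto"


@dataclass
class FragmentSizeEstimate:
    fragment_size: int  # bp; equals peak_lag
    peak_lag: int
    peak_value: float
    technical_peak_lag: int | None
    excluded_band: tuple[int, int]


@dataclass
class Periodogram:
    periods: np.ndarray  # bp, ascending, restricted to period_range
    power: np.ndarray
    dominant_period: float
    period_range: tuple[float, float]


def smooth_running_window(values: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar mean; edge windows are truncated.

    ``window`` is coerced to the next odd integer so the window is centered.
    """
    w = int(round(window))
    if w < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if w % 2 == 0:
        w += 1
    values = np.asarray(values, dtype=float)
    if w > len(values):
        raise ValueError("window longer than the profile")
    if w == 1:
        return values.copy()
    kernel = np.ones(w)
    sums = np.convolve(values, kernel, mode="same")
    norms = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / norms


def _pearson_lags_circular(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """r[d] = Pearson(x[i], y[(i+d) mod n]) for d = 0..max_lag, via FFT."""
    n = len(x)
    fx = np.fft.rfft(x)
    fy = np.fft.rfft(y)
    cross = np.fft.irfft(np.conj(fx) * fy, n)[: max_lag + 1]
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(ddof=0), y.std(ddof=0)
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("a strand count vector has zero variance")
    return (cross / n - mx * my) / (sx * sy)


def _pearson_lags_linear(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson over the overlapping window x[:n-d] vs y[d:] for each lag d."""
    n = len(x)
    if max_lag >= n - 1:
        raise ValueError("max_lag must be smaller than the vector length - 1")
    m = int(2 ** np.ceil(np.log2(n + max_lag + 1)))
    cross_all = np.fft.irfft(np.conj(np.fft.rfft(x, m)) * np.fft.rfft(y, m), m)
    d = np.arange(max_lag + 1)
    lengths = (n - d).astype(float)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    sum_x = cx[n - d]          # sum of x[:n-d]
    sum_x2 = cx2[n - d]
    sum_y = cy[n] - cy[d]      # sum of y[d:]
    sum_y2 = cy2[n] - cy2[d]
    sum_xy = cross_all[: max_lag + 1]
    cov = sum_xy / lengths - (sum_x / lengths) * (sum_y / lengths)
    var_x = sum_x2 / lengths - (sum_x / lengths) ** 2
    var_y = sum_y2 / lengths - (sum_y / lengths) ** 2
    if np.any(var_x <= 0) or np.any(var_y <= 0):
        raise ZeroVarianceError("zero variance in an overlap window")
    return cov / np.sqrt(var_x * var_y)


def _check_occupancy(counts: np.ndarray, label: str) -> None:
    if int((counts > 0).sum()) < 2:
        raise ValueError(f"{label} strand has fewer than 2 occupied positions")


def strand_cross_correlation(tags, max_lag: int = 500, window: int = 25) -> CorrelationProfile:
    """Pearson correlation of plus vs shifted minus strand counts per lag."""
    _check_occupancy(tags.counts_plus, "plus")
    _check_occupancy(tags.counts_minus, "minus")
    x = tags.counts_plus.astype(float)
    y = tags.counts_minus.astype(float)
    if tags.circular:
        raw = _pearson_lags_circular(x, y, max_lag)
    else:
        raw = _pearson_lags_linear(x, y, max_lag)
    w = min(window, max_lag + 1)
    return CorrelationProfile(
        lags=np.arange(max_lag + 1),
        raw=raw,
        smoothed=smooth_running_window(raw, w),
        window=w,
        kind="cross",
    )


def strand_auto_correlation(tags, max_lag: int = 1000, window: int = 25,
                            return_per_strand: bool = False):
    """Mean of the two strands' Pearson autocorrelation profiles.

    A strand with zero variance is excluded with a warning; if both are
    degenerate an error is raised.  ``raw[0]`` is 1 by construction.
    """
    per_strand = {}
    for strand, counts in (("+", tags.counts_plus), ("-", tags.counts_minus)):
        x = counts.astype(float)
        try:
            _check_occupancy(counts, strand)
            if tags.circular:
                per_strand[strand] = _pearson_lags_circular(x, x, max_lag)
            else:
                per_strand[strand] = _pearson_lags_linear(x, x, max_lag)
        except (ZeroVarianceError, ValueError) as exc:
            logger.warning("strand %s excluded from autocorrelation: %s", strand, exc)
    if not per_strand:
        raise ZeroVarianceError("both strands are degenerate")
    raw = np.mean(list(per_strand.values()), axis=0)
    w = min(window, max_lag + 1)
    profile = CorrelationProfile(
        lags=np.arange(max_lag + 1),
        raw=raw,
        smoothed=smooth_running_window(raw, w),
        window=w,
        kind="auto",
    )
    if return_per_strand:
        return profile, per_strand
    return profile


def estimate_fragment_size(
    profile: CorrelationProfile,
    read_length: int = 36,
    exclusion_halfwidth: int = 5,
    min_lag: int = 20,
    min_peak_snr: float = 6.0,
) -> FragmentSizeEstimate:
    """Fragment size = highest significant smoothed peak outside the read-length band.

    Candidate peaks are strict local maxima of the smoothed profile at lags
    >= ``min_lag`` and outside ``read_length ± exclusion_halfwidth``.  A
    candidate counts only if it stands ``min_peak_snr`` robust standard
    deviations (median/MAD over the searched lags) above the profile's
    baseline; otherwise the sample is control-like and a
    :class:`NoEstimateError` is raised.
    """
    if profile.kind != "cross":
        raise ValueError("fragment size is estimated from a cross-correlation profile")
    sm = profile.smoothed
    lags = profile.lags
    band = (read_length - exclusion_halfwidth, read_length + exclusion_halfwidth)
    in_band = (lags >= band[0]) & (lags <= band[1])
    searched = lags >= min_lag

    med = float(np.median(sm[searched]))
    mad = float(np.median(np.abs(sm[searched] - med)))
    scale = max(1.4826 * mad, 1e-12)

    peaks, _ = find_peaks(sm)
    candidates = [p for p in peaks
                  if searched[p] and not in_band[p]
                  and (sm[p] - med) / scale >= min_peak_snr]
    technical = None
    band_peaks = [p for p in peaks if in_band[p]]
    if band_peaks:
        technical = int(max(band_peaks, key=lambda p: sm[p]))
    if not candidates:
        raise NoEstimateError(
            "no significant cross-correlation peak outside the read-length band"
        )
    best = int(max(candidates, key=lambda p: sm[p]))
    return FragmentSizeEstimate(
        fragment_size=best,
        peak_lag=best,
        peak_value=float(sm[best]),
        technical_peak_lag=technical,
        excluded_band=band,
    )


def periodogram(
    profile: CorrelationProfile,
    period_range: tuple[float, float] = (50.0, 500.0),
    nfft: int | None = None,
) -> Periodogram:
    """Discrete Fourier power spectrum of the mean-subtracted correlation profile.

    The profile over lags 1..max_lag is mean-subtracted and transformed; power
    at Fourier frequency k/nfft is ``(2/n)|X_k|^2``, which for ``nfft == n``
    equals the explained sum of squares of a least-squares sinusoid at that
    frequency.  By default the transform is zero-padded so the period grid
    near the dominant period is fine compared with 1 bp.
    """
    lo, hi = period_range
    x = np.asarray(profile.raw[1:], dtype=float)
    n = len(x)
    if n < 2 * lo:
        raise ValueError("profile too short for the requested period range")
    if n < 2 * hi:
        logger.warning("profile shorter than 2x the maximum period; clamping range")
        hi = n / 2.0
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise NoDominantPeriodError("constant correlation profile: flat periodogram")
    if nfft is None:
        nfft = max(4096, int(2 ** np.ceil(np.log2(16 * n))))
    spec = np.fft.rfft(x, nfft)
    k = np.arange(1, nfft // 2 + 1)
    power = (2.0 / n) * np.abs(spec[1:nfft // 2 + 1]) ** 2
    periods = nfft / k
    mask = (periods >= lo) & (periods <= hi)
    if not mask.any():
        raise ValueError("no Fourier frequency falls inside period_range")
    periods_in = periods[mask][::-1]
    power_in = power[mask][::-1]
    dominant = float(periods_in[np.argmax(power_in)])
    return Periodogram(
        periods=periods_in,
        power=power_in,
        dominant_period=dominant,
        period_range=(float(lo), float(hi)),
    )
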