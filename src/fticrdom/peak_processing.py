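"""Peak filtering: m/z window, log-intensity noise threshold, prominence.

The noise threshold is estimated from the spectrum's log-intensity
distribution.  In broadband FT-ICR spectra of natural organic matter the
low-intensity noise population dominates by count and forms a roughly
symmetric mode in log intensity, while real signal contaminates only the
right tail.  The estimator therefore:

1. locates the noise mode with a smoothed Freedman-Diaconis histogram of
   log intensity, then refines it on the data at or below the coarse
   mode's neighborhood (stripping the signal-dominated right tail, whose
   wide overall spread would otherwise force over-coarse bins),
2. estimates the noise spread from the LEFT side only: the distance from
   the mode to the median of the sub-mode observations equals
   0.6745 sigma for a symmetric (Gaussian-in-log) noise population,
3. sets the cutoff at ``exp(mode + k_sigma * sigma)`` (default k=3).

Quantiles of the sub-mode data are used for the spread, rather than the
histogram's half-maximum width, because they average over thousands of
observations instead of a handful of Poisson-noisy bin heights.

Filtering order: the m/z window is applied first, the base peak (for the
relative-prominence rule, default 0.01%) is defined on the windowed list,
and the noise cutoff is applied last.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .spectra_io import PeakList

logger = logging.getLogger("fticrdom")

DEFAULT_MZ_LOW = 100.0
DEFAULT_MZ_HIGH = 700.0
DEFAULT_MIN_PROMINENCE_PCT = 0.01
DEFAULT_K_SIGMA = 3.0
DEFAULT_MIN_PEAKS = 50

_SMOOTH_BINS = 7  # max moving-average window (bins) for the histogram
_MEDIAN_Z = 0.6744897501960817  # half-normal median in sigma units


class NoiseEstimationError(ValueError):
    """Too few peaks, or a degenerate intensity distribution."""


@dataclass(frozen=True)
class NoiseModel:
    """Log-normal noise mode and the derived intensity cutoff."""

    log_mode: float
    log_sigma: float
    k_sigma: float

    @property
    def threshold(self) -> float:
        return math.exp(self.log_mode + self.k_sigma * self.log_sigma)


def estimate_noise_threshold(
    peaks: PeakList,
    k_sigma: float = DEFAULT_K_SIGMA,
    min_peaks: int = DEFAULT_MIN_PEAKS,
) -> NoiseModel:
    """Fit the noise mode of a spectrum's log-intensity distribution."""
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    intensity = peaks.intensity
    intensity = intensity[intensity > 0]
    if len(intensity) < min_peaks:
        raise NoiseEstimationError(
            f"need at least {min_peaks} peaks to estimate noise, got {len(intensity)}")
    x = np.log(intensity)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0 or np.ptp(x) == 0:
        raise NoiseEstimationError("degenerate intensity distribution (no spread)")
    # pass 1: coarse mode from a Freedman-Diaconis histogram of everything
    mode, bin_width = _histogram_mode(x, 2.0 * iqr / len(x) ** (1.0 / 3.0))
    # pass 2: refine on the data at or below the coarse mode's neighborhood,
    # where bin width is set by the noise population alone
    sel = x[x <= mode + 4.0 * bin_width]
    if np.ptp(sel) > 0:
        q75, q25 = np.percentile(sel, [75, 25])
        fine_width = 2.0 * (q75 - q25) / len(sel) ** (1.0 / 3.0)
        if fine_width > 0:
            mode, _ = _histogram_mode(sel, fine_width)
    left = x[x <= mode]
    sigma = (mode - float(np.median(left))) / _MEDIAN_Z
    if sigma <= 0:
        raise NoiseEstimationError("could not resolve the noise mode's width")
    return NoiseModel(log_mode=float(mode), log_sigma=float(sigma), k_sigma=k_sigma)


def _histogram_mode(x: np.ndarray, width: float) -> tuple[float, float]:
    """Tallest-bin center of a lightly smoothed fixed-width histogram.

    Smoothing reduces the Poisson jitter of bin heights; the window stays
    well below the bin count so distinct modes are not merged.
    """
    n_bins = max(10, int(math.ceil(np.ptp(x) / width)))
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    window = min(_SMOOTH_BINS, max(1, n_bins // 8) | 1)
    if window > 1:
        counts = np.convolve(counts, np.full(window, 1.0 / window), mode="same")
    mode_idx = int(np.argmax(counts))
    return float(centers[mode_idx]), float(edges[1] - edges[0])


def filter_peaks(
    peaks: PeakList,
    mz_low: float = DEFAULT_MZ_LOW,
    mz_high: float = DEFAULT_MZ_HIGH,
    min_prominence_pct: float = DEFAULT_MIN_PROMINENCE_PCT,
    noise: NoiseModel | None = None,
) -> PeakList:
    """Apply the m/z window, prominence and noise cuts; idempotent.

    The window is the closed interval [mz_low, mz_high].  The prominence
    cut retains peaks with intensity >= min_prominence_pct/100 of the
    windowed base peak.  An empty result is legal (and logged).
    """
    if not mz_low < mz_high:
        raise ValueError("mz_low must be below mz_high")
    if min_prominence_pct < 0:
        raise ValueError("min_prominence_pct must be non-negative")
    df = peaks.df
    windowed = df[(df["mz"] >= mz_low) & (df["mz"] <= mz_high)]
    keep = windowed
    if len(windowed) and min_prominence_pct > 0:
        floor = min_prominence_pct / 100.0 * windowed["intensity"].max()
        keep = keep[keep["intensity"] >= floor]
    if noise is not None:
        keep = keep[keep["intensity"] >= noise.threshold]
    if len(keep) == 0:
        logger.warning("%s: no peaks survived filtering", peaks.meta.sample_id)
    return peaks.with_df(keep)
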