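"""Baseline image statistics: spreading area, lognormal signal summaries,
KS normality checks, and an information-theoretic two-sample statistic.

These are comparison measures computed alongside the lag-model features, not
inputs to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError
from .image_model import GrayscaleImage

#: Signal pixels are those exceeding this multiple of the image median.
SIGNAL_MEDIAN_FACTOR = 1.1
#: Minimum number of signal pixels required for a lognormal fit.
MIN_SIGNAL_PIXELS = 30


@dataclass(frozen=True)
class SpreadingArea:
    """Binary-threshold footprint of a cell image."""

    threshold: float
    pixel_count: int
    area_um2: float


@dataclass(frozen=True)
class IntensitySummary:
    """Whole-image intensity statistics plus lognormal signal parameters.

    ``lognormal_mu`` / ``lognormal_sigma`` are the sample mean and SD of the
    natural logs of pixels above ``1.1 x median`` (the lognormal MLE); both
    are NaN when fewer than :data:`MIN_SIGNAL_PIXELS` pixels qualify and
    ``insufficient_signal`` is set.
    """

    mean_intensity: float
    total_intensity: float
    background_median: float
    signal_threshold: float
    lognormal_mu: float
    lognormal_sigma: float
    n_signal_pixels: int
    insufficient_signal: bool


def spreading_area(img: GrayscaleImage, threshold: float) -> SpreadingArea:
    """Count pixels strictly above ``threshold`` and convert to area.

    Area uses the image's pixel-size metadata:
    ``pixel_count * (pixel_size_nm / 1000)^2`` square micrometres.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    count = int(np.count_nonzero(img.pixels > threshold))
    area = count * (img.pixel_size / 1000.0) ** 2
    return SpreadingArea(threshold=float(threshold), pixel_count=count, area_um2=area)


def signal_lognormal(img: GrayscaleImage) -> IntensitySummary:
    """Summarise signal pixels (above 1.1x median) with a lognormal fit."""
    px = img.pixels
    med = float(np.median(px))
    thr = SIGNAL_MEDIAN_FACTOR * med
    signal = px[px > thr]
    # logs require positive values; the threshold rule already excludes
    # non-positive pixels whenever the median is non-negative
    signal = signal[signal > 0]
    n_sig = int(signal.size)
    if n_sig < MIN_SIGNAL_PIXELS:
        return IntensitySummary(
            mean_intensity=float(px.mean()),
            total_intensity=float(px.sum()),
            background_median=med,
            signal_threshold=thr,
            lognormal_mu=np.nan,
            lognormal_sigma=np.nan,
            n_signal_pixels=n_sig,
            insufficient_signal=True,
        )
    logs = np.log(signal)
    return IntensitySummary(
        mean_intensity=float(px.mean()),
        total_intensity=float(px.sum()),
        background_median=med,
        signal_threshold=thr,
        lognormal_mu=float(logs.mean()),
        lognormal_sigma=float(logs.std(ddof=0)),
        n_signal_pixels=n_sig,
        insufficient_signal=False,
    )


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's own mean and SD.

    Plug-in parameters make the plain KS p-value conservative (no Lilliefors
    correction is applied).  Returns ``(statistic, p_value)``; the sample
    "passes" normality when ``p >= 0.05``.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 5:
        raise ValueError(f"need at least 5 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance sample")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def kullback_mdi(proj_A: np.ndarray, proj_B: np.ndarray) -> tuple[float, float]:
    """Symmetric KL two-sample statistic for normal-fitted projection sets.

    Fits a normal to each sample and forms the symmetric Kullback-Leibler
    divergence ``J`` between the two fitted normals.  The statistic is
    ``(n_h / 2) * J`` with the harmonic sample size
    ``n_h = 2 n_A n_B / (n_A + n_B)``; under the null of a common normal this
    is asymptotically chi-square with 2 degrees of freedom (one each for mean
    and variance), which supplies the p-value — a documented interpretation,
    not an exact small-sample reference.  Returns ``(statistic, p_value)``.
    """
    a = np.asarray(proj_A, dtype=np.float64).ravel()
    b = np.asarray(proj_B, dtype=np.float64).ravel()
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs at least 5 values")
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise DegenerateDataError("zero-variance sample")
    d2 = (mu_a - mu_b) ** 2
    kl_ab = 0.5 * (np.log(vb / va) + (va + d2) / vb - 1.0)
    kl_ba = 0.5 * (np.log(va / vb) + (vb + d2) / va - 1.0)
    J = kl_ab + kl_ba
    n_h = 2.0 * a.size * b.size / (a.size + b.size)
    statistic = 0.5 * n_h * J
    p_value = float(stats.chi2.sf(statistic, df=2))
    return float(statistic), p_value
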