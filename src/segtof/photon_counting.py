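"""Counting initially detected photons from the early timing signal.

The first nanosecond of each pixel's timing signal is integrated from the
pixel's own trigger time.  Because every fired SPAD contributes the same
pulse, the integrals fall on a periodic "grid" whose pitch is the
single-photon charge; dividing by the calibrated pitch and rounding gives
the initial photon number per pixel.  A 300 ps trigger-time window zeroes
the count of a pixel that triggered much later than its neighbour — such a
pixel saw no prompt (Cherenkov-like) photons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .waveform import Waveform

__all__ = [
    "PhotonCountResult",
    "integrate_initial",
    "calibrate_single_photon_charge",
    "quantize_photon_count",
    "apply_trigger_time_window",
    "poisson_fit",
    "PoissonFit",
]


@dataclass(frozen=True)
class PhotonCountResult:
    """Initial-photon summary of one event (charges in mV*ps)."""

    charge_a: float
    charge_b: float
    n_a: int
    n_b: int
    window_integration: float = 1_000.0
    window_trigger: float = 300.0
    single_photon_charge: float = float("nan")

    @property
    def n_total(self) -> int:
        return self.n_a + self.n_b

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("photon counts must be >= 0")


def integrate_initial(
    waveform: Waveform, start: float | None, window: float = 1_000.0
) -> float | None:
    """Integrate the trace over ``[start, start + window)`` (mV*ps).

    ``start`` is normally the pixel's own leading-edge trigger time; if the
    pixel never triggered (``start is None``) the result is ``None``.
    Rectangular rule over the samples whose time falls in the window, so a
    pulse arriving after the window contributes nothing and a pulse
    arriving late within it contributes only its in-window head.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if start is None:
        return None
    t = waveform.times
    m = (t >= start) & (t < start + window)
    return float(waveform.samples[m].sum() * waveform.dt)


def calibrate_single_photon_charge(
    charges, n_bins: int = 512, min_prominence: float = 0.05
) -> float:
    """Estimate the single-photon charge grid pitch from a charge sample.

    Builds a histogram of the positive charges and measures the spacing of
    its periodic peaks (median spacing of detected local maxima).  With a
    single cluster the cluster location itself is returned.  Robust to the
    inter-grid smear caused by pulses extending past the integration
    window.
    """
    charges = np.asarray(charges, dtype=float)
    charges = charges[np.isfinite(charges) & (charges > 0)]
    if charges.size == 0:
        raise ValueError("need at least one positive charge value")
    lo, hi = charges.min(), np.quantile(charges, 0.995)
    if hi <= lo or (hi - lo) < 1e-9 * max(abs(hi), 1.0):
        return float(np.median(charges))
    counts, edges = np.histogram(charges, bins=n_bins, range=(0.0, hi * 1.05))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # light smoothing suppresses shot noise between grid peaks
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
    peaks, _ = signal.find_peaks(smooth, prominence=min_prominence * smooth.max())
    if peaks.size >= 2:
        return float(np.median(np.diff(centers[peaks])))
    if peaks.size == 1:
        return float(centers[peaks[0]])
    return float(np.median(charges))


def quantize_photon_count(charge: float | None, single_photon_charge: float) -> int:
    """Nearest non-negative photon number for a charge on the grid."""
    if single_photon_charge <= 0:
        raise ValueError("single_photon_charge must be > 0")
    if charge is None:
        return 0
    return max(0, int(round(charge / single_photon_charge)))


def apply_trigger_time_window(
    n_a: int,
    n_b: int,
    t_a: float | None,
    t_b: float | None,
    window: float = 300.0,
) -> tuple[int, int]:
    """Zero the initial count of a pixel that triggered too late.

    If one pixel's trigger comes more than ``window`` ps after the other's
    (strictly later — the boundary itself is kept), its count is set to 0:
    no prompt photons reached it.  A pixel with no trigger at all is also
    zeroed.  Idempotent and symmetric between pixels.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if t_a is None:
        n_a = 0
    if t_b is None:
        n_b = 0
    if t_a is not None and t_b is not None:
        if t_b - t_a > window:
            n_b = 0
        if t_a - t_b > window:
            n_a = 0
    return n_a, n_b


@dataclass(frozen=True)
class PoissonFit:
    """Poisson fit summary: ML mean and chi-square goodness of fit."""

    mean: float
    chi2: float
    dof: int
    pvalue: float


def poisson_fit(counts, min_expected: float = 5.0) -> PoissonFit:
    """Fit a Poisson law to integer counts and test the fit.

    The maximum-likelihood mean is the sample mean.  The chi-square
    statistic compares the observed count histogram against Poisson
    expectations, pooling bins (from both tails inward) until every pooled
    bin expects at least ``min_expected`` events; dof = bins - 2 (one for
    normalisation, one for the fitted mean).
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(int)
    mean = float(counts.mean())
    if mean == 0:
        return PoissonFit(mean=0.0, chi2=0.0, dof=0, pvalue=1.0)
    kmax = int(counts.max())
    observed = np.bincount(counts, minlength=kmax + 2).astype(float)
    expected = stats.poisson.pmf(np.arange(kmax + 2), mean) * counts.size
    expected[-1] += counts.size * stats.poisson.sf(kmax + 1, mean)  # tail mass
    obs_p, exp_p = _pool_bins(observed, expected, min_expected)
    if obs_p.size < 3:
        return PoissonFit(mean=mean, chi2=0.0, dof=0, pvalue=1.0)
    chi2 = float(((obs_p - exp_p) ** 2 / exp_p).sum())
    dof = obs_p.size - 2
    return PoissonFit(mean=mean, chi2=chi2, dof=dof, pvalue=float(stats.chi2.sf(chi2, dof)))


def _pool_bins(observed, expected, min_expected):
    """Pool leading/trailing sparse bins so each kept bin expects enough."""
    lo, hi = 0, expected.size
    while hi - lo > 1 and expected[hi - 1] < min_expected:
        expected[hi - 2] += expected[hi - 1]
        observed[hi - 2] += observed[hi - 1]
        hi -= 1
    while hi - lo > 1 and expected[lo] < min_expected:
        expected[lo + 1] += expected[lo]
        observed[lo + 1] += observed[lo]
        lo += 1
    return observed[lo:hi], expected[lo:hi]
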