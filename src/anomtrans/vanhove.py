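"""Van Hove displacement distributions and their shape/scaling metrics.

For a fixed lag time the van Hove distribution G(dd, dt) is the probability
density of single-axis displacements, pooled over x and y (or per axis).
Crowded media leave three fingerprints on it that this module quantifies:

* departures from Gaussianity — exponential tails from caging and hopping,
  measured by fitting a Gaussian + exponential mixture
  ``G(dd) = A exp(-dd^2 / 2 sigma^2) + B exp(-|dd| / lam)`` and reporting the
  fractional amplitudes ``a = A/(A+B)`` and ``b = B/(A+B)``;
* asymmetry from advective motion — a non-zero mode ``dd_peak`` and unequal
  half-widths of the leading edge (displacements sharing the sign of the
  mode, larger in magnitude) versus the trailing edge, summarized by
  ``asym = (HWHM_trailing - HWHM_leading) / HWHM_leading``;
* scaling — FWHM(dt)^2 grows as dt^alpha, giving an MSD-independent estimate
  of the anomalous exponent per lag regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .spt_msd import PowerLawFit, fit_power_law
from .tracks import TrackTable

logger = logging.getLogger(__name__)

#: lag times (s) at which distributions are evaluated by default; two decades
DEFAULT_LAGS = (0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 3.0, 5.0, 10.0, 15.0)


@dataclass
class VanHoveDistribution:
    lag: float                 # s
    axis: str                  # {"pooled", "x", "y"}
    bin_centers: np.ndarray    # um, uniform
    density: np.ndarray        # 1/um, unit area
    counts: np.ndarray         # raw histogram counts
    n_displacements: int

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, float)
        self.density = np.asarray(self.density, float)
        self.counts = np.asarray(self.counts)
        widths = np.diff(self.bin_centers)
        if len(widths) and not np.allclose(widths, widths[0], rtol=1e-8):
            raise ValueError("bins must be uniform")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"bin_center_um": self.bin_centers,
                      "density": self.density,
                      "counts": self.counts}).to_csv(path, index=False)
        return path


@dataclass
class EdgeStats:
    """Mode and half-width asymmetry of a unimodal displacement distribution."""

    lag: float
    d_peak: float             # um, signed mode (parabolic interpolation)
    hwhm_leading: float       # um, HWHM on the leading side
    hwhm_trailing: float      # um, HWHM on the trailing side
    asym: float               # (HWHM_trailing - HWHM_leading) / HWHM_leading
    fwhm: float               # um
    symmetric: bool = False   # mode within one bin of zero
    unimodal: bool = True


@dataclass
class GaussExpFit:
    A: float                  # Gaussian amplitude, 1/um
    sigma: float              # um
    B: float                  # exponential amplitude, 1/um
    lam: float                # um
    a: float                  # A / (A + B)
    b: float                  # B / (A + B)
    side: str                 # {"both", "leading", "trailing"}
    center: float             # shared center of both terms, um
    resid_norm: float


# ---------------------------------------------------------------------------
# histogram construction
# ---------------------------------------------------------------------------

def compute_van_hove(tracks: TrackTable, lag: float, bin_width: float = 0.05,
                     axis: str = "pooled", min_displacements: int = 100,
                     support_quantile: float = 0.999) -> VanHoveDistribution:
    """Histogram displacements at one lag on symmetric uniform bins.

    ``axis='pooled'`` concatenates x and y displacements of all pairs; the
    support covers the ``support_quantile`` quantile of |dd| and the bins are
    centered so that zero displacement falls on a bin center.
    """
    if axis not in {"pooled", "x", "y"}:
        raise ValueError(f"axis must be pooled/x/y, got {axis!r}")
    dt = tracks.frame_interval
    steps = lag / dt
    if abs(steps - round(steps)) > 1e-6 * max(1.0, steps):
        raise ValueError(f"lag {lag} s is not an integer multiple of the "
                         f"frame interval {dt} s")
    dx, dy = tracks.displacements(int(round(steps)))
    if axis == "pooled":
        d = np.concatenate([dx, dy])
    else:
        d = dx if axis == "x" else dy
    if len(d) < min_displacements:
        raise ValueError(f"only {len(d)} displacements at lag {lag} s "
                         f"(need >= {min_displacements})")
    return histogram_displacements(d, lag=lag, axis=axis, bin_width=bin_width,
                                   support_quantile=support_quantile)


def histogram_displacements(d: np.ndarray, lag: float, axis: str = "pooled",
                            bin_width: float = 0.05,
                            support_quantile: float = 0.999) -> VanHoveDistribution:
    """Unit-area histogram of a displacement sample on zero-centered bins."""
    d = np.asarray(d, float)
    span = np.quantile(np.abs(d), support_quantile)
    m = max(2, int(math.ceil(span / bin_width)) + 1)
    edges = (np.arange(-m, m + 2) - 0.5) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VanHoveDistribution(lag=lag, axis=axis, bin_centers=centers,
                               density=density, counts=counts,
                               n_displacements=len(d))


# ---------------------------------------------------------------------------
# mode, half widths, asymmetry
# ---------------------------------------------------------------------------

def _parabolic_peak(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabolic interpolation of the peak through bin i and neighbors."""
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; fall back to the bin center
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dx = x[1] - x[0]
    peak_y = y1 - 0.25 * (y0 - y2) * delta
    return float(x[i] + delta * dx), float(peak_y)


def _half_crossing(x: np.ndarray, y: np.ndarray, i_peak: int, half: float,
                   direction: int) -> float:
    """Linear-interpolated position where y first drops below half, moving
    from the peak bin in ``direction`` (+1 right, -1 left)."""
    i = i_peak
    while 0 <= i + direction < len(y):
        j = i + direction
        if y[j] < half:
            # interpolate between bins i and j
            frac = (y[i] - half) / (y[i] - y[j])
            return float(x[i] + frac * (x[j] - x[i]))
        i = j
    raise ValueError("half maximum not crossed within histogram support "
                     "(tails under-resolved)")


def _n_modes(density: np.ndarray, rel_prominence: float = 0.1) -> int:
    """Count modes of the 3-bin-smoothed density with appreciable prominence."""
    from scipy.signal import find_peaks

    y = np.convolve(density, np.ones(3) / 3.0, mode="same")
    peaks, _ = find_peaks(y, prominence=rel_prominence * y.max())
    return max(1, len(peaks))


def fwhm_and_edges(dist: VanHoveDistribution) -> EdgeStats:
    """Mode, leading/trailing half-widths and the edge-asymmetry statistic.

    The mode is located by parabolic interpolation through the maximal bin;
    half-maximum crossings are found by linear interpolation on each side.
    The leading edge is the side sharing the sign of the mode; a mode within
    one bin of zero defaults the leading side to positive displacements and
    flags the result symmetric.
    """
    x, y = dist.bin_centers, dist.density
    i_peak = int(np.argmax(y))
    unimodal = _n_modes(y) <= 1
    if not unimodal:
        logger.warning("fwhm_and_edges: distribution at lag %.3g s is not "
                       "unimodal after smoothing", dist.lag)
    d_peak, peak_height = _parabolic_peak(x, y, i_peak)
    half = 0.5 * peak_height
    x_right = _half_crossing(x, y, i_peak, half, +1)
    x_left = _half_crossing(x, y, i_peak, half, -1)
    hw_right = x_right - d_peak
    hw_left = d_peak - x_left
    symmetric = abs(d_peak) < dist.bin_width
    leading_positive = symmetric or d_peak > 0
    if leading_positive:
        hw_lead, hw_trail = hw_right, hw_left
    else:
        hw_lead, hw_trail = hw_left, hw_right
    asym = (hw_trail - hw_lead) / hw_lead
    return EdgeStats(lag=dist.lag, d_peak=d_peak, hwhm_leading=hw_lead,
                     hwhm_trailing=hw_trail, asym=asym,
                     fwhm=hw_lead + hw_trail, symmetric=symmetric,
                     unimodal=unimodal)


# ---------------------------------------------------------------------------
# FWHM scaling -> anomalous exponent
# ---------------------------------------------------------------------------

def fit_fwhm_scaling(stats_series: list[EdgeStats],
                     split_at: float | None = 1.0,
                     min_points: int = 3) -> tuple[PowerLawFit | None, PowerLawFit | None]:
    """Anomalous exponents from FWHM(dt)^2 ~ dt^alpha per lag regime.

    Regresses log FWHM^2 on log dt over the short (dt <= split_at) and long
    (dt >= split_at) regimes; the boundary lag belongs to both.  With
    ``split_at=None`` a single fit over all lags is returned in the first
    slot.  Regimes with fewer than ``min_points`` lags report ``None``.
    """
    lags = np.array([s.lag for s in stats_series], float)
    fwhm2 = np.array([s.fwhm for s in stats_series], float) ** 2
    order = np.argsort(lags)
    lags, fwhm2 = lags[order], fwhm2[order]

    def regime(sel: np.ndarray) -> PowerLawFit | None:
        if sel.sum() < min_points:
            return None
        return fit_power_law(lags[sel], fwhm2[sel])

    if split_at is None:
        return regime(np.ones_like(lags, bool)), None
    return regime(lags <= split_at), regime(lags >= split_at)


# ---------------------------------------------------------------------------
# Gaussian + exponential mixture fits
# ---------------------------------------------------------------------------

def gauss_exp_model(d: np.ndarray, A: float, sigma: float, B: float,
                    lam: float, center: float = 0.0) -> np.ndarray:
    dd = np.asarray(d, float) - center
    return A * np.exp(-dd ** 2 / (2.0 * sigma ** 2)) + B * np.exp(-np.abs(dd) / lam)


def fit_gauss_exp(dist: VanHoveDistribution, side: str = "both",
                  center: float | None = None,
                  lam_starts: tuple[float, ...] = (0.3, 0.6, 1.0, 2.0, 4.0)) -> GaussExpFit:
    """Nonlinear least squares of the Gaussian + exponential sum.

    Both terms share a common center (the mode by default).  ``side`` limits
    the fit to the bins on the leading or trailing side of the center.
    Multiple starting values of ``lam`` (as multiples of the Gaussian width
    guess) guard against the local minimum where the exponential term
    collapses onto the Gaussian core; the best-residual solution wins.
    """
    if side not in {"both", "leading", "trailing"}:
        raise ValueError(f"side must be both/leading/trailing, got {side!r}")
    edges = fwhm_and_edges(dist)
    if center is None:
        # symmetric-flagged distributions share a center at exactly zero
        center = 0.0 if edges.symmetric else edges.d_peak
    x, y = dist.bin_centers, dist.density
    if side != "both":
        leading_positive = edges.symmetric or edges.d_peak > 0
        want_positive = (side == "leading") == leading_positive
        sel = (x - center >= 0) if want_positive else (x - center <= 0)
        x, y = x[sel], y[sel]
    if len(x) < 6:
        raise ValueError(f"too few bins ({len(x)}) for a {side}-side mixture fit")

    sigma0 = max(edges.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))), dist.bin_width)
    peak = float(y.max())
    best = None
    for mult in lam_starts:
        p0 = [0.7 * peak, sigma0, 0.3 * peak, mult * sigma0]
        try:
            popt, _ = optimize.curve_fit(
                lambda d, A, s, B, lam: gauss_exp_model(d, A, s, B, lam, center),
                x, y, p0=p0,
                bounds=([0.0, 1e-6, 0.0, 1e-6], [np.inf] * 4),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(y - gauss_exp_model(x, *popt, center)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError(f"gauss+exp fit failed to converge on side={side!r} "
                           f"at lag {dist.lag} s")
    (A, sigma, B, lam), resid = best
    tot = A + B
    a = A / tot if tot > 0 else float("nan")
    return GaussExpFit(A=A, sigma=sigma, B=B, lam=lam, a=a, b=1.0 - a,
                       side=side, center=center, resid_norm=resid)


def sample_displacement_mixture(n: int, a: float, sigma: float, lam: float,
                                rng: np.random.Generator,
                                center: float = 0.0) -> np.ndarray:
    """Sample displacements whose density is the Gaussian+exponential mixture.

    ``a`` is the amplitude fraction A/(A+B); the corresponding probability
    mass of the Gaussian component is a*sqrt(2 pi)*sigma over the total area
    a*sqrt(2 pi)*sigma + (1-a)*2*lam.
    """
    area_g = a * math.sqrt(2.0 * math.pi) * sigma
    area_e = (1.0 - a) * 2.0 * lam
    w_gauss = area_g / (area_g + area_e)
    pick = rng.random(n) < w_gauss
    out = np.empty(n)
    out[pick] = rng.normal(0.0, sigma, int(pick.sum()))
    out[~pick] = rng.exponential(lam, int((~pick).sum())) * rng.choice(
        [-1.0, 1.0], int((~pick).sum()))
    return out + center


# ---------------------------------------------------------------------------
# per-lag metric tables
# ---------------------------------------------------------------------------

def metrics_table(tracks: TrackTable, lags: tuple[float, ...] = DEFAULT_LAGS,
                  bin_width: float = 0.05, axis: str = "pooled",
                  fit_mixture: bool = True) -> pd.DataFrame:
    """Per-lag mode/width/asymmetry (and optional mixture amplitudes) table."""
    rows = []
    for lag in lags:
        try:
            dist = compute_van_hove(tracks, lag, bin_width=bin_width, axis=axis)
            edges = fwhm_and_edges(dist)
        except ValueError as err:
            logger.warning("van Hove at lag %.3g s skipped: %s", lag, err)
            continue
        row = {"lag_s": lag, "axis": axis, "d_peak_um": edges.d_peak,
               "fwhm_um": edges.fwhm, "hwhm_plus_um": edges.hwhm_leading,
               "hwhm_minus_um": edges.hwhm_trailing, "asym": edges.asym}
        if fit_mixture:
            for side, tag in (("leading", "lead"), ("trailing", "trail")):
                try:
                    fit = fit_gauss_exp(dist, side=side)
                    row[f"a_{tag}"] = fit.a
                    row[f"b_{tag}"] = fit.b
                except (ValueError, RuntimeError) as err:
                    logger.warning("mixture fit (%s) at lag %.3g s failed: %s",
                                   side, lag, err)
                    row[f"a_{tag}"] = np.nan
                    row[f"b_{tag}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def edge_stats_series(tracks: TrackTable, lags: tuple[float, ...] = DEFAULT_LAGS,
                      bin_width: float = 0.05, axis: str = "pooled") -> list[EdgeStats]:
    out = []
    for lag in lags:
        try:
            dist = compute_van_hove(tracks, lag, bin_width=bin_width, axis=axis)
            out.append(fwhm_and_edges(dist))
        except ValueError as err:
            logger.warning("van Hove at lag %.3g s skipped: %s", lag, err)
    return out
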