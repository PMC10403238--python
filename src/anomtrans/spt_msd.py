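"""Ensemble time-averaged MSDs and multi-phasic transport regimes.

The ensemble MSD follows the half-sum convention
``MSD(dt) = 0.5 (<dx^2(dt)> + <dy^2(dt)>)``, time-averaged within each track
and pooled across the ensemble weighted by displacement-pair counts.  From
the curve we extract the multi-phasic regime structure of transport in
crowded active media:

* ``detect_t1`` — the end of the initial power-law regime, defined as the
  largest lag for which a log-log regression from the smallest lag still
  achieves R^2 above a threshold (default 0.99);
* ``detect_t2`` — the onset of superdiffusion, the first local minimum of
  MSD/dt (smoothed) at lags beyond t1;
* ``fit_regimes`` — power-law fits MSD ~ dt^alpha in the short, intermediate
  and long lag windows, yielding alpha_1, alpha_12 and alpha_2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import TrackTable, read_tracks, write_tracks  # noqa: F401  (module surface)

logger = logging.getLogger(__name__)


@dataclass
class MSDCurve:
    lags: np.ndarray          # s, strictly increasing
    msd: np.ndarray           # um^2
    n_pairs: np.ndarray       # displacement pairs per lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(self.lags) <= 0) or np.any(self.lags <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")

    @property
    def msd_over_dt(self) -> np.ndarray:
        return self.msd / self.lags

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"lag_s": self.lags, "msd_um2": self.msd,
                      "n_pairs": self.n_pairs}).to_csv(path, index=False)
        return path


@dataclass
class PowerLawFit:
    exponent: float
    prefactor: float          # um^2 / s^exponent
    dt_lo: float
    dt_hi: float
    r_squared: float
    stderr: float
    n_points: int = 0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(t, float) ** self.exponent


@dataclass
class RegimeResult:
    t1: float | None
    t2: float | None
    alpha1: PowerLawFit | None
    alpha12: PowerLawFit | None
    alpha2: PowerLawFit | None
    has_intermediate: bool = False

    def to_dict(self) -> dict:
        def fit_d(f: PowerLawFit | None) -> dict | None:
            if f is None:
                return None
            return {"exponent": f.exponent, "prefactor": f.prefactor,
                    "dt_lo": f.dt_lo, "dt_hi": f.dt_hi,
                    "r_squared": f.r_squared, "stderr": f.stderr,
                    "n_points": f.n_points}
        return {"t1_s": self.t1, "t2_s": self.t2,
                "alpha1": fit_d(self.alpha1), "alpha12": fit_d(self.alpha12),
                "alpha2": fit_d(self.alpha2),
                "has_intermediate": self.has_intermediate}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path


# ---------------------------------------------------------------------------
# MSD computation
# ---------------------------------------------------------------------------

def _tamsd_contiguous(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Per-track time-averaged squared displacement sums via FFT.

    Returns S[k] = sum over pairs of (x[i+k]-x[i])^2 for k = 1..max_lag.
    O(N log N) autocorrelation algorithm.
    """
    n = len(x)
    fft = np.fft.rfft(x, n=2 * n)
    acf = np.fft.irfft(fft * np.conj(fft))[:n]
    d = x * x
    cs = np.cumsum(d)
    csr = np.cumsum(d[::-1])
    k = np.arange(1, max_lag + 1)
    s1 = 2.0 * d.sum() - cs[k - 1] - csr[k - 1]
    return s1 - 2.0 * acf[1:max_lag + 1]


def compute_msd(tracks: TrackTable, max_lag: float | None = None,
                min_pairs: int = 50) -> MSDCurve:
    """Pooled ensemble time-averaged MSD on the half-sum x/y convention.

    Every integer multiple of the frame interval up to ``max_lag`` (seconds)
    is evaluated; lags whose pooled pair count falls below ``min_pairs`` are
    dropped.  The pooled average weights each track by its pair count, i.e.
    it is the grand mean over all displacement pairs of all particles.
    """
    dt = tracks.frame_interval
    per_particle = tracks.positions()
    longest = max(len(f) for f, _, _ in per_particle.values())
    if max_lag is None:
        max_steps = longest - 1
    else:
        if max_lag < 2 * dt:
            raise ValueError("max_lag must be at least two frame intervals")
        max_steps = min(longest - 1, int(round(max_lag / dt)))
    if max_steps < 1:
        raise ValueError("tracks too short for any lag")

    sum_sq = np.zeros((2, max_steps))
    pairs = np.zeros(max_steps, dtype=np.int64)
    for frames, x, y in per_particle.values():
        n = len(frames)
        if n < 2:
            continue
        kmax = min(n - 1, max_steps)
        if np.all(np.diff(frames) == 1):
            sum_sq[0, :kmax] += _tamsd_contiguous(x, kmax)
            sum_sq[1, :kmax] += _tamsd_contiguous(y, kmax)
            pairs[:kmax] += n - np.arange(1, kmax + 1)
        else:
            span = frames[-1] - frames[0] + 1
            xf = np.full(span, np.nan)
            yf = np.full(span, np.nan)
            idx = frames - frames[0]
            xf[idx], yf[idx] = x, y
            for k in range(1, min(span - 1, max_steps) + 1):
                dx = xf[k:] - xf[:-k]
                good = np.isfinite(dx)
                if not good.any():
                    continue
                dy = (yf[k:] - yf[:-k])[good]
                sum_sq[0, k - 1] += np.sum(dx[good] ** 2)
                sum_sq[1, k - 1] += np.sum(dy ** 2)
                pairs[k - 1] += int(good.sum())

    keep = pairs >= min_pairs
    if not keep.any():
        raise ValueError(f"no lag has >= {min_pairs} displacement pairs")
    k = np.arange(1, max_steps + 1)[keep]
    with np.errstate(invalid="ignore"):
        msd = 0.5 * (sum_sq[0, keep] + sum_sq[1, keep]) / pairs[keep]
    # negative round-off from the FFT path on static input
    msd = np.clip(msd, 0.0, None)
    return MSDCurve(lags=k * dt, msd=msd, n_pairs=pairs[keep])


# ---------------------------------------------------------------------------
# regime detection
# ---------------------------------------------------------------------------

def _loglog_r2(log_t: np.ndarray, log_m: np.ndarray) -> float:
    res = stats.linregress(log_t, log_m)
    return float(res.rvalue ** 2)


def detect_t1(curve: MSDCurve, r2_threshold: float = 0.99,
              min_window: int = 5) -> float:
    """End of the initial power-law regime via expanding-window regression.

    Starting at the smallest lag, windows grow lag-by-lag; the returned t1 is
    the largest window end whose log-log R^2 exceeds ``r2_threshold``.  If
    every window passes (a single power law) the final lag is returned; if
    none passes, the minimum-window end is returned as a conservative floor.
    """
    if len(curve.lags) < min_window:
        raise ValueError(f"need at least {min_window} lags, have {len(curve.lags)}")
    positive = curve.msd > 0
    lags = curve.lags[positive]
    msd = curve.msd[positive]
    if len(lags) < min_window:
        raise ValueError("too few lags with positive MSD")
    log_t, log_m = np.log(lags), np.log(msd)
    best = None
    for end in range(min_window, len(lags) + 1):
        if _loglog_r2(log_t[:end], log_m[:end]) > r2_threshold:
            best = lags[end - 1]
    if best is None:
        logger.warning("detect_t1: no window reached R^2 > %g; returning the "
                       "minimum-window lag", r2_threshold)
        return float(lags[min_window - 1])
    return float(best)


def _smooth_centered(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return y.copy()
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def detect_t2(curve: MSDCurve, smooth_window: int = 5,
              t1: float | None = None) -> float | None:
    """Onset of superdiffusion: first local minimum of smoothed MSD/dt.

    MSD/dt is smoothed with a centered ``smooth_window``-point moving average
    on the lag grid.  When ``t1`` is given, only lags strictly beyond it are
    eligible.  Returns ``None`` when no local minimum exists (monophasic
    curve).  A curve that increases from the very first lag reports the first
    lag (degenerate, logged).  Ties break toward the smaller lag.
    """
    if len(curve.lags) < 10:
        raise ValueError("detect_t2 requires a curve spanning >= 10 lags")
    y = _smooth_centered(curve.msd_over_dt, smooth_window)
    lags = curve.lags
    eligible = np.ones(len(lags), dtype=bool)
    if t1 is not None:
        eligible = lags > t1
    for i in range(1, len(y) - 1):
        if eligible[i] and y[i] < y[i - 1] and y[i] <= y[i + 1]:
            return float(lags[i])
    if t1 is None and y[1] > y[0]:
        logger.warning("detect_t2: MSD/dt increases from the first lag "
                       "(purely superdiffusive curve); reporting the first lag")
        return float(lags[0])
    return None


def fit_power_law(lags: np.ndarray, msd: np.ndarray) -> PowerLawFit:
    """Unweighted least squares of log MSD on log lag."""
    lags = np.asarray(lags, float)
    msd = np.asarray(msd, float)
    good = (msd > 0) & (lags > 0)
    if good.sum() < 3:
        raise ValueError("power-law fit needs >= 3 positive points")
    res = stats.linregress(np.log(lags[good]), np.log(msd[good]))
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(np.exp(res.intercept)),
        dt_lo=float(lags[good].min()),
        dt_hi=float(lags[good].max()),
        r_squared=float(res.rvalue ** 2),
        stderr=float(res.stderr),
        n_points=int(good.sum()),
    )


def _log_subsample(lags: np.ndarray, per_decade: int = 30) -> np.ndarray:
    """Boolean mask keeping <= per_decade log-spaced lags per decade."""
    if len(lags) == 0:
        return np.zeros(0, dtype=bool)
    lo, hi = np.log10(lags[0]), np.log10(lags[-1])
    n = max(2, int(np.ceil((hi - lo) * per_decade)) + 1)
    targets = np.logspace(lo, hi, n)
    idx = np.unique(np.searchsorted(lags, targets).clip(0, len(lags) - 1))
    mask = np.zeros(len(lags), dtype=bool)
    mask[idx] = True
    return mask


def fit_regimes(curve: MSDCurve, t1: float | None, t2: float | None,
                fit_cap: float | None = None, min_points: int = 3,
                min_intermediate: int = 4,
                per_decade: int = 30) -> RegimeResult:
    """Power-law fits in the short, intermediate and long lag regimes.

    Lags are first subsampled to at most ``per_decade`` log-spaced points per
    decade so densely sampled long lags do not dominate the regression.
    ``fit_cap`` (seconds) truncates all regimes, mirroring the practice of
    stopping fits where low statistics dominate.  A regime with fewer than
    ``min_points`` lags reports no exponent; the intermediate exponent is
    fitted only when its window holds at least ``min_intermediate`` lags.
    """
    mask = _log_subsample(curve.lags, per_decade)
    lags = curve.lags[mask]
    msd = curve.msd[mask]
    if fit_cap is not None:
        keep = lags <= fit_cap
        lags, msd = lags[keep], msd[keep]

    def try_fit(sel: np.ndarray) -> PowerLawFit | None:
        if sel.sum() < min_points:
            return None
        try:
            return fit_power_law(lags[sel], msd[sel])
        except ValueError:
            return None

    a1 = try_fit(lags <= t1) if t1 is not None else try_fit(np.ones_like(lags, bool))
    a2 = try_fit(lags >= t2) if t2 is not None else None
    a12 = None
    has_intermediate = False
    if t1 is not None and t2 is not None and t2 > t1:
        sel = (lags >= t1) & (lags <= t2)
        if sel.sum() >= min_intermediate:
            a12 = try_fit(sel)
            has_intermediate = a12 is not None
    return RegimeResult(t1=t1, t2=t2, alpha1=a1, alpha12=a12, alpha2=a2,
                        has_intermediate=has_intermediate)


def analyze_msd(tracks: TrackTable, max_lag: float | None = None,
                r2_threshold: float = 0.99, smooth_window: int = 5,
                fit_cap: float | None = None,
                min_pairs: int = 50) -> tuple[MSDCurve, RegimeResult]:
    """Convenience wrapper: MSD curve, then t1/t2 detection and regime fits."""
    curve = compute_msd(tracks, max_lag=max_lag, min_pairs=min_pairs)
    t1 = detect_t1(curve, r2_threshold=r2_threshold)
    t2 = detect_t2(curve, smooth_window=smooth_window, t1=t1)
    result = fit_regimes(curve, t1, t2, fit_cap=fit_cap)
    return curve, result
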