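"""Differential dynamic microscopy: image structure function and its fits.

The image structure function is the radially averaged power spectrum of
frame differences,

    D(q, dt) = < |FFT2(I(t + dt) - I(t))|^2 >_t,annulus / Npix,

normalized so that summing the unaveraged q-plane reproduces the total power
of the difference image (Parseval).  Each D(q, dt) is fit to the stretched
exponential model

    D(q, dt) = A(q) [1 - exp(-(dt / tau(q))^gamma(q))] + B(q),

with A the dynamic amplitude, B the noise floor, tau the density-fluctuation
decay time and gamma the stretching exponent (gamma < 1: confined or
heterogeneous dynamics; gamma > 1: advective, ballistic-like motion).
The power law tau(q) ~ q^-beta classifies the transport mode — beta = 2
diffusive, beta > 2 subdiffusive, beta < 2 superdiffusive, beta = 1
ballistic — with the anomalous exponent alpha_DDM = 2 / beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .images import ImageStack, load_stack, save_stack  # noqa: F401  (module surface)

logger = logging.getLogger(__name__)


@dataclass
class DDMMatrix:
    q: np.ndarray         # um^-1, radial bin centers (annulus mean |q|)
    lags: np.ndarray      # s
    D: np.ndarray         # (n_q, n_lags)
    n_pairs: np.ndarray   # frame pairs averaged per lag
    n_px: np.ndarray      # pixels per radial annulus
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.D < 0):
            raise ValueError("D must be non-negative")

    def to_csv(self, path: str | Path) -> Path:
        """Long-form (q, lag, D) CSV."""
        path = Path(path)
        qq, ll = np.meshgrid(self.q, self.lags, indexing="ij")
        pd.DataFrame({"q_um_inv": qq.ravel(), "lag_s": ll.ravel(),
                      "D": self.D.ravel()}).to_csv(path, index=False)
        return path


@dataclass
class StretchedExpFit:
    q: np.ndarray
    A: np.ndarray
    B: np.ndarray
    tau: np.ndarray       # s
    gamma: np.ndarray
    converged: np.ndarray  # bool per q
    resid: np.ndarray      # rms residual per q

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"q_um_inv": self.q, "A": self.A, "B": self.B,
                      "tau_s": self.tau, "gamma": self.gamma,
                      "converged": self.converged}).to_csv(path, index=False)
        return path


@dataclass
class ScalingResult:
    beta: float
    beta_stderr: float
    alpha_ddm: float
    tau_prefactor: float        # tau at q = 1 um^-1 from the fit
    q_fit_range: tuple[float, float]
    n_q_used: int
    gamma_mean: float
    gamma_stderr: float
    gamma_q_slope: float        # d gamma / d q diagnostic
    gamma_q_slope_stderr: float
    low_q_plateau: bool
    high_q_uptick: bool

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "beta_stderr": self.beta_stderr,
            "alpha_ddm": self.alpha_ddm, "tau_prefactor_s": self.tau_prefactor,
            "q_fit_lo_um_inv": self.q_fit_range[0],
            "q_fit_hi_um_inv": self.q_fit_range[1],
            "n_q_used": self.n_q_used,
            "gamma_mean": self.gamma_mean, "gamma_stderr": self.gamma_stderr,
            "gamma_q_slope": self.gamma_q_slope,
            "gamma_q_slope_stderr": self.gamma_q_slope_stderr,
            "low_q_plateau": self.low_q_plateau,
            "high_q_uptick": self.high_q_uptick,
        }


def stretched_exp_model(t: np.ndarray, A: float, B: float, tau: float,
                        gamma: float) -> np.ndarray:
    return A * (1.0 - np.exp(-((np.asarray(t, float) / tau) ** gamma))) + B


# ---------------------------------------------------------------------------
# image structure function
# ---------------------------------------------------------------------------

def _log_spaced_steps(max_steps: int, per_decade: int) -> np.ndarray:
    decades = np.log10(max_steps) if max_steps > 1 else 1.0
    n = max(2, int(np.ceil(decades * per_decade)) + 1)
    steps = np.unique(np.round(np.logspace(0, np.log10(max_steps), n)).astype(int))
    return steps[steps >= 1]


def radial_bins(shape: tuple[int, int], pixel_size: float):
    """Flat annulus index map, bin centers (annulus mean |q|) and counts.

    Wave vectors are q = 2 pi f with f the FFT frequencies; annuli are one
    FFT bin wide (dq of the larger image dimension); the zero-frequency bin
    is excluded (index 0 marks it).
    """
    h, w = shape
    qy = 2.0 * np.pi * np.fft.fftfreq(h, d=pixel_size)
    qx = 2.0 * np.pi * np.fft.fftfreq(w, d=pixel_size)
    qmag = np.sqrt(qy[:, None] ** 2 + qx[None, :] ** 2)
    dq = 2.0 * np.pi / (max(h, w) * pixel_size)
    idx = np.floor(qmag / dq + 0.5).astype(int)  # annulus of width dq
    idx_flat = idx.ravel()
    n_bins = idx_flat.max() + 1
    counts = np.bincount(idx_flat, minlength=n_bins)
    qsum = np.bincount(idx_flat, weights=qmag.ravel(), minlength=n_bins)
    centers = np.divide(qsum, counts, out=np.zeros(n_bins), where=counts > 0)
    return idx_flat, centers, counts


def image_structure_function(stack: ImageStack, max_lag: float | None = None,
                             lags_per_decade: int = 20, pair_cap: int = 300,
                             window: str | None = None) -> DDMMatrix:
    """Radially averaged image structure function on log-spaced lags.

    For each lag, |FFT2 of frame differences|^2 / Npix is averaged over up to
    ``pair_cap`` evenly strided frame pairs (deterministic stride), then over
    wave-vector annuli one FFT bin wide.  ``window='hann'`` applies a Hann
    window to every frame before transforming (off by default).
    """
    T = stack.n_frames
    dt = stack.frame_interval
    if max_lag is None:
        max_lag = stack.duration / 2.0
    if max_lag >= stack.duration + dt / 2:
        raise ValueError("max_lag must be below the stack duration")
    max_steps = max(1, int(round(max_lag / dt)))
    max_steps = min(max_steps, T - 1)

    frames = np.asarray(stack.frames, dtype=np.float32)
    if window == "hann":
        h, w = frames.shape[1:]
        frames = frames * (np.hanning(h)[:, None] * np.hanning(w)[None, :]).astype(np.float32)
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    F = np.fft.fft2(frames).astype(np.complex64)
    npix = frames.shape[1] * frames.shape[2]

    idx_flat, centers, counts = radial_bins(frames.shape[1:], stack.pixel_size)
    good_bins = counts > 0
    good_bins[0] = False  # zero-frequency

    steps = _log_spaced_steps(max_steps, lags_per_decade)
    D = np.empty((int(good_bins.sum()), len(steps)))
    n_pairs = np.empty(len(steps), dtype=np.int64)
    for j, k in enumerate(steps):
        n_avail = T - k
        starts = np.unique(np.linspace(0, n_avail - 1,
                                       min(pair_cap, n_avail)).astype(int))
        diff = F[starts + k] - F[starts]
        power = (diff.real ** 2 + diff.imag ** 2).mean(axis=0, dtype=np.float64) / npix
        sums = np.bincount(idx_flat, weights=power.ravel(), minlength=len(counts))
        D[:, j] = sums[good_bins] / counts[good_bins]
        n_pairs[j] = len(starts)
    return DDMMatrix(q=centers[good_bins], lags=steps * dt, D=D,
                     n_pairs=n_pairs, n_px=counts[good_bins],
                     pixel_size=stack.pixel_size, frame_interval=dt)


# ---------------------------------------------------------------------------
# per-q stretched-exponential fits
# ---------------------------------------------------------------------------

def fit_ddm_matrix(matrix: DDMMatrix, lag_cap: float = 100.0,
                   gamma_bounds: tuple[float, float] = (0.2, 3.0),
                   q_max: float | None = None) -> StretchedExpFit:
    """Fit A(q)[1 - exp(-(dt/tau)^gamma)] + B(q) at every q.

    Lags above ``lag_cap`` (seconds) are excluded, where low pair statistics
    dominate.  Initialization: B0 = min D, A0 = max D - B0, tau0 at the lag
    where D first crosses B0 + A0 (1 - 1/e), gamma0 = 1.  Non-converged q
    values are flagged and excluded downstream.  ``q_max`` skips bins above
    it (marked non-converged) — fitting far beyond the optical band is
    wasted work.
    """
    sel = matrix.lags <= lag_cap
    if sel.sum() < 6:
        raise ValueError("need >= 6 lags below lag_cap to fit")
    t = matrix.lags[sel]
    nq = len(matrix.q)
    A = np.full(nq, np.nan)
    B = np.full(nq, np.nan)
    tau = np.full(nq, np.nan)
    gamma = np.full(nq, np.nan)
    resid = np.full(nq, np.nan)
    converged = np.zeros(nq, dtype=bool)
    g_lo, g_hi = gamma_bounds
    for i in range(nq):
        if q_max is not None and matrix.q[i] > q_max:
            continue
        y = matrix.D[i, sel]
        b0 = float(y.min())
        a0 = max(float(y.max()) - b0, 1e-12)
        level = b0 + a0 * (1.0 - np.exp(-1.0))
        above = np.nonzero(y >= level)[0]
        tau0 = float(t[above[0]]) if len(above) else float(t[-1])
        tau0 = max(tau0, float(t[0]) * 0.5)
        try:
            popt, _ = optimize.curve_fit(
                stretched_exp_model, t, y,
                p0=[a0, b0, tau0, 1.0],
                bounds=([0.0, 0.0, 1e-8, g_lo], [np.inf, np.inf, 1e8, g_hi]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        A[i], B[i], tau[i], gamma[i] = popt
        resid[i] = float(np.sqrt(np.mean((y - stretched_exp_model(t, *popt)) ** 2)))
        converged[i] = True
    attempted = nq if q_max is None else int((matrix.q <= q_max).sum())
    n_bad = attempted - int(converged.sum())
    if n_bad > 0:
        logger.info("fit_ddm_matrix: %d of %d fitted q values did not converge",
                    n_bad, attempted)
    return StretchedExpFit(q=matrix.q, A=A, B=B, tau=tau, gamma=gamma,
                           converged=converged, resid=resid)


# ---------------------------------------------------------------------------
# tau(q) scaling and gamma averaging
# ---------------------------------------------------------------------------

def fit_tau_powerlaw(fit: StretchedExpFit,
                     q_range: tuple[float, float] = (1.0, 4.0),
                     min_points: int = 4) -> ScalingResult:
    """beta from log tau ~ -beta log q over converged q in ``q_range``.

    Also attaches the q-averaged stretching exponent over the same band,
    a gamma-vs-q insensitivity diagnostic, and two guard flags: a low-q
    plateau (local slope magnitude of the 3 smallest converged q below 0.5,
    the finite-image signature) and a high-q uptick (tau increasing with q at
    the top of the band, the resolution-limit signature).
    """
    q_lo, q_hi = q_range
    ok = fit.converged & (fit.q >= q_lo) & (fit.q <= q_hi)
    if ok.sum() < min_points:
        raise ValueError(f"only {int(ok.sum())} converged q points in "
                         f"[{q_lo}, {q_hi}] um^-1 (need >= {min_points})")
    q = fit.q[ok]
    tau = fit.tau[ok]
    res = stats.linregress(np.log(q), np.log(tau))
    beta = -float(res.slope)
    alpha = 2.0 / beta

    # low-q plateau: slope over the 3 smallest converged q values overall
    low = np.nonzero(fit.converged)[0][:3]
    low_q_plateau = False
    if len(low) == 3:
        s = stats.linregress(np.log(fit.q[low]), np.log(fit.tau[low]))
        low_q_plateau = abs(float(s.slope)) < 0.5
    # high-q uptick: tau increasing with q among the top 3 in-band points
    top = np.nonzero(ok)[0][-3:]
    high_q_uptick = False
    if len(top) == 3:
        s = stats.linregress(np.log(fit.q[top]), np.log(fit.tau[top]))
        high_q_uptick = float(s.slope) > 0.0

    gmean, gerr, gslope, gslope_err = average_gamma(fit, q_range)
    return ScalingResult(
        beta=beta, beta_stderr=float(res.stderr), alpha_ddm=alpha,
        tau_prefactor=float(np.exp(res.intercept)),
        q_fit_range=(q_lo, q_hi), n_q_used=int(ok.sum()),
        gamma_mean=gmean, gamma_stderr=gerr,
        gamma_q_slope=gslope, gamma_q_slope_stderr=gslope_err,
        low_q_plateau=low_q_plateau, high_q_uptick=high_q_uptick,
    )


def average_gamma(fit: StretchedExpFit,
                  q_range: tuple[float, float] = (1.0, 4.0)
                  ) -> tuple[float, float, float, float]:
    """Mean and standard error of gamma over converged q in range, plus the
    slope of gamma vs q (with stderr) as a q-insensitivity diagnostic."""
    q_lo, q_hi = q_range
    ok = fit.converged & (fit.q >= q_lo) & (fit.q <= q_hi)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"only {n} converged q points in [{q_lo}, {q_hi}] um^-1")
    g = fit.gamma[ok]
    mean = float(np.mean(g))
    stderr = float(np.std(g, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    if np.allclose(g, g[0]):
        slope, slope_err = 0.0, 0.0
    else:
        res = stats.linregress(fit.q[ok], g)
        slope, slope_err = float(res.slope), float(res.stderr)
    return mean, stderr, slope, slope_err


def analyze_stack(stack: ImageStack, max_lag: float | None = None,
                  lag_cap: float = 100.0,
                  q_range: tuple[float, float] = (1.0, 4.0),
                  gamma_bounds: tuple[float, float] = (0.2, 3.0),
                  pair_cap: int = 300,
                  window: str | None = None) -> tuple[DDMMatrix, StretchedExpFit, ScalingResult]:
    """Convenience wrapper: structure function -> per-q fits -> tau(q) scaling."""
    matrix = image_structure_function(stack, max_lag=max_lag, pair_cap=pair_cap,
                                      window=window)
    fits = fit_ddm_matrix(matrix, lag_cap=lag_cap, gamma_bounds=gamma_bounds,
                          q_max=1.5 * q_range[1])
    scaling = fit_tau_powerlaw(fits, q_range=q_range)
    return matrix, fits, scaling
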