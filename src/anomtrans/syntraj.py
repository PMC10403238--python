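"""Synthetic trajectories and rendered image stacks with known transport.

This module emulates the statistical structure of micron-sized tracer motion
in crowded and motor-driven biopolymer networks so that every downstream
analysis stage (MSD regimes, van Hove statistics, DDM) can be validated
against known ground truth:

* fractional Brownian motion (exact covariance, circulant embedding) for
  sub- and superdiffusive motion with a prescribed exponent ``alpha``;
* per-particle constant velocities (quenched disorder) for advective,
  ballistic-like motion, optionally biased along a drift axis;
* Ornstein-Uhlenbeck confinement with Poisson-timed cage hops for
  caging/hopping heterogeneity and exponential van Hove tails;
* a multi-mode sum (caged/fBm + advective) with an analytically known
  crossover lag, mirroring the sub-to-superdiffusive transition of active
  composites;
* a simple widefield renderer (Gaussian PSF, Poisson or Gaussian noise)
  that turns any track table into a 16-bit image stack for DDM.

Conventions.  The ensemble MSD follows the half-sum convention
``MSD(dt) = 0.5 (<dx^2> + <dy^2>)`` so that, per axis,
``Var[x(t)] = K t^alpha`` with ``K`` the generalized transport coefficient
(``K = 2D`` for Brownian motion with per-axis ``<dx^2> = 2 D dt``).
All positions are in micrometres, times in seconds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .images import ImageStack
from .tracks import TrackTable

logger = logging.getLogger(__name__)

# rng stream tags so that each operation draws from an independent,
# reproducible stream derived from the one user-facing seed
_TAG_FBM, _TAG_BALLISTIC, _TAG_CAGED, _TAG_MULTI, _TAG_RENDER = range(5)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry shared by all generators.

    Defaults mirror a light-sheet tracer experiment: 10 fps sampling and a
    ~0.19 um/px camera calibration.
    """

    n_particles: int = 100
    n_frames: int = 1000
    frame_interval: float = 0.1
    pixel_size: float = 0.194
    field_of_view: tuple[int, int] = (256, 256)  # (width px, height px)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.field_of_view[0] * self.pixel_size,
                self.field_of_view[1] * self.pixel_size)


@dataclass
class MotionModel:
    """Parameters of the stochastic motion to synthesize.

    kind : one of {"brownian", "fbm", "ballistic", "caged_hopping", "multimode"}.
    alpha : target MSD exponent of the (sub)diffusive component, in (0, 2].
    generalized_coefficient : K, um^2 / s^alpha (MSD prefactor; K = 2D for
        Brownian motion).
    velocity_mean, velocity_sd : um/s; per-particle speeds are drawn from a
        normal truncated at zero.
    drift_direction_sd : radians of spread about the drift axis; ``None``
        means isotropic (uniform directions).
    drift_axis_angle : mean drift direction, radians; default -pi/2 (-y),
        the skew direction imposed by an elongated sample chamber.
    cage_size : um, stationary per-axis s.d. of the confined motion.
    cage_relax_time : s, OU relaxation time of the confinement.
    hop_rate : 1/s, Poisson rate of cage-center jumps.
    hop_length : um, mean (exponential) jump length.
    crossover_time : s; for multimode, the lag at which the advective MSD
        term overtakes the subdiffusive term (sets the advective amplitude).
    alpha_long : exponent of the multimode long-time component (2 = ballistic).
    """

    kind: str = "brownian"
    alpha: float = 1.0
    generalized_coefficient: float = 0.2
    velocity_mean: float = 0.0
    velocity_sd: float = 0.0
    drift_direction_sd: float | None = None
    drift_axis_angle: float = -math.pi / 2
    cage_size: float = 0.0
    cage_relax_time: float = 1.0
    hop_rate: float = 0.0
    hop_length: float = 0.0
    crossover_time: float | None = None
    alpha_long: float = 2.0
    velocity_dist: str = "truncnorm"  # or "uniform": mean +/- sqrt(3) sd

    def __post_init__(self) -> None:
        if self.kind not in {"brownian", "fbm", "ballistic", "caged_hopping", "multimode"}:
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if not (0.0 < self.alpha <= 2.0):
            raise ValueError(f"alpha must be in (0, 2], got {self.alpha}")
        for name in ("generalized_coefficient", "velocity_mean", "velocity_sd",
                     "cage_size", "cage_relax_time", "hop_rate", "hop_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.velocity_dist not in {"truncnorm", "uniform"}:
            raise ValueError(f"unknown velocity_dist {self.velocity_dist!r}")


@dataclass
class ImageRenderSpec:
    """Point-emitter rendering parameters (widefield-like Gaussian PSF)."""

    psf_sigma: float = 0.4           # um; ~1 um emitter blurred by the optics
    peak_intensity: float = 800.0    # counts at the emitter center
    background_level: float = 100.0  # counts
    noise_model: str = "poisson"     # {"none", "gaussian", "poisson"}
    noise_scale: float = 0.0         # counts, gaussian sd (ignored for poisson)

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.peak_intensity < 0 or self.background_level < 0:
            raise ValueError("intensities must be >= 0")
        if self.noise_model not in {"none", "gaussian", "poisson"}:
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


# ---------------------------------------------------------------------------
# fractional Gaussian noise by circulant embedding (Davies-Harte)
# ---------------------------------------------------------------------------

def fgn_autocovariance(lags: np.ndarray, hurst: float) -> np.ndarray:
    """Autocovariance of unit-variance fGn: 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k ** h2 + np.abs(k - 1.0) ** h2)


def sample_fgn(n_steps: int, hurst: float, n_series: int, rng: np.random.Generator) -> np.ndarray:
    """Exact stationary fGn increments, shape (n_series, n_steps), unit variance.

    Circulant embedding of the fGn covariance: the circulant eigenvalues are
    non-negative for Hurst in (0, 1), so a single FFT of complex Gaussians
    yields two independent exact samples (real and imaginary parts).
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must be in (0, 1)")
    gamma = fgn_autocovariance(np.arange(n_steps + 1), hurst)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    neg = lam.min()
    if neg < -1e-8 * lam.max():
        raise RuntimeError("circulant embedding produced negative eigenvalues")
    lam = np.clip(lam, 0.0, None)
    m = row.size
    n_complex = (n_series + 1) // 2
    z = rng.standard_normal((n_complex, m)) + 1j * rng.standard_normal((n_complex, m))
    x = np.fft.fft(np.sqrt(lam) * z, axis=1) / math.sqrt(m)
    out = np.empty((2 * n_complex, n_steps))
    out[0::2] = x.real[:, :n_steps]
    out[1::2] = x.imag[:, :n_steps]
    return out[:n_series]


def _initial_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = cfg.fov_um
    return rng.uniform([0.0, 0.0], [w, h], size=(cfg.n_particles, 2))


def _to_table(cfg: SimConfig, x: np.ndarray, y: np.ndarray, source: str,
              meta: dict) -> TrackTable:
    """Assemble (n_particles, n_frames) position arrays into a TrackTable."""
    n_p, n_f = x.shape
    df = pd.DataFrame(
        {
            "particle": np.repeat(np.arange(n_p), n_f),
            "frame": np.tile(np.arange(n_f), n_p),
            "x": x.ravel(),
            "y": y.ravel(),
        }
    )
    return TrackTable(data=df, frame_interval=cfg.frame_interval,
                      pixel_size=cfg.pixel_size, source=source, meta=meta)


def _draw_speeds(model: MotionModel, mean: float, sd: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-particle speeds: zero-truncated normal (default) or uniform with
    the same mean and sd (support mean +/- sqrt(3) sd, clipped at zero)."""
    if sd == 0:
        return np.full(n, float(mean))
    if model.velocity_dist == "uniform":
        half = math.sqrt(3.0) * sd
        return rng.uniform(max(0.0, mean - half), mean + half, n)
    from scipy.stats import truncnorm

    a = (0.0 - mean) / sd
    u = rng.random(n)
    return truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def _directions(n: int, model: MotionModel, rng: np.random.Generator) -> np.ndarray:
    if model.drift_direction_sd is None:
        return rng.uniform(0.0, 2.0 * math.pi, n)
    return model.drift_axis_angle + rng.normal(0.0, model.drift_direction_sd, n)


# ---------------------------------------------------------------------------
# trajectory generators
# ---------------------------------------------------------------------------

def gen_fbm_tracks(cfg: SimConfig, model: MotionModel) -> TrackTable:
    """Fractional Brownian motion tracks with ensemble MSD = K dt^alpha.

    Axes are independent; each axis is exact fBm with Hurst alpha/2 scaled so
    the per-axis variance is ``K t^alpha`` (hence the half-sum MSD equals
    ``K dt^alpha``).  ``alpha`` must be in (0, 2); ``alpha = 1`` is Brownian.
    """
    if model.kind not in {"brownian", "fbm"}:
        raise ValueError("gen_fbm_tracks requires kind 'brownian' or 'fbm'")
    if not (0.0 < model.alpha < 2.0):
        raise ValueError(f"fBm requires alpha in (0, 2), got {model.alpha}")
    rng = np.random.default_rng([cfg.seed, _TAG_FBM])
    origins = _initial_positions(cfg, rng)
    n_steps = cfg.n_frames - 1
    K = model.generalized_coefficient
    if K == 0.0:
        x = np.repeat(origins[:, :1], cfg.n_frames, axis=1)
        y = np.repeat(origins[:, 1:], cfg.n_frames, axis=1)
    else:
        scale = math.sqrt(K) * cfg.frame_interval ** (model.alpha / 2.0)
        incr = sample_fgn(n_steps, model.alpha / 2.0, 2 * cfg.n_particles, rng) * scale
        disp = np.cumsum(incr, axis=1)
        x = np.concatenate(
            [origins[:, :1], origins[:, :1] + disp[: cfg.n_particles]], axis=1)
        y = np.concatenate(
            [origins[:, 1:], origins[:, 1:] + disp[cfg.n_particles:]], axis=1)
    meta = {"model": "fbm", "alpha": model.alpha, "K": K}
    return _to_table(cfg, x, y, "syntraj:fbm", meta)


def gen_ballistic_tracks(cfg: SimConfig, model: MotionModel) -> TrackTable:
    """Straight-path tracks with quenched per-particle velocities.

    Speed magnitudes come from a normal truncated at zero; directions are
    isotropic unless ``drift_direction_sd`` is set, in which case they spread
    about ``drift_axis_angle``.  Optional Brownian jitter is added when
    ``generalized_coefficient`` > 0 (per-axis variance K dt).  With sd = 0 and
    no jitter the half-sum ensemble MSD is exactly ``0.5 v^2 dt^2``.
    """
    if model.velocity_sd < 0:
        raise ValueError("velocity_sd must be >= 0")
    rng = np.random.default_rng([cfg.seed, _TAG_BALLISTIC])
    origins = _initial_positions(cfg, rng)
    speeds = _draw_speeds(model, model.velocity_mean, model.velocity_sd,
                          cfg.n_particles, rng)
    theta = _directions(cfg.n_particles, model, rng)
    t = np.arange(cfg.n_frames) * cfg.frame_interval
    x = origins[:, :1] + np.outer(speeds * np.cos(theta), t)
    y = origins[:, 1:] + np.outer(speeds * np.sin(theta), t)
    if model.generalized_coefficient > 0:
        sd = math.sqrt(model.generalized_coefficient * cfg.frame_interval)
        x[:, 1:] += np.cumsum(rng.normal(0.0, sd, (cfg.n_particles, cfg.n_frames - 1)), axis=1)
        y[:, 1:] += np.cumsum(rng.normal(0.0, sd, (cfg.n_particles, cfg.n_frames - 1)), axis=1)
    meta = {"model": "ballistic", "velocity_mean": model.velocity_mean,
            "velocity_sd": model.velocity_sd, "K_jitter": model.generalized_coefficient}
    return _to_table(cfg, x, y, "syntraj:ballistic", meta)


def gen_caged_hopping_tracks(cfg: SimConfig, model: MotionModel) -> TrackTable:
    """Ornstein-Uhlenbeck confinement with Poisson-timed cage hops.

    Each axis relaxes toward the current cage center with timescale
    ``cage_relax_time`` and stationary s.d. ``cage_size``; between hops the
    half-sum MSD plateaus at ``2 cage_size^2``.  Hops displace the cage center
    by an exponential length (mean ``hop_length``) in a random (or drift-
    biased) direction at rate ``hop_rate``.
    """
    if model.cage_size <= 0:
        raise ValueError("cage_size must be positive")
    if model.hop_rate < 0:
        raise ValueError("hop_rate must be >= 0")
    rng = np.random.default_rng([cfg.seed, _TAG_CAGED])
    n_p, n_f, dt = cfg.n_particles, cfg.n_frames, cfg.frame_interval
    centers = _initial_positions(cfg, rng)  # (n_p, 2)
    s = model.cage_size
    rho = math.exp(-dt / model.cage_relax_time)
    kick = s * math.sqrt(1.0 - rho * rho)
    pos = centers + s * rng.standard_normal((n_p, 2))  # stationary start
    x = np.empty((n_p, n_f))
    y = np.empty((n_p, n_f))
    x[:, 0], y[:, 0] = pos[:, 0], pos[:, 1]
    p_hop = model.hop_rate * dt
    for k in range(1, n_f):
        if p_hop > 0:
            n_hops = rng.poisson(p_hop, n_p)
            movers = n_hops > 0
            if movers.any():
                nm = int(movers.sum())
                length = rng.exponential(model.hop_length, nm) * n_hops[movers]
                ang = _directions(nm, model, rng)
                centers[movers, 0] += length * np.cos(ang)
                centers[movers, 1] += length * np.sin(ang)
        noise = kick * rng.standard_normal((n_p, 2))
        pos = centers + (pos - centers) * rho + noise
        x[:, k], y[:, k] = pos[:, 0], pos[:, 1]
    meta = {"model": "caged_hopping", "cage_size": s,
            "cage_relax_time": model.cage_relax_time,
            "hop_rate": model.hop_rate, "hop_length": model.hop_length,
            "plateau_msd": 2.0 * s * s}
    return _to_table(cfg, x, y, "syntraj:caged", meta)


def multimode_analytic_msd(model: MotionModel) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form ensemble MSD of the multimode model: K1 t^a1 + K2 t^a2."""
    K1 = model.generalized_coefficient
    a1 = model.alpha
    a2 = model.alpha_long
    if model.crossover_time is None:
        return lambda t: K1 * np.asarray(t, float) ** a1
    K2 = K1 * model.crossover_time ** (a1 - a2)
    return lambda t: K1 * np.asarray(t, float) ** a1 + K2 * np.asarray(t, float) ** a2


def multimode_msd_over_dt_minimum(model: MotionModel) -> float | None:
    """Lag of the analytic local minimum of MSD/dt (the crossover detector target)."""
    if model.crossover_time is None or model.alpha_long <= 1.0:
        return None
    a1, a2 = model.alpha, model.alpha_long
    return model.crossover_time * ((1.0 - a1) / (a2 - 1.0)) ** (1.0 / (a2 - a1))


def multimode_effective_exponents(model: MotionModel, lags: np.ndarray,
                                  t1: float | None, t2: float | None,
                                  fit_cap: float | None = None) -> dict:
    """Regime exponents of the analytic multimode MSD over given fit windows.

    Because the analytic MSD is a *sum* of two power laws, a finite fit
    window returns slopes between the component exponents; this evaluates
    exactly the slopes an unbiased estimator should recover over the windows
    actually fitted, for use as ground truth in recovery tests.
    """
    from .spt_msd import MSDCurve, fit_regimes

    lags = np.asarray(lags, float)
    curve = MSDCurve(lags=lags, msd=multimode_analytic_msd(model)(lags),
                     n_pairs=np.ones(len(lags), dtype=int))
    rr = fit_regimes(curve, t1, t2, fit_cap=fit_cap)
    return {
        "alpha1": None if rr.alpha1 is None else rr.alpha1.exponent,
        "alpha12": None if rr.alpha12 is None else rr.alpha12.exponent,
        "alpha2": None if rr.alpha2 is None else rr.alpha2.exponent,
    }


def gen_multimode_tracks(cfg: SimConfig, model: MotionModel) -> TrackTable:
    """Subdiffusive fBm plus an advective component with a known crossover.

    The advective term is ballistic (``alpha_long = 2``, quenched per-particle
    speeds rescaled so the sample mean-square speed matches the analytic
    amplitude exactly) or, for ``alpha_long`` in (0, 2), a superdiffusive fBm
    component.  The two analytic MSD terms are equal at ``crossover_time``.
    Ground truth (input exponents, amplitudes, analytic MSD/dt minimum) is
    recorded in the output metadata.
    """
    if model.kind != "multimode":
        raise ValueError("gen_multimode_tracks requires kind 'multimode'")
    rng = np.random.default_rng([cfg.seed, _TAG_MULTI])
    sub_model = MotionModel(kind="fbm", alpha=model.alpha,
                            generalized_coefficient=model.generalized_coefficient)
    sub_cfg = SimConfig(**{**asdict(cfg), "seed": cfg.seed})
    sub = gen_fbm_tracks(sub_cfg, sub_model)
    n_p, n_f, dt = cfg.n_particles, cfg.n_frames, cfg.frame_interval
    xs = sub.data["x"].to_numpy().reshape(n_p, n_f)
    ys = sub.data["y"].to_numpy().reshape(n_p, n_f)

    meta = {"model": "multimode", "alpha_short": model.alpha,
            "alpha_long": model.alpha_long,
            "K": model.generalized_coefficient,
            "crossover_time": model.crossover_time}
    if model.crossover_time is not None:
        t_max = (n_f - 1) * dt
        if not (dt <= model.crossover_time <= t_max):
            logger.warning("crossover_time %.3g s outside simulated lag range "
                           "[%.3g, %.3g] s", model.crossover_time, dt, t_max)
            meta["crossover_out_of_range"] = True
        K2 = model.generalized_coefficient * model.crossover_time ** (
            model.alpha - model.alpha_long)
        meta["K_long"] = K2
        if model.alpha_long >= 2.0:
            # ballistic: half-sum MSD of random-direction speeds is 0.5 <v^2> t^2
            v_rms = math.sqrt(2.0 * K2)
            sd = model.velocity_sd if model.velocity_sd > 0 else 0.3 * v_rms
            speeds = _draw_speeds(model, v_rms, sd, n_p, rng)
            speeds *= v_rms / math.sqrt(np.mean(speeds ** 2))  # exact amplitude
            theta = _directions(n_p, model, rng)
            t = np.arange(n_f) * dt
            xs = xs + np.outer(speeds * np.cos(theta), t)
            ys = ys + np.outer(speeds * np.sin(theta), t)
            meta["speeds_rms"] = v_rms
        else:
            adv_model = MotionModel(kind="fbm", alpha=model.alpha_long,
                                    generalized_coefficient=K2)
            adv_cfg = SimConfig(**{**asdict(cfg), "seed": cfg.seed + 1_000_003})
            adv = gen_fbm_tracks(adv_cfg, adv_model)
            xs = xs + (adv.data["x"].to_numpy().reshape(n_p, n_f)
                       - adv.data["x"].to_numpy().reshape(n_p, n_f)[:, :1])
            ys = ys + (adv.data["y"].to_numpy().reshape(n_p, n_f)
                       - adv.data["y"].to_numpy().reshape(n_p, n_f)[:, :1])
        meta["msd_over_dt_min_time"] = multimode_msd_over_dt_minimum(model)
    return _to_table(cfg, xs, ys, "syntraj:multimode", meta)


def generate_tracks(cfg: SimConfig, model: MotionModel) -> TrackTable:
    """Dispatch on ``model.kind``."""
    if model.kind in {"brownian", "fbm"}:
        return gen_fbm_tracks(cfg, model)
    if model.kind == "ballistic":
        return gen_ballistic_tracks(cfg, model)
    if model.kind == "caged_hopping":
        return gen_caged_hopping_tracks(cfg, model)
    if model.kind == "multimode":
        return gen_multimode_tracks(cfg, model)
    raise ValueError(f"unknown motion kind {model.kind!r}")


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def render_image_stack(tracks: TrackTable, spec: ImageRenderSpec,
                       cfg: SimConfig) -> ImageStack:
    """Render tracks to a 16-bit stack of Gaussian emitters plus noise.

    Each frame is ``background_level`` plus, for every particle inside the
    field of view in that frame, a symmetric Gaussian of width ``psf_sigma``
    and peak ``peak_intensity``.  Particles outside the field are simply not
    rendered.  Pixel (0, 0) is the top-left corner; positions in um map to
    pixel coordinates via ``pixel_size``.
    """
    if len(tracks.data) == 0:
        raise ValueError("cannot render an empty TrackTable")
    rng = np.random.default_rng([cfg.seed, _TAG_RENDER])
    w_px, h_px = cfg.field_of_view
    sigma_px = spec.psf_sigma / cfg.pixel_size
    r = max(1, int(math.ceil(4.0 * sigma_px)))
    win = 2 * r + 1
    off = np.arange(-r, r + 1)

    n_frames = int(tracks.data["frame"].max()) + 1
    stack = np.full((n_frames, h_px, w_px), float(spec.background_level), dtype=np.float64)

    frames_idx = tracks.data["frame"].to_numpy(int)
    cols = tracks.data["x"].to_numpy(float) / cfg.pixel_size
    rows = tracks.data["y"].to_numpy(float) / cfg.pixel_size
    order = np.argsort(frames_idx, kind="stable")
    frames_idx, cols, rows = frames_idx[order], cols[order], rows[order]
    bounds = np.searchsorted(frames_idx, np.arange(n_frames + 1))

    for t in range(n_frames):
        lo, hi = bounds[t], bounds[t + 1]
        if hi == lo:
            continue
        c, rw = cols[lo:hi], rows[lo:hi]
        inside = (c >= 0) & (c < w_px) & (rw >= 0) & (rw < h_px)
        if not inside.any():
            continue
        c, rw = c[inside], rw[inside]
        c0 = np.round(c).astype(int)
        r0 = np.round(rw).astype(int)
        # (n, win) per-axis Gaussian profiles around each emitter
        gx = np.exp(-((c0[:, None] + off[None, :] - c[:, None]) ** 2)
                    / (2.0 * sigma_px ** 2))
        gy = np.exp(-((r0[:, None] + off[None, :] - rw[:, None]) ** 2)
                    / (2.0 * sigma_px ** 2))
        patch = spec.peak_intensity * gy[:, :, None] * gx[:, None, :]
        rr = r0[:, None, None] + off[None, :, None]
        cc = c0[:, None, None] + off[None, None, :]
        rr_b = np.broadcast_to(rr, patch.shape)
        cc_b = np.broadcast_to(cc, patch.shape)
        ok = (rr_b >= 0) & (rr_b < h_px) & (cc_b >= 0) & (cc_b < w_px)
        np.add.at(stack[t], (rr_b[ok], cc_b[ok]), patch[ok])

    if spec.noise_model == "poisson":
        stack = rng.poisson(np.clip(stack, 0.0, None)).astype(np.float64)
    elif spec.noise_model == "gaussian":
        stack = stack + rng.normal(0.0, spec.noise_scale, stack.shape)
    frames_u16 = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return ImageStack(frames=frames_u16, pixel_size=cfg.pixel_size,
                      frame_interval=tracks.frame_interval)


def ground_truth_sidecar(tracks: TrackTable) -> dict:
    """Flat key-value ground-truth record for test harnesses."""
    out = {}
    for k, v in tracks.meta.items():
        out[k] = v if v is not None else "none"
    return out
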