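"""Generator correctness: exact covariances, closed-form MSDs, determinism."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps

from anomtrans import syntraj as st
from anomtrans import spt_msd, vanhove
from anomtrans.spt_msd import compute_msd, detect_t2, fit_power_law


def small_cfg(**kw):
    defaults = dict(n_particles=50, n_frames=200, frame_interval=0.1,
                    pixel_size=0.2, field_of_view=(128, 128), seed=9)
    defaults.update(kw)
    return st.SimConfig(**defaults)


# ---------------------------------------------------------------------------
# validation and determinism
# ---------------------------------------------------------------------------

def test_config_and_model_validation():
    with pytest.raises(ValueError):
        st.SimConfig(n_particles=0)
    with pytest.raises(ValueError):
        st.SimConfig(n_frames=1)
    with pytest.raises(ValueError):
        st.MotionModel(alpha=0.0)
    with pytest.raises(ValueError):
        st.MotionModel(alpha=2.5)
    with pytest.raises(ValueError):
        st.MotionModel(velocity_sd=-1.0)
    with pytest.raises(ValueError):
        st.MotionModel(hop_rate=-0.1)
    # fBm generator itself rejects the alpha = 2 boundary
    with pytest.raises(ValueError):
        st.gen_fbm_tracks(small_cfg(), st.MotionModel(kind="fbm", alpha=2.0))


@pytest.mark.parametrize("kind,model_kw", [
    ("fbm", dict(alpha=0.5, generalized_coefficient=0.05)),
    ("ballistic", dict(velocity_mean=0.1, velocity_sd=0.03)),
    ("caged_hopping", dict(cage_size=0.3, hop_rate=0.2, hop_length=0.5)),
    ("multimode", dict(alpha=0.4, generalized_coefficient=0.01, crossover_time=3.0)),
])
def test_seed_determinism(kind, model_kw):
    """Identical SimConfig/MotionModel must give bit-identical trajectories."""
    cfg = small_cfg()
    model = st.MotionModel(kind=kind, **model_kw)
    a = st.generate_tracks(cfg, model)
    b = st.generate_tracks(cfg, model)
    assert a.data.equals(b.data)
    c = st.generate_tracks(small_cfg(seed=10), model)
    assert not a.data.equals(c.data)


def test_render_determinism():
    cfg = small_cfg(n_particles=10, n_frames=20)
    tracks = st.gen_fbm_tracks(cfg, st.MotionModel(kind="brownian",
                                                   generalized_coefficient=0.4))
    spec = st.ImageRenderSpec()
    s1 = st.render_image_stack(tracks, spec, cfg)
    s2 = st.render_image_stack(tracks, spec, cfg)
    np.testing.assert_array_equal(s1.frames, s2.frames)


# ---------------------------------------------------------------------------
# fBm
# ---------------------------------------------------------------------------

def test_fbm_zero_coefficient_is_static():
    cfg = small_cfg()
    tracks = st.gen_fbm_tracks(cfg, st.MotionModel(kind="fbm", alpha=1.0,
                                                   generalized_coefficient=0.0))
    for _, grp in tracks.data.groupby("particle"):
        assert grp["x"].nunique() == 1
        assert grp["y"].nunique() == 1


def test_brownian_increments_uncorrelated():
    cfg = st.SimConfig(n_particles=200, n_frames=1000, seed=21)
    tracks = st.gen_fbm_tracks(cfg, st.MotionModel(kind="brownian", alpha=1.0,
                                                   generalized_coefficient=0.2))
    x = tracks.data["x"].to_numpy().reshape(200, 1000)
    inc = np.diff(x, axis=1)
    a, b = inc[:, :-1].ravel(), inc[:, 1:].ravel()
    rho = np.corrcoef(a, b)[0, 1]
    assert abs(rho) < 3.0 / math.sqrt(a.size)


@pytest.mark.parametrize("alpha", [0.4, 1.0, 1.4])
def test_fgn_sample_covariance_matches_analytic(alpha):
    """Sample increment covariance equals the fGn covariance within MC error."""
    rng = np.random.default_rng(5)
    n_series, n_steps = 50, 400  # 2e4 increments
    inc = st.sample_fgn(n_steps, alpha / 2.0, n_series, rng)
    expected = st.fgn_autocovariance(np.arange(6), alpha / 2.0)
    n_eff = n_series * (n_steps - 5)
    for k in range(6):
        prod = inc[:, : n_steps - k] * inc[:, k:]
        got = prod.mean()
        mc_sd = prod.std() / math.sqrt(n_eff)
        assert got == pytest.approx(expected[k], abs=4 * mc_sd + 1e-3)


def test_fbm_ensemble_msd_matches_closed_form():
    """alpha = 0.5, K = 0.05: ensemble MSD fits K dt^0.5 (exponent +/- 0.05)."""
    cfg = st.SimConfig(n_particles=200, n_frames=2000, frame_interval=0.1, seed=31)
    model = st.MotionModel(kind="fbm", alpha=0.5, generalized_coefficient=0.05)
    curve = compute_msd(st.gen_fbm_tracks(cfg, model), max_lag=20.0)
    fit = fit_power_law(curve.lags, curve.msd)
    assert fit.exponent == pytest.approx(0.5, abs=0.05)
    assert fit.prefactor == pytest.approx(0.05, rel=0.10)
    # pointwise agreement with the independent closed form K dt^0.5
    closed = 0.05 * curve.lags ** 0.5
    assert np.max(np.abs(curve.msd / closed - 1.0)) < 0.25


# ---------------------------------------------------------------------------
# ballistic
# ---------------------------------------------------------------------------

def test_ballistic_exact_half_sum_msd():
    """sd = 0, no jitter, v = 1 um/s: MSD(dt) = 0.5 v^2 dt^2 to fp precision."""
    cfg = small_cfg(n_particles=40, n_frames=50)
    model = st.MotionModel(kind="ballistic", velocity_mean=1.0, velocity_sd=0.0,
                           generalized_coefficient=0.0)
    curve = compute_msd(st.gen_ballistic_tracks(cfg, model), min_pairs=1)
    np.testing.assert_allclose(curve.msd, 0.5 * curve.lags ** 2, rtol=1e-9)


def test_ballistic_zero_velocity_reduces_to_brownian():
    cfg = st.SimConfig(n_particles=150, n_frames=1000, seed=13)
    model = st.MotionModel(kind="ballistic", velocity_mean=0.0, velocity_sd=0.0,
                           generalized_coefficient=0.2)  # K = 2D, D = 0.1
    curve = compute_msd(st.gen_ballistic_tracks(cfg, model), max_lag=10.0)
    fit = fit_power_law(curve.lags, curve.msd)
    assert fit.exponent == pytest.approx(1.0, abs=0.05)


def test_ballistic_plus_cage_crossover_detected():
    """MSD/dt local minimum lands within 2x of the analytic term crossover."""
    cage, v = 0.25, 0.05
    cfg = st.SimConfig(n_particles=200, n_frames=1500, seed=14)
    caged = st.gen_caged_hopping_tracks(
        cfg, st.MotionModel(kind="caged_hopping", cage_size=cage,
                            cage_relax_time=0.5, hop_rate=0.0))
    ball = st.gen_ballistic_tracks(
        cfg, st.MotionModel(kind="ballistic", velocity_mean=v, velocity_sd=0.0,
                            generalized_coefficient=0.0))
    combined = caged.data.copy()
    combined[["x", "y"]] += ball.data[["x", "y"]].to_numpy() \
        - ball.data.groupby("particle")[["x", "y"]].transform("first").to_numpy()
    tracks = st.TrackTable(data=combined, frame_interval=cfg.frame_interval)
    curve = compute_msd(tracks, max_lag=60.0)
    t2 = detect_t2(curve)
    # analytic crossover: 2 cage^2 = 0.5 v^2 t^2
    t_cross = math.sqrt(2.0 * 2.0 * cage ** 2 / v ** 2)
    assert t2 is not None
    assert t_cross / 2.0 <= t2 <= t_cross * 2.0


def test_isotropy_without_drift():
    """With drift disabled, dx and dy distributions are indistinguishable.

    Independent samples only: lag-1 Brownian increments (independent within
    and across tracks) and per-particle ballistic velocity components
    (independent across particles); pooled overlapping-window displacements
    of quenched-velocity tracks are not i.i.d. and would invalidate the test.
    """
    cfg = st.SimConfig(n_particles=100, n_frames=101, seed=17)
    tracks = st.gen_fbm_tracks(cfg, st.MotionModel(kind="brownian",
                                                   generalized_coefficient=0.2))
    dx, dy = tracks.displacements(1)  # 10^4 independent increments
    assert sps.ks_2samp(dx, dy).pvalue > 0.01

    cfg = st.SimConfig(n_particles=3000, n_frames=3, seed=17)
    model = st.MotionModel(kind="ballistic", velocity_mean=0.05, velocity_sd=0.02)
    ball = st.gen_ballistic_tracks(cfg, model)
    vx, vy = ball.displacements(1)  # one velocity sample per particle per step
    assert sps.ks_2samp(vx[::2], vy[1::2]).pvalue > 0.01


# ---------------------------------------------------------------------------
# caged / hopping
# ---------------------------------------------------------------------------

def test_cage_plateau_without_hops():
    """OU confinement plateaus at 2 cage_size^2 on the half-sum convention."""
    cfg = st.SimConfig(n_particles=300, n_frames=600, seed=15)
    model = st.MotionModel(kind="caged_hopping", cage_size=0.3,
                           cage_relax_time=0.5, hop_rate=0.0)
    curve = compute_msd(st.gen_caged_hopping_tracks(cfg, model))
    plateau = curve.msd[curve.lags > 10 * model.cage_relax_time].mean()
    assert plateau == pytest.approx(2.0 * 0.3 ** 2, rel=0.10)


def test_cage_distribution_gaussian_without_hops():
    """OU is Gaussian: long-lag displacement mixture fit gives b < 0.05."""
    cfg = st.SimConfig(n_particles=300, n_frames=600, seed=16)
    model = st.MotionModel(kind="caged_hopping", cage_size=0.3,
                           cage_relax_time=0.5, hop_rate=0.0)
    tracks = st.gen_caged_hopping_tracks(cfg, model)
    dist = vanhove.compute_van_hove(tracks, lag=5.0, bin_width=0.03)
    fit = vanhove.fit_gauss_exp(dist)
    assert fit.b < 0.05


def test_hopping_produces_exponential_tails():
    """Poisson hops at 0.2/s with 0.5 um mean length: b > 0.1 at 5 s lag."""
    cfg = st.SimConfig(n_particles=300, n_frames=600, seed=18)
    model = st.MotionModel(kind="caged_hopping", cage_size=0.1,
                           cage_relax_time=0.5, hop_rate=0.2, hop_length=0.5)
    tracks = st.gen_caged_hopping_tracks(cfg, model)
    dist = vanhove.compute_van_hove(tracks, lag=5.0, bin_width=0.05)
    fit = vanhove.fit_gauss_exp(dist)
    assert fit.b > 0.1


# ---------------------------------------------------------------------------
# multimode
# ---------------------------------------------------------------------------

def test_multimode_pure_subdiffusion_without_advection(multimode_tracks):
    cfg = st.SimConfig(n_particles=100, n_frames=1000, seed=19)
    model = st.MotionModel(kind="multimode", alpha=0.4,
                           generalized_coefficient=0.01, crossover_time=None)
    curve = compute_msd(st.gen_multimode_tracks(cfg, model), max_lag=50.0)
    t1 = spt_msd.detect_t1(curve)
    assert detect_t2(curve, t1=t1) is None


def test_multimode_crossover_metadata_and_detection(multimode_tracks):
    tracks, model = multimode_tracks
    # amplitude construction makes the analytic terms cross exactly at 5 s
    K2 = tracks.meta["K_long"]
    t_eq = (model.generalized_coefficient / K2) ** (1.0 / (2.0 - model.alpha))
    assert t_eq == pytest.approx(5.0, rel=0.05)
    curve = compute_msd(tracks, max_lag=100.0)
    t1 = spt_msd.detect_t1(curve)
    t2 = detect_t2(curve, t1=t1)
    assert t2 is not None and 2.5 <= t2 <= 10.0
    assert t1 <= t2


def test_multimode_superdiffusive_fbm_component():
    """alpha_long = 1.6 long-time component: both exponents recovered."""
    cfg = st.SimConfig(n_particles=200, n_frames=2000, seed=23)
    model = st.MotionModel(kind="multimode", alpha=0.35, alpha_long=1.6,
                           generalized_coefficient=0.01, crossover_time=5.0)
    curve = compute_msd(st.gen_multimode_tracks(cfg, model), max_lag=100.0)
    t1 = spt_msd.detect_t1(curve)
    t2 = detect_t2(curve, t1=t1)
    rr = spt_msd.fit_regimes(curve, t1, t2, fit_cap=100.0)
    eff = st.multimode_effective_exponents(model, curve.lags, t1, t2, fit_cap=100.0)
    assert rr.alpha1.exponent == pytest.approx(eff["alpha1"], abs=0.1)
    assert rr.alpha2.exponent == pytest.approx(eff["alpha2"], abs=0.1)


def test_multimode_drift_skews_distributions():
    """Unidirectional drift along -y: y van Hove mode grows negative with lag."""
    cfg = st.SimConfig(n_particles=300, n_frames=400, seed=25)
    model = st.MotionModel(kind="multimode", alpha=0.4,
                           generalized_coefficient=0.005, crossover_time=2.0,
                           drift_direction_sd=0.2)  # about the default -y axis
    tracks = st.gen_multimode_tracks(cfg, model)
    peaks = []
    for lag in (2.0, 5.0, 10.0):
        dist = vanhove.compute_van_hove(tracks, lag=lag, bin_width=0.05, axis="y")
        peaks.append(vanhove.fwhm_and_edges(dist).d_peak)
    assert peaks[0] < 0 and peaks[-1] < 0
    assert abs(peaks[-1]) > abs(peaks[0])
    # pooled distribution skews negative as well
    dist = vanhove.compute_van_hove(tracks, lag=10.0, bin_width=0.05)
    d = np.concatenate(tracks.displacements(100))
    assert sps.skew(d) < 0


def test_multimode_out_of_range_crossover_warns(caplog):
    cfg = small_cfg(n_frames=50)
    model = st.MotionModel(kind="multimode", alpha=0.4,
                           generalized_coefficient=0.01, crossover_time=500.0)
    with caplog.at_level("WARNING"):
        tracks = st.gen_multimode_tracks(cfg, model)
    assert tracks.meta.get("crossover_out_of_range")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_render_static_particles_identical_frames():
    cfg = small_cfg(n_particles=5, n_frames=10)
    tracks = st.gen_fbm_tracks(cfg, st.MotionModel(kind="fbm", alpha=1.0,
                                                   generalized_coefficient=0.0))
    spec = st.ImageRenderSpec(noise_model="none")
    stack = st.render_image_stack(tracks, spec, cfg)
    for t in range(1, stack.n_frames):
        np.testing.assert_array_equal(stack.frames[t], stack.frames[0])


def test_render_position_mapping_and_intensity():
    """An emitter at (x, y) um peaks at pixel (row y/px, col x/px)."""
    cfg = st.SimConfig(n_particles=1, n_frames=2, pixel_size=0.2,
                       field_of_view=(64, 64), seed=1)
    import pandas as pd
    data = pd.DataFrame({"particle": [0, 0], "frame": [0, 1],
                         "x": [4.0, 4.0], "y": [8.0, 8.0]})
    tracks = st.TrackTable(data=data, frame_interval=0.1, pixel_size=0.2)
    spec = st.ImageRenderSpec(noise_model="none", background_level=10,
                              peak_intensity=500)
    stack = st.render_image_stack(tracks, spec, cfg)
    row, col = np.unravel_index(np.argmax(stack.frames[0]), stack.frames[0].shape)
    assert (row, col) == (40, 20)
    assert stack.frames[0][row, col] == pytest.approx(510, abs=2)
    # far corner is pure background
    assert stack.frames[0][0, 0] == 10


def test_render_rejects_empty_tracktable():
    cfg = small_cfg()
    import pandas as pd
    with pytest.raises(ValueError):
        st.TrackTable(data=pd.DataFrame(columns=["particle", "frame", "x", "y"]),
                      frame_interval=0.1)
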