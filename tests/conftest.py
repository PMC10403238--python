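"""Shared fixtures: synthetic ensembles reused across test modules.

Heavy ensembles are session-scoped so the suite generates each once.
"""

from __future__ import annotations

import numpy as np
import pytest

from anomtrans import syntraj as st
from anomtrans.spt_msd import MSDCurve


@pytest.fixture(scope="session")
def brownian_tracks():
    """200 Brownian tracks x 2000 frames, D = 0.1 um^2/s (K = 2D = 0.2)."""
    cfg = st.SimConfig(n_particles=200, n_frames=2000, frame_interval=0.1,
                       pixel_size=0.2, field_of_view=(512, 512), seed=123)
    model = st.MotionModel(kind="brownian", alpha=1.0, generalized_coefficient=0.2)
    return st.gen_fbm_tracks(cfg, model)


@pytest.fixture(scope="session")
def multimode_tracks():
    """Caged-to-advective ensemble with an analytic crossover at 5 s."""
    cfg = st.SimConfig(n_particles=200, n_frames=2000, frame_interval=0.1, seed=77)
    model = st.MotionModel(kind="multimode", alpha=0.35,
                           generalized_coefficient=0.01, crossover_time=5.0)
    return st.gen_multimode_tracks(cfg, model), model


@pytest.fixture(scope="session")
def rendered_brownian():
    """Rendered Brownian stack (D = 0.2 um^2/s) plus its source tracks.

    Moderate geometry (128 px, 400 frames) keeps unit tests quick; the
    acceptance suite exercises the full 256 px / 800 frame geometry.
    """
    cfg = st.SimConfig(n_particles=100, n_frames=400, frame_interval=0.1,
                       pixel_size=0.2, field_of_view=(128, 128), seed=55)
    model = st.MotionModel(kind="brownian", alpha=1.0, generalized_coefficient=0.4)
    tracks = st.gen_fbm_tracks(cfg, model)
    stack = st.render_image_stack(tracks, st.ImageRenderSpec(), cfg)
    return tracks, stack, cfg


def make_curve(lags: np.ndarray, msd: np.ndarray) -> MSDCurve:
    return MSDCurve(lags=np.asarray(lags, float), msd=np.asarray(msd, float),
                    n_pairs=np.full(len(lags), 1000, dtype=int))
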