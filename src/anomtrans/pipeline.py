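"""Orchestration: run both analysis tracks per condition and join the metrics.

A single configuration (dict or YAML file) names, per experimental condition,
a track table and/or an image stack plus the calibration, and the pipeline
executes the real-space stage (MSD regimes, van Hove metrics and FWHM
scaling) and the reciprocal-space stage (DDM) as inputs allow.  The result is
a cross-method summary table comparing the anomalous exponent estimated from
the MSD, the van Hove width scaling and the DDM tau(q) power law, together
with the regime timescales and the q-averaged stretching exponent.  Partial
inputs produce partial rows with explicit nulls, never silent gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ddm, spt_msd, vanhove
from .images import ImageStack, load_stack
from .tracks import TrackTable, read_tracks

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "label", "phi_a", "alpha_msd_1", "alpha_msd_1_err", "alpha_msd_12",
    "alpha_msd_12_err", "alpha_msd_2", "alpha_msd_2_err", "t1_s", "t2_s",
    "alpha_vh_1", "alpha_vh_1_err", "alpha_vh_2", "alpha_vh_2_err",
    "alpha_ddm", "beta", "beta_err", "gamma_mean", "gamma_stderr",
]


@dataclass
class ConditionMeta:
    """Identity of one experimental condition.

    phi_a is the molar actin fraction of an actin-microtubule composite (a
    pure condition label here); myosin_ratio the motor:actin molar ratio;
    total_molar the combined protein molarity in uM.
    """

    label: str
    phi_a: float = float("nan")
    myosin_ratio: float = float("nan")
    total_molar: float = float("nan")
    notes: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.phi_a) and not (0.0 <= self.phi_a <= 1.0):
            raise ValueError("phi_a must be in [0, 1]")


@dataclass
class TransportSummary:
    """Joined per-condition metric table (one row per condition)."""

    table: pd.DataFrame
    details: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    def to_text(self) -> str:
        with pd.option_context("display.width", 200, "display.max_columns", 50):
            return self.table.round(4).to_string(index=False)


def compute_detectability_timescale(resolution: float, speed: float) -> float:
    """Lag time above which advective motion is detectable: resolution / speed.

    Both inputs share any length unit (commonly nm and nm/s); the result is
    in seconds.  A 100 nm localization floor and a network speed v give the
    shortest lag at which the network can carry a tracer across the floor.
    """
    if resolution <= 0 or speed <= 0:
        raise ValueError("resolution and speed must be positive")
    return resolution / speed


def _fit_fields(fit) -> tuple[float, float]:
    if fit is None:
        return (np.nan, np.nan)
    return (fit.exponent, fit.stderr)


def analyze_condition(label: str,
                      tracks: TrackTable | None = None,
                      stack: ImageStack | None = None,
                      phi_a: float = float("nan"),
                      msd_params: dict | None = None,
                      vanhove_params: dict | None = None,
                      ddm_params: dict | None = None) -> tuple[dict, dict]:
    """Run every applicable stage for one condition.

    Returns the summary row (nulls for unavailable or failed stages) and a
    details dict holding the intermediate artifacts.
    """
    msd_params = dict(msd_params or {})
    vanhove_params = dict(vanhove_params or {})
    ddm_params = dict(ddm_params or {})
    row: dict = {c: np.nan for c in SUMMARY_COLUMNS}
    row["label"] = label
    row["phi_a"] = phi_a
    details: dict = {}

    if tracks is not None:
        try:
            curve, regimes = spt_msd.analyze_msd(
                tracks,
                max_lag=msd_params.get("max_lag_s"),
                r2_threshold=msd_params.get("r2_threshold", 0.99),
                smooth_window=msd_params.get("smooth_window", 5),
                fit_cap=msd_params.get("fit_cap_s"),
                min_pairs=msd_params.get("min_pairs", 50),
            )
            details["msd_curve"] = curve
            details["regimes"] = regimes
            row["t1_s"] = regimes.t1
            row["t2_s"] = regimes.t2 if regimes.t2 is not None else np.nan
            row["alpha_msd_1"], row["alpha_msd_1_err"] = _fit_fields(regimes.alpha1)
            row["alpha_msd_12"], row["alpha_msd_12_err"] = _fit_fields(regimes.alpha12)
            row["alpha_msd_2"], row["alpha_msd_2_err"] = _fit_fields(regimes.alpha2)
        except Exception as err:  # a failing stage nulls its metrics and continues
            logger.error("[%s] MSD stage failed: %s", label, err)
        try:
            lags = tuple(vanhove_params.get("lags_s", vanhove.DEFAULT_LAGS))
            max_lag_avail = (tracks.data.groupby("particle")["frame"].size().max() - 1) \
                * tracks.frame_interval
            lags = tuple(l for l in lags if l <= max_lag_avail)
            series = vanhove.edge_stats_series(
                tracks, lags=lags,
                bin_width=vanhove_params.get("bin_width_um", 0.05))
            details["vanhove_edges"] = series
            details["vanhove_metrics"] = vanhove.metrics_table(
                tracks, lags=lags,
                bin_width=vanhove_params.get("bin_width_um", 0.05),
                fit_mixture=vanhove_params.get("fit_mixture", True))
            short, long_ = vanhove.fit_fwhm_scaling(
                series, split_at=vanhove_params.get("split_at_s", 1.0))
            row["alpha_vh_1"], row["alpha_vh_1_err"] = _fit_fields(short)
            row["alpha_vh_2"], row["alpha_vh_2_err"] = _fit_fields(long_)
        except Exception as err:
            logger.error("[%s] van Hove stage failed: %s", label, err)

    if stack is not None:
        try:
            matrix, fits, scaling = ddm.analyze_stack(
                stack,
                max_lag=ddm_params.get("max_lag_s"),
                lag_cap=ddm_params.get("lag_cap_s", 100.0),
                q_range=(ddm_params.get("q_fit_lo", 1.0),
                         ddm_params.get("q_fit_hi", 4.0)),
                gamma_bounds=tuple(ddm_params.get("gamma_bounds", (0.2, 3.0))),
                pair_cap=ddm_params.get("pair_cap", 300),
                window=ddm_params.get("window"),
            )
            details["ddm_matrix"] = matrix
            details["ddm_fits"] = fits
            details["ddm_scaling"] = scaling
            row["alpha_ddm"] = scaling.alpha_ddm
            row["beta"] = scaling.beta
            row["beta_err"] = scaling.beta_stderr
            row["gamma_mean"] = scaling.gamma_mean
            row["gamma_stderr"] = scaling.gamma_stderr
        except Exception as err:
            logger.error("[%s] DDM stage failed: %s", label, err)

    return row, details


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "conditions" not in config:
        raise ValueError("config must be a mapping with a 'conditions' list")
    return config


def run_full_analysis(config: dict | str | Path,
                      outdir: str | Path | None = None) -> TransportSummary:
    """Execute every stage for every condition of a config; emit the summary.

    Config schema (YAML-compatible)::

        conditions:
          - label: phiA0
            phi_a: 0.0
            tracks: tracks.csv          # optional
            stack: stack.tif            # optional (sidecar supplies calibration)
            pixel_size: 0.194           # um/px, for the track CSV
            frame_interval: 0.1         # s
        msd: {max_lag_s: 40, r2_threshold: 0.99, smooth_window: 5, fit_cap_s: 100}
        vanhove: {lags_s: [...], bin_width_um: 0.05, split_at_s: 1.0}
        ddm: {lag_cap_s: 100, q_fit_lo: 1.0, q_fit_hi: 4.0}

    Config errors abort before any computation; stage failures inside a
    condition null that condition's metrics and continue.
    """
    config = load_config(config)
    base = Path(config.get("base_dir", "."))
    conditions = config["conditions"]
    if not conditions:
        raise ValueError("config lists no conditions")
    for cond in conditions:  # validate everything up front
        if "label" not in cond:
            raise ValueError("every condition needs a label")
        if "tracks" not in cond and "stack" not in cond:
            raise ValueError(f"condition {cond['label']!r} names neither "
                             "tracks nor a stack")

    rows = []
    details: dict = {}
    for cond in conditions:
        label = cond["label"]
        tracks = None
        stack = None
        if "tracks" in cond:
            tracks = read_tracks(
                base / cond["tracks"],
                pixel_size=float(cond.get("pixel_size", 1.0)),
                frame_interval=float(cond.get("frame_interval", 0.1)),
                min_track_length=int(cond.get("min_track_length", 10)),
            )
        if "stack" in cond:
            stack = load_stack(base / cond["stack"],
                               pixel_size=cond.get("stack_pixel_size"),
                               frame_interval=cond.get("stack_frame_interval"))
        row, det = analyze_condition(
            label, tracks=tracks, stack=stack,
            phi_a=float(cond.get("phi_a", float("nan"))),
            msd_params=config.get("msd"),
            vanhove_params=config.get("vanhove"),
            ddm_params=config.get("ddm"),
        )
        rows.append(row)
        details[label] = det

    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    summary = TransportSummary(table=table, details=details)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "transport_summary.csv")
        (outdir / "transport_summary.txt").write_text(summary.to_text() + "\n")
        for label, det in details.items():
            if "msd_curve" in det:
                det["msd_curve"].to_csv(outdir / f"{label}_msd.csv")
            if "regimes" in det:
                det["regimes"].to_json(outdir / f"{label}_regimes.json")
            if "vanhove_metrics" in det:
                det["vanhove_metrics"].to_csv(outdir / f"{label}_vanhove_metrics.csv",
                                              index=False)
            if "ddm_matrix" in det:
                det["ddm_matrix"].to_csv(outdir / f"{label}_ddm_matrix.csv")
            if "ddm_fits" in det:
                det["ddm_fits"].to_csv(outdir / f"{label}_ddm_fits.csv")
    return summary
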