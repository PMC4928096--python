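"""Orchestration: fitted trajectory -> the 13 instantaneous estimators ->
stimulus-locked features -> force/velocity classification.

The classification estimator set is fixed at the 13 quantities used for the
force/velocity problems: mean and SD of the interval distribution, heart-rate
SD, the three spectral indices (LF, HF, LF/HF), the three bispectral
integrals (LL, LH, HH), the two entropies (A_I, S_I) and the first two
Lyapunov exponents.  With the max/median/MAD summaries this yields the
39-dimensional per-stimulus feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import complexity as cx
from . import features as ft
from . import spectral as sp
from .pp_model import FitConfig, ParameterTrajectory, fit_trajectory
from .rr_io import EventSeries
from .synthetic import ProtocolSpec, simulate_protocol

log = logging.getLogger(__name__)

__all__ = [
    "CLASSIFICATION_ESTIMATORS",
    "PipelineConfig",
    "InstantaneousEstimates",
    "compute_estimates",
    "run_protocol_study",
]

#: the 13 classification estimators, in canonical order
CLASSIFICATION_ESTIMATORS = (
    "muRR", "sigmaRR", "sigmaHR", "LF", "HF", "LFHF",
    "LL", "LH", "HH", "AI", "SI", "lambda1", "lambda2",
)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings: model fit, spectral grids, complexity, features."""

    fit: FitConfig = field(default_factory=FitConfig)
    freq_df: float = 0.002
    bispec_df: float = 0.01
    bispec_time_stride: int = 50
    entropy_m: int = 2
    entropy_radius_scale: float = 0.2
    lyap_alpha: float = 0.2
    lyap_functions: int = 2
    fos_threshold: float = 1e-4
    rest_baseline_window: float = 10.0
    last_window: float = 1.0
    svm_nu: float = 0.5


@dataclass(frozen=True)
class InstantaneousEstimates:
    """Time-resolved estimator panel (one column per estimator)."""

    frame: pd.DataFrame
    estimator_columns: tuple = CLASSIFICATION_ESTIMATORS

    def classification_frame(self) -> pd.DataFrame:
        return self.frame[["time", *self.estimator_columns]]


def compute_estimates(events: EventSeries,
                      config: PipelineConfig = PipelineConfig(),
                      traj: ParameterTrajectory | None = None
                      ) -> InstantaneousEstimates:
    """Compute the full instantaneous estimator panel for one recording.

    Fits the quadratic NARL trajectory (unless one is supplied), derives the
    spectral and bispectral indices, the Lyapunov exponents from the cubic
    refit, and the point-process entropies.  Missing complexity values
    (burn-in, singular windows) are carried forward/backward so the feature
    stage sees a complete panel.
    """
    if traj is None:
        traj = fit_trajectory(events, config.fit)
    basis = traj.basis
    freqs = np.round(np.arange(0.0, 0.5 + config.freq_df / 2, config.freq_df), 10)
    surf = sp.instantaneous_spectrum(traj, basis, freqs)
    bis = sp.instantaneous_bispectrum(traj, basis, df=config.bispec_df,
                                      time_stride=config.bispec_time_stride)
    lya = cx.lyapunov_spectrum(events, traj, alpha=config.lyap_alpha,
                               num_functions=config.lyap_functions,
                               fos_threshold=config.fos_threshold)
    ent = cx.instantaneous_entropy(events, traj, m=config.entropy_m,
                                   radius_scale=config.entropy_radius_scale)
    frame = pd.DataFrame({
        "time": traj.grid_times,
        "muRR": traj.mu_rr,
        "sigmaRR": traj.sigma_rr,
        "sigmaHR": traj.sigma_hr,
        "muHR": traj.mu_hr,
        "VLF": surf.bands["VLF"].to_numpy(),
        "LF": surf.bands["LF"].to_numpy(),
        "HF": surf.bands["HF"].to_numpy(),
        "LFHF": surf.bands["lf_hf"].to_numpy(),
        "LL": bis.band_integrals["LL"].to_numpy(),
        "LH": bis.band_integrals["LH"].to_numpy(),
        "HH": bis.band_integrals["HH"].to_numpy(),
        "lambda1": lya.lambda1,
        "lambda2": lya.lambda2,
        "AI": ent.approx_entropy,
        "SI": ent.sample_entropy,
        "converged": traj.converged.astype(int),
    })
    filled = frame.replace([np.inf, -np.inf], np.nan).ffill().bfill()
    n_missing = int(frame[list(CLASSIFICATION_ESTIMATORS)].isna().sum().sum())
    if n_missing:
        log.info("estimates: %d missing estimator values carried", n_missing)
    return InstantaneousEstimates(frame=filled)


def run_protocol_study(spec: ProtocolSpec = ProtocolSpec(), seed: int = 0,
                       config: PipelineConfig = PipelineConfig(),
                       screen_outliers: bool = True):
    """Simulate the protocol and run the full chain to both classifications.

    Returns ``(feature_table, force_result, velocity_result)``.
    """
    recordings = simulate_protocol(spec, seed=seed)
    all_features = []
    for rec in recordings:
        est = compute_estimates(rec.events, config)
        feats = ft.extract_stimulus_features(
            est.frame, rec.annotations, CLASSIFICATION_ESTIMATORS,
            rest_baseline_window=config.rest_baseline_window,
            last_window=config.last_window)
        all_features.extend(feats)
    table = ft.features_to_table(all_features)
    if screen_outliers and len(table) >= 3:
        table, removed = ft.remove_outliers(table)
        if removed:
            log.info("outlier screen removed %d stimuli", len(removed))
    feat_cols = [c for c in table.columns
                 if c not in ("subject", "stimulus", "force_class",
                              "velocity_class")]
    X = table[feat_cols].to_numpy(dtype=float)
    force_res = ft.loo_classify(X, table["force_class"].to_numpy(),
                                nu=config.svm_nu)
    vel_res = ft.loo_classify(X, table["velocity_class"].to_numpy(),
                              nu=config.svm_nu)
    return table, force_res, vel_res
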