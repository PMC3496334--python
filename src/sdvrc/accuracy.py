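"""Probe-panel design simulation: accuracy vs number of calibration points.

How well can the cytoplasmic DC of a target-sized probe (GFP, 2.8 nm, by
default) be predicted when the reference curve is calibrated from a panel
of n synthetic measurements?  Panels are spread log-uniformly across the
experimentally accessible radius range, corrupted by normal measurement
noise (relative error on the radius as derived from the dilute-solution DC,
plus noise on the ln-viscosity ratio), refitted, and scored by the relative
error of the prediction at the target radius.  Roughly 20 well-spread
probes suffice for ~20% accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import SdvrcParams, ln_viscosity_ratio, predict_Dcyto
from .fitting import (
    FitFailureError,
    FitResult,
    IllPosedError,
    ProbeMeasurement,
    fit_sdvrc,
    load_ecoli_probes,
    prediction_band,
)

__all__ = ["SimConfig", "generate_synthetic_probes", "prediction_error_curve"]

DEFAULT_N_GRID = (6, 10, 15, 20, 30, 40, 50, 70, 85, 100)


@dataclass
class SimConfig:
    """Configuration of one accuracy experiment.

    ``rel_err_D0`` is the relative measurement error on the probe radius as
    inferred from its dilute-solution DC; ``noise_sd_ln`` the standard
    deviation of the normal noise on ln(eta_eff/eta_0), sized to the ~40%
    scatter of the literature calibration data.  ``truth`` defaults to the
    curve fitted to the packaged *E. coli* probe table.
    """

    n_points_grid: tuple[int, ...] = DEFAULT_N_GRID
    n_reps: int = 10
    r_range: tuple[float, float] = (0.16, 203.9)
    rel_err_D0: float = 0.05
    noise_sd_ln: float = 0.2
    target_r: float = 2.8
    truth: SdvrcParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 4 for n in self.n_points_grid):
            raise ValueError("every panel size must be >= 4 (three fit parameters)")
        lo, hi = self.r_range
        if not (0 < lo < hi):
            raise ValueError("radius range must be positive and ordered")
        if self.rel_err_D0 < 0 or self.noise_sd_ln < 0:
            raise ValueError("noise parameters must be non-negative")
        if not (self.target_r > 0):
            raise ValueError("target radius must be positive")

    def resolved_truth(self) -> SdvrcParams:
        if self.truth is None:
            self.truth = fit_sdvrc(load_ecoli_probes()).params
        return self.truth


def generate_synthetic_probes(
    n: int, config: SimConfig, rng: np.random.Generator | None = None
) -> list[ProbeMeasurement]:
    """One synthetic calibration panel of ``n`` probes.

    Radii are exactly log-uniformly spaced over ``config.r_range``; the
    observed radius carries Gaussian relative error ``rel_err_D0`` and the
    observed ln-viscosity ratio Gaussian noise ``noise_sd_ln`` around the
    truth curve.
    """
    if n < 4:
        raise ValueError("need at least 4 probes")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = config.resolved_truth()
    r_true = np.logspace(*np.log10(config.r_range), n)
    ln_true = np.asarray(ln_viscosity_ratio(r_true, truth))
    r_obs = r_true * (1.0 + config.rel_err_D0 * rng.standard_normal(n))
    r_obs = np.maximum(r_obs, 1e-3)  # a radius measurement cannot go negative
    ln_obs = np.maximum(ln_true + config.noise_sd_ln * rng.standard_normal(n), 0.0)
    return [
        ProbeMeasurement(name=f"synthetic-{i}", r_p=float(r), ln_ratio=float(y))
        for i, (r, y) in enumerate(zip(r_obs, ln_obs))
    ]


def prediction_uncertainty(fit: FitResult, r_p: float) -> float:
    """Relative DC uncertainty at ``r_p`` from the fitting-error envelope.

    Half the relative width of the DC interval implied by the maximum-error
    band of the fit: ``(D_hi - D_lo) / (2 * D_central)``, where the D bounds
    come from the ln-viscosity envelope (low viscosity -> high DC).
    """
    lo, hi = prediction_band(fit, r_p)
    central = float(np.asarray(ln_viscosity_ratio(r_p, fit.params)))
    return (np.exp(central - lo) - np.exp(central - hi)) / 2.0


def prediction_error_curve(config: SimConfig) -> pd.DataFrame:
    """Relative error of the predicted target-probe DC vs panel size.

    For each panel size in the grid, ``n_reps`` independent noisy panels
    are generated and refitted.  Two error measures are averaged over the
    replicates:

    ``mean_rel_err``
        the headline accuracy: the fitting-uncertainty envelope of the
        refit curve at ``target_r``, reduced to a relative half-width
        (:func:`prediction_uncertainty`).  This is the "error of the
        calculated DC" a calibration of that size supports.
    ``mean_truth_dev``
        the realized deviation ``|D_pred - D_truth| / D_truth`` from the
        generating curve — systematically smaller, because averaging over
        noise cancels much of the parameter scatter near well-covered radii.

    Panels whose fit fails are excluded and counted in ``n_failed``.
    """
    truth = config.resolved_truth()
    d_truth = predict_Dcyto(config.target_r, truth)
    streams = np.random.SeedSequence(config.seed).spawn(len(config.n_points_grid))
    rows = []
    for n, stream in zip(config.n_points_grid, streams):
        rngs = [np.random.default_rng(s) for s in stream.spawn(config.n_reps)]
        errors, deviations, n_failed = [], [], 0
        for rng in rngs:
            panel = generate_synthetic_probes(n, config, rng)
            try:
                fit = fit_sdvrc(panel)
            except (FitFailureError, IllPosedError):
                n_failed += 1
                continue
            errors.append(prediction_uncertainty(fit, config.target_r))
            d_pred = predict_Dcyto(config.target_r, fit.params)
            deviations.append(abs(d_pred - d_truth) / d_truth)
        rows.append(
            {
                "n_points": n,
                "mean_rel_err": float(np.mean(errors)) if errors else np.nan,
                "sd_rel_err": float(np.std(errors, ddof=1)) if len(errors) > 1 else np.nan,
                "mean_truth_dev": float(np.mean(deviations)) if deviations else np.nan,
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(rows)
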