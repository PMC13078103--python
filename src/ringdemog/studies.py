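"""Self-validation studies for the fitting pipeline.

Synthetic-data experiments that quantify how well the pipeline recovers
known truths: the logistic parameters of a generating response, and the
identity of the month window that actually drives latewood density.  Both
are used by the acceptance harness and are handy when re-tuning the
pipeline's knobs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import (
    FittingConfig,
    best_month_window,
    bin_and_average,
    fit_best,
    make_pairs,
    remove_outliers_per_site,
    site_annual_aggregate,
)
from .response import DensityResponse, evaluate_lwd
from .synth import DEFAULT_RESPONSE, derive_seed, gen_climate, gen_lwd_dataset, gen_site_gradient

__all__ = ["parameter_recovery_study", "window_recovery_study"]


def parameter_recovery_study(
    n_trials: int = 100,
    seed: int = 0,
    true_response: DensityResponse = DEFAULT_RESPONSE,
    n_years: int = 99,
    n_trees: int = 10,
    noise_sd: float = 10.0,
    cfg: FittingConfig = FittingConfig(),
) -> dict:
    """Fit the logistic to many synthetic multi-site datasets with known truth.

    Each trial generates per-tree latewood densities at the default 5-site
    gradient (99 years each, Gaussian noise of ``noise_sd`` kgC/m^3), runs
    aggregation, outlier screening, binning and the best fit, and records the
    errors of the recovered parameters.

    Returns a dict with per-trial error arrays and their medians:
    ``median_d_abs_err`` (degC) and ``median_b_rel_err`` (fraction).
    """
    gradient = gen_site_gradient(response=true_response)
    d_errs, b_errs, a_errs, c_errs = [], [], [], []
    for trial in range(n_trials):
        frames, clims = [], {}
        for i, site in enumerate(gradient):
            clim = gen_climate(site, n_years, seed=derive_seed(seed, trial, i), start_year=1901)
            clims[site.site_id] = clim
            frames.append(
                gen_lwd_dataset(true_response, clim, n_trees=n_trees, noise_sd=noise_sd, seed=derive_seed(seed, trial, i, 1))
            )
        annual = site_annual_aggregate(pd.concat(frames, ignore_index=True))
        filtered = remove_outliers_per_site(annual, cfg.z_threshold)
        pairs = make_pairs(filtered, clims, (7, 8, 9))
        fitted = fit_best(bin_and_average(pairs, cfg.bin_width), cfg).response
        d_errs.append(abs(fitted.d - true_response.d))
        b_errs.append(abs(fitted.b - true_response.b) / true_response.b)
        a_errs.append(abs(fitted.a - true_response.a) / true_response.a)
        c_errs.append(abs(fitted.c - true_response.c) / true_response.c)
    return {
        "d_abs_err": np.asarray(d_errs),
        "b_rel_err": np.asarray(b_errs),
        "a_rel_err": np.asarray(a_errs),
        "c_rel_err": np.asarray(c_errs),
        "median_d_abs_err": float(np.median(d_errs)),
        "median_b_rel_err": float(np.median(b_errs)),
        "n_trials": n_trials,
    }


def window_recovery_study(
    n_trials: int = 100,
    seed: int = 0,
    true_response: DensityResponse = DEFAULT_RESPONSE,
    target_r2: float = 0.34,
    n_years: int = 500,
    cfg: FittingConfig = FittingConfig(),
) -> dict:
    """How often does the window search identify the generating JAS window?

    Single-site series of ``n_years`` years: latewood density is the response
    evaluated at the actual JAS mean plus Gaussian noise calibrated so the
    population coefficient of determination against JAS temperature equals
    ``target_r2``.  A trial is a hit when the searched window is exactly
    July--September.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must lie in (0, 1)")
    gradient = gen_site_gradient(response=true_response)
    site = gradient[len(gradient) // 2]  # steepest part of the response
    hits = 0
    r2s = []
    for trial in range(n_trials):
        clim = gen_climate(site, n_years, seed=derive_seed(seed, trial), start_year=1901)
        jas = clim.jas_series()
        signal = evaluate_lwd(jas.to_numpy(), true_response)
        noise_sd = signal.std() * np.sqrt((1.0 - target_r2) / target_r2)
        rng = np.random.default_rng(derive_seed(seed, trial, 1))
        density = pd.DataFrame(
            {
                "site_id": site.site_id,
                "year": jas.index,
                "lwd": signal + rng.normal(0.0, noise_sd, signal.size),
            }
        )
        window, r2 = best_month_window(density, clim, cfg)
        hits += window == (7, 8, 9)
        r2s.append(r2)
    return {
        "hit_rate": hits / n_trials,
        "n_trials": n_trials,
        "mean_best_r2": float(np.mean(r2s)),
    }
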