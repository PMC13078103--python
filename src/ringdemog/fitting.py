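"""Construct latewood-density response functions from data.

The pipeline mirrors standard dendroclimatological practice: average trees
to site-year series, drop gross outliers (|z| > 3, single pass), find the
contiguous month window whose mean temperature best explains latewood
density, bin the pooled pairs into 0.5 degC temperature intervals to avoid
over-weighting data-dense temperatures, and fit the four-parameter logistic
to the bin means by nonlinear least squares.  Two response variants come
out: the *best* fit, and a *range* variant that keeps the midpoint but
stretches the asymptotes to the rounded observed extremes (re-fitting only
the growth rate), bounding the largest plausible density effect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .climate import ClimateSeries
from .response import DensityResponse, SiteConfig, lapse_adjust

__all__ = [
    "FittingConfig",
    "BinnedMeans",
    "FitResult",
    "FittingError",
    "FitConvergenceError",
    "default_window_candidates",
    "site_annual_aggregate",
    "remove_outliers",
    "remove_outliers_per_site",
    "window_mean_table",
    "best_month_window",
    "make_pairs",
    "bin_and_average",
    "fit_best",
    "fit_range",
    "fit_density_response",
]


class FittingError(RuntimeError):
    """Raised when the fitting pipeline cannot proceed."""


class FitConvergenceError(FittingError):
    """No start point of the multi-start least squares converged."""

    def __init__(self, message: str, starts: Sequence[tuple]):
        super().__init__(f"{message}; starts tried: {list(starts)}")
        self.starts = list(starts)


def default_window_candidates(first_month: int = 4, last_month: int = 10, max_length: int = 4):
    """All contiguous month windows of length 1..max_length within [first, last]."""
    out = []
    for length in range(1, max_length + 1):
        for start in range(first_month, last_month - length + 2):
            out.append(tuple(range(start, start + length)))
    return tuple(out)


@dataclass(frozen=True)
class FittingConfig:
    """Tunable knobs of the response-fitting pipeline."""

    z_threshold: float = 3.0
    bin_width: float = 0.5
    window_candidates: tuple = field(default_factory=default_window_candidates)
    range_rounding: float = 1.0
    c_starts: tuple = (0.1, 0.5, 1.0, 2.0, 5.0)

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.range_rounding <= 0:
            raise ValueError("range_rounding must be positive")


@dataclass
class BinnedMeans:
    """Mean latewood density per half-open temperature bin [k*w, (k+1)*w)."""

    bin_centers: np.ndarray
    mean_lwd: np.ndarray
    n_per_bin: np.ndarray
    bin_width: float

    def __len__(self) -> int:
        return len(self.bin_centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center_C": self.bin_centers, "mean_lwd_kgC_m3": self.mean_lwd, "n": self.n_per_bin}
        )


@dataclass
class FitResult:
    """A fitted response plus least-squares diagnostics."""

    response: DensityResponse
    sse: float
    n_bins: int
    starts_tried: list
    n_converged: int

    def to_dict(self) -> dict:
        return {
            "response": self.response.to_dict(),
            "sse": self.sse,
            "n_bins": self.n_bins,
            "n_converged": self.n_converged,
        }


def site_annual_aggregate(tree_series: pd.DataFrame, value_col: str = "lwd_kgC_m3") -> pd.DataFrame:
    """Mean latewood density over trees within each site-year.

    Expects columns ``site_id, tree_id, year`` plus ``value_col``; returns a
    frame with one row per observed site-year (missing tree-years simply do
    not contribute).
    """
    if tree_series.empty:
        raise FittingError("empty ring-density table")
    out = (
        tree_series.dropna(subset=[value_col])
        .groupby(["site_id", "year"], as_index=False)[value_col]
        .mean()
        .rename(columns={value_col: "lwd"})
    )
    if out.empty:
        raise FittingError("no usable site-year values after dropping missing data")
    return out


def remove_outliers(values, z_threshold: float = 3.0) -> np.ndarray:
    """Drop values with |x - mean| / sd > threshold (strict), single pass.

    Uses the population standard deviation and does not re-iterate; a
    constant series (sd = 0) is returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise FittingError("need at least 2 values for outlier screening")
    sd = x.std()  # population sd, computed once on the full series
    if sd == 0:
        return x.copy()
    z = np.abs(x - x.mean()) / sd
    return x[z <= z_threshold]


def remove_outliers_per_site(df: pd.DataFrame, z_threshold: float = 3.0, value_col: str = "lwd") -> pd.DataFrame:
    """Apply :func:`remove_outliers` within each site of a site-year table."""

    def _keep(g: pd.DataFrame) -> pd.DataFrame:
        x = g[value_col].to_numpy(float)
        if x.size < 2:
            return g
        sd = x.std()
        if sd == 0:
            return g
        return g[np.abs(x - x.mean()) / sd <= z_threshold]

    parts = [_keep(g) for _, g in df.groupby("site_id", sort=False)]
    return pd.concat(parts, ignore_index=True)


def window_mean_table(climate: Mapping[str, ClimateSeries] | ClimateSeries, months) -> pd.DataFrame:
    """Window-mean temperatures per site-year: columns site_id, year, t_window."""
    if isinstance(climate, ClimateSeries):
        climate = {climate.site_id: climate}
    frames = []
    for site_id, series in climate.items():
        s = series.window_means(months)
        frames.append(pd.DataFrame({"site_id": site_id, "year": s.index, "t_window": s.to_numpy()}))
    return pd.concat(frames, ignore_index=True).dropna(subset=["t_window"])


def best_month_window(
    density: pd.DataFrame,
    climate: Mapping[str, ClimateSeries] | ClimateSeries,
    cfg: FittingConfig = FittingConfig(),
) -> tuple[tuple, float]:
    """Search candidate month windows for the strongest density--temperature link.

    ``density`` is a site-year table (columns ``site_id, year, lwd``); pairs
    are pooled across sites and the coefficient of determination of the
    simple linear regression of density on window-mean temperature is
    compared across windows.  Returns ``(window_months, r_squared)``; ties
    keep the earlier candidate.
    """
    if not cfg.window_candidates:
        raise FittingError("no candidate windows configured")
    best: tuple | None = None
    best_r2 = -np.inf
    n_overlap = 0
    for window in cfg.window_candidates:
        t = window_mean_table(climate, window)
        merged = density.merge(t, on=["site_id", "year"], how="inner")
        n_overlap = max(n_overlap, len(merged))
        if len(merged) < 2:
            continue
        x = merged["t_window"].to_numpy(float)
        y = merged["lwd"].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            continue
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        if r2 > best_r2:
            best, best_r2 = window, r2
    if best is None:
        raise FittingError("no overlapping density/climate years for any candidate window")
    if n_overlap < 10:
        raise FittingError(f"only {n_overlap} overlapping years; need at least 10")
    return best, best_r2


def make_pairs(
    density: pd.DataFrame,
    climate: Mapping[str, ClimateSeries] | ClimateSeries,
    window,
    site_configs: Mapping[str, SiteConfig] | None = None,
) -> pd.DataFrame:
    """Join site-year densities with window-mean temperatures.

    When ``site_configs`` is given, gridcell temperatures are lapse-adjusted
    to each site's elevation before pairing.  Returns columns
    ``site_id, year, lwd, t_window``.
    """
    t = window_mean_table(climate, window)
    if site_configs is not None:
        adj = np.array(
            [
                lapse_adjust(v, site_configs[s]) if s in site_configs else v
                for s, v in zip(t["site_id"], t["t_window"])
            ]
        )
        t = t.assign(t_window=adj)
    merged = density.merge(t, on=["site_id", "year"], how="inner")
    if merged.empty:
        raise FittingError("no overlapping site-years between density and climate")
    return merged


def bin_and_average(pairs: pd.DataFrame, bin_width: float = 0.5) -> BinnedMeans:
    """Mean latewood density per half-open temperature bin anchored at 0 degC."""
    if pairs.empty:
        raise FittingError("no pairs to bin")
    t = pairs["t_window"].to_numpy(float)
    y = pairs["lwd"].to_numpy(float)
    k = np.floor(t / bin_width).astype(int)
    order = np.argsort(k, kind="stable")
    k_sorted, y_sorted = k[order], y[order]
    uniq, start = np.unique(k_sorted, return_index=True)
    sums = np.add.reduceat(y_sorted, start)
    counts = np.diff(np.append(start, k_sorted.size))
    return BinnedMeans(
        bin_centers=(uniq + 0.5) * bin_width,
        mean_lwd=sums / counts,
        n_per_bin=counts,
        bin_width=bin_width,
    )


def _logistic(t, a, b, c, d):
    return a + (b - a) / (1.0 + np.exp(np.clip(-c * (t - d), -700.0, 700.0)))


def fit_best(binned: BinnedMeans, cfg: FittingConfig = FittingConfig()) -> FitResult:
    """Multi-start nonlinear least squares of the logistic on the bin means.

    Start points combine data-driven quantile initialisations of the
    asymptotes and midpoint with a grid of growth rates; the converged fit
    with the smallest sum of squared errors wins.  Bin means are unweighted.
    """
    t = np.asarray(binned.bin_centers, float)
    y = np.asarray(binned.mean_lwd, float)
    if len(binned) < 5:
        raise FittingError(f"need at least 5 non-empty bins, got {len(binned)}")
    if np.ptp(y) < 1e-9:
        raise FittingError("flat bin means: degenerate (a == b) response; nothing to fit")
    mid = 0.5 * (y.min() + y.max())
    if not (np.any(y < mid) and np.any(y > mid)):
        raise FittingError("bin means do not span both sides of the apparent midpoint")

    a0 = float(np.quantile(y, 0.05))
    b0 = float(np.quantile(y, 0.95))
    # midpoint start: temperature of the bin whose mean is closest to mid value
    d0 = float(t[np.argmin(np.abs(y - mid))])
    d1 = float(np.median(t))
    lower = [0.0, 0.0, 0.0, t.min() - 20.0]
    upper = [np.inf, np.inf, np.inf, t.max() + 20.0]
    starts = [(a0, b0, c0, dd) for c0, dd in itertools.product(cfg.c_starts, (d0, d1))]

    best_popt, best_sse, n_conv = None, np.inf, 0
    for p0 in starts:
        try:
            popt, _ = curve_fit(_logistic, t, y, p0=p0, bounds=(lower, upper), maxfev=20_000)
        except (RuntimeError, ValueError):
            continue
        if popt[0] > popt[1]:
            continue
        sse = float(np.sum((y - _logistic(t, *popt)) ** 2))
        n_conv += 1
        if sse < best_sse:
            best_popt, best_sse = popt, sse
    if best_popt is None:
        raise FitConvergenceError("nonlinear least squares failed from every start", starts)
    resp = DensityResponse(
        a=float(best_popt[0]), b=float(best_popt[1]), c=float(best_popt[2]), d=float(best_popt[3]), label="best"
    )
    return FitResult(response=resp, sse=best_sse, n_bins=len(binned), starts_tried=starts, n_converged=n_conv)


def fit_range(
    raw_pairs: pd.DataFrame,
    best: DensityResponse,
    binned: BinnedMeans,
    cfg: FittingConfig = FittingConfig(),
) -> DensityResponse:
    """Range variant: asymptotes at the rounded observed extremes, midpoint kept.

    ``a`` and ``b`` are the observed minimum and maximum latewood density
    rounded to ``cfg.range_rounding``; ``d`` is copied from the best fit and
    only the growth rate ``c`` is re-estimated on the bin means.
    """
    lwd = raw_pairs["lwd"].to_numpy(float) if isinstance(raw_pairs, pd.DataFrame) else np.asarray(raw_pairs, float)
    u = cfg.range_rounding
    a = float(np.round(lwd.min() / u) * u)
    b = float(np.round(lwd.max() / u) * u)
    if a == b:
        raise FittingError("observed minimum equals maximum after rounding; no range to span")
    t = np.asarray(binned.bin_centers, float)
    y = np.asarray(binned.mean_lwd, float)

    def f(tt, c):
        return _logistic(tt, a, b, c, best.d)

    try:
        popt, _ = curve_fit(f, t, y, p0=[max(best.c, 1e-3)], bounds=([0.0], [np.inf]), maxfev=20_000)
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError("growth-rate re-fit failed", [(a, b, best.c, best.d)]) from exc
    return DensityResponse(a=a, b=b, c=float(popt[0]), d=best.d, label="range")


def fit_density_response(
    tree_series: pd.DataFrame,
    climate: Mapping[str, ClimateSeries] | ClimateSeries,
    cfg: FittingConfig = FittingConfig(),
    site_configs: Mapping[str, SiteConfig] | None = None,
    window=None,
) -> dict:
    """Run the whole pipeline; returns a report dict.

    Steps: site-year aggregation -> per-site outlier removal -> month-window
    search (unless ``window`` is given) -> pairing (with lapse adjustment if
    ``site_configs`` is provided) -> binning -> best fit -> range variant.

    The report holds both responses, the binned means, the chosen window and
    fit diagnostics, and serialises cleanly to JSON via
    :func:`ringdemog.io.fit_report_to_json`.
    """
    annual = site_annual_aggregate(tree_series)
    filtered = remove_outliers_per_site(annual, cfg.z_threshold)
    if window is None:
        window, r2 = best_month_window(filtered, climate, cfg)
    else:
        window = tuple(window)
        r2 = None
    pairs = make_pairs(filtered, climate, window, site_configs)
    binned = bin_and_average(pairs, cfg.bin_width)
    best = fit_best(binned, cfg)
    rng = fit_range(pairs, best.response, binned, cfg)
    return {
        "window": window,
        "window_r_squared": r2,
        "best": best.response,
        "range": rng,
        "binned": binned,
        "diagnostics": best.to_dict(),
        "n_pairs": int(len(pairs)),
    }
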