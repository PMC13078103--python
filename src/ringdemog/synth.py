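"""Synthetic inputs: climate cycles, ring-density datasets, site gradients.

Everything the fitting pipeline and the simulator consume can be generated
here with no external data.  The climate generator emulates the experimental
forcing design of the simulation study: a single stochastic 30-year monthly
cycle per site, tiled indefinitely, with ensemble members entering the cycle
at different offsets, and optional uniform warming steps.  The ring-density
generator draws per-tree annual latewood densities from a known logistic
temperature response plus Gaussian noise, so fitted parameters can be
checked against their generating values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .climate import ClimateSeries, WarmingScenario
from .response import (
    DensityResponse,
    RingComposition,
    SiteConfig,
    compose_trd,
    evaluate_lwd,
    invert_trd,
)

__all__ = [
    "DEFAULT_RESPONSE",
    "DEFAULT_RANGE_RESPONSE",
    "SiteGradient",
    "derive_seed",
    "gen_climate",
    "gen_lwd_dataset",
    "gen_site_gradient",
]

#: Spruce-like default logistic latewood-density response used throughout the
#: synthetic experiments.  Asymptotes bracket the 186 kgC/m^3 static total
#: ring density once composed with the default 70:30 earlywood split
#: (TRD range ~169-202 kgC/m^3); parameters are fit from synthetic data, not
#: literature values.
DEFAULT_RESPONSE = DensityResponse(a=240.0, b=350.0, c=0.8, d=11.5, label="best")

#: Wider-asymptote variant standing in for a "full observed range" response:
#: same midpoint, asymptotes stretched, shallower growth rate.
DEFAULT_RANGE_RESPONSE = DensityResponse(a=220.0, b=370.0, c=0.6, d=11.5, label="range")


def derive_seed(master: int, *keys: int) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and keys.

    Hierarchical seeding lets any sub-experiment (site, member, patch, ...) be
    regenerated independently of the rest of the run.
    """
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class SiteGradient:
    """An ordered set of sites with strictly increasing JAS-mean temperature."""

    sites: Sequence[SiteConfig]

    def __post_init__(self) -> None:
        means = [s.jas_mean for s in self.sites]
        if len(means) < 2:
            raise ValueError("a gradient needs at least 2 sites")
        if not all(b > a for a, b in zip(means, means[1:])):
            raise ValueError("site JAS means must be strictly increasing")

    def __iter__(self) -> Iterator[SiteConfig]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __getitem__(self, i) -> SiteConfig:
        return self.sites[i]

    @property
    def coldest(self) -> SiteConfig:
        return self.sites[0]

    @property
    def hottest(self) -> SiteConfig:
        return self.sites[-1]


def _base_cycle(
    site: SiteConfig,
    cycle_length: int,
    seed: int,
    seasonal_amplitude: float,
    noise_sd: float,
) -> np.ndarray:
    """One stochastic (cycle_length, 12) monthly cycle honouring the site JAS mean.

    Seasonal shape is a cosine peaking in July; interannual variability is
    white monthly noise.  The whole cycle is shifted so its mean JAS
    temperature equals ``site.jas_mean`` exactly.
    """
    rng = np.random.default_rng(seed)
    months = np.arange(12)
    seasonal = seasonal_amplitude * np.cos(2.0 * np.pi * (months - 6) / 12.0)
    cycle = seasonal[None, :] + rng.normal(0.0, noise_sd, size=(cycle_length, 12))
    cycle += site.jas_mean - cycle[:, 6:9].mean()
    return cycle


def gen_climate(
    site: SiteConfig,
    n_years: int,
    cycle_length: int = 30,
    member_offset: int = 0,
    warming: WarmingScenario | None = None,
    seed: int = 0,
    seasonal_amplitude: float = 8.0,
    noise_sd: float = 1.2,
    start_year: int = 0,
) -> ClimateSeries:
    """Tile a stochastic base cycle into an ``n_years`` monthly series.

    The base cycle depends only on ``(site, seed)``; ensemble members differ
    purely by ``member_offset``, i.e. by where in the cycle they start, so two
    members of the same site are cyclic shifts of one another.  ``warming``
    adds a uniform step to every month from its onset year onward.
    """
    if not 0 <= member_offset < cycle_length:
        raise ValueError(f"member_offset must be in [0, {cycle_length}), got {member_offset}")
    cycle = _base_cycle(site, cycle_length, seed, seasonal_amplitude, noise_sd)
    idx = (np.arange(n_years) + member_offset) % cycle_length
    temps = cycle[idx, :]
    series = ClimateSeries(
        site.site_id,
        start_year,
        temps,
        cycle_length=cycle_length,
        provenance={
            "generator": "gen_climate",
            "seed": seed,
            "member_offset": member_offset,
            "seasonal_amplitude": seasonal_amplitude,
            "noise_sd": noise_sd,
            "jas_mean": site.jas_mean,
        },
    )
    if warming is not None:
        series = series.warmed(warming)
    return series


def gen_lwd_dataset(
    true_resp: DensityResponse,
    climate: ClimateSeries,
    n_trees: int = 10,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tree annual latewood densities from a known temperature response.

    Each tree-year value is ``evaluate_lwd(JAS mean) + N(0, noise_sd)``.
    Returns a tidy frame with columns site_id, tree_id, year, lwd_kgC_m3.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    jas = climate.jas_series()
    years = jas.index.to_numpy()
    signal = evaluate_lwd(jas.to_numpy(), true_resp)
    n_years = len(years)
    noise = rng.normal(0.0, noise_sd, size=(n_trees, n_years)) if noise_sd > 0 else np.zeros((n_trees, n_years))
    return pd.DataFrame(
        {
            "site_id": climate.site_id,
            "tree_id": np.repeat([f"{climate.site_id}_t{i:03d}" for i in range(n_trees)], n_years),
            "year": np.tile(years, n_trees),
            "lwd_kgC_m3": (signal[None, :] + noise).ravel(),
        }
    )


def gen_site_gradient(
    n_sites: int = 5,
    static_density: float = 186.0,
    response: DensityResponse = DEFAULT_RESPONSE,
    composition: RingComposition = RingComposition(),
    span: float = 9.0,
    base_elevation: float = 1600.0,
    elevation_step: float = 150.0,
) -> SiteGradient:
    """Sites whose composed equilibrium ring density brackets ``static_density``.

    The middle site sits at the temperature where the composed total ring
    density equals ``static_density`` (within +-2 kgC/m^3), the coldest site
    composes below it and the hottest above -- mirroring the roles of the
    coolest, inflection-point and warmest study sites.  JAS means are spread
    over ``span`` degC; elevations decrease with temperature.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    lwd_star = invert_trd(static_density, composition)
    if not response.a < lwd_star < response.b:
        raise ValueError(
            f"static density {static_density} composes to latewood {lwd_star:.1f}, outside the "
            f"response asymptotes ({response.a}, {response.b}); gradient infeasible"
        )
    if response.c <= 0:
        raise ValueError("gradient infeasible for a flat response (c = 0)")
    # temperature whose composed TRD equals the static density
    ratio = (response.b - response.a) / (lwd_star - response.a) - 1.0
    if ratio <= 0:
        raise ValueError("gradient infeasible: static density too close to a response asymptote")
    t_star = response.d - math.log(ratio) / response.c
    offsets = np.linspace(-span / 2.0, span / 2.0, n_sites)
    if n_sites % 2 == 1:
        offsets[n_sites // 2] = 0.0
    sites = [
        SiteConfig(
            site_id=f"site{i + 1:02d}",
            jas_mean=float(t_star + off),
            elevation_site=float(base_elevation - i * elevation_step),
            elevation_ref=float(base_elevation - i * elevation_step),
        )
        for i, off in enumerate(offsets)
    ]
    grad = SiteGradient(sites)
    trd = [compose_trd(evaluate_lwd(s.jas_mean, response), composition) for s in grad]
    if not (trd[0] < static_density < trd[-1] and any(abs(t - static_density) <= 2.0 for t in trd)):
        raise ValueError("gradient construction failed to bracket the static density")
    return grad
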