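"""Recovery and staged-warming experiment harnesses.

Two stylised experiments exercise the cascade from climate through ring
density to stand structure:

* **Recovery** -- a stand-destroying disturbance followed by replanting at
  200 trees/ha and 300 years of regrowth under a repeating 30-year climate
  cycle.  Thirty ensemble members enter the cycle at different years; each
  member runs 25 replicate patches whose only difference is small
  multiplicative productivity noise; reported series are patch means.
  The fixed-density baseline and the dynamic-density variants share climate
  and noise realisations so their differences isolate the density effect.

* **Warming** -- a +2 degC uniform step applied at canopy-stage-specific
  onset years (open / mid / near-closed / closed canopy) to a single
  representative ensemble member per site, chosen by lowest RMSE of its
  canopy-area series against the ensemble mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .climate import WarmingScenario
from .demography import (
    AllometryParams,
    NppParams,
    SimulatorConfig,
    canopy_closure_year,
    simulate_stand,
)
from .response import DensityResponse, RingComposition
from .synth import (
    DEFAULT_RANGE_RESPONSE,
    DEFAULT_RESPONSE,
    SiteGradient,
    derive_seed,
    gen_climate,
    gen_site_gradient,
)

__all__ = [
    "ExperimentConfig",
    "StageDefinition",
    "ExperimentResult",
    "run_recovery",
    "run_warming",
    "relative_difference",
    "relative_difference_table",
    "select_representative",
]

log = logging.getLogger(__name__)

#: Variables recorded per (site, mode, member, year) as patch means.
REPORT_VARS = (
    "trees_ha",
    "diameter_m",
    "height_m",
    "cwood_per_tree_kgC",
    "cwood_per_m2_kgC",
    "canopy_fraction_pre",
    "canopy_fraction",
    "ring_width_m",
    "ring_density_kgC_m3",
    "swd_kgC_m3",
    "sapwood_density_kgC_m3",
)


def _default_responses() -> dict:
    return {"static": None, "wd-best": DEFAULT_RESPONSE, "wd-range": DEFAULT_RANGE_RESPONSE}


@dataclass
class ExperimentConfig:
    """Design of the gradient experiments.

    ``responses`` maps mode label to a :class:`DensityResponse` (``None``
    means the fixed-density baseline).  All modes share climates and noise.
    """

    sites: SiteGradient = field(default_factory=gen_site_gradient)
    responses: Mapping[str, DensityResponse | None] = field(default_factory=_default_responses)
    n_members: int = 30
    n_patches: int = 25
    replant_density: float = 200.0       # trees per hectare
    recovery_years: int = 300
    cycle_length: int = 30
    static_density: float = 186.0
    composition: RingComposition = field(default_factory=RingComposition)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    npp_params: NppParams = field(default_factory=NppParams)
    sapwood_density_window: int = 3
    patch_noise_sd: float = 0.02
    climate_noise_sd: float = 1.2
    seasonal_amplitude: float = 8.0

    def __post_init__(self) -> None:
        if self.n_members > self.cycle_length:
            raise ValueError("n_members must not exceed cycle_length (offsets must be distinct)")
        if self.replant_density <= 0:
            raise ValueError("replant_density must be positive")
        if self.n_patches < 1 or self.n_members < 1:
            raise ValueError("need at least one member and one patch")

    def simulator_config(self, mode: str) -> SimulatorConfig:
        response = self.responses[mode]
        return SimulatorConfig(
            mode="static" if response is None else "dynamic",
            static_density=self.static_density,
            response=response,
            composition=self.composition,
            allometry=self.allometry,
            npp_params=self.npp_params,
            sapwood_density_window=self.sapwood_density_window,
            patch_noise_sd=self.patch_noise_sd,
        )


@dataclass
class StageDefinition:
    """Canopy-fraction thresholds at which warming may switch on."""

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"open": 0.10, "mid": 0.50, "near_closed": 0.90, "closed": 1.00}
    )

    def __post_init__(self) -> None:
        vals = list(self.thresholds.values())
        if not vals:
            raise ValueError("need at least one stage")
        if not all(0.0 < v <= 1.0 for v in vals):
            raise ValueError("stage thresholds must lie in (0, 1]")
        if not all(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("stage thresholds must be strictly increasing")


@dataclass
class ExperimentResult:
    """Tidy per-(site, mode, member, year) trajectories plus closure years."""

    data: pd.DataFrame
    closure: pd.DataFrame
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def ensemble_mean(self) -> pd.DataFrame:
        """Arithmetic mean over ensemble members per (site, mode, year)."""
        return (
            self.data.groupby(["site", "mode", "year"], as_index=False)[list(REPORT_VARS)].mean()
        )

    def member_series(self, site: str, mode: str, var: str) -> pd.DataFrame:
        """Pivot one variable to a (year x member) frame."""
        sub = self.data[(self.data["site"] == site) & (self.data["mode"] == mode)]
        return sub.pivot(index="year", columns="member", values=var)

    @property
    def max_conservation_error(self) -> float:
        return self.diagnostics.get("max_conservation_rel_err", float("nan"))


def _member_jas_matrix(site, cfg: ExperimentConfig, climate_seed: int, warming=None, members=None):
    """JAS temperatures, shape (recovery_years, n_members_selected)."""
    members = range(cfg.n_members) if members is None else members
    cols = []
    for m in members:
        series = gen_climate(
            site,
            cfg.recovery_years,
            cycle_length=cfg.cycle_length,
            member_offset=m,
            warming=warming,
            seed=climate_seed,
            seasonal_amplitude=cfg.seasonal_amplitude,
            noise_sd=cfg.climate_noise_sd,
        )
        cols.append(series.jas_series().to_numpy())
    return np.column_stack(cols)


def _patch_noise(cfg: ExperimentConfig, seed: int, site_index: int) -> np.ndarray:
    """Lognormal productivity noise, shape (years, members, patches).

    Depends only on (seed, site), never on mode, so the baseline and the
    dynamic variants see identical realisations.
    """
    rng = np.random.default_rng(derive_seed(seed, site_index, 1))
    if cfg.patch_noise_sd <= 0:
        return np.ones((cfg.recovery_years, cfg.n_members, cfg.n_patches))
    sigma = cfg.patch_noise_sd
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=(cfg.recovery_years, cfg.n_members, cfg.n_patches))


def run_recovery(cfg: ExperimentConfig, seed: int = 0) -> ExperimentResult:
    """Disturbance -> replant -> 300-year recovery over the whole gradient.

    For every site x mode x member the stand is replanted at
    ``cfg.replant_density`` in year 0 and grown for ``cfg.recovery_years``
    under that member's cycle offset; reported values are means over
    ``cfg.n_patches`` replicate patches.  Closure year per member is the
    first year the patch-mean pre-thinning canopy fraction reaches 1.
    """
    rows = []
    closure_rows = []
    max_cons = 0.0
    years = np.arange(1, cfg.recovery_years + 1)
    for si, site in enumerate(cfg.sites):
        climate_seed = derive_seed(seed, si, 0)
        t_jas = _member_jas_matrix(site, cfg, climate_seed)              # (Y, M)
        noise = _patch_noise(cfg, seed, si)                              # (Y, M, P)
        Y, M, P = noise.shape
        t_lanes = np.repeat(t_jas, P, axis=1)                            # (Y, M*P)
        noise_lanes = noise.reshape(Y, M * P)
        for mode in cfg.responses:
            sim_cfg = cfg.simulator_config(mode)
            rec = simulate_stand(t_lanes, sim_cfg, replant_density_ha=cfg.replant_density, noise=noise_lanes)
            max_cons = max(max_cons, float(rec["conservation_rel_err"].max()))
            member_mean = {k: rec[k].reshape(Y, M, P).mean(axis=2) for k in REPORT_VARS}
            for m in range(M):
                frame = {k: member_mean[k][:, m] for k in REPORT_VARS}
                df = pd.DataFrame(frame)
                df.insert(0, "year", years)
                df.insert(0, "member", m)
                df.insert(0, "mode", mode)
                df.insert(0, "site", site.site_id)
                rows.append(df)
                closure_rows.append(
                    {
                        "site": site.site_id,
                        "mode": mode,
                        "member": m,
                        "closure_year": canopy_closure_year(member_mean["canopy_fraction_pre"][:, m], years=years),
                    }
                )
    data = pd.concat(rows, ignore_index=True)
    closure = pd.DataFrame(closure_rows)
    return ExperimentResult(
        data=data,
        closure=closure,
        seed=seed,
        diagnostics={"max_conservation_rel_err": max_cons},
    )


def relative_difference(wd_series, std_series):
    """Elementwise percent difference 100 * (wd - std) / std.

    Entries with a zero baseline come back as NaN (flagged, not dropped).
    """
    wd = np.asarray(wd_series, dtype=float)
    std = np.asarray(std_series, dtype=float)
    if wd.shape != std.shape:
        raise ValueError("series must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(std != 0, 100.0 * (wd - std) / np.where(std != 0, std, 1.0), np.nan)
    return out


def relative_difference_table(
    result: ExperimentResult,
    var: str,
    baseline_mode: str = "static",
    modes: list[str] | None = None,
) -> pd.DataFrame:
    """Member-matched percent differences of ``var`` against the baseline mode.

    Each dynamic member is compared with the baseline member that shares its
    climate offset and noise, per site and year.
    """
    base = result.data[result.data["mode"] == baseline_mode]
    base = base.set_index(["site", "member", "year"])[var]
    out = []
    for mode in modes or [m for m in result.data["mode"].unique() if m != baseline_mode]:
        sub = result.data[result.data["mode"] == mode]
        matched = base.loc[list(zip(sub["site"], sub["member"], sub["year"]))].to_numpy()
        out.append(
            pd.DataFrame(
                {
                    "site": sub["site"].to_numpy(),
                    "mode": mode,
                    "member": sub["member"].to_numpy(),
                    "year": sub["year"].to_numpy(),
                    "rel_diff_pct": relative_difference(sub[var].to_numpy(), matched),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def select_representative(member_trajectories) -> int:
    """Index of the member closest (RMSE) to the ensemble-mean trajectory.

    Accepts an ``(n_members, n_years)`` array or a (year x member)
    DataFrame.  Ties resolve to the lowest index.
    """
    if isinstance(member_trajectories, pd.DataFrame):
        arr = member_trajectories.to_numpy(float).T
    else:
        arr = np.atleast_2d(np.asarray(member_trajectories, dtype=float))
    mean = arr.mean(axis=0)
    rmse = np.sqrt(((arr - mean) ** 2).mean(axis=1))
    return int(np.argmin(rmse))


def run_warming(
    cfg: ExperimentConfig,
    stages: StageDefinition = StageDefinition(),
    delta_t: float = 2.0,
    seed: int = 0,
    baseline: ExperimentResult | None = None,
    select_mode: str | None = None,
) -> dict:
    """Staged +``delta_t`` warming on one representative member per site.

    Per site: the member whose canopy-area series best matches the ensemble
    mean (in ``select_mode``, default the first dynamic mode) is selected
    from the baseline recovery; for each canopy stage the first year its
    threshold is reached becomes the warming onset; the member is then
    re-simulated in every mode under the stepped climate.  Stages a site
    never reaches are skipped with a logged warning.

    Returns ``{stage_name: ExperimentResult}`` (member column holds the
    representative member's index).
    """
    if baseline is None:
        baseline = run_recovery(cfg, seed=seed)
    if select_mode is None:
        dynamic_modes = [m for m, r in cfg.responses.items() if r is not None]
        select_mode = dynamic_modes[0] if dynamic_modes else next(iter(cfg.responses))

    results: dict[str, ExperimentResult] = {}
    years = np.arange(1, cfg.recovery_years + 1)
    site_rep: dict[str, int] = {}
    for site in cfg.sites:
        canopy = baseline.member_series(site.site_id, select_mode, "canopy_fraction_pre")
        site_rep[site.site_id] = select_representative(canopy)

    for stage_name, threshold in stages.thresholds.items():
        rows = []
        closure_rows = []
        max_cons = 0.0
        any_site = False
        for si, site in enumerate(cfg.sites):
            rep = site_rep[site.site_id]
            canopy = baseline.member_series(site.site_id, select_mode, "canopy_fraction_pre")[rep].to_numpy()
            onset = canopy_closure_year(canopy, years=years, threshold=threshold)
            if onset is None:
                log.warning("site %s never reaches canopy stage %r (%.2f); stage skipped", site.site_id, stage_name, threshold)
                continue
            any_site = True
            climate_seed = derive_seed(seed, si, 0)
            # stage observed at the end of recorded year `onset`; the step
            # applies from the following growth year (simulation index = onset)
            warming = WarmingScenario(delta_t=delta_t, onset_year=int(onset))
            t_jas = _member_jas_matrix(site, cfg, climate_seed, warming=warming, members=[rep])  # (Y, 1)
            noise = _patch_noise(cfg, seed, si)[:, rep, :]                                       # (Y, P)
            t_lanes = np.repeat(t_jas, cfg.n_patches, axis=1)
            for mode in cfg.responses:
                sim_cfg = cfg.simulator_config(mode)
                rec = simulate_stand(t_lanes, sim_cfg, replant_density_ha=cfg.replant_density, noise=noise)
                max_cons = max(max_cons, float(rec["conservation_rel_err"].max()))
                frame = {k: rec[k].mean(axis=1) for k in REPORT_VARS}
                df = pd.DataFrame(frame)
                df.insert(0, "year", years)
                df.insert(0, "member", rep)
                df.insert(0, "mode", mode)
                df.insert(0, "site", site.site_id)
                df["onset_year"] = onset
                rows.append(df)
                closure_rows.append(
                    {
                        "site": site.site_id,
                        "mode": mode,
                        "member": rep,
                        "closure_year": canopy_closure_year(frame["canopy_fraction_pre"], years=years),
                    }
                )
        if any_site:
            results[stage_name] = ExperimentResult(
                data=pd.concat(rows, ignore_index=True),
                closure=pd.DataFrame(closure_rows),
                seed=seed,
                diagnostics={"max_conservation_rel_err": max_cons, "delta_t": delta_t, "stage": stage_name},
            )
    return results
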