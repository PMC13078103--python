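"""Cohort-based tree and stand demography with per-ring wood density.

The model follows the gap-model tradition: a cohort is a group of same-aged
trees represented by one *average individual* plus a stem density
(individuals per m^2).  Each year the cohort

1. fixes carbon with a simple stand-in productivity model (leaf area x
   unimodal temperature modifier x Beer--Lambert mean light availability),
2. loses leaf and fine-root carbon to turnover and a fixed share to
   reproduction,
3. receives this year's ring density -- a fixed parameter in ``static`` mode,
   or composed from the logistic latewood-density response to the JAS
   temperature in ``dynamic`` mode,
4. allocates the remaining carbon by solving for the diameter increment whose
   stem cost (ring density x cylindrical volume increment) plus the leaf and
   root increments needed to restore the pipe-model and root:leaf targets
   exactly exhausts the carbon,
5. transfers a fixed fraction of sapwood to heartwood, and
6. is thinned whenever summed crown area exceeds the patch area.

Denser wood makes each unit of stem volume more expensive, so warm years
(dense rings) buy less diameter and height -- the structural trade-off the
dynamic-density mode exists to express.

All low-level steps are written as vectorised numpy primitives over "lanes"
so that a single code path serves both the scalar :class:`Cohort`/
:class:`Patch` objects (one lane) and ensembles of replicate patches and
climate members (many lanes) at full speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .response import DensityResponse, RingComposition, compose_trd, evaluate_lwd

__all__ = [
    "AllometryParams",
    "NppParams",
    "SimulatorConfig",
    "RingRecord",
    "Cohort",
    "Patch",
    "ring_density_for_year",
    "allometric_height",
    "allometric_crown_area",
    "stem_volume",
    "annual_npp",
    "allocate",
    "grow_year",
    "self_thin",
    "stem_density_summaries",
    "canopy_closure_year",
    "simulate_stand",
]


@dataclass(frozen=True)
class AllometryParams:
    """Allometric and turnover constants of the average individual.

    Height and crown area are power laws of stem diameter; leaf area is tied
    to sapwood cross-sectional area through the pipe model (``k_latosa``).
    ``ca_max`` caps crown area at 80 m^2: with the fixed replanting density of
    200 trees/ha, a 50 m^2 cap would let summed crown area only asymptote to
    the patch area and crowding mortality would never engage, so the cap is
    set above 1/(replant density) to leave self-thinning operational.
    """

    k_height: float = 40.0          # height = k_height * D^k_height_exp  [m]
    k_height_exp: float = 0.67
    k_crown: float = 150.0          # crown area = k_crown * D^k_crown_exp  [m^2]
    k_crown_exp: float = 1.6
    ca_max: float = 80.0            # maximum crown area per individual [m^2]
    k_latosa: float = 3000.0        # leaf area : sapwood cross-section [m^2/m^2]
    sla: float = 9.3                # specific leaf area [m^2 / kgC]
    root_leaf_ratio: float = 1.0    # fine-root : leaf carbon target
    reproduction_fraction: float = 0.1
    leaf_turnover: float = 0.33     # annual fraction of leaf carbon lost
    root_turnover: float = 0.7      # annual fraction of root carbon lost
    sap_to_heart_rate: float = 0.05  # annual sapwood -> heartwood fraction

    def __post_init__(self) -> None:
        for name in ("k_height", "k_crown", "ca_max", "k_latosa", "sla"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("k_height_exp", "k_crown_exp"):
            if not 0.0 < getattr(self, name) < 3.0:
                raise ValueError(f"{name} must lie in (0, 3)")
        for name in ("reproduction_fraction", "leaf_turnover", "root_turnover", "sap_to_heart_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class NppParams:
    """Stand-in productivity constants (no daily physiology).

    ``p0`` is potential annual NPP per unit leaf area; realised NPP is
    ``p0 * leaf_area * f(T) * light`` with a Gaussian temperature modifier
    centred on ``t_opt`` and mean Beer--Lambert light availability over the
    patch leaf-area index.
    """

    p0: float = 0.55                # kgC per m^2 leaf per year
    t_opt: float = 12.0             # degC, optimum of the unimodal modifier
    t_width: float = 10.0           # degC, breadth of the modifier
    k_ext: float = 0.5              # Beer-Lambert extinction coefficient

    def __post_init__(self) -> None:
        if self.p0 < 0 or self.t_width <= 0 or self.k_ext <= 0:
            raise ValueError("invalid productivity constants")


@dataclass(frozen=True)
class SimulatorConfig:
    """Everything one simulation run needs.

    ``mode`` selects between the fixed-density baseline (``"static"``,
    186 kgC/m^3 by default) and the temperature-responsive ring density
    (``"dynamic"``, requiring ``response``).
    """

    mode: str = "static"
    static_density: float = 186.0
    response: DensityResponse | None = None
    composition: RingComposition = RingComposition()
    allometry: AllometryParams = AllometryParams()
    npp_params: NppParams = NppParams()
    sapwood_density_window: int = 3
    patch_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"mode must be 'static' or 'dynamic', got {self.mode!r}")
        if self.static_density <= 0:
            raise ValueError("static_density must be positive")
        if self.mode == "dynamic" and self.response is None:
            raise ValueError("dynamic mode requires a DensityResponse")
        if self.sapwood_density_window < 1:
            raise ValueError("sapwood_density_window must be >= 1")


@dataclass(frozen=True)
class RingRecord:
    """Bookkeeping for one annual ring of the average individual."""

    year: int
    width: float      # radial increment [m]
    density: float    # total ring density [kgC/m^3]
    volume: float     # stem volume added this year [m^3]
    carbon: float     # = density * volume [kgC]


# ---------------------------------------------------------------------------
# vectorised primitives
# ---------------------------------------------------------------------------

def ring_density_for_year(t_jas, cfg: SimulatorConfig):
    """This year's total ring density (kgC/m^3) given the JAS temperature."""
    if cfg.mode == "static":
        t = np.asarray(t_jas, dtype=float)
        out = np.full_like(t, cfg.static_density)
        return float(out) if t.ndim == 0 else out
    return compose_trd(evaluate_lwd(t_jas, cfg.response), cfg.composition)


def allometric_height(diameter, allom: AllometryParams = AllometryParams()):
    """Tree height (m) from stem diameter (m)."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    out = allom.k_height * d**allom.k_height_exp
    return float(out) if d.ndim == 0 else out


def allometric_crown_area(diameter, allom: AllometryParams = AllometryParams()):
    """Crown area (m^2) from stem diameter, capped at ``ca_max``."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    out = np.minimum(allom.k_crown * d**allom.k_crown_exp, allom.ca_max)
    return float(out) if d.ndim == 0 else out


def stem_volume(diameter, height):
    """Cylindrical stem volume (m^3)."""
    return 0.25 * np.pi * np.asarray(diameter, float) ** 2 * np.asarray(height, float)


def mean_light_fraction(lai, k_ext: float):
    """Mean Beer--Lambert light availability over a canopy of leaf-area index ``lai``.

    (1 - exp(-k L)) / (k L), tending to 1 as L -> 0.
    """
    lai = np.asarray(lai, dtype=float)
    x = k_ext * lai
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(x > 1e-12, -np.expm1(-x) / np.where(x > 1e-12, x, 1.0), 1.0)
    return out


def temperature_modifier(t, npp: NppParams):
    """Unimodal Gaussian temperature modifier, 1 at the optimum."""
    t = np.asarray(t, dtype=float)
    return np.exp(-(((t - npp.t_opt) / npp.t_width) ** 2))


def _allocation_cost(d_diam, diameter, height0, sap_area, c_leaf, c_root, rho, al):
    """Total carbon cost of a diameter increment, plus its components."""
    d_new = diameter + d_diam
    h_new = al.k_height * d_new**al.k_height_exp
    v0 = 0.25 * np.pi * diameter * diameter * height0
    d_vol = 0.25 * np.pi * d_new * d_new * h_new - v0
    sap_new = sap_area + 0.25 * np.pi * (d_new * d_new - diameter * diameter)
    leaf_target = al.k_latosa * sap_new / al.sla
    leaf_inc = np.maximum(leaf_target - c_leaf, 0.0)
    root_inc = np.maximum(al.root_leaf_ratio * leaf_target - c_root, 0.0)
    return rho * d_vol + leaf_inc + root_inc, d_vol, leaf_inc, root_inc


def solve_allocation(
    diameter,
    height,
    sap_area,
    c_leaf,
    c_root,
    growth_carbon,
    ring_density,
    allom: AllometryParams,
    max_iter: int = 100,
):
    """Find the diameter increment whose total cost equals ``growth_carbon``.

    Vectorised bisection.  Where even a zero-width ring cannot cover the
    pipe-model leaf/root deficits, the carbon is split between leaves and
    roots in proportion to their deficits and the ring width is zero.

    Returns ``(d_diameter, d_volume, leaf_inc, root_inc, stem_carbon)`` as
    arrays broadcast to lane shape.
    """
    D = np.atleast_1d(np.asarray(diameter, dtype=float))
    H = np.atleast_1d(np.asarray(height, dtype=float))
    A = np.atleast_1d(np.asarray(sap_area, dtype=float))
    L = np.atleast_1d(np.asarray(c_leaf, dtype=float))
    R = np.atleast_1d(np.asarray(c_root, dtype=float))
    g = np.atleast_1d(np.asarray(growth_carbon, dtype=float))
    rho = np.broadcast_to(np.asarray(ring_density, dtype=float), g.shape).astype(float)
    if np.any(g < 0):
        raise ValueError("growth_carbon must be non-negative")
    if np.any(rho <= 0):
        raise ValueError("ring_density must be positive")

    zero = np.zeros_like(g)
    cost0, _, leaf_def, root_def = _allocation_cost(zero, D, H, A, L, R, rho, allom)
    feasible = cost0 <= g

    # bracket the root, expanding per lane where needed
    hi = np.full_like(g, 0.05)
    for _ in range(64):
        c_hi, _, _, _ = _allocation_cost(hi, D, H, A, L, R, rho, allom)
        need = feasible & (c_hi < g)
        if not need.any():
            break
        hi = np.where(need, 2.0 * hi, hi)
    lo = zero.copy()
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c_mid, _, _, _ = _allocation_cost(mid, D, H, A, L, R, rho, allom)
        above = c_mid > g
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    d_diam = np.where(feasible, 0.5 * (lo + hi), 0.0)
    # lanes whose zero-increment cost already matches (e.g. growth 0 with
    # compartments at target) get an exactly zero-width ring
    d_diam = np.where(feasible & (cost0 == g), 0.0, d_diam)

    _, d_vol, leaf_inc, root_inc = _allocation_cost(d_diam, D, H, A, L, R, rho, allom)
    stem_carbon = rho * d_vol
    # infeasible lanes: leaves and roots only, proportional to their deficits
    if not feasible.all():
        deficit = leaf_def + root_def
        share = np.where(deficit > 0, leaf_def / np.where(deficit > 0, deficit, 1.0), 0.0)
        d_vol = np.where(feasible, d_vol, 0.0)
        stem_carbon = np.where(feasible, stem_carbon, 0.0)
        leaf_inc = np.where(feasible, leaf_inc, g * share)
        root_inc = np.where(feasible, root_inc, g * (1.0 - share))
    return d_diam, d_vol, leaf_inc, root_inc, stem_carbon


# ---------------------------------------------------------------------------
# object layer: Cohort and Patch
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """The average individual of a group of same-aged trees, plus its density."""

    n_per_m2: float
    diameter: float
    height: float
    sap_area: float               # sapwood cross-sectional area [m^2]
    c_leaf: float
    c_root: float
    c_sap: float
    c_heart: float = 0.0
    age: int = 0
    rings: list[RingRecord] = field(default_factory=list)

    @property
    def crown_area(self) -> float:
        return self._crown_area

    _crown_area: float = field(default=0.0, repr=False)

    def _update_crown(self, allom: AllometryParams) -> None:
        self._crown_area = allometric_crown_area(self.diameter, allom)

    @property
    def cwood(self) -> float:
        """Carbon in wood (sapwood + heartwood) per individual [kgC]."""
        return self.c_sap + self.c_heart

    @classmethod
    def plant(
        cls,
        cfg: SimulatorConfig,
        n_per_m2: float,
        ring_density: float,
        diameter: float = 0.005,
        year: int = 0,
    ) -> "Cohort":
        """A freshly planted sapling cohort with pipe-consistent compartments.

        The initial stem is one ring of width ``diameter/2`` priced at the
        planting year's ring density.
        """
        al = cfg.allometry
        height = allometric_height(diameter, al)
        vol = float(stem_volume(diameter, height))
        sap_area = 0.25 * math.pi * diameter**2
        c_leaf = al.k_latosa * sap_area / al.sla
        c_root = al.root_leaf_ratio * c_leaf
        c_sap = ring_density * vol
        cohort = cls(
            n_per_m2=n_per_m2,
            diameter=diameter,
            height=height,
            sap_area=sap_area,
            c_leaf=c_leaf,
            c_root=c_root,
            c_sap=c_sap,
            rings=[RingRecord(year=year, width=diameter / 2.0, density=ring_density, volume=vol, carbon=ring_density * vol)],
        )
        cohort._update_crown(al)
        return cohort


@dataclass
class Patch:
    """A replicate unit of ground area over which cohorts compete for light."""

    cohorts: list[Cohort]
    area: float = 1000.0

    @property
    def canopy_fraction(self) -> float:
        return float(sum(c.crown_area * c.n_per_m2 for c in self.cohorts))

    def lai(self, allom: AllometryParams) -> float:
        """Patch leaf-area index (m^2 leaf per m^2 ground)."""
        return float(sum(allom.sla * c.c_leaf * c.n_per_m2 for c in self.cohorts))


def annual_npp(
    cohort: Cohort,
    patch: Patch,
    t_growing: float,
    cfg: SimulatorConfig,
    noise: float = 1.0,
) -> float:
    """Annual net primary production of the average individual [kgC].

    Potential NPP per leaf area x leaf area x temperature modifier x mean
    light availability over the patch LAI x multiplicative noise.
    """
    al, npp = cfg.allometry, cfg.npp_params
    leaf_area = al.sla * cohort.c_leaf
    lai = patch.lai(al)
    value = (
        npp.p0
        * leaf_area
        * float(temperature_modifier(t_growing, npp))
        * float(mean_light_fraction(lai, npp.k_ext))
        * noise
    )
    return max(value, 0.0)


def allocate(cohort: Cohort, growth_carbon: float, ring_density: float, allom: AllometryParams, year: int | None = None) -> RingRecord:
    """Spend ``growth_carbon`` on a new ring plus leaf/root restoration.

    Mutates the cohort and appends the resulting :class:`RingRecord`.
    Carbon is conserved: ring carbon + leaf and root increments equal
    ``growth_carbon`` up to the bisection tolerance.
    """
    if growth_carbon < 0:
        raise ValueError("growth_carbon must be non-negative")
    d_diam, d_vol, leaf_inc, root_inc, stem_c = solve_allocation(
        cohort.diameter,
        cohort.height,
        cohort.sap_area,
        cohort.c_leaf,
        cohort.c_root,
        growth_carbon,
        ring_density,
        allom,
    )
    d_diam, d_vol, leaf_inc, root_inc, stem_c = (
        float(d_diam[0]),
        float(d_vol[0]),
        float(leaf_inc[0]),
        float(root_inc[0]),
        float(stem_c[0]),
    )
    ring_area = 0.25 * math.pi * ((cohort.diameter + d_diam) ** 2 - cohort.diameter**2)
    cohort.diameter += d_diam
    cohort.height = allometric_height(cohort.diameter, allom)
    cohort.sap_area += ring_area
    cohort.c_leaf += leaf_inc
    cohort.c_root += root_inc
    cohort.c_sap += stem_c
    cohort._update_crown(allom)
    ring = RingRecord(
        year=cohort.age if year is None else year,
        width=d_diam / 2.0,
        density=ring_density,
        volume=d_vol,
        carbon=stem_c,
    )
    cohort.rings.append(ring)
    return ring


def self_thin(patch: Patch) -> Patch:
    """Scale stem densities so summed crown area never exceeds the patch area."""
    cf = patch.canopy_fraction
    if cf > 1.0:
        scale = 1.0 / cf
        for c in patch.cohorts:
            c.n_per_m2 = c.n_per_m2 * scale
    return patch


def grow_year(patch: Patch, t_jas: float, cfg: SimulatorConfig, noise: float = 1.0, year: int | None = None) -> dict:
    """Advance the patch one year; returns a per-year diagnostics mapping.

    Order: NPP -> leaf/root turnover and reproduction -> ring density from
    the JAS temperature -> allocation -> sapwood-to-heartwood transfer ->
    self-thinning.  Tree numbers never increase (no establishment).
    """
    al = cfg.allometry
    rho = float(ring_density_for_year(t_jas, cfg))
    diag = {"npp": 0.0, "reproduction": 0.0, "turnover": 0.0, "conservation_err": 0.0}
    for cohort in patch.cohorts:
        before = cohort.c_leaf + cohort.c_root + cohort.c_sap + cohort.c_heart
        npp = annual_npp(cohort, patch, t_jas, cfg, noise=noise)
        leaf_loss = al.leaf_turnover * cohort.c_leaf
        root_loss = al.root_turnover * cohort.c_root
        cohort.c_leaf -= leaf_loss
        cohort.c_root -= root_loss
        repro = al.reproduction_fraction * npp
        growth = npp - repro
        allocate(cohort, growth, rho, al, year=year)
        transfer = al.sap_to_heart_rate * cohort.c_sap
        cohort.c_sap -= transfer
        cohort.c_heart += transfer
        cohort.sap_area *= 1.0 - al.sap_to_heart_rate
        cohort.age += 1
        after = cohort.c_leaf + cohort.c_root + cohort.c_sap + cohort.c_heart
        err = abs(npp - (after - before + leaf_loss + root_loss + repro))
        diag["npp"] += npp
        diag["reproduction"] += repro
        diag["turnover"] += leaf_loss + root_loss
        diag["conservation_err"] = max(diag["conservation_err"], err / max(npp, 1e-12))
    diag["canopy_fraction_pre"] = patch.canopy_fraction
    self_thin(patch)
    diag["canopy_fraction"] = patch.canopy_fraction
    return diag


def stem_density_summaries(cohort: Cohort, window: int = 3) -> dict:
    """Whole-stem and recent-ring (sapwood) densities of the average individual.

    ``swd`` is total ring carbon over total ring volume; ``sapwood_density``
    is the volume-weighted mean density of the most recent ``window`` rings
    (clamped to the rings available).
    """
    if not cohort.rings:
        raise ValueError("cohort has no rings")
    vols = np.array([r.volume for r in cohort.rings])
    carbons = np.array([r.carbon for r in cohort.rings])
    if vols.sum() <= 0:
        raise ValueError("total ring volume is zero")
    recent_v = vols[-window:]
    recent_c = carbons[-window:]
    recent_sum = recent_v.sum()
    sap = recent_c.sum() / recent_sum if recent_sum > 0 else carbons.sum() / vols.sum()
    return {"swd": float(carbons.sum() / vols.sum()), "sapwood_density": float(sap)}


def canopy_closure_year(canopy_fractions: Sequence[float], years: Sequence[int] | None = None, threshold: float = 1.0):
    """First year the (pre-thinning) canopy fraction reaches ``threshold``.

    ``years`` defaults to 1..n.  Returns ``None`` if the threshold is never
    reached.
    """
    fr = np.asarray(canopy_fractions, dtype=float)
    if fr.size == 0:
        raise ValueError("need at least one simulated year")
    idx = np.nonzero(fr >= threshold)[0]
    if idx.size == 0:
        return None
    if years is None:
        return int(idx[0]) + 1
    return years[int(idx[0])]


# ---------------------------------------------------------------------------
# lane engine
# ---------------------------------------------------------------------------

def simulate_stand(
    t_jas,
    cfg: SimulatorConfig,
    replant_density_ha: float = 200.0,
    noise=None,
    initial_diameter: float = 0.005,
):
    """Simulate a single replanted cohort over ``t_jas.shape[0]`` years.

    Parameters
    ----------
    t_jas
        JAS temperatures, shape ``(n_years,)`` or ``(n_years, n_lanes)``.
        Each lane is an independent stand (e.g. a replicate patch or a
        climate-ensemble member).
    cfg
        Simulator configuration (mode, response, allometry, productivity).
    replant_density_ha
        Trees per hectare planted in year 0.
    noise
        Multiplicative NPP noise factors with the same shape as ``t_jas``
        (default: none, factor 1).

    Returns
    -------
    dict of ``(n_years, n_lanes)`` arrays: trees_ha, diameter_m, height_m,
    crown_area_m2, canopy_fraction_pre, canopy_fraction, cwood_per_tree_kgC,
    cwood_per_m2_kgC, ring_width_m, ring_density_kgC_m3, swd_kgC_m3,
    sapwood_density_kgC_m3, npp_kgC, conservation_rel_err.

    The planting-year ring is priced at year 0's ring density; recorded row
    ``y`` holds the state after growth year ``y`` (age ``y + 1``).
    """
    t = np.asarray(t_jas, dtype=float)
    squeeze = t.ndim == 1
    if squeeze:
        t = t[:, None]
    n_years, n_lanes = t.shape
    if noise is None:
        noise_arr = np.ones_like(t)
    else:
        noise_arr = np.asarray(noise, dtype=float)
        if squeeze and noise_arr.ndim == 1:
            noise_arr = noise_arr[:, None]
        if noise_arr.shape != t.shape:
            raise ValueError("noise must match t_jas shape")

    al, npp_p = cfg.allometry, cfg.npp_params
    window = cfg.sapwood_density_window

    rho0 = np.broadcast_to(np.asarray(ring_density_for_year(t[0], cfg), dtype=float), (n_lanes,)).copy()
    n = np.full(n_lanes, replant_density_ha / 10_000.0)
    D = np.full(n_lanes, float(initial_diameter))
    H = np.broadcast_to(allometric_height(D, al), (n_lanes,)).copy()
    V0 = stem_volume(D, H)
    A_sap = 0.25 * np.pi * D**2
    c_leaf = al.k_latosa * A_sap / al.sla
    c_root = al.root_leaf_ratio * c_leaf
    c_sap = rho0 * V0
    c_heart = np.zeros(n_lanes)
    ring_c_total = c_sap.copy()
    ring_v_total = V0.copy()
    recent_v = [V0.copy()]
    recent_c = [c_sap.copy()]

    names = [
        "trees_ha",
        "diameter_m",
        "height_m",
        "crown_area_m2",
        "canopy_fraction_pre",
        "canopy_fraction",
        "cwood_per_tree_kgC",
        "cwood_per_m2_kgC",
        "ring_width_m",
        "ring_density_kgC_m3",
        "swd_kgC_m3",
        "sapwood_density_kgC_m3",
        "npp_kgC",
        "conservation_rel_err",
    ]
    rec = {k: np.empty((n_years, n_lanes)) for k in names}

    for y in range(n_years):
        before = c_leaf + c_root + c_sap + c_heart
        leaf_area = al.sla * c_leaf
        lai = leaf_area * n
        npp = (
            npp_p.p0
            * leaf_area
            * temperature_modifier(t[y], npp_p)
            * mean_light_fraction(lai, npp_p.k_ext)
            * noise_arr[y]
        )
        npp = np.maximum(npp, 0.0)
        leaf_loss = al.leaf_turnover * c_leaf
        root_loss = al.root_turnover * c_root
        c_leaf = c_leaf - leaf_loss
        c_root = c_root - root_loss
        repro = al.reproduction_fraction * npp
        growth = npp - repro
        rho = np.broadcast_to(np.asarray(ring_density_for_year(t[y], cfg), dtype=float), (n_lanes,))
        d_diam, d_vol, leaf_inc, root_inc, stem_c = solve_allocation(
            D, H, A_sap, c_leaf, c_root, growth, rho, al
        )
        ring_area = 0.25 * np.pi * ((D + d_diam) ** 2 - D**2)
        D = D + d_diam
        H = al.k_height * D**al.k_height_exp
        A_sap = A_sap + ring_area
        c_leaf = c_leaf + leaf_inc
        c_root = c_root + root_inc
        c_sap = c_sap + stem_c
        ring_c_total = ring_c_total + stem_c
        ring_v_total = ring_v_total + d_vol
        recent_v.append(d_vol)
        recent_c.append(stem_c)
        if len(recent_v) > window:
            recent_v.pop(0)
            recent_c.pop(0)
        transfer = al.sap_to_heart_rate * c_sap
        c_sap = c_sap - transfer
        c_heart = c_heart + transfer
        A_sap = A_sap * (1.0 - al.sap_to_heart_rate)
        crown = allometric_crown_area(D, al)
        cf_pre = crown * n
        scale = np.where(cf_pre > 1.0, 1.0 / cf_pre, 1.0)
        n = n * scale
        after = c_leaf + c_root + c_sap + c_heart

        rec["trees_ha"][y] = n * 10_000.0
        rec["diameter_m"][y] = D
        rec["height_m"][y] = H
        rec["crown_area_m2"][y] = crown
        rec["canopy_fraction_pre"][y] = cf_pre
        rec["canopy_fraction"][y] = crown * n
        rec["cwood_per_tree_kgC"][y] = c_sap + c_heart
        rec["cwood_per_m2_kgC"][y] = (c_sap + c_heart) * n
        rec["ring_width_m"][y] = d_diam / 2.0
        rec["ring_density_kgC_m3"][y] = rho
        rec["swd_kgC_m3"][y] = ring_c_total / ring_v_total
        rv = np.sum(recent_v, axis=0)
        rc = np.sum(recent_c, axis=0)
        rec["sapwood_density_kgC_m3"][y] = np.where(rv > 0, rc / np.where(rv > 0, rv, 1.0), ring_c_total / ring_v_total)
        rec["npp_kgC"][y] = npp
        rec["conservation_rel_err"][y] = np.abs(npp - ((after - before) + leaf_loss + root_loss + repro)) / np.maximum(npp, 1e-12)

    if squeeze:
        rec = {k: v[:, 0] for k, v in rec.items()}
    return rec
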