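"""Wood-density math core.

Latewood density (LWD) in conifers such as Norway spruce tracks late-summer
temperature: warm July--September (JAS) seasons produce thicker-walled
latewood cells and hence denser latewood.  This module provides the
four-parameter logistic response LWD(T), the composition of total ring
density (TRD) from a fixed earlywood fraction, the unit conversions from
reported air-dry densities to carbon densities, and the elevation lapse-rate
adjustment used to downscale gridcell temperatures to a site.

All densities are expressed in kgC/m^3 unless a function says otherwise;
temperatures are in degrees Celsius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "DensityResponse",
    "RingComposition",
    "UnitConversion",
    "SiteConfig",
    "evaluate_lwd",
    "compose_trd",
    "invert_trd",
    "convert_density",
    "lapse_adjust",
    "jas_mean",
    "JAS_MONTHS",
]

#: July, August, September -- the temperature window that drives latewood density.
JAS_MONTHS = (7, 8, 9)


@dataclass(frozen=True)
class DensityResponse:
    """Symmetric four-parameter logistic response of latewood density to temperature.

    LWD(T) = a + (b - a) / (1 + exp(-c * (T - d)))

    Parameters
    ----------
    a, b
        Lower and upper asymptotes of latewood density (kgC/m^3).
    c
        Growth-rate parameter (1/degC); c >= 0 gives a non-decreasing response.
    d
        Midpoint temperature (degC) where LWD = (a + b) / 2.
    label
        Identifier, e.g. ``"best"``, ``"range"``, ``"flat"`` or a custom tag.
    """

    a: float
    b: float
    c: float
    d: float
    label: str = "custom"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"DensityResponse.{name} must be finite, got {v!r}")
        if self.a > self.b:
            raise ValueError(f"lower asymptote a={self.a} exceeds upper b={self.b}")
        if self.c < 0:
            raise ValueError(f"growth rate c must be >= 0, got {self.c}")

    def __call__(self, temperature):
        return evaluate_lwd(temperature, self)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "DensityResponse":
        return cls(**{k: mapping[k] for k in ("a", "b", "c", "d", "label") if k in mapping})


@dataclass(frozen=True)
class RingComposition:
    """Fixed earlywood/latewood make-up of an annual ring.

    ``f_ew`` is the earlywood share of the ring's volume contribution and
    ``ewd`` the (constant) earlywood density.  Defaults encode the 70:30
    earlywood:latewood split and 139 kgC/m^3 earlywood density typical of
    Norway spruce.
    """

    ewd: float = 139.0
    f_ew: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_ew <= 1.0:
            raise ValueError(f"f_ew must be in [0, 1], got {self.f_ew}")
        if self.ewd <= 0:
            raise ValueError(f"earlywood density must be positive, got {self.ewd}")


@dataclass(frozen=True)
class UnitConversion:
    """Multiplicative factors from reported air-dry density to carbon density.

    ``airdry_to_ovendry`` rescales air-dry to oven-dry mass (default 0.828);
    ``carbon_fraction`` converts dry biomass to carbon (default 0.5).
    """

    airdry_to_ovendry: float = 0.828
    carbon_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("airdry_to_ovendry", "carbon_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class SiteConfig:
    """A study site on the temperature gradient.

    ``jas_mean`` is the long-run mean July--September temperature at the site
    (after lapse adjustment).  ``elevation_site``/``elevation_ref`` let
    gridcell temperatures be downscaled with ``lapse_rate`` (degC per 100 m,
    default 0.649).
    """

    site_id: str
    jas_mean: float
    elevation_site: float = 0.0
    elevation_ref: float = 0.0
    lapse_rate: float = 0.649
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.lapse_rate < 0:
            raise ValueError(f"lapse_rate must be >= 0, got {self.lapse_rate}")


def evaluate_lwd(temperature, resp: DensityResponse):
    """Latewood density (kgC/m^3) at JAS temperature ``temperature`` (degC).

    Accepts scalars or arrays.  The result is always bounded by ``[a, b]``.
    Raises ``ValueError`` on non-finite temperatures.
    """
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    # clip the exponent so extreme temperatures saturate instead of overflowing
    z = np.clip(-resp.c * (t - resp.d), -700.0, 700.0)
    out = resp.a + (resp.b - resp.a) / (1.0 + np.exp(z))
    return float(out) if np.isscalar(temperature) or out.ndim == 0 else out


def compose_trd(lwd, comp: RingComposition = RingComposition()):
    """Total ring density from latewood density via the fixed EW:LW split.

    TRD = f_ew * ewd + (1 - f_ew) * LWD
    """
    arr = np.asarray(lwd, dtype=float)
    if np.any(arr < 0):
        raise ValueError("latewood density must be non-negative")
    out = comp.f_ew * comp.ewd + (1.0 - comp.f_ew) * arr
    return float(out) if arr.ndim == 0 else out


def invert_trd(trd: float, comp: RingComposition = RingComposition()) -> float:
    """Latewood density whose composed total ring density equals ``trd``.

    Undefined for an all-earlywood ring (f_ew == 1).
    """
    if comp.f_ew >= 1.0:
        raise ValueError("cannot invert composition with f_ew = 1 (no latewood)")
    return (trd - comp.f_ew * comp.ewd) / (1.0 - comp.f_ew)


def convert_density(rho_airdry, conv: UnitConversion = UnitConversion(), apply_carbon: bool = True):
    """Convert reported air-dry density (kg/m^3) to oven-dry or carbon density.

    With ``apply_carbon`` the result is in kgC/m^3 (both factors applied);
    otherwise kg/m^3 oven-dry.
    """
    arr = np.asarray(rho_airdry, dtype=float)
    if np.any(arr < 0):
        raise ValueError("density must be non-negative")
    out = arr * conv.airdry_to_ovendry
    if apply_carbon:
        out = out * conv.carbon_fraction
    return float(out) if arr.ndim == 0 else out


def lapse_adjust(temperature, site: SiteConfig):
    """Downscale a gridcell temperature to the site elevation.

    T_site = T_gridcell - lapse_rate * (elevation_site - elevation_ref) / 100

    so a site above its gridcell reference is cooler.
    """
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    out = t - site.lapse_rate * (site.elevation_site - site.elevation_ref) / 100.0
    return float(out) if t.ndim == 0 else out


def jas_mean(monthly, year: int) -> float:
    """Mean July--September temperature of ``year`` in a monthly series.

    ``monthly`` is a :class:`ringdemog.climate.ClimateSeries`.  Raises
    ``KeyError``/``ValueError`` naming the gap if the year or a month is
    missing.
    """
    return monthly.window_mean(year, JAS_MONTHS)


def flat_response_for_density(
    trd: float, comp: RingComposition = RingComposition(), label: str = "flat"
) -> DensityResponse:
    """A constant (a == b) response whose composed TRD equals ``trd`` exactly.

    The algebraic inverse is nudged by ulps so that ``compose_trd`` of the
    returned asymptote reproduces ``trd`` bit-for-bit, which makes a
    dynamic-mode simulation with this response an exact stand-in for a
    static-density run.
    """
    lwd = invert_trd(trd, comp)
    if compose_trd(lwd, comp) == trd:
        return DensityResponse(a=lwd, b=lwd, c=0.0, d=0.0, label=label)
    for direction in (math.inf, -math.inf):
        x = lwd
        for _ in range(64):
            x = float(np.nextafter(x, direction))
            if compose_trd(x, comp) == trd:
                return DensityResponse(a=x, b=x, c=0.0, d=0.0, label=label)
    raise ValueError(f"no float latewood density composes exactly to {trd}")
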