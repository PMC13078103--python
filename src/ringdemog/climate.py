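"""Monthly temperature series and warming scenarios.

A :class:`ClimateSeries` holds monthly mean temperatures for one site as a
dense ``(n_years, 12)`` array (NaN = missing month), which is the shape both
the fitting pipeline (window means over calendar months) and the simulator
(one JAS value per simulation year) need.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClimateSeries", "WarmingScenario"]


@dataclass
class WarmingScenario:
    """A uniform step increase applied to every month from an onset year onward."""

    delta_t: float = 2.0
    onset_year: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_t):
            raise ValueError("delta_t must be finite")
        if self.onset_year < 0:
            raise ValueError("onset_year must be >= 0")


@dataclass
class ClimateSeries:
    """Monthly mean temperatures (degC) for one site.

    ``temps[i, m-1]`` is the temperature of month ``m`` in year
    ``start_year + i``.  ``cycle_length`` records the repeat period when the
    series was tiled from a base cycle; ``provenance`` keeps generator
    parameters and seeds for reproducibility.
    """

    site_id: str
    start_year: int
    temps: np.ndarray
    cycle_length: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        if self.temps.ndim != 2 or self.temps.shape[1] != 12:
            raise ValueError("temps must have shape (n_years, 12)")

    @property
    def n_years(self) -> int:
        return self.temps.shape[0]

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)

    def _year_index(self, year: int) -> int:
        i = year - self.start_year
        if not 0 <= i < self.n_years:
            raise KeyError(f"year {year} not in series ({self.start_year}..{self.start_year + self.n_years - 1})")
        return i

    def month(self, year: int, month: int) -> float:
        if not 1 <= month <= 12:
            raise ValueError(f"month must be 1..12, got {month}")
        v = self.temps[self._year_index(year), month - 1]
        if np.isnan(v):
            raise ValueError(f"{calendar.month_name[month]} {year} missing for site {self.site_id}")
        return float(v)

    def window_mean(self, year: int, months) -> float:
        """Mean temperature over calendar ``months`` of one year; errors name any gap."""
        i = self._year_index(year)
        vals = self.temps[i, [m - 1 for m in months]]
        if np.any(np.isnan(vals)):
            gaps = [calendar.month_name[m] for m, v in zip(months, vals) if np.isnan(v)]
            raise ValueError(f"missing month(s) {', '.join(gaps)} in year {year} for site {self.site_id}")
        return float(vals.mean())

    def window_means(self, months) -> pd.Series:
        """Window-mean series over all years (NaN where any month is missing)."""
        vals = self.temps[:, [m - 1 for m in months]].mean(axis=1)
        return pd.Series(vals, index=self.years, name="t_window")

    def jas(self, year: int) -> float:
        return self.window_mean(year, (7, 8, 9))

    def jas_series(self) -> pd.Series:
        return self.window_means((7, 8, 9))

    def warmed(self, scenario: WarmingScenario) -> "ClimateSeries":
        """A copy with ``scenario.delta_t`` added to all months from the onset year on."""
        temps = self.temps.copy()
        i = max(scenario.onset_year - self.start_year, 0)
        if i < self.n_years:
            temps[i:, :] += scenario.delta_t
        prov = dict(self.provenance)
        prov["warming"] = {"delta_t": scenario.delta_t, "onset_year": scenario.onset_year}
        return ClimateSeries(self.site_id, self.start_year, temps, self.cycle_length, prov)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with columns site_id, year, month, tmean_C (missing months dropped)."""
        years = np.repeat(self.years, 12)
        months = np.tile(np.arange(1, 13), self.n_years)
        vals = self.temps.ravel()
        keep = ~np.isnan(vals)
        return pd.DataFrame(
            {"site_id": self.site_id, "year": years[keep], "month": months[keep], "tmean_C": vals[keep]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, site_id: str | None = None) -> "ClimateSeries":
        """Build from a tidy frame with columns year, month, tmean_C (one site)."""
        if site_id is not None:
            df = df[df["site_id"] == site_id]
        elif "site_id" in df.columns:
            ids = df["site_id"].unique()
            if len(ids) != 1:
                raise ValueError(f"frame holds {len(ids)} sites; pass site_id")
            site_id = ids[0]
        else:
            site_id = "site"
        if df.empty:
            raise ValueError(f"no climate rows for site {site_id!r}")
        y0, y1 = int(df["year"].min()), int(df["year"].max())
        temps = np.full((y1 - y0 + 1, 12), np.nan)
        temps[df["year"].to_numpy() - y0, df["month"].to_numpy() - 1] = df["tmean_C"].to_numpy(float)
        return cls(str(site_id), y0, temps)
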