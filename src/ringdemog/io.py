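"""Readers and writers for the package's tabular interfaces.

Ring-density tables, monthly climate tables and experiment outputs travel
as plain CSV/TSV; fitted responses and run manifests as JSON.  A minimal
reader for the Tucson decadal (``.rwl``) dendrochronology format is
included for measurement series exported from ring databanks; because
``.rwl`` files do not declare units, the caller must state how raw values
scale to kg/m^3.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .climate import ClimateSeries
from .fitting import BinnedMeans
from .response import DensityResponse, UnitConversion, convert_density

__all__ = [
    "read_ring_table",
    "read_climate_table",
    "read_rwl",
    "fit_report_to_json",
    "fit_report_from_json",
    "write_manifest",
]


def read_ring_table(
    path,
    units: str = "kgC",
    conversion: UnitConversion = UnitConversion(),
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a per-tree annual latewood-density table (CSV/TSV).

    Expected columns: ``site_id, tree_id, year`` and either ``lwd_kgC_m3``
    (``units="kgC"``) or ``lwd_airdry`` in kg/m^3 (``units="airdry"``, which
    is converted with ``conversion``).  Returns a frame with a
    ``lwd_kgC_m3`` column in all cases.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"site_id", "tree_id", "year"}
    if not required.issubset(df.columns):
        raise ValueError(f"ring table must have columns {sorted(required)}; got {list(df.columns)}")
    if units == "kgC":
        if "lwd_kgC_m3" not in df.columns:
            raise ValueError("units='kgC' requires a lwd_kgC_m3 column")
    elif units == "airdry":
        if "lwd_airdry" not in df.columns:
            raise ValueError("units='airdry' requires a lwd_airdry column")
        df = df.assign(lwd_kgC_m3=convert_density(df["lwd_airdry"].to_numpy(float), conversion))
    else:
        raise ValueError(f"units must be 'kgC' or 'airdry', got {units!r}")
    return df


def read_climate_table(path, sep: str | None = None) -> dict[str, ClimateSeries]:
    """Read a monthly climate CSV (site_id, year, month, tmean_C) into series per site."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"site_id", "year", "month", "tmean_C"}
    if not required.issubset(df.columns):
        raise ValueError(f"climate table must have columns {sorted(required)}; got {list(df.columns)}")
    return {site: ClimateSeries.from_frame(g) for site, g in df.groupby("site_id")}


def read_rwl(path, site_id: str, scale: float, stop_values=(999, -9999)) -> pd.DataFrame:
    """Parse a Tucson decadal-format ring file into a tidy per-tree table.

    Each line carries a series (tree) identifier, the decade's first year,
    and up to ten values; a stop marker (999 or -9999 by convention) ends a
    series.  ``scale`` converts raw integers to kg/m^3 air-dry density --
    the format itself is unit-less, so it must be supplied explicitly.
    Returns columns ``site_id, tree_id, year, lwd_airdry``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive (units flag is required for .rwl input)")
    rows = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        series_id = raw[:8].strip()
        fields = raw[8:].split()
        if not series_id or len(fields) < 2:
            continue
        try:
            decade_year = int(fields[0])
            values = [int(v) for v in fields[1:]]
        except ValueError:
            continue
        for k, v in enumerate(values):
            if v in stop_values:
                break
            rows.append(
                {"site_id": site_id, "tree_id": series_id, "year": decade_year + k, "lwd_airdry": v * scale}
            )
    if not rows:
        raise ValueError(f"no measurement rows parsed from {path}")
    return pd.DataFrame(rows)


def fit_report_to_json(report: Mapping, path=None) -> str:
    """Serialise a fit-pipeline report (responses, bins, diagnostics) to JSON."""
    binned: BinnedMeans = report["binned"]
    payload = {
        "window": list(report["window"]),
        "window_r_squared": report.get("window_r_squared"),
        "best": report["best"].to_dict(),
        "range": report["range"].to_dict(),
        "binned": {
            "bin_centers": [float(x) for x in binned.bin_centers],
            "mean_lwd": [float(x) for x in binned.mean_lwd],
            "n_per_bin": [int(x) for x in binned.n_per_bin],
            "bin_width": binned.bin_width,
        },
        "diagnostics": report.get("diagnostics"),
        "n_pairs": report.get("n_pairs"),
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def fit_report_from_json(source) -> dict:
    """Inverse of :func:`fit_report_to_json` (accepts a path or a JSON string)."""
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    payload = json.loads(text)
    import numpy as np

    binned = BinnedMeans(
        bin_centers=np.asarray(payload["binned"]["bin_centers"], float),
        mean_lwd=np.asarray(payload["binned"]["mean_lwd"], float),
        n_per_bin=np.asarray(payload["binned"]["n_per_bin"], int),
        bin_width=float(payload["binned"]["bin_width"]),
    )
    return {
        "window": tuple(payload["window"]),
        "window_r_squared": payload.get("window_r_squared"),
        "best": DensityResponse.from_dict(payload["best"]),
        "range": DensityResponse.from_dict(payload["range"]),
        "binned": binned,
        "diagnostics": payload.get("diagnostics"),
        "n_pairs": payload.get("n_pairs"),
    }


def write_manifest(path, seed: int, config_summary: Mapping, extra: Mapping | None = None) -> None:
    """Write a JSON manifest of configuration, seeds and package version."""
    from . import __version__

    payload = {"package": "ringdemog", "version": __version__, "seed": seed, "config": dict(config_summary)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
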