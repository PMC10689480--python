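"""Climate covariates along elevation gradients.

Covariates are summarized in 100 m elevation bands: for each band the mean
diurnal temperature range (DTR, bio2), temperature seasonality (TS, bio4),
mean annual temperature (MAT, bio1) and annual precipitation (AP, bio12)
over the pixels whose elevation falls in the band.  Band intervals are
half-open ``[lower, upper)`` and anchored at 0 m a.s.l., so a pixel at
exactly 1300 m belongs to the band [1300, 1400).

Long-term temperature variability is a single number per mountain:
``delta_mat``, the max minus min of a series of 30-year mean annual
temperatures spanning 0-1980 AD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: climate variables carried through every band table
CLIMATE_VARS = ("dtr", "ts", "mat", "ap")

#: required columns of a band-climate table
BAND_COLUMNS = ("mountain_id", "band_lower", "band_upper", *CLIMATE_VARS)

DEFAULT_BAND_WIDTH = 100.0


def validate_band_table(bands: pd.DataFrame, band_width: float = DEFAULT_BAND_WIDTH) -> None:
    """Check the band-table schema and interval invariants.

    Bands must be 100 m wide (``band_upper - band_lower == band_width``),
    sorted, and non-overlapping within each mountain.
    """
    missing = [c for c in BAND_COLUMNS if c not in bands.columns]
    if missing:
        raise ValueError(f"band table missing columns: {missing}")
    widths = bands["band_upper"].to_numpy() - bands["band_lower"].to_numpy()
    if not np.allclose(widths, band_width):
        raise ValueError(f"all bands must be {band_width} m wide")
    for mid, grp in bands.groupby("mountain_id"):
        lower = grp["band_lower"].to_numpy()
        if not np.all(np.diff(lower) > 0):
            raise ValueError(f"bands of mountain {mid!r} not sorted/unique")


@dataclass
class PaleoSeries:
    """Per-mountain series of 30-year-mean MAT values, 0-1980 AD."""

    mountain_id: str
    years: np.ndarray  # AD timestamps, strictly increasing
    values: np.ndarray  # deg C, one per timestamp

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("paleo series needs at least 2 values")
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have equal length")
        if not np.all(np.diff(self.years) > 0):
            raise ValueError("timestamps must be strictly increasing")


def zonal_band_means(
    dem_grid: np.ndarray,
    climate_grid: np.ndarray,
    band_width: float = DEFAULT_BAND_WIDTH,
) -> pd.DataFrame:
    """Mean climate value per elevation band (zonal statistics).

    Each pixel is assigned to the band ``[k*w, (k+1)*w)`` containing its DEM
    value; the band mean is the unweighted mean of the climate pixels in the
    band.  Bands with no pixels are omitted.

    Returns a frame with columns ``band_lower``, ``band_upper``, ``mean``,
    ``n_pixels``, sorted by band.
    """
    dem = np.asarray(dem_grid, dtype=float)
    clim = np.asarray(climate_grid, dtype=float)
    if dem.shape != clim.shape:
        raise ValueError(f"shape mismatch: dem {dem.shape} vs climate {clim.shape}")
    if not np.all(np.isfinite(dem)):
        raise ValueError("DEM contains non-finite values")
    band_idx = np.floor(dem.ravel() / band_width).astype(int)
    df = pd.DataFrame({"band": band_idx, "value": clim.ravel()})
    agg = df.groupby("band")["value"].agg(["mean", "count"]).reset_index()
    out = pd.DataFrame(
        {
            "band_lower": agg["band"] * band_width,
            "band_upper": (agg["band"] + 1) * band_width,
            "mean": agg["mean"],
            "n_pixels": agg["count"],
        }
    )
    return out.sort_values("band_lower", ignore_index=True)


def mountain_mean_climate(
    bands: pd.DataFrame,
    domain_min: float,
    domain_max: float,
    weighted: bool = False,
) -> dict[str, float]:
    """Mountain-level covariates: mean over bands inside a domain.

    Only bands whose interval lies entirely within ``[domain_min,
    domain_max]`` contribute.  By default each band counts once (unweighted
    band means); with ``weighted=True`` bands are weighted by an
    ``n_pixels`` column if present.
    """
    inside = (bands["band_lower"] >= domain_min) & (bands["band_upper"] <= domain_max)
    sub = bands.loc[inside]
    if sub.empty:
        raise ValueError(
            f"no elevation band lies within domain [{domain_min}, {domain_max}]"
        )
    if weighted and "n_pixels" in sub.columns:
        w = sub["n_pixels"].to_numpy(dtype=float)
    else:
        w = np.ones(len(sub))
    return {
        var: float(np.average(sub[var].to_numpy(dtype=float), weights=w))
        for var in CLIMATE_VARS
        if var in sub.columns
    }


def delta_mat(series: PaleoSeries) -> float:
    """Long-term temperature variability: max - min of the paleo series."""
    return float(np.max(series.values) - np.min(series.values))


def assign_midpoint_climate(
    min_elev: float,
    max_elev: float,
    bands: pd.DataFrame,
    variables: tuple[str, ...] = ("dtr", "ts"),
) -> dict[str, float]:
    """Climate of the band containing a species' range midpoint.

    The midpoint is ``(min_elev + max_elev) / 2``; the matching band is the
    one whose half-open interval ``[lower, upper)`` contains it.
    """
    midpoint = (float(min_elev) + float(max_elev)) / 2.0
    hit = bands.loc[
        (bands["band_lower"] <= midpoint) & (midpoint < bands["band_upper"])
    ]
    if hit.empty:
        raise ValueError(f"midpoint {midpoint} m falls outside all elevation bands")
    row = hit.iloc[0]
    return {var: float(row[var]) for var in variables}


def assign_midpoint_climate_table(
    records: pd.DataFrame,
    bands: pd.DataFrame,
    variables: tuple[str, ...] = ("dtr", "ts"),
) -> pd.DataFrame:
    """Vectorized midpoint-climate assignment for one mountain's records."""
    out = records.copy()
    mids = (out["min_elev"].to_numpy(float) + out["max_elev"].to_numpy(float)) / 2.0
    b = bands.sort_values("band_lower")
    lowers = b["band_lower"].to_numpy(float)
    uppers = b["band_upper"].to_numpy(float)
    idx = np.searchsorted(lowers, mids, side="right") - 1
    bad = (idx < 0) | (mids >= uppers[np.clip(idx, 0, len(b) - 1)])
    if np.any(bad):
        culprit = out.iloc[int(np.flatnonzero(bad)[0])]
        raise ValueError(
            f"midpoint of species {culprit['species_id']!r} outside all bands"
        )
    for var in variables:
        out[var] = b[var].to_numpy(float)[idx]
    return out
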