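"""Data hygiene and gradient standardization for elevation range tables.

A dataset is a table with one row per species x mountain carrying that
species' minimum and maximum recorded elevation.  The range size is simply
``max_elev - min_elev`` (0 m for singletons, species with one observation).

Cleaning and standardization follow a fixed order:

1. ``validate_records`` drops rows with min > max, elevations above 6500 m
   (the highest elevation recorded for vascular plants) or non-finite
   values.
2. ``filter_mountains`` drops whole mountains with poor sampling: more than
   25% singletons, or a sampling gap of more than 500 m between covered
   elevation sections.
3. ``standardize_gradient`` trims every gradient to a common length
   (anchored at the mountain top by default), truncating ranges that cross
   the new boundary and discarding species entirely outside it.
4. ``apply_exclusion_zones`` removes species found exclusively within E
   meters of the domain ends, where truncation artifacts concentrate.
5. ``transform_range_sizes`` floors singletons at 10 m and takes natural
   logs, the response used by the hierarchical models.

The ``PipelineState`` guard enforces this ordering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: required columns of a species range table
RECORD_COLUMNS = ("species_id", "mountain_id", "min_elev", "max_elev")

#: elevation ceiling for vascular plants, m a.s.l.
MAX_PLANT_ELEVATION = 6500.0

#: minimum elevation span of an included mountain, m
MIN_GRADIENT_SPAN = 1500.0

#: range size assigned to singletons before the log transform, m
SINGLETON_FLOOR = 10.0

DEFAULT_GAP_THRESHOLD = 500.0
DEFAULT_MAX_SINGLETON_FRACTION = 0.25


@dataclass
class MountainGradient:
    """A mountain's elevation domain, land type and band climate table."""

    mountain_id: str
    land_type: str  # "island" or "continental"
    domain_min: float
    domain_max: float
    band_climate: pd.DataFrame | None = None
    paleo: "object | None" = None  # PaleoSeries, attached by the pipeline

    def __post_init__(self) -> None:
        if self.land_type not in ("island", "continental"):
            raise ValueError(f"land_type must be island/continental, got {self.land_type!r}")
        if self.domain_max - self.domain_min < MIN_GRADIENT_SPAN:
            raise ValueError(
                f"mountain {self.mountain_id!r}: span "
                f"{self.domain_max - self.domain_min:.0f} m < {MIN_GRADIENT_SPAN:.0f} m"
            )

    @property
    def span(self) -> float:
        return self.domain_max - self.domain_min


@dataclass(frozen=True)
class StandardizationConfig:
    """Gradient standardization: common length, exclusion zones, anchoring.

    ``length`` is the standardized gradient length in meters, ``exclusion_zone``
    the width E of the no-keep band at each domain end, and ``anchor`` whether
    the retained window hugs the mountain top or bottom.
    """

    length: float = 2500.0
    exclusion_zone: float = 250.0
    anchor: str = "top"

    def __post_init__(self) -> None:
        if self.anchor not in ("top", "bottom"):
            raise ValueError(f"anchor must be 'top' or 'bottom', got {self.anchor!r}")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.exclusion_zone < 0:
            raise ValueError("exclusion_zone must be >= 0")
        if 2 * self.exclusion_zone >= self.length:
            raise ValueError("exclusion zones may not cover the whole gradient")


class PipelineState(enum.IntEnum):
    """Stage ordering guard: each stage requires the previous one."""

    RAW = 0
    VALIDATED = 1
    FILTERED = 2
    STANDARDIZED = 3
    EXCLUDED = 4
    TRANSFORMED = 5


def _require_state(records: pd.DataFrame, minimum: PipelineState, stage: str) -> None:
    state = records.attrs.get("pipeline_state", PipelineState.RAW)
    if state < minimum:
        raise RuntimeError(
            f"{stage} requires stage >= {minimum.name}, got {PipelineState(state).name}; "
            "run the pipeline stages in order"
        )


def _with_state(records: pd.DataFrame, state: PipelineState) -> pd.DataFrame:
    records.attrs["pipeline_state"] = state
    return records


def compute_range_size(record) -> float | pd.Series:
    """Elevation range size: max minus min elevation, in meters.

    Accepts a single record (mapping or Series) or a whole table, in which
    case a Series is returned.
    """
    if isinstance(record, pd.DataFrame):
        return record["max_elev"] - record["min_elev"]
    size = float(record["max_elev"]) - float(record["min_elev"])
    if size < 0:
        raise ValueError("min_elev > max_elev; validate records first")
    return size


def validate_records(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop invalid rows, returning (kept, rejection log).

    Rejection reasons: ``min_gt_max`` (inverted elevations), ``above_6500``
    (above the vascular-plant ceiling), ``non_finite``.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"range table missing columns: {missing}")
    lo = records["min_elev"].to_numpy(dtype=float)
    hi = records["max_elev"].to_numpy(dtype=float)
    non_finite = ~(np.isfinite(lo) & np.isfinite(hi))
    above = (~non_finite) & ((hi > MAX_PLANT_ELEVATION) | (lo > MAX_PLANT_ELEVATION))
    inverted = (~non_finite) & (~above) & (lo > hi)
    reason = np.full(len(records), "", dtype=object)
    reason[non_finite] = "non_finite"
    reason[above] = "above_6500"
    reason[inverted] = "min_gt_max"
    bad = reason != ""
    log = records.loc[bad, list(RECORD_COLUMNS)].copy()
    log["reason"] = reason[bad]
    kept = records.loc[~bad].reset_index(drop=True)
    return _with_state(kept, PipelineState.VALIDATED), log.reset_index(drop=True)


def singleton_fraction(records: pd.DataFrame) -> float:
    """Fraction of species with a zero-width elevation range."""
    if len(records) == 0:
        raise ValueError("cannot compute singleton fraction of an empty table")
    sizes = compute_range_size(records)
    return float((sizes == 0).mean())


def detect_sampling_gaps(
    records: pd.DataFrame, gap_threshold: float = DEFAULT_GAP_THRESHOLD
) -> list[tuple[float, float]]:
    """Elevation gaps wider than the threshold between sampled sections.

    Sampled sections are the union of the species' elevation intervals
    (singletons contribute points).  Returned intervals are the maximal
    uncovered stretches strictly between sections, each wider than
    ``gap_threshold``; an empty list means continuous sampling.
    """
    if len(records) == 0:
        raise ValueError("cannot detect gaps in an empty table")
    ivals = records[["min_elev", "max_elev"]].to_numpy(dtype=float)
    order = np.argsort(ivals[:, 0])
    gaps: list[tuple[float, float]] = []
    cur_lo, cur_hi = ivals[order[0]]
    for lo, hi in ivals[order[1:]]:
        if lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            if lo - cur_hi > gap_threshold:
                gaps.append((float(cur_hi), float(lo)))
            cur_lo, cur_hi = lo, hi
    return gaps


def filter_mountains(
    records: pd.DataFrame,
    max_singleton_fraction: float = DEFAULT_MAX_SINGLETON_FRACTION,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop mountains failing the singleton or sampling-continuity rule.

    A mountain is kept iff its singleton fraction is <= the threshold
    (inclusive at exactly 25%) AND it has no sampling gap wider than the
    gap threshold.  Returns (kept records, exclusion log with one row per
    dropped mountain and the rule it failed).
    """
    _require_state(records, PipelineState.VALIDATED, "filter_mountains")
    rows = []
    keep_ids = []
    for mid, grp in records.groupby("mountain_id", sort=True):
        frac = singleton_fraction(grp)
        gaps = detect_sampling_gaps(grp, gap_threshold)
        reasons = []
        if frac > max_singleton_fraction:
            reasons.append("singleton_fraction")
        if gaps:
            reasons.append("sampling_gap")
        if reasons:
            rows.append(
                {
                    "mountain_id": mid,
                    "reason": "+".join(reasons),
                    "singleton_fraction": frac,
                    "n_gaps": len(gaps),
                }
            )
        else:
            keep_ids.append(mid)
    kept = records[records["mountain_id"].isin(keep_ids)].reset_index(drop=True)
    log = pd.DataFrame(rows, columns=["mountain_id", "reason", "singleton_fraction", "n_gaps"])
    return _with_state(kept, PipelineState.FILTERED), log


def standardize_gradient(
    records: pd.DataFrame,
    gradient: MountainGradient,
    config: StandardizationConfig,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Trim one mountain's gradient to the standardized length.

    With ``anchor='top'`` the new domain is
    ``[domain_max - length, domain_max]``; with ``anchor='bottom'`` it is
    ``[domain_min, domain_min + length]``.  Species ranges crossing the new
    boundary are truncated to it (zero-width leftovers are kept and treated
    as singletons downstream); species entirely outside are dropped.
    Raises ``GradientTooShortError`` when the mountain's span is below the
    requested length.
    """
    _require_state(records, PipelineState.FILTERED, "standardize_gradient")
    if gradient.span < config.length:
        raise GradientTooShortError(
            f"mountain {gradient.mountain_id!r}: span {gradient.span:.0f} m "
            f"< standardized length {config.length:.0f} m"
        )
    if config.anchor == "top":
        new_min, new_max = gradient.domain_max - config.length, gradient.domain_max
    else:
        new_min, new_max = gradient.domain_min, gradient.domain_min + config.length
    out = records.copy()
    inside = (out["max_elev"] >= new_min) & (out["min_elev"] <= new_max)
    out = out.loc[inside].copy()
    out["min_elev"] = out["min_elev"].clip(lower=new_min, upper=new_max)
    out["max_elev"] = out["max_elev"].clip(lower=new_min, upper=new_max)
    out = out.reset_index(drop=True)
    return _with_state(out, PipelineState.STANDARDIZED), (float(new_min), float(new_max))


class GradientTooShortError(ValueError):
    """Raised when a mountain's span is below the standardized length."""


def apply_exclusion_zones(
    records: pd.DataFrame,
    domain_min: float,
    domain_max: float,
    exclusion_zone: float,
) -> pd.DataFrame:
    """Drop species confined to the top or bottom E meters of the domain.

    A species is removed iff its whole range lies within
    ``[domain_min, domain_min + E]`` or ``[domain_max - E, domain_max]``
    (closed intervals: a range exactly touching the zone's inner edge is
    kept).  ``E = 0`` is the identity.
    """
    _require_state(records, PipelineState.STANDARDIZED, "apply_exclusion_zones")
    if 2 * exclusion_zone >= domain_max - domain_min:
        raise ValueError("exclusion zones cover the whole domain")
    out = records.copy()
    if exclusion_zone > 0:
        in_bottom = (out["min_elev"] >= domain_min) & (
            out["max_elev"] < domain_min + exclusion_zone
        )
        in_top = (out["min_elev"] > domain_max - exclusion_zone) & (
            out["max_elev"] <= domain_max
        )
        out = out.loc[~(in_bottom | in_top)].reset_index(drop=True)
    return _with_state(out, PipelineState.EXCLUDED)


def transform_range_sizes(range_sizes) -> np.ndarray:
    """Natural-log range sizes with the 10 m singleton floor.

    Zero-width ranges are set to 10 m -- the smallest positive elevation
    range observable at 10 m recording precision -- before taking logs, so
    the output is always finite.
    """
    sizes = np.asarray(range_sizes, dtype=float)
    if np.any(sizes < 0):
        raise ValueError("range sizes must be non-negative")
    floored = np.where(sizes < SINGLETON_FLOOR, SINGLETON_FLOOR, sizes)
    return np.log(floored)


def transform_records(records: pd.DataFrame) -> pd.DataFrame:
    """Append ``range_size`` (m) and ``log_range`` columns to excluded records."""
    _require_state(records, PipelineState.EXCLUDED, "transform_records")
    out = records.copy()
    out["range_size"] = compute_range_size(out)
    out["log_range"] = transform_range_sizes(out["range_size"].to_numpy())
    return _with_state(out, PipelineState.TRANSFORMED)
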