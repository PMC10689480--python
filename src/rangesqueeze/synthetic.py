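"""Synthetic mountains, climates and species elevation ranges.

The generator emulates the statistical structure the hierarchical models
assume: every mountain has a mean log range size that responds linearly to
a mountain-level climate covariate, species' log ranges scatter normally
around that mean, and island mountains have systematically lower diurnal
temperature range (DTR) than continental ones.  It exists so that the whole
pipeline -- cleaning, standardization, covariates, model fits, model
comparison -- can be exercised and validated with no external data.

Defaults mirror the study system: 44 mountains (15 of them islands),
gradient spans of 1500-6000 m, roughly 2000 species ranges per mountain,
and a moderate singleton fraction.

Also provided: the conceptual suitable-habitat "squeeze" calculator.  Under
a constant lapse rate, a species tolerating temperatures in
``[t_lower, t_upper]`` can persist only over the elevation span where
neither limit is exceeded; a diurnal/seasonal temperature oscillation of
amplitude ``delta_T`` shaves that span symmetrically:

    span = max(0, t_upper - t_lower - delta_T) / lapse_rate * 100  [m]

so the suitable span shrinks linearly as thermal variability grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import CLIMATE_VARS, DEFAULT_BAND_WIDTH, PaleoSeries
from .preprocessing import MIN_GRADIENT_SPAN, MountainGradient

DEFAULT_LAPSE_RATE = 0.5  # deg C per 100 m


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Parameters of a synthetic world of mountains and species."""

    n_mountains: int = 44
    island_fraction: float = 15 / 44
    span_range: tuple[float, float] = (1500.0, 6000.0)
    dtr_island: tuple[float, float] = (8.0, 1.5)  # (mean, sd) deg C
    dtr_continental: tuple[float, float] = (13.0, 2.0)
    ts_range: tuple[float, float] = (1.0, 9.0)  # deg C
    lapse_rate: float = DEFAULT_LAPSE_RATE  # deg C per 100 m
    base_mat_range: tuple[float, float] = (10.0, 28.0)  # sea-level MAT deg C
    ap_range: tuple[float, float] = (300.0, 4000.0)  # mm
    n_species_per_mountain: int | tuple[int, int] = 2000
    singleton_fraction: float = 0.15
    dmat_range: tuple[float, float] = (0.5, 2.5)  # deg C, paleo amplitude
    paleo_points: int = 67  # 30-yr steps covering 0-1980 AD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mountains < 0:
            raise ValueError("n_mountains must be >= 0")
        if not 0.0 <= self.island_fraction <= 1.0:
            raise ValueError("island_fraction must be in [0, 1]")
        if self.span_range[0] < MIN_GRADIENT_SPAN:
            raise ValueError(
                f"span_range minimum must be >= {MIN_GRADIENT_SPAN:.0f} m"
            )
        if self.span_range[0] > self.span_range[1]:
            raise ValueError("span_range must be (min, max) with min <= max")
        for name in ("dtr_island", "dtr_continental"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} sd must be > 0")
        if self.lapse_rate <= 0:
            raise ValueError("lapse_rate must be > 0")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValueError("singleton_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameters of the hierarchical range-size model.

    Global model: mountain mean log range is ``alpha_V + beta_V * V_site``
    plus Normal(0, sigma2_site) scatter; species log ranges scatter around
    the mountain mean with variance sigma2_RS.  Optional per-mountain
    intercepts/slopes drive the within-mountain (local) generative model.
    """

    alpha_V: float = 7.5  # log-m at V = 0
    beta_V: float = -0.1  # log-m per covariate unit
    sigma2_site: float = 0.09  # between-mountain variance
    sigma2_RS: float = 0.64  # within-mountain variance
    local_alphas: np.ndarray | None = None
    local_betas: np.ndarray | None = None
    sigma2_local: float = 0.64

    def __post_init__(self) -> None:
        for name in ("sigma2_site", "sigma2_RS", "sigma2_local"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _snap(x: np.ndarray, step: float = DEFAULT_BAND_WIDTH) -> np.ndarray:
    return np.round(x / step) * step


def generate_mountains(config: SyntheticWorldConfig) -> list[MountainGradient]:
    """Draw a set of mountains with contiguous 100 m band climate tables.

    Within each mountain, MAT decreases with band elevation at the
    configured lapse rate; DTR is drawn from the island or continental
    distribution (plus mild band-level variation), TS and AP from their
    configured ranges.  Pure function of (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    mountains: list[MountainGradient] = []
    n_island = int(round(config.n_mountains * config.island_fraction))
    is_island = np.zeros(config.n_mountains, dtype=bool)
    is_island[:n_island] = True
    rng.shuffle(is_island)
    for i in range(config.n_mountains):
        span = _snap(rng.uniform(*config.span_range))
        span = max(span, MIN_GRADIENT_SPAN)
        dmin = _snap(rng.uniform(0.0, 500.0))
        dmax = dmin + span
        land = "island" if is_island[i] else "continental"
        mu_dtr, sd_dtr = config.dtr_island if is_island[i] else config.dtr_continental
        dtr_m = rng.normal(mu_dtr, sd_dtr)
        ts_m = rng.uniform(*config.ts_range)
        ap_m = rng.uniform(*config.ap_range)
        base_mat = rng.uniform(*config.base_mat_range)
        lowers = np.arange(dmin, dmax, DEFAULT_BAND_WIDTH)
        mids = lowers + DEFAULT_BAND_WIDTH / 2
        bands = pd.DataFrame(
            {
                "mountain_id": f"M{i:03d}",
                "band_lower": lowers,
                "band_upper": lowers + DEFAULT_BAND_WIDTH,
                "dtr": dtr_m + rng.normal(0.0, 0.2, size=len(lowers)),
                "ts": ts_m + rng.normal(0.0, 0.1, size=len(lowers)),
                "mat": base_mat - config.lapse_rate * mids / DEFAULT_BAND_WIDTH,
                "ap": np.clip(ap_m + rng.normal(0.0, 50.0, size=len(lowers)), 0, None),
            }
        )
        mountains.append(
            MountainGradient(
                mountain_id=f"M{i:03d}",
                land_type=land,
                domain_min=float(dmin),
                domain_max=float(dmax),
                band_climate=bands,
            )
        )
    return mountains


def generate_species_ranges(
    mountains: list[MountainGradient],
    true_params: TrueParameters,
    config: SyntheticWorldConfig,
    covariate: str = "dtr",
) -> pd.DataFrame:
    """Draw species elevation ranges around covariate-driven mountain means.

    For each mountain, the mean log range is ``alpha_V + beta_V * V_site``
    (V_site = mountain-mean covariate over its bands) plus
    Normal(0, sigma2_site) noise; species log ranges are Normal around it
    with variance sigma2_RS, back-transformed to meters, placed uniformly
    at random within the gradient (uniform midpoint) and clipped to the
    domain.  A configured fraction of species is collapsed to singletons
    (min = max, at the range midpoint).
    """
    if covariate not in CLIMATE_VARS:
        raise ValueError(f"unknown covariate {covariate!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    frames = []
    for m in mountains:
        v_site = float(m.band_climate[covariate].mean())
        mu_site = true_params.alpha_V + true_params.beta_V * v_site
        alpha_site = rng.normal(mu_site, np.sqrt(true_params.sigma2_site))
        n = config.n_species_per_mountain
        if isinstance(n, tuple):
            n = int(rng.integers(n[0], n[1] + 1))
        log_ranges = rng.normal(alpha_site, np.sqrt(true_params.sigma2_RS), size=n)
        widths = np.exp(log_ranges)
        mids = rng.uniform(m.domain_min, m.domain_max, size=n)
        lo = np.clip(mids - widths / 2, m.domain_min, m.domain_max)
        hi = np.clip(mids + widths / 2, m.domain_min, m.domain_max)
        single = rng.random(n) < config.singleton_fraction
        point = (lo + hi) / 2
        lo = np.where(single, point, lo)
        hi = np.where(single, point, hi)
        frames.append(
            pd.DataFrame(
                {
                    "species_id": [f"{m.mountain_id}_sp{j:05d}" for j in range(n)],
                    "mountain_id": m.mountain_id,
                    "min_elev": lo,
                    "max_elev": hi,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["species_id", "mountain_id", "min_elev", "max_elev"])
    return pd.concat(frames, ignore_index=True)


def simulate_global_dataset(
    v_site: np.ndarray,
    true_params: TrueParameters,
    n_species_per_site: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact generative draw of the global hierarchical model.

    Returns ``(y, site_index, alpha_site)`` with
    ``alpha_site ~ N(alpha_V + beta_V * V, sigma2_site)`` and
    ``y ~ N(alpha_site[site], sigma2_RS)``.  Used for parameter-recovery
    and calibration checks where the model must hold exactly (no placement
    or clipping effects).
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(v_site, dtype=float)
    mu = true_params.alpha_V + true_params.beta_V * v
    alpha_site = rng.normal(mu, np.sqrt(true_params.sigma2_site))
    site_index = np.repeat(np.arange(v.size), n_species_per_site)
    y = rng.normal(alpha_site[site_index], np.sqrt(true_params.sigma2_RS))
    return y, site_index, alpha_site


def generate_world(
    config: SyntheticWorldConfig,
    true_params: TrueParameters,
    covariate: str = "dtr",
) -> tuple[list[MountainGradient], pd.DataFrame]:
    """Full synthetic world: mountains (with paleo series) plus species.

    Convenience wrapper over ``generate_mountains``,
    ``generate_paleo_series`` (one per mountain, amplitude drawn from
    ``config.dmat_range``) and ``generate_species_ranges`` driven by the
    named covariate.
    """
    mountains = generate_mountains(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    for m in mountains:
        amp = float(rng.uniform(*config.dmat_range))
        mean_mat = float(m.band_climate["mat"].mean())
        m.paleo = generate_paleo_series(
            config.paleo_points,
            mean=mean_mat,
            amplitude=amp,
            seed=int(rng.integers(0, 2**31 - 1)),
            mountain_id=m.mountain_id,
        )
    records = generate_species_ranges(mountains, true_params, config, covariate)
    return mountains, records


def generate_paleo_series(
    n_points: int,
    mean: float,
    amplitude: float,
    seed: int,
    mountain_id: str = "M000",
) -> PaleoSeries:
    """Random-walk series of 30-year-mean MAT values, 0-1980 AD.

    A Gaussian random walk is rescaled so its max - min equals the
    requested amplitude exactly (only that difference matters downstream).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    years = np.arange(n_points) * 30.0
    years = years * (1980.0 / years[-1]) if years[-1] > 1980 else years
    walk = np.cumsum(rng.normal(0.0, 1.0, size=n_points))
    spread = walk.max() - walk.min()
    if amplitude == 0 or spread == 0:
        values = np.full(n_points, mean)
    else:
        centered = (walk - walk.mean()) / spread * amplitude
        values = mean + centered
    return PaleoSeries(mountain_id=mountain_id, years=years, values=values)


def suitable_habitat_span(
    t_lower: float, t_upper: float, delta_T: float, lapse_rate: float = DEFAULT_LAPSE_RATE
) -> float:
    """Elevation span (m) over which no lethal temperature is encountered.

    The "squeeze": a thermal tolerance window of width ``t_upper - t_lower``
    minus the temperature oscillation amplitude ``delta_T``, converted to
    meters through the lapse rate (deg C per 100 m).  Strictly decreasing
    in ``delta_T`` while positive, and zero once the oscillation swallows
    the tolerance window.
    """
    if lapse_rate <= 0:
        raise ValueError("lapse_rate must be > 0")
    if t_upper <= t_lower:
        raise ValueError("t_upper must exceed t_lower")
    if delta_T < 0:
        raise ValueError("delta_T must be >= 0")
    return max(0.0, t_upper - t_lower - delta_T) / lapse_rate * 100.0


def generate_raster_pair(
    shape: tuple[int, int],
    elevation_relief: float,
    climate_fn,
    seed: int,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired DEM and climate grids with a known elevation-climate link.

    The DEM is uniform noise over ``[0, elevation_relief]``; the climate
    grid is ``climate_fn(elevation)`` per pixel plus optional Gaussian
    noise, so band means have a closed form.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("shape must be positive in both dimensions")
    rng = np.random.default_rng(seed)
    dem = rng.uniform(0.0, elevation_relief, size=shape)
    clim = np.asarray(climate_fn(dem), dtype=float)
    if clim.shape != dem.shape:
        clim = np.broadcast_to(clim, dem.shape).copy()
    if noise_sd > 0:
        clim = clim + rng.normal(0.0, noise_sd, size=shape)
    return dem, clim
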