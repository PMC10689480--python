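"""End-to-end orchestration: data -> preprocessing -> covariates -> fits.

The stage order is fixed (and enforced by the preprocessing state guard):
validate records, filter poorly sampled mountains, standardize gradients
(global analyses only), apply exclusion zones, log-transform, compute
mountain covariates, fit, evaluate.  Every run is a pure function of
(config, seed): reports embed the config hash and seed so reruns are
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate, evaluation, preprocessing, synthetic
from .climate import PaleoSeries, delta_mat, mountain_mean_climate
from .evaluation import (
    ComparisonTable,
    SlopeSummary,
    classify_local_slopes,
    diagnostics_table,
)
from .models import (
    GlobalModelData,
    LocalModelData,
    MCMCConfig,
    PosteriorDraws,
    fit_global,
    fit_local,
)
from .preprocessing import (
    GradientTooShortError,
    MountainGradient,
    StandardizationConfig,
)
from .synthetic import SyntheticWorldConfig, TrueParameters

log = logging.getLogger("rangesqueeze")

GLOBAL_COVARIATES = ("dtr", "ts", "dmat")
LOCAL_COVARIATES = ("dtr", "ts")

#: sensitivity grid of the global analyses
GRID_LENGTHS = (1500.0, 2000.0, 2500.0)
GRID_EXCLUSIONS = (0.0, 250.0, 500.0)
GRID_ANCHORS = ("top", "bottom")


@dataclass
class RunConfig:
    """One analysis run: data source, preprocessing rules, MCMC settings.

    Defaults mirror the headline analysis: 2500 m standardized gradients
    anchored at the top, 250 m exclusion zones, 3 chains of 50,000
    iterations with 20,000 burn-in.
    """

    world: SyntheticWorldConfig | None = None
    true_params: TrueParameters = field(default_factory=TrueParameters)
    driver_covariate: str = "dtr"
    species_csv: str | Path | None = None
    mountains_csv: str | Path | None = None
    bands_csv: str | Path | None = None
    paleo_csv: str | Path | None = None
    standardization: StandardizationConfig = field(default_factory=StandardizationConfig)
    covariates: tuple[str, ...] = GLOBAL_COVARIATES
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    max_singleton_fraction: float = preprocessing.DEFAULT_MAX_SINGLETON_FRACTION
    gap_threshold: float = preprocessing.DEFAULT_GAP_THRESHOLD
    out_dir: str | Path | None = None

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def load_dataset(
    species_csv: str | Path,
    mountains_csv: str | Path,
    bands_csv: str | Path | None = None,
    paleo_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, list[MountainGradient]]:
    """Read range and mountain tables from CSV.

    Species CSV columns: species_id, mountain_id, min_elev_m, max_elev_m.
    Mountain CSV: mountain_id, land_type, domain_min_m, domain_max_m.
    Optional band CSV follows the band-table schema; optional paleo CSV has
    columns mountain_id, year, mat.
    """
    records = pd.read_csv(species_csv).rename(
        columns={"min_elev_m": "min_elev", "max_elev_m": "max_elev"}
    )
    mdf = pd.read_csv(mountains_csv)
    bands = None
    if bands_csv is not None:
        bands = pd.read_csv(bands_csv)
        climate.validate_band_table(bands)
    paleo: dict[str, PaleoSeries] = {}
    if paleo_csv is not None:
        pdf = pd.read_csv(paleo_csv)
        for mid, grp in pdf.groupby("mountain_id"):
            grp = grp.sort_values("year")
            paleo[mid] = PaleoSeries(
                mountain_id=str(mid),
                years=grp["year"].to_numpy(float),
                values=grp["mat"].to_numpy(float),
            )
    mountains = []
    for _, row in mdf.iterrows():
        mid = str(row["mountain_id"])
        mountains.append(
            MountainGradient(
                mountain_id=mid,
                land_type=str(row["land_type"]),
                domain_min=float(row["domain_min_m"]),
                domain_max=float(row["domain_max_m"]),
                band_climate=(
                    bands[bands["mountain_id"] == mid].reset_index(drop=True)
                    if bands is not None
                    else None
                ),
                paleo=paleo.get(mid),
            )
        )
    return records, mountains


def _inputs(config: RunConfig) -> tuple[pd.DataFrame, list[MountainGradient]]:
    if config.species_csv is not None:
        if config.mountains_csv is None:
            raise ValueError("mountains_csv is required with species_csv")
        return load_dataset(
            config.species_csv, config.mountains_csv, config.bands_csv, config.paleo_csv
        )
    world = config.world if config.world is not None else SyntheticWorldConfig()
    mountains, records = synthetic.generate_world(
        world, config.true_params, config.driver_covariate
    )
    return records, mountains


@dataclass
class PreparedGlobal:
    """Cleaned, standardized species table with mountain covariates."""

    records: pd.DataFrame  # with range_size, log_range, site index
    mountains: list[MountainGradient]  # retained mountains, in site order
    domains: dict[str, tuple[float, float]]  # standardized bounds
    covariates: pd.DataFrame  # one row per mountain: dtr, ts, mat, ap, dmat
    attrition: pd.DataFrame  # per-mountain exclusion log


def prepare_global(
    records: pd.DataFrame,
    mountains: list[MountainGradient],
    std: StandardizationConfig,
    max_singleton_fraction: float = preprocessing.DEFAULT_MAX_SINGLETON_FRACTION,
    gap_threshold: float = preprocessing.DEFAULT_GAP_THRESHOLD,
) -> PreparedGlobal:
    """Run the full preprocessing chain for the across-mountain analysis."""
    by_id = {m.mountain_id: m for m in mountains}
    validated, _rej = preprocessing.validate_records(records)
    filtered, filter_log = preprocessing.filter_mountains(
        validated, max_singleton_fraction, gap_threshold
    )
    attrition = [
        {"mountain_id": r["mountain_id"], "stage": "filter", "reason": r["reason"]}
        for _, r in filter_log.iterrows()
    ]
    kept_frames, kept_mountains, domains, cov_rows = [], [], {}, []
    for mid, grp in filtered.groupby("mountain_id", sort=True):
        m = by_id[mid]
        grp = grp.reset_index(drop=True)
        grp.attrs["pipeline_state"] = preprocessing.PipelineState.FILTERED
        try:
            std_recs, (lo, hi) = preprocessing.standardize_gradient(grp, m, std)
        except GradientTooShortError as e:
            log.debug("dropping %s: %s", mid, e)
            attrition.append(
                {"mountain_id": mid, "stage": "standardize", "reason": "span_lt_length"}
            )
            continue
        excl = preprocessing.apply_exclusion_zones(std_recs, lo, hi, std.exclusion_zone)
        if len(excl) == 0:
            attrition.append(
                {"mountain_id": mid, "stage": "exclusion", "reason": "no_species_left"}
            )
            continue
        done = preprocessing.transform_records(excl)
        cov = mountain_mean_climate(m.band_climate, lo, hi)
        if m.paleo is not None:
            cov["dmat"] = delta_mat(m.paleo)
        cov["mountain_id"] = mid
        cov["land_type"] = m.land_type
        cov_rows.append(cov)
        kept_frames.append(done)
        kept_mountains.append(m)
        domains[mid] = (lo, hi)
    if not kept_frames:
        raise ValueError("no mountains survive preprocessing")
    out = pd.concat(kept_frames, ignore_index=True)
    site_ids = [m.mountain_id for m in kept_mountains]
    out["site"] = out["mountain_id"].map({mid: i for i, mid in enumerate(site_ids)})
    covs = pd.DataFrame(cov_rows).set_index("mountain_id").loc[site_ids].reset_index()
    return PreparedGlobal(
        records=out,
        mountains=kept_mountains,
        domains=domains,
        covariates=covs,
        attrition=pd.DataFrame(attrition, columns=["mountain_id", "stage", "reason"]),
    )


def global_model_data(prep: PreparedGlobal, covariate: str) -> GlobalModelData:
    """Assemble the global model's response and site-level design."""
    if covariate not in prep.covariates.columns:
        raise ValueError(f"covariate {covariate!r} not available")
    v = prep.covariates[covariate].to_numpy(float)
    return GlobalModelData.from_covariates(
        y=prep.records["log_range"].to_numpy(),
        site_index=prep.records["site"].to_numpy(int),
        v_site=v,
        covariate_name=covariate,
        site_ids=[m.mountain_id for m in prep.mountains],
    )


def run_global_analysis(config: RunConfig) -> dict:
    """Across-mountain analysis: one global fit per requested covariate.

    Returns a bundle with the prepared data, fits, WAIC/LOO comparison
    table, slope summaries (with P(beta<0) and site-level R2), the
    site-mean table (posterior mean and SD of every mountain's mean log
    range) and per-mountain attrition.
    """
    records, mountains = _inputs(config)
    prep = prepare_global(
        records,
        mountains,
        config.standardization,
        config.max_singleton_fraction,
        config.gap_threshold,
    )
    fits: dict[str, PosteriorDraws] = {}
    slopes: dict[str, SlopeSummary] = {}
    for cov in config.covariates:
        log.info("fitting global model: %s", cov)
        data = global_model_data(prep, cov)
        fit = fit_global(data, config.mcmc)
        fits[cov] = fit
        slopes[cov] = SlopeSummary.from_fit(fit, f"beta_{cov}", X=data.X)
    comparison = ComparisonTable.from_fits(fits)
    first = fits[config.covariates[0]]
    alpha = first.stacked("alpha_site")
    site_table = pd.DataFrame(
        {
            "mountain_id": [m.mountain_id for m in prep.mountains],
            "land_type": [m.land_type for m in prep.mountains],
            "mean_log_range": alpha.mean(axis=0),
            "sd_log_range": alpha.std(axis=0, ddof=1),
        }
    )
    bundle = {
        "prep": prep,
        "fits": fits,
        "slopes": slopes,
        "comparison": comparison,
        "site_table": site_table,
        "diagnostics": {c: diagnostics_table(f) for c, f in fits.items()},
        "config_hash": config.config_hash(),
        "seed": config.mcmc.seed,
        "n_mountains": len(prep.mountains),
    }
    if config.out_dir is not None:
        _write_global_bundle(bundle, Path(config.out_dir), config)
    return bundle


def prepare_local(
    records: pd.DataFrame,
    mountains: list[MountainGradient],
    exclusion_zone: float,
    covariate: str,
    max_singleton_fraction: float = preprocessing.DEFAULT_MAX_SINGLETON_FRACTION,
    gap_threshold: float = preprocessing.DEFAULT_GAP_THRESHOLD,
) -> tuple[LocalModelData, list[str]]:
    """Preprocessing for the within-mountain analysis.

    Gradients are NOT standardized (each mountain is modelled on its own
    scale); exclusion zones apply on the original domains.  The covariate
    is assigned at each species' range midpoint.
    """
    if covariate not in LOCAL_COVARIATES:
        raise ValueError(
            f"covariate {covariate!r} is not testable at the local scale; "
            "the past-climate data underlying dmat is too coarse to resolve "
            "within-mountain elevation variation"
        )
    by_id = {m.mountain_id: m for m in mountains}
    validated, _ = preprocessing.validate_records(records)
    filtered, _ = preprocessing.filter_mountains(
        validated, max_singleton_fraction, gap_threshold
    )
    frames = []
    for mid, grp in filtered.groupby("mountain_id", sort=True):
        m = by_id[mid]
        grp = grp.reset_index(drop=True)
        # exclusion zones act on the original gradient (no standardization)
        grp.attrs["pipeline_state"] = preprocessing.PipelineState.STANDARDIZED
        excl = preprocessing.apply_exclusion_zones(
            grp, m.domain_min, m.domain_max, exclusion_zone
        )
        if len(excl) < 2:
            continue
        done = preprocessing.transform_records(excl)
        done = climate.assign_midpoint_climate_table(
            done, m.band_climate, variables=(covariate,)
        )
        frames.append(done)
    if not frames:
        raise ValueError("no mountains survive local preprocessing")
    out = pd.concat(frames, ignore_index=True)
    site_ids = sorted(out["mountain_id"].unique())
    out["site"] = out["mountain_id"].map({mid: i for i, mid in enumerate(site_ids)})
    data = LocalModelData(
        y=out["log_range"].to_numpy(),
        site_index=out["site"].to_numpy(int),
        v=out[covariate].to_numpy(float),
        site_ids=site_ids,
    )
    return data, site_ids


def run_local_analysis(config: RunConfig, covariates: tuple[str, ...] = LOCAL_COVARIATES) -> dict:
    """Within-mountain analysis: per-mountain slopes for DTR and TS.

    Refuses ``dmat`` as a covariate: one paleo value per mountain cannot
    resolve within-gradient variation.
    """
    for cov in covariates:
        if cov not in LOCAL_COVARIATES:
            raise ValueError(
                f"covariate {cov!r} is not testable at the local scale; "
                "the past-climate data underlying dmat is too coarse to "
                "resolve within-mountain elevation variation"
            )
    records, mountains = _inputs(config)
    results = {}
    for cov in covariates:
        log.info("fitting local model: %s", cov)
        data, site_ids = prepare_local(
            records,
            mountains,
            config.standardization.exclusion_zone,
            cov,
            config.max_singleton_fraction,
            config.gap_threshold,
        )
        fit = fit_local(data, config.mcmc)
        per_site, agg = classify_local_slopes(fit)
        results[cov] = {
            "fit": fit,
            "per_site": per_site,
            "aggregate": agg,
            "diagnostics": diagnostics_table(fit),
        }
    bundle = {
        "results": results,
        "config_hash": config.config_hash(),
        "seed": config.mcmc.seed,
    }
    if config.out_dir is not None:
        _write_local_bundle(bundle, Path(config.out_dir), config)
    return bundle


def run_sensitivity_grid(
    config: RunConfig,
    covariate: str = "dtr",
    lengths: tuple[float, ...] = GRID_LENGTHS,
    exclusion_zones: tuple[float, ...] = GRID_EXCLUSIONS,
    anchors: tuple[str, ...] = GRID_ANCHORS,
) -> pd.DataFrame:
    """Global fits over the standardization grid (lengths x zones x anchors).

    One row per grid cell: slope sign, P(beta<0), site-level R2 and the
    number of mountains retained.  Cells whose preconditions fail (e.g.
    every gradient shorter than the requested length) are recorded as
    excluded rather than failing the grid.
    """
    records, mountains = _inputs(config)
    rows = []
    for length in lengths:
        for ez in exclusion_zones:
            for anchor in anchors:
                cell = {
                    "length": length,
                    "exclusion_zone": ez,
                    "anchor": anchor,
                    "covariate": covariate,
                }
                try:
                    std = StandardizationConfig(length=length, exclusion_zone=ez, anchor=anchor)
                    prep = prepare_global(
                        records,
                        mountains,
                        std,
                        config.max_singleton_fraction,
                        config.gap_threshold,
                    )
                    data = global_model_data(prep, covariate)
                    fit = fit_global(data, config.mcmc, store_loglik=False)
                    summ = SlopeSummary.from_fit(fit, f"beta_{covariate}", X=data.X)
                    cell.update(
                        {
                            "status": "ok",
                            "n_mountains": len(prep.mountains),
                            "slope_mean": summ.mean,
                            "slope_sign": "negative" if summ.mean < 0 else "positive",
                            "prob_negative": summ.prob_negative,
                            "r2": summ.r2,
                        }
                    )
                except ValueError as e:
                    cell.update(
                        {
                            "status": "excluded",
                            "n_mountains": 0,
                            "slope_mean": np.nan,
                            "slope_sign": "",
                            "prob_negative": np.nan,
                            "r2": np.nan,
                        }
                    )
                    log.info("grid cell excluded (%s/%s/%s): %s", length, ez, anchor, e)
                rows.append(cell)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def _sidecar(config: RunConfig, extra: dict) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.mcmc.seed,
        "standardization": {
            "length": config.standardization.length,
            "exclusion_zone": config.standardization.exclusion_zone,
            "anchor": config.standardization.anchor,
        },
        **extra,
    }


def _write_global_bundle(bundle: dict, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["comparison"].table.to_csv(out_dir / "comparison.csv", index=False)
    bundle["site_table"].to_csv(out_dir / "site_means.csv", index=False)
    bundle["prep"].attrition.to_csv(out_dir / "attrition.csv", index=False)
    slopes = pd.DataFrame([vars(s) for s in bundle["slopes"].values()])
    slopes.to_csv(out_dir / "slopes.csv", index=False)
    gates = {
        cov: {
            "max_rhat": float(d["rhat"].max()),
            "min_ess": float(d["ess"].min()),
            "converged": bool((d["rhat"] <= evaluation.RHAT_THRESHOLD).all()),
        }
        for cov, d in bundle["diagnostics"].items()
    }
    (out_dir / "report.json").write_text(
        json.dumps(_sidecar(config, {"kind": "global", "gates": gates}), indent=2)
    )


def _write_local_bundle(bundle: dict, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    aggs = {}
    for cov, res in bundle["results"].items():
        res["per_site"].to_csv(out_dir / f"local_slopes_{cov}.csv", index=False)
        aggs[cov] = res["aggregate"]
    (out_dir / "report.json").write_text(
        json.dumps(_sidecar(config, {"kind": "local", "aggregates": aggs}), indent=2)
    )
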