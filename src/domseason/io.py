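"""Tabular readers/writers, configuration, and the pipeline driver.

File schemas (CSV: comma-separated, UTF-8, ``.`` decimal, empty field for
missing; timestamps ISO-8601, treated as UTC; monthly binning by calendar
month):

* profile CSV      — ``timestamp, depth_m, variable, value, units``
* bottle CSV       — ``timestamp, depth_m, variable, replicate, value, units``
* amino-acid CSV   — ``timestamp, depth_m, amino_acid, replicate,
  concentration_umol_L``
* ASV counts TSV   — ASV x sample with an ``asv_id`` index column
* taxonomy TSV     — ``asv_id, taxonomy``
* sample metadata  — ``sample_id, timestamp, depth_m``

``run_pipeline`` chains hydrography -> DOM quality -> mixing-null ->
rates/flux -> community response and writes one CSV per product plus a run
log recording the seed and every default in effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import ResponderCriteria, select_responders
from .dom_quality import (
    load_reference_table,
    mole_percent,
    degradation_index,
    replicate_qc_table,
    tdaa_carbon,
)
from .hydrography import (
    EUPHOTIC_ZONE,
    MESOPELAGIC_ZONE,
    DepthZone,
    MLDCriterion,
    classify_seasons,
    compute_aou,
    compute_mld,
    detect_dcm_dcml,
    zone_mean,
)
from .mixing_null import (
    flag_production_loss,
    mixing_deviation,
    null_threshold,
    pair_inventories,
    standardize_deviations,
)
from .rates import export_flux, correlation_matrix, rate_regression

log = logging.getLogger("domseason")

FLOAT_FORMAT = "%.10g"

# TOC and DOC are analytically indistinguishable here and pooled.
DEFAULT_VARIABLE_ALIASES = {"TOC": "DOC"}


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    profiles: str | None = None
    bottle: str | None = None
    amino_acids: str | None = None
    asv_counts: str | None = None
    taxonomy: str | None = None
    sample_metadata: str | None = None
    di_reference: str | None = None
    outdir: str = "domseason_out"

    mld_delta_T: float = 0.2
    mld_reference_depth: float = 10.0
    boundary_fraction: float = 0.35
    season_persistence: int = 2
    euphotic: tuple = (0.0, 120.0)
    mesopelagic: tuple = (120.0, 300.0)
    quantile: float = 0.95
    sidedness: str = "two"
    cv_max: float = 0.20
    rate_window: tuple = ("2017-04-15", "2017-08-29")
    mixing_window: tuple = ("2017-04", "2017-07")
    max_mix_time: str = "2017-04"
    pre_mix_time: str = "2016-11"
    max_lag: int = 4
    ccf_alpha: float = 0.05
    variable_aliases: dict = field(default_factory=lambda: dict(DEFAULT_VARIABLE_ALIASES))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    @property
    def euphotic_zone(self) -> DepthZone:
        return DepthZone("euphotic", *self.euphotic)

    @property
    def mesopelagic_zone(self) -> DepthZone:
        return DepthZone("mesopelagic", *self.mesopelagic)

    @property
    def mld_criterion(self) -> MLDCriterion:
        return MLDCriterion(
            delta_T=self.mld_delta_T, reference_depth=self.mld_reference_depth
        )


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def read_profile_table(path) -> pd.DataFrame:
    """Read a long profile CSV and reject physically invalid rows."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _require_columns(df, ["timestamp", "depth_m", "variable", "value"], "profile table")
    bad = df["depth_m"] < 0
    if bad.any():
        log.warning("rejecting %d negative-depth profile rows", int(bad.sum()))
        df = df[~bad]
    return df


def read_bottle_table(path, variable_aliases=None) -> pd.DataFrame:
    """Read a bottle replicate CSV; negative concentrations are rejected
    with a log entry, unknown variables pass through."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _require_columns(
        df, ["timestamp", "depth_m", "variable", "replicate", "value"], "bottle table"
    )
    aliases = DEFAULT_VARIABLE_ALIASES if variable_aliases is None else variable_aliases
    df["variable"] = df["variable"].replace(aliases)
    bad = (df["value"] < 0) | (df["depth_m"] < 0)
    if bad.any():
        log.warning("rejecting %d invalid bottle rows (negative depth/value)", int(bad.sum()))
        df = df[~bad]
    return df


def read_amino_acid_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _require_columns(
        df,
        ["timestamp", "depth_m", "amino_acid", "replicate", "concentration_umol_L"],
        "amino-acid table",
    )
    bad = (df["concentration_umol_L"] < 0) | (df["depth_m"] < 0)
    if bad.any():
        log.warning("rejecting %d invalid amino-acid rows", int(bad.sum()))
        df = df[~bad]
    return df


def read_asv_tables(counts_path, taxonomy_path, metadata_path):
    counts = pd.read_csv(counts_path, sep="\t", index_col="asv_id")
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="asv_id")["taxonomy"]
    metadata = pd.read_csv(metadata_path, parse_dates=["timestamp"]).set_index("sample_id")
    _require_columns(metadata, ["timestamp", "depth_m"], "sample metadata")
    return counts, taxonomy, metadata


def write_table(df: pd.DataFrame, path, **kwargs) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, **kwargs)


# --------------------------------------------------------------------------
# pipeline stages


def hydrography_stage(config: PipelineConfig, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-timestamp MLD, chlorophyll layer, and season labels."""
    crit = config.mld_criterion
    rows = []
    for ts, grp in profiles.groupby("timestamp"):
        wide = (
            grp.pivot_table(index="depth_m", columns="variable", values="value")
            .sort_index()
        )
        depth = wide.index.to_numpy(dtype=float)
        if "temperature" in wide and "salinity" in wide:
            mld = compute_mld(
                depth,
                sigma=wide["sigma_theta"].to_numpy() if "sigma_theta" in wide else None,
                temperature=wide["temperature"].to_numpy(),
                salinity=wide["salinity"].to_numpy(),
                criterion=crit,
            )
        elif "sigma_theta" in wide:
            raise ValueError(
                "density-mode MLD needs temperature and salinity profiles; "
                "supply them or use a direct sigma increment"
            )
        else:
            raise ValueError(f"no density information in profile at {ts}")
        layer = (np.nan, np.nan, np.nan)
        if "chlorophyll" in wide:
            chl = wide["chlorophyll"].to_numpy()
            try:
                lay = detect_dcm_dcml(depth, chl, config.boundary_fraction)
                layer = (lay.dcm_depth, lay.dcml_top, lay.dcml_bottom)
            except ValueError:
                pass
        rows.append((ts, mld.depth, mld.fully_mixed, *layer))
    out = pd.DataFrame(
        rows,
        columns=["timestamp", "mld_m", "fully_mixed", "dcm_m", "dcml_top_m", "dcml_bottom_m"],
    ).sort_values("timestamp")
    seasons = classify_seasons(
        out.set_index("timestamp")["mld_m"],
        out.set_index("timestamp")[["dcm_m", "dcml_top_m"]],
        persistence=config.season_persistence,
    )
    out["season"] = seasons.to_numpy()
    return out


def dom_quality_stage(
    config: PipelineConfig, amino: pd.DataFrame, reference: pd.DataFrame | None
) -> pd.DataFrame:
    """Replicate QC, TDAA-C, and DI per (timestamp, depth)."""
    qc, excluded_frac = replicate_qc_table(
        amino,
        value_col="concentration_umol_L",
        group_cols=("timestamp", "depth_m", "amino_acid"),
        cv_max=config.cv_max,
    )
    log.info("amino-acid replicate QC excluded %.1f%% of groups", 100 * excluded_frac)
    kept = qc[qc["kept"]]
    rows = []
    for (ts, depth), grp in kept.groupby(["timestamp", "depth_m"]):
        panel = grp.set_index("amino_acid")["mean"]
        tdaa_c = tdaa_carbon(panel)
        di = np.nan
        if reference is not None:
            try:
                di = degradation_index(mole_percent(panel), reference)
            except (KeyError, ValueError) as err:
                log.warning("DI undefined at %s %.0f m: %s", ts, depth, err)
        rows.append((ts, depth, tdaa_c, di))
    return pd.DataFrame(rows, columns=["timestamp", "depth_m", "tdaa_c_umol_L", "di"])


def mixing_null_stage(
    config: PipelineConfig, tracer_long: pd.DataFrame, mld_series: pd.Series
):
    """Inventory pairing, 1:1-line deviations, null fit, and flags."""
    pairs = pair_inventories(tracer_long, mld_series)
    dev = mixing_deviation(pairs)
    standardized = standardize_deviations(dev)
    model = null_threshold(standardized["z"], q=config.quantile)
    flags = flag_production_loss(standardized, model, sidedness=config.sidedness)
    return flags, model


def rates_stage(
    config: PipelineConfig,
    monthly_zone_means: pd.DataFrame,
    month_season: pd.Series,
):
    """Table of regression rates plus the convective export flux.

    ``monthly_zone_means`` has a Period index and columns named
    ``{zone}:{analyte}`` in umol L^-1.
    """
    rate_rows = []
    for col in monthly_zone_means.columns:
        zone, analyte = col.split(":", 1)
        series = monthly_zone_means[col].dropna()
        series.index = pd.PeriodIndex(series.index, freq="M").to_timestamp() + pd.Timedelta(days=14)
        try:
            est = rate_regression(series, config.rate_window, zone=zone, analyte=analyte)
        except ValueError as err:
            log.warning("rate regression skipped for %s: %s", col, err)
            continue
        rate_rows.append(
            (zone, analyte, f"{config.rate_window[0]}..{config.rate_window[1]}",
             est.duration_days, est.delta, est.slope, est.r_squared, est.n)
        )
    rates = pd.DataFrame(
        rate_rows,
        columns=["zone", "analyte", "window", "duration_days", "delta",
                 "rate_nmol_L_d", "R2", "n"],
    )
    flux = None
    meso_doc = f"mesopelagic:DOC"
    if meso_doc in monthly_zone_means.columns:
        aligned = month_season.reindex(monthly_zone_means.index)
        try:
            flux = export_flux(
                monthly_zone_means[meso_doc], aligned, config.mesopelagic_zone
            )
        except ValueError as err:
            log.warning("export flux skipped: %s", err)
    return rates, flux


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on the configured inputs.

    Stages with missing inputs are skipped with an explicit log entry;
    any stage failure is re-raised naming the stage.  Returns a dict of
    product DataFrames and writes them under ``config.outdir`` together
    with ``run_log.yaml``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    products: dict = {}
    run_log: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "defaults": {
            "mld_reference_depth_m": config.mld_reference_depth,
            "dcml_boundary_fraction": config.boundary_fraction,
            "season_persistence": config.season_persistence,
            "replicate_cv_max": config.cv_max,
            "null_quantile": config.quantile,
            "flag_sidedness": config.sidedness,
            "variable_aliases": config.variable_aliases,
            "standardization_sd": "sample (ddof=1)",
            "distance_metric": "perpendicular distance to the 1:1 line",
        },
    }

    def _stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as err:
            run_log["stages"][name] = f"failed: {err}"
            _write_log(outdir, run_log)
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        run_log["stages"][name] = "ok"
        return result

    # -- hydrography -------------------------------------------------------
    if config.profiles is None:
        raise ValueError("a profile table is required")
    profiles = read_profile_table(config.profiles)
    seasons = _stage("hydrography", hydrography_stage, config, profiles)
    write_table(seasons, outdir / "seasons.csv")
    products["seasons"] = seasons
    mld_by_ts = seasons.set_index("timestamp")["mld_m"]
    months = pd.PeriodIndex(seasons["timestamp"], freq="M")
    month_season = pd.Series(seasons["season"].to_numpy(), index=months)
    mld_by_month = pd.Series(seasons["mld_m"].to_numpy(), index=months)

    # -- DOM quality -------------------------------------------------------
    di_table = None
    if config.amino_acids is not None:
        amino = read_amino_acid_table(config.amino_acids)
        reference = (
            load_reference_table(config.di_reference) if config.di_reference else None
        )
        di_table = _stage("dom_quality", dom_quality_stage, config, amino, reference)
        write_table(di_table, outdir / "di_series.csv")
        products["di_series"] = di_table
    else:
        run_log["stages"]["dom_quality"] = "skipped: no amino-acid input"
        log.info("dom_quality stage skipped (no amino-acid input)")

    # -- mixing null -------------------------------------------------------
    flags = None
    if config.bottle is not None:
        bottle = read_bottle_table(config.bottle, config.variable_aliases)
        qc, _ = replicate_qc_table(bottle, cv_max=config.cv_max)
        tracer_long = (
            qc[qc["kept"]]
            .rename(columns={"variable": "analyte", "mean": "value"})
            [["analyte", "timestamp", "depth_m", "value"]]
        )
        if di_table is not None:
            tdaa_long = di_table.rename(columns={"tdaa_c_umol_L": "value"})[
                ["timestamp", "depth_m", "value"]
            ].assign(analyte="TDAA-C")
            tracer_long = pd.concat([tracer_long, tdaa_long], ignore_index=True)
        flags, model = _stage(
            "mixing_null", mixing_null_stage, config, tracer_long, mld_by_ts
        )
        write_table(
            flags[["analyte", "t", "t_next", "mld_next_m", "inv_prev", "inv_next",
                   "distance", "z", "label"]],
            outdir / "mixing_flags.csv",
        )
        products["mixing_flags"] = flags
        run_log["null_model"] = {
            "mu": model.mu, "sigma": model.sigma,
            "quantile": model.quantile, "threshold": model.threshold, "n": model.n,
        }
    else:
        run_log["stages"]["mixing_null"] = "skipped: no bottle input"
        log.info("mixing_null stage skipped (no bottle input)")

    # -- rates and export flux --------------------------------------------
    if config.bottle is not None:
        zone_means = _monthly_zone_mean_table(config, tracer_long)
        rates, flux = _stage("rates_flux", rates_stage, config, zone_means, month_season)
        write_table(rates, outdir / "rates.csv")
        products["rates"] = rates
        if flux is not None:
            products["export_flux"] = flux
            run_log["export_flux_mol_m2"] = flux.flux
            run_log["export_flux_mode"] = flux.mode
    else:
        run_log["stages"]["rates_flux"] = "skipped: no bottle input"

    # -- community response ------------------------------------------------
    have_asv = all(
        p is not None
        for p in (config.asv_counts, config.taxonomy, config.sample_metadata)
    )
    if have_asv and config.bottle is not None:
        counts, taxonomy, metadata = read_asv_tables(
            config.asv_counts, config.taxonomy, config.sample_metadata
        )
        meso = config.mesopelagic_zone
        doc_series = _monthly_zone_series_from_long(tracer_long, "DOC", meso)
        tdaa_series = (
            _monthly_zone_series_from_long(tracer_long, "TDAA-C", meso)
            if (tracer_long["analyte"] == "TDAA-C").any()
            else None
        )
        criteria = ResponderCriteria(
            meso_zone=meso,
            mixing_window=tuple(config.mixing_window),
            max_mix_time=config.max_mix_time,
            pre_mix_time=config.pre_mix_time,
            max_lag=config.max_lag,
            ccf_alpha=config.ccf_alpha,
        )
        responders = _stage(
            "community", select_responders, counts, taxonomy, metadata,
            doc_series, tdaa_series, mld_by_month, criteria,
        )
        write_table(responders, outdir / "responders.csv")
        products["responders"] = responders
    else:
        run_log["stages"]["community"] = "skipped: ASV inputs incomplete"
        log.info("community stage skipped (ASV inputs incomplete)")

    _write_log(outdir, run_log)
    products["run_log"] = run_log
    return products


def _write_log(outdir: Path, run_log: dict) -> None:
    with open(Path(outdir) / "run_log.yaml", "w") as fh:
        yaml.safe_dump(_plain(run_log), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (pd.Timestamp, pd.Period)):
        return str(obj)
    return obj


def _monthly_zone_series_from_long(
    tracer_long: pd.DataFrame, analyte: str, zone: DepthZone
) -> pd.Series:
    sub = tracer_long[tracer_long["analyte"] == analyte]
    months = pd.PeriodIndex(pd.to_datetime(sub["timestamp"]), freq="M")
    out = {}
    for month, grp in sub.groupby(months):
        prof = grp.groupby("depth_m")["value"].mean().sort_index()
        if len(prof) >= 2:
            try:
                out[month] = zone_mean(
                    prof.index.to_numpy(), prof.to_numpy(), zone
                )
            except ValueError:
                continue
    return pd.Series(out).sort_index()


def _monthly_zone_mean_table(config: PipelineConfig, tracer_long: pd.DataFrame) -> pd.DataFrame:
    zones = (config.euphotic_zone, config.mesopelagic_zone)
    cols = {}
    for analyte in tracer_long["analyte"].unique():
        for zone in zones:
            s = _monthly_zone_series_from_long(tracer_long, analyte, zone)
            if not s.empty:
                cols[f"{zone.name}:{analyte}"] = s
    return pd.DataFrame(cols)
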