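"""Synthetic seasonal water column with known ground truth.

Generates the fixtures every analysis stage consumes: a seasonal
mixed-layer-depth cycle deepening into the upper mesopelagic in late
winter, stably stratified hydrographic profiles with a subsurface
chlorophyll maximum, tracers evolving under conservative mixed-layer
homogenization with optional injected production/loss events, replicate
measurement noise, and an ASV community in which planted taxa respond to
the mesopelagic DOC pulse with a known monthly lag while null taxa are
stationary noise.

The mixing model is a box model: at each (monthly) time step the tracer is
instantaneously homogenized over the mixed layer; there is no diffusion
below it.  Homogenization is defined to be exactly consistent with
trapezoidal depth integration, so both the full-column inventory and any
integral to the mixed layer depth are conserved to machine precision (see
``homogenize_mixed_layer``).  Measurement noise is multiplicative
lognormal (mean-one) with coefficient of variation ``noise_cv``; all
randomness derives from the single integer seed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .seawater import oxygen_saturation, sigma_theta

__all__ = [
    "SimulationConfig",
    "EventSpec",
    "ResponderSpec",
    "TracerGrid",
    "simulate_seasonal_mld",
    "simulate_hydrography",
    "homogenize_mixed_layer",
    "simulate_conservative_tracer",
    "simulate_community",
    "synthetic_reference_table",
    "default_events",
    "default_responders",
    "generate_dataset",
    "write_fixtures",
]


def _default_depths() -> np.ndarray:
    return np.arange(0.0, 505.0, 5.0)


def _default_times() -> pd.PeriodIndex:
    return pd.period_range("2016-07", "2017-09", freq="M")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic water column.

    Defaults mimic the observed study conditions: a 0-500 m column at 5 m
    resolution sampled monthly for 15 months, winter mixing December
    through April reaching 242 m, a deep chlorophyll maximum near 95 m,
    and 10-20% replicate measurement noise.
    """

    depth_grid: np.ndarray = field(default_factory=_default_depths)
    times: pd.PeriodIndex = field(default_factory=_default_times)
    mld_min: float = 20.0
    mld_max: float = 242.0
    mixing_window: tuple = ("2016-12", "2017-04")
    dcm_depth: float = 95.0
    dcm_width: float = 20.0
    noise_cv: float = 0.12
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        z = np.asarray(self.depth_grid, dtype=float)
        object.__setattr__(self, "depth_grid", z)
        if z.ndim != 1 or z.size < 3 or np.any(np.diff(z) <= 0):
            raise ValueError("depth_grid must be strictly increasing with >= 3 levels")
        if len(self.times) < 14:
            raise ValueError("time grid must span at least 14 months")
        if not (0 < self.mld_min < self.mld_max <= z[-1]):
            raise ValueError("need 0 < mld_min < mld_max <= max depth")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        start, end = self.window_periods
        if start not in self.times or end not in self.times or start > end:
            raise ValueError("mixing_window must lie inside the time grid")

    @property
    def window_periods(self) -> tuple[pd.Period, pd.Period]:
        return (
            pd.Period(self.mixing_window[0], "M"),
            pd.Period(self.mixing_window[1], "M"),
        )

    def rng(self, *tags: int) -> np.random.Generator:
        """Named child generator: all randomness flows from the one seed."""
        return np.random.default_rng([self.seed, *tags])


@dataclass(frozen=True)
class EventSpec:
    """A ground-truth production (+) or loss (-) event in the mixed layer.

    ``magnitude`` is areal (tracer units x m, e.g. mmol m^-2 for a
    umol L^-1 tracer) and is spread uniformly over the mixed layer at
    ``time``; ``z_bottom`` may restrict the event to a shallower extent
    but must not exceed the MLD at that time.
    """

    analyte: str
    time: str | pd.Period
    magnitude: float
    z_bottom: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.magnitude) or self.magnitude == 0:
            raise ValueError("event magnitude must be finite and nonzero")
        object.__setattr__(self, "time", pd.Period(self.time, "M"))


@dataclass(frozen=True)
class ResponderSpec:
    """A planted DOM-responder ASV.

    ``lag_months`` is the (non-positive) lag of the ASV relative to the
    DOC driver: abundance at month t follows the driver at t + lag.
    ``response_amplitude`` is in relative-abundance units added at the
    driver's seasonal maximum; the response is expressed at sample depths
    inside ``depth_zone``.
    """

    asv_id: str
    lag_months: int
    response_amplitude: float
    depth_zone: tuple = (120.0, 300.0)
    baseline: float = 0.004
    taxonomy: str = "Bacteria;Proteobacteria;Alphaproteobacteria;SAR11 clade;Ia"

    def __post_init__(self):
        if not (-4 <= self.lag_months <= 0):
            raise ValueError("lag_months must lie in [-4, 0]")
        if self.response_amplitude <= 0:
            raise ValueError("response_amplitude must be positive")


def simulate_seasonal_mld(config: SimulationConfig) -> pd.Series:
    """Monthly MLD series: shallow when stratified, deepening to the
    configured maximum at the end of the mixing window, then rapidly
    shoaling.

    Within the window the MLD ramps linearly in depth fraction from 0.25
    to 1.0 of (mld_max - mld_min), so the first mixing month sits inside
    the chlorophyll layer band (the fall-transition regime) and the final
    month reaches exactly ``mld_max``.  Deterministic for a given
    configuration.
    """
    start, end = config.window_periods
    n_win = end.ordinal - start.ordinal + 1
    mld = pd.Series(config.mld_min, index=config.times, dtype=float, name="mld_m")
    for i in range(n_win):
        frac = 0.25 + 0.75 * (i / (n_win - 1)) if n_win > 1 else 1.0
        mld.loc[start + i] = config.mld_min + frac * (config.mld_max - config.mld_min)
    return mld


def simulate_hydrography(mld_series: pd.Series, config: SimulationConfig) -> xr.Dataset:
    """Temperature, salinity, oxygen, chlorophyll, and sigma-theta grids.

    Temperature is uniform above the MLD (so density is too) and decays
    below it steeply enough that the density criterion recovers the
    prescribed MLD within a grid step.  Chlorophyll holds a Gaussian deep
    maximum while stratified and is homogenized over the mixed layer once
    the MLD reaches the DCM.  Oxygen is saturated in the mixed layer with
    AOU accumulating below it.
    """
    if not mld_series.index.equals(config.times):
        raise ValueError("mld_series must be aligned to the configured time grid")
    z = config.depth_grid
    nt, nz = len(config.times), z.size
    T = np.empty((nz, nt))
    chl = np.empty((nz, nt))
    o2 = np.empty((nz, nt))
    sal = np.full((nz, nt), 36.6)
    for j, t in enumerate(config.times):
        h = float(mld_series.iloc[j])
        t_surf = 28.0 - 9.0 * (h - config.mld_min) / (config.mld_max - config.mld_min)
        below = np.clip(z - h, 0.0, None)
        T[:, j] = t_surf - 4.0 * (1.0 - np.exp(-below / 30.0)) - 0.008 * below
        if h >= config.dcm_depth:
            chl[:, j] = np.where(z <= h, 0.30, 0.02)
        else:
            chl[:, j] = 0.02 + np.exp(-((z - config.dcm_depth) ** 2) / (2 * config.dcm_width**2))
        aou = 40.0 * (1.0 - np.exp(-below / 80.0))
        o2[:, j] = oxygen_saturation(T[:, j], sal[:, j]) - aou
    sig = sigma_theta(T, sal)
    coords = {"depth": z, "time": config.times.to_timestamp() + pd.Timedelta(days=14)}
    return xr.Dataset(
        {
            "temperature": (("depth", "time"), T),
            "salinity": (("depth", "time"), sal),
            "oxygen": (("depth", "time"), o2),
            "chlorophyll": (("depth", "time"), chl),
            "sigma_theta": (("depth", "time"), sig),
        },
        coords=coords,
        attrs={"units": "degC, psu, umol/L, RFU, kg/m^3"},
    )


def _snap_index(depths: np.ndarray, mld: float) -> int:
    k = int(np.argmin(np.abs(depths - mld)))
    return max(k, 1)


def _trapz_weights(depths: np.ndarray) -> np.ndarray:
    w = np.empty_like(depths)
    w[1:-1] = (depths[2:] - depths[:-2]) / 2.0
    w[0] = (depths[1] - depths[0]) / 2.0
    w[-1] = (depths[-1] - depths[-2]) / 2.0
    return w


def homogenize_mixed_layer(conc: np.ndarray, depths: np.ndarray, k: int) -> np.ndarray:
    """Instantaneously mix the layer spanning grid nodes 0..k.

    Nodes 0..k are set to the trapezoid mean of the layer, which preserves
    the trapezoidal integral over [depths[0], depths[k]] exactly; the
    first node below the layer absorbs a compensating adjustment so the
    full-column trapezoidal inventory is also preserved exactly.  The
    compensation is the discrete analogue of the thin entrainment
    interface a sharp mixed-layer base leaves behind.
    """
    c = conc.astype(float).copy()
    z = depths
    layer = slice(0, k + 1)
    thickness = z[k] - z[0]
    m = float(np.trapezoid(c[layer], z[layer]) / thickness)
    jump = m - c[k]
    c[layer] = m
    if k + 1 < z.size:
        w = _trapz_weights(z)
        c[k + 1] -= jump * (z[k + 1] - z[k]) / (2.0 * w[k + 1])
    return c


@dataclass
class TracerGrid:
    """Depth x time field for one analyte, with optional noisy replicates."""

    analyte: str
    depths: np.ndarray
    times: pd.PeriodIndex
    values: np.ndarray                 # (n_depth, n_time) noise-free truth
    replicates: np.ndarray | None = None  # (n_rep, n_depth, n_time)
    units: str = "umol/L"

    def to_frame(self, replicate_means: bool = False) -> pd.DataFrame:
        """Long bottle-style table (analyte, timestamp, depth_m, value)."""
        vals = (
            self.replicates.mean(axis=0)
            if (replicate_means and self.replicates is not None)
            else self.values
        )
        stamps = self.times.to_timestamp() + pd.Timedelta(days=14)
        rows = []
        for j, ts in enumerate(stamps):
            for i, z in enumerate(self.depths):
                rows.append((self.analyte, ts, float(z), float(vals[i, j])))
        return pd.DataFrame(rows, columns=["analyte", "timestamp", "depth_m", "value"])


def simulate_conservative_tracer(
    initial_profile: np.ndarray,
    mld_series: pd.Series,
    events: list[EventSpec],
    config: SimulationConfig,
    analyte: str = "tracer",
    units: str = "umol/L",
) -> TracerGrid:
    """Evolve a tracer under mixed-layer homogenization plus events.

    At each time step the column is homogenized over the (grid-snapped)
    mixed layer — entraining deeper water when the MLD deepens — and any
    events scheduled for that month add or remove their areal magnitude
    spread uniformly over the mixed layer (or over ``[0, z_bottom]`` if the
    event restricts its extent; an extent below the MLD is an error).
    With no events and ``noise_cv = 0`` the full-column inventory is
    conserved to machine precision.  Mean-one lognormal noise is applied
    last, per replicate, from the configuration's seeded generator.
    """
    z = config.depth_grid
    c = np.asarray(initial_profile, dtype=float)
    if c.shape != z.shape:
        raise ValueError("initial_profile must live on the configured depth grid")
    if not mld_series.index.equals(config.times):
        raise ValueError("mld_series must be aligned to the configured time grid")
    by_time: dict[pd.Period, list[EventSpec]] = {}
    for ev in events:
        if ev.analyte != analyte:
            continue
        if ev.time not in config.times:
            raise ValueError(f"event time {ev.time} outside the time grid")
        by_time.setdefault(ev.time, []).append(ev)

    values = np.empty((z.size, len(config.times)))
    for j, t in enumerate(config.times):
        k = _snap_index(z, float(mld_series.iloc[j]))
        c = homogenize_mixed_layer(c, z, k)
        for ev in by_time.get(t, []):
            if ev.z_bottom is None:
                k_ev = k
            else:
                if ev.z_bottom > z[k] + 1e-9:
                    raise ValueError(
                        f"event at {t} extends to {ev.z_bottom} m, deeper than the "
                        f"mixed layer ({z[k]} m)"
                    )
                k_ev = _snap_index(z, float(ev.z_bottom))
            inc = ev.magnitude / (z[k_ev] - z[0])
            c[: k_ev + 1] += inc
            if k_ev + 1 < z.size:
                w = _trapz_weights(z)
                c[k_ev + 1] -= inc * (z[k_ev + 1] - z[k_ev]) / (2.0 * w[k_ev + 1])
        values[:, j] = c

    replicates = None
    if config.n_replicates >= 1:
        if config.noise_cv > 0:
            sigma = float(np.sqrt(np.log(1.0 + config.noise_cv**2)))
            rng = config.rng(101, _stable_tag(analyte))
            eps = rng.standard_normal((config.n_replicates, *values.shape))
            factors = np.exp(sigma * eps - 0.5 * sigma**2)
        else:
            factors = np.ones((config.n_replicates, *values.shape))
        replicates = values[None, :, :] * factors
    return TracerGrid(analyte, z, config.times, values, replicates, units)


def _stable_tag(name: str) -> int:
    # Deterministic small integer from a name (hash() is salted per process).
    return sum((i + 1) * b for i, b in enumerate(name.encode())) % 100003


def simulate_community(
    doc_zone_series: pd.Series,
    responders: list[ResponderSpec],
    n_null_taxa: int,
    config: SimulationConfig,
    sample_depths=(10.0, 60.0, 120.0, 160.0, 200.0, 250.0),
    mld_series: pd.Series | None = None,
    total_reads: int = 50_000,
    include_cyanobacterium: bool = True,
    include_chloroplast: bool = True,
    include_unclassified: bool = True,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """ASV count table with planted lagged responders.

    Responder relative weight at month t (at depths inside the responder's
    zone) is baseline + amplitude * D(t + lag), where D is the driver
    series min-max normalized to [0, 1]; null taxa are stationary noise; a
    cyanobacterium is planted with responder-like dynamics to exercise the
    autotroph exclusion, plus optional chloroplast / class-unclassified
    taxa for the taxonomic screen.  Counts are multinomial draws per
    sample, so each sample's relative abundances sum to one by
    construction.

    Returns ``(counts, taxonomy, metadata)``: counts ASV x sample,
    taxonomy per ASV, metadata indexed by sample id with ``timestamp`` and
    ``depth_m``.
    """
    if n_null_taxa < 1:
        raise ValueError("n_null_taxa must be >= 1")
    doc = pd.Series(doc_zone_series).astype(float).reindex(config.times)
    span = float(doc.max() - doc.min())
    norm = (doc - doc.min()) / (span if span > 0 else 1.0)

    rng = config.rng(202)
    null_base = 0.002 + 0.02 * rng.random(n_null_taxa)

    asv_ids, taxonomies, weight_fns = [], [], []

    def _lagged(lag: int) -> pd.Series:
        shifted = norm.copy()
        shifted.index = shifted.index - lag  # value at t+lag shows up at t
        return shifted.reindex(config.times).fillna(0.0)

    for r in responders:
        sig = _lagged(r.lag_months)
        zone_lo, zone_hi = r.depth_zone

        def fn(t, depth, r=r, sig=sig, lo=zone_lo, hi=zone_hi):
            w = r.baseline
            if lo <= depth < hi:
                w = w + r.response_amplitude * float(sig.loc[t])
            return w

        asv_ids.append(r.asv_id)
        taxonomies.append(r.taxonomy)
        weight_fns.append(fn)

    for i in range(n_null_taxa):
        def fn(t, depth, b=float(null_base[i])):
            return b

        asv_ids.append(f"ASV_null_{i:03d}")
        taxonomies.append(
            f"Bacteria;Proteobacteria;Gammaproteobacteria;Order{i % 7};Family{i % 5}"
        )
        weight_fns.append(fn)

    if include_cyanobacterium:
        # Responder-like dynamics so only the taxonomy rule can reject it.
        sig = _lagged(-1)

        def fn(t, depth, sig=sig):
            w = 0.004
            if 120.0 <= depth < 300.0:
                w = w + 0.02 * float(sig.loc[t])
            return w + 0.03 * np.exp(-depth / 60.0)

        asv_ids.append("ASV_cyano")
        taxonomies.append("Bacteria;Cyanobacteria;Cyanobacteriia;Synechococcales;Synechococcus")
        weight_fns.append(fn)

    if include_chloroplast:
        asv_ids.append("ASV_chloroplast")
        taxonomies.append("Bacteria;Cyanobacteria;Cyanobacteriia;Chloroplast")
        weight_fns.append(lambda t, depth: 0.01 * np.exp(-depth / 80.0) + 1e-4)

    if include_unclassified:
        asv_ids.append("ASV_unclassified")
        taxonomies.append("Bacteria;Proteobacteria")
        weight_fns.append(lambda t, depth: 0.005)

    sigma = float(np.sqrt(np.log(1.0 + config.noise_cv**2))) if config.noise_cv > 0 else 0.0
    samples, meta_rows = {}, []
    for t in config.times:
        mld_t = float(mld_series.loc[t]) if mld_series is not None else None
        for depth in sample_depths:
            sid = f"S{t.strftime('%Y%m')}_{int(depth):03d}"
            w = np.array([fn(t, depth) for fn in weight_fns], dtype=float)
            if sigma > 0:
                w = w * np.exp(sigma * rng.standard_normal(w.size) - 0.5 * sigma**2)
            w = np.clip(w, 1e-8, None)
            counts = rng.multinomial(total_reads, w / w.sum())
            samples[sid] = counts
            meta_rows.append(
                (sid, (t.to_timestamp() + pd.Timedelta(days=14)), float(depth))
            )
    counts = pd.DataFrame(samples, index=asv_ids)
    taxonomy = pd.Series(taxonomies, index=asv_ids, name="taxonomy")
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "timestamp", "depth_m"]
    ).set_index("sample_id")
    return counts, taxonomy, metadata


def apply_zone_trend(
    grid: TracerGrid,
    zone: tuple,
    rate_per_day: float,
    window: tuple,
) -> TracerGrid:
    """Superimpose a linear biological trend on a depth zone.

    Adds ``rate_per_day`` (tracer units per day) to every node inside
    ``zone = (z_top, z_bottom)`` for months within ``window`` (a pair of
    monthly periods), accumulating linearly from the window start and held
    constant afterwards.  This represents net non-conservative
    production (positive rate, e.g. euphotic photoautotrophy) or removal
    (negative rate, e.g. mesopelagic microbial remineralization of
    exported DOM) and is the ground truth the rate-regression stage
    recovers.  Replicates are rescaled so their multiplicative noise
    factors are preserved.
    """
    start, end = (pd.Period(p, "M") for p in window)
    z = grid.depths
    mask = (z >= zone[0]) & (z < zone[1])
    stamps = grid.times.to_timestamp() + pd.Timedelta(days=14)
    t0 = start.to_timestamp() + pd.Timedelta(days=14)
    t1 = end.to_timestamp() + pd.Timedelta(days=14)
    values = grid.values.copy()
    for j, (per, ts) in enumerate(zip(grid.times, stamps)):
        if per <= start:
            continue
        days = float((min(ts, t1) - t0) / pd.Timedelta(days=1))
        values[mask, j] += rate_per_day * days
    if np.any(values <= 0):
        raise ValueError("zone trend drove concentrations non-positive")
    replicates = None
    if grid.replicates is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.where(grid.values > 0, grid.replicates / grid.values, 1.0)
        replicates = values[None] * factors
    return TracerGrid(grid.analyte, z, grid.times, values, replicates, grid.units)


# --- packaged synthetic DOM composition endmembers -------------------------

# Synthetic endmember mole-percent compositions (labelled synthetic: these
# are NOT literature reference statistics).  "Fresh" mimics plankton-like
# material; "degraded" is glycine-enriched as diagenesis leaves behind.
_FRESH = {
    "Asp": 12.0, "Glu": 12.0, "Ser": 9.0, "Gly": 18.0, "Ala": 12.0,
    "Thr": 6.0, "Val": 7.0, "Leu": 8.0, "Ile": 5.0, "Lys": 4.0,
    "Arg": 4.0, "Tyr": 3.0,
}
_DEGRADED = {
    "Asp": 13.0, "Glu": 8.0, "Ser": 10.0, "Gly": 30.0, "Ala": 14.0,
    "Thr": 5.0, "Val": 5.0, "Leu": 4.0, "Ile": 3.0, "Lys": 3.0,
    "Arg": 3.0, "Tyr": 2.0,
}


def synthetic_reference_table() -> pd.DataFrame:
    """Synthetic DI reference statistics spanning the two endmembers.

    AVG is the endmember midpoint, STD half the endmember separation
    (floored at 0.5 mole %), and the factor coefficient is +-1/sqrt(n)
    signed toward the fresh endmember, so DI is ~+1 for fresh material and
    ~-1 for degraded material.  For analysis of real data supply a
    literature-derived table instead.
    """
    aas = list(_FRESH)
    n = len(aas)
    rows = []
    for aa in aas:
        f, d = _FRESH[aa], _DEGRADED[aa]
        avg = (f + d) / 2.0
        std = max(abs(f - d) / 2.0, 0.5)
        coef = np.sign(f - d) / np.sqrt(n)
        rows.append((aa, avg, std, coef))
    return pd.DataFrame(
        rows, columns=["amino_acid", "avg_molepct", "std_molepct", "fac_coef"]
    ).set_index("amino_acid")


def default_events(config: SimulationConfig) -> list[EventSpec]:
    """Ground-truth events used by the packaged end-to-end fixtures."""
    start, end = config.window_periods
    return [
        EventSpec("metab_A", end, 60.0),          # production at max mixing
        EventSpec("metab_B", end, -45.0),         # loss at max mixing
        EventSpec("DOC", end - 1, 400.0),         # mmol C m^-2 pulse
    ]


def default_responders() -> list[ResponderSpec]:
    """Planted responders with lags in the reliably recoverable 1-2 month range.

    Longer lags are legitimate responder behaviour but interact badly with
    the dual enrichment criteria at monthly cadence: a taxon lagging three
    or more months behind a driver that only starts rising mid-winter has
    not yet responded at maximal mixing, so its mixed-layer
    maximal-mixing-vs-pre-mixing comparison is decided by noise.
    """
    return [
        ResponderSpec(
            "ASV_sar11", -1, 0.025,
            taxonomy="Bacteria;Proteobacteria;Alphaproteobacteria;SAR11 clade;Ia",
        ),
        ResponderSpec(
            "ASV_sar202", -2, 0.020,
            taxonomy="Bacteria;Chloroflexi;Dehalococcoidia;SAR202 clade",
        ),
        ResponderSpec(
            "ASV_flavo", -2, 0.030,
            taxonomy="Bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;NS4 marine group",
        ),
    ]


def _doc_initial(config: SimulationConfig) -> np.ndarray:
    z = config.depth_grid
    return 45.0 + 20.0 * np.exp(-z / 120.0)  # umol C / L


def generate_dataset(
    config: SimulationConfig,
    events: list[EventSpec] | None = None,
    responders: list[ResponderSpec] | None = None,
    n_null_taxa: int = 20,
):
    """Full synthetic study: hydrography, tracers, amino acids, community.

    Returns a dict with the MLD series, hydrography dataset, tracer grids
    (DOC, bacterioplankton abundance, two metabolites), a long amino-acid
    replicate table, the community triple, and the ground truth
    (events, responders).
    """
    events = default_events(config) if events is None else events
    responders = default_responders() if responders is None else responders
    mld = simulate_seasonal_mld(config)
    hydro = simulate_hydrography(mld, config)

    z = config.depth_grid
    doc = simulate_conservative_tracer(
        _doc_initial(config), mld, events, config, analyte="DOC"
    )
    # Post-restratification biology: euphotic net production and mesopelagic
    # removal of the exported DOC (ground truth for the rate regressions),
    # at the observed order of tens of nmol C L^-1 d^-1.
    _, win_end = config.window_periods
    trend_window = (win_end, min(win_end + 4, config.times[-1]))
    truth_rates = {
        "DOC:euphotic": 24.0,    # nmol L^-1 d^-1 net production
        "DOC:mesopelagic": -30.0,  # net removal
    }
    doc = apply_zone_trend(doc, (0.0, 120.0), 24e-3, trend_window)
    doc = apply_zone_trend(doc, (120.0, 300.0), -30e-3, trend_window)
    ba = simulate_conservative_tracer(
        (5.0 + 4.0 * np.exp(-z / 100.0)) * 1e5, mld, events, config,
        analyte="BA", units="cells/mL",
    )
    metab_a = simulate_conservative_tracer(
        2.0 + 1.0 * np.exp(-z / 150.0), mld, events, config, analyte="metab_A"
    )
    metab_b = simulate_conservative_tracer(
        1.5 + 0.8 * np.exp(-z / 150.0), mld, events, config, analyte="metab_B"
    )

    amino = _simulate_amino_acids(config, mld)

    start, end = config.window_periods
    meso_mask = (z >= 120.0) & (z < 300.0)
    doc_meso = pd.Series(doc.values[meso_mask].mean(axis=0), index=config.times)
    counts, taxonomy, metadata = simulate_community(
        doc_meso, responders, n_null_taxa, config, mld_series=mld
    )
    return {
        "config": config,
        "mld": mld,
        "hydrography": hydro,
        "tracers": {g.analyte: g for g in (doc, ba, metab_a, metab_b)},
        "amino_acids": amino,
        "doc_meso_series": doc_meso,
        "community": (counts, taxonomy, metadata),
        "events": events,
        "responders": responders,
        "truth_rates_nmol_L_d": truth_rates,
        "trend_window": trend_window,
    }


def _simulate_amino_acids(config: SimulationConfig, mld: pd.Series) -> pd.DataFrame:
    """Long replicate table of per-amino-acid concentrations.

    Total TDAA follows a surface-enriched profile homogenized like any
    conservative tracer; the composition blends the fresh endmember in the
    surface (and down the mixed layer during deep mixing) toward the
    degraded endmember at depth, so the degradation index decreases with
    depth and rises in the mesopelagic during export.
    """
    total = simulate_conservative_tracer(
        0.25 + 0.55 * np.exp(-config.depth_grid / 100.0),
        mld, [], config, analyte="TDAA",
    )
    _, win_end = config.window_periods
    trend_window = (win_end, min(win_end + 4, config.times[-1]))
    total = apply_zone_trend(total, (0.0, 120.0), 0.05e-3, trend_window)
    total = apply_zone_trend(total, (120.0, 300.0), -0.175e-3, trend_window)
    z = config.depth_grid
    aas = list(_FRESH)
    fresh = np.array([_FRESH[a] for a in aas]) / 100.0
    degr = np.array([_DEGRADED[a] for a in aas]) / 100.0
    rng = config.rng(303)
    sigma = float(np.sqrt(np.log(1.0 + config.noise_cv**2))) if config.noise_cv else 0.0
    rows = []
    stamps = config.times.to_timestamp() + pd.Timedelta(days=14)
    sample_depths = np.array([0.0, 40.0, 80.0, 120.0, 160.0, 200.0, 250.0, 300.0, 400.0])
    for j, t in enumerate(config.times):
        h = float(mld.iloc[j])
        for depth in sample_depths:
            # Fresh fraction: high in the surface, extended down during mixing.
            f = float(np.exp(-depth / 110.0))
            if depth <= h:
                f = max(f, 0.8)
            comp = f * fresh + (1.0 - f) * degr
            i = int(np.argmin(np.abs(z - depth)))
            conc = total.values[i, j] * comp
            for rep in range(1, config.n_replicates + 1):
                noise = (
                    np.exp(sigma * rng.standard_normal(len(aas)) - 0.5 * sigma**2)
                    if sigma > 0
                    else np.ones(len(aas))
                )
                for aa, cval, nval in zip(aas, conc, noise):
                    rows.append((stamps[j], depth, aa, rep, float(cval * nval)))
    return pd.DataFrame(
        rows,
        columns=["timestamp", "depth_m", "amino_acid", "replicate", "concentration_umol_L"],
    )


def write_fixtures(outdir, config: SimulationConfig, dataset=None) -> dict:
    """Write the synthetic study to the pipeline's CSV/TSV schemas.

    Emits profile and bottle CSVs, the amino-acid replicate CSV, ASV
    counts/taxonomy/metadata tables, the synthetic DI reference table, and
    ground-truth sidecars for tests.  Returns the path map.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = dataset or generate_dataset(config)
    hydro = ds["hydrography"]

    prof_rows = []
    var_units = {
        "temperature": "degC", "salinity": "psu", "oxygen": "umol/L",
        "chlorophyll": "RFU", "sigma_theta": "kg/m^3",
    }
    for var, units in var_units.items():
        arr = hydro[var].values
        for j, ts in enumerate(pd.DatetimeIndex(hydro["time"].values)):
            for i, depth in enumerate(hydro["depth"].values):
                prof_rows.append((ts, float(depth), var, float(arr[i, j]), units))
    profiles = pd.DataFrame(
        prof_rows, columns=["timestamp", "depth_m", "variable", "value", "units"]
    )

    bottle_rows = []
    for grid in ds["tracers"].values():
        stamps = grid.times.to_timestamp() + pd.Timedelta(days=14)
        reps = grid.replicates if grid.replicates is not None else grid.values[None]
        for r in range(reps.shape[0]):
            for j, ts in enumerate(stamps):
                for i, depth in enumerate(grid.depths):
                    bottle_rows.append(
                        (ts, float(depth), grid.analyte, r + 1,
                         float(reps[r, i, j]), grid.units)
                    )
    bottle = pd.DataFrame(
        bottle_rows,
        columns=["timestamp", "depth_m", "variable", "replicate", "value", "units"],
    )

    counts, taxonomy, metadata = ds["community"]
    paths = {
        "profiles": out / "profiles.csv",
        "bottle": out / "bottle.csv",
        "amino_acids": out / "amino_acids.csv",
        "asv_counts": out / "asv_counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "sample_metadata": out / "sample_metadata.csv",
        "di_reference": out / "di_reference_synthetic.csv",
        "truth_events": out / "ground_truth_events.csv",
        "truth_responders": out / "ground_truth_responders.csv",
    }
    fmt = "%.10g"
    profiles.to_csv(paths["profiles"], index=False, float_format=fmt)
    bottle.to_csv(paths["bottle"], index=False, float_format=fmt)
    ds["amino_acids"].to_csv(paths["amino_acids"], index=False, float_format=fmt)
    counts.rename_axis("asv_id").to_csv(paths["asv_counts"], sep="\t")
    taxonomy.rename_axis("asv_id").to_frame().to_csv(paths["taxonomy"], sep="\t")
    metadata.reset_index().to_csv(paths["sample_metadata"], index=False)
    synthetic_reference_table().reset_index().to_csv(
        paths["di_reference"], index=False, float_format=fmt
    )
    pd.DataFrame(
        [(e.analyte, str(e.time), e.magnitude, e.z_bottom) for e in ds["events"]],
        columns=["analyte", "time", "magnitude_areal", "z_bottom_m"],
    ).to_csv(paths["truth_events"], index=False)
    pd.DataFrame(
        [
            (r.asv_id, r.lag_months, r.response_amplitude,
             r.depth_zone[0], r.depth_zone[1], r.taxonomy)
            for r in ds["responders"]
        ],
        columns=["asv_id", "lag_months", "response_amplitude", "zone_top_m",
                 "zone_bottom_m", "taxonomy"],
    ).to_csv(paths["truth_responders"], index=False)
    return {k: str(v) for k, v in paths.items()}
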