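"""Accumulation/removal rates, convective export flux, and correlations.

Net production (euphotic zone) and removal (upper mesopelagic) rates of
DOC and TDAA-C are the ordinary-least-squares slopes of depth-zone mean
concentration against time over a stated window, reported in
nmol L^-1 d^-1.  The annual convective DOC export flux is, by default, the
difference between mixed-period and other-period mean mesopelagic
concentrations times the zone thickness (1 umol L^-1 = 1e-3 mol m^-3),
reported in mol m^-2 per annual mixing event.  Seasonal covariation among
zone-mean variables is summarized with a Spearman rank-correlation matrix
on pairwise-complete observations.

``SARGASSO_RATE_TABLE`` holds the published BATS 2016-2017 field estimates
(concentration change, duration, rate, fit quality) used for arithmetic
consistency checks; they are inputs, not outputs of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hydrography import DepthZone, MESOPELAGIC_ZONE

__all__ = [
    "RateEstimate",
    "ExportFlux",
    "SARGASSO_RATE_TABLE",
    "rate_regression",
    "export_flux",
    "correlation_matrix",
    "rate_consistency",
]


@dataclass(frozen=True)
class RateEstimate:
    zone: str
    analyte: str
    window: tuple
    duration_days: float
    delta: float        # fitted concentration change over the window, umol L^-1
    slope: float        # nmol L^-1 d^-1
    r_squared: float
    n: int


@dataclass(frozen=True)
class ExportFlux:
    zone: DepthZone
    flux: float         # mol m^-2 per annual mixing event
    mode: str
    mixed_mean: float   # umol L^-1
    other_mean: float   # umol L^-1


# Published seasonal field estimates for the northwestern Sargasso Sea
# (BATS site, April-August 2017): concentration changes over the window,
# regression rates, R^2 and point counts, as printed (two significant
# figures for deltas; rates to the printed decimal).
SARGASSO_RATE_TABLE = pd.DataFrame(
    [
        ("euphotic", "DOC", 136, 3.2, 1, 24.0, 0, 0.43, 9),
        ("mesopelagic", "DOC", 136, 4.0, 1, 30.0, 0, 0.49, 9),
        ("euphotic", "TDAA-C", 136, 0.03, 2, 0.2, 1, 0.10, 6),
        ("mesopelagic", "TDAA-C", 136, 0.10, 2, 0.7, 1, 0.60, 6),
    ],
    columns=[
        "zone", "analyte", "duration_days",
        "delta_umol_L", "delta_decimals",
        "rate_nmol_L_d", "rate_decimals",
        "r_squared", "n",
    ],
)


def rate_regression(series: pd.Series, window, zone: str = "", analyte: str = "") -> RateEstimate:
    """OLS rate of change of a zone-mean concentration series.

    ``series`` is timestamp-indexed in umol L^-1; ``window`` is a
    (start, end) pair of timestamps (inclusive).  The slope is regressed
    against days since the window start and reported in nmol L^-1 d^-1;
    ``delta`` is the fitted change over the full window duration.
    """
    start, end = (pd.Timestamp(w) for w in window)
    if not start < end:
        raise ValueError("window start must precede end")
    s = series.dropna()
    idx = pd.DatetimeIndex(s.index)
    mask = (idx >= start) & (idx <= end)
    s = s[mask]
    if len(s) < 2:
        raise ValueError("need at least two points inside the window")
    t_days = (pd.DatetimeIndex(s.index) - start) / pd.Timedelta(days=1)
    if np.ptp(t_days) == 0:
        raise ValueError("zero time span inside the window")
    fit = stats.linregress(np.asarray(t_days, dtype=float), s.to_numpy(dtype=float))
    duration = float((end - start) / pd.Timedelta(days=1))
    return RateEstimate(
        zone=zone,
        analyte=analyte,
        window=(start, end),
        duration_days=duration,
        delta=float(fit.slope * duration),
        slope=float(fit.slope * 1000.0),
        r_squared=float(fit.rvalue**2),
        n=int(len(s)),
    )


def export_flux(
    zone_mean_series: pd.Series,
    season_series: pd.Series,
    zone: DepthZone = MESOPELAGIC_ZONE,
    mode: str = "period-mean-difference",
    mixed_label: str = "Mixed",
) -> ExportFlux:
    """Annual convective export into a depth zone, mol m^-2.

    Default mode: (mean zone concentration during the mixed season - mean
    during all other seasons) x zone thickness, with umol L^-1 converted
    via 1 umol L^-1 = 1e-3 mol m^-3.  Both periods must contain data.
    """
    if mode != "period-mean-difference":
        raise ValueError(f"unknown export-flux mode {mode!r}")
    s = pd.Series(zone_mean_series).astype(float)
    lab = pd.Series(season_series).reindex(s.index)
    mixed = s[lab == mixed_label].dropna()
    other = s[(lab != mixed_label) & lab.notna()].dropna()
    if mixed.empty or other.empty:
        raise ValueError("both the mixed period and the other period need data")
    m, o = float(mixed.mean()), float(other.mean())
    flux = (m - o) * 1e-3 * zone.thickness
    return ExportFlux(zone=zone, flux=float(flux), mode=mode, mixed_mean=m, other_mean=o)


def correlation_matrix(
    frame: pd.DataFrame, method: str = "spearman", min_overlap: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-correlation matrix with p-values on pairwise-complete data.

    Entries with fewer than ``min_overlap`` overlapping points or a
    constant series are NaN.  Returns (rho, p) DataFrames; the diagonal of
    rho is 1.
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    cols = list(frame.columns)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            sub = frame[[a, b]].dropna()
            if len(sub) < min_overlap or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(sub[a], sub[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def rate_consistency(
    delta: float,
    duration_days: float,
    printed_rate: float,
    delta_decimals: int,
    rate_decimals: int,
) -> tuple[float, bool]:
    """Check a printed (delta, duration, rate) triple for arithmetic consistency.

    The computed rate is delta / duration in nmol L^-1 d^-1.  Both printed
    numbers carry rounding half-widths set by their printed precision; the
    triple is consistent when the computed rate lies within the combined
    rounding tolerance of the printed rate.  Returns (computed_rate, ok).
    """
    computed = delta / duration_days * 1000.0
    tol = 0.5 * 10.0 ** (-rate_decimals) + (0.5 * 10.0 ** (-delta_decimals)) / duration_days * 1000.0
    return float(computed), bool(abs(computed - printed_rate) <= tol)
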