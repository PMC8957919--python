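"""Conservative-mixing null model for mixed-layer tracer budgets.

Winter convective mixing homogenizes the mixed layer; a tracer whose
concentration changes are purely physical ("conservative dilution") keeps
its areal inventory unchanged when both of two consecutive profiles are
integrated to the *later* time's mixed layer depth.  Departures from that
1:1 line indicate net production or loss.  The detector:

1. pair consecutive profiles into inventory pairs (both integrated to the
   MLD of the later time point);
2. signed perpendicular distance of each pair to the 1:1 line,
   d = (I_next - I_prev) / sqrt(2), positive on the production side;
3. standardize per analyte (z-score across that analyte's time points);
4. fit a normal distribution to the pooled z-scores and set the flagging
   threshold at its q-quantile (default 0.95);
5. label each analyte/interval production, loss, or mixing-only.

A PERMDISP-style multivariate homogeneity-of-dispersion test is provided
for checking whether one sampling period's multivariate samples disperse
differently from the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hydrography import integrate_inventory

__all__ = [
    "NullModel",
    "GroupDispersionResult",
    "pair_inventories",
    "mixing_deviation",
    "standardize_deviations",
    "null_threshold",
    "flag_production_loss",
    "group_dispersion",
]

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class NullModel:
    mu: float
    sigma: float
    quantile: float
    threshold: float
    n: int


@dataclass(frozen=True)
class GroupDispersionResult:
    statistic: float
    p_value: float
    n_permutations: int
    test: str


def pair_inventories(tracer: pd.DataFrame, mld_series: pd.Series) -> pd.DataFrame:
    """Build per-analyte inventory pairs for consecutive time points.

    ``tracer`` is a long table with columns ``analyte, timestamp, depth_m,
    value`` (replicate-averaged concentrations); ``mld_series`` maps each
    timestamp to an MLD in metres.  For the pair (t, t_next) both profiles
    are integrated from the surface to the MLD at t_next.

    Returns a DataFrame with columns ``analyte, t, t_next, mld_next_m,
    inv_prev, inv_next``; analytes with fewer than two time points yield no
    rows.
    """
    required = {"analyte", "timestamp", "depth_m", "value"}
    missing = required - set(tracer.columns)
    if missing:
        raise ValueError(f"tracer table missing columns: {sorted(missing)}")
    rows = []
    for analyte, grp in tracer.groupby("analyte", sort=False):
        times = sorted(grp["timestamp"].unique())
        profiles = {
            ts: sub.sort_values("depth_m") for ts, sub in grp.groupby("timestamp")
        }
        for t, t_next in zip(times[:-1], times[1:]):
            if t_next not in mld_series.index:
                raise KeyError(f"no MLD available at {t_next}")
            mld_next = float(mld_series.loc[t_next])
            inv = {}
            for label, ts in (("inv_prev", t), ("inv_next", t_next)):
                prof = profiles[ts]
                inv[label] = integrate_inventory(
                    prof["depth_m"].to_numpy(),
                    prof["value"].to_numpy(),
                    0.0,
                    mld_next,
                )
            rows.append((analyte, t, t_next, mld_next, inv["inv_prev"], inv["inv_next"]))
    return pd.DataFrame(
        rows, columns=["analyte", "t", "t_next", "mld_next_m", "inv_prev", "inv_next"]
    )


def mixing_deviation(pairs: pd.DataFrame) -> pd.DataFrame:
    """Signed perpendicular distance of each inventory pair to the 1:1 line.

    d = (inv_next - inv_prev) / sqrt(2); positive means the analyte gained
    inventory beyond conservative mixing (production side).  The vertical
    difference inv_next - inv_prev differs only by the constant sqrt(2) and
    yields identical z-scores downstream.
    """
    out = pairs.copy()
    out["distance"] = (out["inv_next"] - out["inv_prev"]) / SQRT2
    return out


def standardize_deviations(deviations: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte z-scores of the 1:1-line distances.

    z = (d - mean_d) / sd_d with the sample standard deviation (ddof=1),
    computed across each analyte's time intervals.  Analytes with fewer
    than 3 intervals or degenerate variance are dropped and flagged in the
    ``excluded_analytes`` attribute of the result; "degenerate" means the
    distance spread is zero to within floating-point residue of the
    inventory magnitudes (an exactly conservative tracer).
    """
    frames, excluded = [], {}
    for analyte, grp in deviations.groupby("analyte", sort=False):
        d = grp["distance"].to_numpy(dtype=float)
        if d.size < 3:
            excluded[analyte] = "too_few_intervals"
            continue
        sd = float(np.std(d, ddof=1))
        if {"inv_prev", "inv_next"} <= set(grp.columns):
            scale = float(grp[["inv_prev", "inv_next"]].abs().to_numpy().max())
        else:
            scale = float(np.abs(d).max())
        if not np.isfinite(sd) or sd <= 1e-12 * max(scale, 1e-300):
            excluded[analyte] = "degenerate_variance"
            continue
        g = grp.copy()
        g["z"] = (d - float(np.mean(d))) / sd
        frames.append(g)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else deviations.iloc[0:0].assign(z=pd.Series(dtype=float))
    )
    out.attrs["excluded_analytes"] = excluded
    return out


def null_threshold(z_values, q: float = 0.95) -> NullModel:
    """Fit a normal distribution to pooled z-scores and take its q-quantile.

    The fit uses the maximum-likelihood mean with the unbiased standard
    deviation (matching the common statistics-toolbox normal fit).  Fewer
    than 10 pooled values is an error: the tail quantile is unreliable.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 10:
        raise ValueError("need at least 10 pooled z-scores to fit the null")
    mu = float(np.mean(z))
    sigma = float(np.std(z, ddof=1))
    if sigma <= 0:
        raise ValueError("pooled z-scores are degenerate")
    thr = mu + sigma * float(stats.norm.ppf(q))
    return NullModel(mu, sigma, q, thr, int(z.size))


def flag_production_loss(
    standardized: pd.DataFrame, model: NullModel, sidedness: str = "two"
) -> pd.DataFrame:
    """Label each analyte/interval as production, loss, or mixing-only.

    Two-sided (default): production for z above the threshold, loss for z
    below its mirror image 2*mu - threshold.  One-sided reproduces the
    literal single-quantile rule: only exceedances above the threshold are
    flagged, with the sign of the distance deciding production vs loss.
    """
    if sidedness not in ("two", "one"):
        raise ValueError("sidedness must be 'two' or 'one'")
    out = standardized.copy()
    upper = model.threshold
    if sidedness == "two":
        lower = 2.0 * model.mu - model.threshold
        label = np.where(
            out["z"] > upper,
            "production",
            np.where(out["z"] < lower, "loss", "mixing-only"),
        )
    else:
        exceed = out["z"] > upper
        label = np.where(
            exceed & (out["distance"] > 0),
            "production",
            np.where(exceed, "loss", "mixing-only"),
        )
    out["label"] = label
    return out


def group_dispersion(
    dissimilarity: pd.DataFrame | np.ndarray,
    group_labels,
    n_perm: int = 999,
    seed: int = 0,
    test: str = "centroid",
) -> GroupDispersionResult:
    """Multivariate homogeneity of group dispersions (PERMDISP).

    Principal-coordinate embedding of the dissimilarities, per-sample
    distance to the group centroid (or spatial median with
    ``test="median"``), an F statistic on those distances, and a
    permutation p-value.  Negative eigenvalues from non-Euclidean
    dissimilarities are handled by the standard correction in the
    underlying scikit-bio routine.
    """
    from skbio.stats.distance import DistanceMatrix, permdisp

    mat = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(group_labels)
    if mat.shape[0] != mat.shape[1] or mat.shape[0] != labels.size:
        raise ValueError("dissimilarity matrix and labels have mismatched sizes")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")
    # Degenerate case: every group is a set of identical points (all
    # within-group dissimilarities zero).  All centroid distances are zero,
    # the F ratio is 0/0, and no permutation can look more extreme: p = 1.
    if all(
        np.allclose(mat[np.ix_(labels == g, labels == g)], 0.0) for g in uniq
    ):
        return GroupDispersionResult(0.0, 1.0, n_perm, test)
    dm = DistanceMatrix(mat)
    res = permdisp(
        dm,
        labels.tolist(),
        test=test,
        permutations=n_perm,
        seed=seed,
        dimensions=min(10, mat.shape[0] - 1),
    )
    return GroupDispersionResult(
        statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_perm,
        test=test,
    )
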