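"""Water-column structure from profile data.

Mixed layer depth (MLD) from a density criterion, the deep chlorophyll
maximum (DCM) and its layer (DCML, bounded where fluorescence falls to a
fraction of the maximum), the four-season classification driven by the
relative position of the MLD and the chlorophyll layer, oxygen saturation /
AOU, and depth-zone integrals and means.

Depth convention: metres, positive downward; depth zones are half-open
``[z_top, z_bottom)`` for discrete sample membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seawater import (
    compute_aou,
    oxygen_saturation,
    sigma_theta,
    thermal_expansion,
    density,
)

__all__ = [
    "MLDCriterion",
    "MLDResult",
    "ChlorophyllLayer",
    "DepthZone",
    "EUPHOTIC_ZONE",
    "MESOPELAGIC_ZONE",
    "SEASONS",
    "ExtrapolationWarning",
    "compute_mld",
    "detect_dcm_dcml",
    "classify_seasons",
    "oxygen_saturation",
    "compute_aou",
    "integrate_inventory",
    "zone_mean",
]

SEASONS = ("Stratified", "FallTransition", "Mixed", "SpringTransition")


class ExtrapolationWarning(UserWarning):
    """A zone integral extended beyond the sampled depth range."""


@dataclass(frozen=True)
class MLDCriterion:
    """Density-increment MLD criterion.

    In ``density`` mode the sigma-theta threshold is rho * alpha(T_ref,
    S_ref) * delta_T, with alpha from the equation of state at the
    reference depth; ``sigma`` mode applies a user-supplied increment
    directly.
    """

    delta_T: float = 0.2            # deg C
    reference_depth: float = 10.0   # m
    mode: str = "density"           # "density" | "sigma"
    sigma_increment: float | None = None  # kg m^-3, used in sigma mode

    def __post_init__(self):
        if self.delta_T <= 0:
            raise ValueError("delta_T must be positive")
        if self.reference_depth < 0:
            raise ValueError("reference_depth must be >= 0")
        if self.mode not in ("density", "sigma"):
            raise ValueError("mode must be 'density' or 'sigma'")
        if self.mode == "sigma" and (
            self.sigma_increment is None or self.sigma_increment <= 0
        ):
            raise ValueError("sigma mode requires a positive sigma_increment")


@dataclass(frozen=True)
class MLDResult:
    depth: float            # m
    fully_mixed: bool       # no threshold crossing above the deepest sample
    threshold: float        # sigma-theta increment actually applied, kg m^-3
    reference_sigma: float  # sigma-theta at the reference depth


@dataclass(frozen=True)
class ChlorophyllLayer:
    dcm_depth: float
    dcml_top: float
    dcml_bottom: float
    max_value: float
    boundary_fraction: float = 0.35
    clamped_top: bool = False
    clamped_bottom: bool = False

    def __post_init__(self):
        if not (0 < self.boundary_fraction < 1):
            raise ValueError("boundary_fraction must lie in (0, 1)")
        if not (self.dcml_top <= self.dcm_depth <= self.dcml_bottom):
            raise ValueError("layer boundaries must bracket the DCM")


@dataclass(frozen=True)
class DepthZone:
    name: str
    z_top: float
    z_bottom: float
    averaging_mode: str = "inventory"  # "inventory" | "discrete"

    def __post_init__(self):
        if not self.z_top < self.z_bottom:
            raise ValueError("z_top must be shallower than z_bottom")
        if self.averaging_mode not in ("inventory", "discrete"):
            raise ValueError("averaging_mode must be 'inventory' or 'discrete'")

    @property
    def thickness(self) -> float:
        return self.z_bottom - self.z_top

    def contains(self, depths) -> np.ndarray:
        z = np.asarray(depths, dtype=float)
        return (z >= self.z_top) & (z < self.z_bottom)


EUPHOTIC_ZONE = DepthZone("euphotic", 0.0, 120.0)
MESOPELAGIC_ZONE = DepthZone("mesopelagic", 120.0, 300.0)


def _check_profile(depth, values, name="profile"):
    z = np.asarray(depth, dtype=float)
    v = np.asarray(values, dtype=float)
    if z.ndim != 1 or z.shape != v.shape:
        raise ValueError(f"{name}: depth and values must be matching 1-D arrays")
    if z.size < 2:
        raise ValueError(f"{name}: need at least two samples")
    if np.any(np.diff(z) <= 0):
        raise ValueError(f"{name}: depths must be strictly increasing")
    return z, v


def compute_mld(
    depth,
    sigma=None,
    temperature=None,
    salinity=None,
    criterion: MLDCriterion | None = None,
) -> MLDResult:
    """Mixed layer depth from a sigma-theta increment criterion.

    The MLD is the shallowest depth below the reference depth where
    sigma-theta exceeds its reference-depth value by the threshold
    increment, linearly interpolated between the bracketing samples.  If no
    crossing exists the column is flagged fully mixed and the deepest
    sample depth is returned.

    Either ``sigma`` or both ``temperature`` and ``salinity`` must be
    supplied; density mode needs T and S at the reference depth to evaluate
    the thermal expansion coefficient.
    """
    criterion = criterion or MLDCriterion()
    have_ts = temperature is not None and salinity is not None
    if sigma is None:
        if not have_ts:
            raise ValueError("supply sigma, or temperature and salinity")
        zt, t = _check_profile(depth, temperature, "temperature")
        _, s = _check_profile(depth, salinity, "salinity")
        sig = sigma_theta(t, s)
        z = zt
    else:
        z, sig = _check_profile(depth, sigma, "sigma")
    if not np.all(np.isfinite(sig)):
        raise ValueError("profile values must be finite")
    z_ref = criterion.reference_depth
    if z[0] > z_ref:
        raise ValueError(
            f"profile must include a sample at or above the reference depth ({z_ref} m)"
        )
    sig_ref = float(np.interp(z_ref, z, sig))

    if criterion.mode == "sigma":
        thr = float(criterion.sigma_increment)
    else:
        if not have_ts:
            raise ValueError("density mode requires temperature and salinity profiles")
        t_ref = float(np.interp(z_ref, z, np.asarray(temperature, dtype=float)))
        s_ref = float(np.interp(z_ref, z, np.asarray(salinity, dtype=float)))
        alpha = float(thermal_expansion(t_ref, s_ref))
        thr = float(density(t_ref, s_ref)) * alpha * criterion.delta_T

    target = sig_ref + thr
    below = z > z_ref
    idx = np.flatnonzero(below & (sig >= target))
    if idx.size == 0:
        return MLDResult(float(z[-1]), True, thr, sig_ref)
    i = idx[0]
    # Bracket: previous sample, or the reference point itself.
    if i == 0 or z[i - 1] <= z_ref:
        z0, s0 = z_ref, sig_ref
    else:
        z0, s0 = z[i - 1], sig[i - 1]
    if sig[i] == s0:
        mld = float(z[i])
    else:
        mld = float(z0 + (target - s0) * (z[i] - z0) / (sig[i] - s0))
    return MLDResult(mld, False, thr, sig_ref)


def detect_dcm_dcml(
    depth, chlorophyll, boundary_fraction: float = 0.35
) -> ChlorophyllLayer:
    """Locate the deep chlorophyll maximum and its layer boundaries.

    The DCM is the depth of the (first) profile maximum; the layer
    boundaries are the interpolated depths nearest above and below the DCM
    where the signal falls to ``boundary_fraction`` of the maximum.  A
    boundary never crossed is clamped to the profile end and flagged.
    """
    z, chl = _check_profile(depth, chlorophyll, "chlorophyll")
    if not (0 < boundary_fraction < 1):
        raise ValueError("boundary_fraction must lie in (0, 1)")
    finite = np.isfinite(chl)
    if not finite.any() or np.nanmax(chl) <= 0:
        raise ValueError("no positive chlorophyll maximum in profile")
    chl = np.where(finite, chl, -np.inf)
    i_max = int(np.argmax(chl))
    c_max = float(chl[i_max])
    target = boundary_fraction * c_max

    def _cross(i_from: int, step: int) -> tuple[float, bool]:
        j = i_from
        while 0 <= j + step < z.size:
            k = j + step
            if chl[k] <= target:
                # Linear interpolation between samples j and k.
                if chl[k] == chl[j]:
                    return float(z[k]), False
                frac = (chl[j] - target) / (chl[j] - chl[k])
                return float(z[j] + frac * (z[k] - z[j])), False
            j = k
        return float(z[0] if step < 0 else z[-1]), True

    top, clamp_top = _cross(i_max, -1)
    bottom, clamp_bot = _cross(i_max, +1)
    return ChlorophyllLayer(
        dcm_depth=float(z[i_max]),
        dcml_top=top,
        dcml_bottom=bottom,
        max_value=c_max,
        boundary_fraction=boundary_fraction,
        clamped_top=clamp_top,
        clamped_bottom=clamp_bot,
    )


def classify_seasons(
    mld_series: pd.Series,
    layer_series: pd.DataFrame,
    persistence: int = 2,
) -> pd.Series:
    """Label each time point with one of the four hydrographic seasons.

    State machine driven by the MLD relative to the chlorophyll layer
    (``layer_series`` columns ``dcm_m`` and ``dcml_top_m``, aligned to
    ``mld_series``):

    * Stratified -> FallTransition when the MLD first reaches below the top
      of the DCML;
    * FallTransition -> Mixed when the MLD reaches below the DCM;
    * Mixed -> SpringTransition when the MLD shoals back above the DCM;
    * SpringTransition -> Stratified once the MLD has remained above the
      DCML top for ``persistence`` consecutive observations.

    Transitions cascade within a single time step (a jump past both
    thresholds in one step lands in Mixed).  Missing layer data carries the
    previous label forward with a warning.
    """
    if len(mld_series) < 3:
        raise ValueError("need at least three time points")
    if not mld_series.index.equals(layer_series.index):
        raise ValueError("mld_series and layer_series must share an index")
    labels = []
    state = None
    run_above = 0  # consecutive points with MLD above the DCML top
    for ts, mld in mld_series.items():
        dcm = layer_series.at[ts, "dcm_m"]
        top = layer_series.at[ts, "dcml_top_m"]
        if not np.isfinite(mld) or not np.isfinite(dcm) or not np.isfinite(top):
            if state is None:
                raise ValueError(f"missing layer data at first time point {ts}")
            warnings.warn(
                f"missing MLD/layer data at {ts}; carrying season forward",
                UserWarning,
                stacklevel=2,
            )
            labels.append(state)
            continue
        if state is None:
            if mld > dcm:
                state = "Mixed"
            elif mld > top:
                state = "FallTransition"
            else:
                state = "Stratified"
        # Cascade transitions until stable for this observation.
        while True:
            if state == "Stratified" and mld > top:
                state = "FallTransition"
            elif state == "FallTransition" and mld > dcm:
                state = "Mixed"
            elif state == "Mixed" and mld < dcm:
                state = "SpringTransition"
                run_above = 0
            else:
                break
        if state == "SpringTransition":
            run_above = run_above + 1 if mld < top else 0
            if run_above >= persistence:
                state = "Stratified"
        labels.append(state)
    return pd.Series(labels, index=mld_series.index, name="season")


def integrate_inventory(depth, values, z_top: float, z_bottom: float) -> float:
    """Trapezoidal areal inventory of a profile over ``[z_top, z_bottom]``.

    Concentrations are linearly interpolated between samples and held
    constant beyond the shallowest/deepest sample (constant extrapolation,
    flagged with :class:`ExtrapolationWarning`).  For concentrations in
    umol L^-1 the result is in mmol m^-2 (1 umol L^-1 = 1 mmol m^-3).
    """
    z, v = _check_profile(depth, values, "profile")
    if not z_top < z_bottom:
        raise ValueError("z_top must be shallower than z_bottom")
    if z_bottom <= z[0] or z_top >= z[-1]:
        raise ValueError("zone lies entirely outside the sampled depth range")
    if z_top < z[0] or z_bottom > z[-1]:
        warnings.warn(
            f"zone [{z_top}, {z_bottom}] m extends beyond samples "
            f"[{z[0]}, {z[-1]}] m; constant extrapolation applied",
            ExtrapolationWarning,
            stacklevel=2,
        )
    inside = z[(z > z_top) & (z < z_bottom)]
    grid = np.concatenate(([z_top], inside, [z_bottom]))
    vals = np.interp(grid, z, v)  # np.interp clamps at the ends
    return float(np.trapezoid(vals, grid))


def zone_mean(depth, values, zone: DepthZone) -> float:
    """Depth-zone mean of a profile.

    ``inventory`` mode divides the trapezoidal inventory by the zone
    thickness (the convention for concentration-type variables);
    ``discrete`` mode averages the samples inside the half-open zone (the
    convention for temperature, DI, AOU, and relative abundance).
    """
    if zone.averaging_mode == "inventory":
        return integrate_inventory(depth, values, zone.z_top, zone.z_bottom) / zone.thickness
    z = np.asarray(depth, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = zone.contains(z) & np.isfinite(v)
    if not mask.any():
        raise ValueError(f"no samples inside zone {zone.name}")
    return float(np.mean(v[mask]))
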