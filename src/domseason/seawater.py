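"""Seawater physical properties at atmospheric pressure.

Surface density (sigma-theta), the thermal expansion coefficient, oxygen
solubility, and apparent oxygen utilization (AOU).  Density follows the
UNESCO 1983 one-atmosphere equation of state (EOS-80); oxygen solubility
follows the Garcia & Gordon (1992) refit of the Benson & Krause data.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "density",
    "sigma_theta",
    "thermal_expansion",
    "oxygen_saturation",
    "compute_aou",
]

# Valid ranges enforced for the oxygen solubility fit.
_T_MIN, _T_MAX = -2.0, 40.0
_S_MIN, _S_MAX = 0.0, 42.0


def density(temperature, salinity):
    """Seawater density at 0 dbar, kg m^-3 (UNESCO 1983 polynomial).

    Parameters
    ----------
    temperature : array_like
        In-situ temperature, deg C (ITS-68 vs ITS-90 differences are far
        below the precision relevant here).
    salinity : array_like
        Practical salinity, psu.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


def sigma_theta(temperature, salinity):
    """Potential density anomaly referenced to the surface, kg m^-3.

    At 0 dbar potential temperature equals in-situ temperature, so this is
    simply ``density - 1000``.
    """
    return density(temperature, salinity) - 1000.0


def thermal_expansion(temperature, salinity, dt: float = 1e-3):
    """Thermal expansion coefficient alpha = -(1/rho) d(rho)/dT, 1/degC.

    Central finite difference of the EOS-80 polynomial; ``dt`` is the
    half-width of the difference stencil in deg C.
    """
    rho = density(temperature, salinity)
    t = np.asarray(temperature, dtype=float)
    drho = (density(t + dt, salinity) - density(t - dt, salinity)) / (2.0 * dt)
    return -drho / rho


# Garcia & Gordon (1992) coefficients, Benson & Krause fit, umol kg^-1 basis.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def oxygen_saturation(temperature, salinity, basis: str = "umol_L"):
    """Oxygen solubility at one atmosphere of water-saturated air.

    Parameters
    ----------
    temperature, salinity : array_like
        deg C and psu; valid over T in [-2, 40], S in [0, 42].
    basis : {"umol_L", "umol_kg"}
        Volumetric basis (default, matching bottle concentration units;
        converted with the surface density) or gravimetric.

    Returns
    -------
    ndarray or float
        Saturation concentration in the requested basis.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if np.any(t < _T_MIN) or np.any(t > _T_MAX):
        raise ValueError(f"temperature outside [{_T_MIN}, {_T_MAX}] degC")
    if np.any(s < _S_MIN) or np.any(s > _S_MAX):
        raise ValueError(f"salinity outside [{_S_MIN}, {_S_MAX}] psu")

    ts = np.log((298.15 - t) / (273.15 + t))
    a0, a1, a2, a3, a4, a5 = _GG_A
    b0, b1, b2, b3 = _GG_B
    ln_c = (
        a0 + a1 * ts + a2 * ts**2 + a3 * ts**3 + a4 * ts**4 + a5 * ts**5
        + s * (b0 + b1 * ts + b2 * ts**2 + b3 * ts**3)
        + _GG_C0 * s**2
    )
    o2_umol_kg = np.exp(ln_c)
    if basis == "umol_kg":
        out = o2_umol_kg
    elif basis == "umol_L":
        out = o2_umol_kg * density(t, s) / 1000.0
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return out if out.ndim else float(out)


def compute_aou(temperature, salinity, o2_observed, basis: str = "umol_L"):
    """Apparent oxygen utilization: saturation minus observed oxygen.

    ``o2_observed`` must be on the same unit basis as requested; positive
    AOU indicates net oxygen consumption since last atmospheric contact.
    """
    o2 = np.asarray(o2_observed, dtype=float)
    if np.any(o2 < 0):
        raise ValueError("observed oxygen must be non-negative")
    out = oxygen_saturation(temperature, salinity, basis=basis) - o2
    return out if np.ndim(out) else float(out)
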