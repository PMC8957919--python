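"""Dissolved amino-acid composition and the DOM degradation index.

The degradation index (DI) is a weighted sum of standardized amino-acid
mole percentages,

    DI = sum_i ((var_i - AVG_i) / STD_i) * coef_i,

where var_i is the mole percent of amino acid i in the dissolved pool,
AVG_i / STD_i are its reference mean and standard deviation, and coef_i is
its factor coefficient from a principal-component analysis of degradation
gradients.  Lower DI means more diagenetically altered (degraded) material.
The reference statistics are inputs (a CSV table), not package constants.

Also here: replicate quality control (coefficient-of-variation screen) and
TDAA carbon from per-amino-acid stoichiometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CARBON_ATOMS",
    "DEFAULT_EXCLUDED",
    "QCResult",
    "replicate_qc",
    "replicate_qc_table",
    "tdaa_carbon",
    "mole_percent",
    "degradation_index",
    "load_reference_table",
]

# Carbon atoms per molecule, from the standard molecular formulas.
CARBON_ATOMS: dict[str, int] = {
    "Ala": 3, "Arg": 6, "Asn": 4, "Asp": 4, "Cys": 3, "Gln": 5, "Glu": 5,
    "Gly": 2, "His": 6, "Ile": 6, "Leu": 6, "Lys": 6, "Met": 5, "Phe": 9,
    "Pro": 5, "Ser": 3, "Thr": 4, "Trp": 11, "Tyr": 9, "Val": 5,
    # Non-protein amino acids common in hydrolysate panels.
    "GABA": 4, "bAla": 3,
}

# Phenylalanine co-elutes with an interfering peak in many seawater
# chromatograms and contributes <3% of TDAA in oligotrophic gyres, so it is
# excluded from composition work by default.
DEFAULT_EXCLUDED = frozenset({"Phe"})


@dataclass(frozen=True)
class QCResult:
    mean: float
    cv: float
    kept: bool
    flag: str = ""  # "", "high_cv", "zero_mean"


def replicate_qc(replicates, cv_max: float = 0.20) -> QCResult:
    """Screen a replicate set by its coefficient of variation.

    Replicate sets with CV strictly greater than ``cv_max`` are excluded
    (the boundary CV == cv_max is kept).  CV uses the sample standard
    deviation (ddof=1).
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two replicates")
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if m == 0.0:
        if sd > 0.0:
            return QCResult(m, np.inf, False, "zero_mean")
        return QCResult(0.0, 0.0, True)
    cv = abs(sd / m)
    if cv > cv_max:
        return QCResult(m, cv, False, "high_cv")
    return QCResult(m, cv, True)


def replicate_qc_table(
    df: pd.DataFrame,
    value_col: str = "value",
    group_cols=("timestamp", "depth_m", "variable"),
    cv_max: float = 0.20,
) -> tuple[pd.DataFrame, float]:
    """Apply :func:`replicate_qc` per group of a long replicate table.

    Returns the table of kept group means plus the excluded fraction.
    Groups with a single replicate are kept as-is (nothing to screen).
    """
    rows, n_excluded, n_groups = [], 0, 0
    for key, grp in df.groupby(list(group_cols), sort=False):
        n_groups += 1
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size < 2:
            rows.append((*key, float(vals[0]), 0.0, True, "single"))
            continue
        qc = replicate_qc(vals, cv_max=cv_max)
        if not qc.kept:
            n_excluded += 1
        rows.append((*key, qc.mean, qc.cv, qc.kept, qc.flag))
    out = pd.DataFrame(rows, columns=[*group_cols, "mean", "cv", "kept", "flag"])
    frac = n_excluded / n_groups if n_groups else 0.0
    return out, frac


def _split_panel(panel: pd.Series, excluded) -> tuple[pd.Series, set]:
    conc = pd.Series(panel, dtype=float)
    if (conc < 0).any():
        raise ValueError("amino-acid concentrations must be non-negative")
    excl = set(DEFAULT_EXCLUDED if excluded is None else excluded)
    return conc, excl


def tdaa_carbon(panel: pd.Series, excluded=None, carbon_atoms=None) -> float:
    """Total dissolved amino-acid carbon, umol C L^-1.

    Sum of concentration x carbon atoms over the non-excluded amino acids
    (pass ``excluded=()`` to include everything, e.g. to count Phe carbon).
    """
    conc, excl = _split_panel(panel, excluded)
    table = CARBON_ATOMS if carbon_atoms is None else carbon_atoms
    total = 0.0
    for aa, c in conc.items():
        if aa in excl:
            continue
        if aa not in table:
            raise KeyError(f"no carbon stoichiometry for amino acid {aa!r}")
        total += c * table[aa]
    return float(total)


def mole_percent(panel: pd.Series, excluded=None) -> pd.Series:
    """Mole percent of each included amino acid (sums to 100).

    Excluded amino acids are dropped and the remainder renormalized.
    """
    conc, excl = _split_panel(panel, excluded)
    included = conc.drop(labels=[a for a in conc.index if a in excl])
    if included.size < 1:
        raise ValueError("no included amino acids")
    total = included.sum()
    if total <= 0:
        raise ValueError("total included concentration must be positive")
    out = 100.0 * included / total
    out.name = "mole_percent"
    return out


def degradation_index(composition: pd.Series, reference: pd.DataFrame) -> float:
    """Evaluate the degradation index for one composition vector.

    ``composition`` holds mole percents (as from :func:`mole_percent`);
    ``reference`` is indexed by amino acid with columns ``avg_molepct``,
    ``std_molepct``, ``fac_coef``.
    """
    missing = [aa for aa in composition.index if aa not in reference.index]
    if missing:
        raise KeyError(f"amino acids missing from reference table: {missing}")
    ref = reference.loc[composition.index]
    std = ref["std_molepct"].to_numpy(dtype=float)
    if np.any(std <= 0):
        raise ValueError("reference std_molepct must be strictly positive")
    z = (composition.to_numpy(dtype=float) - ref["avg_molepct"].to_numpy(dtype=float)) / std
    return float(np.sum(z * ref["fac_coef"].to_numpy(dtype=float)))


def load_reference_table(path) -> pd.DataFrame:
    """Read a DI reference table CSV (amino_acid, avg_molepct, std_molepct, fac_coef)."""
    df = pd.read_csv(Path(path))
    required = {"amino_acid", "avg_molepct", "std_molepct", "fac_coef"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    return df.set_index("amino_acid")
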