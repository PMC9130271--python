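"""Ecophysiological energetics: thermoregulatory effectiveness, metabolic
scaling, the SVL-to-mass allometry, and mass-specific reproductive production.

Thermoregulatory effectiveness follows the Hertz index

    E = 1 - db_bar / de_bar,

where db_bar is the mean deviation of field body temperatures (Tb) from the
preferred range [Tset25, Tset75] and de_bar the mean deviation of operative
environmental temperatures (Te) from the same range; E near 1 marks an
effective thermoregulator, E near 0 a thermoconformer.

Metabolic rates use the metabolic theory of ecology. Note the symbol
collision in the source equations: `E` denotes the effectiveness index above
but also the activation energy in the Arrhenius factor. The code keeps them
apart as ``E_index`` (returned by :func:`effectiveness`) and ``E_act`` (a
field of :class:`MetabolicConstants`).

The individual metabolic rate is

    I = i0 * M^(3/4) * exp(-E_act / (k T)),         B = I / M,

with i0 = ln(20.3) (reptile normalization), E_act = 0.63 eV, k the Boltzmann
constant in eV/K, M in grams and T in Kelvin. These forms are implemented
literally, including the multiplicative i0 = ln(20.3); the absolute scale of
I and B is therefore an arbitrary "MTE unit" and only relative comparisons
are meaningful. A dimensionally consistent log-scale variant
ln I = ln(i0) + 3/4 ln M - E_act/(kT) is available via ``log_scale=True``.

The size- and temperature-corrected linear forms are

    temperature-corrected MR = 0.71 ln(M) + 18.02
    mass-corrected MR        = -0.69 (1/(kT)) + 20.3,

the latter applied to field body temperatures for activity and to nocturnal
operative temperatures (Te_night) for inactivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MetabolicConstants", "ThermoregSample", "AllometryFit",
    "band_deviations", "deviations", "effectiveness",
    "metabolic_I", "metabolic_B", "temp_corrected_mr", "mass_corrected_mr",
    "fit_allometry", "predict_mass", "annual_fecundity", "production",
    "species_energetics",
]

KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class MetabolicConstants:
    """Constants of the Arrhenius metabolic model (overridable)."""

    i0: float = math.log(20.3)       # reptile normalization constant
    E_act: float = 0.63              # activation energy, eV
    k: float = 8.617333e-5           # Boltzmann constant, eV / K

    def __post_init__(self):
        if self.i0 <= 0 or self.E_act < 0 or self.k <= 0:
            raise ValueError("metabolic constants must be positive")


DEFAULT_CONSTANTS = MetabolicConstants()


# ----------------------------------------------------- thermoregulation
def band_deviations(values, lo: float, hi: float) -> np.ndarray:
    """Per-observation distance to the interval [lo, hi] (0 inside it)."""
    if lo > hi:
        raise ValueError("Tset25 must be <= Tset75")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty temperature sample")
    return np.where(v < lo, lo - v, np.where(v > hi, v - hi, 0.0))


@dataclass
class ThermoregSample:
    """Per-species Tb/Te observations plus the preferred-range bounds."""

    Tb: np.ndarray
    Te: np.ndarray
    Tset25: float
    Tset75: float
    Te_night: np.ndarray | None = None

    def deviations(self) -> tuple[float, float]:
        """Mean accuracy of body temperature (db_bar) and mean thermal
        quality of the habitat (de_bar)."""
        db = band_deviations(self.Tb, self.Tset25, self.Tset75)
        de = band_deviations(self.Te, self.Tset25, self.Tset75)
        return float(db.mean()), float(de.mean())

    def effectiveness(self) -> float:
        db_bar, de_bar = self.deviations()
        return effectiveness(db_bar, de_bar)


def deviations(sample: ThermoregSample) -> tuple[float, float]:
    return sample.deviations()


def effectiveness(db_bar: float, de_bar: float) -> float:
    """E = 1 - db_bar/de_bar. Undefined when the habitat is thermally
    perfect (de_bar = 0): there is nothing to thermoregulate against."""
    if db_bar < 0 or de_bar < 0:
        raise ValueError("deviations must be >= 0")
    if de_bar == 0:
        raise ZeroDivisionError(
            "de_bar = 0: thermal quality is perfect and E is not computable")
    return 1.0 - db_bar / de_bar


# ------------------------------------------------------------ metabolism
def _kelvin(T_celsius):
    T = np.asarray(T_celsius, dtype=float)
    if np.any(T <= -KELVIN_OFFSET):
        raise ValueError("temperature below absolute zero")
    return T + KELVIN_OFFSET


def metabolic_I(M, T_celsius, c: MetabolicConstants = DEFAULT_CONSTANTS,
                log_scale: bool = False):
    """Individual metabolic rate I = i0 M^(3/4) e^{-E_act/kT} (arbitrary
    MTE units), or ln I with ``log_scale=True``."""
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("body mass must be positive")
    TK = _kelvin(T_celsius)
    if log_scale:
        out = math.log(c.i0) + 0.75 * np.log(M) - c.E_act / (c.k * TK)
    else:
        out = c.i0 * M ** 0.75 * np.exp(-c.E_act / (c.k * TK))
    return float(out) if np.isscalar(M) or out.ndim == 0 else out


def metabolic_B(M, T_celsius, c: MetabolicConstants = DEFAULT_CONSTANTS,
                log_scale: bool = False):
    """Mass-specific metabolic rate B = I / M = i0 M^(-1/4) e^{-E_act/kT}."""
    M = np.asarray(M, dtype=float)
    if log_scale:
        return metabolic_I(M, T_celsius, c, log_scale=True) - np.log(M)
    out = metabolic_I(M, T_celsius, c) / M
    return float(out) if out.ndim == 0 else out


def temp_corrected_mr(M):
    """Temperature-corrected metabolic rate = 0.71 ln(M) + 18.02."""
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("body mass must be positive")
    out = 0.71 * np.log(M) + 18.02
    return float(out) if out.ndim == 0 else out


def mass_corrected_mr(T_celsius, c: MetabolicConstants = DEFAULT_CONSTANTS):
    """Mass-corrected metabolic rate = -0.69 / (k T) + 20.3 (T in Kelvin)."""
    TK = _kelvin(T_celsius)
    out = -0.69 / (c.k * TK) + 20.3
    return float(out) if out.ndim == 0 else out


# -------------------------------------------------------------- allometry
@dataclass(frozen=True)
class AllometryFit:
    """OLS of log10(mass) on log10(SVL); deliberately non-phylogenetic."""

    slope: float
    intercept: float
    r2: float
    n: int

    def predict_mass(self, svl_mm):
        return predict_mass(svl_mm, self)


def fit_allometry(svl_mm, mass_g) -> AllometryFit:
    """Fit log10(mass) = slope * log10(SVL) + intercept by ordinary least
    squares (no phylogenetic correction, matching how the predictive
    equation is built from species means)."""
    svl = np.asarray(svl_mm, dtype=float)
    mass = np.asarray(mass_g, dtype=float)
    ok = np.isfinite(svl) & np.isfinite(mass)
    svl, mass = svl[ok], mass[ok]
    if svl.size < 3:
        raise ValueError("need >= 3 species")
    if np.any(svl <= 0) or np.any(mass <= 0):
        raise ValueError("SVL and mass must be positive")
    x, y = np.log10(svl), np.log10(mass)
    if np.ptp(x) == 0:
        raise ValueError("degenerate SVL values (no variance)")
    res = sps.linregress(x, y)
    return AllometryFit(float(res.slope), float(res.intercept),
                        float(res.rvalue ** 2), int(svl.size))


def predict_mass(svl_mm, coeffs) -> float:
    """Back-transformed mass prediction 10^(slope log10(SVL) + intercept)."""
    slope, intercept = (coeffs.slope, coeffs.intercept) \
        if isinstance(coeffs, AllometryFit) else coeffs
    svl = np.asarray(svl_mm, dtype=float)
    if np.any(svl <= 0):
        raise ValueError("SVL must be positive")
    out = 10.0 ** (slope * np.log10(svl) + intercept)
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------------- production
def annual_fecundity(clutch_size, clutches_per_year):
    """Offspring produced per year = clutch/litter size x bouts per year."""
    out = np.asarray(clutch_size, dtype=float) * np.asarray(clutches_per_year, dtype=float)
    return float(out) if out.ndim == 0 else out


def production(offspring_mass_g, annual_fecundity_per_yr, female_mass_g):
    """Mass-specific production Pr = offspring mass x annual fecundity /
    female mass (per year; a dimensionless mass ratio)."""
    fm = np.asarray(female_mass_g, dtype=float)
    if np.any(fm <= 0):
        raise ValueError("female mass must be positive")
    om = np.asarray(offspring_mass_g, dtype=float)
    af = np.asarray(annual_fecundity_per_yr, dtype=float)
    if np.any(om < 0) or np.any(af < 0):
        raise ValueError("offspring mass and fecundity must be >= 0")
    out = om * af / fm
    return float(out) if out.ndim == 0 else out


# -------------------------------------------------------- species table
def species_energetics(species: pd.DataFrame, observations: pd.DataFrame | None = None,
                       constants: MetabolicConstants = DEFAULT_CONSTANTS,
                       allometry: AllometryFit | tuple | None = None) -> pd.DataFrame:
    """Per-species energetics table from a trait table and (optionally) a
    long-format table of thermoregulation observations.

    `species` must be indexed by species name and may carry columns
    Tb, Tpref, Tset25, Tset75, SVL, mass, clutch_size, clutches_per_year,
    offspring_mass. `observations` has columns (species, kind, value) with
    kind in {Tb, Te, Te_night}. Missing mass is predicted from SVL when an
    allometry is given. Derived columns: db_bar, de_bar, E, I, B,
    temp_corrected_mr, mass_corrected_mr_activity, mass_corrected_mr_inactivity,
    annual_fecundity, Pr.
    """
    out = species.copy()
    if allometry is not None and "SVL" in out:
        mass = out.get("mass", pd.Series(np.nan, index=out.index, dtype=float))
        pred = pd.Series(
            [predict_mass(s, allometry) if np.isfinite(s) and s > 0 else np.nan
             for s in out["SVL"]], index=out.index)
        out["mass"] = mass.fillna(pred)
    if observations is not None:
        for sp, grp in observations.groupby("species"):
            if sp not in out.index or not {"Tset25", "Tset75"} <= set(out.columns):
                continue
            lo, hi = out.loc[sp, "Tset25"], out.loc[sp, "Tset75"]
            tb = grp.loc[grp["kind"] == "Tb", "value"].to_numpy()
            te = grp.loc[grp["kind"] == "Te", "value"].to_numpy()
            ten = grp.loc[grp["kind"] == "Te_night", "value"].to_numpy()
            if not (np.isfinite(lo) and np.isfinite(hi)) or tb.size == 0 or te.size == 0:
                continue
            sample = ThermoregSample(tb, te, float(lo), float(hi),
                                     ten if ten.size else None)
            db_bar, de_bar = sample.deviations()
            out.loc[sp, "db_bar"] = db_bar
            out.loc[sp, "de_bar"] = de_bar
            out.loc[sp, "E"] = (1.0 - db_bar / de_bar) if de_bar > 0 else np.nan
            if ten.size:
                out.loc[sp, "mass_corrected_mr_inactivity"] = float(
                    np.mean(mass_corrected_mr(ten, constants)))
    if {"mass", "Tb"} <= set(out.columns):
        ok = out["mass"].gt(0) & out["Tb"].notna()
        out.loc[ok, "I"] = metabolic_I(out.loc[ok, "mass"], out.loc[ok, "Tb"], constants)
        out.loc[ok, "B"] = metabolic_B(out.loc[ok, "mass"], out.loc[ok, "Tb"], constants)
    if "mass" in out:
        ok = out["mass"].gt(0).fillna(False)
        out.loc[ok, "temp_corrected_mr"] = temp_corrected_mr(out.loc[ok, "mass"])
    if "Tb" in out:
        ok = out["Tb"].notna()
        out.loc[ok, "mass_corrected_mr_activity"] = mass_corrected_mr(
            out.loc[ok, "Tb"], constants)
    if {"clutch_size", "clutches_per_year"} <= set(out.columns):
        out["annual_fecundity"] = annual_fecundity(out["clutch_size"],
                                                   out["clutches_per_year"])
    if {"offspring_mass", "annual_fecundity", "mass"} <= set(out.columns):
        ok = out["mass"].gt(0) & out["offspring_mass"].notna() \
            & out["annual_fecundity"].notna()
        out.loc[ok, "Pr"] = (out.loc[ok, "offspring_mass"]
                             * out.loc[ok, "annual_fecundity"] / out.loc[ok, "mass"])
    return out
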