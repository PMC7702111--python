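"""Dissolved greenhouse-gas chemistry and DOM optics.

Dissolved concentrations follow Henry's law, Gas_aq = K_H(T) x pGas, with the
solubility constant adjusted for water temperature by a van't Hoff factor.
Field observations made with the headspace technique (a known water volume
shaken with a known volume of ambient air) are inverted to in-situ
concentrations by an ideal-gas mass balance, correcting for the gas carried
in with the ambient air.  Saturation is expressed relative to air
equilibrium.  A Box-Cox power transform with profile-likelihood lambda
selection supports regressions between gas concentrations and community
descriptors such as the estimated methanotroph abundance (read fraction times
microscopic cell count).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

R_L_ATM = 0.0820574  # gas constant, L atm mol^-1 K^-1
T0_K = 298.15


@dataclass(frozen=True)
class GasSpec:
    """A gas with its solubility and atmospheric background.

    ``kh25`` is the Henry solubility at 25 C in mol L^-1 atm^-1;
    ``vant_hoff_coeff`` (K) controls the temperature dependence;
    ``atm_mixing_ratio`` is the mole fraction in ambient air.
    """

    name: str
    kh25: float
    vant_hoff_coeff: float
    atm_mixing_ratio: float

    def __post_init__(self) -> None:
        if self.kh25 <= 0 or self.vant_hoff_coeff <= 0:
            raise ValueError("kh25 and vant_hoff_coeff must be positive")
        if not 0.0 < self.atm_mixing_ratio < 1.0:
            raise ValueError("atm_mixing_ratio must be in (0,1)")

    @classmethod
    def co2(cls) -> "GasSpec":
        # standard compilation solubility; 407 ppm global mean mixing ratio (2018)
        return cls("CO2", 0.0334, 2400.0, 407e-6)

    @classmethod
    def ch4(cls) -> "GasSpec":
        return cls("CH4", 1.4e-3, 1700.0, 1.85e-6)


@dataclass
class HeadspaceSample:
    """One headspace equilibration: volumes, temperature and mixing ratios."""

    water_volume_ml: float
    headspace_volume_ml: float
    temperature_c: float
    headspace_mixing_ratio: float  # measured after shaking, mole fraction
    ambient_mixing_ratio: float  # of the air used as headspace

    def __post_init__(self) -> None:
        if self.water_volume_ml <= 0 or self.headspace_volume_ml <= 0:
            raise ValueError("volumes must be positive")
        if self.headspace_mixing_ratio < 0 or self.ambient_mixing_ratio < 0:
            raise ValueError("mixing ratios must be >= 0")


def henry_constant(spec: GasSpec, temp_c: float) -> float:
    """Henry solubility (mol L^-1 atm^-1) at ``temp_c``.

    K_H(T) = K_H25 exp(coeff (1/T - 1/298.15)), T in kelvin.
    """
    if not -5.0 <= temp_c <= 40.0:
        raise ValueError(f"temperature {temp_c} C outside plausible range")
    t_k = temp_c + 273.15
    return spec.kh25 * math.exp(spec.vant_hoff_coeff * (1.0 / t_k - 1.0 / T0_K))


def dissolved_gas(spec: GasSpec, p_gas_atm: float, temp_c: float) -> float:
    """Equilibrium dissolved concentration in uM for partial pressure ``p_gas_atm``."""
    if p_gas_atm < 0:
        raise ValueError("partial pressure must be >= 0")
    return henry_constant(spec, temp_c) * p_gas_atm * 1e6


def equilibrate_headspace(
    c0_mol_per_l: float, sample: HeadspaceSample, spec: GasSpec
) -> float:
    """Forward model: headspace mixing ratio after full equilibration.

    Water initially at ``c0_mol_per_l`` is shaken with headspace air at the
    sample's ambient mixing ratio; total moles are conserved and partitioned
    by Henry's law.  Returns the equilibrium headspace mole fraction at 1 atm.
    """
    t_k = sample.temperature_c + 273.15
    vw = sample.water_volume_ml / 1000.0
    vh = sample.headspace_volume_ml / 1000.0
    kh = henry_constant(spec, sample.temperature_c)
    n_tot = c0_mol_per_l * vw + sample.ambient_mixing_ratio * vh / (R_L_ATM * t_k)
    p_eq = n_tot / (kh * vw + vh / (R_L_ATM * t_k))
    return p_eq


def headspace_to_insitu(sample: HeadspaceSample, spec: GasSpec) -> float:
    """Invert a headspace measurement to the original dissolved concentration (uM).

    Mass balance at 1 atm total pressure: the moles found at equilibrium
    (dissolved at K_H(T) p_eq plus ideal-gas headspace) minus the moles
    injected with the ambient air, divided by the water volume.  A negative
    result (measurement below the ambient injection) is clamped to zero with
    a warning.
    """
    t_k = sample.temperature_c + 273.15
    vw = sample.water_volume_ml / 1000.0
    vh = sample.headspace_volume_ml / 1000.0
    kh = henry_constant(spec, sample.temperature_c)
    p_eq = sample.headspace_mixing_ratio  # x 1 atm
    n_total = kh * p_eq * vw + p_eq * vh / (R_L_ATM * t_k)
    n_original = n_total - sample.ambient_mixing_ratio * vh / (R_L_ATM * t_k)
    c0 = n_original / vw
    if c0 < 0:
        warnings.warn(
            f"{spec.name}: recovered concentration below zero ({c0:.3g} M); "
            "clamping to 0"
        )
        c0 = 0.0
    return c0 * 1e6


def saturation_percent(observed_um: float, equilibrium_um: float) -> float:
    """Observed concentration as a percentage of air-equilibrium concentration."""
    if equilibrium_um <= 0:
        raise ValueError("equilibrium concentration must be positive")
    return 100.0 * observed_um / equilibrium_um


def methanotroph_abundance(read_fraction: float, total_cells_per_ml: float) -> float:
    """Estimated methanotroph cells per ml: read fraction x total cell count."""
    if not 0.0 <= read_fraction <= 1.0:
        raise ValueError("read_fraction must be in [0,1]")
    if total_cells_per_ml < 0:
        raise ValueError("total_cells_per_ml must be >= 0")
    return read_fraction * total_cells_per_ml


# ---------------------------------------------------------------------------
# Box-Cox transform and regression
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxFit:
    lam: float
    transformed: np.ndarray
    lambdas: np.ndarray
    log_likelihood: np.ndarray


def box_cox(x: np.ndarray, lam: float) -> np.ndarray:
    """(x^lambda - 1)/lambda, with the log limit at lambda = 0; requires x > 0."""
    x = np.asarray(x, dtype=float)
    bad = x[x <= 0]
    if bad.size:
        raise ValueError(f"box_cox requires positive values; offending: {bad[:5]}")
    if lam == 0.0:
        return np.log(x)
    return (x ** lam - 1.0) / lam


def inverse_box_cox(y: np.ndarray, lam: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        return np.exp(y)
    return (lam * y + 1.0) ** (1.0 / lam)


def fit_box_cox(
    x: np.ndarray, lam_min: float = -5.0, lam_max: float = 5.0, step: float = 0.01
) -> BoxCoxFit:
    """Select lambda by maximizing the normal profile log-likelihood on a grid."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fit_box_cox requires positive values")
    lambdas = np.arange(lam_min, lam_max + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, x) for l in lambdas])
    lam = float(lambdas[np.argmax(llf)])
    return BoxCoxFit(
        lam=lam, transformed=box_cox(x, lam), lambdas=lambdas, log_likelihood=llf
    )


def regress(y: np.ndarray, x: np.ndarray) -> dict:
    """Ordinary least-squares fit of y on x; slope, intercept, r, p, stderr."""
    res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r_value": res.rvalue,
        "p_value": res.pvalue,
        "stderr": res.stderr,
    }


# ---------------------------------------------------------------------------
# DOM optics
# ---------------------------------------------------------------------------

@dataclass
class DomOptics:
    a320: float
    suva254: float | None
    slope_275_295: float | None
    slope_350_400: float | None

    @property
    def slope_ratio(self) -> float | None:
        if self.slope_275_295 is None or self.slope_350_400 is None:
            return None
        return self.slope_275_295 / self.slope_350_400


def _band_slope(
    wavelength: np.ndarray, a: np.ndarray, lo: float, hi: float
) -> float | None:
    """Spectral slope S (nm^-1) from a log-linear fit of a(lambda) on [lo, hi]."""
    mask = (wavelength >= lo) & (wavelength <= hi)
    w, av = wavelength[mask], a[mask]
    if w.size < 3 or np.any(av <= 0):
        return None
    fit = np.polyfit(w, np.log(av), 1)
    return float(-fit[0])


def dom_optics(
    spectrum: pd.DataFrame,
    path_length_m: float,
    doc_mg_per_l: float | None = None,
) -> DomOptics:
    """Optical indices of chromophoric DOM from an absorbance spectrum.

    ``spectrum`` needs columns wavelength_nm and absorbance (dimensionless,
    for the given cuvette path).  Napierian absorption a(lambda) =
    2.303 A / path (m^-1); SUVA254 = A(254) / (path_m x DOC) in
    L mg^-1 m^-1; spectral slopes from log-linear fits over 275-295 and
    350-400 nm, and their ratio S_R.
    """
    w = np.asarray(spectrum["wavelength_nm"], dtype=float)
    absorbance = np.asarray(spectrum["absorbance"], dtype=float)
    if path_length_m <= 0:
        raise ValueError("path length must be positive")
    order = np.argsort(w)
    w, absorbance = w[order], absorbance[order]
    a = 2.303 * absorbance / path_length_m

    def _at(target: float, values: np.ndarray) -> float:
        return float(np.interp(target, w, values))

    a320 = _at(320.0, a)
    suva = None
    if doc_mg_per_l is not None:
        if doc_mg_per_l <= 0:
            raise ValueError("DOC must be positive for SUVA")
        suva = _at(254.0, absorbance) / (path_length_m * doc_mg_per_l)
    return DomOptics(
        a320=a320,
        suva254=suva,
        slope_275_295=_band_slope(w, a, 275.0, 295.0),
        slope_350_400=_band_slope(w, a, 350.0, 400.0),
    )


def process_gas_table(table: pd.DataFrame) -> pd.DataFrame:
    """Headspace inversion + saturation for a tidy gas measurement table.

    Expects columns sample_id, gas, temperature_C, headspace_ppm, ambient_ppm,
    V_water_ml, V_head_ml.  Adds dissolved_uM, equilibrium_uM, saturation_pct.
    """
    specs = {"CO2": GasSpec.co2(), "CH4": GasSpec.ch4()}
    out = table.copy()
    dissolved, equilibrium, saturation = [], [], []
    for _, row in table.iterrows():
        spec = specs[row["gas"]]
        sample = HeadspaceSample(
            water_volume_ml=row["V_water_ml"],
            headspace_volume_ml=row["V_head_ml"],
            temperature_c=row["temperature_C"],
            headspace_mixing_ratio=row["headspace_ppm"] * 1e-6,
            ambient_mixing_ratio=row["ambient_ppm"] * 1e-6,
        )
        c = headspace_to_insitu(sample, spec)
        eq = dissolved_gas(spec, spec.atm_mixing_ratio, row["temperature_C"])
        dissolved.append(c)
        equilibrium.append(eq)
        saturation.append(saturation_percent(c, eq))
    out["dissolved_uM"] = dissolved
    out["equilibrium_uM"] = equilibrium
    out["saturation_pct"] = saturation
    return out
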