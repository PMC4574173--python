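"""Steps II-III of the CO2 method and the covariate formulas.

Daily CH4 is obtained by scaling the measured CH4:CO2 ratio with a
modelled daily CO2 excretion:

    HP  = 5.6 * BW^0.75 + 22 * Y + 1.6e-5 * P^3        [W]
    CO2 = HP/1000 * 180 * 24                           [L/day]
    CH4 = ratio * CO2                                  [L/day]

with BW the body weight (kg), Y milk yield (kg/day) and P days pregnant
(CIGR dairy-cow heat production; one heat-producing unit = 1000 W emits
180 L CO2 per hour).  The module also provides estimated dry-matter
intake (herd TMR corrected for individual concentrate at a 0.5
substitution rate plus a parity correction), energy-corrected milk
(Sjaunja fat-protein form), CH4 intensities, and linear standardization
of CH4 and the ratio to a 30 kg/day ECM reference.

All operations are vectorised over pandas Series / numpy arrays as well
as scalars.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .config import FeedContext, FormulaCoefficients

__all__ = [
    "heat_production",
    "daily_co2",
    "daily_ch4",
    "estimated_dmi",
    "energy_corrected_milk",
    "intensities",
    "fit_standardization_slopes",
    "standardize_to_ecm",
    "StandardizationSlopes",
    "build_daily_phenotypes",
    "hourly_phenotypes",
]

_DEFAULT = FormulaCoefficients()

PARITY_CORRECTION = {"primiparous": -1.61, "multiparous": 0.39}


class DomainError(ValueError):
    """Raised for physically impossible inputs (negative BW etc.)."""


def _check_nonneg(name: str, value) -> None:
    if np.any(np.asarray(value, dtype=float) < 0):
        raise DomainError(f"{name} must be >= 0")


def heat_production(bw_kg, milk_kg_day, days_pregnant, coefficients: FormulaCoefficients = _DEFAULT):
    """Total heat production in watts from BW, milk yield and pregnancy."""
    if np.any(np.asarray(bw_kg, dtype=float) <= 0):
        raise DomainError("bw_kg must be > 0")
    _check_nonneg("milk_kg_day", milk_kg_day)
    _check_nonneg("days_pregnant", days_pregnant)
    c = coefficients
    bw = np.asarray(bw_kg, dtype=float)
    y = np.asarray(milk_kg_day, dtype=float)
    p = np.asarray(days_pregnant, dtype=float)
    hp = c.hp_bw * bw ** c.hp_bw_exp + c.hp_milk * y + c.hp_preg * p ** 3
    return hp if hp.ndim else float(hp)


def daily_co2(hp_watts, coefficients: FormulaCoefficients = _DEFAULT):
    """Daily CO2 excretion (L/day): HP/1000 HPU x 180 L/HPU/h x 24 h."""
    _check_nonneg("hp_watts", hp_watts)
    hp = np.asarray(hp_watts, dtype=float)
    out = hp / 1000.0 * coefficients.co2_l_per_hpu_hour * 24.0
    return out if out.ndim else float(out)


def daily_ch4(ratio, co2_l_day):
    """Daily CH4 (L/day) = CH4:CO2 ratio x daily CO2 (L/day)."""
    r = np.asarray(ratio, dtype=float)
    out = r * np.asarray(co2_l_day, dtype=float)
    return out if out.ndim else float(out)


def estimated_dmi(
    concentrate_individual,
    parity,
    feed: FeedContext,
    coefficients: FormulaCoefficients = _DEFAULT,
):
    """Estimated dry-matter intake (kg DM/day).

    EDMI = a - substitution_rate * (c - b) + d + c, where a is the herd
    TMR mean, b the herd concentrate mean, c the individual concentrate
    and d the parity correction (-1.61 first lactation, +0.39 later).
    Rows ending non-positive are implausible and returned as NaN with a
    warning rather than silently propagated.
    """
    c_ind = np.asarray(concentrate_individual, dtype=float)
    scalar = c_ind.ndim == 0
    c_ind = np.atleast_1d(c_ind)
    par = np.atleast_1d(np.asarray(parity, dtype=object))
    d = np.where(
        par == "primiparous",
        coefficients.parity_correction_primiparous,
        coefficients.parity_correction_multiparous,
    )
    edmi = (
        feed.tmr_herd_mean
        - feed.substitution_rate * (c_ind - feed.concentrate_herd_mean)
        + d
        + c_ind
    )
    bad = edmi <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} EDMI value(s) <= 0 marked implausible (NaN)")
        edmi = np.where(bad, np.nan, edmi)
    return float(edmi[0]) if scalar else edmi


def energy_corrected_milk(milk_kg_day, fat_pct, protein_pct, coefficients: FormulaCoefficients = _DEFAULT):
    """Energy-corrected milk (kg/day), Sjaunja fat-protein form."""
    _check_nonneg("milk_kg_day", milk_kg_day)
    c = coefficients
    m = np.asarray(milk_kg_day, dtype=float)
    out = m * (c.ecm_fat * np.asarray(fat_pct, float)
               + c.ecm_protein * np.asarray(protein_pct, float)
               + c.ecm_const) / c.ecm_denom
    return out if out.ndim else float(out)


def intensities(ch4_l_day, edmi_kg_day, ecm_kg_day):
    """CH4 per kg intake and per kg ECM; zero/missing denominators -> NaN."""
    ch4 = np.asarray(ch4_l_day, dtype=float)
    edmi = np.asarray(edmi_kg_day, dtype=float)
    ecm = np.asarray(ecm_kg_day, dtype=float)
    bad_edmi = ~(edmi > 0)
    bad_ecm = ~(ecm > 0)
    if np.any(bad_edmi & np.isfinite(edmi) & (edmi == 0)) or np.any(bad_ecm & np.isfinite(ecm) & (ecm == 0)):
        warnings.warn("zero EDMI/ECM denominator; intensity set to NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_edmi = np.where(bad_edmi, np.nan, ch4 / edmi)
        per_ecm = np.where(bad_ecm, np.nan, ch4 / ecm)
    if per_edmi.ndim == 0:
        return float(per_edmi), float(per_ecm)
    return per_edmi, per_ecm


class EstimationError(ValueError):
    pass


from dataclasses import dataclass


@dataclass(frozen=True)
class StandardizationSlopes:
    """Per-year OLS slopes used to move phenotypes to a reference ECM."""

    s: float                 # ratio units per kg ECM
    q: float                 # L CH4/day per kg ECM
    year: object = None
    ecm_reference: float = 30.0


def fit_standardization_slopes(
    phenotypes: pd.DataFrame,
    year: object = None,
    ecm_reference: float = 30.0,
) -> StandardizationSlopes:
    """OLS slopes of cow-mean ratio (s) and CH4 L/day (q) on ECM, one year.

    Expects one row per cow with ``ratio``, ``ch4_l_day`` and
    ``ecm_kg_day`` columns (cow period means).
    """
    df = phenotypes.dropna(subset=["ratio", "ch4_l_day", "ecm_kg_day"])
    if len(df) < 3:
        raise EstimationError("need at least 3 cows to fit standardization slopes")
    x = df["ecm_kg_day"].to_numpy(dtype=float)
    if np.isclose(np.var(x), 0.0):
        raise EstimationError("zero ECM variance; slopes are unidentifiable")
    s = float(np.polyfit(x, df["ratio"].to_numpy(dtype=float), 1)[0])
    q = float(np.polyfit(x, df["ch4_l_day"].to_numpy(dtype=float), 1)[0])
    return StandardizationSlopes(s=s, q=q, year=year, ecm_reference=ecm_reference)


def standardize_to_ecm(value, ecm, slope, ecm_reference: float = 30.0):
    """Linear translation of a phenotype to the reference ECM level.

    standardized = value - slope * (ecm - ecm_reference)
    """
    v = np.asarray(value, dtype=float)
    out = v - slope * (np.asarray(ecm, dtype=float) - ecm_reference)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# assembly

def build_daily_phenotypes(
    day_ratios: pd.DataFrame,
    cows: pd.DataFrame,
    feed: FeedContext,
    coefficients: FormulaCoefficients = _DEFAULT,
    ecm_reference: float = 30.0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Assemble the per cow-day phenotype table from day-level ratios.

    HP, CO2, EDMI and ECM are computed once per cow from the cow table
    (one BW / milk record per cow-year); the daily ratio then scales CO2
    into daily CH4 and the intensities.  When ``standardize`` is set and
    at least 3 cows are available, per-period slopes on ECM are fitted
    and ECM-standardized CH4 / ratio columns are added.
    """
    cows = cows.copy()
    cows["hp_watts"] = heat_production(
        cows["bw_kg"], cows["milk_kg_day"], cows["days_pregnant"], coefficients
    )
    cows["co2_l_day"] = daily_co2(cows["hp_watts"], coefficients)
    cows["edmi_kg_day"] = estimated_dmi(
        cows["concentrate_kg_dm"], cows["parity"], feed, coefficients
    )
    cows["ecm_kg_day"] = energy_corrected_milk(
        cows["milk_kg_day"], cows["fat_pct"], cows["protein_pct"], coefficients
    )
    phen = day_ratios.merge(cows, on="cow_id", how="left")
    phen["ch4_l_day"] = daily_ch4(phen["ratio"], phen["co2_l_day"])
    phen["ch4_per_edmi"], phen["ch4_per_ecm"] = intensities(
        phen["ch4_l_day"], phen["edmi_kg_day"], phen["ecm_kg_day"]
    )
    if standardize:
        cow_means = (
            phen.groupby("cow_id", as_index=False)
            .agg(ratio=("ratio", "mean"), ch4_l_day=("ch4_l_day", "mean"),
                 ecm_kg_day=("ecm_kg_day", "first"))
        )
        try:
            slopes = fit_standardization_slopes(cow_means, ecm_reference=ecm_reference)
        except EstimationError:
            slopes = None
        if slopes is not None:
            phen["ch4_std_l_day"] = standardize_to_ecm(
                phen["ch4_l_day"], phen["ecm_kg_day"], slopes.q, ecm_reference
            )
            phen["ratio_std"] = standardize_to_ecm(
                phen["ratio"], phen["ecm_kg_day"], slopes.s, ecm_reference
            )
    keep = [c for c in [
        "cow_id", "date", "ratio", "n", "hp_watts", "co2_l_day", "ch4_l_day",
        "edmi_kg_day", "ecm_kg_day", "ch4_per_edmi", "ch4_per_ecm",
        "ch4_std_l_day", "ratio_std", "parity", "bw_kg", "milk_kg_day",
        "days_pregnant",
    ] if c in phen.columns]
    return phen[keep]


def hourly_phenotypes(
    visit_ratios: pd.DataFrame,
    daily_phenotypes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-visit hourly CH4 (L/h) for the diurnal analysis.

    Each visit's ratio is scaled by the cow's daily CO2 and divided by
    24, giving the emission rate the visit's hour represents.  Covariates
    (EDMI, ECM, parity) are carried along for model adjustment.
    """
    cow_cov = daily_phenotypes.groupby("cow_id", as_index=False).agg(
        co2_l_day=("co2_l_day", "first"),
        edmi_kg_day=("edmi_kg_day", "first"),
        ecm_kg_day=("ecm_kg_day", "first"),
        parity=("parity", "first"),
    )
    out = visit_ratios.merge(cow_cov, on="cow_id", how="left")
    out["ch4_l_h"] = out["ratio"] * out["co2_l_day"] / 24.0
    return out
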