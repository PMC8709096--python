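"""Derived clinical covariates: estimated GFR from serum creatinine.

Implements the 2009 CKD-EPI creatinine equation

    eGFR = 141 x min(Scr/kappa, 1)^alpha x max(Scr/kappa, 1)^-1.209
           x 0.993^age x 1.018 [if female]

with kappa = 0.7 (female) / 0.9 (male) and alpha = -0.329 / -0.411, in
mL/min/1.73 m^2.  The historical race coefficient (1.159) is omitted by
default, matching modern race-free practice; it can be opted into through
:class:`EgfrParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: mg/dL -> umol/L conversion for serum creatinine.
CREATININE_UMOL_PER_MGDL = 88.4

#: Typical plasma concentrations (g/L) of the two complement proteins whose
#: urinary fragments dominate this analysis.  C3 circulates at roughly
#: 1.0-1.5 g/L while factor B is near 0.2 g/L, so unspecific glomerular
#: leakage alone delivers several-fold more C3 than CFB into urine.
C3_PLASMA_G_PER_L = (1.0, 1.5)
CFB_PLASMA_G_PER_L = 0.2


def c3_cfb_plasma_ratio() -> float:
    """Fold-excess of plasma C3 over factor B at the lower C3 bound."""
    return C3_PLASMA_G_PER_L[0] / CFB_PLASMA_G_PER_L


@dataclass(frozen=True)
class EgfrParams:
    """Constants of the CKD-EPI creatinine equation."""

    kappa_female: float = 0.7
    kappa_male: float = 0.9
    alpha_female: float = -0.329
    alpha_male: float = -0.411
    age_base: float = 0.993
    female_factor: float = 1.018
    max_exponent: float = -1.209
    scale: float = 141.0
    race_factor: float = 1.0  # set to 1.159 to opt into the 2009 coefficient

    def __post_init__(self) -> None:
        if self.kappa_female <= 0 or self.kappa_male <= 0:
            raise ValueError("kappa must be > 0")
        if not (0 < self.age_base <= 1):
            raise ValueError("age_base must lie in (0, 1]")

    def with_race_coefficient(self) -> "EgfrParams":
        return replace(self, race_factor=1.159)


DEFAULT_EGFR_PARAMS = EgfrParams()


def ckd_epi_egfr(
    scr: float | np.ndarray,
    age: float | np.ndarray,
    sex: str | np.ndarray,
    params: EgfrParams = DEFAULT_EGFR_PARAMS,
) -> float | np.ndarray:
    """CKD-EPI eGFR (mL/min/1.73 m^2) from creatinine (mg/dL), age, sex.

    Vectorized over numpy arrays; scalar in, scalar out.  Strictly
    decreasing in creatinine and in age.
    """
    scr_arr = np.asarray(scr, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    female = np.asarray(sex) == "female"
    if np.any(scr_arr <= 0):
        raise ValueError("serum creatinine must be > 0")
    if np.any((age_arr <= 0) | (age_arr >= 130)):
        raise ValueError("age must lie in (0, 130)")

    kappa = np.where(female, params.kappa_female, params.kappa_male)
    alpha = np.where(female, params.alpha_female, params.alpha_male)
    ratio = scr_arr / kappa
    egfr = (
        params.scale
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** params.max_exponent
        * params.age_base**age_arr
        * np.where(female, params.female_factor, 1.0)
        * params.race_factor
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def invert_ckd_epi(
    egfr: float | np.ndarray,
    age: float | np.ndarray,
    sex: str | np.ndarray,
    params: EgfrParams = DEFAULT_EGFR_PARAMS,
) -> float | np.ndarray:
    """Serum creatinine (mg/dL) that yields the given eGFR at age/sex.

    The equation is strictly monotone in creatinine, so the inverse is
    unique: with A = eGFR / (141 x 0.993^age x sex factor), the low branch
    (Scr <= kappa) applies when A >= 1 and inverts the alpha exponent, the
    high branch otherwise.
    """
    egfr_arr = np.asarray(egfr, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    female = np.asarray(sex) == "female"
    if np.any(egfr_arr <= 0):
        raise ValueError("eGFR must be > 0")
    kappa = np.where(female, params.kappa_female, params.kappa_male)
    alpha = np.where(female, params.alpha_female, params.alpha_male)
    base = (
        params.scale
        * params.age_base**age_arr
        * np.where(female, params.female_factor, 1.0)
        * params.race_factor
    )
    a = egfr_arr / base
    scr = np.where(
        a >= 1.0,
        kappa * a ** (1.0 / alpha),
        kappa * a ** (1.0 / params.max_exponent),
    )
    if scr.ndim == 0:
        return float(scr)
    return scr


def fill_egfr(
    clinical: pd.DataFrame,
    params: EgfrParams = DEFAULT_EGFR_PARAMS,
    discrepancy_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing eGFR from creatinine/age/sex; flag inconsistent values.

    Supplied eGFR values take precedence over recomputation.  Where both a
    supplied value and the required inputs exist, relative discrepancies
    above ``discrepancy_threshold`` are returned in a consistency report
    (sample_id, supplied, recomputed, relative difference).
    """
    out = clinical.copy()
    can_compute = (
        out["serum_creatinine"].notna() & out["age"].notna() & out["sex"].notna()
    )
    computed = pd.Series(np.nan, index=out.index, dtype=float)
    if can_compute.any():
        sub = out.loc[can_compute]
        computed.loc[can_compute] = ckd_epi_egfr(
            sub["serum_creatinine"].to_numpy(float),
            sub["age"].to_numpy(float),
            sub["sex"].to_numpy(),
            params,
        )
    both = can_compute & out["egfr"].notna()
    rel = ((out.loc[both, "egfr"] - computed[both]).abs() / computed[both]).astype(float)
    flagged = rel[rel > discrepancy_threshold]
    report = pd.DataFrame(
        {
            "supplied_egfr": out.loc[flagged.index, "egfr"],
            "recomputed_egfr": computed[flagged.index],
            "relative_difference": flagged,
        }
    )
    fill = out["egfr"].isna() & can_compute
    out.loc[fill, "egfr"] = computed[fill]
    return out, report
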