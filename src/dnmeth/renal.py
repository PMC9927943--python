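"""eGFR computation, albuminuria staging, and KDIGO risk categorization."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RiskCategory",
    "ckd_epi_egfr",
    "gfr_category",
    "albuminuria_stage",
    "kdigo_risk",
    "KDIGO_MATRIX",
]

GFR_CATEGORIES = ("G1", "G2", "G3a", "G3b", "G4", "G5")
ALBUMINURIA_CATEGORIES = ("A1", "A2", "A3")
RISK_LEVELS = ("low", "moderate", "high", "very_high")

# KDIGO G x A risk heatmap
KDIGO_MATRIX = {
    ("G1", "A1"): "low", ("G1", "A2"): "moderate", ("G1", "A3"): "high",
    ("G2", "A1"): "low", ("G2", "A2"): "moderate", ("G2", "A3"): "high",
    ("G3a", "A1"): "moderate", ("G3a", "A2"): "high", ("G3a", "A3"): "very_high",
    ("G3b", "A1"): "high", ("G3b", "A2"): "very_high", ("G3b", "A3"): "very_high",
    ("G4", "A1"): "very_high", ("G4", "A2"): "very_high", ("G4", "A3"): "very_high",
    ("G5", "A1"): "very_high", ("G5", "A2"): "very_high", ("G5", "A3"): "very_high",
}

# albuminuria stage labels by clinical naming
STAGE_ALIASES = {"A1": "Normo", "A2": "Micro", "A3": "Macro"}


@dataclass(frozen=True)
class RiskCategory:
    gfr_category: str
    albuminuria_category: str
    risk: str


def ckd_epi_egfr(creatinine_mg_dl: float, age_years: float, sex: str) -> float:
    """CKD-EPI 2009 creatinine eGFR (mL/min/1.73 m^2), no race term.

    ``141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age * 1.018[female]``
    with k = 0.7 (F) / 0.9 (M) and a = -0.329 (F) / -0.411 (M).
    """
    if creatinine_mg_dl <= 0:
        raise ValueError("creatinine must be positive")
    if age_years <= 0:
        raise ValueError("age must be positive")
    sex = str(sex).upper()
    female = sex in ("F", "FEMALE", "1")
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    ratio = creatinine_mg_dl / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993**age_years
    if female:
        egfr *= 1.018
    return egfr


def gfr_category(egfr: float) -> str:
    if egfr >= 90:
        return "G1"
    if egfr >= 60:
        return "G2"
    if egfr >= 45:
        return "G3a"
    if egfr >= 30:
        return "G3b"
    if egfr >= 15:
        return "G4"
    return "G5"


def albuminuria_stage(value: float, measure: str = "uacr") -> str:
    """A1/A2/A3 from UACR (mg/g) or AER (mg/24 h).

    Thresholds: A1 < 30, A2 in [30, 300], A3 > 300 — the same numeric cutoffs
    for both measures, with the lower bound inclusive for A2.
    """
    if measure.lower() not in ("uacr", "aer"):
        raise ValueError(f"unknown albuminuria measure {measure!r}")
    if value is None:
        raise ValueError("albuminuria measurement missing")
    if value < 0:
        raise ValueError("albuminuria value must be >= 0")
    if value < 30:
        return "A1"
    if value <= 300:
        return "A2"
    return "A3"


def kdigo_risk(egfr: float | None, albuminuria_category: str, esrd_flag: bool = False) -> RiskCategory:
    """KDIGO risk category from eGFR band x albuminuria category.

    Dialysis or kidney transplant (``esrd_flag``) forces G5 / very high risk
    regardless of measured eGFR.
    """
    if albuminuria_category not in ALBUMINURIA_CATEGORIES:
        raise ValueError(f"invalid albuminuria category {albuminuria_category!r}")
    if esrd_flag:
        return RiskCategory("G5", albuminuria_category, "very_high")
    if egfr is None or egfr <= 0:
        raise ValueError("eGFR must be positive unless esrd_flag is set")
    g = gfr_category(egfr)
    return RiskCategory(g, albuminuria_category, KDIGO_MATRIX[(g, albuminuria_category)])
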