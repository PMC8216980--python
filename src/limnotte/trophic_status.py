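"""Trophic classification of lakes: Carlson TSI and a dystrophy index.

The Carlson trophic state index (TSI) is computed from Secchi disk
visibility (m), chlorophyll a (µg/L) and total phosphorus (µg/L) with the
classical natural-log equations

    TSI(SD)  = 60 − 14.41·ln(SD)
    TSI(Chl) = 9.81·ln(Chl) + 30.6
    TSI(TP)  = 14.42·ln(TP) + 4.15

and the lake's TSI is the arithmetic mean of the three components.
Humic (dystrophic) lakes are flagged separately by a hydrochemical
dystrophy index (HDI) built from surface pH, electric conductivity and
the DIC/DOC ratio: dystrophic water is acidic, ion-poor and DOC-rich, so
the score decreases in all three drivers.  The exact published HDI
coefficients are not reproduced here; the index is a configurable linear
score in (pH, log10 EC, log10 DIC/DOC) whose defaults place typical
advanced-dystrophy chemistry near 70, within the 60–80 band reported for
strongly humic lakes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, ValidationError

#: Canonical trophic class labels, in order of increasing trophy for the
#: three TSI classes; dystrophic is decided by HDI, not TSI.
CLASSES = ("oligotrophic", "mesotrophic", "eutrophic", "dystrophic")


@dataclass(frozen=True)
class LakeChemistry:
    """Surface-water chemistry of one lake.

    sdv: Secchi depth (m); chl: chlorophyll a (µg/L); tp: total
    phosphorus (µg/L); ph: pH; ec: conductivity (µS/cm); dic/doc:
    dissolved inorganic/organic carbon (mg/L).
    """

    sdv: float
    chl: float
    tp: float
    ph: float
    ec: float
    dic: float
    doc: float

    def __post_init__(self) -> None:
        for name in ("sdv", "chl", "tp", "ec", "dic", "doc"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.ph < 14:
            raise ValidationError(f"ph must be in (0, 14), got {self.ph}")


@dataclass(frozen=True)
class HDICoefficients:
    """Linear HDI coefficients; the pH/EC/DIC:DOC terms must be ≤ 0 for
    the score to increase with dystrophy."""

    intercept: float = 120.0
    ph: float = -8.0
    log10_ec: float = -10.0
    log10_dic_doc: float = -8.0


@dataclass(frozen=True)
class ClassThresholds:
    """TSI cutoffs between oligo/meso (t1) and meso/eu (t2), plus the HDI
    dystrophy threshold.  Ties resolve toward the higher-trophy class."""

    tsi_oligo_meso: float = 40.0
    tsi_meso_eu: float = 50.0
    hdi_dystrophic: float = 50.0

    def __post_init__(self) -> None:
        if not self.tsi_oligo_meso < self.tsi_meso_eu:
            raise ValidationError(
                "tsi_oligo_meso must be < tsi_meso_eu "
                f"(got {self.tsi_oligo_meso} >= {self.tsi_meso_eu})"
            )


@dataclass(frozen=True)
class TrophicAssessment:
    tsi_sd: float
    tsi_chl: float
    tsi_tp: float
    tsi_mean: float
    hdi: float
    assigned_class: str


def tsi_components(chem: LakeChemistry) -> tuple:
    """The three Carlson TSI components (SD, Chl, TP)."""
    if chem.sdv <= 0 or chem.chl <= 0 or chem.tp <= 0:
        raise DomainError("sdv, chl and tp must all be > 0")
    tsi_sd = 60.0 - 14.41 * math.log(chem.sdv)
    tsi_chl = 9.81 * math.log(chem.chl) + 30.6
    tsi_tp = 14.42 * math.log(chem.tp) + 4.15
    return tsi_sd, tsi_chl, tsi_tp


def carlson_tsi(chem: LakeChemistry) -> float:
    """Arithmetic mean of the three TSI components."""
    return sum(tsi_components(chem)) / 3.0


def hdi(chem: LakeChemistry, coeffs: HDICoefficients = HDICoefficients()) -> float:
    """Hydrochemical dystrophy index: linear in pH, log10 EC, log10 DIC/DOC."""
    if chem.doc <= 0:
        raise DomainError("doc must be > 0 (DIC/DOC undefined)")
    return (
        coeffs.intercept
        + coeffs.ph * chem.ph
        + coeffs.log10_ec * math.log10(chem.ec)
        + coeffs.log10_dic_doc * math.log10(chem.dic / chem.doc)
    )


def classify(
    tsi_mean: float, hdi_score: float, thresholds: ClassThresholds = ClassThresholds()
) -> str:
    """Assign a trophic class: dystrophic iff HDI ≥ threshold, else by TSI."""
    if hdi_score >= thresholds.hdi_dystrophic:
        return "dystrophic"
    if tsi_mean < thresholds.tsi_oligo_meso:
        return "oligotrophic"
    if tsi_mean < thresholds.tsi_meso_eu:
        return "mesotrophic"
    return "eutrophic"


def assess(
    chem: LakeChemistry,
    coeffs: HDICoefficients = HDICoefficients(),
    thresholds: ClassThresholds = ClassThresholds(),
) -> TrophicAssessment:
    """Full trophic assessment of one lake."""
    tsi_sd, tsi_chl, tsi_tp = tsi_components(chem)
    tsi_mean = (tsi_sd + tsi_chl + tsi_tp) / 3.0
    score = hdi(chem, coeffs)
    return TrophicAssessment(
        tsi_sd=tsi_sd,
        tsi_chl=tsi_chl,
        tsi_tp=tsi_tp,
        tsi_mean=tsi_mean,
        hdi=score,
        assigned_class=classify(tsi_mean, score, thresholds),
    )
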