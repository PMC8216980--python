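"""Trophic transfer efficiency of C, N, P and ω-3 PUFA.

The efficiency for a substance is

    TTE = 100 · consumer production / producer production  (%)

with both productions expressed for the same substance and the same
areal basis (mg m⁻² day⁻¹).  Production of an element other than carbon
is obtained from the carbon production via the element:carbon mass ratio
of the compartment (GPP and SP are measured in carbon, so multiplying a
carbon flux by an element % of dry weight would double-count carbon;
that naive reading remains available as ``basis="naive_pct"`` for
sensitivity analysis).  ω-3 production uses the compartment's ω-3 mass
per unit carbon.

Values above 100% are flagged as artefacts (in the field they arise when
seston ω-3 is too low for reliable measurement); artefacts are excluded
from summary statistics and fold ranges but always retained, flagged, in
per-lake output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .composition import ElementalComposition
from .errors import DomainError

logger = logging.getLogger(__name__)

SUBSTANCES = ("C", "N", "P", "omega3")


@dataclass(frozen=True)
class SubstanceTTE:
    lake_id: str
    substance: str
    producer_production: float  # mg m⁻² day⁻¹
    consumer_production: float  # mg m⁻² day⁻¹
    tte_pct: Optional[float]  # None when producer production is 0
    artefact: bool


def substance_production(
    carbon_production: float,
    comp: Union[ElementalComposition, float],
    substance: str,
    basis: str = "element_ratio",
) -> float:
    """Production of a substance from the compartment's carbon production.

    ``comp`` is the compartment's elemental composition for N and P, the
    ω-3 mass per unit carbon (µg/µg) for ``"omega3"``, and is ignored for
    carbon.
    """
    if carbon_production < 0:
        raise DomainError("carbon production must be >= 0")
    if substance == "C":
        return carbon_production
    if substance == "omega3":
        if not isinstance(comp, (int, float)):
            raise DomainError("omega3 requires the ω-3:C mass ratio of the compartment")
        if comp < 0:
            raise DomainError("ω-3:C ratio must be >= 0")
        return carbon_production * comp
    if substance not in ("N", "P"):
        raise DomainError(f"unknown substance {substance!r}")
    if not isinstance(comp, ElementalComposition):
        raise DomainError(f"{substance} requires an ElementalComposition")
    pct = comp.n_pct if substance == "N" else comp.p_pct
    if basis == "element_ratio":
        return carbon_production * pct / comp.c_pct
    if basis == "naive_pct":
        return carbon_production * pct / 100.0
    raise DomainError(f"unknown basis {basis!r}")


def tte(consumer_production: float, producer_production: float) -> tuple:
    """(TTE %, artefact flag); TTE is ``None`` when producer production is 0."""
    if consumer_production < 0 or producer_production < 0:
        raise DomainError("productions must be >= 0")
    if producer_production == 0:
        return None, False
    pct = 100.0 * consumer_production / producer_production
    return pct, pct > 100.0


def lake_tte(
    lake_id: str,
    areal_gpp_gc: float,
    areal_sp_gc: float,
    seston_comp: ElementalComposition,
    zoo_comp: ElementalComposition,
    seston_omega3_per_c: float,
    zoo_omega3_per_c: float,
    basis: str = "element_ratio",
) -> list:
    """Per-substance TTE of one lake from areal carbon productions (gC m⁻² d⁻¹)."""
    producer_c = areal_gpp_gc * 1000.0  # mg C m⁻² d⁻¹
    consumer_c = areal_sp_gc * 1000.0
    rows = []
    for substance in SUBSTANCES:
        if substance == "omega3":
            pcomp, ccomp = seston_omega3_per_c, zoo_omega3_per_c
        else:
            pcomp, ccomp = seston_comp, zoo_comp
        prod = substance_production(producer_c, pcomp, substance, basis)
        cons = substance_production(consumer_c, ccomp, substance, basis)
        pct, artefact = tte(cons, prod)
        rows.append(
            SubstanceTTE(
                lake_id=lake_id,
                substance=substance,
                producer_production=prod,
                consumer_production=cons,
                tte_pct=pct,
                artefact=artefact,
            )
        )
    return rows


@dataclass(frozen=True)
class FoldRange:
    minimum: float
    maximum: float
    fold: float
    fold_rounded: int


def fold_range(values: Iterable[float], exclude_artefacts: bool = True) -> FoldRange:
    """Between-lake fold difference max/min of positive TTE values.

    Artefacts (> 100%) are excluded first when ``exclude_artefacts``;
    non-positive values are dropped with a logged warning.
    """
    vals = [v for v in values if v is not None]
    if exclude_artefacts:
        vals = [v for v in vals if v <= 100.0]
    nonpos = [v for v in vals if v <= 0]
    if nonpos:
        logger.warning("fold_range: excluding %d non-positive values", len(nonpos))
        vals = [v for v in vals if v > 0]
    if not vals:
        raise DomainError("fold_range needs at least one positive value")
    lo, hi = min(vals), max(vals)
    fold = hi / lo
    return FoldRange(minimum=lo, maximum=hi, fold=fold, fold_rounded=round(fold))


def summarize_by_class(
    tte_rows: Sequence[SubstanceTTE], classes: Mapping[str, str]
) -> pd.DataFrame:
    """Mean ± sd TTE per (trophic class, substance) plus overall rows.

    Artefact-flagged values are excluded from the statistics (they remain
    in ``tte_rows`` with their flag); ``n_artefacts`` counts them.
    ``classes`` maps lake_id to its trophic class; every lake must be
    present.
    """
    missing = sorted({r.lake_id for r in tte_rows} - set(classes))
    if missing:
        raise DomainError("no trophic class for lakes: " + ", ".join(missing))
    recs = []
    for r in tte_rows:
        recs.append(
            {
                "lake_id": r.lake_id,
                "class": classes[r.lake_id],
                "substance": r.substance,
                "tte_pct": r.tte_pct,
                "artefact": r.artefact,
            }
        )
    df = pd.DataFrame.from_records(recs)
    def _summary(cls_label: str, substance: str, g: pd.DataFrame) -> dict:
        kept = g.loc[~g["artefact"] & g["tte_pct"].notna(), "tte_pct"]
        if kept.size > 1:
            sd = float(kept.std(ddof=1))
        else:
            sd = 0.0 if kept.size == 1 else math.nan
        return {
            "class": cls_label,
            "substance": substance,
            "n": int(kept.size),
            "mean_tte_pct": float(kept.mean()) if kept.size else math.nan,
            "sd_tte_pct": sd,
            "n_artefacts": int(g["artefact"].sum()),
        }

    out = []
    for (cls, substance), g in df.groupby(["class", "substance"], sort=False):
        out.append(_summary(cls, substance, g))
    for substance, g in df.groupby("substance", sort=False):
        out.append(_summary("all", substance, g))
    return pd.DataFrame(out)
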