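"""Elemental and fatty-acid composition of seston and zooplankton.

Elemental content is carried as percent of dry weight; stoichiometric
ratios (C:N, C:P) are mass ratios by default.  Fatty acids are identified
by the shorthand ``chain:double-bonds`` with an optional ``n-x`` omega
position and an optional iso/anteiso (``i``/``a``) or summed (``Σ``)
prefix, e.g. ``18:3n-3``, ``i15:0``, ``Σ14:1``.  The ω-3 sum used for
transfer efficiencies covers exactly six acids of the n-3 family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import DomainError, ValidationError

# Atomic masses for the optional molar-ratio basis.
_ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974}

#: The six n-3 acids summed for the ω-3 PUFA transfer efficiency.
OMEGA3_ACIDS = (
    "18:3n-3",
    "18:4n-3",
    "20:4n-3",
    "20:5n-3",
    "22:5n-3",
    "22:6n-3",
)

_FA_RE = re.compile(
    r"^(?P<prefix>i|a|Σ)?(?P<chain>\d{1,2}):(?P<db>\d{1,2})"
    r"(?:n-(?P<omega>\d{1,2}))?(?P<tail>\+\d{1,2}:\d{1,2})?$"
)


def normalize_fa_name(name: str) -> str:
    """Return the canonical form of a fatty-acid shorthand name.

    Case-insensitive; maps the omega aliases ``n3``/``ω3``/``w3`` to
    ``n-3`` and the summed prefixes ``sum``/``σ`` to ``Σ``.  Raises
    :class:`ValidationError` if the name does not parse.
    """
    s = name.strip().lower()
    s = s.replace("sum", "Σ").replace("σ", "Σ")
    # unify omega notation: "ω3", "w3", "n3", "n‐3" (any dash) -> "n-3"
    s = s.replace("ω", "n").replace("w", "n")
    s = re.sub(r"[‐–—‑-]", "-", s)
    s = re.sub(r"n-?(\d)", r"n-\1", s)
    s = s.replace(" ", "")
    if not _FA_RE.match(s):
        raise ValidationError(f"unparseable fatty-acid name: {name!r}")
    return s


@dataclass(frozen=True)
class ElementalComposition:
    """Carbon, nitrogen and phosphorus content as % of dry weight."""

    c_pct: float
    n_pct: float
    p_pct: float

    def __post_init__(self) -> None:
        for name in ("c_pct", "n_pct", "p_pct"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValidationError(f"{name}={v} outside (0, 100)")
        if self.c_pct + self.n_pct + self.p_pct >= 100:
            raise ValidationError("elemental percents sum to >= 100")


def cp_ratio(comp: ElementalComposition, molar: bool = False) -> float:
    """C:P ratio of a compartment (mass basis by default)."""
    if comp.p_pct <= 0:
        raise DomainError("p_pct must be > 0 for a C:P ratio")
    r = comp.c_pct / comp.p_pct
    if molar:
        r *= _ATOMIC_MASS["P"] / _ATOMIC_MASS["C"]
    return r


def cn_ratio(comp: ElementalComposition, molar: bool = False) -> float:
    """C:N ratio of a compartment (mass basis by default)."""
    if comp.n_pct <= 0:
        raise DomainError("n_pct must be > 0 for a C:N ratio")
    r = comp.c_pct / comp.n_pct
    if molar:
        r *= _ATOMIC_MASS["N"] / _ATOMIC_MASS["C"]
    return r


@dataclass
class FattyAcidProfile:
    """Fatty-acid profile: name -> (% of total FA, optional µg/L).

    ``complete=True`` asserts the percent column covers the whole profile
    and must then sum to 100 ± 0.5.  Partial profiles (a few acids of
    interest) use ``complete=False``.
    """

    percents: dict = field(default_factory=dict)
    concentrations: dict = field(default_factory=dict)
    complete: bool = False

    def __post_init__(self) -> None:
        self.percents = {normalize_fa_name(k): float(v) for k, v in self.percents.items()}
        self.concentrations = {
            normalize_fa_name(k): float(v) for k, v in self.concentrations.items()
        }
        for k, v in self.percents.items():
            if v < 0:
                raise ValidationError(f"negative FA percent for {k}")
        for k, v in self.concentrations.items():
            if v < 0:
                raise ValidationError(f"negative FA concentration for {k}")
        if self.complete:
            total = sum(self.percents.values())
            if abs(total - 100.0) > 0.5:
                raise ValidationError(
                    f"complete profile percents sum to {total:.3f}, not 100 ± 0.5"
                )

    def percent(self, name: str) -> float:
        return self.percents.get(normalize_fa_name(name), 0.0)

    def concentration(self, name: str) -> Optional[float]:
        return self.concentrations.get(normalize_fa_name(name))


#: Marker groups of source organisms / material, keyed by group name.
DEFAULT_MARKERS: Mapping[str, tuple] = {
    "bacteria": (
        "i14:0", "Σ14:1", "i15:0", "a15:0", "i15:1", "15:0", "i16:0",
        "i17:0", "a17:0", "17:0", "Σ17:1", "18:1n-7",
    ),
    "detritus": ("16:0", "18:0", "20:0", "Σ22:0+24:0"),
    "terrestrial": ("18:2n-6", "20:4n-6"),
    "diatom": ("16:1n-7", "16:2n-4", "20:5n-3"),
    "green_cyano": ("16:2n-6", "16:3n-3", "16:4n-3", "18:3n-3"),
    "dinophyte": ("22:6n-3",),
    "cryptophyte_flagellate": ("18:4n-3",),
}


def omega3_sum(profile: FattyAcidProfile) -> tuple:
    """Sum of the six ω-3 acids, as (% of total FA, µg/L or None).

    Missing acids contribute zero; the concentration sum is ``None`` when
    no ω-3 acid carries a concentration.
    """
    pct = sum(profile.percents.get(a, 0.0) for a in OMEGA3_ACIDS)
    concs = [profile.concentrations[a] for a in OMEGA3_ACIDS if a in profile.concentrations]
    conc = sum(concs) if concs else None
    return pct, conc


def omega3_per_carbon(profile: FattyAcidProfile, carbon_ug_l: float) -> float:
    """ω-3 mass per unit carbon of a compartment (µg ω-3 per µg C)."""
    if carbon_ug_l <= 0:
        raise DomainError("carbon concentration must be > 0")
    _, conc = omega3_sum(profile)
    if conc is None:
        raise DomainError("profile carries no ω-3 concentrations")
    return conc / carbon_ug_l


def marker_aggregate(
    profile: FattyAcidProfile, markers: Mapping[str, tuple] = DEFAULT_MARKERS
) -> dict:
    """Aggregate FA percents into marker-group totals.

    Acids not listed in any group are summed under ``"unassigned"``.
    """
    norm = {g: {normalize_fa_name(a) for a in acids} for g, acids in markers.items()}
    assigned = set().union(*norm.values()) if norm else set()
    out = {g: sum(profile.percents.get(a, 0.0) for a in acids) for g, acids in norm.items()}
    out["unassigned"] = sum(v for k, v in profile.percents.items() if k not in assigned)
    return out
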