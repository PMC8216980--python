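"""Zooplankton biomass from counts and body lengths.

Individual mass follows the allometric power law W = a·L^b with L in mm.
Crustacean coefficients yield wet weight (µg); rotifer coefficients are
length–weight fits of the same form.  The per-species individual mass of
a sample is the arithmetic mean of the per-individual masses of the
measured lengths (ten individuals per species in the field protocol),
not the mass of the mean length.  Species biomass (mg/L, wet basis) is
mean individual mass (µg) × abundance (ind/L) / 1000.

The coefficient table shipped here carries literature-plausible defaults
for the common north-temperate lake species; real applications should
override it with taxon-specific fits (see ``allometry.csv`` I/O in
:mod:`limnotte.io_cli`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import DomainError, ValidationError

GROUPS = ("Cladocera", "Copepoda", "Rotifera")

#: Default wet→dry mass fraction for crustacean zooplankton.
DEFAULT_WW_TO_DW = 0.10


@dataclass(frozen=True)
class ZooRecord:
    species: str
    group: str
    abundance: float  # ind/L
    lengths: tuple  # mm

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown zooplankton group {self.group!r} for {self.species}"
            )
        if self.abundance < 0:
            raise ValidationError(f"negative abundance for {self.species}")
        if any(l <= 0 for l in self.lengths):
            raise ValidationError(f"non-positive length for {self.species}")


@dataclass(frozen=True)
class ZooplanktonSample:
    lake_id: str
    layer: str
    records: tuple = ()


@dataclass(frozen=True)
class AllometricParams:
    """Power-law coefficients W = a·L^b for one species."""

    species: str
    a: float
    b: float
    output_basis: str = "wet"  # {"wet", "dry"}, µg
    source: str = "default"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError(f"a must be > 0 for {self.species}")
        if not 0 <= self.b <= 5:
            raise ValidationError(f"b must be in [0, 5] for {self.species}")
        if self.output_basis not in ("wet", "dry"):
            raise ValidationError(f"output_basis must be wet or dry for {self.species}")


# (species, group, a [µg], b, basis) — plausible defaults, override for real data.
_DEFAULT_TABLE = [
    ("Daphnia cucullata", "Cladocera", 8.0, 2.7, "wet"),
    ("Daphnia cristata", "Cladocera", 9.0, 2.7, "wet"),
    ("Daphnia longispina", "Cladocera", 11.0, 2.8, "wet"),
    ("Ceriodaphnia quadrangula", "Cladocera", 10.0, 2.6, "wet"),
    ("Bosmina longispina", "Cladocera", 12.0, 2.8, "wet"),
    ("Bosmina thersites", "Cladocera", 12.0, 2.8, "wet"),
    ("Bosmina crassicornis", "Cladocera", 12.0, 2.8, "wet"),
    ("Chydorus sphaericus", "Cladocera", 15.0, 3.0, "wet"),
    ("Diaphanosoma brachyurum", "Cladocera", 7.0, 2.6, "wet"),
    ("Bythotrephes brevimanus", "Cladocera", 20.0, 2.5, "wet"),
    ("Eudiaptomus gracilis", "Copepoda", 6.5, 2.4, "wet"),
    ("Eudiaptomus graciloides", "Copepoda", 6.5, 2.4, "wet"),
    ("Eurytemora lacustris", "Copepoda", 6.5, 2.4, "wet"),
    ("Heterocope appendiculata", "Copepoda", 7.0, 2.5, "wet"),
    ("Mesocyclops leuckarti", "Copepoda", 5.5, 2.4, "wet"),
    ("Thermocyclops oithonoides", "Copepoda", 5.5, 2.4, "wet"),
    ("Asplanchna priodonta", "Rotifera", 5.0, 3.0, "wet"),
    ("Keratella cochlearis", "Rotifera", 1.5, 3.0, "wet"),
    ("Pompholyx sulcata", "Rotifera", 1.2, 3.0, "wet"),
    ("Conochilus unicornis", "Rotifera", 1.8, 3.0, "wet"),
    ("Conochiloides dossuarius", "Rotifera", 1.8, 3.0, "wet"),
    ("Trichocerca spp.", "Rotifera", 1.0, 3.0, "wet"),
]


def default_allometry() -> dict:
    """Species → :class:`AllometricParams` default table."""
    return {
        sp: AllometricParams(species=sp, a=a, b=b, output_basis=basis)
        for sp, _grp, a, b, basis in _DEFAULT_TABLE
    }


def default_species_groups() -> dict:
    """Species → taxonomic group for the default table."""
    return {sp: grp for sp, grp, *_ in _DEFAULT_TABLE}


def individual_mass(length_mm: float, params: AllometricParams) -> float:
    """Mass (µg, on ``params.output_basis``) of one individual of given length."""
    if length_mm <= 0:
        raise DomainError("length must be > 0")
    return params.a * length_mm ** params.b


def mean_individual_mass(lengths: Sequence[float], params: AllometricParams) -> float:
    """Arithmetic mean of per-individual masses (µg)."""
    if not lengths:
        raise DomainError(f"no lengths measured for {params.species}")
    return sum(individual_mass(l, params) for l in lengths) / len(lengths)


@dataclass
class LayerBiomass:
    """Biomass of one sample (mg/L, wet basis) with per-species detail."""

    lake_id: str
    layer: str
    species_biomass: dict = field(default_factory=dict)  # mg/L wet
    group_totals: dict = field(default_factory=dict)  # mg/L wet
    total: float = 0.0  # mg/L wet
    dominance: dict = field(default_factory=dict)  # fraction of total
    mean_dry_ug: dict = field(default_factory=dict)  # µg per individual
    abundance: dict = field(default_factory=dict)  # ind/L
    groups: dict = field(default_factory=dict)  # species -> group


def sample_biomass(
    sample: ZooplanktonSample,
    params_table: Mapping[str, AllometricParams],
    ww_to_dw: float = DEFAULT_WW_TO_DW,
) -> LayerBiomass:
    """Per-species, per-group and total biomass of one sample.

    Raises a single error listing every species missing from the
    parameter table, and errors on a record with nonzero abundance but no
    measured lengths.
    """
    missing = sorted(
        {r.species for r in sample.records if r.species not in params_table}
    )
    if missing:
        raise DomainError(
            "no allometric parameters for species: " + ", ".join(missing)
        )
    out = LayerBiomass(lake_id=sample.lake_id, layer=sample.layer)
    out.group_totals = {g: 0.0 for g in GROUPS}
    for rec in sample.records:
        params = params_table[rec.species]
        if rec.abundance > 0 and not rec.lengths:
            raise DomainError(
                f"{rec.species}: nonzero abundance but no measured lengths"
            )
        if rec.lengths:
            mass = mean_individual_mass(rec.lengths, params)
        else:
            mass = 0.0
        if params.output_basis == "dry":
            dry, wet = mass, mass / ww_to_dw
        else:
            wet, dry = mass, mass * ww_to_dw
        b = wet * rec.abundance / 1000.0  # µg/L -> mg/L
        out.species_biomass[rec.species] = out.species_biomass.get(rec.species, 0.0) + b
        out.group_totals[rec.group] = out.group_totals.get(rec.group, 0.0) + b
        out.mean_dry_ug[rec.species] = dry
        out.abundance[rec.species] = out.abundance.get(rec.species, 0.0) + rec.abundance
        out.groups[rec.species] = rec.group
    out.total = sum(out.species_biomass.values())
    if out.total > 0:
        out.dominance = {s: b / out.total for s, b in out.species_biomass.items()}
    else:
        out.dominance = {}
    return out
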