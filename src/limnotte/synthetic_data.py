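"""Seeded, class-stratified synthetic lake surveys.

The generator emulates a mid-summer survey of north-temperate lakes in
four trophic classes (oligotrophic, mesotrophic, eutrophic, dystrophic):
surface chemistry, layered chlorophyll/φPSII/PAR profiles, per-layer
zooplankton counts with ten measured lengths per species, and seston /
zooplankton elemental and fatty-acid composition.  Class-specific
defaults follow the published survey statistics this pipeline targets
(whole-profile chlorophyll class means; Secchi depths; shallow two-layer
dystrophic lakes; distinct zooplankton assemblages; high seston C:P in
dystrophic and oligotrophic lakes; fatty-acid marker structure with a
green-algae-enriched dystrophic subset).

Strictly positive quantities are drawn from lognormal distributions
re-parameterized to the stated arithmetic mean and sd (right-skewed like
field data); pH is drawn normal.  One master seed drives per-lake
substreams derived by stable hashing of (seed, lake_id), so output is
independent of generation order and bit-identical across runs.

The ``tte_structure`` entry of the configuration co-scales each lake's
zooplankton abundances against its modelled GPP so that the lake's
carbon transfer efficiency equals a lognormal draw with the configured
class mean/sd — the generated surveys therefore carry a known TTE
structure that the analysis pipeline can be asked to recover.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import biomass as _biomass
from . import production as _production
from .biomass import AllometricParams, ZooRecord, ZooplanktonSample
from .composition import ElementalComposition, FattyAcidProfile
from .errors import ConfigurationError
from .production import ConversionConstants, LayerProfile, LightResponseParams
from .trophic_status import CLASSES, LakeChemistry

#: Diffuse-attenuation over Secchi-depth product used to build PAR profiles.
K_PAR_TIMES_SDV = 1.7


def _normalized(template: Mapping[str, float]) -> dict:
    total = sum(template.values())
    return {k: v / total for k, v in template.items()}


# --- fatty-acid proportion templates (sum to 1) ----------------------------

_SESTON_GROUP1 = _normalized({
    "14:0": 0.05, "i14:0": 0.01, "Σ14:1": 0.01, "i15:0": 0.015, "a15:0": 0.015,
    "i15:1": 0.005, "15:0": 0.01, "i16:0": 0.01, "i17:0": 0.005, "a17:0": 0.005,
    "17:0": 0.005, "Σ17:1": 0.005, "18:1n-7": 0.03,
    "16:0": 0.18, "18:0": 0.05, "20:0": 0.01, "Σ22:0+24:0": 0.02,
    "18:2n-6": 0.06, "20:4n-6": 0.02,
    "16:1n-7": 0.10, "16:2n-4": 0.02,
    "16:2n-6": 0.005, "16:3n-3": 0.01, "16:4n-3": 0.01,
    "18:1n-9": 0.06,
    "18:3n-3": 0.06, "18:4n-3": 0.02, "20:4n-3": 0.005,
    "20:5n-3": 0.07, "22:5n-3": 0.005, "22:6n-3": 0.04,
})

_SESTON_DYSTROPHIC = _normalized({
    "14:0": 0.05, "i14:0": 0.01, "Σ14:1": 0.01, "i15:0": 0.02, "a15:0": 0.02,
    "i15:1": 0.005, "15:0": 0.01, "i16:0": 0.01, "i17:0": 0.005, "a17:0": 0.005,
    "17:0": 0.005, "Σ17:1": 0.005, "18:1n-7": 0.03,
    "16:0": 0.15, "18:0": 0.05, "20:0": 0.01, "Σ22:0+24:0": 0.02,
    "18:2n-6": 0.06, "20:4n-6": 0.02,
    "16:1n-7": 0.04, "16:2n-4": 0.01,
    "16:2n-6": 0.05, "16:3n-3": 0.06, "16:4n-3": 0.04,
    "18:1n-9": 0.05,
    "18:3n-3": 0.12, "18:4n-3": 0.02, "20:4n-3": 0.005,
    "20:5n-3": 0.03, "22:5n-3": 0.005, "22:6n-3": 0.02,
})

_ZOO_BASE = _normalized({
    "14:0": 0.04, "i15:0": 0.01, "a15:0": 0.01, "15:0": 0.01,
    "16:0": 0.14, "18:0": 0.03,
    "16:1n-7": 0.07, "18:1n-9": 0.08, "18:1n-7": 0.03,
    "18:2n-6": 0.05, "20:4n-6": 0.02,
    "16:2n-6": 0.005, "16:3n-3": 0.005,
    "18:3n-3": 0.08, "18:4n-3": 0.04, "20:4n-3": 0.01,
    "20:5n-3": 0.17, "22:5n-3": 0.01, "22:6n-3": 0.09,
})

_ZOO_DYS_ENRICHED = _normalized({**_ZOO_BASE, "16:2n-6": 0.05, "16:3n-3": 0.06})


@dataclass(frozen=True)
class SpeciesSpec:
    """Abundance and length distributions of one species in an assemblage."""

    species: str
    group: str
    abundance_mean: float  # ind/L
    abundance_sd: float
    length_mean_mm: float
    length_sd_mm: float


def _sp(species, group, am, asd, lm, lsd):
    return SpeciesSpec(species, group, am, asd, lm, lsd)


_COMMON = [
    _sp("Daphnia cucullata", "Cladocera", 30, 20, 1.0, 0.15),
    _sp("Diaphanosoma brachyurum", "Cladocera", 15, 10, 0.8, 0.12),
    _sp("Thermocyclops oithonoides", "Copepoda", 25, 15, 0.7, 0.10),
    _sp("Mesocyclops leuckarti", "Copepoda", 15, 10, 0.9, 0.12),
    _sp("Eudiaptomus graciloides", "Copepoda", 12, 8, 1.1, 0.15),
    _sp("Keratella cochlearis", "Rotifera", 100, 80, 0.15, 0.02),
]

_ASSEMBLAGES = {
    "oligotrophic": _COMMON + [
        _sp("Daphnia cristata", "Cladocera", 10, 6, 1.1, 0.15),
        _sp("Eurytemora lacustris", "Copepoda", 6, 4, 1.2, 0.15),
        _sp("Heterocope appendiculata", "Copepoda", 2, 1.5, 1.6, 0.20),
        _sp("Conochilus unicornis", "Rotifera", 40, 30, 0.25, 0.04),
    ],
    "mesotrophic": _COMMON + [
        _sp("Daphnia cristata", "Cladocera", 8, 5, 1.1, 0.15),
        _sp("Bosmina crassicornis", "Cladocera", 15, 10, 0.45, 0.07),
    ],
    "eutrophic": _COMMON + [
        _sp("Bosmina thersites", "Cladocera", 40, 30, 0.45, 0.07),
        _sp("Chydorus sphaericus", "Cladocera", 30, 20, 0.30, 0.05),
        _sp("Pompholyx sulcata", "Rotifera", 120, 100, 0.12, 0.02),
    ],
    "dystrophic": [
        _sp("Asplanchna priodonta", "Rotifera", 40, 30, 0.8, 0.15),
        _sp("Ceriodaphnia quadrangula", "Cladocera", 25, 15, 0.5, 0.08),
        _sp("Eudiaptomus gracilis", "Copepoda", 15, 10, 1.1, 0.15),
        _sp("Bosmina longispina", "Cladocera", 20, 12, 0.5, 0.08),
        _sp("Mesocyclops leuckarti", "Copepoda", 12, 8, 0.9, 0.12),
        _sp("Diaphanosoma brachyurum", "Cladocera", 10, 6, 0.8, 0.12),
        _sp("Conochiloides dossuarius", "Rotifera", 60, 40, 0.20, 0.03),
    ],
}

_CHL_WEIGHTS_3 = {
    "epilimnion-max": (2.2, 0.7, 0.3),
    "metalimnion-max": (0.7, 2.5, 0.5),
    "uniform": (1.0, 1.0, 1.0),
}
_CHL_WEIGHTS_2 = {
    "epilimnion-max": (2.0, 0.5),
    "metalimnion-max": (0.6, 2.4),
    "uniform": (1.0, 1.0),
}


@dataclass(frozen=True)
class LakeSurvey:
    """One lake's full observation set."""

    lake_id: str
    true_class: str
    chemistry: LakeChemistry
    profiles: tuple  # LayerProfile, surface first
    zoo_samples: tuple  # ZooplanktonSample, one per layer
    seston_comp: ElementalComposition
    seston_fa: FattyAcidProfile
    zoo_comp: ElementalComposition
    zoo_fa: FattyAcidProfile

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ConfigurationError(f"{self.lake_id}: survey needs at least one layer")
        layers = {p.layer for p in self.profiles}
        for s in self.zoo_samples:
            if s.layer not in layers:
                raise ConfigurationError(
                    f"{self.lake_id}: zoo sample references unknown layer {s.layer!r}"
                )


@dataclass
class GeneratorConfig:
    """Seeded distributional parameters of the synthetic survey.

    All (mean, sd) pairs parameterize arithmetic moments; positive
    variables are drawn lognormal, pH normal.  ``tte_structure`` holds
    the per-class target carbon-TTE (mean %, sd %) used to co-scale
    zooplankton abundances against modelled GPP; set a class entry to
    ``None`` to leave abundances unscaled.
    """

    seed: int = 0
    n_lakes_per_class: dict = field(
        default_factory=lambda: {
            "oligotrophic": 5, "mesotrophic": 7, "eutrophic": 8, "dystrophic": 10,
        }
    )
    chl_mean_sd: dict = field(
        default_factory=lambda: {
            "oligotrophic": (4.79, 7.95), "mesotrophic": (5.97, 5.92),
            "eutrophic": (14.62, 17.56), "dystrophic": (47.65, 35.76),
        }
    )
    sdv_mean_sd: dict = field(
        default_factory=lambda: {
            "oligotrophic": (5.6, 1.5), "mesotrophic": (2.5, 1.1),
            "eutrophic": (1.3, 0.6), "dystrophic": (1.3, 0.5),
        }
    )
    tp_mean_sd: dict = field(
        default_factory=lambda: {
            "oligotrophic": (8.0, 4.0), "mesotrophic": (18.0, 6.0),
            "eutrophic": (45.0, 20.0), "dystrophic": (30.0, 15.0),
        }
    )
    ph_mean_sd: dict = field(
        default_factory=lambda: {
            "oligotrophic": (8.1, 0.25), "mesotrophic": (8.2, 0.25),
            "eutrophic": (8.4, 0.30), "dystrophic": (5.5, 0.50),
        }
    )
    ec_mean_sd: dict = field(
        default_factory=lambda: {
            "oligotrophic": (280.0, 50.0), "mesotrophic": (300.0, 60.0),
            "eutrophic": (320.0, 70.0), "dystrophic": (30.0, 10.0),
        }
    )
    dic_mean_sd: dict = field(
        default_factory=lambda: {
            "oligotrophic": (18.0, 4.0), "mesotrophic": (20.0, 4.0),
            "eutrophic": (22.0, 5.0), "dystrophic": (2.0, 0.8),
        }
    )
    doc_mean_sd: dict = field(
        default_factory=lambda: {
            "oligotrophic": (6.0, 1.5), "mesotrophic": (7.0, 2.0),
            "eutrophic": (9.0, 2.5), "dystrophic": (20.0, 6.0),
        }
    )
    depth_layers: dict = field(
        default_factory=lambda: {
            cls: [("epilimnion", 0.0, 5.0), ("metalimnion", 5.0, 10.0),
                  ("hypolimnion", 10.0, 20.0)]
            for cls in ("oligotrophic", "mesotrophic", "eutrophic")
        } | {"dystrophic": [("epilimnion", 0.0, 2.0), ("metalimnion", 2.0, 5.0)]}
    )
    chl_vertical_mode: dict = field(
        default_factory=lambda: {
            "oligotrophic": "metalimnion-max", "mesotrophic": "metalimnion-max",
            "eutrophic": "epilimnion-max", "dystrophic": "metalimnion-max",
        }
    )
    zoo_assemblage: dict = field(default_factory=lambda: {
        cls: list(spp) for cls, spp in _ASSEMBLAGES.items()
    })
    seston_cp_mean_sd: dict = field(
        default_factory=lambda: {
            "oligotrophic": (140.0, 30.0), "mesotrophic": (85.0, 20.0),
            "eutrophic": (95.0, 25.0), "dystrophic": (160.0, 45.0),
        }
    )
    seston_cn_mean_sd: dict = field(
        default_factory=lambda: {cls: (8.0, 2.1) for cls in CLASSES}
    )
    fa_profile_template: dict = field(
        default_factory=lambda: {
            "oligotrophic": dict(_SESTON_GROUP1), "mesotrophic": dict(_SESTON_GROUP1),
            "eutrophic": dict(_SESTON_GROUP1), "dystrophic": dict(_SESTON_DYSTROPHIC),
        }
    )
    zoo_fa_template: dict = field(
        default_factory=lambda: {cls: dict(_ZOO_BASE) for cls in CLASSES}
    )
    tte_structure: dict = field(
        default_factory=lambda: {
            "oligotrophic": (14.31, 6.50), "mesotrophic": (8.0, 4.0),
            "eutrophic": (4.28, 4.49), "dystrophic": (2.89, 3.45),
        }
    )
    # secondary knobs
    seston_c_pct_mean_sd: tuple = (35.0, 4.0)
    zoo_c_pct_mean_sd: tuple = (47.7, 1.7)
    zoo_cp_mean_sd: tuple = (53.7, 13.0)
    zoo_cn_mean_sd: tuple = (4.9, 1.0)
    phi_psii_mean_sd: tuple = (0.55, 0.08)
    surface_par_mean_sd: tuple = (1200.0, 300.0)
    chl_weight_noise_sd: float = 0.35
    fa_noise_sd: float = 0.20
    seston_fa_per_c: float = 0.040  # g total FA per g seston C
    zoo_fa_per_c: float = 0.064  # g total FA per g zooplankton C
    dystrophic_green_zoo_fraction: float = 0.3
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    light: LightResponseParams = field(default_factory=LightResponseParams)
    allometry: dict = field(default_factory=_biomass.default_allometry)


def table1_preset(config: Optional[GeneratorConfig] = None) -> GeneratorConfig:
    """Alternate preset with the survey's summary-table chlorophyll class
    means (epilimnion-weighted) instead of the whole-profile averages."""
    cfg = config or GeneratorConfig()
    cfg = replace(cfg) if isinstance(cfg, GeneratorConfig) else cfg
    cfg.chl_mean_sd = {
        "oligotrophic": (9.2, 13.2), "mesotrophic": (7.5, 2.3),
        "eutrophic": (29.2, 21.9), "dystrophic": (70.2, 37.8),
    }
    return cfg


def validate_config(config: GeneratorConfig) -> None:
    """Raise :class:`ConfigurationError` naming the offending field."""
    class_keyed = (
        "n_lakes_per_class", "chl_mean_sd", "sdv_mean_sd", "tp_mean_sd",
        "ph_mean_sd", "ec_mean_sd", "dic_mean_sd", "doc_mean_sd",
        "depth_layers", "chl_vertical_mode", "zoo_assemblage",
        "seston_cp_mean_sd", "seston_cn_mean_sd", "fa_profile_template",
        "zoo_fa_template", "tte_structure",
    )
    for name in class_keyed:
        keys = set(getattr(config, name).keys())
        if keys != set(CLASSES):
            raise ConfigurationError(
                f"{name}: class keys must be exactly {set(CLASSES)}, got {keys}"
            )
    for name in ("chl_mean_sd", "sdv_mean_sd", "tp_mean_sd", "ph_mean_sd",
                 "ec_mean_sd", "dic_mean_sd", "doc_mean_sd",
                 "seston_cp_mean_sd", "seston_cn_mean_sd"):
        for cls, (mean, sd) in getattr(config, name).items():
            if mean <= 0:
                raise ConfigurationError(f"{name}[{cls}]: mean must be > 0")
            if sd < 0:
                raise ConfigurationError(f"{name}[{cls}]: sd must be >= 0")
    for cls, n in config.n_lakes_per_class.items():
        if n < 0 or int(n) != n:
            raise ConfigurationError(f"n_lakes_per_class[{cls}] must be a non-negative integer")
    for cls, layers in config.depth_layers.items():
        for (name_a, top_a, bot_a), (name_b, top_b, bot_b) in zip(layers, layers[1:]):
            if bot_a <= top_a or bot_b <= top_b or top_b < bot_a:
                raise ConfigurationError(
                    f"depth_layers[{cls}]: intervals must be ordered and non-overlapping"
                )
        if layers and layers[0][2] <= layers[0][1]:
            raise ConfigurationError(f"depth_layers[{cls}]: empty interval")
    for cls, mode in config.chl_vertical_mode.items():
        if mode not in _CHL_WEIGHTS_3:
            raise ConfigurationError(
                f"chl_vertical_mode[{cls}]: unknown mode {mode!r}"
            )
    for name in ("fa_profile_template", "zoo_fa_template"):
        for cls, template in getattr(config, name).items():
            total = sum(template.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{name}[{cls}]: proportions sum to {total}, not 1"
                )
    for cls, entry in config.tte_structure.items():
        if entry is None:
            continue
        mean, sd = entry
        if mean <= 0 or sd < 0:
            raise ConfigurationError(f"tte_structure[{cls}]: mean > 0 and sd >= 0 required")
    for cls, spp in config.zoo_assemblage.items():
        for s in spp:
            if s.abundance_mean < 0 or s.abundance_sd < 0:
                raise ConfigurationError(
                    f"zoo_assemblage[{cls}]: negative abundance parameters for {s.species}"
                )
            if s.group not in _biomass.GROUPS:
                raise ConfigurationError(
                    f"zoo_assemblage[{cls}]: unknown group {s.group!r} for {s.species}"
                )


def _lake_rng(seed: int, lake_id: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{lake_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Lognormal draw with the given arithmetic mean and sd (sd=0 → mean)."""
    if sd == 0:
        return mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _normal_clipped(rng, mean, sd, lo, hi) -> float:
    if sd == 0:
        return mean
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_zoo_sample(
    assemblage: Sequence[SpeciesSpec],
    layer: LayerProfile,
    seed: Union[int, np.random.Generator],
    lake_id: str = "",
    n_lengths: int = 10,
) -> ZooplanktonSample:
    """Draw one layer's zooplankton sample (counts in ind/L, ``n_lengths``
    body lengths per species present)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for spec in assemblage:
        abundance = _lognormal(rng, spec.abundance_mean, spec.abundance_sd) \
            if spec.abundance_mean > 0 else 0.0
        lengths = tuple(
            _lognormal(rng, spec.length_mean_mm, spec.length_sd_mm)
            for _ in range(n_lengths)
        )
        records.append(
            ZooRecord(species=spec.species, group=spec.group,
                      abundance=abundance, lengths=lengths)
        )
    return ZooplanktonSample(lake_id=lake_id, layer=layer.layer, records=tuple(records))


def _layer_par(surface_par: float, k: float, top: float, bottom: float) -> float:
    """Depth-average PAR of an exponentially attenuated profile."""
    return surface_par * (math.exp(-k * top) - math.exp(-k * bottom)) / (k * (bottom - top))


def _chl_profile(rng, config, cls, layers, lake_chl) -> list:
    mode = config.chl_vertical_mode[cls]
    base = (_CHL_WEIGHTS_3 if len(layers) >= 3 else _CHL_WEIGHTS_2)[mode]
    base = base[: len(layers)]
    noise = [
        _lognormal(rng, 1.0, config.chl_weight_noise_sd) for _ in layers
    ]
    w = [b * e for b, e in zip(base, noise)]
    thick = [bot - top for _, top, bot in layers]
    wmean = sum(wi * t for wi, t in zip(w, thick)) / sum(thick)
    return [lake_chl * wi / wmean for wi in w]


def _draw_composition(rng, c_mean_sd, cp_mean_sd, cn_mean_sd) -> ElementalComposition:
    c = _normal_clipped(rng, *c_mean_sd, 5.0, 90.0)
    cp = _lognormal(rng, *cp_mean_sd)
    cn = _lognormal(rng, *cn_mean_sd)
    cn = max(cn, 1.2)  # keep n below c and the total under 100
    return ElementalComposition(c_pct=c, n_pct=c / cn, p_pct=c / cp)


def _draw_fa_profile(rng, template, noise_sd, total_conc_ug_l) -> FattyAcidProfile:
    noisy = {k: v * _lognormal(rng, 1.0, noise_sd) for k, v in template.items()}
    total = sum(noisy.values())
    pct = {k: 100.0 * v / total for k, v in noisy.items()}
    conc = {k: p / 100.0 * total_conc_ug_l for k, p in pct.items()}
    return FattyAcidProfile(percents=pct, concentrations=conc, complete=True)


def _mean_wet_biomass_mg_l(samples, layers, allometry, ww_to_dw) -> float:
    thick = [bot - top for _, top, bot in layers]
    total = 0.0
    for s, t in zip(samples, thick):
        lb = _biomass.sample_biomass(s, allometry, ww_to_dw)
        total += lb.total * t
    return total / sum(thick)


def generate_survey(config: GeneratorConfig) -> list:
    """Generate the configured number of lakes per class.

    Deterministic for a given configuration (including seed); lakes are
    returned in class order (oligo-, meso-, eu-, dystrophic)."""
    validate_config(config)
    surveys = []
    for cls in CLASSES:
        for i in range(int(config.n_lakes_per_class[cls])):
            lake_id = f"{cls[:5]}-{i + 1:04d}"
            surveys.append(_generate_lake(config, cls, lake_id))
    return surveys


def _generate_lake(config: GeneratorConfig, cls: str, lake_id: str) -> LakeSurvey:
    rng = _lake_rng(config.seed, lake_id)
    chem = LakeChemistry(
        sdv=_lognormal(rng, *config.sdv_mean_sd[cls]),
        chl=_lognormal(rng, *config.chl_mean_sd[cls]),
        tp=_lognormal(rng, *config.tp_mean_sd[cls]),
        ph=_normal_clipped(rng, *config.ph_mean_sd[cls], 0.1, 13.9),
        ec=_lognormal(rng, *config.ec_mean_sd[cls]),
        dic=_lognormal(rng, *config.dic_mean_sd[cls]),
        doc=_lognormal(rng, *config.doc_mean_sd[cls]),
    )
    layers = config.depth_layers[cls]
    chl_layers = _chl_profile(rng, config, cls, layers, chem.chl)
    surface_par = _lognormal(rng, *config.surface_par_mean_sd)
    k = K_PAR_TIMES_SDV / chem.sdv
    profiles = tuple(
        LayerProfile(
            layer=name,
            top_m=top,
            bottom_m=bot,
            chl=chl,
            phi_psii=_normal_clipped(rng, *config.phi_psii_mean_sd, 0.05, 0.95),
            par=_layer_par(surface_par, k, top, bot),
        )
        for (name, top, bot), chl in zip(layers, chl_layers)
    )
    samples = [
        generate_zoo_sample(config.zoo_assemblage[cls], p, rng, lake_id=lake_id)
        for p in profiles
    ]

    # Co-scale abundances so the lake's carbon TTE equals a drawn target.
    target = config.tte_structure[cls]
    if target is not None and samples:
        prod = _production.compute_production(
            lake_id, profiles, samples, config.allometry,
            constants=config.constants, light=config.light,
        )
        if prod.areal_sp > 0 and prod.areal_gpp > 0:
            tte_target = _lognormal(rng, *target)
            factor = (tte_target / 100.0) * prod.areal_gpp / prod.areal_sp
            samples = [
                ZooplanktonSample(
                    lake_id=s.lake_id,
                    layer=s.layer,
                    records=tuple(
                        ZooRecord(
                            species=r.species, group=r.group,
                            abundance=r.abundance * factor, lengths=r.lengths,
                        )
                        for r in s.records
                    ),
                )
                for s in samples
            ]

    seston_comp = _draw_composition(
        rng, config.seston_c_pct_mean_sd,
        config.seston_cp_mean_sd[cls], config.seston_cn_mean_sd[cls],
    )
    zoo_comp = _draw_composition(
        rng, config.zoo_c_pct_mean_sd, config.zoo_cp_mean_sd, config.zoo_cn_mean_sd,
    )

    seston_c_ug_l = chem.chl * config.constants.c_per_chl
    seston_fa = _draw_fa_profile(
        rng, config.fa_profile_template[cls], config.fa_noise_sd,
        seston_c_ug_l * config.seston_fa_per_c,
    )
    zoo_template = config.zoo_fa_template[cls]
    if cls == "dystrophic" and rng.random() < config.dystrophic_green_zoo_fraction:
        zoo_template = _ZOO_DYS_ENRICHED
    zoo_wet_mg_l = _mean_wet_biomass_mg_l(
        samples, layers, config.allometry, config.constants.ww_to_dw
    )
    zoo_c_ug_l = zoo_wet_mg_l * 1000.0 * config.constants.ww_to_dw * config.constants.dw_to_c
    zoo_fa = _draw_fa_profile(
        rng, zoo_template, config.fa_noise_sd, zoo_c_ug_l * config.zoo_fa_per_c,
    )
    return LakeSurvey(
        lake_id=lake_id,
        true_class=cls,
        chemistry=chem,
        profiles=profiles,
        zoo_samples=tuple(samples),
        seston_comp=seston_comp,
        seston_fa=seston_fa,
        zoo_comp=zoo_comp,
        zoo_fa=zoo_fa,
    )
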