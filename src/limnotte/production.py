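"""Primary and secondary production in carbon units.

Gross primary production (GPP) is modelled per layer from chlorophyll,
the DCMU-derived potential photochemical activity of PSII (φPSII) and
PAR through a pluggable light-response model, in mg O₂ m⁻³ day⁻¹, then
converted to carbon with the fixed factor 0.32 gC/gO₂.  The default
model is a saturating tanh response,

    GPP_O₂(z) = p_max_per_chl · chl(z) · φPSII(z) · tanh(PAR(z)/PAR_sat) · daylength,

with ``p_max_per_chl`` in mg O₂ per mg chl per hour (chl in µg/L equals
mg/m³, so the product is volumetric).

Crustacean secondary production uses the allometric regression

    SP = 10^(−0.23·log₁₀(M) − 0.73) · 1.12 · M · N
       = 1.12 · 10^(−0.73) · M^0.77 · N

with SP in µg DW L⁻¹ day⁻¹, M the mean individual dry weight (µg) and N
the abundance (ind/L).  Dry weight converts to carbon by the 1/2.3
quotient.  SP is computed per crustacean species from that species' mean
individual dry weight and summed; rotifers contribute to biomass but are
outside the regression's scope.

Areal (m⁻²) values come from thickness-weighted rectangular integration
of the per-layer volumetric composites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from . import biomass as _biomass
from .errors import ConfigurationError, DomainError, ValidationError


@dataclass(frozen=True)
class LayerProfile:
    """One depth layer: interval (m), chl (µg/L), φPSII (0–1), PAR
    (µmol photons m⁻² s⁻¹, layer average)."""

    layer: str
    top_m: float
    bottom_m: float
    chl: float
    phi_psii: float
    par: float

    def __post_init__(self) -> None:
        if self.bottom_m <= self.top_m:
            raise ValidationError(f"layer {self.layer}: bottom must exceed top")
        if self.chl < 0:
            raise ValidationError(f"layer {self.layer}: negative chl")
        if not 0 <= self.phi_psii <= 1:
            raise ValidationError(f"layer {self.layer}: phi_psii outside [0, 1]")
        if self.par < 0:
            raise ValidationError(f"layer {self.layer}: negative par")

    @property
    def thickness(self) -> float:
        return self.bottom_m - self.top_m


def validate_profiles(profiles: Sequence[LayerProfile]) -> None:
    """Check layers are ordered, non-overlapping and light-attenuating."""
    for a, b in zip(profiles, profiles[1:]):
        if b.top_m < a.bottom_m:
            raise ValidationError(f"layers {a.layer} and {b.layer} overlap")
        if b.par > a.par:
            raise ValidationError("par must be non-increasing with depth")


@dataclass(frozen=True)
class ConversionConstants:
    """Fixed unit conversions of the pipeline."""

    o2_to_c: float = 0.32  # gC per gO₂
    dw_to_c: float = 1.0 / 2.3  # gC per g dry weight
    ww_to_dw: float = _biomass.DEFAULT_WW_TO_DW
    c_per_chl: float = 50.0  # g seston C per g chl a (mass ratio)

    def __post_init__(self) -> None:
        for name in ("o2_to_c", "dw_to_c", "ww_to_dw", "c_per_chl"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass(frozen=True)
class LightResponseParams:
    p_max_per_chl: float = 10.0  # mg O₂ (mg chl)⁻¹ hr⁻¹
    par_sat: float = 200.0  # µmol photons m⁻² s⁻¹
    daylength_hr: float = 16.0


def _tanh_model(layer: LayerProfile, params: LightResponseParams) -> float:
    """Saturating light response; returns mg O₂ m⁻³ day⁻¹."""
    return (
        params.p_max_per_chl
        * layer.chl
        * layer.phi_psii
        * math.tanh(layer.par / params.par_sat)
        * params.daylength_hr
    )


#: Registry of light-response models (name -> callable(layer, params) -> mgO₂ m⁻³ d⁻¹).
LIGHT_MODELS: dict = {"tanh": _tanh_model}


def gpp_o2_to_carbon(gpp_o2: float, constants: ConversionConstants = ConversionConstants()) -> float:
    """Convert a GPP value from O₂ to carbon units (× 0.32 by default)."""
    if gpp_o2 < 0:
        raise DomainError("gpp_o2 must be >= 0")
    return gpp_o2 * constants.o2_to_c


def dw_to_carbon(dw: float, constants: ConversionConstants = ConversionConstants()) -> float:
    """Convert a dry-weight mass to carbon (÷ 2.3 by default)."""
    if dw < 0:
        raise DomainError("dw must be >= 0")
    return dw * constants.dw_to_c


def secondary_production(m_ug: float, n_per_l: float, log_base: int = 10) -> float:
    """Daily crustacean production (µg DW L⁻¹ day⁻¹) from mean individual
    dry weight M (µg) and abundance N (ind/L).

    ``log_base`` selects the logarithm used inside the regression's
    exponent (10, the source convention, or ``math.e``).
    """
    if n_per_l < 0:
        raise DomainError("abundance must be >= 0")
    if n_per_l == 0:
        return 0.0
    if m_ug <= 0:
        raise DomainError("mean individual dry weight must be > 0")
    if log_base == 10:
        logm = math.log10(m_ug)
    else:
        logm = math.log(m_ug)
    return 10.0 ** (-0.23 * logm - 0.73) * 1.12 * m_ug * n_per_l


def gpp_profile(
    profiles: Sequence[LayerProfile],
    model: str = "tanh",
    constants: ConversionConstants = ConversionConstants(),
    params: LightResponseParams = LightResponseParams(),
) -> list:
    """Per-layer GPP in mg C m⁻³ day⁻¹ under the named light-response model."""
    if model not in LIGHT_MODELS:
        raise ConfigurationError(
            f"unknown light-response model {model!r}; registered: "
            + ", ".join(sorted(LIGHT_MODELS))
        )
    fn: Callable = LIGHT_MODELS[model]
    return [gpp_o2_to_carbon(fn(layer, params), constants) for layer in profiles]


def sp_profile(
    samples: Sequence[_biomass.ZooplanktonSample],
    params_table: Mapping[str, _biomass.AllometricParams],
    constants: ConversionConstants = ConversionConstants(),
    log_base: int = 10,
) -> list:
    """Per-sample crustacean SP in mg C m⁻³ day⁻¹ (order follows ``samples``).

    µg C L⁻¹ day⁻¹ and mg C m⁻³ day⁻¹ are numerically identical, so the
    dry-weight regression output converts by ``dw_to_c`` alone.
    """
    out = []
    for sample in samples:
        lb = _biomass.sample_biomass(sample, params_table, constants.ww_to_dw)
        sp_dw = 0.0
        for species, group in lb.groups.items():
            if group == "Rotifera":
                continue
            n = lb.abundance[species]
            if n == 0:
                continue
            sp_dw += secondary_production(lb.mean_dry_ug[species], n, log_base)
        out.append(dw_to_carbon(sp_dw, constants))
    return out


def depth_integrate(volumetric: Sequence[float], thicknesses: Sequence[float]) -> tuple:
    """Integrate per-layer volumetric values (mg m⁻³ day⁻¹) over depth.

    Returns (areal g m⁻² day⁻¹, per-layer shares).  Shares are an empty
    list when the areal total is zero.
    """
    if len(volumetric) != len(thicknesses):
        raise DomainError("volumetric and thickness lists differ in length")
    if any(t <= 0 for t in thicknesses):
        raise DomainError("thicknesses must be > 0")
    contrib = [v * t / 1000.0 for v, t in zip(volumetric, thicknesses)]
    total = sum(contrib)
    shares = [c / total for c in contrib] if total > 0 else []
    return total, shares


@dataclass
class ProductionProfile:
    """Depth-resolved and areal production of one lake (carbon units)."""

    lake_id: str
    layers: list = field(default_factory=list)
    gpp_volumetric: list = field(default_factory=list)  # mg C m⁻³ d⁻¹
    sp_volumetric: list = field(default_factory=list)  # mg C m⁻³ d⁻¹
    areal_gpp: float = 0.0  # g C m⁻² d⁻¹
    areal_sp: float = 0.0  # g C m⁻² d⁻¹
    gpp_shares: list = field(default_factory=list)
    epilimnion_gpp_share: float = float("nan")


def compute_production(
    lake_id: str,
    profiles: Sequence[LayerProfile],
    samples: Sequence[_biomass.ZooplanktonSample],
    params_table: Mapping[str, _biomass.AllometricParams],
    model: str = "tanh",
    constants: ConversionConstants = ConversionConstants(),
    light: LightResponseParams = LightResponseParams(),
    log_base: int = 10,
) -> ProductionProfile:
    """Full production profile of one lake.

    ``samples`` must be ordered like ``profiles`` (one per layer).
    """
    if len(samples) != len(profiles):
        raise DomainError("one zooplankton sample per layer is required")
    gpp = gpp_profile(profiles, model, constants, light)
    sp = sp_profile(samples, params_table, constants, log_base)
    thick = [p.thickness for p in profiles]
    areal_gpp, shares = depth_integrate(gpp, thick)
    areal_sp, _ = depth_integrate(sp, thick)
    epi_share = float("nan")
    if shares:
        for p, s in zip(profiles, shares):
            if p.layer == "epilimnion":
                epi_share = s
                break
    return ProductionProfile(
        lake_id=lake_id,
        layers=[p.layer for p in profiles],
        gpp_volumetric=gpp,
        sp_volumetric=sp,
        areal_gpp=areal_gpp,
        areal_sp=areal_sp,
        gpp_shares=shares,
        epilimnion_gpp_share=epi_share,
    )
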