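# Methods

This note documents the models, parameter defaults and design choices in
`limnotte`, and what the synthetic-data tests do and do not demonstrate
about real surveys.

## Pipeline overview

For each lake: (1) trophic assessment from surface chemistry; (2)
zooplankton biomass per layer from counts and lengths; (3) depth-resolved
gross primary production (GPP) and crustacean secondary production (SP)
in carbon units, depth-integrated to areal rates; (4) seston and
zooplankton composition reduced to element:carbon and ω-3:carbon ratios;
(5) per-substance transfer efficiency TTE = 100·SP_X/GPP_X with artefact
flagging; (6) between-class statistics (ANOVA + Fisher LSD letters, box
statistics, Bray–Curtis clustering of communities, correspondence
analysis of fatty-acid tables).

## Trophic status

Carlson TSI components use natural logarithms with SD in m and Chl/TP in
µg/L; the lake index is their arithmetic mean. Class cutoffs are the
standard 40 (oligo/meso) and 50 (meso/eu); boundary ties resolve toward
the higher-trophy class.

The hydrochemical dystrophy index (HDI) is a linear score
`intercept + b₁·pH + b₂·log₁₀EC + b₃·log₁₀(DIC/DOC)` with all slopes
negative, so the score rises in acidic, ion-poor, DOC-rich (humic)
water. The published formulation is not reproduced in the survey
literature this pipeline follows, so the coefficients are configuration;
the defaults (120, −8, −10, −8) place the mean dystrophic chemistry
preset at ≈ 69 — inside the 60.4–79.9 band observed for strongly humic
lakes — and clear-water chemistry near 26. The dystrophy decision
threshold defaults to 50; a lake with HDI at or above it is classed
dystrophic regardless of TSI.

## Biomass

Individual mass follows W = a·L^b (L in mm, W in µg). Because no
coefficient table is printed in the survey literature, the package ships
a literature-plausible default per species (exportable as
`allometry.csv`); real applications should override it. Crustacean
coefficients give wet weight; a configurable wet→dry fraction (default
0.10) produces the dry weights the SP regression needs. The per-species
individual mass of a sample is the mean of per-individual masses of the
measured lengths (unbiased for the sample), not the mass of the mean
length. Species biomass (mg/L) = mean mass (µg) × abundance (ind/L) /
1000; dominance is the within-sample biomass fraction.

## Production

GPP is modelled per layer as
`p_max_per_chl · chl · φPSII · tanh(PAR/PAR_sat) · daylength` in
mg O₂ m⁻³ day⁻¹ and converted with 0.32 gC/gO₂ (exact constant). The
fluorometric procedure behind the field φPSII values is instrument-side
and out of scope; the light-response model is therefore pluggable (a
registry keyed by name) and the default is a saturating tanh with
`p_max_per_chl` = 10 mg O₂ (mg chl)⁻¹ h⁻¹, `PAR_sat` = 200 µmol m⁻² s⁻¹
and 16 h daylength — mid-summer, mid-latitude values giving areal GPP in
the 0.3–13 g C m⁻² day⁻¹ range surveys report.

SP uses the crustacean regression `1.12·10^(−0.73)·M^0.77·N` with
log base 10 (the source convention; a config switch selects ln),
computed per crustacean species from that species' mean individual dry
weight and summed. Rotifers count toward biomass but not SP: the
regression is fitted to crustacean zooplankton only. Dry weight converts
to carbon by 1/2.3 (exact constant). Since µg L⁻¹ day⁻¹ equals
mg m⁻³ day⁻¹, no further unit factor is needed.

Areal values use thickness-weighted rectangular integration (the layer
values are composites of the layer, not point measurements); a trapezoid
alternative would suit point profiles but is not the survey situation.

## Composition and transfer efficiencies

C:N and C:P are mass ratios by default — the survey numbers themselves
(e.g. 47.7% C and 0.9% P giving C:P ≈ 53) are only consistent with mass
basis — with a molar option behind a flag. The ω-3 sum covers exactly
six n-3 acids (18:3n-3, 18:4n-3, 20:4n-3, 20:5n-3, 22:5n-3, 22:6n-3);
Σ-prefixed names (Σ14:1, Σ22:0+24:0) are treated as single profile keys,
and names are normalized case-insensitively with ω/w/n aliases.

Producer and consumer "substance content" enters TTE as the
element:carbon ratio of the compartment, because GPP and SP are carbon
fluxes; multiplying a carbon flux by an element % of dry weight would
divide by the wrong denominator (that naive reading is available as
`basis="naive_pct"` for sensitivity analysis). ω-3 content is ω-3 mass
per unit carbon. Seston carbon per litre is derived from mean profile
chlorophyll via a configurable C:chl mass ratio (default 50, a common
summer seston value); zooplankton carbon from wet biomass via the
wet→dry and dry→carbon quotients. These choices make
TTE_X/TTE_C = (X:C)_zoo/(X:C)_seston an exact identity, asserted to
machine precision in the tests; with the survey-mean C:P ratios (seston
115.2, zooplankton 53.7) phosphorus moves ≈ 2.15× more efficiently than
carbon.

TTE is computed on areal (m⁻²) productions: for whole-profile
efficiencies the depth-integrated ratio is the meaningful quantity and
equals the volumetric ratio when profiles are uniform. TTE > 100% is
flagged as an artefact (in the field: seston ω-3 too low for reliable
measurement); artefacts are excluded from summary statistics and fold
ranges but retained with flags in per-lake output. Fold ranges report
the raw max/min ratio alongside a rounded convenience value, since
printed survey folds show rounding ambiguity (71.57/0.57 = 125.6).

## Statistics

ANOVA uses the classical sum-of-squares decomposition; the F and t
distributions come from scipy. Degenerate inputs: all values identical →
F = 0, p = 1; zero within-group variance with unequal means → F = ∞,
p = 0. Fisher LSD is protected by default (pairwise tests only run when
the omnibus test is significant); letters come from maximal cliques of
the non-significance graph, with the alphabet assigned in order of
descending group mean. Quartiles use linear interpolation (type 7);
whiskers are min/max and outliers use the Tukey 1.5·IQR rule — the
box-plot convention in the survey figures is internally inconsistent
(min/max whiskers *and* outlier points), so the Tukey rule is adopted
and documented. Bray–Curtis is Σ|x−y|/Σ(x+y); the agglomerative
clustering is a naive O(n³) implementation (n ≈ 30 lakes) with
average/complete/single linkage and ties broken by the lexicographically
smallest cluster-id pair. Correspondence analysis decomposes the
chi-square-standardized residual matrix by SVD; the constrained variant
projects its rows onto the span of row-mass-weighted site covariates
(trophic-class dummies when requested) before decomposition, reporting
inertia fractions relative to total inertia. Whether the original survey
ordination was truly constrained is ambiguous; unconstrained CA is the
default and CCA a config option.

## Synthetic-data generator

The generator emulates the study conditions: 30 lakes in four classes
(5/7/8/10 by default). Strictly positive variables are lognormal,
re-parameterized to the stated arithmetic mean/sd; pH is normal. No
distributional forms are given in the survey literature — lognormal is
this package's choice for right-skewed positive field data.

Class chlorophyll defaults are the whole-profile survey averages
(4.79/5.97/14.62/47.65 µg/L with their printed sds), matching the
per-layer averaging the pipeline performs; the survey's summary-table
values (9.2/7.5/29.2/70.2) ship as `table1_preset()`. Secchi depths
follow the summary table. TP, pH, EC, DIC and DOC class means are not
printed and were chosen once as limnologically typical values that put
class-mean TSI in the right bands and dystrophic HDI in 60–80.

Lakes have fixed layers: epi-/meta-/hypolimnion at 0–5/5–10/10–20 m for
the three deep classes; dystrophic lakes are shallow (two layers,
0–2/2–5 m, max depth 5 m). Layer chlorophyll follows a class vertical
mode (epilimnion-max for eutrophic, metalimnion-max otherwise) as noisy
weight templates rescaled so the thickness-weighted profile mean equals
the lake's drawn chlorophyll exactly. PAR decays exponentially with
k = 1.7/SDV from a lognormal surface irradiance, stored as layer
averages; φPSII is normal (0.55 ± 0.08, clipped).

Zooplankton assemblages are class-specific species pools (the dystrophic
pool is dominated by *Asplanchna priodonta*, *Ceriodaphnia quadrangula*
and *Eudiaptomus gracilis*; the others share a common north-temperate
pool with class-specific additions), with lognormal abundances and ten
lognormal lengths per species per layer. Seston C:P is high in
dystrophic and oligotrophic classes and lower in meso-/eutrophic ones;
zooplankton composition is class-independent (C 47.7 ± 1.7%, C:P
53.7 ± 13.0, C:N 4.9 ± 1.0). Fatty-acid profiles come from
marker-group templates: a bacteria/detritus/terrestrial/diatom-loaded
template for most classes and a green-algae/cyanobacteria-enriched
dystrophic template, with a configurable fraction (default 0.3) of
dystrophic lakes whose *zooplankton* are also enriched in 16:2n-6 and
16:3n-3, reproducing the seston–zooplankton correspondence seen in a
few humic lakes. Total FA per unit carbon defaults to 0.040 (seston) and
0.064 (zooplankton), whose templates give a zoo:seston ω-3:C ratio of
≈ 3.2 and hence ω-3 efficiencies ≈ 3.2× carbon's.

`tte_structure` is the generator's link to the response variable: after
drawing profiles and assemblages, each lake's zooplankton abundances are
co-scaled against its modelled GPP so that the lake's carbon TTE equals
a lognormal draw with the configured class mean/sd (defaults 14.31 ± 6.5,
8.0 ± 4.0, 4.28 ± 4.49, 2.89 ± 3.45 %; the mesotrophic pair is not
printed in the survey and was chosen once for a comparable coefficient
of variation). Because SP is linear in abundance, the scaling is exact,
so parameter-recovery tests measure the pipeline's bookkeeping, not a
fitting procedure.

Seeding: one master seed; each lake's substream comes from SHA-256 of
`(seed, lake_id)`, so output is bit-identical across runs and
independent of generation order.

### What the generator does not emulate

Seasonal succession, hydrodynamics, within-layer heterogeneity,
covariance between chemistry variables beyond class membership (each
variable is drawn independently given the class, so TSI-based class
assignment of synthetic lakes is noisier than for real, jointly
correlated field data — parameter-recovery tests therefore group by the
generator's true labels), measurement error models, and
individual-based zooplankton dynamics. Passing tests demonstrate the
pipeline's arithmetic, invariants and statistical calibration under
these idealized conditions, not field accuracy.

## Problem sizes and numerical choices

Tests run the full pipeline at the study scale (30 lakes), parameter
recovery at 50 lakes/class, ANOVA power over 200 replicates at the
study's group sizes (5/7/8/10), null ANOVA calibration over 2,000
replicates, and generator calibration at 1,000 dystrophic lakes — sizes
chosen so Monte-Carlo error is small relative to the tolerances while a
full run stays interactive. Tolerances: algebraic identities at 1e-9 to
1e-12 relative; ordination against a brute-force eigendecomposition at
1e-8; stochastic calibrations at their Monte-Carlo error (2 SE, or the
stated 5% band). Ties, degenerate distributions (sd = 0) and empty
inputs are all defined behaviors, tested explicitly.

## Known limitations

The default light-response and allometry parameters are plausible, not
calibrated to any instrument; absolute GPP/SP levels (and hence absolute
TTE without `tte_structure` scaling) inherit that uncertainty. The HDI
is a stand-in formulation with configurable coefficients. Reproducing
the original survey's absolute dataset-level values (overall 6.55% C
TTE, etc.) requires the deposited raw data and the unpublished
fluorometric GPP internals; the package tracks those only qualitatively
at desk scale.
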