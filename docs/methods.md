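# Methods

## Scope

famefuel implements the desk half of a microalgal feedstock assessment:
from a GC-MS FAME composition it estimates nine biodiesel-relevant
properties by empirical correlation and scores them against fuel
standards; from a two-timepoint optical-density screen on a temperature
× light grid it derives a specific-growth-rate surface and its optimum.
It does not model measured fuel properties (density, viscosity, flash
point), parse chromatograms, or fit mechanistic thermal/light response
curves to real screen data.

## Fatty-acid identities

Labels are resolved by a small shorthand grammar (`Cn:d` with an
optional `n-x` ω suffix and optional trivial-name prefix). The ω class
is taken from the suffix only — double-bond positions are not inferred —
and collapses to `unknown` for unsaturated acids without an n-3/6/9
suffix, which affects nothing downstream except reporting (every
correlation uses only n, d and mass).

Molar masses are computed from the free-fatty-acid formula
C_nH_{2n−2d}O_2 with standard atomic masses (C 12.011, H 1.008,
O 15.999). The free-acid convention, rather than the methyl ester, is
deliberate: the SV/IV correlations used here were calibrated on it, and
recomputing a published nine-property row from its published composition
reproduces the printed SV/IV only under this convention (the methyl-ester
masses shift SV by ≈ −10 mg KOH/g). Different published atomic-mass
tables move SV/IV by ≲ 0.02, which is why golden checks carry ±0.05
tolerances.

## Property correlations

With Nᵢ the mass % of total FAMEs, Mᵢ the free-acid molar mass and Dᵢ
the double-bond count:

SV = Σ 560·Nᵢ/Mᵢ; IV = Σ 254·Dᵢ·Nᵢ/Mᵢ; SFA/MUFA/PUFA are mass sums over
d = 0 / 1 / ≥2; DU = MUFA + 2·PUFA; LCSF = 0.1·C16:0 + 0.5·C18:0 +
C20:0 + 1.5·C22:0 + 2·C24:0; CFPP = 3.1417·LCSF − 16.477;
CN = 46.3 + 5458/SV − 0.225·IV; OS = 117.9295/X + 2.5905 with
X = C18:2 + C18:3 mass share (positional-isomer-blind, so γ-linolenic
counts like α-linolenic).

Three identities hold by construction and are enforced as invariants:
CN + 0.225·IV − 5458/SV = 46.3; DU = MUFA + 2·PUFA; SFA + MUFA + PUFA
equals the profile total.

Degenerate inputs: an empty profile is rejected rather than yielding
zeros; OS is reported as *undefined* (not 0 or ∞) when X = 0, and a
compliance criterion on an undefined property is `not-evaluated`, which
fail-safes the overall verdict to `not-evaluated`.

Rounding cascade: published comparison tables commonly apply the CFPP
correlation to an LCSF already rounded to two decimals. The record
therefore carries both `cfpp` (full precision, e.g. −7.099 for
LCSF 2.985) and `cfpp_cascade` (−7.083 via LCSF 2.99). Only the profile
whose composition is fully printed is treated as a strict golden test.

Percentages are used as printed — totals slightly off 100 (the canonical
profile sums to 100.04) are accepted up to 100.5 and NOT renormalised by
default, since renormalisation shifts SV/IV in the third decimal;
`renormalize()` is opt-in and records its factor. Totals below 95 flag
the profile as partial without rejecting it.

## Fuel standards

Standards are data, not code: YAML files listing (property, bound kind,
threshold, units) with bound kinds `min`, `max`, `range` and
`informational`. Boundary comparisons are inclusive. The bundled
EN 14214 encodes IV ≤ 120, CN ≥ 51, OS ≥ 6 h, and carries the CFPP entry
as an informational −20…+5 °C span because the concrete limit is a
national climate-class choice; users wanting a hard CFPP limit supply
their own YAML (tested). The bundled ASTM D6751-02 subset encodes
CN ≥ 47 and OS ≥ 3 h; properties that standard does not limit are absent
criteria, not zero thresholds.

## Growth screen

μ = (ln A₂ − ln A₁)/(t₂ − t₁), per hour internally, ×24 for human
reports. Non-positive OD cells (blank-subtraction artifacts) are flagged
NaN individually instead of failing the plate. Optimum detection is the
grid argmax, optionally after a NaN-aware mean filter (window 1 = none,
3 or 5, edge-truncated); exact ties break toward lower temperature, then
lower light, making the result deterministic. The viability mask uses
μ > 0.05·max(μ) by default — a reporting convenience with no published
basis, hence configurable.

## Synthetic data

Compositions are drawn by the Dirichlet construction (independent gammas
normalised to the target total): the simplest mechanism guaranteeing
nonnegativity and exact closure. Default weights equal the canonical
five-component profile's shares, so expected shares match it; draws are
still compositions of five majors only, with none of the trace FAMEs,
co-eluting peaks or detection thresholds of real GC-MS work — passing
tests demonstrate correctness of the arithmetic, not robustness to real
chromatography.

Growth plates follow a separable surface
μ(T, L) = μmax·exp(−(T−T*)²/(2σ_T²)) · L/(L+K_L) · exp(−β·max(0, L−L*)),
i.e. a Gaussian thermal-performance curve times Monod light saturation
with an exponential photoinhibition penalty above the light optimum, and
lognormal multiplicative noise on the final OD. Defaults: 8 × 12 grid
(96-well geometry) spanning 5–40 °C and 0–350 µmol m⁻² s⁻¹ with both
stated optima (24 °C, 88 µmol m⁻² s⁻¹) on-grid; μmax 0.03 h⁻¹
(≈ 0.72 d⁻¹, a realistic green-microalga maximum), σ_T 6 °C, K_L
30 µmol m⁻² s⁻¹, β 0.006 per unit PFD, noise σ 0.05, initial OD 0.05,
72 h duration. These emulate the *shape* of a real screen (unimodal in
temperature, saturating-then-declining in light); none of the values is
claimed to be any strain's. Real screens additionally show edge effects,
evaporation and lag phases that this generator omits. All randomness
flows from one `numpy.random.default_rng` (PCG64) generator per call,
seeded explicitly; outputs record the seed.

Monte-Carlo check sizes (200 seeded plates for optimum recovery; 1,000
compositions for identity and oracle-equivalence suites; 100 for report
round-trips) were chosen to give stable rates at sub-minute runtimes.

## Known limitations

- All nine properties are empirical correlations, valid for typical
  plant/algal FAME ranges; extrapolation to unusual compositions (very
  short chains, >4 double bonds) inherits the correlations' errors.
- cis/trans isomerism, branched chains and hydroxy acids are out of
  scope; labels carrying them parse to the plain (n, d) backbone.
- The growth module analyses grids; it does not fit continuous response
  surfaces, so the reported optimum is always a grid point.
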