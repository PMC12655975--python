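# Methods

This note documents the models implemented in `pterisk`, the defaults they
ship with, and the choices made where the methodology was genuinely open.

## Scope and media

The pipeline assesses potentially toxic elements (PTEs) — Pb, Cr, Ni, Cu,
Zn, As, Mo, Cd, Sb, V — in three environmental media: surface water (μg/L),
agricultural topsoil and crop edible tissue (both mg/kg dry weight).
Pollution and ecological indices are computed for all three media; the
health risk model covers water and soil only (no dietary-intake route for
crops is implemented: residents' produce consumption patterns are a
separate exposure model with its own parameter base).

## Pollution and ecological indices

For element *i* with measured concentration *C_i* and screening or
background value *S_i*:

- single pollution index `PI_i = C_i / S_i`;
- Nemerow comprehensive index `NI = sqrt((PI_max² + PI_mean²)/2)`, which
  weights the worst single element alongside the average — `NI` always
  lies between mean(PI) and max(PI);
- Hakanson single ecological risk index `EI_i = T_r_i · PI_i` with the
  toxicity response coefficient `T_r` (Zn 1, Cr/V 2, Cu/Ni/Pb/Mo 5, Sb 7,
  As 10, Cd 30; Sb/Mo/V are literature extensions of Hakanson's set), and
  the comprehensive index `PERI = Σ EI_i`.

Category schemes follow the conventional breakpoints (PI: safe ≤ 1, alert
1–2, slight 2–3, moderate 3–5, severe > 5; NI: safe ≤ 0.7, alert 0.7–1,
slight 1–2, moderate 2–3, severe > 3; EI: low < 40, moderate 40–80,
considerable 80–160, high 160–320, extremely high ≥ 320; PERI: low < 150,
moderate 150–300, considerable 300–600, high 600–1200, extremely high
≥ 1200). The printed breakpoints overlap at the interval ends, so the
boundary convention is explicit: PI/NI interior boundaries belong to the
lower class (left-open/right-closed intervals), EI/PERI boundaries to the
upper class. The classifier is total and monotone.

Descriptive statistics use the sample SD (n−1) and the adjusted
Fisher–Pearson skewness (the convention of common spreadsheet output). CV%
is kept at full precision internally and rounded half-away-from-zero for
display. Elements without a screening value for a medium (Mo and V in
crops under the default bundle — no unified crop criteria exist) are
excluded from that medium's indices via the absent value, not hard-coded.

## Health risk model

Average daily intake (mg·kg⁻¹·day⁻¹) per pathway:

    ADI_ing = C · R_ing · EF · ED / (BW · AT) · uf
    ADI_der = C · SA · AF · ABS · EF · ED / (BW · AT) · uf
    ADI_inh = C · R_inh · EF · ED / (PEF · BW · AT)

`uf` converts the medium's native unit into the mg-based quantity the
equations expect: 10⁻⁶ for soil (mg/kg concentration, mg/day intake rate)
and 10⁻³ for water (μg/L concentration, L/day intake rate). Inhalation
carries no unit factor (PEF, m³/kg, does the conversion) and is disabled
for water, where no particulate-emission analogue is meaningful. ABS is
0.001 generically with an element-specific override (As 0.03).

Non-carcinogenic risk `NRI = Σ_i Σ_j ADI_ij / RfD_ij` (concern threshold
1) uses `AT = ED·365` days; carcinogenic risk `CRI = Σ_i Σ_j ADI_ij ·
SF_ij` (threshold 1×10⁻⁴) uses a 70-year lifetime `AT`. Elements without a
slope factor contribute to NRI only and are recorded as such, never
zero-filled.

Default exposure parameters (all replaceable via the YAML bundle): child
R_ing 200 mg/d soil and 0.7 L/d water, adult 100 mg/d and 2 L/d; R_inh
7.5/14.5 m³/d; EF 350 d/y; ED 6/24 y; BW 15/60 kg; SA 2800/5700 cm²; AF
0.2/0.07 mg/cm²·d; PEF 1.36×10⁹ m³/kg. With these defaults child risks
from soil always dominate adult risks at equal concentrations. For water
the same does not hold for the carcinogenic endpoint: the adult's larger
drinking-water intake and fourfold exposure duration outweigh the child's
lower body weight, so the child ≥ adult ordering is asserted (and should
be expected) for soil only.

Lead is treated through the generic RfD/SF route; no blood-lead (IEUBK)
modelling.

## Monte Carlo engine

Concentrations are fixed per site; exposure parameters are sampled
independently from configured distributions (normal, lognormal
(moment-parameterised), uniform, triangular, point; truncation by
rejection). The distribution means equal the deterministic defaults, so
the deterministic run is the central case of the probabilistic one, and
with all distributions collapsed to points the Monte Carlo samples equal
the deterministic result bit-for-bit.

Each (site, population) run draws from its own generator seeded by a CRC32
hash of the site and population mixed with the master seed, making results
independent of execution order and reproducible bit-identically.
Exceedance probabilities are strict-inequality fractions against the 1 and
1×10⁻⁴ thresholds; basin-level probabilities pool all iterations across
sites with equal weight (per-site values are also reported, since any
aggregation rule is a modelling choice). Default 10,000 iterations.

Sensitivity analysis uses the signed Spearman-ρ² share:
`contribution_p = sign(ρ_p) · 100 · ρ_p² / Σ_q ρ_q²`, with constant
parameters contributing 0. Absolute contributions sum to 100 % and the
measure is invariant to monotone rescaling of the output. Body weight, the
only parameter appearing only in denominators, always carries negative
sensitivity. Standardised regression coefficients would be an alternative;
the rank-correlation share was chosen for robustness to the strongly
skewed outputs.

## Source apportionment

PCA is performed on column-standardised concentrations (correlation-matrix
PCA — element scales span four orders of magnitude, so covariance PCA
would be dominated by the largest-variance element). Components with
eigenvalue strictly greater than 1 are retained (Kaiser criterion; at
least one component is always kept), and retained loadings are
varimax-rotated for interpretability — an unrotated mode is available.
Loading signs are normalised so each component's dominant loading is
positive; rotated components are ordered by explained variance.

The element-to-source contribution matrix is built from squared rotated
loadings normalised per element, `M_ik = L_ik² / Σ_k' L_ik'²`, which
guarantees rows sum to 1 and is invariant to sign conventions and
component order. This is one of several defensible constructions (absolute
loadings or an APCS-style regression are alternatives); the squared-loading
form was chosen because it makes the downstream source-risk decomposition
exactly conservative.

## Source-oriented risk attribution

Element shares of basin-total risk are computed by summing risks over
sites and pathways first, then normalising: `NP_i` for NRI, `CP_i` for CRI
(over slope-factor-bearing elements only). Source contributions follow as
`NQ_k = Σ_i M_ik · NP_i` and `CQ_k = Σ_i M_ik · CP_i`, reported as
percents; because M rows and the share vectors each sum to 1, NQ and CQ
sum to 100 % identically. Shares default to the child population (the most
exposed group) and can be computed from deterministic risks or Monte Carlo
means.

## Synthetic data

`generate_mixture` produces tables with known source structure:
`C_si = (Σ_k a_sk · g_ki) · ε_si`, with per-site source weights `a` drawn
from gamma distributions (shape 2, scale 1 by default — nonnegative,
right-skewed site loadings) and multiplicative lognormal noise ε with unit
median and configurable CV (default 20 %). Multiplicative lognormal noise
was chosen over additive Gaussian noise because observed survey data show
strong right skew and CVs above 100 % on strictly positive support. The
presets (`soil_3source`, `water_4source`, `crop_2source`) assign each
element predominantly to one source — geogenic, mining or agricultural —
with 5 % cross-contamination, and scale strengths so mean concentrations
resemble the published survey means.

Recovery is assessed in correlation space: a true profile's loading-space
direction is the vector of correlations between its mixing weights and
each element's concentrations (`truth_loading_directions`), because
loadings live on the standardised scale where a source's low-concentration
member (Cd, say) carries the same loading as a high-concentration one. On
the soil preset at 500 sites and 20 % noise, Kaiser retention recovers
exactly 3 components and each truth profile matches a rotated loading with
cosine similarity above 0.99.

`mimic_table1` draws each element independently from a lognormal
moment-matched to target mean m and SD s (μ = ln m − σ²/2,
σ² = ln(1+s²/m²)); it reproduces marginal moments only — inter-element
correlation comes from `generate_mixture`, and neither generator emulates
spatial autocorrelation, censoring patterns, or inter-medium coupling of
real surveys, so passing tests demonstrate correctness of the estimators,
not field realism. For very heavy-tailed targets (CV ≳ 200 %) sample
arithmetic moments converge slowly (the sample variance has relative
standard error √(kurtosis/n), with kurtosis in the thousands), so fidelity
checks are performed on the light-tailed log scale, chained with a
quadrature proof that the moment-matched parameters imply the target
moments.

## Reference defaults

The shipped bundle uses conventional values throughout: surface-water
Class III screening limits (including the special-item limits for Ni 20,
Mo 70, Sb 5, V 50 μg/L), regional soil geochemical backgrounds, vegetable
food-contaminant limits, and USEPA-conventional RfD/SF tables. They are
stand-ins for site-specific regulatory values and are meant to be replaced
via `load_reference_bundle` for any real assessment; all tests that depend
on numeric outcomes either pin their own parameters or assert structural
properties that hold for any valid bundle.

## Numerical choices and degenerate inputs

- Below-detection cells substitute DL/2 (configurable to 0 or DL); the
  substitution is idempotent and never exceeds the detection limit.
- Constant columns: SD 0, skewness reported as 0; standardisation refuses
  constant columns by name.
- Constant Monte Carlo sample vectors report SD exactly 0.
- Degenerate uniform(a, a) distributions are allowed and draw the constant.
- Truncation that excludes essentially all probability mass raises after
  bounded rejection attempts rather than looping forever.
- Varimax is delegated to `statsmodels.multivariate.factor_rotation`;
  communalities are preserved to ~1e-8.
- All CSV output carries 6 significant digits; JSON sidecars keep full
  precision; write/read round-trips are bit-identical.

## Problem sizes

Default problem sizes used by the test-suite and the acceptance script:
10,000 Monte Carlo iterations per site (the standard choice for stable
1 %-level exceedance estimates), 500 sites for source-recovery fixtures,
79 sites (matching the published soil survey) for the basin-level
simulation, and 12-site tables for unit-level checks.

## Known limitations

- Exposure parameters are sampled independently; real BW/SA or age/intake
  correlations are not modelled.
- Concentrations are treated as fixed per site (parameter uncertainty
  only); a two-dimensional variability/uncertainty separation is out of
  scope.
- PCA-based apportionment assumes linear mixing and approximately
  orthogonal source behaviour in correlation space; PMF/UNMIX-style
  receptor models are not implemented.
- No spatial statistics: site identifiers are opaque, and index maps or
  spatially autocorrelated simulation are out of scope.
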