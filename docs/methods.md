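# Methods

This note documents the models, constants, numerical choices and known
limitations of soilstoich, in the spirit of a statistical-software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Derivation layer

All pool concentrations are carried in µg per g dry soil, all enzyme
activities in µmol g⁻¹ h⁻¹. The loaders never rescale: a unit string that
does not match the internal convention is a hard error, because silently
mixed mg/µg scales are the classic failure mode of stoichiometric ratios.

**Fumigation–extraction.** Biomass X_mic = (fumigated − unfumigated)/k_X
with k_EC = 0.45, k_EN = 0.54, K_P = 0.4 — the standard
chloroform-fumigation extraction efficiencies. A fumigated extract below its
unfumigated pair yields a negative biomass value; it is returned as computed
and *flagged*, never clamped, because clamping would bias pre/post
differences and every downstream ratio. Ratio operations treat non-positive
denominators as missing (NaN).

**Titration CO₂-C.** Closed-trap alkali titration: CO₂ absorbed by NaOH
forms carbonate (precipitated with BaCl₂), consuming 2 meq of alkalinity per
mmol CO₂, hence 12/2 = 6 mg C per meq of acid difference between blank and
sample:

    CO2-C [µg g⁻¹] = (V_blank − V_sample) · M_HCl · 6 · 1000 / m_dry

A sample titre exceeding the blank (apparent negative respiration) is
titration noise, not a CO₂ sink; it is clamped to zero with a warning. The
calculation is invariant to splitting an interval into two with the same
total acid difference.

**qCO₂** is reported per whole 19-day incubation (a unitless quotient of
accumulated CO₂-C over post-incubation C_mic); a per-day normalization flag
exists but defaults off, since the study-scale magnitudes (≈0.6–1.9) are
whole-period values.

**Summaries are means of per-replicate values.** qCO₂, ratios, SEA, TER and
CUE are computed per replicate first and averaged after. For nonlinear
quantities this differs from plugging group means into the formula (e.g. a
ratio-of-means 739/1283 ≈ 0.576 is not the mean-of-ratios ≈ 0.59), and the
per-replicate convention is the one consistent with the reported group
statistics.

## Stoichiometric engine

**SMA regression.** slope = sign(r)·sd(y)/sd(x), intercept through the
means. This closed form minimizes the sum of triangle areas
Σ(y − a − bx)²/(2|b|); the test suite checks the equivalence against a
Nelder–Mead minimizer of that loss to 1e-6. An SMA slope cannot be zero, so
all significance statements ride on the correlation test. Zero variance on
either axis is a hard "degenerate axis" error.

**Normalization constants.** ρ₀ comes from the SMA of ln BG on ln(Phm+Phd),
n₀ from ln BG on ln NAG, fit on the pooled per-sample panel (one source
soil). By default the constants are the *exponentiated* intercepts, so that
TER computed on the raw ratio scale is dimensionless; `intercept_scale="raw"`
preserves the literal intercept reading for comparison. Samples with any
non-positive activity are excluded from the ln-ln fits with a warning; fewer
than three usable samples is an error.

**CUE.** The scarcity index is S_C:X = (1/EEA_C:X)·(B_C:X/L_C:X) — the
biomass-to-resource ratio discounted by enzymatic allocation (the B:L
quotient reading of the index). CUE_C:X = 0.6·S/(S+0.5) is strictly
increasing in S and bounded in (0, 0.6); at S = K_X it equals CUE_max/2
exactly. Which EEA ratio enters the C:P index defaults to BG/(Phm+Phd),
mirroring the TER definition, with the BG/Phm variant available by flag.

**Homeostasis.** Default regression is OLS of ln(biomass ratio) on
ln(resource ratio) with the standard slope t-test, because a slope-vs-zero
test is ill-posed for SMA; `regression_kind="sma"` is available, carrying
the test on the correlation p-value. Orientation (biomass on resource) was
fixed by back-substituting treatment means into the published per-treatment
regression equations, which only balance in that orientation. Both plain and
adjusted R² are reported — small-n adjusted R² can be negative, which
explains negative values sometimes quoted for such fits.

**Limitation verdicts** use a two-sample Student's t (equal-variance by
default, Welch by flag) between per-replicate ln TER and ln resource-ratio
values at α = 0.05. TER significantly below the resource ratio ⇒
"nutrient-limited (immobilization)"; above ⇒ "energy-limited
(mineralization)"; otherwise "co-limited". The verdict is monotone in
resource-ratio shifts by construction (property-tested).

## Inferential battery

One-way ANOVA (scipy) with Tukey HSD pairwise comparisons (statsmodels) or
Fisher's LSD on the pooled within-group mean square; compact letter displays
are derived from the non-significance graph by a greedy insert–absorb scheme
visiting groups in descending mean order (groups with equal means always
share a letter). Pearson correlations are computed separately inside three
treatment clusters — control alone; MAP + calcium phosphate + phytate; AMP +
RNA — supplied as a fixed default map rather than re-derived by automated
clustering, since the grouping is an ordination-level judgement call.
PCA is a correlation-matrix eigendecomposition (standardize on by default)
with a deterministic sign convention (largest-magnitude loading positive);
SEA and qCO₂ are excluded from the default PCA variable set as derived
quotients of variables already present. The residual-normality screen is
Shapiro–Wilk on within-group-centered residuals and is reported as a
diagnostic only — it never gates the ANOVA.

## Synthetic-data generator

The generator's defaults are the study conditions: 6 treatments × 5
replicates × 2 phases, per-treatment post-incubation targets and the
pre-incubation baseline taken from the published treatment means ± SEs, with
per-replicate sd reconstructed as SE·√5. Post-incubation enzyme activity
targets are not printed as raw activities in the main tables, so they are
reconstructed as SEA × mean C_mic per treatment. The default noise family is
a truncated-at-zero normal (pools are nonnegative); a moment-matched
lognormal family is available for strictly positive small pools. Pre and
post values of the same replicate share a latent replicate effect
(rank correlation ρ = 0.5 via a Gaussian copula), so Δ-pool variances are
realistic rather than twice the marginal variance. Within a phase, analytes
are independent — true replicate-level covariances are unknown, and this is
the main acknowledged gap between synthetic and real data.

Construction inverses are exact by design: fumigated/unfumigated pairs
back-transform through the k-factors to the intended biomass bit-for-bit,
and each replicate's titration series accumulates exactly to its drawn
mineralization target (interval weights proportional to the 3-day schedule
closing on day 19).

Structured layers impose known parameters for recovery studies:

* **Enzyme coupling** (`rho0`, `n0` set): ln BG = ln ρ₀ + ln(Phm+Phd) + ε,
  ln NAG = ln BG − ln n₀ + ε′, with ε ~ N(0, 0.1²). The SMA-recovered
  constants then carry a small bias of order (slope−1)·mean(x) from the
  noise-inflated SMA slope — a few percent at these settings, inside the
  ±10% recovery tolerance used in the tests.
* **Homeostasis slopes** (per treatment; default 0 everywhere except a
  phytate-like −0.2 for C:P and −2.5 for C:N, matching the published
  non-homeostatic phytate community): ln(biomass ratio) = α + β·ln(resource
  ratio) + ε, with α calibrated to the treatment's published biomass-ratio
  mean and sd(ε) = |β|·sd(x)·√(1/R² − 1) targeting R² = 0.9.
* **TER separations** (`ter_offset_ln`): BG is generated so that
  ln TER_C:P − ln(DOC:DOP) has a chosen mean, for limitation-verdict power
  studies. Requires the structured coupling (the offset is defined relative
  to a known ρ₀).

Without the structured coupling, the normalization constants are an emergent
property of the moment-matched marginal panel and are *not* anchored to the
study's (unpublished) values — so per-treatment TER orderings and limitation
verdicts on default synthetic data characterize the machinery, not the
original soil. Passing tests on synthetic data therefore demonstrate
arithmetic correctness, parameter recovery and error control, not field
conclusions.

## Problem sizes and tolerances

Monte-Carlo checks use 200 seeds; verdict-rate and constant-recovery sweeps
run at n = 30 replicates per treatment, where the decisive generating
effects (slope −0.2 at R² 0.9; ln-TER separation −3) are detected in ≥90% of
seeds and null configurations stay at their nominal type-I rates. At the
study's own n = 5, the power for the phytate-like slope is materially lower
(≈70–80%), which the unit test acknowledges by bounding the detection rate
away from the false-positive rate rather than demanding 90%. SMA/oracle
agreement is asserted at 1e-6; exact-arithmetic checks (Δ-pools, ratios,
closed-form CUE) at the printed precision of the corresponding quantities.

## Known limitations

* No mechanistic mineralization dynamics (no ODEs); the titration series is
  a moment-matched artifact, so day-resolved respiration curves carry no
  kinetic information.
* One pool-change cell of the published change table (control
  nitrification) is inconsistent with the difference of the published
  pre/post means — per-replicate pairing in the original data presumably
  explains it. The pipeline computes per-replicate differences; the
  discrepancy is documented here, not patched.
* The PCA variance structure, per-treatment TER/CUE orderings and
  table-level F statistics of the original experiment require its raw
  per-replicate data, which has no public accession; these are covered by
  property and recovery tests on synthetic data instead.
* Enzyme panels pre-incubation are optional in the data model (the original
  design is ambiguous on whether they were assayed per replicate before
  incubation); the generator emits them, the validator does not require them.
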