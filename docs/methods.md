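# Methods

## Trophic level assignment

Isotope route: TL = baseline_tl + (δ15N − δ15N_baseline)/Δ15N, with the
baseline δ15N taken as the arithmetic mean over the designated baseline
species' samples and baseline_tl = 2.0 by convention.  Samples of the
baseline species itself are pinned to the baseline TL exactly — their
individual isotopic scatter defines the baseline, not a trophic signal.
TLs below the baseline are reported with a warning and never clipped:
clipping would hide a misspecified baseline.  The enrichment factor
defaults to 3.4‰ per TL step (the conventional value for aquatic
poikilotherm food webs; plausible values span 3.0–5.0‰, and values
outside that window warn without failing).  The package deliberately
implements only the single-baseline relation; two-baseline
(pelagic+benthic) mixing models are out of scope and flagged as a
limitation.  When several baseline candidates exist, the user must
designate one explicitly — the package does not choose.

Diet route: TL = 1 + Σ p_ij·TL_j solved in topological order over an
acyclic diet graph, with producers and detrital/sediment pools anchored
at TL 1.  A linear producer→herbivore→forage fish→piscivore chain puts
the piscivore at exactly TL 4.

TL range for quality screening is the highest-TL fish species mean
minus the lowest-TL nonvertebrate taxon mean (species TLs are
arithmetic means of per-sample TLs — the simplest defensible summary),
or a δ15N spread divided by the enrichment factor when TLs are not
assigned.

## Basis normalization

All conversions are multiplicative: lipid weight = ww/lipid_fraction,
dry weight = ww/(1 − water_fraction), protein proxy =
ww/(nitrogen_fraction × 6.25).  Default water fractions by taxon (fish
0.74, zooplankton and phytoplankton 0.90, other invertebrates 0.80,
chironomids 0.79 available as an override) are used only when a sample
carries no measured water content.  The fillet→whole-body conversion is
whole_body = factor × fillet with a default factor of 3 (literature
ratios cluster at ~3, range 2.6–4.9); the direction is chosen so that
lipophilic chemicals depleted in muscle are corrected upward, which is
what makes fillet-based TMFs underestimates.  The factor is exposed per
species/chemical because published phrasing on the ratio's direction is
ambiguous; the convention used here is stated rather than guessed.
Because a species-constant factor only shifts the regression intercept,
these conversions cannot change a TMF; only factors correlated with TL
(e.g. a lipid gradient) do.

## TMF regression

Default: OLS of log10 concentration (lipid basis for lipophilic
chemicals; dry weight for protein-associated ones such as PFOS or Hg)
on TL, individual samples as the unit (species-means mode available;
both appear in practice).  Base-10 logs are the default, natural logs
supported and recorded.  95% CI from the t distribution with n−2 df;
two-sided α = 0.05 throughout; single-slope inference, so no
multiple-testing correction.  TMF and its CI are exact antilogs of the
slope and its CI.  Pooled rows count as one observation regardless of
pool size (no published weighting rule exists); pool-size weighting is
available as an option, off by default.  An optional nonparametric,
observation-level bootstrap (percentile CI, 2000 reps default, seed
required) accompanies the t interval.

Nondetects: substitution by LOD/2 or LOD/√2 (neither is labelled
"correct"; both are offered), dropping, or a left-censored Gaussian
maximum-likelihood fit of the same line in which a nondetect
contributes Φ((log LOD − a − b·TL)/σ).  The censored MLE refuses to fit
above 90% censoring (the slope is not identifiable from thresholds
alone); its standard errors come from the inverse observed information
with normal-approximation intervals.  In simulation (30% censoring,
200 replicates) the censored MLE's slope bias is an order of magnitude
smaller than LOD/2 substitution's.

Unbalanced designs: a linear mixed model with a random intercept per
species and fixed TL slope (fitted by REML via statsmodels).  It
requires ≥4 species groups spanning ≥2 TLs.  When the between-species
variance is zero it reproduces OLS; when one heavily sampled species
dominates, it has lower slope RMSE in simulation.

Endotherm handling: TMFs for standard application refer to
water-respiring organisms, so fits can exclude birds and mammals; the
result records whether they were excluded.

## Study screening and selection

Eleven design criteria are scored pass/fail/unknown: TL range ≥ 2.0,
whole-body fish tissue, normalized basis, ≥3 lower-TL nonvertebrate
taxa ("several" is quantified as 3, configurable), sample balance
(largest unit-TL-bin share ≤ 0.5, anchored to the documented case of a
top predator holding ~50% of samples), diet linkage evidence, shared
habitat, isotope baseline use, nondetect fraction (warn above 20%,
fail above 50% — the literature offers only a 70% cautionary example,
so both cut-offs are configurable and always reported), single-season
sampling, and absence of endotherms.  Unknown inputs yield unknown
verdicts, never silent passes.  Failed diet linkage or habitat is
terminal (the organisms are not one food chain).  Other deficiencies
map to actions: fillet conversion (or lipid normalization for nonionic
organics when conversion is impossible), endotherm-exclusion refit,
mixed-model refit, or explicit expert-judgment outcomes — the package
surfaces expert-judgment nodes rather than deciding them.
Recalculation actions are executed through the regression module when
raw data accompany a record; otherwise they are emitted as unresolved
requirements.

Similarity tiers: same system > similar ecosystem and species >
similar ecosystem > similar species > other (ecosystem listed first
deliberately).  Ecosystem similarity requires matching type and
latitude class; species similarity requires the target species or a
congener in the study's species list.  Qualifying studies in the best
tier are pooled by geometric mean.  For readily metabolized chemicals
whose pooled TMF is below 1, TL adjustment is flagged as not advisable
and compliance in lower-TL taxa (bivalves, crustaceans) is recommended
instead.  With no qualifying study the fallback chain is: BMF for the
species of interest, BMF for a similar species, BMF for any fish
(TMF ≈ BMF for one TL step, tagged fallback_tier_1), then BCF-derived
mass-balance modelling, then modelling with an externally estimated
biotransformation rate.  Every node visited is recorded in an ordered
decision path, so identical inputs provably give identical decisions.

## Adjustment and compliance

C_adj = C_meas × TMF^(TL_ref − TL(x)) × f_ref/f_sample with reference
fractions 0.05 (lipid) and 0.26 (dry weight) as named, overridable
constants, and reference TL 4 for fresh waters, 5 for marine systems.
A TMF interval is propagated through the same power transform by
mapping its endpoints (exact under monotonicity — no delta-method
approximation).  Compliance is a point comparison; an interval that
straddles the standard is reported as indeterminate with both bounds,
a deliberately conservative choice since failing to flag a true
exceedance is the less protective error.  No statistical compliance
rule (e.g. which percentile of samples must pass) is imposed, because
none is established; the package reports point and interval.

## Steady-state food-web model

A deliberately small mass-balance for fallback TMF estimation, not a
re-implementation of any calibrated food-web code; its contract is
directional and limiting behaviour.  Producers and sediment sit at
equilibrium partitioning (C = C_water × lipid_fraction × K_OW, with
the sediment's "lipid" slot holding an organic-carbon fraction);
each consumer balances uptake and loss:

    C_i = (k1·C_w + kD·Σ_j p_ij·C_j) / (k2 + kE + kG + kM)

with k1 = gill_uptake_coeff/W^0.25 (a documented allometric closure —
no standard formula exists at this level of abstraction), k2 =
k1/(lipid·K_OW) from lipid–water partitioning, kD = assimilation
efficiency × feeding rate, kE = egestion_ratio × kD, kG growth
dilution, and kM (fish only) the whole-organism biotransformation
rate.  The same balance inverted under water-only exposure gives
kM = k1/BCF − k2 − kG; a negative result is clipped to zero with a
"metabolism not identifiable" warning.  The TMF is the base-10 antilog
of the regression slope of log lipid-normalized concentration on
diet-weighted TL over biota nodes; sediment feeds benthic diets but
never enters the regression (the TMF is defined over biota).

The default five-node lake web (sediment, phytoplankton, zooplankton,
forage fish, piscivorous fish; piscivore at TL 4 by diet) uses generic
temperate-lake weights, lipid fractions and feeding rates, chosen once
so that a slowly metabolized log K_OW ≈ 5 chemical biomagnifies
(TMF ≈ 1.2 at kM = 0), biotransformation in the low 10⁻²/d range
prevents magnification, and kM = 0.025/d produces clear trophic
dilution — the qualitative behaviour expected of such food webs.  All
coefficients are plain config fields.  Three exact properties hold by
construction and are tested: the equilibrium-partitioning limit (no
feeding, growth, egestion or metabolism) gives TMF = 1; concentrations
are linear in the water concentration while the TMF is invariant to
it; and the TMF is non-increasing in kM, so the smallest grid kM with
TMF ≤ 1 in a scan is well defined.

## Power analysis

Monte-Carlo power: per replicate, TLs are drawn uniformly over the
design interval (or fixed from an explicit list), log concentrations
simulated with the scenario slope and residual SD, and the two-sided
OLS slope test applied; power is the rejection fraction, with binomial
Monte-Carlo SE, fully vectorized and seed-reproducible.  The analytic
minimal detectable slope comes from the noncentral-t distribution of
the slope statistic (noncentrality b·√Sxx/σ), solved by bracketing and
Brent root finding; it is exact for fixed designs and uses the
expected Sxx = (n−1)·range²/12 for uniform designs (an approximation
the tests cross-validate against simulation).  For very large
noncentrality, where scipy's noncentral t underflows, the normal
approximation is substituted.  The residual SD is a required user
input: no canonical value exists, and the examples document plausible
ones (≈0.5 log10 units reproduces the familiar result that 30–40
sample studies only resolve TMFs above ~2–3).

## Synthetic data generator

The generator emulates exactly the structure the regression assumes:
species at evenly spaced TLs, log10 lipid-basis concentration linear
in TL (slope log10 of the true TMF) plus Normal residual noise, δ15N
back-computed through the isotope relation, wet weight derived from a
configurable lipid gradient (default ~1% at TL 2 rising to ~10% at TL
4, the pattern that makes wet-weight TMFs exceed lipid-normalized
ones), water fractions from the taxon defaults, optional per-species
random intercepts and unbalanced sample counts, and left-censoring at
a detection limit placed at a stated quantile of the noiseless
concentration distribution (a reproducible, documented censoring
mechanism).  Default study conditions are 12 species × 5 samples over
TL 2–4, true TMF 2.0, residual SD 0.3 log10 units.  What it does not
emulate — omnivory-driven curvature, seasonal and spatial
heterogeneity, migration, TL-assignment error, species-specific
censoring — bounds what passing tests show about real data: they
verify the estimators against the model the TMF framework itself
assumes, not against field complications.

## Numerical choices and degenerate inputs

Censored MLE starts from the substitution OLS fit and uses BFGS;
singular information matrices raise rather than return nonsense.
Regressions require ≥3 distinct TLs; all-censored data refuse to fit.
CSV round-trips write floats at full repr precision, so
write→read is lossless.  Decision outcomes sort candidate studies by
id before evaluation, making paths order-invariant.  Problem sizes in
the test suite (500 regression replicates for recovery/coverage, 200
for the censoring and mixed-model comparisons, 3000–5000 Monte-Carlo
power replicates) were chosen as the smallest sizes at which the
Monte-Carlo error is comfortably below the effects being demonstrated.

## Known limitations

Single-baseline TL assignment only; no Bayesian TMF estimation; no
spatial or migration covariance structure; no water- or sediment-EQS
conversions; no phospholipid- or protein-binding bioaccumulation
models (the protein proxy is a simple %N normalization); the food-web
model is steady-state only, with no bioenergetics submodel; BMF/BCF
records are curated inputs — there is no literature retrieval.
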