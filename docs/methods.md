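# Methods

This note documents the models, defaults and numerical conventions behind
`streamscreen`, and what the synthetic cohort does and does not emulate.

## Passive-sampler kinetics

POCIS accumulation is modeled in its **linear (integrative) phase**: the
mass accumulated over a deployment of duration T is
M(T) = R_s ∫ c_w(t) dt, so the daily average mass is
m_POCIS = R_s · c̄_w, with R_s the sampling rate (L/d, the effective water
volume cleared per day) and c̄_w the time-average water concentration.
This is the standard assumption for hydrophilic-sorbent samplers over
~3-week deployments and is what makes c_TWA = m_POCIS / R_s well defined.
A curvilinear mode (`elimination_rate` k_e > 0, giving
M(T) = R_s ∫ c_w(t) e^{−k_e (T−t)} dt) is provided to study the bias
incurred when uptake leaves the integrative phase; it is off by default.

Field R_s is estimated per compound as the slope of the ordinary
least-squares regression of m_POCIS on c_grab across sites, requiring at
least 5 co-occurring quantified pairs. The regression includes an
intercept by default — the pragmatic choice when matrix effects or blank
offsets may shift the response — with a through-origin option
(`kinetics.intercept = false`) for sensitivity analysis. Nondetect pairs
are excluded, not substituted: substitution at LOQ/2 biases the slope.
Estimates are accepted when R² > 0.90 (strict) with a positive slope.
The c_TWA standard deviation combines the replicate-disk SD and the slope
standard error by the first-order delta method.

## Source model and clustering

Compound levels are z-score standardized across sites (population SD,
nondetect policy: exclude | LOQ/2 | zero; default exclude) and
rank-correlated with the eight watershed attributes. Spearman ρ uses
midranks for ties. Two-sided p-values come from the **exhaustive
permutation null for n ≤ 9** (the centered norm of a rank vector is
permutation-invariant, so all n! pairings reduce to one matrix product;
the tie-free null is cached per n) and from the t-approximation with n − 2
degrees of freedom otherwise. Significance is marked at raw p < 0.05,
matching the reporting convention of field studies of this design;
Benjamini–Hochberg q-values are emitted alongside for multiplicity
transparency.

Rows of the ρ matrix (items × attributes) are clustered with Ward linkage
on Euclidean distance; rows are sorted lexicographically by item id before
linkage so the result is independent of input order, and missing ρ cells
are imputed as 0 (no evidence of association). The tree is cut at k = 3 by
default. Cluster semantics: the cluster with the largest mean ρ over
{ag_pct, cafo_count, rpi} is labeled A (agricultural), over
{septic_density, dev_pct, road_density, pop_density} B (developed/septic),
over {wwtp_capacity} C (wastewater); assignment is greedy by descending
block score with ties resolved A > B > C. For items quantified in both
POCIS and grab matrices, the matrix with better site coverage supplies the
levels (union convention).

## Suspect screening conventions

Feature–database matching uses the neutral mass (feature m/z minus the
adduct mass; [M+H]⁺ and [M−H]⁻ supported, selected by polarity) within a
relative tolerance of 5 ppm of the candidate mass. Theoretical isotope
envelopes are computed by convolving elemental isotope distributions
(IUPAC abundances from `pyteomics`; elements C, H, N, O, S, P, Cl, Br, F)
with binary exponentiation per element, pruning terms below 10⁻⁸, and
aggregating the fine structure into nominal-mass isotopologue peaks
(abundance-weighted mean mass offsets), truncated at 0.1 % relative
abundance and normalized to base peak 100 — the resolution at which vendor
isotope-fit scores operate. The isotope-fit score is
100 · (1 − L1/2) on sum-normalized abundances with peaks aligned within
10 mDa; unmatched peaks on either side contribute their full mass. The
vendor threshold ">50 %" is exposed as `screening.isofit_min = 50`.

## Nontarget prioritization

Criteria (a)–(d) as in the README. Two conventions deserve note:

* Criterion (a) is the intensity floor alone. Peak width/symmetry checks
  require chromatographic profiles that tabulated feature matrices do not
  carry; this is a documented deviation and the floor (max cross-site
  intensity ≥ 10⁵) is the binding part of the criterion in practice.
* "Detected" at a site means intensity above 3× the feature's field-blank
  intensity. Criterion (d) keeps features with positive ρ and two-sided
  p < 0.05 against at least one attribute; all eight attributes count as
  anthropogenic by default.

The spectral match factor is a greedy cosine: all peak pairs within
10 mDa are accepted greedily by descending intensity product (mass
distance breaks ties; the ordering makes the score symmetric), and the
score is 100 × the cosine of the aligned intensity vectors. Confirmation
cutoff 70.

## Loads

Load (g/d) = c (ng/L) × Q (m³/s) × 0.0864 (= 10⁻⁹ g/ng · 10³ L/m³ ·
86400 s/d). Grab concentrations are interpolated linearly between sampling
days onto the daily grid with constant extrapolation beyond the first/last
sample; TWA concentrations enter as a single constant over the deployment.
The window load is the mean daily load; a stratified design combines
sub-window loads by duration weighting (sub-windows must partition the
union period). Nondetect concentrations contribute zero load
(lower-bound convention). Both TWA and grab loads use the same deployment
window and discharge record for comparability.

## Mixture risk

∑EAR sums c/ACC within each bioassay endpoint and takes the maximum
endpoint sum per site (the screening-framework convention; a grand-sum
option exists). msPAF assumes response addition over log-normal SSDs:
PAF = Φ((log₁₀c − μ)/σ), msPAF = 1 − Π(1 − PAF), computed in log space
(`log1p`/`expm1`) for numerical stability; PAF(0) = 0 by convention.
Per-compound contributions are reported as PAF_i plus the leave-one-out
msPAF drop. Thresholds: ∑EAR ≥ 0.001 (precautionary effects screening)
and msPAF ≥ 5 % (generally accepted effect threshold). Monte-Carlo
uncertainty redraws R_s and concentrations from normal distributions
truncated at zero (reported uncertainties are symmetric ± SDs on
nonnegative quantities), recomputing the metric per draw; vectorized
closed-form evaluators keep 500-draw propagation per site cheap.

## Synthetic cohort: what it emulates, and defaults

The generator encodes the study design the analysis assumes: 20 stream
sites, one deployment of 23 ± 2 days per site, triplicate POCIS disks,
grab samples at deployment and retrieval.

* **Attributes.** A Gaussian copula ties the developed block (dev_pct,
  road_density, pop_density, septic_density) and, separately, the
  agricultural block (ag_pct, cafo_count, rpi) at rank correlation ≈ 0.7
  (copula r = 2 sin(πρ/6)); wwtp_capacity is independent. Marginals are
  uniform/lognormal/Poisson shapes chosen so ag_pct + dev_pct ≤ 100 holds
  by construction.
* **Concentrations.** log₁₀ c_w = α_k + Σ β_a z_a + ε + η with per-compound
  baseline α ~ N(1, 0.5) (≈10 ng/L median), attribute effects β = 0.3 per
  loading attribute (0.6 for the single-attribute wastewater block, so the
  three sources carry comparable total signal), site scatter
  ε ~ N(0, 0.2), and day-to-day variability η ~ N(0, 0.05), all on the
  log₁₀ scale. LOQ per compound ~ 10^U(−0.5, 0.5) ng/L.
* **Sampling rates.** Right-skewed over [0.02, 0.22] L/d (piecewise-uniform
  quantile with median 0.07); the suspect subset — the compounds whose
  field R_s the pipeline estimates — receives stratified quantiles of that
  distribution, randomly assigned, so the cohort median is exactly
  0.07 L/d. Disk replicates carry 10 % CV; grab measurements 10 % CV.
* **Features.** Compound-linked intensities are gain (10⁶) × m_POCIS ×
  lognormal noise (0.10 decades) with formula-derived envelopes (3 %
  per-peak noise) and 6-fragment template spectra. Background features are
  attribute-independent lognormal peaks (median ≈ 3×10⁵), present per site
  with probability 0.85, 30 % without a candidate formula, 20 % envelope
  noise, half without fragments. These encode the premise the published
  filters exploit: genuine compounds are ubiquitous with clean isotope
  envelopes, noise peaks are sporadic and poorly fitting.
* **Bioactivity.** ACC ~ lognormal with median 5×10⁴ ng/L for agricultural
  compounds and 5×10⁵ otherwise (two endpoints per compound); SSD
  μ ~ N(4.8, 0.3) log₁₀ ng/L for agricultural compounds and N(5.2, 0.3)
  otherwise, σ ~ U(0.6, 1.0). The potency ordering makes the agricultural
  cluster dominate mixture risk and keeps site msPAF in the few-percent
  range typical of mixed-use stream cohorts, with a minority of sites
  crossing the 5 % flag.
* **Discharge.** Q = baseflow (lognormal, median 2 m³/s) + storm pulses
  (lognormal peaks, 1–4 day exponential recessions), two storms per
  window.

What the generator does **not** emulate: chromatographic peak shapes and
retention-time drift (features arrive tabulated), matrix suppression and
SPE recovery, biofouling or flow/temperature effects on R_s, hydrological
routing, chemograph–hydrograph covariance, and two-season repetition.
Passing recovery tests therefore demonstrates that the analysis correctly
inverts the generative assumptions it states — not that those assumptions
hold in any particular field campaign.

## Problem sizes and numerics

Default cohort: 20 sites, 45 suspect + 30 planted nontarget compounds,
300 background features, 30-day series. Recovery experiments use 100
replicate cohorts for sampling-rate recovery and 20 for nontarget
prioritization; the full pipeline runs in seconds, the whole acceptance
sweep in under a minute on one CPU. All generators and the pipeline are
deterministic under a fixed seed (child seeds drawn once from a master
generator). Trapezoidal quadrature on the daily grid is exact for the
constant and linear cases used as oracles; Ward merge heights are
monotone by construction of the linkage; zero-variance items are excluded
from standardization with an explicit error rather than silently dropped.

## Known limitations

* The exact permutation p-value is limited to n ≤ 9 pairs (9! ≈ 3.6×10⁵
  permutations); beyond that the t-approximation is used, which is mildly
  anticonservative for |ρ| near 1 at small n.
* The isotope-fit and spectral-match scores are package-defined
  conventions (vendor metrics are unpublished); thresholds are exposed in
  the configuration rather than hard-coded.
* ∑EAR endpoint aggregation is a config-exposed default, as screening
  frameworks disagree on it. SSD parameters (log-mean/log-SD) are taken
  as inputs; fitting them from per-species toxicity values is upstream of
  this package.
* Load estimates ignore within-day concentration–discharge covariance;
  with storm-driven chemographs the daily-grid mean can under- or
  over-state the true flux.
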