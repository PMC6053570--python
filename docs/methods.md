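# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `plantmet`.

## Preprocessing

**Total-intensity normalization.** Every injection row is scaled so its
feature sum equals `target_sum` (default 10,000, in arbitrary counts; the
choice only fixes the reporting scale). Zeros are preserved; an all-zero
injection is an error because its scale is undefined.

**QC-RSD filtering.** For each feature, RSD = 100·sd/mean over the
pooled-QC injections, using the sample (n−1) standard deviation. Features
with RSD above the threshold (default 30 %, the usual biomarker-discovery
guideline) *or with undefined RSD* (QC mean of zero — a feature invisible
in the pool cannot be certified stable) are removed. RSD is computed on
normalized intensities; computing it before normalization gives virtually
identical decisions under multiplicative technical noise, and the order
used is recorded in the removal report workflow. Filtering precedes
replicate averaging, matching the usual order of operations.

**Replicate averaging and paired differencing.** Triplicate injections are
collapsed by the arithmetic mean per leaf; a leaf absent (all-zero) in
every injection stays exactly zero, so the hurdle structure survives
averaging. The herbivory contrast works on within-plant differences
(undamaged minus damaged leaf, per feature), which removes plant-level
intercepts; the paired table carries the leaf-area difference and the
damaged leaf's damage percentage as its covariates.

## Spatial predictors

Distances between sites are planar Euclidean distances on decimal degrees
(no projection). At this spatial extent (~3° × ~4°) the lat/lon anisotropy
is modest and the PCNM axes are insensitive to it; passing projected
coordinates works unchanged if preferred. PCNM: truncate the distance
matrix at the longest minimum-spanning-tree edge (keeping the neighbour
graph connected), replace larger distances by 4× the truncation, take the
principal-coordinates decomposition of the double-centred −½D² matrix, and
keep positive-eigenvalue axes scaled by √eigenvalue. Axis signs are fixed
by making each axis's first nonzero score positive. Axes 1–2 are the
default "geographic distance" predictors downstream. The implementation
reproduces vegan's `pcnm` exactly (eigenvalues, truncation, axes up to the
documented √eigenvalue scaling).

## Ordination

Bray–Curtis dissimilarity (Σ|x−y| / Σ(x+y)) feeds a SMACOF-style NMDS:
monotone (isotonic) regression of configuration distances on the observed
dissimilarity order, followed by a Guttman majorization step, iterated
while Kruskal stress-1 decreases (tolerance 1e-7, so the recorded stress
trace is non-increasing by construction). Restart 0 starts from the
principal-coordinates configuration; further restarts are seeded random
configurations; the best final stress wins. Returned scores are centred,
rotated to principal axes, and sign-fixed. Ties in the dissimilarities are
handled by the secondary (within-tie monotone) approach.

## Variation partitioning

Explained variance of the feature matrix is the redundancy-analysis R²
(trace of fitted sums of squares of column-centred Y on an
intercept-augmented predictor matrix over total), adjusted by Ezekiel's
formula. For 2–3 named blocks, the adjusted R² of every block union is
computed and the Venn cells solved by inclusion–exclusion (a small linear
system); the residual is 1 − adjR²(all blocks). Adjusted unique/shared
fractions can be slightly negative, as usual. Marginal (block-alone)
per-block significance uses a permutation F test: F = (R²/p)/((1−R²)/(n−p−1)),
rows of Y permuted, p = (1+#{F* ≥ F})/(1+n_perm) — never exactly zero.
Categorical predictors are treatment-coded against the alphabetically
first level. The population-level model (soil pH/EC/C:N, region,
phenology) runs on per-plant means (n = 45); the leaf-area/damage model
runs on the paired-difference table (n = 45). Fractions match vegan's
`varpart` to ~1e-8 on shared inputs.

## The conditional log-normal model

Each feature is a two-part model: a logit regression of presence/absence
and, conditional on presence, a linear mixed model of log intensity with
plant-within-population random intercepts. Covariate corrections are log
leaf area and centred soil pH + pH² (dropped when the factor of interest
is that covariate). Eligibility: ≥ 5 positive observations overall and,
for categorical factors, ≥ 2 positives in every level; all-positive
features simply skip the binary part (0 df). Ineligible and non-converged
features are reported with reason codes, which is why per-factor feature
counts differ slightly.

**Positive-part fitting.** The nested random-intercept likelihood is
profiled analytically: plant blocks invert in closed form and the
population level follows by a diagonal Woodbury step, leaving a 2-parameter
optimization over the variance ratios (boundary candidates evaluated
explicitly, then Nelder–Mead from the best). ML is used for
likelihood-ratio comparisons, REML for Wald/F inference and post hoc
contrasts. The solver agrees with statsmodels MixedLM and lme4 to ~1e-5 in
log-likelihood at ~20× less cost, which the simulation-based calibration
experiments depend on.

**Binary part.** A plain maximum-likelihood logit. A logistic model with
population random intercepts is not estimable by ML at this design size
(90 leaves, often very few zeros), so no grouping is used; perfect or
quasi-separation (non-convergence, runaway coefficients) drops the binary
contribution for that feature, with degrees of freedom then taken from the
positive part alone.

**Combining the parts.** Default (`method="fisher_f"`): the factor is
tested in the positive part with a conditional F statistic — Wald form on
the REML fit with *between–within (containment)* denominator degrees of
freedom, where each design column is assigned the stratum (population /
plant / leaf) carrying its dominant variance share and
denDF = N_level − N_outer − q_level. This matters: only 15 populations
carry region, habitat, light, PCNM and (effectively) soil-pH contrasts,
and a χ² reference there is badly anticonservative. The binary part
contributes its LR χ² p-value, and the two independent p-values (the
hurdle likelihood factorizes) combine by Fisher's method. The plain
factorized-likelihood combination — LR statistics and df added across
parts, χ² reference — is retained as `method="lr_chi2"`; it is the
textbook construction and fine for leaf-level factors, but inflates
population-level tests at this replication (null P(p<0.05) up to ~0.12
versus 0.02–0.08 for the default). Null calibration of the default was
verified by simulation for all eight factors.

**FDR and post hoc.** q-values are Benjamini–Hochberg per factor
(significance tiers reported at q < 0.20/0.10/0.05 and raw
p < 0.001/0.01/0.05). Tukey contrasts compare factor-level means on the
positive-part scale using the REML coefficient covariance and the
studentized-range distribution with k = number of levels observed among
positives and df = n_pos − rank; for k = 2 this reduces exactly to the
unadjusted two-sided t contrast. Levels with no positive observations are
reported untestable.

## Co-occurrence network

Spearman correlations between selected features (default: the
region-significant set) across all averaged biological samples. Edges
require ρ ≥ threshold and ρ > 0; the default threshold is the constant
0.372, equivalent to two-sided p < 0.01 under the t approximation at
n ≈ 47, and `critical_rho(n, alpha)` recomputes a threshold from first
principles (exact enumeration of the rank-permutation distribution for
n ≤ 8, inverted t approximation above; the exact path is capped at n = 8
because the permutation space grows factorially and the t approximation is
already accurate there). Constant features have undefined ρ and never form
edges. Nodes carry per-region mean-abundance profiles; connected
components label co-occurrence clusters.

## Targeted screening

Standards match features when |ΔRT| ≤ 0.20 min and |Δm/z| ≤ 0.05 Da (the
preprocessing tolerances, adopted for screening); all matches are reported
ranked by combined normalized distance and downstream tests use the
closest. Screening runs on the unfiltered normalized table, since QC
filtering serves discovery and may remove a known compound. Detected
compounds are compared between undamaged and damaged leaves with an
unpaired two-sided Mann–Whitney U (exact null for both n ≤ 8 without ties,
tie-corrected normal approximation otherwise); a paired Wilcoxon would also
respect the design, but the unpaired test is the package default for this
comparison.

## Synthetic-data generator

The generator emulates the survey design exactly (15 sites with the real
coordinates/regions/habitats/light levels, 3 plants × 2 leaves × 3
injections, two batches, 24 pooled-QC injections per batch) and the
intensity model described in the README. Defaults, chosen to mirror the
study shape and held fixed: 541 features, 344 QC violators (filter leaves
197); per-feature baseline log-mean ~ N(5, 1.2²); σ_resid = 0.5,
σ_pop = 0.4, σ_plant = 0.3 (log scale); presence probability per feature
~ U(0.65, 1); technical CV 10 % (80 % for violators); effect sets of 30
(region, log-fold shift δ = 2 applied as three disjoint per-region
blocks), 8 (soil pH, quadratic β = (0.5, −0.4) on pH centred at 6.25), 4
(habitat, δ = 1.5 on forest), 3 (log leaf area, slope 1). Soil pH is
population-level U(4.5, 8) with 0.15 within-site scatter; EC and C:N are
monotone transforms of Gaussian-copula partners targeting Spearman 0.49
and 0.39 with pH. Leaf areas are log-normal around ~30 cm²; damaged-leaf
damage fractions are Beta(2, 20). Presence is drawn at leaf level, so
zeros survive replicate averaging. All draws come from one seeded
generator; identical config + seed is bit-identical.

What the generator does **not** emulate: chromatographic drift and
retention-time shifts between batches, correlated feature families
(adducts/fragments of one metabolite), presence probabilities that depend
on covariates, non-log-normal intensity tails, and spatially structured
residuals beyond the region means. Passing tests therefore demonstrate
correctness and calibration of the *methods* under the declared model, not
robustness of the science to every real-data pathology.

## Validation experiments and their sizes

Problem sizes were chosen for single-CPU minutes-scale runs and are fixed:
FDR control = 50 null studies × 40 features (region factor; mean
false-discovery proportion of q < 0.20 calls, FDP = V/max(R,1), nominal
0.20); null p-value uniformity = KS on p-values pooled over 3 independent
null studies × 60 features (pooling across studies is required because
features within one study share the realized design and are weakly coupled
by normalization, so a single-study KS over-rejects); effect recovery =
3 replicate studies at the full 541-feature shape (sensitivity and
unplanted-discovery fraction for region; sign recovery for pH, compared
against the planted truth reparameterized to the model's pH centring);
QC-filter exactness = 100 seeds × 120 features; variation-partitioning
recovery = orthogonal blocks planted at 5 %/8 % of variance, n = 500;
primitive oracles = brute-force enumeration/closed forms on small
instances. The network block-recovery experiment (adjusted Rand ≥ 0.9 of
components against planted region blocks) generates its features with full
presence: it validates thresholding and component labelling, and rank
correlations on sparse features are intrinsically degraded by zeros (a
limitation worth remembering when interpreting co-occurrence of
low-presence features).

## Known limitations

- The binary part has no random effects; with strongly clustered
  presence/absence patterns its LR p-values would be anticonservative.
  In the declared generator presence is independent across leaves, and the
  combined test's null calibration was verified by simulation.
- Between–within denominator df is an approximation; Satterthwaite or
  Kenward–Roger df would be preferable for severely unbalanced positive
  subsets but cost far more per fit.
- Compositional coupling from total-intensity normalization leaks strong
  planted effects into other features when the affected share of total
  intensity is large (small panels); at the study-shaped panel the effect
  is minor but visible as a few unplanted region discoveries.
- Exact Spearman p-values stop at n = 8; exact Mann–Whitney at n = 8 per
  group and no ties.
- NMDS convergence is declared when stress-1 improves by < 1e-7; stress is
  reported and never hidden, and non-convergence is flagged, not fatal.
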