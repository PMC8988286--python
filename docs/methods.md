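# Methods

`migprs` implements, end to end, a family-study analysis of how a common-variant
migraine polygenic risk score (PRS) relates to the ICHD-3 diagnostic criteria:
score construction by clumping and thresholding, population-referenced scaling,
an empirical genetic relatedness matrix (GRM), and variance-component linear
mixed models with Wald inference and Holm multiple-testing control. Because the
family data such analyses run on are private, the package ships a synthetic
cohort generator whose output has the statistical structure the analysis
assumes; everything below documents the models, the defaults, and what the
synthetic conditions do and do not establish.

## Synthetic cohort

**Pedigrees.** Each family starts from one founder couple. Sibship sizes are
Poisson(`mean_sibs`, default 2.5) truncated at one; every child in a
non-terminal generation marries a new unrelated founder; depth is
`n_generations` (default 3). With the defaults a family has ~14 members, so 600
simulated families give a cohort in the high single-digit thousands, the scale
of a large clinic-recruited family study. Real family studies do not publish
their pedigree shapes; these defaults are a scale choice, not an inference.

**Genotypes.** Variants live on contiguous LD blocks (a few kb between
variants within a block, ~1 Mb between blocks). Founder haplotypes are drawn
from a per-block exchangeable latent-Gaussian (probit) model: within block *b*
a haplotype has one latent factor *u*, and variant *v* carries the effect
allele iff `sqrt(rho)*u + sqrt(1-rho)*eps_v < Phi^-1(f_v)`. This gives exact
Bernoulli(*f_v*) marginal frequencies — so founder allele frequencies converge
to the panel frequencies with ordinary binomial error — together with positive,
tunable within-block r² (default `ld_rho = 0.5`). A finite haplotype-pool
design was considered and rejected: a small pool biases realized frequencies by
O(sqrt(f(1-f)/pool)), which breaks frequency-sensitive downstream steps (QC,
GRM standardization). Children are produced by gene dropping: per block each
gamete copies one of the parent's two haplotypes, chosen independently across
blocks (inter-block recombination 1/2, within-block transmission intact), so
Mendelian consistency is exact and block LD survives transmission.

**Summary statistics.** Published effects are true effects plus estimation
noise: `se = 1/sqrt(2 f (1-f) N)` under a standardized-trait approximation at
GWAS sample size `N` (default 375,000), `beta_pub ~ Normal(beta_true, se)`,
two-sided normal p-values. Under the null the p-values are uniform by
construction.

**Phenotypes.** A single liability
`L_i = standardized(score_i) * sqrt(prs_weight) + e_i`, with
`e ~ Normal(0, env_sd)` and `env_sd = sqrt(1 - prs_weight)` by default so L is
approximately standard normal. Each battery item is a thresholded copy of L
plus item-specific Normal(0, 0.6) noise. Thresholds are set from target
population prevalences via `Phi^-1(1 - prev) * sqrt(1 + 0.6^2)`; the defaults
(attack count 35%, duration 30%, pain features 25–40%, nausea 30%, vomiting
15%, photo/phonophobia 32/28%, osmophobia 10%, visual/sensory/speech/motor aura
10/5/3.5/2%) were chosen once to make the diagnostic ladder well populated and
correctly ordered (any headache > migraine headache > visual aura > motor
aura). `prs_weight` defaults to 0.35 — enough polygenic signal that diagnostic
categories form a rising PRS continuum by construction, while most liability
remains environmental. A `family_env_sd` knob adds a shared-family component
for sensitivity analyses; it defaults to 0 because genotype sharing already
induces familial correlation.

**Ascertainment.** Families are retained when at least `min_affected`
(default 4) members carry a migraine diagnosis (MwoA, MwA, or HM on the
exclusive ladder); all members of retained families are kept regardless of
their own status. Under the defaults roughly a third of simulated families
qualify, and affected members of ascertained families have above-average true
polygenic scores, reproducing the enrichment such sampling causes.

**What the generator does not emulate:** genotyping error, imputation
uncertainty, X-linked or sex-specific effects, assortative mating, real LD
decay within blocks, questionnaire measurement error beyond the boolean
coercion, and secular/age structure in symptom reporting. Passing tests show
the analysis machinery is correct and calibrated under the stated generative
model, not that any particular real-data effect size is right.

## Diagnostic rule engine

On a complete boolean battery (missing answers coerced to "no"): A = ≥5
attacks, B = 4–72 h duration, C = ≥2 of {unilateral, pulsating,
moderate/severe, aggravated by activity}, D1 = nausea or vomiting, D2 =
photophobia and phonophobia, D = D1 or D2. MwoA requires A∧B∧C∧D. Aura
diagnoses are driven by the aura indicators directly (visual/sensory/speech →
MwA, motor → HM) and do not require the full headache criteria; the attack-
count requirements for aura are folded into the indicators at simulation time.
Probable migraine means exactly one of A–D missing and no aura diagnosis;
"headache" means more than one missing but some headache symptom reported;
"no headache" means none reported. The exclusive ladder orders
no_headache < headache < probable_migraine < MwoA < MwA < HM and each person
gets the highest rung whose flag is set — so the ladder is a partition by
construction, and criterion percentages among MwoA cases are identically 100%.
The complexity score counts the 10 headache symptoms plus visual and motor
aura (range 0–12); osmophobia is carried in the battery but excluded from both
criteria and the count, since it is not part of ICHD-3. D is read as D1 OR D2
(the ICHD-3 letter); the engine exposes no "D1 and D2" variant.

## Scoring

QC keeps a variant when sample MAF ≥ `maf_min` (0.01), missingness ≤
`missing_max` (0.05), and the Hardy–Weinberg exact test p ≥ `hwe_p_min`
(1e-6). HWE is computed by full enumeration of heterozygote counts conditional
on allele counts, among pedigree founders only, because Mendelian transmission
within families distorts genotype frequencies; boundary p-values compare
inclusively. Harmonization aligns published alleles to the genotype panel:
swapped alleles flip the sign, strand flips are resolved by complementing,
palindromic (A/T, C/G) variants are dropped as ambiguous. Clumping is greedy
in ascending p with fully deterministic tie-breaking (p, chrom, pos, id);
an index variant removes in-window (`window_kb`, default 500) same-chromosome
variants with sample r² > `r2_max` (default 0.1). The p-value threshold
(default 0.05) is boundary-inclusive. These C+T settings are conventional
defaults — the variant count a real score ends up with is data-dependent, and
all three knobs are configuration. The raw score is the weighted dosage sum
with missing dosages mean-imputed to `2*freq`; scaling subtracts the reference
cohort's mean and divides by its n−1 standard deviation, so 0 is the reference
population mean and 1 its SD. In the pipeline the reference is a separately
simulated unrelated population sample from the same panel.

## Relatedness

LD pruning is the classic sliding-window greedy rule (window 50 variants,
step 5, r² cutoff 0.2, all configurable): within a window the highest-r² pair
above the cutoff repeatedly loses its later-positioned member. The GRM is the
frequency-standardized ("GCTA-style") average
`K = (1/M) Σ_v z_v z_v'`, `z_iv = (d_iv − 2p_v)/sqrt(2 p_v (1−p_v))` with
in-sample allele frequencies; missing dosages contribute zero after
standardization. Because in-sample centering makes each variant's z sum to
zero, K's rows sum to ~0: K approximates the pedigree relationship matrix A
elementwise only when the cohort contains many families, which is how the
pipeline uses it (and how the convergence tests measure it). The
pedigree-expected A (tabular recursion) is provided both as a validation
oracle and as a block-diagonal K for very large cohorts. Small negative
eigenvalues from finite M are absorbed by a 1e-6 ridge on the eigenvalues,
logged when applied; matrices below −1e-8 are rejected as non-PSD.

## Mixed model

`y = Xβ + g + e`, `g ~ N(0, σg² K)`, `e ~ N(0, σe² I)`, fitted by REML (the
standard criterion for variance components; intervals are Wald-style). The
solver eigendecomposes K once (block-wise for family-block matrices, so an
8,000-person cohort never materializes a dense 8,000² matrix), rotates y and X,
and profiles the restricted likelihood over h² = σg²/(σg²+σe²): a 129-point
scan on [0, 1−1e-6] followed by bounded scalar refinement (tolerance 1e-8),
with both boundaries evaluated explicitly and ties resolved toward h² = 0.
The total variance is profiled out analytically
(σ̂² = weighted RSS/(n−p)); at the optimum β̂ is GLS and
`cov(β̂) = (X'V⁻¹X)⁻¹`. Degenerate inputs are handled deliberately: a zero
residual floors the RSS at 1e-30 (σe² reported at the lower bound), boundary
solutions are flagged and logged but reported as converged, rank-deficient
designs fail naming the collinear columns.

Inference: Wald z = estimate/se against the standard normal, 95% CIs as
estimate ± 1.959964·se, no degrees-of-freedom correction. Group comparisons
fit one cell-means model (one-hot design, no intercept) so every group mean
shares the variance components; each group is reported as its model-based mean
with CI plus the Wald p of its contrast against the reference group (the
reference's self-contrast is difference 0, p 1). Multivariable models put all
criteria (A, B, C, D1, D2) or all four auras in one design with an intercept
and report partial effects. Univariate p-value families are Holm–Bonferroni
adjusted (step-down: sort, scale by m−i+1, enforce the cumulative maximum,
cap at 1).

## Pipeline

The pipeline's GRM is computed on the LD-pruned variant set *excluding the
variants that entered the final score*. The response in every model is itself
a weighted sum of dosages, so if the GRM's column space contained all score
variants the residual variance would be exactly zero and REML would collapse
onto the h² = 1 boundary with degenerate (near-zero) standard errors — the
mixed-model analogue of proximal contamination, handled here the way
leave-one-chromosome-out GRMs handle it in mixed-model association testing.
At realistic scale (GRM rank far above n) the collapse is not exact, but the
exclusion is the right behaviour at any scale.

`run_full_pipeline` is a pure function of `RunConfig`: identical
configurations produce byte-identical bundles (GRM gzip written with zero
mtime for this reason). It emits the criteria-by-category percentage table
(overall and by sex; empty categories report NaN, not 0), exclusive-ladder
category means contrasted to the no-headache group, per-criterion and
per-symptom univariate means (Holm-adjusted), the 0–12 symptom-count trend,
aura analyses restricted to individuals whose headache fulfils the full
ICHD-3 criteria, and the two multivariable tables. Intermediates (FAM, scores,
diagnoses, harmonization log, GRM) are always written so any table can be
regenerated by rerunning the corresponding module in isolation. Covariate
adjustment (age/sex) is supported by the model layer but off by default; the
category analyses condition on family structure only.

## Problem sizes in the checks

The test suite exercises the statistical guarantees at sizes chosen to make
the Monte-Carlo margins meaningful: REML is verified against a dense 2-D
grid-search oracle on n ≤ 12 toys; type-I error calibration uses 1,000 null
replicates of a 50-family (~580-person) cohort with a family-clustered
predictor, where the GRM-LMM rejects at ~5% and position-blind OLS visibly
over-rejects; ladder-effect recovery injects the category means
(0, 0.07, 0.13, 0.17, 0.29, 0.37) on a ~8,700-person, 600-family cohort and
checks monotone recovery over 50 seeds, with CI coverage assessed over 500
replicates of a 50-family cohort; GRM convergence uses 20,000 independent
variants over a ≥30-member family embedded in a multi-family cohort; clumping
and pruning are compared to brute-force reimplementations on 100 random
instances each.

## Known limitations

Gaussian response only (no binomial/Poisson mixed models); a single GRM
random effect; no score or likelihood-ratio alternatives to Wald; no external
LD reference (r² always comes from the supplied genotypes); no Bayesian
shrinkage scores; symptom grades are boolean, so "strength of symptom"
analyses on ordinal grades are out of scope; exact heritability of the real
trait and real effect-size spectra are not calibrated to any dataset.
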