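# Methods

## Concordance model and the ESS screen

Twin–twin methylation concordance at a probe is measured inversely by the
mean squared deviation from the line of identity,
MSE = (1/n) Σᵢ (β_iA − β_iB)², computed separately over monozygotic (MZ),
dizygotic (DZ), and randomized (RZ) pairs. RZ pairs are a perfect matching
drawn uniformly over the pooled MZ+DZ individuals (one seeded pairing per
run, the paper-style normalization; `n_rz > 1` averages several re-pairings
for variance reduction). Normalized MSEs are MZ/RZ and DZ/RZ.

Under purely genetic, additive determination DZ twins share half their
haplotypes and MZ twins all of them, which motivates the classification
boundary DZ/MZ = 2 on normalized MSEs. The epigenetic-supersimilarity (ESS)
call is the conjunction

* normalized DZ / normalized MZ > 2 (strict),
* interindividual beta range (max − min over the pooled population) > 0.4,
* normalized MZ ≤ 0.5 (probes whose MZ concordance is no better than half
  the population level are excluded as unreliable).

A probe with normalized MZ MSE exactly 0 and positive DZ MSE is treated as
maximal ESS (infinite ratio): a perfectly concordant MZ probe with
discordant DZ pairs is the strongest possible signal. Probes with fewer
than 10 complete pairs in any class are flagged `low_support`. Missing
betas contribute nothing: a pair enters a probe's MSE only when both
members are observed.

Note a model subtlety the simulator makes visible: with small measurement
noise, *genetically determined* loci also exceed the DZ/MZ = 2 boundary
(normalized MZ MSE collapses toward the noise floor while DZ MSE retains
half the genetic variance). The 2× bound is an argument about means across
many noisy probes, not a per-probe invariant; this is why the pipeline
separately annotates substantial mQTL (variance explained by nearby SNPs
β_SNP > 0.33) and filters on it downstream rather than relying on the twin
screen alone to exclude genetic effects.

The left-skew of the normalized MZ MSE distribution is tested with the
moment-based D'Agostino skewness test, one-sided toward negative skew; no
specific test is canonical for this claim, and a direct moment test of the
stated property is the most interpretable choice. Per-value z-scores
(value − mean)/SD support the "> 5 SD below the normal mean" argument.

## SIV screen

For an individuals × tissues panel spanning the three germ layers,
interindividual variation is the range over individuals of each
individual's cross-tissue mean beta, and tissue-specific variation is the
range over tissues of each tissue's cross-individual mean. The SIV call is
interindividual > 0.2 (strict) and tissue-specific < 1/3 of
interindividual. By default a probe is excluded if any panel cell is
missing (complete-case, mirroring a strict all-samples filter);
`complete_case=False` permits per-individual means over available tissues.

Negative controls — probes as variable between individuals as ESS probes
but with no evidence of supersimilarity or systemic variation — require
beta range > 0.4, normalized MZ MSE > 0.5, and tissue-specific variation at
least twice interindividual variation.

The targeted inter-tissue correlation call (pyrosequencing-style
validation) computes Pearson correlations over individuals for every tissue
pair on locus-average methylation and calls a locus systemic when **all**
pairwise R² exceed 0.50. The all-pairs rule is the stricter reading of
"systemic" (concordance across every germ layer); `require_all=False`
relaxes to at-least-one pair. A zero-variance tissue vector renders the
correlation undefined and the call negative.

## Enrichment statistics

All enrichment is computed on caller-supplied 2×2 tables — there is no
implicit probe universe; when the comparison is set vs non-set the caller
passes the complement explicitly. Fold enrichment is the rate ratio
(a/(a+b)) / (c/(c+d)). The chi-squared test is Pearson's without Yates
correction (counts in all intended uses are large; a warning recommends
Fisher when an expected cell falls below 1). Fisher's exact test is
one-sided (greater) by default, matching the directional enrichment
question. Subtelomeric means strictly within 2 Mb of either chromosome
end. FDR control is Benjamini–Hochberg step-up.

## Genotype association

Methylation-on-genotype regression uses additive allele-count coding
(0/1/2) by OLS; a one-way ANOVA across genotype classes is available for
non-additive patterns. The reported R² is the internal variance-explained
estimate and is kept distinct from externally supplied β_SNP annotations.
Variance heterogeneity between genotype classes uses Bartlett's test with
the p-value taken from the χ²(k−1) reference computed directly (the scipy
wrapper returns NaN at a statistic of exactly zero). The pipeline default
compares the two homozygote classes, the comparison relevant for
genotype-dependent metastability, where one homozygote is locked to a fixed
state and the others retain the full stochastic state distribution.

## Season-of-conception EWAS

Each probe's beta values are regressed on a dry/rainy conception-season
indicator plus covariates (infant sex, principal-component scores, cell-type
proportions) by Huber M-estimation: IRLS, tuning constant 1.345 (the
standard 95%-efficiency choice; the estimator family is specified but not
its tuning), MAD scale, convergence on coefficients at 1e−8 within 50
iterations. Coefficient p-values use a normal reference (the choice between
normal and t references is open; normal is used and documented — at n ≈ 128
the difference is only visible in the far tail). A constant response
returns zero slopes; non-convergence is flagged and the probe keeps an NA
p-value. Probes at BH FDR < 10% are SoC-DMPs. Conception season derives
from the conception date directly or from birth date minus a configurable
gestation offset (default 280 days); conceptions outside February–April
(dry) and July–September (rainy) are excluded as out-of-window.

Principal components are consumed from the covariate table, never computed
internally; sensitivity variants (no cell-composition adjustment, an extra
PC) are configuration choices on the design matrix.

## Cancer-risk clusters

Probes are grouped by single-linkage chaining along each chromosome with a
500 bp gap threshold (gap of exactly 500 joins); clusters need ≥ 2 probes.
Within a study, per-probe M-values are rank-normalized in ascending order
(plain ranks, average ties — not inverse-normal scores) across all samples.
The association between methylation rank and case status in 1:1 matched
pairs is the conditional logistic likelihood, maximized by Newton–Raphson
on within-pair (case − control) differences — the exact equivalence to an
intercept-free logit with constant outcome. Wald p-values use a normal
reference. An exposure that never differs within a pair is uninformative
(coefficient 0, p = 1); complete separation (unbounded likelihood, detected
by coefficient divergence) is flagged and yields an NA p-value, which also
means a shift so large that every within-pair difference has the same sign
is reported as unestimable rather than maximally significant — a known
property of Wald-based CLR, documented as a limitation.

Cluster evidence per cancer type: N = the count of significant (p < 0.05)
probes of the majority coefficient sign (the tie/sign rule is not uniquely
determined; the majority-sign count implements the intent of rewarding
same-direction clusters), and P_min = the minimal probe p-value.
Recurrence counts the cancer types with N ≥ 2. Permutations keep the
pairing but reassign case/control status independently within each pair
(probability ½), reusing cached within-pair differences with flipped signs
— a computational contract only, the refit is complete. Event i counts
permutations with N_rnd ≥ N_obs and P_min,rnd ≤ P_min,obs; event ii counts
Recurrence_rnd ≥ Recurrence_obs. P-values use the add-one estimator
(r+1)/(n+1), avoiding zero p-values. Selection restricts to the top-k
(default 10) most CpG-rich clusters, BH-adjusts event-i p-values within
each cancer type, and flags q < 0.25.

## Synthetic-data generator

The generator encodes the early-embryo establishment model. A locus has
preferred methylation states (default trimodal {0.1, 0.5, 0.9} with weights
{¼, ½, ¼} — two alleles of a bistable switch yield three population
states); measurement noise is additive Gaussian on the beta scale (default
SD 0.03, pyrosequencing-scale technical error) followed by clipping to
[0, 1]. Locus classes:

* `EARLY_STOCHASTIC` — one state per zygote; MZ co-twins share it, DZ
  co-twins draw independently.
* `LATE_STOCHASTIC` — every individual draws independently.
* `GENETIC` — beta = lowest level + allele count × span/2; MZ share the
  genotype, DZ share each haplotype with probability ½ independently per
  locus (within-chromosome linkage is ignored: the screening statistics are
  per-probe). Allele frequency defaults to 0.5.
* `GENETIC_METASTABLE` — the 2-allele homozygote is locked to the top
  state; other classes draw from the full distribution.

Establishment is treated as perfectly maintained through differentiation —
the only error is measurement noise; the fidelity of post-cleavage mitotic
maintenance is not separately parameterized.

The tissue panel draws systemic loci one state per individual (shared
across tissues) and tissue-specific loci one state per tissue, from levels
0.5 ± effect (default effect 0.4, noise SD 0.02, 4 individuals × 3
tissues). The trimodal individual draw gives the panel a ≈ 93% ceiling on
systemic-locus sensitivity at 4 individuals (all four individuals draw the
same state with probability Σ pₖ⁴ ≈ 0.07) — the same small-panel saturation
that limits any four-individual design. When a panel is built over an
existing twin cohort's loci, pre-cleavage loci are systemic and 5% of the
remaining loci are systemic without being supersimilar (establishment
between cleavage and gastrulation), so the ESS/SIV overlap is strong but
imperfect and the enrichment fold is finite.

The seasonal cohort gives affected loci a +delta (default 0.05) rainy-season
mean shift over a U(0.2, 0.7) baseline with nuisance covariates (sex, three
PCs, five of six cell proportions — recording all six would be collinear
with the intercept) that carry no true effect. The matched case-control
generator shifts case betas by +delta at every probe of an affected cluster
(concordant sign), over a shared pair-level random effect (SD 0.05) that
models the matching; covariates (BMI, alcohol, smoking, cell proportions)
vary within pairs with no true effect, and `covariates="none"` suits small
toy studies where a nine-column model would be over-parameterized.

What the generator does **not** emulate: array probe-type bias, batch
effects, linkage disequilibrium across loci, cell-composition shifts that
correlate with exposure, and non-Gaussian heavy-tailed noise. Passing
recovery tests on these cohorts therefore demonstrates correctness of the
statistics under the stated model, not robustness to every artifact of real
arrays — the robust-regression and rank-based stages exist precisely
because real data violate Gaussianity.

## Numerical choices and degenerate inputs

* Beta values of exactly 0 or 1 are clamped to [1e−6, 1 − 1e−6] before the
  M-transform (configurable; disabling clamping makes boundary values an
  error). The inverse transform round-trips to 1e−12.
* Genomic positions are 0-based (BED-derived).
* Variance ranking ties break lexicographically by probe ID; the top
  fraction keeps ceil(f·P) probes.
* Newton–Raphson for the conditional likelihood: tolerance 1e−10 on the
  step, 60 iterations, a 1e−12 ridge for numerical safety, separation bound
  |β| > 30.
* Permutation p-values are reproducible given the seed; observed statistics
  are exactly invariant to pair ordering (the Monte-Carlo p is invariant in
  distribution, not per RNG stream).

## Problem sizes used in validation

Twin screen: 100 MZ + 160 DZ pairs, 1000 loci (100/800/100 split). Panel:
4 × 3 with 100 + 100 loci. Seasonal cohort: n = 128, 1000 loci, 50
affected, delta 0.05. Permutation exactness: an 8-pair toy study against
the exhaustive 256-assignment distribution with 20,000 Monte-Carlo draws;
null calibration: 50 seeds × 4 three-probe clusters at 30 pairs with 400
permutations each. These sizes make every stage's recovery measurable in
seconds while matching the cohort dimensions the statistics are designed
for.

## Known limitations

* The SoC stage's false-discovery count follows BH mathematics: at FDR 10%
  with ~50 strong signals among 1000 loci, about five null loci are
  expected to be called alongside them; the realized count fluctuates
  (3–15 across seeds). Sensitivity and sign recovery are stable.
* Wald-based CLR reports complete separation as NA rather than as extreme
  significance; permutation comparisons treat such probes as missing.
* The event-i permutation p is the probability of a bivariate quadrant
  {N ≥ N_obs, P_min ≤ P_min,obs}; it is exact-to-conservative under the
  null (empirically 0.045 rejection at α = 0.05) but is not a marginal
  order statistic, so its null distribution is only approximately uniform.
* Single-RZ normalization leaves Monte-Carlo noise in normalized MSEs;
  averaging over several RZ pairings reduces it at linear cost.
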