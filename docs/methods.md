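# Methods

`aberlink` reconstructs *association modules* — an effector molecular
aberration (a copy-number segment, gene mutation, DNA methylation
cluster, SNP locus, or microRNA) together with the set of mRNA targets
whose expression it statistically explains — from a sample-matched
multi-omics cohort. This note records the model, the numerical choices,
and the places where the design was genuinely open.

## Probabilistic tristate quantization

All continuous profiles (mRNA, microRNA, CNV segment values,
methylation) are rank-transformed per feature into CDF values
`v = (rank − 0.5)/n` with mid-ranks for ties, which keeps every value
strictly inside (0, 1) and makes the whole pipeline invariant to any
strictly monotone transformation of the raw measurements. Each CDF
value is then mapped to a probability triple
`[P(down), P(nochange), P(up)]` by integrating over a family of
two-threshold step quantizers: a hard quantizer calls *down* below
`a ~ Uniform(0, c)` and *up* above `b ~ Uniform(c, 1)` with `a ⊥ b`;
averaging the calls over the family gives the closed form

    p_down = max(0, (c − v)/c),   p_up = max(0, (v − c)/(1 − c)),

with center `c = 0.5` by default (configurable). We chose this family
because it is the simplest monotone one with a closed-form integral
while preserving the key property of probabilistic quantization:
continuous information survives as *graded* state probabilities rather
than hard calls. Mutations and SNPs are intrinsically discrete and are
encoded as point masses (wildtype → nochange, any mutation → up; SNP
dosage 0/1/2 → down/nochange/up under the additive mapping).

The scalar regression encoding of a triple is the expected state
`e = P(up) − P(down) ∈ [−1, 1]`.

## CNV segmentation

Copy-number events span contiguous probe runs, so the unit of analysis
is a segment. Within a segment, probes are modelled as conditionally
independent Gaussians whose mean is one of three hidden copy states
(means −0.5/0/+0.5 by default on the log-ratio scale; shared σ estimated
robustly from the median absolute probe-to-probe difference). Each
chromosome is segmented per sample by recursive bisection: the best
single split is accepted when its log-likelihood gain exceeds a
BIC-style penalty (default `2·log n_probes` per added segment —
unpenalized likelihood always favours splitting). Because a focal
aberration flanked by two equal-state arms admits no profitable *single*
split, the recursion falls back to the best *pair* of simultaneous
splits (accepted against twice the penalty) before stopping — the same
device circular binary segmentation uses. On ≤12-probe instances the
procedure attains the exhaustive-enumeration optimum up to one penalty
(asserted in tests).

Per-sample boundaries are pooled across samples, single-linkage
clustered with a 2-probe tolerance, and kept when ≥10% of samples
support a cluster; the representative is the floored median position.
Consensus segments tile each chromosome exactly. Segment values are
per-sample means over member probes and are quantized across samples by
the same rank-CDF path as mRNA. A chromosome-level representative
profile (probe-count-weighted mean of its segment values) is available
because intra-chromosome probe correlations are long-ranged; it is used
for reporting, while association scoring operates on segments with at
most one segment per chromosome admitted per target model.

## Soft-label association model

For a target with tristate labels `w_s(i)` and effector expected states
`x_i`, associations follow the shared-slope multinomial logistic model

    P(y = s | x) ∝ exp(α_s + s · Σ_j λ_j x_j),   s ∈ {−1, 0, +1},  α_0 = 0,

fitted by maximizing the expected complete-data log-likelihood
`Σ_i Σ_s w_s(i) log P(y = s | x_i)`. One signed coefficient per
effector makes "positive/negative association" well defined. The
optimizer is a damped Newton iteration with analytic gradient and
Hessian, a ridge of 1e−6 on the slopes for identifiability under
collinearity, gradient tolerance 1e−6, and a configurable slope cap
(±20) against runaway separation. With point-mass labels the objective
reduces exactly to ordinary multinomial logistic regression.

**Marginal screening.** Each candidate pair is scored by
`llr = 2(LL_fit − LL_intercept-only)`; the intercept-only optimum is
closed-form (class probabilities = mean soft labels). Screening keeps
pairs with `llr ≥ 5.0` and `|Pearson r of expected states| ≥ 0.3`
(SNPs: `llr ≥ 7.0`, no correlation floor, reflecting their far larger
hypothesis space), then applies the per-type direction rules: cis
segment CNVs act positively only; methylation and microRNA negatively
only; trans CNVs, mutations and SNPs either way. These thresholds are
package defaults exposed in configuration, not calibrated constants.

**Dispersion-corrected p-values.** With graded labels the classical
χ²(1) reference is wrong: the model-based information overstates the
sampling variance of the score, so the raw LLR is stochastically smaller
than χ²(1) and naive p-values are conservative. The asymptotic null is
`c · χ²(1)` with

    c = Var(e) / [ (q_down + q_up) − (q_up − q_down)² ],

the ratio of the empirical variance of the target's expected state to
the variance a hard label with the same marginal state probabilities
would have (c = 1 exactly for point masses). All 1-df tests divide the
LLR by c before the χ² tail. Null simulations at n = 200 confirm
uniform p-values (KS distance < 0.08) and type-I error at α = 0.01
inside [0.005, 0.02].

**Permutation FDR.** The null model permutes the target matrix's sample
labels as a unit (preserving all inter-feature correlation), reruns the
full screen, and records the passing count R₀. FDR1 = mean(R₀)/R;
FDR2 = π̂₀·FDR1 with π̂₀ = min(1, 2·mean(p > 0.5)). Both are clipped to
[0, 1]; R = 0 leaves the estimate undefined rather than zero.

## Layered model selection

Per target, screened candidates are admitted by forward selection in
four priority levels of decreasing mechanistic directness: (1)
aberrations of the gene itself — its mutations and methylations,
segment CNVs covering or within 1 Mb, same-chromosome SNPs; (2)
positive trans segment CNVs, non-local mutations (both signs),
non-local methylations (negative), non-local SNPs; (3) negative trans
segment CNVs; (4) microRNA repression. Same-chromosome segments beyond
the 1 Mb window count as trans. Within a level, the greedy step adds
the candidate with the largest conditional LLR given the current model,
provided its dispersion-corrected 1-df p-value is ≤ `alpha_add`
(default 1e−3) and its refitted sign obeys the type rule; all
coefficients are re-estimated jointly after each addition (standard
forward selection — the alternative of freezing earlier coefficients
was rejected as statistically weaker). Ties break by (LLR descending,
effector ID ascending) for determinism. Guards: at most one segment
effector per chromosome, at most 10 effectors per target. SNP
effectors are scored but excluded from module assembly by default
(`include_snps` overrides): in practice too few SNP pairs survive the
stringent threshold to support modules.

## Module assembly

Related effectors are consolidated first: segment CNVs on the same
chromosome are always combined; methylation and microRNA profiles are
clustered as connected components of the graph joining pairs with
Pearson correlation ≥ `r_min` (default 0.6) of expected states —
the simplest graph-theoretic clustering, chosen over modularity-style
algorithms for transparency and determinism. Each (effector cluster,
sign) pair seeds a proto-module whose targets are the union over member
effectors; positive and negative target sets of the same effector stay
separate. Modules merge when their target overlap strictly exceeds one
third of the smaller module or reaches 50 genes ("exceeds … 50" is read
as ≥ 50, "exceeds one-third" as strictly >; both configurable).
Merging iterates in a deterministic order (size descending, ID
ascending) to a fixed point, is order-independent (tested against a
brute-force oracle), and may join modules of opposite sign — a CNV-gain
module and a methylation module sharing targets merge into a mixed-sign
(±) module, with each effector keeping its own sign. Module activity
is the per-sample median expected state over targets.

## Validation suite

Six per-module tests, each per dataset, with a cross-dataset summarizer
applying the counting rules (prognosis significant in ≥3 datasets;
coherence in ≥5; effector-target in ≥6):

1. **Prognosis** — univariate Cox proportional-hazards coefficient per
   gene (in-package 1-D Newton on the Breslow partial likelihood;
   cross-checked against lifelines, which is Efron-only, on tie-free
   data), then a KS comparison of the module targets' coefficient
   distribution against the all-gene background. Both one-sided
   directions are examined; the reported p is the exact two-sided test
   (their calibrated combination) and the dominant side gives the
   direction — positive deviation means worse survival.
2. **Coherence** — within-module pairwise expression correlations
   versus those of a strongly co-expressed reference set (ribosomal
   genes by convention), one-sided KS for stochastic dominance.
3. **Effector–target** — in external expression-only cohorts, effector
   gene expressions proxy the unmeasured aberrations (cis-target median
   for chromosome CNVs). Proxy×target correlations are compared against
   proxy×all-genes, one-sided in the direction implied by the module
   sign *times the proxy sign*: methylated-gene expression anti-tracks
   its own methylation, so the expected correlation direction flips for
   methylation modules. microRNA modules are skipped (no mRNA proxy).
4. **Recurrence** — two-sided KS of proxy expression between disease
   and comparison groups; direction = sign of the median difference.
5. **Enrichment** — one-sided Fisher exact tests against GMT gene-set
   collections over a declared universe, Bonferroni-corrected by the
   number of sets.
6. **Co-citation** — consumed from a precomputed count table (strictly
   offline): upper binomial tail of the co-cited-target count with
   background frequency q = genome-wide co-citations / 22 697.

α = 0.05 for all KS-based tests by default, exposed in configuration.

## Subtype alignment

Each module's representative per-sample value is the median target
expression on the CDF scale; `≥ 0.5` classifies a sample as *high*. A
subtype is *concentrated* in a binary class when at most 10 of its
samples (configurable slack) fall in the complementary class. A joint
hallmark is a conjunction of required polarities over a module list;
precision/recall are computed against a binary truth label
(methylator-phenotype status in the study design), and flagged versus
unflagged samples are compared by Kaplan–Meier curves with the logrank
test (lifelines). Subtype and methylator labels are inputs, never
inferred.

## Synthetic data generator

The generator is first-class code defining the package's study
conditions: 120 samples, 400 genes on 4 chromosomes of 80 CNV probes
(one planted breakpoint each, segment states −1/0/+1 with 20%/20%
gain/loss prevalence, probe noise SD 0.3 at state magnitude 0.5); 40%
of each chromosome's genes as cis targets; two trans-driver
chromosomes (25 targets each, one positive, one negative); three
mutation effectors (prevalence 0.1, 15 targets plus the gene itself);
two methylation clusters of four genes (prevalence 0.3, 25 non-local
targets, silencing their own genes); two microRNA clusters of two
(20 targets each); planted shifts of 0.8 against expression noise SD
0.4 — roughly the two-standard-deviation effects typical of driver
aberrations in array data. Survival is exponential with log-hazard
linear in planted module activities, with 30% independent censoring —
the simplest law satisfying the Cox tests' assumptions. Subtype labels
derive from the planted activities by noisy argmax; methylator status
is the first methylation cluster's latent. External cohorts re-draw new
samples from the same blueprint, attenuating aberration prevalence in
the comparison group.

What the generator does **not** emulate: array-platform noise profiles
and batch effects, intratumoral heterogeneity, realistic linkage
between SNPs and expression (SNPs are pure noise by default), gene-gene
regulatory cascades beyond single latent drivers, and real cohort
sample sizes. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated generative law,
not performance on real tumor cohorts.

## Problem sizes and determinism

The packaged tests run the full pipeline at the default conditions for
the 20-seed recovery figure and at a half-scale configuration (60
samples, 200 genes, same effect sizes, noise and prevalences) for
fixtures exercised repeatedly; segmentation and calibration figures use
200–500 seeded replicates. All randomness flows through
`numpy.random.default_rng` seeded per run; pipeline outputs are
byte-identical under a fixed seed and independent of parallel
scheduling (there is none — stages are sequential and deterministic).

## Known limitations

- Supplementary details of the original modelling framework
  (quantization family, segmentation stopping rule, screening threshold
  table, FDR2 formula, effector clustering algorithm) are not public;
  the choices above are this package's own, exposed in configuration.
- Greedy forward selection is not optimal subset selection; strongly
  collinear effectors resolve by the level ordering and tie-breaks.
- The dispersion-corrected χ² reference is asymptotic; below ~30
  effective samples the permutation FDR machinery is the safer guide.
- Merged mixed-sign modules lose a single direction for the
  effector-target test; the two-sided variant is used there.
- The univariate Cox fitter assumes proportional hazards and reports
  Wald p-values; no covariate adjustment is performed.
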