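# Methods

## Model and scores

The scanner treats a case-control sample of N individuals at L SNP loci
(genotypes coded as minor-allele counts 0/1/2, phenotype 0/1) as arising
from a partition penetrance model: a model assigns each individual to one
of d classes and gives every class its own disease probability. Five
elementary templates generate the model space — the full (M1) and dominant
(M2) single-locus models and the full (M3), dominant-with-main-effects (M4)
and pure-interaction (M5) two-locus models — and a combined model is any
set of elementary models on pairwise-disjoint loci, whose partition is the
product (all intersections) of the component partitions. Disjointness is
required because, e.g., M1(j) asserts a main effect at j while M5(j,k)
denies one; overlapping components would contradict each other. The empty
combination is the null model M0 (one class).

With independent beta(α, α) priors on the class probabilities, the marginal
likelihood factorizes over classes into beta-binomial terms and is
evaluated exactly with log-gamma functions; empty structural classes
contribute a factor of one, so they are retained in the bookkeeping at no
cost to the score. All score arithmetic is in natural logs: the likelihood
product underflows in double precision around N ≈ 1700, which is well
inside the intended sample-size range. The structure prior P(M) ∝ ξ^{L_M}
(L_M = number of SNPs in the model) is used only through ratios and
self-normalized sums, so its normalizing constant is never computed.

### Model identity

M3(j,k) induces exactly the partition of {M1(j), M1(k)}, and M4(j,k) that
of {M2(j), M2(k)}. Model identity therefore canonicalizes M3 and M4 into
their single-locus products; otherwise the averaging step would count one
statistical model twice whenever the search visits it under both names.
M3/M4 remain in the proposal pool as single moves, which makes plausible
two-locus building blocks reachable in one step. Canonicalization changes
neither the partition nor L_M, hence neither the likelihood nor the prior —
this is asserted property-wise in the test suite.

### Search and averaging

The learning procedure: (1) score all 2L + 3·C(L,2) elementary models
analytically (vectorized via indicator-matrix cross products, chunked over
row blocks so memory stays bounded at chromosome scale); (2) retain the K
highest-posterior elementary models plus all single-locus models, with
score ties broken by a fixed canonical ordering so the pool is
deterministic; (3) run a non-reversible Metropolis–Hastings chain over
conflict-free combinations, starting from M0, drawing the operators
add/remove/switch with probabilities (0.5, 0.45, 0.05). Add inserts a
uniformly drawn pool model after deleting every conflicting component;
remove deletes a uniform component (on M0 it proposes M0 itself, keeping
the printed operator probabilities unconditional); switch is remove-then-
add. A proposal is accepted with probability min{1, score ratio}; the
proposal-probability ratio is deliberately omitted, which makes the chain
non-reversible. The chain is *not* used for ergodic averaging: (4) every
state whose score is evaluated — current or proposed, accepted or not — is
recorded with its exact unnormalized posterior, and the per-SNP inclusion
probability is the renormalized sum over the distinct recorded models.
Since scoring a state constitutes a visit, recording proposals strictly
enlarges the support of the estimator at no extra cost. Loci contained in
no visited model are flagged and reported with inclusion probability 0 and
score −inf (serialized as the string "-inf"; rankings place them last, ties
by locus index).

Defaults follow the replicate study scale: α = 3 (mildly informative,
favoring class probabilities near 0.5 as appropriate for balanced designs;
α = 1 gives practically identical results), ξ = 1/L (1/460 at replicate
scale), K = 5000, 200,000 iterations; the chromosome profile uses
K = 50,000, 3.5M iterations and ξ = 1/1000. Convergence is left to trace
inspection (the current model's log score is logged every 1,000
iterations); no automatic diagnostic is imposed.

### Comparators

The marginal LRT compares the three-parameter genotype logistic model to
the intercept; the pairwise score maximizes, over partners, the LRT of the
dominant-coded 2×2 interaction logistic model. Both alternatives are
saturated on their class partitions, so the maximized log-likelihoods are
closed form (class case fractions, with the 0·log 0 = 0 convention for
empty or pure cells — the limiting value of the iterative fit under
separation) and agree with an IRLS fit to ≥ 8 digits where the fit
converges. Degrees of freedom are fixed at 2 and 3 even when empty classes
reduce the effective dimension: the comparator is reproduced as commonly
run, not improved. The gene–gene Bayes factor scores each locus by its best
partner under the equal-weight mixture of the M3/M4/M5 marginal
likelihoods against the null; a max-over-templates variant is available
behind a flag and behaves nearly identically.

## Synthetic data generator

Real genotype panels with realistic linkage are not redistributable, so the
simulator synthesizes its own pool: haplotypes follow a first-order Markov
allele-copying process in independent blocks, with the adjacent-pair
allele correlation drawn uniformly from [0.2, 0.95] within a block and zero
across blocks. Each requested correlation is truncated to the feasible
maximum of a binary Markov step for the adjacent frequency pair, which
keeps every marginal frequency exact (clipping conditional probabilities
instead would inflate low-MAF SNPs). Genotypes are sums of two independent
haplotypes (Hardy–Weinberg). Non-causal SNP frequencies are uniform on
[0.15, 0.45]; each causal-capable block centers one SNP at the target
causal MAF.

A replicate draws four causal SNPs (empirical MAF within ±1% of target)
from distinct blocks, takes the 20 closest flanking SNPs with MAF > 0.1 per
side (the ascertainment floor), deletes the causal column — leaving it
hidden in the gap between the 20th and 21st retained SNPs of its 40-SNP
area — and concatenates three 100-SNP null intervals between the four
areas: 460 SNPs, of which 160 (≈ 0.35) are in disease-associated areas.
Disease statuses come from the multiplicative, threshold or triplet
penetrance model with genotype relative risk GRR; the baseline risk is
calibrated by monotone bisection so the capped mean disease probability
over the 2131-individual pool equals the 40% target prevalence (≈ 850
cases; probabilities are capped at min(1, ·) because the strongest
multiplicative settings would otherwise exceed 1, and the calibration
accounts for the cap). All cases and an equal number of uniformly drawn
controls form the data set; a replicate with more cases than non-cases is
rejected and redrawn from a fresh sub-seed. The chromosome variant cuts
five roughly equal null intervals from one long synthetic chromosome
(~8,700 SNPs total) and inserts the four areas between them.

What the generator does *not* emulate: long-range LD and LD-block
structure of real panels (correlation decays geometrically with marker
distance here, so only a few markers tag each hidden causal SNP, and at
MAF 0.05 the feasible tagging correlation of a binary Markov step next to a
0.15–0.45-MAF neighbor is itself bounded ≈ 0.35–0.6), population
structure, genotyping error, and X-chromosome dosage. Passing tests
therefore demonstrate correctness of the machinery and qualitative power
behaviour under controlled LD, not quantitative power on any real panel.

## Evaluation conventions

Detection is per area: walking the ranked SNP list (ties broken by
ascending locus index), an area counts as detected at its first SNP and
every outside SNP is a false positive; curves are summarized by the mean
and 2.5/97.5 percentiles (linear-interpolation convention) across
replicates. The AUC normalizes both axes to unity and integrates the
left-continuous step function, extended at the attained level to x = 1 —
perfect ranking gives 1, detecting everything only after all outsiders
gives 0. Location accuracy is the marker distance from the top SNP to its
area's gap (positions 20/21 are distance 1; maximum and outside-sentinel
20); for triplet data the area of the main-effect locus is excluded from
the arg-max, since it is trivially easiest to find. Win/loss comparisons
drop exact ties and use a two-sided binomial test at 0.05, with
|wins − losses| < 5 reported as a practical tie. Table-style summaries
report the across-replicate (min, max) of the per-replicate maximum area
score — labelled as such, since pooled percentiles would be an equally
defensible convention.

## Numerical and design choices

* Missing genotypes are imputed at the allele level: two independent draws
  from the locus's empirical allele frequency (Hardy–Weinberg pairing), not
  a genotype-level draw; frequencies are computed on the table as given.
* Mixed-radix class labels (component order = canonical sorted order) make
  partitions, scores and serialized model strings reproducible across runs;
  model strings are 1-based ("M5(12,47)+M2(3)", "M0").
* Per-replicate seeds derive from the master seed by hashing the grid-cell
  key, so enlarging the grid never changes existing replicates; every
  random path is a `numpy` Generator seeded below 2^31.
* The experiment driver checkpoints per-replicate score files with SHA-256
  checksums and skips completed work on rerun.
* Test and acceptance problem sizes are scaled to single-CPU runs: the
  exhaustive-enumeration cross-check uses 3-locus tables where the full
  combined-model space is enumerable, power/recovery uses 20 replicates at
  50,000 search iterations, and null calibration uses 200 replicates.

## Known limitations

* The likelihood is prospective; no retrospective/matched correction is
  applied (the α > 1 prior partially encodes the balanced design instead).
* No recessive elementary templates; three-way and higher interactions are
  representable only through products of full models, at the cost of
  redundant parameters.
* Single-chain behaviour: the visited-set estimator can assign a spuriously
  low score to a locus whose low-scoring models happened not to be visited;
  longer searches shrink this risk but nothing detects it automatically.
* Continuous covariates cannot be added without losing the closed-form
  marginal likelihood.
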