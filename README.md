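# bmagene

Bayesian model averaging for multilocus case-control association mapping
with explicit gene–gene interactions.

Single-marker tests dominate genome-wide association analysis, but they can
miss causal variants whose effect only appears jointly with another locus
(epistasis without main effects). `bmagene` implements a Bayesian
model-averaging (BMA) scanner for dichotomous phenotypes that scores
single-locus and two-locus penetrance models analytically, searches the
space of their conflict-free combinations with a non-reversible MCMC
algorithm, and averages exact model posteriors into per-SNP evidence of
association. It is aimed at statistical geneticists who want interaction
awareness in a case-control scan, and at methodologists who want a fully
reproducible simulation/evaluation harness for comparing association
scores.

## The model

For individual *i* with genotypes *Z<sub>ij</sub>* ∈ {0, 1, 2} (minor-allele
counts) and phenotype *y<sub>i</sub>* ∈ {0, 1}, five elementary penetrance
templates define disease-probability classes:

* **M1(j)** — full single-locus model (3 classes, one per genotype);
* **M2(j)** — dominant single-locus model (carrier vs non-carrier);
* **M3(j,k)** — full two-locus model (9 classes);
* **M4(j,k)** — dominant two-locus model with main effects (4 classes);
* **M5(j,k)** — pure dominant interaction: both-carrier vs the rest (2 classes).

A *combined model* M is a set of elementary models on disjoint loci; its
partition is the product of the component partitions. With independent
beta(α, α) priors on the class probabilities the marginal likelihood is
closed-form:

P(Data | M) = ∏<sub>c</sub> Γ(2α)/Γ(2α+|s<sub>c</sub>|) ·
Γ(α+n<sub>c1</sub>) Γ(α+n<sub>c0</sub>) / Γ(α)²,

where n<sub>cb</sub> counts individuals of class *c* with status *b*. The
structure prior P(M) ∝ ξ<sup>L<sub>M</sub></sup> penalizes each of the
L<sub>M</sub> SNPs in the model geometrically. The scanner (1) scores all
2L + 3·C(L,2) elementary models analytically, (2) keeps the K best plus all
single-locus models, (3) runs a non-reversible Metropolis–Hastings search
over their combinations — a proposal M\* is accepted with probability
min{1, P(Data|M\*)P(M\*) / P(Data|M)P(M)}, with no proposal-ratio term —
and (4) renormalizes the exact unnormalized posteriors over the distinct
visited models ℳ\* into per-SNP inclusion probabilities
P(X<sub>j</sub>=1 | Data) and the BMA score
S<sub>BMA</sub>(j) = log posterior odds.

Three comparator scores are included: the marginal LRT (χ², 2 df), the
best-partner dominant-coded interaction LRT (χ², 3 df), and the best-partner
gene–gene Bayes factor (an equal-weight mixture of the M3/M4/M5 marginal
likelihoods against the null). A simulation module generates LD-structured
case-control replicates with four hidden causal SNPs under multiplicative,
threshold (pairwise-interaction) and triplet (three-way) penetrance models,
and an evaluation module computes area-detection curves, normalized AUC,
location accuracy and win/loss comparisons.

## Worked example

Simulate a strong pairwise-interaction data set (threshold model, GRR 2.0,
MAF 0.2: two causal pairs, no main effects, 40% prevalence, equal numbers
of cases and controls) and scan it:

```python
from bmagene import BmaScanner, SimConfig, simulate_replicate
from bmagene.evaluate import auc, detection_curve, location_accuracy

ds = simulate_replicate(SimConfig(generative_model="threshold",
                                  grr=2.0, maf=0.2, seed=42))
scanner = BmaScanner(alpha=3.0, xi=1/460, K=5000, n_iter=50_000,
                     random_state=0).fit_table(ds.table)
for j in scanner.ranking_()[:3]:
    print(j + 1, scanner.inclusion_probabilities_[j], scanner.scores_[j])
```

Output (N = 1742 individuals, L = 460 SNPs, disease areas at loci 1–40,
141–180, 281–320, 421–460):

```
top 5 loci:
  locus  21  P_incl=1.000  S_BMA=+11.35  in_area=True
  locus 160  P_incl=0.836  S_BMA=+1.63   in_area=True
  locus 161  P_incl=0.313  S_BMA=-0.79   in_area=True
  locus 301  P_incl=0.241  S_BMA=-1.15   in_area=True
  locus 438  P_incl=0.068  S_BMA=-2.61   in_area=True
detection curve FP counts [0 0 0 0 0], AUC 1.0, location distance 1
best visited model: M5(21,160)
```

All five top-ranked SNPs flank hidden causal positions; the highest-scoring
model is the pure interaction M5 between markers adjacent to the two causal
SNPs of the first pair, and the top SNP sits one marker from the hidden
causal position (distance 1 of a worst case 20). A locus that appears in no
visited model has inclusion probability 0 and score −inf.

The same pipeline is available from the shell:

```bash
bmagene simulate --model threshold --grr 2.0 --maf 0.2 --seed 42 --out sim/
bmagene scan --genotypes sim/rep000_genotypes.tsv --alpha 3 --xi 1/460 \
             --k 5000 --iters 50000 --seed 0 --out scan/
bmagene classic --genotypes sim/rep000_genotypes.tsv --method marginal --out classic/
bmagene evaluate --scores classic/marginal_scores.tsv \
                 --truth sim/rep000_truth.json --out eval.json
```

`bmagene experiment` drives the full replicate grid (3 generative models ×
GRR ∈ {1.3, 1.6, 2.0} × MAF ∈ {0.05, 0.1, 0.2} × 100 replicates, resumable
with checksums) and `bmagene sweep` reruns the scan over
α ∈ {1, 3, 10} × ξ ∈ {1/46, 1/460, 1/4600} for prior-sensitivity overlays.

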