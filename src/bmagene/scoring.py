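"""Closed-form Bayesian scores for partition penetrance models.

With independent beta(alpha, alpha) priors on the per-class disease
probabilities, the marginal likelihood of a partition model factorises over
classes into beta-binomial terms:

    P(Data | M) = prod_c  Gamma(2a) / Gamma(2a + |s_c|)
                          * Gamma(a + n_c1) Gamma(a + n_c0) / Gamma(a)^2,

where n_cb counts individuals of class c with phenotype b.  The structure
prior penalises each SNP geometrically, P(M) propto xi^{L_M}.  Everything
is computed in natural-log space (the product underflows around N ~ 1700).

The module also provides vectorized scorers that evaluate all single-locus
and all pairwise elementary models at once via indicator-matrix products,
and the pairwise gene-gene Bayes-factor score (an equally weighted mixture
of the M3/M4/M5 marginal likelihoods against the null model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .models import CombinedModel, Partition

__all__ = [
    "PriorSpec",
    "ModelScore",
    "class_counts",
    "log_marginal_likelihood",
    "log_prior",
    "score_model",
    "null_log_marginal_likelihood",
    "single_locus_log_ml",
    "pairwise_log_ml",
    "gxg_bayes_factor_score",
    "gxg_bayes_factor_scores_all",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters: ``alpha`` of the symmetric beta prior on class
    disease probabilities, and the structure parameter ``xi`` in (0, 1)
    penalising each SNP included in a model."""

    alpha: float = 3.0
    xi: float = 1.0 / 460.0

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not 0.0 < self.xi < 1.0:
            raise ValueError("xi must lie in (0, 1)")


@dataclass(frozen=True)
class ModelScore:
    log_marginal_likelihood: float
    log_prior: float

    @property
    def log_unnorm_posterior(self) -> float:
        return self.log_marginal_likelihood + self.log_prior


def class_counts(partition: Partition, phenotype: np.ndarray) -> np.ndarray:
    """Per-class (controls, cases) counts, shape (d, 2); empty classes zero."""
    y = np.asarray(phenotype)
    if y.shape[0] != partition.class_of.shape[0]:
        raise ValueError("phenotype length does not match partition")
    flat = np.bincount(
        2 * partition.class_of + y, minlength=2 * partition.n_classes
    )
    return flat.reshape(partition.n_classes, 2)


def log_marginal_likelihood(counts: np.ndarray, alpha: float) -> float:
    """Natural log of the beta-binomial marginal likelihood given per-class
    (controls, cases) counts.  Empty classes contribute exactly 0."""
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    counts = np.asarray(counts, dtype=np.float64).reshape(-1, 2)
    n0, n1 = counts[:, 0], counts[:, 1]
    tot = n0 + n1
    terms = (
        gammaln(2 * alpha)
        - gammaln(2 * alpha + tot)
        + gammaln(alpha + n1)
        + gammaln(alpha + n0)
        - 2 * gammaln(alpha)
    )
    return float(terms.sum())


def _log_ml_terms(n1, n0, alpha):
    """Vectorized per-class log beta-binomial term (arrays broadcast)."""
    return (
        gammaln(2 * alpha)
        - gammaln(2 * alpha + n1 + n0)
        + gammaln(alpha + n1)
        + gammaln(alpha + n0)
        - 2 * gammaln(alpha)
    )


def log_prior(model: CombinedModel | int, xi: float) -> float:
    """Unnormalized log structure prior L_M * log(xi); the normalizing
    constant cancels in every posterior ratio used downstream."""
    if not 0.0 < xi < 1.0:
        raise ValueError("xi must lie in (0, 1)")
    n_loci = model if isinstance(model, int) else model.n_loci
    return n_loci * float(np.log(xi))


def score_model(
    model: CombinedModel,
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    prior: PriorSpec,
) -> ModelScore:
    """Log marginal likelihood + log prior of a combined model on data."""
    part = Partition(model.class_labels(genotypes), model.n_classes)
    counts = class_counts(part, phenotype)
    return ModelScore(
        log_marginal_likelihood=log_marginal_likelihood(counts, prior.alpha),
        log_prior=log_prior(model, prior.xi),
    )


def null_log_marginal_likelihood(phenotype: np.ndarray, alpha: float) -> float:
    y = np.asarray(phenotype)
    n1 = int(y.sum())
    return log_marginal_likelihood(np.array([[y.size - n1, n1]]), alpha)


def _indicator_stacks(genotypes: np.ndarray, phenotype: np.ndarray):
    """Per-genotype-value indicator matrices split by phenotype, float32
    for fast BLAS cross products."""
    y = np.asarray(phenotype).astype(bool)
    out = []
    for rows in (~y, y):  # controls first, cases second
        z = genotypes[rows]
        out.append([(z == a).astype(np.float32) for a in (0, 1, 2)])
    return out  # [controls[a], cases[a]]


def single_locus_log_ml(
    genotypes: np.ndarray, phenotype: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Log marginal likelihoods of M1(j) and M2(j) for every locus j.

    Returns two length-L arrays.
    """
    y = np.asarray(phenotype).astype(bool)
    counts = np.empty((2, 3, genotypes.shape[1]))  # [pheno, genotype, locus]
    for b, rows in enumerate((~y, y)):
        z = genotypes[rows]
        for a in (0, 1, 2):
            counts[b, a] = (z == a).sum(axis=0)
    m1 = _log_ml_terms(counts[1], counts[0], alpha).sum(axis=0)
    carrier = counts[:, 1] + counts[:, 2]
    m2 = _log_ml_terms(counts[1, 0], counts[0, 0], alpha) + _log_ml_terms(
        carrier[1], carrier[0], alpha
    )
    return m1, m2


def pairwise_log_ml(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    alpha: float,
    rows: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Log marginal likelihoods of M3/M4/M5 for locus pairs.

    Computes, for every pair (j, k) with j taken from ``rows`` (default: all
    loci) and k over all loci, the nine genotype-pair cell counts by
    indicator-matrix products and folds them into the three two-locus model
    scores.  Returns arrays of shape (len(rows), L) keyed "M3", "M4", "M5";
    the diagonal (j == k) is -inf.  Row-chunking via ``rows`` keeps memory
    bounded on large L.
    """
    (ctrl, case) = _indicator_stacks(genotypes, phenotype)
    L = genotypes.shape[1]
    rows = np.arange(L) if rows is None else np.asarray(rows)
    # cell[b][a1][a2][r, k] = #individuals with pheno b, Z_j=a1, Z_k=a2
    cells = np.empty((2, 3, 3, rows.size, L))
    for b, stack in enumerate((ctrl, case)):
        for a1 in range(3):
            block = stack[a1][:, rows]
            for a2 in range(3):
                cells[b, a1, a2] = block.T @ stack[a2]
    m3 = _log_ml_terms(cells[1], cells[0], alpha).sum(axis=(0, 1))
    # dominant collapse: 2x2 cells from the 3x3 table
    dom = np.empty((2, 2, 2, rows.size, L))
    dom[:, 0, 0] = cells[:, 0, 0]
    dom[:, 0, 1] = cells[:, 0, 1] + cells[:, 0, 2]
    dom[:, 1, 0] = cells[:, 1, 0] + cells[:, 2, 0]
    dom[:, 1, 1] = cells[:, 1:, 1:].sum(axis=(1, 2))
    m4 = _log_ml_terms(dom[1], dom[0], alpha).sum(axis=(0, 1))
    rest = dom[:, 0, 0] + dom[:, 0, 1] + dom[:, 1, 0]
    m5 = _log_ml_terms(dom[1, 1, 1], dom[0, 1, 1], alpha) + _log_ml_terms(
        rest[1], rest[0], alpha
    )
    diag = rows[:, None] == np.arange(L)[None, :]
    for arr in (m3, m4, m5):
        arr[diag] = -np.inf
    return {"M3": m3, "M4": m4, "M5": m5}


def gxg_bayes_factor_scores_all(
    table_or_genotypes,
    phenotype: np.ndarray | None = None,
    alpha: float = 3.0,
    combine: str = "mean",
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise gene-gene Bayes-factor score for every locus.

    For each j the score is max over partners k of
    log P(Data | M(j,k)) - log P(Data | M0), where P(Data | M(j,k)) is the
    equally weighted mixture (1/3 each) of the M3, M4 and M5 marginal
    likelihoods (``combine='max'`` takes the best of the three instead).
    Returns (scores, best_partner) arrays of length L.
    """
    if phenotype is None:
        genotypes, phenotype = table_or_genotypes.genotypes, table_or_genotypes.phenotype
    else:
        genotypes = np.asarray(table_or_genotypes)
    L = genotypes.shape[1]
    if L < 2:
        raise ValueError("need at least two loci")
    log_ml0 = null_log_marginal_likelihood(phenotype, alpha)
    scores = np.empty(L)
    partners = np.empty(L, dtype=np.int64)
    for start in range(0, L, chunk):
        rows = np.arange(start, min(start + chunk, L))
        ml = pairwise_log_ml(genotypes, phenotype, alpha, rows=rows)
        stack = np.stack([ml["M3"], ml["M4"], ml["M5"]])
        if combine == "mean":
            mix = logsumexp(stack, axis=0) - np.log(3.0)
        elif combine == "max":
            mix = stack.max(axis=0)
        else:
            raise ValueError("combine must be 'mean' or 'max'")
        partners[rows] = np.argmax(mix, axis=1)
        scores[rows] = mix[np.arange(rows.size), partners[rows]] - log_ml0
    return scores, partners


def gxg_bayes_factor_score(
    table, j: int, alpha: float = 3.0, combine: str = "mean"
) -> float:
    """Gene-gene Bayes-factor score of a single locus (see the _all variant)."""
    scores, _ = gxg_bayes_factor_scores_all(table, alpha=alpha, combine=combine)
    return float(scores[j])
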