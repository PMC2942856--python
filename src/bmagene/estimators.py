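"""Scikit-learn style scanners over case-control genotype matrices.

Each estimator takes ``fit(X, y)`` with X an (N, L) matrix of minor-allele
counts in {0, 1, 2} and y a binary phenotype, and exposes a per-locus
``scores_`` array (higher = stronger evidence of association) plus
method-specific fitted attributes.  They compose with sklearn tooling
(``get_params``/``set_params``/``clone``); a ``fit_table`` convenience
accepts a :class:`~bmagene.io.GenotypeTable`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GenotypeTable
from .scoring import PriorSpec, gxg_bayes_factor_scores_all
from .classic import gxg_lrt_scores_all, marginal_lrt_scores_all
from .search import SearchConfig, naive_bma, run_search, select_top_k, snp_posteriors

__all__ = [
    "BmaScanner",
    "MarginalLrtScanner",
    "PairwiseLrtScanner",
    "PairwiseBayesFactorScanner",
]


def _validate(X, y):
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be an (N, L) genotype matrix")
    if y.shape != (X.shape[0],):
        raise ValueError("y must be a length-N phenotype vector")
    if not np.isin(X, (0, 1, 2)).all():
        raise ValueError("genotypes must be minor-allele counts in {0, 1, 2}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("phenotype must be binary 0/1")
    return GenotypeTable(genotypes=X.astype(np.int8), phenotype=y.astype(np.int8))


class _TableScanner(BaseEstimator):
    def fit_table(self, table: GenotypeTable):
        return self.fit(table.genotypes, table.phenotype)


class BmaScanner(_TableScanner):
    """Bayesian model-averaging association scanner.

    Scores every elementary single-locus and pairwise penetrance model
    analytically, retains the ``K`` best, explores their conflict-free
    combinations by a non-reversible Metropolis-Hastings search of
    ``n_iter`` iterations, and averages exact model posteriors over the
    distinct visited models into per-locus inclusion probabilities.

    Parameters
    ----------
    alpha : beta(alpha, alpha) hyperparameter of the class disease
        probabilities (default 3, mildly favoring probabilities near 0.5
        as appropriate for balanced case-control designs).
    xi : structure-prior penalty per included SNP; ``None`` (default) uses
        1/L at fit time.
    K, n_iter, operator_probs, random_state : search controls; see
        :class:`~bmagene.search.SearchConfig`.
    naive : average over {null} + the elementary pool only, without any
        model search or combined models (the naive comparator).

    Attributes
    ----------
    inclusion_probabilities_ : (L,) posterior P(X_j = 1 | Data).
    scores_ : (L,) log posterior odds; -inf for never-visited loci.
    never_visited_ : (L,) bool flag.
    visited_ : the scored distinct-model set.
    trace_ : per-iteration log unnormalized posterior of the current model.
    pool_ : the retained elementary models.
    """

    def __init__(
        self,
        alpha: float = 3.0,
        xi: float | None = None,
        K: int = 5000,
        n_iter: int = 200_000,
        operator_probs: tuple[float, float, float] = (0.5, 0.45, 0.05),
        random_state: int = 0,
        naive: bool = False,
    ):
        self.alpha = alpha
        self.xi = xi
        self.K = K
        self.n_iter = n_iter
        self.operator_probs = operator_probs
        self.random_state = random_state
        self.naive = naive

    def fit(self, X, y):
        table = _validate(X, y)
        xi = 1.0 / table.n_loci if self.xi is None else self.xi
        config = SearchConfig(
            K=self.K,
            n_iter=self.n_iter,
            operator_probs=tuple(self.operator_probs),
            seed=self.random_state,
            prior=PriorSpec(alpha=self.alpha, xi=xi),
        )
        self.pool_ = select_top_k(table, config)
        if self.naive:
            post = naive_bma(table, self.pool_, config.prior)
            self.visited_, self.trace_ = None, None
        else:
            self.visited_, self.trace_ = run_search(table, self.pool_, config)
            post = snp_posteriors(self.visited_)
        self.inclusion_probabilities_ = post.inclusion_probability
        self.scores_ = post.score
        self.never_visited_ = post.never_visited
        self.prior_ = config.prior
        return self

    def ranking_(self) -> np.ndarray:
        return np.lexsort((np.arange(self.scores_.size), -self.scores_))


class MarginalLrtScanner(_TableScanner):
    """Single-locus likelihood-ratio comparator.

    Tests the full three-parameter genotype logistic model against the null
    per locus; the statistic is chi-square with 2 df and ``scores_`` is
    -log10 of the upper-tail p-value.
    """

    df = 2

    def fit(self, X, y):
        table = _validate(X, y)
        self.statistics_ = marginal_lrt_scores_all(table)
        self.p_values_ = np.clip(
            stats.chi2.sf(self.statistics_, self.df), np.finfo(float).tiny, 1.0
        )
        self.scores_ = -np.log10(self.p_values_)
        return self


class PairwiseLrtScanner(_TableScanner):
    """Pairwise-interaction likelihood-ratio comparator.

    For each locus, fits the dominant-coded 2x2 interaction logistic model
    with every partner and keeps the best: chi-square with 3 df,
    ``scores_`` = max_k -log10 p, ``best_partners_`` the arg-max locus.
    """

    df = 3

    def fit(self, X, y):
        table = _validate(X, y)
        self.statistics_, self.best_partners_ = gxg_lrt_scores_all(table)
        self.p_values_ = np.clip(
            stats.chi2.sf(self.statistics_, self.df), np.finfo(float).tiny, 1.0
        )
        self.scores_ = -np.log10(self.p_values_)
        return self


class PairwiseBayesFactorScanner(_TableScanner):
    """Pairwise gene-gene Bayes-factor comparator.

    ``scores_[j]`` = max over partners k of the log Bayes factor of the
    two-locus model at (j, k) against the null, where the two-locus marginal
    likelihood is the equally weighted mixture of the full (M3), dominant
    (M4) and pure-interaction (M5) templates (``combine='max'`` takes the
    best template instead of the mixture).
    """

    def __init__(self, alpha: float = 3.0, combine: str = "mean"):
        self.alpha = alpha
        self.combine = combine

    def fit(self, X, y):
        table = _validate(X, y)
        self.scores_, self.best_partners_ = gxg_bayes_factor_scores_all(
            table, alpha=self.alpha, combine=self.combine
        )
        return self
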