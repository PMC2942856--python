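"""Model-averaging search: top-K elementary selection, non-reversible MCMC
over combined models, and per-SNP inclusion posteriors.

The learning procedure has four steps: (1) score every elementary model
analytically; (2) keep the K highest-posterior elementary models, always
retaining all single-locus models; (3) run a non-reversible
Metropolis-Hastings search over conflict-free combinations of that pool,
accepting a proposal M* with probability

    min{1, P(Data|M*) P(M*) / P(Data|M) P(M)}

(the proposal-probability ratio is deliberately omitted); (4) estimate the
posterior of each model by renormalizing the exact unnormalized posteriors
over the set of distinct models visited, and from that the per-SNP
inclusion probability P(X_j = 1 | Data) and the log-posterior-odds score.

Every state whose score is evaluated (current or proposal, accepted or not)
is recorded in the visited set: the renormalized estimator sums over
visited models and scoring a state constitutes a visit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .models import CombinedModel, ElementaryModel, enumerate_elementary
from .scoring import (
    ModelScore,
    PriorSpec,
    log_marginal_likelihood,
    log_prior,
    pairwise_log_ml,
    single_locus_log_ml,
)

logger = logging.getLogger(__name__)

TRACE_CADENCE = 1000  # iterations between trace-log lines

__all__ = [
    "SearchConfig",
    "ScoredModelSet",
    "SnpPosterior",
    "select_top_k",
    "run_search",
    "snp_posteriors",
    "naive_bma",
    "enumerate_conflict_free",
]


@dataclass
class SearchConfig:
    """Knobs of the stochastic model search.

    ``K`` elementary models are retained for the combination pool and the
    chain runs ``n_iter`` iterations drawing the (add, remove, switch)
    operators with ``operator_probs``.  The defaults match the replicate
    scale; the chromosome profile uses K=50,000 and n_iter=3,500,000.
    """

    K: int = 5000
    n_iter: int = 200_000
    operator_probs: tuple[float, float, float] = (0.5, 0.45, 0.05)
    seed: int = 0
    prior: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        if self.K < 1 or self.n_iter < 1:
            raise ValueError("K and n_iter must be >= 1")
        if abs(sum(self.operator_probs) - 1.0) > 1e-12:
            raise ValueError("operator_probs must sum to 1")


@dataclass
class ScoredModelSet:
    """The distinct combined models visited, keyed by canonical identity,
    with their exact (never re-estimated) scores."""

    models: dict[str, tuple[CombinedModel, ModelScore]] = field(default_factory=dict)
    n_loci_total: int = 0

    def record(self, model: CombinedModel, score: ModelScore) -> None:
        self.models.setdefault(model.key(), (model, score))

    def __len__(self) -> int:
        return len(self.models)

    def __contains__(self, key: str) -> bool:
        return key in self.models


@dataclass
class SnpPosterior:
    """Per-locus inclusion probabilities P(X_j=1 | Data) and the BMA score
    log(p / (1-p)); loci absent from every visited model are flagged and
    carry probability 0 / score -inf."""

    inclusion_probability: np.ndarray
    score: np.ndarray
    never_visited: np.ndarray

    def ranking(self) -> np.ndarray:
        """Locus indices by descending score; -inf (never-visited) loci sort
        last, ties broken by ascending locus index."""
        return np.lexsort((np.arange(self.score.size), -self.score))


def _elementary_sort_key(m: ElementaryModel):
    return (m.loci, m.kind)


def _model_from_flat_index(idx: int, n_loci: int) -> ElementaryModel:
    """Inverse of the flat enumeration order used by
    :func:`score_elementary_models`: single-locus models first (per locus,
    M1 then M2), then locus pairs in (j, k) order with M3, M4, M5 each."""
    if idx < 2 * n_loci:
        return ElementaryModel("M1" if idx % 2 == 0 else "M2", (idx // 2,))
    pair, t = divmod(idx - 2 * n_loci, 3)
    # invert pair = C(L,2) - C(L-j,2) + (k - j - 1)
    j = 0
    remaining = pair
    while remaining >= n_loci - j - 1:
        remaining -= n_loci - j - 1
        j += 1
    k = j + 1 + remaining
    return ElementaryModel(("M3", "M4", "M5")[t], (j, k))


def score_elementary_models(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    prior: PriorSpec,
    chunk: int = 512,
) -> np.ndarray:
    """Log unnormalized posterior of every elementary model, vectorized.

    Returns a flat score array in the deterministic enumeration order of
    :func:`_model_from_flat_index`; model objects are materialized lazily
    from indices because all-pairs enumeration is quadratic in L.
    """
    L = genotypes.shape[1]
    lp1 = log_prior(1, prior.xi)
    lp2 = log_prior(2, prior.xi)
    m1, m2 = single_locus_log_ml(genotypes, phenotype, prior.alpha)
    singles = np.empty(2 * L)
    singles[0::2] = m1 + lp1
    singles[1::2] = m2 + lp1
    pair_blocks = []
    for start in range(0, L, chunk):
        rows = np.arange(start, min(start + chunk, L))
        ml = pairwise_log_ml(genotypes, phenotype, prior.alpha, rows=rows)
        for ridx, j in enumerate(rows):
            if j + 1 < L:
                block = np.stack(
                    [ml["M3"][ridx, j + 1 :], ml["M4"][ridx, j + 1 :], ml["M5"][ridx, j + 1 :]],
                    axis=1,
                )
                pair_blocks.append(block.ravel() + lp2)
    return np.concatenate([singles] + pair_blocks)


def select_top_k(table, config: SearchConfig) -> list[ElementaryModel]:
    """Step 2: the K highest-posterior elementary models, unioned with all
    single-locus models.  Ranking ties are broken by the canonical model
    ordering so the pool is deterministic."""
    genotypes, phenotype = table.genotypes, table.phenotype
    L = genotypes.shape[1]
    if L < 2:
        raise ValueError("need at least two loci")
    scores = score_elementary_models(genotypes, phenotype, config.prior)
    k = min(config.K, scores.size)
    order = np.lexsort((np.arange(scores.size), -scores))[:k]
    chosen = {_model_from_flat_index(int(i), L) for i in order}
    chosen.update(
        ElementaryModel(kind, (j,))
        for j in range(genotypes.shape[1])
        for kind in ("M1", "M2")
    )
    return sorted(chosen, key=_elementary_sort_key)


class _Scorer:
    """Scores combined-model states with caching by canonical identity."""

    def __init__(self, genotypes, phenotype, prior: PriorSpec):
        self.genotypes = genotypes
        self.phenotype = np.asarray(phenotype)
        self.prior = prior
        self._label_cache: dict[ElementaryModel, np.ndarray] = {}
        self._score_cache: dict[str, tuple[CombinedModel, ModelScore]] = {}

    def _labels(self, comp: ElementaryModel) -> np.ndarray:
        lab = self._label_cache.get(comp)
        if lab is None:
            lab = comp.class_labels(self.genotypes)
            self._label_cache[comp] = lab
        return lab

    def score(self, components: tuple[ElementaryModel, ...]):
        model = CombinedModel(components)
        key = model.key()
        hit = self._score_cache.get(key)
        if hit is not None:
            return key, hit[1]
        labels = np.zeros(self.phenotype.size, dtype=np.int64)
        d = 1
        for comp in model.components:
            labels = labels * comp.n_classes + self._labels(comp)
            d *= comp.n_classes
        counts = np.bincount(2 * labels + self.phenotype, minlength=2 * d).reshape(d, 2)
        score = ModelScore(
            log_marginal_likelihood=log_marginal_likelihood(counts, self.prior.alpha),
            log_prior=log_prior(model, self.prior.xi),
        )
        self._score_cache[key] = (model, score)
        return key, score


def run_search(
    table, pool: list[ElementaryModel], config: SearchConfig
) -> tuple[ScoredModelSet, np.ndarray]:
    """Step 3: non-reversible MCMC over conflict-free combinations of the
    pool, starting from the empty model.

    Operators (drawn with ``config.operator_probs``): ADD inserts a
    uniformly chosen pool model after deleting every conflicting component;
    REMOVE deletes a uniformly chosen component (a self-loop proposal on the
    null model); SWITCH is REMOVE followed by ADD.  Acceptance uses the
    exact score ratio without the proposal-ratio term.  Returns the visited
    set (every scored state) and the per-iteration trace of the current
    model's log unnormalized posterior.
    """
    if not pool:
        raise ValueError("elementary-model pool is empty")
    genotypes, phenotype = table.genotypes, table.phenotype
    rng = np.random.default_rng(config.seed)
    scorer = _Scorer(genotypes, phenotype, config.prior)

    ops = rng.choice(3, size=config.n_iter, p=list(config.operator_probs))
    u_accept = rng.random(config.n_iter)
    u_pick = rng.random((config.n_iter, 2))

    state: tuple[ElementaryModel, ...] = ()
    key, score = scorer.score(state)
    visited = ScoredModelSet(n_loci_total=genotypes.shape[1])
    visited.record(*scorer._score_cache[key])
    cur_logpost = score.log_unnorm_posterior
    trace = np.empty(config.n_iter)

    n_pool = len(pool)
    for it in range(config.n_iter):
        op = ops[it]
        proposal = state
        if op == 0 or op == 2:  # ADD (possibly after REMOVE for SWITCH)
            if op == 2 and proposal:  # SWITCH: remove first
                drop = int(u_pick[it, 1] * len(proposal))
                proposal = proposal[:drop] + proposal[drop + 1 :]
            new = pool[int(u_pick[it, 0] * n_pool)]
            new_loci = set(new.loci)
            proposal = tuple(
                c for c in proposal if not new_loci.intersection(c.loci)
            ) + (new,)
        elif op == 1:  # REMOVE; self-loop on the null model
            if proposal:
                drop = int(u_pick[it, 0] * len(proposal))
                proposal = proposal[:drop] + proposal[drop + 1 :]
        pkey, pscore = scorer.score(proposal)
        visited.record(*scorer._score_cache[pkey])
        delta = pscore.log_unnorm_posterior - cur_logpost
        if delta >= 0 or u_accept[it] < np.exp(delta):
            state = proposal
            cur_logpost = pscore.log_unnorm_posterior
        trace[it] = cur_logpost
        if (it + 1) % TRACE_CADENCE == 0:
            logger.debug(
                "iter %d: log score %.4f, %d distinct models",
                it + 1,
                cur_logpost,
                len(visited),
            )
    return visited, trace


def snp_posteriors(visited: ScoredModelSet, n_loci: int | None = None) -> SnpPosterior:
    """Step 4: self-normalized per-SNP inclusion posteriors over the
    distinct visited models (log-sum-exp throughout)."""
    if not len(visited):
        raise ValueError("visited model set is empty")
    L = visited.n_loci_total if n_loci is None else n_loci
    logposts = np.array(
        [s.log_unnorm_posterior for _, s in visited.models.values()]
    )
    membership = np.zeros((len(logposts), L), dtype=bool)
    for row, (model, _) in enumerate(visited.models.values()):
        for j in model.loci:
            membership[row, j] = True
    total = logsumexp(logposts)
    prob = np.zeros(L)
    score = np.full(L, -np.inf)
    never = ~membership.any(axis=0)
    for j in range(L):
        if never[j]:
            continue
        log_in = logsumexp(logposts[membership[:, j]])
        out_mask = ~membership[:, j]
        if not out_mask.any():
            prob[j], score[j] = 1.0, np.inf
            continue
        log_out = logsumexp(logposts[out_mask])
        prob[j] = float(np.exp(log_in - total))
        score[j] = float(log_in - log_out)
    return SnpPosterior(prob, score, never)


def naive_bma(table, pool: list[ElementaryModel], prior: PriorSpec) -> SnpPosterior:
    """Model averaging over {M0} union the elementary pool only, with no
    search and no combined models (the naive comparator)."""
    if not pool:
        raise ValueError("elementary-model pool is empty")
    scorer = _Scorer(table.genotypes, table.phenotype, prior)
    visited = ScoredModelSet(n_loci_total=table.genotypes.shape[1])
    key, _ = scorer.score(())
    visited.record(*scorer._score_cache[key])
    for m in pool:
        key, _ = scorer.score((m,))
        visited.record(*scorer._score_cache[key])
    return snp_posteriors(visited)


def enumerate_conflict_free(pool: list[ElementaryModel]):
    """Yield every conflict-free component tuple over the pool (the full
    combined-model space; exponential, for small oracles only)."""

    def rec(i: int, used: frozenset, current: tuple):
        if i == len(pool):
            yield current
            return
        yield from rec(i + 1, used, current)
        m = pool[i]
        if not used.intersection(m.loci):
            yield from rec(i + 1, used.union(m.loci), current + (m,))

    yield from rec(0, frozenset(), ())
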