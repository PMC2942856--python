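import numpy as np
import pytest
from scipy.special import logsumexp

from bmagene.models import CombinedModel, ElementaryModel, enumerate_elementary
from bmagene.scoring import PriorSpec, score_model
from bmagene.search import (
    ScoredModelSet,
    SearchConfig,
    enumerate_conflict_free,
    naive_bma,
    run_search,
    select_top_k,
    snp_posteriors,
)
from bmagene.scoring import ModelScore
from conftest import random_table


def exact_posterior(table, pool, prior):
    """Oracle: exhaustive enumeration of all conflict-free combinations of
    the pool, deduplicated by canonical identity."""
    out = {}
    for comps in enumerate_conflict_free(pool):
        cm = CombinedModel(comps)
        key = cm.key()
        if key not in out:
            out[key] = (cm, score_model(cm, table.genotypes, table.phenotype, prior))
    return out


class TestTopKSelection:
    def test_saturation_returns_all_elementary(self, rng):
        t = random_table(rng, 50, 3)
        cfg = SearchConfig(K=10_000, n_iter=10, prior=PriorSpec(3.0, 1 / 3))
        pool = select_top_k(t, cfg)
        assert set(pool) == set(enumerate_elementary(3))

    def test_matches_brute_force_ranking(self, rng):
        t = random_table(rng, 80, 3)
        prior = PriorSpec(3.0, 1 / 3)
        cfg = SearchConfig(K=2, n_iter=10, prior=prior)
        pool = select_top_k(t, cfg)
        scored = sorted(
            enumerate_elementary(3),
            key=lambda m: -score_model(
                CombinedModel((m,)), t.genotypes, t.phenotype, prior
            ).log_unnorm_posterior,
        )
        expected = set(scored[:2]) | {
            m for m in enumerate_elementary(3) if len(m.loci) == 1
        }
        assert set(pool) == expected

    def test_deterministic_across_runs(self, rng):
        t = random_table(rng, 60, 4)
        cfg = SearchConfig(K=5, n_iter=10, prior=PriorSpec(3.0, 0.25))
        assert select_top_k(t, cfg) == select_top_k(t, cfg)


class TestRunSearch:
    def test_fixed_seed_reproducible(self, rng):
        t = random_table(rng, 60, 3)
        cfg = SearchConfig(K=100, n_iter=3000, seed=11, prior=PriorSpec(3.0, 1 / 3))
        pool = select_top_k(t, cfg)
        v1, tr1 = run_search(t, pool, cfg)
        v2, tr2 = run_search(t, pool, cfg)
        assert set(v1.models) == set(v2.models)
        np.testing.assert_array_equal(tr1, tr2)

    def test_no_state_with_overlapping_loci(self, rng):
        # CombinedModel construction rejects overlaps, so every recorded
        # model being constructible is itself the audit
        t = random_table(rng, 60, 4)
        cfg = SearchConfig(K=50, n_iter=5000, seed=2, prior=PriorSpec(3.0, 0.25))
        visited, _ = run_search(t, select_top_k(t, cfg), cfg)
        for model, _score in visited.models.values():
            loci = [j for c in model.components for j in c.loci]
            assert len(loci) == len(set(loci))

    def test_cached_scores_match_fresh_recomputation(self, rng):
        t = random_table(rng, 60, 3)
        prior = PriorSpec(3.0, 1 / 3)
        cfg = SearchConfig(K=100, n_iter=2000, seed=5, prior=prior)
        visited, _ = run_search(t, select_top_k(t, cfg), cfg)
        for model, score in visited.models.values():
            fresh = score_model(model, t.genotypes, t.phenotype, prior)
            assert score.log_unnorm_posterior == pytest.approx(
                fresh.log_unnorm_posterior, rel=1e-12
            )

    def test_chain_converges_to_exact_enumeration(self, rng):
        """On a 3-locus table the renormalized posterior over visited models
        approaches exhaustive enumeration (total-variation < 0.01)."""
        t = random_table(rng, 100, 3)
        prior = PriorSpec(3.0, 1 / 3)
        cfg = SearchConfig(K=10_000, n_iter=50_000, seed=3, prior=prior)
        pool = select_top_k(t, cfg)
        visited, _ = run_search(t, pool, cfg)
        exact = exact_posterior(t, pool, prior)
        keys = sorted(exact)
        ex = np.array([exact[k][1].log_unnorm_posterior for k in keys])
        ex = np.exp(ex - logsumexp(ex))
        est = np.full(len(keys), -np.inf)
        for i, k in enumerate(keys):
            if k in visited.models:
                est[i] = visited.models[k][1].log_unnorm_posterior
        est = np.exp(est - logsumexp(est))
        assert 0.5 * np.abs(ex - est).sum() < 0.01


class TestSnpPosteriors:
    def _fabricate(self, entries, L):
        s = ScoredModelSet(n_loci_total=L)
        for comps, logpost in entries:
            cm = CombinedModel(comps)
            s.record(cm, ModelScore(log_marginal_likelihood=logpost, log_prior=0.0))
        return s

    def test_null_only_gives_zero_probabilities(self):
        s = self._fabricate([((), -3.0)], L=2)
        post = snp_posteriors(s)
        np.testing.assert_array_equal(post.inclusion_probability, [0.0, 0.0])
        assert post.never_visited.all()
        assert np.isneginf(post.score).all()

    def test_equal_scores_give_even_odds(self):
        s = self._fabricate(
            [((), -5.0), ((ElementaryModel("M2", (0,)),), -5.0)], L=2
        )
        post = snp_posteriors(s)
        assert post.inclusion_probability[0] == pytest.approx(0.5)
        assert post.score[0] == pytest.approx(0.0, abs=1e-12)
        assert post.never_visited[1]

    def test_matches_high_precision_linear_sum(self, rng):
        import math

        entries = []
        kinds = [("M2", (0,)), ("M1", (1,)), ("M5", (0, 1)), ("M2", (2,))]
        entries.append(((), float(rng.normal(-100, 5))))
        for kind, loci in kinds:
            entries.append(
                ((ElementaryModel(kind, loci),), float(rng.normal(-100, 5)))
            )
        s = self._fabricate(entries, L=3)
        post = snp_posteriors(s)
        shift = max(lp for _, lp in entries)
        weights = [(CombinedModel(c).loci, math.exp(lp - shift)) for c, lp in entries]
        total = math.fsum(w for _, w in weights)
        for j in range(3):
            inc = math.fsum(w for loci, w in weights if j in loci)
            assert post.inclusion_probability[j] == pytest.approx(inc / total, rel=1e-12)

    def test_ranking_puts_never_visited_last(self):
        s = self._fabricate(
            [((), -2.0), ((ElementaryModel("M2", (1,)),), -1.0)], L=3
        )
        post = snp_posteriors(s)
        order = post.ranking()
        assert order[0] == 1 and list(order[1:]) == [0, 2]


class TestNaiveBma:
    def test_matches_direct_enumeration(self, rng):
        t = random_table(rng, 80, 3)
        prior = PriorSpec(3.0, 1 / 3)
        pool = enumerate_elementary(3)
        post = naive_bma(t, pool, prior)
        # oracle: {M0} + each elementary model standalone, canonically deduped
        scored = {}
        for m in [()] + [(m,) for m in pool]:
            cm = CombinedModel(m)
            scored.setdefault(
                cm.key(),
                (cm, score_model(cm, t.genotypes, t.phenotype, prior)),
            )
        logposts = np.array(
            [s.log_unnorm_posterior for _, s in scored.values()]
        )
        total = logsumexp(logposts)
        for j in range(3):
            inc = [
                s.log_unnorm_posterior
                for cm, s in scored.values()
                if j in cm.loci
            ]
            expected = np.exp(logsumexp(inc) - total)
            assert post.inclusion_probability[j] == pytest.approx(expected, rel=1e-10)

    def test_zero_weight_model_changes_nothing(self, rng):
        t = random_table(rng, 50, 3)
        prior = PriorSpec(3.0, 1 / 3)
        pool = [ElementaryModel("M2", (0,)), ElementaryModel("M2", (1,))]
        base = naive_bma(t, pool, prior)
        s = ScoredModelSet(n_loci_total=3)
        # fabricate the same set plus a -inf-score model at locus 2
        from bmagene.search import _Scorer

        scorer = _Scorer(t.genotypes, t.phenotype, prior)
        for comps in [(), (pool[0],), (pool[1],)]:
            key, _ = scorer.score(tuple(comps))
            s.record(*scorer._score_cache[key])
        s.record(
            CombinedModel((ElementaryModel("M2", (2,)),)),
            ModelScore(log_marginal_likelihood=-np.inf, log_prior=0.0),
        )
        post = snp_posteriors(s)
        np.testing.assert_allclose(
            post.inclusion_probability[:2], base.inclusion_probability[:2], rtol=1e-12
        )


class TestAcceptanceRule:
    def test_equal_score_proposals_always_accepted(self, rng):
        """With a constant phenotype every model scores identically, so the
        score ratio is 1 and the chain must accept every proposal; all
        reachable canonical states get visited quickly."""
        from bmagene.io import GenotypeTable

        g = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        t = GenotypeTable(g, phenotype=np.zeros(30, dtype=np.int8))
        prior = PriorSpec(3.0, 0.999999)  # essentially flat structure prior
        cfg = SearchConfig(K=100, n_iter=4000, seed=9, prior=prior)
        pool = select_top_k(t, cfg)
        visited, trace = run_search(t, pool, cfg)
        exact = exact_posterior(t, pool, prior)
        assert set(visited.models) == set(exact)
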