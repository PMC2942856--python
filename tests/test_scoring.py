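import numpy as np
import pytest
from scipy import integrate, stats

from bmagene.models import CombinedModel, ElementaryModel, Partition
from bmagene.scoring import (
    PriorSpec,
    class_counts,
    gxg_bayes_factor_score,
    gxg_bayes_factor_scores_all,
    log_marginal_likelihood,
    log_prior,
    null_log_marginal_likelihood,
    pairwise_log_ml,
    score_model,
    single_locus_log_ml,
)
from conftest import random_table


def quadrature_log_ml(counts, alpha):
    """Independent oracle: per-class numeric integration of the
    beta-binomial integrand integral p^n1 (1-p)^n0 beta(p; a, a) dp.

    The substitution p = sin^2(theta) removes the endpoint singularities of
    the beta density for alpha < 1, so plain adaptive quadrature converges
    to full precision for every alpha used here.
    """
    total = 0.0
    for n0, n1 in np.asarray(counts).reshape(-1, 2):
        if n0 + n1 == 0:
            continue

        def integrand(theta, n1=n1, n0=n0):
            p = np.sin(theta) ** 2
            jac = 2.0 * np.sin(theta) * np.cos(theta)
            return p ** n1 * (1 - p) ** n0 * stats.beta.pdf(p, alpha, alpha) * jac

        val, _ = integrate.quad(integrand, 0.0, np.pi / 2, epsabs=0, epsrel=1e-13, limit=200)
        total += np.log(val)
    return total


class TestClassCounts:
    def test_single_class_tally(self):
        part = Partition(np.zeros(5, dtype=int), 1)
        counts = class_counts(part, np.array([1, 1, 1, 0, 0]))
        np.testing.assert_array_equal(counts, [[2, 3]])

    def test_empty_class_has_zero_counts(self):
        part = Partition(np.zeros(4, dtype=int), 2)
        counts = class_counts(part, np.array([1, 0, 1, 0]))
        np.testing.assert_array_equal(counts, [[2, 2], [0, 0]])

    def test_matches_brute_force(self, rng):
        labels = rng.integers(0, 5, 200)
        y = rng.integers(0, 2, 200)
        counts = class_counts(Partition(labels, 5), y)
        for c in range(5):
            for b in (0, 1):
                assert counts[c, b] == np.sum((labels == c) & (y == b))


class TestLogMarginalLikelihood:
    def test_uniform_prior_single_case_control(self):
        # alpha = 1: integral p(1-p) dp = B(2,2) = 1/6
        assert log_marginal_likelihood(np.array([[1, 1]]), 1.0) == pytest.approx(
            np.log(1 / 6), abs=1e-12
        )

    def test_empty_data_gives_zero(self):
        assert log_marginal_likelihood(np.zeros((3, 2)), 3.0) == 0.0

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 3.0])
    def test_agrees_with_quadrature(self, rng, alpha):
        for _ in range(20):
            counts = rng.integers(0, 25, size=(rng.integers(1, 5), 2))
            ours = log_marginal_likelihood(counts, alpha)
            assert ours == pytest.approx(quadrature_log_ml(counts, alpha), rel=1e-10)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            log_marginal_likelihood(np.array([[1, 1]]), 0.0)

    def test_invariant_to_relabeling_and_empty_classes(self, rng):
        counts = rng.integers(0, 30, size=(4, 2))
        base = log_marginal_likelihood(counts, 3.0)
        shuffled = counts[rng.permutation(4)]
        padded = np.vstack([counts, np.zeros((3, 2), dtype=int)])
        assert log_marginal_likelihood(shuffled, 3.0) == pytest.approx(base, abs=1e-12)
        assert log_marginal_likelihood(padded, 3.0) == pytest.approx(base, abs=1e-12)

    def test_sequential_chain_rule(self, rng):
        """The marginal likelihood equals the product of beta-binomial
        posterior-predictive terms accumulated one individual at a time."""
        alpha = 3.0
        labels = rng.integers(0, 3, 50)
        y = rng.integers(0, 2, 50)
        counts = class_counts(Partition(labels, 3), y)
        seen = np.zeros((3, 2))
        log_seq = 0.0
        for c, b in zip(labels, y):
            a_post = alpha + seen[c, 1]
            b_post = alpha + seen[c, 0]
            p1 = a_post / (a_post + b_post)
            log_seq += np.log(p1 if b == 1 else 1 - p1)
            seen[c, b] += 1
        assert log_marginal_likelihood(counts, alpha) == pytest.approx(log_seq, rel=1e-12)


class TestStructurePrior:
    def test_null_model_has_zero_log_prior(self):
        assert log_prior(CombinedModel(()), 0.5) == 0.0

    def test_one_extra_snp_costs_log_xi(self):
        xi = 1 / 460
        m1 = CombinedModel((ElementaryModel("M2", (0,)),))
        m2 = CombinedModel((ElementaryModel("M2", (0,)), ElementaryModel("M2", (1,))))
        assert log_prior(m2, xi) - log_prior(m1, xi) == pytest.approx(np.log(xi))

    def test_three_locus_model(self):
        cm = CombinedModel((ElementaryModel("M2", (0,)), ElementaryModel("M5", (1, 2))))
        assert log_prior(cm, 1 / 460) == pytest.approx(3 * np.log(1 / 460))

    @pytest.mark.parametrize("xi", [0.0, 1.0, -2.0])
    def test_invalid_xi_rejected(self, xi):
        with pytest.raises(ValueError):
            log_prior(1, xi)


class TestModelScore:
    def test_posterior_is_exact_sum(self, small_table):
        prior = PriorSpec(alpha=3.0, xi=0.1)
        cm = CombinedModel((ElementaryModel("M1", (0,)),))
        s = score_model(cm, small_table.genotypes, small_table.phenotype, prior)
        assert s.log_unnorm_posterior == s.log_marginal_likelihood + s.log_prior


class TestVectorizedScorers:
    def test_single_locus_batch_matches_scalar(self, rng):
        t = random_table(rng, 80, 5)
        m1, m2 = single_locus_log_ml(t.genotypes, t.phenotype, 3.0)
        for j in range(5):
            for kind, arr in (("M1", m1), ("M2", m2)):
                cm = CombinedModel((ElementaryModel(kind, (j,)),))
                ref = score_model(cm, t.genotypes, t.phenotype, PriorSpec(3.0, 0.5))
                assert arr[j] == pytest.approx(ref.log_marginal_likelihood, rel=1e-12)

    def test_pairwise_batch_matches_scalar(self, rng):
        t = random_table(rng, 80, 5)
        ml = pairwise_log_ml(t.genotypes, t.phenotype, 3.0)
        for j in range(5):
            for k in range(5):
                if j == k:
                    assert np.isneginf(ml["M3"][j, k])
                    continue
                for kind in ("M3", "M4", "M5"):
                    cm = CombinedModel((ElementaryModel(kind, (j, k)),))
                    ref = score_model(cm, t.genotypes, t.phenotype, PriorSpec(3.0, 0.5))
                    assert ml[kind][j, k] == pytest.approx(
                        ref.log_marginal_likelihood, rel=1e-12
                    )


class TestGxgBayesFactor:
    def test_monomorphic_table_scores_zero(self):
        g = np.zeros((30, 3), dtype=np.int8)
        from bmagene.io import GenotypeTable

        t = GenotypeTable(g, phenotype=np.tile([0, 1], 15))
        for j in range(3):
            assert gxg_bayes_factor_score(t, j) == pytest.approx(0.0, abs=1e-10)

    def test_matches_exhaustive_enumeration(self, rng):
        t = random_table(rng, 60, 4)
        alpha = 3.0
        log_ml0 = null_log_marginal_likelihood(t.phenotype, alpha)
        scores, partners = gxg_bayes_factor_scores_all(t, alpha=alpha)
        for j in range(4):
            best, best_k = -np.inf, None
            for k in range(4):
                if k == j:
                    continue
                terms = [
                    score_model(
                        CombinedModel((ElementaryModel(kind, (j, k)),)),
                        t.genotypes,
                        t.phenotype,
                        PriorSpec(alpha, 0.5),
                    ).log_marginal_likelihood
                    for kind in ("M3", "M4", "M5")
                ]
                mix = np.logaddexp.reduce(terms) - np.log(3.0)
                if mix > best:
                    best, best_k = mix, k
            assert scores[j] == pytest.approx(best - log_ml0, rel=1e-10)
            assert partners[j] == best_k

    def test_max_variant_upper_bounds_mean(self, rng):
        t = random_table(rng, 100, 5)
        mean_s, _ = gxg_bayes_factor_scores_all(t, alpha=3.0, combine="mean")
        max_s, _ = gxg_bayes_factor_scores_all(t, alpha=3.0, combine="max")
        assert (max_s >= mean_s - 1e-12).all()

    def test_strong_pure_interaction_finds_its_partner(self):
        """A planted both-carrier interaction at (0, 1) should make locus 1
        the preferred partner of locus 0 at large N."""
        rng = np.random.default_rng(5)
        n = 2000
        g = rng.binomial(2, 0.3, size=(n, 4)).astype(np.int8)
        risk = np.where((g[:, 0] > 0) & (g[:, 1] > 0), 0.7, 0.3)
        y = (rng.random(n) < risk).astype(np.int8)
        from bmagene.io import GenotypeTable

        t = GenotypeTable(g, phenotype=y)
        _, partners = gxg_bayes_factor_scores_all(t, alpha=3.0)
        assert partners[0] == 1 and partners[1] == 0
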