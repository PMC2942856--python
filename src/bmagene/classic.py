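"""Frequentist comparator scores: marginal and pairwise-interaction
likelihood-ratio tests for logistic models.

Both tested models are saturated on a small genotype-defined partition (the
3 genotype classes for the marginal test; the 2x2 dominant-coded cells with
an interaction term for the pairwise test), so the maximized log-likelihood
has the closed form sum_c [n_c1 log(n_c1/n_c) + n_c0 log(n_c0/n_c)] with the
0*log 0 = 0 convention, and no iterative fit is needed.  Degrees of freedom
are fixed at 2 (marginal) and 3 (pairwise) regardless of empty cells,
reproducing the standard asymptotic comparator as commonly run.  Scores are
-log10 of the chi-square upper-tail p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import xlogy

__all__ = [
    "LrtResult",
    "marginal_lrt",
    "marginal_lrt_scores_all",
    "gxg_lrt_score",
    "gxg_lrt_scores_all",
]


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p_value: float
    score: float  # -log10(p)
    best_partner: int | None = None


def _saturated_loglik(n1, n0):
    """Maximized Bernoulli log-likelihood of a saturated partition model;
    vectorized over leading axes of per-class case/control counts."""
    tot = n1 + n0
    with np.errstate(divide="ignore", invalid="ignore"):
        return xlogy(n1, n1 / np.where(tot > 0, tot, 1)) + xlogy(
            n0, n0 / np.where(tot > 0, tot, 1)
        )


def _lrt_from_counts(n1, n0, null_ll, class_axis):
    ll = _saturated_loglik(n1, n0).sum(axis=class_axis)
    lam = 2.0 * (ll - null_ll)
    return np.maximum(lam, 0.0)  # guard tiny negative round-off


def _null_loglik(phenotype) -> float:
    y = np.asarray(phenotype)
    n1 = float(y.sum())
    return float(_saturated_loglik(np.array(n1), np.array(y.size - n1)))


def _chi2_result(lam: float, df: int, partner=None) -> LrtResult:
    p = float(stats.chi2.sf(lam, df))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return LrtResult(float(lam), df, p, float(-np.log10(p)), partner)


def marginal_lrt_scores_all(table) -> np.ndarray:
    """Marginal LRT statistic Lambda_j for every locus (df = 2)."""
    z, y = table.genotypes, np.asarray(table.phenotype).astype(bool)
    counts = np.empty((2, 3, z.shape[1]))
    for b, rows in enumerate((~y, y)):
        sub = z[rows]
        for a in (0, 1, 2):
            counts[b, a] = (sub == a).sum(axis=0)
    return _lrt_from_counts(counts[1], counts[0], _null_loglik(y), class_axis=0)


def marginal_lrt(table, j: int) -> LrtResult:
    """LRT of the full three-parameter single-locus logistic model against
    the null; the 3-parameter model is saturated on the genotype classes."""
    lam = marginal_lrt_scores_all(table)[j]
    return _chi2_result(lam, df=2)


def _pairwise_lrt_matrix(table, rows=None) -> np.ndarray:
    """Lambda_jk for the dominant-coded 2x2 interaction logistic model
    (saturated on the four cells), rows j x all k; diagonal set to 0."""
    z, y = table.genotypes, np.asarray(table.phenotype).astype(bool)
    L = z.shape[1]
    rows = np.arange(L) if rows is None else np.asarray(rows)
    null_ll = _null_loglik(y)
    cells = np.empty((2, 2, 2, rows.size, L))
    for b, sel in enumerate((~y, y)):
        d = (z[sel] > 0).astype(np.float32)
        nd = 1.0 - d
        cells[b, 0, 0] = nd[:, rows].T @ nd
        cells[b, 0, 1] = nd[:, rows].T @ d
        cells[b, 1, 0] = d[:, rows].T @ nd
        cells[b, 1, 1] = d[:, rows].T @ d
    lam = _lrt_from_counts(cells[1], cells[0], null_ll, class_axis=(0, 1))
    lam[rows[:, None] == np.arange(L)[None, :]] = 0.0
    return lam


def gxg_lrt_scores_all(table, chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-interaction LRT score for every locus: the best partner's
    -log10 p with df = 3.  Returns (statistics, best_partner)."""
    L = table.genotypes.shape[1]
    if L < 2:
        raise ValueError("need at least two loci")
    stat = np.empty(L)
    partner = np.empty(L, dtype=np.int64)
    for start in range(0, L, chunk):
        rows = np.arange(start, min(start + chunk, L))
        lam = _pairwise_lrt_matrix(table, rows=rows)
        lam[rows - start, rows] = -np.inf  # exclude self from the argmax
        partner[rows] = np.argmax(lam, axis=1)
        stat[rows] = lam[np.arange(rows.size), partner[rows]]
    return stat, partner


def gxg_lrt_score(table, j: int) -> LrtResult:
    """Maximum over partners k of the 4-parameter interaction LRT at (j, k),
    with the arg-max partner reported."""
    stats_, partners = gxg_lrt_scores_all(table)
    return _chi2_result(stats_[j], df=3, partner=int(partners[j]))
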