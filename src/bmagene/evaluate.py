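"""Evaluation of per-SNP scores against the simulated ground truth.

Detection is per disease-associated *area*, not per SNP: walking down the
ranked SNP list, an area counts as detected at the first of its SNPs
encountered, and every SNP outside all areas is a false positive.  The
detection curve records the false-positive count at the first attainment of
each number of detected areas; curves are summarized across replicates by
the mean and the 2.5th/97.5th percentiles, and reduced to a normalized AUC
(axes scaled to unity, left-continuous step integration).

Location accuracy is the marker distance from the top-ranked SNP to the
hidden causal position of its area (the causal SNP sits in the gap between
within-area positions 20 and 21, so distances run 1..20), with the sentinel
20 when the top SNP lies outside every area.  For triplet-model data the
area of the main-effect locus Z_j4 is excluded from the arg-max, since that
locus is trivially easiest to find.

Method comparisons count per-replicate wins/losses (ties dropped) and
classify each grid cell by a two-sided binomial test at level 0.05, with
|wins - losses| < 5 declared a practical tie ("white").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DetectionCurve",
    "detection_curve",
    "mean_and_percentile_curves",
    "auc",
    "location_accuracy",
    "compare_methods",
    "WinLoss",
    "setting_summary",
]


@dataclass
class DetectionCurve:
    """``false_positives[k]`` = false positives accumulated when the k-th
    distinct area was first detected (k = 0..n_areas); plus the full ranked
    locus list."""

    false_positives: np.ndarray
    n_areas: int
    ranking: np.ndarray


def rank_loci(scores: np.ndarray) -> np.ndarray:
    """Descending-score ranking; ties (including -inf) broken by ascending
    locus index so reports are deterministic."""
    scores = np.asarray(scores, dtype=float)
    return np.lexsort((np.arange(scores.size), -scores))


def _area_of(n_loci: int, areas) -> np.ndarray:
    owner = np.full(n_loci, -1, dtype=np.int64)
    for a, (lo, hi) in enumerate(areas):
        owner[lo : hi + 1] = a
    return owner


def detection_curve(scores, areas) -> DetectionCurve:
    """Walk the ranked SNP list and record the false-positive count at each
    first attainment of k detected areas."""
    scores = np.asarray(scores, dtype=float)
    owner = _area_of(scores.size, areas)
    order = rank_loci(scores)
    n_areas = len(areas)
    fps = np.zeros(n_areas + 1, dtype=np.int64)
    seen: set[int] = set()
    fp = 0
    for j in order:
        a = owner[j]
        if a < 0:
            fp += 1
        elif a not in seen:
            seen.add(a)
            fps[len(seen)] = fp
        if len(seen) == n_areas:
            break
    return DetectionCurve(fps, n_areas, order)


def mean_and_percentile_curves(curves: list[DetectionCurve]) -> dict[str, np.ndarray]:
    """Mean and 2.5th/97.5th percentile (linear-interpolation convention)
    false-positive counts per number of detected areas, across replicates."""
    if not curves:
        raise ValueError("need at least one curve")
    fp = np.stack([c.false_positives for c in curves]).astype(float)
    return {
        "mean": fp.mean(axis=0),
        "p2.5": np.percentile(fp, 2.5, axis=0),
        "p97.5": np.percentile(fp, 97.5, axis=0),
    }


def auc(curve: DetectionCurve, n_outside: int, n_areas: int | None = None) -> float:
    """Area under the detection curve with both axes normalized to unity.

    x = false positives / n_outside, y = detected areas / n_areas; the
    curve is integrated as the left-continuous step function through its
    points and extended at the attained y to x = 1.
    """
    n_areas = curve.n_areas if n_areas is None else n_areas
    x = curve.false_positives / float(n_outside)
    area = 0.0
    for k in range(n_areas):
        area += (x[k + 1] - x[k]) * (k / n_areas)
    area += (1.0 - x[n_areas]) * 1.0
    return float(area)


def location_accuracy(scores, dataset, triplet_mode: bool = False) -> int:
    """Marker distance from the top-ranked SNP to the nearest causal gap.

    Within an area the gap sits after ``dataset.gap_offset`` retained SNPs
    (position p in 1..40 gives distance 21-p for p <= 20, p-20 otherwise);
    a top SNP outside every area scores the sentinel ``gap_offset`` (= 20).
    ``triplet_mode`` removes the last area (the main-effect locus Z_j4's)
    from consideration before taking the arg-max.
    """
    scores = np.asarray(scores, dtype=float)
    areas = list(dataset.causal_areas)
    g = dataset.gap_offset
    excluded: tuple[int, int] | None = None
    if triplet_mode:
        excluded = areas.pop()  # area of Z_j4, by construction the last
    eligible = np.ones(scores.size, dtype=bool)
    if excluded is not None:
        eligible[excluded[0] : excluded[1] + 1] = False
    order = rank_loci(scores)
    top = order[eligible[order]][0]
    for lo, hi in areas:
        if lo <= top <= hi:
            p = top - lo + 1  # 1-based within-area position
            return g + 1 - p if p <= g else p - g
    return g


@dataclass(frozen=True)
class WinLoss:
    wins: int
    losses: int
    p_value: float
    category: str  # red / light-red / white / light-blue / blue


def compare_methods(
    metric_a, metric_b, criterion: str = "auc"
) -> WinLoss:
    """Paired win/loss comparison of method A against method B.

    ``criterion='auc'`` counts a win when A's value is higher;
    ``criterion='location'`` when it is lower (distances: smaller is
    better).  Exact ties are dropped.  The cell is 'white' when
    |wins - losses| < 5; otherwise colored for the winning side, dark when
    the two-sided binomial test (p = 0.5) rejects at 0.05.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metrics must have equal length")
    diff = a - b if criterion == "auc" else b - a
    wins = int((diff > 0).sum())
    losses = int((diff < 0).sum())
    n = wins + losses
    p = float(stats.binomtest(wins, n, 0.5).pvalue) if n else 1.0
    if abs(wins - losses) < 5:
        cat = "white"
    else:
        side = "red" if wins > losses else "blue"
        cat = side if p < 0.05 else f"light-{side}"
    return WinLoss(wins, losses, p, cat)


def setting_summary(replicates: list[tuple[np.ndarray, "object"]]) -> dict:
    """Summary row for one (model, GRR, MAF) cell.

    ``replicates`` pairs a per-SNP score vector with its ReplicateDataset.
    Reports the across-replicate (min, max) of the per-replicate maximum
    score among disease-area SNPs, and the proportion of replicates whose
    overall top-ranked SNP lies inside a disease area.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    max_scores, hits = [], []
    for scores, ds in replicates:
        scores = np.asarray(scores, dtype=float)
        mask = ds.area_mask()
        max_scores.append(scores[mask].max())
        hits.append(bool(mask[rank_loci(scores)[0]]))
    return {
        "max_score_range": (float(min(max_scores)), float(max(max_scores))),
        "accuracy": float(np.mean(hits)),
        "n_replicates": len(replicates),
    }
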