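"""Synthetic case-control simulation with hidden causal SNPs.

The protocol emulates simulation on a real genotype panel (which is not
publicly available) with a synthetic block-structured pool:

1. A pool of ``n_pool`` individuals is synthesized as pairs of haplotypes
   from a first-order Markov allele-copying process.  SNPs come in
   independent blocks; within a block the adjacent-haplotype allele
   correlation is drawn per pair from a configurable distribution (default
   uniform on [0.2, 0.95]), so linkage decays with marker distance and
   vanishes across blocks.  Each causal-capable block carries a center SNP
   at the target causal minor-allele frequency; flanking SNP frequencies are
   drawn from a broad range above the ascertainment floor.
2. Four causal SNPs whose empirical MAF matches the target within +-1% are
   drawn from distinct blocks; each is surrounded by the 20 closest flanking
   SNPs with MAF > 0.1 per side, and then deleted from the emitted data, so
   the causal variant sits in the gap between the 20th and 21st retained
   SNPs of its 40-SNP disease-associated area.
3. Null intervals of 100 SNPs are cut from unused blocks and concatenated
   between the causal areas (area, null, area, null, area, null, area;
   460 SNPs at replicate scale).
4. Disease statuses are drawn from one of three generative penetrance
   models (multiplicative, threshold, triplet), with the baseline risk
   calibrated by bisection so the pool prevalence hits the target (default
   40%, about 850 cases of 2131); probabilities are capped at 1 and the
   calibration is cap-aware.
5. All cases and an equal number of uniformly drawn controls form the
   replicate data set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "ReplicateDataset",
    "SimulationError",
    "synthesize_pool",
    "build_replicate",
    "disease_probability",
    "calibrate_beta0",
    "simulate_replicate",
]


class SimulationError(RuntimeError):
    """Raised when a replicate cannot be built from the given pool."""


@dataclass
class SimConfig:
    """Parameters of one simulation setting.

    ``grr`` is the genotype relative risk (multiplicative factor on disease
    probability per active indicator), ``maf`` the target causal
    minor-allele frequency, and ``prevalence`` the target mean disease
    probability over the pool.  Study-grid values: GRR in {1.3, 1.6, 2.0},
    MAF in {0.05, 0.1, 0.2}, prevalence 0.40, pool 2131 individuals, 20
    flanking SNPs (MAF > 0.1) per side of each of 4 causal SNPs, 3 null
    intervals of 100 SNPs.
    """

    generative_model: str = "threshold"
    grr: float = 1.6
    maf: float = 0.2
    prevalence: float = 0.40
    n_pool: int = 2131
    flank: int = 20
    null_interval_len: int = 100
    n_null_intervals: int = 3
    maf_floor_flank: float = 0.1
    seed: int = 0
    scale: str = "replicate"
    # synthetic-pool knobs
    n_blocks: int = 10
    block_len: int = 131
    ld_corr_range: tuple[float, float] = (0.2, 0.95)
    flank_maf_range: tuple[float, float] = (0.15, 0.45)
    chromosome_len: int = 8700

    def __post_init__(self):
        if self.generative_model not in ("multiplicative", "threshold", "triplet"):
            raise ValueError(f"unknown generative model {self.generative_model!r}")
        if self.grr < 1:
            raise ValueError("grr must be >= 1")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.scale not in ("replicate", "chromosome"):
            raise ValueError("scale must be 'replicate' or 'chromosome'")

    @property
    def area_len(self) -> int:
        return 2 * self.flank

    @property
    def n_areas(self) -> int:
        return 4


@dataclass
class ReplicateDataset:
    """One simulated case-control data set with its ground truth.

    ``causal_areas`` are (start, end) inclusive 0-based column intervals of
    the emitted table; the hidden causal SNP of each area sits in the gap
    after ``gap_offset`` retained SNPs from the area start (between the
    20th and 21st).
    """

    table: GenotypeTable
    causal_areas: list[tuple[int, int]]
    gap_offset: int
    truth: dict = field(default_factory=dict)

    @property
    def n_outside(self) -> int:
        in_areas = sum(b - a + 1 for a, b in self.causal_areas)
        return self.table.n_loci - in_areas

    def area_mask(self) -> np.ndarray:
        mask = np.zeros(self.table.n_loci, dtype=bool)
        for a, b in self.causal_areas:
            mask[a : b + 1] = True
        return mask


def _max_feasible_corr(p: float, q: float) -> float:
    """Largest correlation a binary Markov step can realize while keeping
    both marginals exact: conditional probabilities must stay in [0, 1],
    bounding r by sqrt(min(p(1-q)/(q(1-p)), q(1-p)/(p(1-q))))."""
    ratio = (p * (1 - q)) / (q * (1 - p))
    return float(np.sqrt(min(ratio, 1.0 / ratio)))


def _markov_haplotypes(rng, n_hap: int, mafs: np.ndarray, corrs: np.ndarray):
    """First-order Markov binary haplotypes with given per-SNP allele
    frequencies and per-adjacent-pair correlations.

    corrs[s] couples SNP s-1 and s; each requested correlation is truncated
    to the feasible maximum for the adjacent frequency pair so that the
    conditional probabilities stay in [0, 1] and every marginal frequency is
    preserved exactly (clipping conditionals instead would bias low-MAF
    SNPs upward)."""
    n_snp = mafs.size
    H = np.empty((n_hap, n_snp), dtype=np.int8)
    u = rng.random((n_hap, n_snp))
    H[:, 0] = u[:, 0] < mafs[0]
    for s in range(1, n_snp):
        p, q = mafs[s], mafs[s - 1]
        r = min(corrs[s], _max_feasible_corr(p, q))
        slope = r * np.sqrt(p * (1 - p) / (q * (1 - q)))
        cond = p + slope * (H[:, s - 1] - q)
        H[:, s] = u[:, s] < cond
    return H


def synthesize_pool(config: SimConfig, rng=None) -> GenotypeTable:
    """Synthesize the genotype pool (no phenotype yet).

    Replicate scale: ``n_blocks`` independent blocks of ``block_len`` SNPs,
    each with its center SNP at the target causal MAF.  Chromosome scale
    additionally appends one long null "chromosome" of ``chromosome_len``
    minus the causal-area SNPs.  Genotypes are the sum of two independent
    haplotypes (Hardy-Weinberg).  Deterministic given the generator state.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.ld_corr_range
    flo, fhi = config.flank_maf_range
    mafs_parts, corrs_parts, ids = [], [], []
    for b in range(config.n_blocks):
        m = rng.uniform(flo, fhi, size=config.block_len)
        m[config.block_len // 2] = config.maf
        r = rng.uniform(lo, hi, size=config.block_len)
        r[0] = 0.0  # blocks are independent
        mafs_parts.append(m)
        corrs_parts.append(r)
        ids += [f"b{b:02d}_s{s:03d}" for s in range(config.block_len)]
    if config.scale == "chromosome":
        n_chrom = config.chromosome_len - config.n_areas * config.area_len
        m = rng.uniform(flo, fhi, size=n_chrom)
        r = rng.uniform(lo, hi, size=n_chrom)
        r[0] = 0.0
        mafs_parts.append(m)
        corrs_parts.append(r)
        ids += [f"chr_s{s:05d}" for s in range(n_chrom)]
    mafs = np.concatenate(mafs_parts)
    corrs = np.concatenate(corrs_parts)
    h1 = _markov_haplotypes(rng, config.n_pool, mafs, corrs)
    h2 = _markov_haplotypes(rng, config.n_pool, mafs, corrs)
    return GenotypeTable(genotypes=h1 + h2, locus_ids=ids)


def disease_probability(genotypes_at_causal, config: SimConfig, beta0: float):
    """Per-individual disease probability given the four causal genotypes.

    multiplicative: beta0 * GRR^(number of carrier loci);
    threshold:      beta0 * GRR^I(both of pair 1 carry) * GRR^I(both of pair 2 carry);
    triplet:        beta0 * GRR^(I(Z1>0 and Z2=0) * Z3) * GRR^(I(Z4>0)/2).
    Values are capped at 1.
    """
    if not beta0 > 0:
        raise ValueError("beta0 must be positive")
    g = np.atleast_2d(np.asarray(genotypes_at_causal))
    return np.minimum(1.0, beta0 * _risk_multiplier(g, config))


def _risk_multiplier(g: np.ndarray, config: SimConfig) -> np.ndarray:
    carrier = g > 0
    if config.generative_model == "multiplicative":
        expo = carrier.sum(axis=1)
    elif config.generative_model == "threshold":
        expo = (carrier[:, 0] & carrier[:, 1]).astype(float) + (
            carrier[:, 2] & carrier[:, 3]
        )
    else:  # triplet
        expo = (carrier[:, 0] & (g[:, 1] == 0)) * g[:, 2] + carrier[:, 3] / 2.0
    return config.grr ** expo


def calibrate_beta0(genotypes_at_causal, config: SimConfig) -> float:
    """Baseline risk such that the capped mean disease probability over the
    pool equals the target prevalence (monotone bisection; reduces to
    prevalence / mean multiplier when no individual is capped)."""
    g = np.atleast_2d(np.asarray(genotypes_at_causal))
    f = _risk_multiplier(g, config)

    def mean_pi(b):
        return float(np.minimum(1.0, b * f).mean())

    b = config.prevalence / float(f.mean())
    if np.all(b * f <= 1.0):
        return b
    lo_b, hi_b = 0.0, max(b, 1.0)
    while mean_pi(hi_b) < config.prevalence:
        hi_b *= 2.0
        if hi_b > 1e12:
            raise SimulationError("target prevalence unattainable")
    for _ in range(200):
        mid = 0.5 * (lo_b + hi_b)
        if mean_pi(mid) < config.prevalence:
            lo_b = mid
        else:
            hi_b = mid
    logger.info("cap-aware calibration active: beta0=%.6g", hi_b)
    return hi_b


def _block_of(locus_ids) -> np.ndarray:
    return np.array([lid.split("_")[0] for lid in locus_ids])


def _pick_area(pool_maf, block_idx, causal, flank, floor):
    """The ``flank`` closest eligible flanking SNPs per side of ``causal``
    within its block, or None if the block cannot supply them."""
    eligible = pool_maf > floor
    left = [j for j in range(causal - 1, block_idx[0] - 1, -1) if eligible[j]]
    right = [j for j in range(causal + 1, block_idx[-1] + 1) if eligible[j]]
    if len(left) < flank or len(right) < flank:
        return None
    return left[:flank][::-1] + right[:flank]


def build_replicate(pool: GenotypeTable, config: SimConfig, rng=None) -> ReplicateDataset:
    """Steps 2-6: select causal SNPs and areas from the pool, cut null
    intervals, generate disease statuses, and sample cases/controls.

    Raises :class:`SimulationError` when the pool cannot supply four
    matching causal SNPs with full eligible flanks, or when there are fewer
    non-cases than cases.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    maf = pool.minor_allele_frequencies()
    blocks = _block_of(pool.locus_ids)
    block_names = [b for b in dict.fromkeys(blocks) if b.startswith("b")]

    area_per_block: dict[str, tuple[int, list[int]]] = {}
    for name in block_names:
        idx = np.flatnonzero(blocks == name)
        cand = idx[np.abs(maf[idx] - config.maf) <= 0.01]
        cand = cand[rng.permutation(cand.size)]
        for causal in cand:
            area = _pick_area(maf, idx, int(causal), config.flank, config.maf_floor_flank)
            if area is not None:
                area_per_block[name] = (int(causal), area)
                break
    if len(area_per_block) < config.n_areas:
        raise SimulationError(
            f"only {len(area_per_block)} blocks supply a causal SNP with full "
            f"eligible flanks (need {config.n_areas})"
        )
    chosen_blocks = list(
        rng.permutation(sorted(area_per_block))[: config.n_areas]
    )
    causal_loci = [area_per_block[b][0] for b in chosen_blocks]
    areas = [area_per_block[b][1] for b in chosen_blocks]

    null_runs = _null_intervals(pool, config, blocks, chosen_blocks, rng)

    # concatenate: area, null, area, null, area, null, area  (replicate)
    # or null, area, null, ..., area, null                   (chromosome)
    columns: list[int] = []
    causal_areas: list[tuple[int, int]] = []
    if config.scale == "replicate":
        for i, area in enumerate(areas):
            causal_areas.append((len(columns), len(columns) + len(area) - 1))
            columns += area
            if i < len(null_runs):
                columns += null_runs[i]
    else:
        for i, run in enumerate(null_runs):
            columns += run
            if i < len(areas):
                causal_areas.append((len(columns), len(columns) + len(areas[i]) - 1))
                columns += areas[i]

    g_causal = pool.genotypes[:, causal_loci]
    beta0 = calibrate_beta0(g_causal, config)
    pi = disease_probability(g_causal, config, beta0)
    y = (rng.random(config.n_pool) < pi).astype(np.int8)
    case_idx = np.flatnonzero(y == 1)
    noncase_idx = np.flatnonzero(y == 0)
    if noncase_idx.size < case_idx.size:
        raise SimulationError(
            f"{case_idx.size} cases but only {noncase_idx.size} non-cases"
        )
    controls = rng.choice(noncase_idx, size=case_idx.size, replace=False)
    keep = np.sort(np.concatenate([case_idx, controls]))

    table = GenotypeTable(
        genotypes=pool.genotypes[np.ix_(keep, columns)],
        phenotype=y[keep],
        locus_ids=[pool.locus_ids[j] for j in columns],
        missing_mask=pool.missing_mask[np.ix_(keep, columns)],
    )
    truth = {
        "generative_model": config.generative_model,
        "grr": config.grr,
        "maf": config.maf,
        "beta0": beta0,
        "n_pool_cases": int(case_idx.size),
        "causal_locus_ids": [pool.locus_ids[j] for j in causal_loci],
        "causal_pool_maf": [float(maf[j]) for j in causal_loci],
    }
    return ReplicateDataset(table, causal_areas, gap_offset=config.flank, truth=truth)


def _null_intervals(pool, config, blocks, chosen_blocks, rng):
    if config.scale == "chromosome":
        idx = np.flatnonzero(blocks == "chr")
        if idx.size == 0:
            raise SimulationError("chromosome-scale pool has no 'chr' block")
        pieces = np.array_split(idx, config.n_areas + 1)
        return [list(p) for p in pieces]
    spare = [
        b
        for b in dict.fromkeys(blocks)
        if b.startswith("b") and b not in chosen_blocks
    ]
    if len(spare) < config.n_null_intervals:
        raise SimulationError("not enough spare blocks for null intervals")
    runs = []
    for name in list(rng.permutation(spare))[: config.n_null_intervals]:
        idx = np.flatnonzero(blocks == name)
        if idx.size < config.null_interval_len:
            raise SimulationError("block too short for a null interval")
        start = int(rng.integers(0, idx.size - config.null_interval_len + 1))
        runs.append(list(idx[start : start + config.null_interval_len]))
    return runs


def simulate_replicate(config: SimConfig, max_attempts: int = 50) -> ReplicateDataset:
    """Synthesize a pool and build one replicate; rejected draws (e.g. a
    control shortfall) are retried with fresh sub-seeds, logged."""
    seq = np.random.SeedSequence(config.seed)
    for attempt, child in enumerate(seq.spawn(max_attempts)):
        rng = np.random.default_rng(child)
        try:
            pool = synthesize_pool(config, rng)
            return build_replicate(pool, config, rng)
        except SimulationError as exc:
            logger.warning("replicate attempt %d rejected: %s", attempt, exc)
    raise SimulationError(f"no valid replicate in {max_attempts} attempts")
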