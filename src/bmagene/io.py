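"""Reading, writing, validation and imputation of case-control genotype tables.

Genotypes are stored as minor-allele counts ``Z_ij`` in {0, 1, 2} for
individual ``i`` at locus ``j``; the phenotype ``y_i`` is 1 for cases and 0
for controls.  Missing genotypes are held as the sentinel ``-1`` with a
parallel boolean mask, and can be imputed by drawing the two missing alleles
independently from the locus's empirical allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

__all__ = [
    "GenotypeTable",
    "GenotypeParseError",
    "read_genotype_table",
    "write_genotype_table",
    "impute_missing",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the expected dialect."""


@dataclass
class GenotypeTable:
    """An N x L matrix of minor-allele counts with a binary phenotype.

    Parameters
    ----------
    genotypes
        Integer matrix of shape (N, L) with entries in {0, 1, 2}; missing
        cells hold ``-1`` and are flagged in ``missing_mask``.
    phenotype
        Binary vector of length N (1 = case), or None for a genotype pool
        that has not yet been assigned disease statuses.
    locus_ids
        Unique string identifiers, length L.
    missing_mask
        Boolean matrix of shape (N, L); all False after imputation.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray | None = None
    locus_ids: list[str] = field(default_factory=list)
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, l = self.genotypes.shape
        if self.missing_mask is None:
            self.missing_mask = self.genotypes == MISSING
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, l):
            raise ValueError("missing_mask shape mismatch")
        observed = self.genotypes[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("non-missing genotype entries must be 0, 1 or 2")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
            if self.phenotype.shape != (n,):
                raise ValueError("phenotype length mismatch")
            if not np.isin(self.phenotype, (0, 1)).all():
                raise ValueError("phenotype entries must be 0 or 1")
        if not self.locus_ids:
            self.locus_ids = [f"snp{j + 1}" for j in range(l)]
        if len(self.locus_ids) != l:
            raise ValueError("locus_ids length mismatch")
        if len(set(self.locus_ids)) != l:
            raise ValueError("locus_ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def minor_allele_frequencies(self) -> np.ndarray:
        """Empirical per-locus minor-allele frequency over non-missing cells."""
        g = np.ma.masked_array(self.genotypes, mask=self.missing_mask)
        counts = (~self.missing_mask).sum(axis=0)
        with np.errstate(invalid="ignore"):
            maf = np.where(counts > 0, g.sum(axis=0).filled(0) / (2.0 * counts), np.nan)
        return maf

    def subset_loci(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            genotypes=self.genotypes[:, idx],
            phenotype=None if self.phenotype is None else self.phenotype.copy(),
            locus_ids=[self.locus_ids[j] for j in idx],
            missing_mask=self.missing_mask[:, idx],
        )

    def subset_individuals(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            genotypes=self.genotypes[idx],
            phenotype=None if self.phenotype is None else self.phenotype[idx],
            locus_ids=list(self.locus_ids),
            missing_mask=self.missing_mask[idx],
        )


_TOKENS = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "-1": MISSING}


def _parse_tsv(path) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 3 or cols[0] != "id" or cols[1] != "phenotype":
            raise GenotypeParseError(
                f"{path}: header must start with 'id<TAB>phenotype', got {cols[:2]!r}"
            )
        locus_ids = cols[2:]
        if len(set(locus_ids)) != len(locus_ids):
            dup = sorted({x for x in locus_ids if locus_ids.count(x) > 1})
            raise GenotypeParseError(f"{path}: duplicate locus id(s) {dup}")
        rows, pheno = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise GenotypeParseError(
                    f"{path}: row {lineno} has {len(fields)} fields, expected {len(cols)}"
                )
            if fields[1] not in ("0", "1"):
                raise GenotypeParseError(
                    f"{path}: row {lineno} column 2: phenotype must be 0 or 1, got {fields[1]!r}"
                )
            pheno.append(int(fields[1]))
            row = []
            for col, tok in enumerate(fields[2:], start=3):
                try:
                    row.append(_TOKENS[tok])
                except KeyError:
                    raise GenotypeParseError(
                        f"{path}: row {lineno} column {col}: invalid genotype token {tok!r}"
                    ) from None
            rows.append(row)
    if not rows:
        raise GenotypeParseError(f"{path}: no individual rows")
    return GenotypeTable(
        genotypes=np.array(rows, dtype=np.int8),
        phenotype=np.array(pheno, dtype=np.int8),
        locus_ids=locus_ids,
    )


def _parse_plink_raw(path) -> GenotypeTable:
    # PLINK --recode A style: FID IID PAT MAT SEX PHENOTYPE then per-SNP
    # additive allele counts; phenotype coded 1/2 (control/case) or 0/1.
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 7 or header[5] != "PHENOTYPE":
            raise GenotypeParseError(
                f"{path}: not a PLINK additive-coded text matrix (.raw header expected)"
            )
        locus_ids = header[6:]
        if len(set(locus_ids)) != len(locus_ids):
            raise GenotypeParseError(f"{path}: duplicate locus id in header")
        rows, pheno = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(header):
                raise GenotypeParseError(
                    f"{path}: row {lineno} has {len(fields)} fields, expected {len(header)}"
                )
            ph = fields[5]
            if ph in ("1", "2"):
                pheno.append(int(ph) - 1)
            elif ph in ("0",):  # already 0/1 coded files put controls at 0
                pheno.append(0)
            else:
                raise GenotypeParseError(
                    f"{path}: row {lineno}: unsupported phenotype code {ph!r}"
                )
            row = []
            for col, tok in enumerate(fields[6:], start=7):
                if tok in ("NA", "-9"):
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise GenotypeParseError(
                        f"{path}: row {lineno} column {col}: invalid allele count {tok!r}"
                    )
            rows.append(row)
    if not rows:
        raise GenotypeParseError(f"{path}: no individual rows")
    return GenotypeTable(
        genotypes=np.array(rows, dtype=np.int8),
        phenotype=np.array(pheno, dtype=np.int8),
        locus_ids=locus_ids,
    )


def read_genotype_table(path, format: str = "tsv") -> GenotypeTable:
    """Read a case-control genotype table.

    ``format='tsv'`` expects a header ``id<TAB>phenotype<TAB><locus ids...>``
    and one row per individual with genotype tokens 0/1/2/NA (or -1 for
    missing).  ``format='plink_text'`` reads a PLINK ``--recode A`` style
    additive matrix (read-only support).
    """
    if format == "tsv":
        return _parse_tsv(path)
    if format == "plink_text":
        return _parse_plink_raw(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotype_table(table: GenotypeTable, path) -> None:
    """Write a table in the TSV dialect; missing cells emitted as ``NA``."""
    with open(path, "w") as fh:
        fh.write("id\tphenotype\t" + "\t".join(table.locus_ids) + "\n")
        pheno = table.phenotype
        if pheno is None:
            raise ValueError("cannot write a table without phenotypes")
        for i in range(table.n_individuals):
            toks = [
                "NA" if table.missing_mask[i, j] else str(int(table.genotypes[i, j]))
                for j in range(table.n_loci)
            ]
            fh.write(f"ind{i + 1}\t{int(pheno[i])}\t" + "\t".join(toks) + "\n")


def impute_missing(table: GenotypeTable, seed: int | np.random.Generator = 0) -> GenotypeTable:
    """Impute missing genotypes from the marginal allele distributions.

    For every missing cell the two alleles are drawn independently as
    Bernoulli(minor-allele frequency) from the locus's empirical frequency
    over its non-missing cells (Hardy-Weinberg pairing), so the imputed
    genotype is Binomial(2, MAF).  Deterministic given ``seed``.  Tables
    without missing values are returned unchanged.
    """
    if not table.has_missing:
        return table
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maf = table.minor_allele_frequencies()
    bad = np.flatnonzero(np.isnan(maf) & table.missing_mask.any(axis=0))
    if bad.size:
        raise ValueError(
            f"locus {table.locus_ids[bad[0]]!r} is entirely missing; cannot impute"
        )
    genotypes = table.genotypes.copy()
    rows, cols = np.nonzero(table.missing_mask)
    draws = rng.binomial(2, maf[cols]).astype(np.int8)
    genotypes[rows, cols] = draws
    return replace(
        table,
        genotypes=genotypes,
        missing_mask=np.zeros_like(table.missing_mask),
        phenotype=None if table.phenotype is None else table.phenotype.copy(),
        locus_ids=list(table.locus_ids),
    )
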