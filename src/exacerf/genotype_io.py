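"""Reading, writing and additive encoding of cohort genotype/covariate files.

Genotypes travel as a :class:`GenotypeMatrix`: an n_samples x n_snps matrix of
minor-allele counts in {0, 1, 2} with :data:`MISSING` (= -1) marking no-calls,
plus per-SNP metadata (chromosome, position, alleles).  On disk the cohort
uses the PLINK 1.x text dialect — a whitespace-separated ``.ped`` with the
binary outcome in column 6 (1 = control, 2 = case) and a 4-column ``.map`` —
and a headered CSV/TSV covariate table keyed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call inside a GenotypeMatrix.
MISSING: int = -1

VALID_ALLELES = frozenset("ACGT")

COVARIATE_COLUMNS = ("age", "sex", "fev1_pct_pred", "treatment")


class FormatError(ValueError):
    """A genotype file violates the expected text dialect."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant (codes, ranges, uniqueness)."""


@dataclass(frozen=True)
class SNPMeta:
    """Metadata for one biallelic SNP.

    ``allele_b`` is the counted (minor) allele; ``allele_a`` the other.  A
    monomorphic SNP observed with a single allele carries ``allele_b = "0"``
    (unknown minor allele).
    """

    snp_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"SNP {self.snp_id}: negative position")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive genotype counts with per-SNP metadata."""

    samples: list[str]
    snps: list[SNPMeta]
    counts: np.ndarray  # int8, values in {0, 1, 2, MISSING}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        n, p = self.counts.shape
        if n != len(self.samples) or p != len(self.snps):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.counts, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("genotype counts outside {0, 1, 2, MISSING}")
        if len(set(self.samples)) != n:
            raise ValidationError("duplicate sample ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != p:
            raise ValidationError("duplicate SNP ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        """Column subset (in the order given), by SNP id."""
        index = {s.snp_id: j for j, s in enumerate(self.snps)}
        missing = [i for i in snp_ids if i not in index]
        if missing:
            raise KeyError(f"SNPs absent from panel: {missing[:5]}")
        cols = [index[i] for i in snp_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in cols],
            counts=self.counts[:, cols].copy(),
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            samples=[s for s, m in zip(self.samples, mask) if m],
            snps=list(self.snps),
            counts=self.counts[mask].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.counts, other.counts)
        )


CovariateTable = pd.DataFrame
"""Covariate table: DataFrame indexed by sample id with columns
``age`` (years), ``sex`` (1 = male, 2 = female), ``fev1_pct_pred``
(pre-bronchodilator FEV1 % predicted), ``treatment`` (code 1/2/3)."""


def validate_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Check covariate invariants; raise ValidationError naming the first bad row."""
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"covariate table missing columns: {missing_cols}")
    if table[list(COVARIATE_COLUMNS)].isna().any().any():
        row = table.index[table[list(COVARIATE_COLUMNS)].isna().any(axis=1)][0]
        raise ValidationError(f"missing covariate value for sample {row!r}")
    for col, ok in (
        ("sex", table["sex"].isin((1, 2))),
        ("treatment", table["treatment"].isin((1, 2, 3))),
        ("age", table["age"] > 0),
        ("fev1_pct_pred", table["fev1_pct_pred"] > 0),
    ):
        if not ok.all():
            row = table.index[~ok][0]
            raise ValidationError(
                f"invalid {col}={table.loc[row, col]!r} for sample {row!r}"
            )
    return table


def _minor_allele(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[str, str]:
    """(major, minor) over the pooled non-missing calls; lexicographic tie-break."""
    pooled = np.concatenate([calls_a, calls_b])
    pooled = pooled[pooled != "0"]
    alleles, counts = np.unique(pooled, return_counts=True)
    if len(alleles) == 0:
        return "0", "0"
    if len(alleles) == 1:
        return str(alleles[0]), "0"
    if len(alleles) > 2:
        raise FormatError(f"more than two alleles observed: {alleles.tolist()}")
    a1, a2 = str(alleles[0]), str(alleles[1])  # a1 < a2 lexicographically
    c1, c2 = int(counts[0]), int(counts[1])
    if c1 < c2:
        return a2, a1
    if c2 < c1:
        return a1, a2
    return a2, a1  # tie: minor = lexicographically smaller


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read a PLINK text ``.ped``/``.map`` pair.

    Returns the genotype matrix (additive counts of the empirical minor
    allele; ``0 0`` calls become :data:`MISSING`) and the phenotype vector
    (``.ped`` column 6 mapped 1 -> 0 = no exacerbation, 2 -> 1 = case).
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts
            map_rows.append((chrom, snp_id, int(pos)))
    p = len(map_rows)
    ids = [r[1] for r in map_rows]
    if len(set(ids)) != p:
        raise ValidationError(f"{map_path}: duplicate SNP ids")

    samples: list[str] = []
    phenos: list[int] = []
    allele_rows_a: list[np.ndarray] = []
    allele_rows_b: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * p:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * p} columns, got {len(parts)}"
                )
            iid = parts[1]
            pheno_code = parts[5]
            if pheno_code not in ("1", "2"):
                raise ValidationError(
                    f"{ped_path}:{lineno}: phenotype code {pheno_code!r} not in {{1, 2}}"
                )
            alleles = np.array(parts[6:], dtype="U1")
            bad = ~np.isin(alleles, list(VALID_ALLELES | {"0"}))
            if bad.any():
                raise FormatError(
                    f"{ped_path}:{lineno}: invalid allele {alleles[bad][0]!r}"
                )
            samples.append(iid)
            phenos.append(int(pheno_code) - 1)
            allele_rows_a.append(alleles[0::2])
            allele_rows_b.append(alleles[1::2])
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{ped_path}: duplicate sample ids")

    A = np.array(allele_rows_a)  # n x p
    B = np.array(allele_rows_b)
    n = len(samples)
    counts = np.full((n, p), MISSING, dtype=np.int8)
    snps: list[SNPMeta] = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        major, minor = _minor_allele(A[:, j], B[:, j])
        called = (A[:, j] != "0") & (B[:, j] != "0")
        counts[called, j] = (A[called, j] == minor).astype(np.int8) + (
            B[called, j] == minor
        ).astype(np.int8)
        snps.append(SNPMeta(snp_id, chrom, pos, major, minor))
    return (
        GenotypeMatrix(samples=samples, snps=snps, counts=counts),
        np.array(phenos, dtype=np.int8),
    )


def write_ped_map(
    genotypes: GenotypeMatrix, phenotype: np.ndarray, ped_path, map_path
) -> None:
    """Write a PLINK text ``.ped``/``.map`` pair (deterministic byte output).

    MISSING cells are written as ``0 0``; the phenotype is written as
    1 = control, 2 = case in column 6.  A monomorphic SNP (allele_b unknown)
    writes allele_a for every call.
    """
    phenotype = np.asarray(phenotype)
    if len(phenotype) != genotypes.n_samples:
        raise ValidationError("phenotype length does not match sample count")
    with open(map_path, "w") as fh:
        for s in genotypes.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    call_table = {}  # per-SNP: count -> "a b"
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.samples):
            fields = [sid, sid, "0", "0", "0", str(int(phenotype[i]) + 1)]
            row = genotypes.counts[i]
            for j, s in enumerate(genotypes.snps):
                if (j) not in call_table:
                    b = s.allele_b if s.allele_b != "0" else s.allele_a
                    call_table[j] = {
                        0: f"{s.allele_a} {s.allele_a}",
                        1: f"{s.allele_a} {b}",
                        2: f"{b} {b}",
                        MISSING: "0 0",
                    }
                fields.append(call_table[j][int(row[j])])
            fh.write("\t".join(fields) + "\n")


def read_covariate_table(path) -> CovariateTable:
    """Read the covariate CSV/TSV (header; sample-id column + the 4 covariates)."""
    table = pd.read_csv(path, sep=None, engine="python")
    id_col = next(
        (c for c in table.columns if c.lower() in ("sample_id", "sample", "iid", "id")),
        None,
    )
    if id_col is None:
        raise FormatError(f"{path}: no sample-id column found")
    table = table.set_index(id_col)
    table.index = table.index.astype(str)
    if table.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    return validate_covariates(table)


def align_covariates(table: CovariateTable, samples: list[str]) -> CovariateTable:
    """Reorder covariates to the genotype sample order; error listing orphans."""
    orphans = [s for s in samples if s not in table.index]
    extra = [s for s in table.index if s not in set(samples)]
    if orphans or extra:
        raise ValidationError(
            f"covariate/genotype sample mismatch: missing={orphans[:5]} extra={extra[:5]}"
        )
    return table.loc[samples]


def encode_additive(genotypes: GenotypeMatrix) -> np.ndarray:
    """Emit the numeric feature block: float64 minor-allele counts, NaN = MISSING."""
    out = genotypes.counts.astype(np.float64)
    out[genotypes.counts == MISSING] = np.nan
    return out
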