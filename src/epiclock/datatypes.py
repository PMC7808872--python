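"""Core containers shared across the pipeline.

A study is represented by a :class:`GenotypeMatrix` (individuals x SNPs,
minor-allele counts) together with a phenotype vector (total morningness
score) and a covariate table (sex, age).  SNP metadata travels with the
matrix as a list of :class:`SnpRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MISSING = -1  # sentinel for a missing genotype call


@dataclass
class SnpRecord:
    """Annotation for one biallelic SNP.

    ``alleles`` is ordered (major, minor) once the matrix has been oriented
    to minor-allele counts; ``maf`` is the estimated minor allele frequency
    for the dataset at hand (None until estimated).
    """

    id: str
    gene: str
    chromosome: str
    position: int
    alleles: tuple[str, str]
    maf: float | None = None

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a == b:
            raise ValueError(f"SNP {self.id}: alleles must be distinct, got {self.alleles!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"SNP {self.id}: maf {self.maf} outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """n x p matrix of minor-allele counts with missingness.

    ``values`` holds integer codes in {0, 1, 2}; missing calls are stored as
    :data:`MISSING` (-1).  Rows are individuals (``iids``), columns are SNPs
    (``snps``).
    """

    values: np.ndarray
    snps: list[SnpRecord]
    iids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, p = self.values.shape
        if len(self.iids) != n:
            raise ValueError(f"{len(self.iids)} iids for {n} genotype rows")
        if len(self.snps) != p:
            raise ValueError(f"{len(self.snps)} SNP records for {p} genotype columns")
        bad = ~np.isin(self.values, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean n x p mask, True where the genotype call is missing."""
        return self.values == MISSING

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP columns (order preserved)."""
        idx = list(indices)
        return GenotypeMatrix(
            values=self.values[:, idx].copy(),
            snps=[replace(self.snps[j]) for j in idx],
            iids=list(self.iids),
        )

    def index_of(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from None

    def genes(self) -> dict[str, list[int]]:
        """Column indices grouped by gene symbol, in panel order."""
        out: dict[str, list[int]] = {}
        for j, rec in enumerate(self.snps):
            out.setdefault(rec.gene, []).append(j)
        return out
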