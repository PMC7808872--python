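"""SNP quality control: allele frequencies and Hardy-Weinberg filtering.

Genotypes arrive as minor-allele counts per individual.  QC consists of
estimating each SNP's minor allele frequency (re-orienting columns whose
coded allele turns out to be the major one), testing each SNP for
Hardy-Weinberg equilibrium with the exact conditional test, and dropping
SNPs whose HWE p-value falls below a threshold before any association
analysis.

The exact test conditions on the observed allele counts and sums the
probabilities of all heterozygote counts (same parity) whose conditional
probability does not exceed that of the observed table — the standard
"minimum likelihood" two-sided exact test.  Probabilities are evaluated in
exact integer arithmetic, so p-values carry no roundoff beyond the final
float division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

DEFAULT_HWE_ALPHA = 0.05


def genotype_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """(hom reference, het, hom coded-allele) counts ignoring missing."""
    codes = np.asarray(codes)
    ok = codes != MISSING
    return (
        int(np.sum(codes[ok] == 0)),
        int(np.sum(codes[ok] == 1)),
        int(np.sum(codes[ok] == 2)),
    )


def allele_frequency(codes: np.ndarray) -> float:
    """Frequency of the allele coded 1/2, ignoring missing calls."""
    n0, n1, n2 = genotype_counts(codes)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all genotypes missing for this SNP")
    return (2 * n2 + n1) / (2 * n)


def compute_maf(codes: np.ndarray) -> tuple[float, bool]:
    """Minor allele frequency and whether the column needs re-orienting.

    Returns ``(maf, flip)``: ``flip`` is True when the coded allele has
    frequency > 0.5, i.e. the codes count the major allele and should be
    replaced by ``2 - code``.
    """
    f = allele_frequency(codes)
    if f > 0.5:
        return 1.0 - f, True
    return f, False


def orient_minor(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Re-orient every column to minor-allele counts and record MAFs.

    Columns whose coded allele frequency exceeds 0.5 are flipped
    (codes 0<->2, alleles swapped).  MAF estimates are stored on the
    returned matrix's SNP records; the input is not modified.
    """
    values = matrix.values.copy()
    snps = []
    for j, rec in enumerate(matrix.snps):
        maf, flip = compute_maf(values[:, j])
        alleles = rec.alleles
        if flip:
            col = values[:, j]
            ok = col != MISSING
            col[ok] = 2 - col[ok]
            alleles = (alleles[1], alleles[0])
        snps.append(replace(rec, alleles=alleles, maf=maf))
    return GenotypeMatrix(values=values, snps=snps, iids=list(matrix.iids))


def _het_weights(n: int, n_minor: int) -> list[tuple[int, int]]:
    """Unnormalised exact-test weights for every admissible het count.

    Weight of h hets given n diploids carrying m minor alleles is
    ``2**h * n! / (((m-h)/2)! * h! * (n-(m+h)/2)!)``; all weights share the
    hypergeometric normaliser, so p-values are ratios of integer sums.
    """
    weights = []
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        w = (2**h) * math.factorial(n) // (
            math.factorial(hom_minor) * math.factorial(h) * math.factorial(hom_major)
        )
        weights.append((h, w))
    return weights


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Monomorphic SNPs (no copies of one allele) return 1.0 by convention —
    there is nothing to test.
    """
    for c in (n_hom_major, n_het, n_hom_minor):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # symmetric in the two alleles
    if n_minor == 0:
        return 1.0
    weights = _het_weights(n, n_minor)
    w_obs = dict(weights)[n_het]
    num = sum(w for _, w in weights if w <= w_obs)
    den = sum(w for _, w in weights)
    return num / den


@dataclass
class SnpFilterReport:
    """Outcome of HWE filtering: per-SNP p-values and actions."""

    table: pd.DataFrame  # columns: snp_id, gene, maf, hwe_p, action

    @property
    def removed_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["action"] == "removed", "snp_id"])


def filter_snps(
    matrix: GenotypeMatrix, alpha: float = DEFAULT_HWE_ALPHA
) -> tuple[GenotypeMatrix, SnpFilterReport]:
    """Drop SNPs with HWE exact p < ``alpha``; keep column order otherwise.

    The input should already be minor-allele oriented (see
    :func:`orient_minor`); orientation does not affect the test.  Returns
    the filtered matrix and a report listing every SNP with its p-value and
    the action taken.
    """
    rows = []
    keep: list[int] = []
    for j, rec in enumerate(matrix.snps):
        n0, n1, n2 = genotype_counts(matrix.values[:, j])
        p = hwe_exact_test(n0, n1, n2)
        removed = p < alpha
        rows.append(
            {
                "snp_id": rec.id,
                "gene": rec.gene,
                "maf": rec.maf,
                "hwe_p": p,
                "action": "removed" if removed else "kept",
            }
        )
        if not removed:
            keep.append(j)
    report = SnpFilterReport(table=pd.DataFrame(rows))
    return matrix.subset_snps(keep), report
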