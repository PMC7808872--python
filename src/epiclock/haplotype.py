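"""Per-gene haplotype frequency estimation and omnibus association.

Unphased genotypes within a gene (2-5 tag SNPs) are phased statistically:
haplotype frequencies are estimated by maximum likelihood with an EM
algorithm over each individual's compatible diplotype resolutions.  The
association with the quantitative CS score is then an omnibus F-test —
OLS of the phenotype on posterior-expected haplotype dosages for all
common haplotypes but one reference, jointly testing the dosage
coefficients with numerator df = (number of common haplotypes - 1).

"Common" means estimated frequency >= 0.01 by default.  Individuals with
any missing genotype inside the block are excluded from both estimation
and testing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import MISSING, GenotypeMatrix

COMMON_THRESHOLD = 0.01
EM_TOL = 1e-6
EM_MAX_ITER = 1000
EM_PRUNE = 1e-10

Haplotype = tuple[int, ...]  # 0 = major, 1 = minor allele at each SNP


def enumerate_diplotypes(genotype: tuple[int, ...]) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with a multi-SNP genotype.

    A genotype with h heterozygous sites has 2**(h-1) distinct resolutions
    (1 when fully homozygous).
    """
    het = [i for i, g in enumerate(genotype) if g == 1]
    base = [g // 2 for g in genotype]  # 0 for g in {0,1}, 1 for g=2
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = set()
    for assign in itertools.product((0, 1), repeat=len(het)):
        h1, h2 = list(base), list(base)
        for pos, a in zip(het, assign):
            h1[pos], h2[pos] = a, 1 - a
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        pairs.add(pair)
    return sorted(pairs)


@dataclass
class HaplotypeBlock:
    """Fitted haplotype frequencies for one gene's SNPs."""

    gene: str
    snp_ids: list[str]
    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    n_individuals: int
    log_likelihood_trace: list[float] = field(default_factory=list)
    common_threshold: float = COMMON_THRESHOLD

    @property
    def n_common(self) -> int:
        return int(np.sum(self.frequencies >= self.common_threshold))

    @property
    def common_indices(self) -> list[int]:
        return [i for i, f in enumerate(self.frequencies) if f >= self.common_threshold]

    def haplotype_strings(self, alleles: list[tuple[str, str]] | None = None) -> list[str]:
        """Human-readable haplotypes, using allele letters when provided."""
        out = []
        for h in self.haplotypes:
            if alleles is None:
                out.append("".join(str(a) for a in h))
            else:
                out.append("".join(alleles[i][a] for i, a in enumerate(h)))
        return out


def _complete_rows(codes: np.ndarray) -> np.ndarray:
    return ~np.any(codes == MISSING, axis=1)


def em_haplotype_frequencies(
    codes: np.ndarray,
    snp_ids: list[str] | None = None,
    gene: str = "",
    common_threshold: float = COMMON_THRESHOLD,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaplotypeBlock:
    """Maximum-likelihood haplotype frequencies by EM.

    ``codes`` is n x s minor-allele counts for the block's SNPs (s in 2..5).
    Starts from uniform frequencies over every haplotype compatible with
    some observed genotype; iterates expectation (weight each individual's
    diplotype resolutions by current frequencies) and maximisation
    (re-estimate frequencies from expected haplotype counts) until the
    largest frequency change is below ``tol``.  The log-likelihood trace is
    recorded and checked to be non-decreasing at every step.
    """
    codes = np.asarray(codes)
    if codes.ndim != 2 or codes.shape[1] < 2:
        raise ValueError("need a 2-D block of at least two SNPs")
    if codes.shape[1] > 5:
        raise ValueError("blocks larger than five SNPs are not supported")
    keep = _complete_rows(codes)
    codes = codes[keep]
    n = codes.shape[0]
    if n == 0:
        raise ValueError("no individuals with complete genotypes in the block")
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(codes.shape[1])]

    # collapse identical genotypes; EM cost then scales with distinct patterns
    patterns, counts = np.unique(codes, axis=0, return_counts=True)
    pattern_pairs = [enumerate_diplotypes(tuple(g)) for g in patterns]

    hap_set: set[Haplotype] = set()
    for pairs in pattern_pairs:
        for h1, h2 in pairs:
            hap_set.update((h1, h2))
    haps = sorted(hap_set)
    index = {h: i for i, h in enumerate(haps)}
    H = len(haps)
    freq = np.full(H, 1.0 / H)

    # precompute (i1, i2, multiplicity) per pattern
    resolved = [
        [(index[h1], index[h2], 2.0 if h1 != h2 else 1.0) for h1, h2 in pairs]
        for pairs in pattern_pairs
    ]

    ll_trace: list[float] = []
    for _ in range(max_iter):
        new = np.zeros(H)
        ll = 0.0
        for (pairs, cnt) in zip(resolved, counts):
            like = np.array([m * freq[i1] * freq[i2] for i1, i2, m in pairs])
            tot = like.sum()
            ll += cnt * np.log(tot) if tot > 0 else -np.inf
            if tot <= 0:
                continue
            w = like / tot
            for (i1, i2, _), wk in zip(pairs, w):
                new[i1] += cnt * wk
                new[i2] += cnt * wk
        new /= 2.0 * n
        if ll_trace and ll < ll_trace[-1] - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        ll_trace.append(float(ll))
        delta = np.max(np.abs(new - freq))
        freq = new
        if delta < tol:
            break

    keep_h = freq > EM_PRUNE
    haps = [h for h, k in zip(haps, keep_h) if k]
    freq = freq[keep_h]
    freq = freq / freq.sum()
    return HaplotypeBlock(
        gene=gene,
        snp_ids=list(snp_ids),
        haplotypes=haps,
        frequencies=freq,
        n_individuals=n,
        log_likelihood_trace=ll_trace,
        common_threshold=common_threshold,
    )


def block_log_likelihood(block: HaplotypeBlock, codes: np.ndarray) -> float:
    """Log-likelihood of complete-genotype individuals under the block."""
    codes = np.asarray(codes)
    codes = codes[_complete_rows(codes)]
    index = {h: i for i, h in enumerate(block.haplotypes)}
    f = block.frequencies
    ll = 0.0
    for g in codes:
        tot = 0.0
        for h1, h2 in enumerate_diplotypes(tuple(g)):
            if h1 in index and h2 in index:
                m = 2.0 if h1 != h2 else 1.0
                tot += m * f[index[h1]] * f[index[h2]]
        ll += np.log(tot) if tot > 0 else -np.inf
    return float(ll)


def haplotype_dosages(
    block: HaplotypeBlock, codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-expected haplotype counts (0-2) per individual.

    Returns ``(dosages, kept)`` where ``dosages`` is n_kept x n_haplotypes
    over *all* fitted haplotypes (rows sum to 2) and ``kept`` is the boolean
    mask of individuals with complete block genotypes.
    """
    codes = np.asarray(codes)
    kept = _complete_rows(codes)
    sub = codes[kept]
    index = {h: i for i, h in enumerate(block.haplotypes)}
    f = block.frequencies
    D = np.zeros((sub.shape[0], len(block.haplotypes)))
    cache: dict[tuple[int, ...], np.ndarray] = {}
    for r, g in enumerate(map(tuple, sub)):
        if g not in cache:
            row = np.zeros(len(block.haplotypes))
            pairs, weights = [], []
            for h1, h2 in enumerate_diplotypes(g):
                if h1 in index and h2 in index:
                    m = 2.0 if h1 != h2 else 1.0
                    pairs.append((index[h1], index[h2]))
                    weights.append(m * f[index[h1]] * f[index[h2]])
            w = np.asarray(weights, dtype=float)
            if w.sum() <= 0:
                raise ValueError(f"genotype {g} incompatible with fitted haplotypes")
            w /= w.sum()
            for (i1, i2), wk in zip(pairs, w):
                row[i1] += wk
                row[i2] += wk
            cache[g] = row
        D[r] = cache[g]
    return D, kept


@dataclass
class HaplotypeAssocResult:
    gene: str
    n_snps: int
    n_common: int
    F: float
    df_num: int
    df_den: int
    p: float


def omnibus_f_test(
    pheno: np.ndarray,
    dosages: np.ndarray,
    block: HaplotypeBlock,
) -> HaplotypeAssocResult:
    """Joint F-test of common-haplotype dosage effects on the phenotype.

    The most frequent common haplotype is the omitted reference; the
    remaining common haplotypes' dosages enter an OLS model whose overall
    F-statistic (all dosage slopes zero) is reported with numerator df
    = n_common - 1.  Collinear dosage columns are dropped with a warning,
    reducing the df accordingly.
    """
    y = np.asarray(pheno, dtype=float)
    common = block.common_indices
    if len(common) < 2:
        raise ValueError("need at least two common haplotypes for an omnibus test")
    ref = common[int(np.argmax(block.frequencies[common]))]
    cols = [i for i in common if i != ref]
    X = dosages[:, cols]

    # drop collinear columns (rare: e.g. complementary 2-SNP haplotypes)
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = np.column_stack([np.ones(len(y))] + [X[:, k] for k in keep + [j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
    if len(keep) < X.shape[1]:
        warnings.warn(
            f"{block.gene}: dropped {X.shape[1] - len(keep)} collinear dosage column(s)",
            stacklevel=2,
        )
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("all dosage columns collinear with the intercept")

    fit = sm.OLS(y, sm.add_constant(X)).fit()
    F = float(fit.fvalue)
    p = float(fit.f_pvalue)
    if not np.isfinite(F):  # perfect fit: zero residual variance
        F, p = float(np.inf), 0.0
    return HaplotypeAssocResult(
        gene=block.gene,
        n_snps=len(block.snp_ids),
        n_common=len(common),
        F=F,
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        p=p,
    )


def haplotype_association_table(
    matrix: GenotypeMatrix,
    pheno: np.ndarray,
    min_snps: int = 2,
    common_threshold: float = COMMON_THRESHOLD,
) -> pd.DataFrame:
    """Gene-by-gene haplotype omnibus tests (genes with >= ``min_snps``).

    Output columns: gene, n_snps, n_common_haplotypes, F, df_num, df_den, p.
    """
    y = np.asarray(pheno, dtype=float)
    rows = []
    for gene, cols in matrix.genes().items():
        if len(cols) < min_snps:
            continue
        codes = matrix.values[:, cols]
        block = em_haplotype_frequencies(
            codes,
            snp_ids=[matrix.snps[j].id for j in cols],
            gene=gene,
            common_threshold=common_threshold,
        )
        if block.n_common < 2:
            continue
        D, kept = haplotype_dosages(block, codes)
        res = omnibus_f_test(y[kept], D, block)
        rows.append(
            {
                "gene": gene,
                "n_snps": res.n_snps,
                "n_common_haplotypes": res.n_common,
                "F": res.F,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
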