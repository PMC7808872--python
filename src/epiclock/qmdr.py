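"""Quantitative multifactor dimensionality reduction (QMDR).

QMDR extends MDR to quantitative traits.  For a candidate set of k SNPs,
the 3**k multi-locus genotype cells are each labelled *high* when the
training-sample mean phenotype in the cell exceeds the overall training
mean, otherwise *low*; pooling cells by label collapses the k-dimensional
genotype space into one binary attribute.  The quality of a candidate is
the two-sample t-statistic comparing phenotypes between the pooled high
and low groups — computed on the training split (training score, used to
pick the best candidate) and on the held-out split with the training
labels (testing score).

The search is exhaustive over all C(p, k) combinations under 10-fold
cross-validation.  Each fold contributes one winning combination (largest
training score); a model's cross-validation consistency (CVC) is the
number of folds it wins, and its reported score is the average testing
score over those folds.  The best model of an order is the one with
maximal CVC (ties broken by score).  Statistical significance is assessed
empirically: the phenotype is permuted B times, the whole order-k search
is re-run per permutation, and the permutation distribution of the
*best-model* average testing score serves as the common null against
which every observed model is ranked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix


@dataclass
class QmdrConfig:
    """Search settings; defaults reproduce the conventional analysis."""

    n_folds: int = 10
    k_max: int = 3
    n_permutations: int = 1000
    rng_seed: int = 0
    t_variant: str = "pooled"  # "pooled" | "welch"
    empty_cell_rule: str = "low"  # label given to cells with no training data
    tie_rule: str = "low"  # label when a cell mean equals the overall mean

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError("t_variant must be 'pooled' or 'welch'")
        for name in ("empty_cell_rule", "tie_rule"):
            if getattr(self, name) not in ("low", "high"):
                raise ValueError(f"{name} must be 'low' or 'high'")


@dataclass
class CellPartition:
    """High/low labelling of multi-locus genotype cells, learned on training data."""

    loci: tuple[int, ...]
    cell_label: np.ndarray  # (3**k,) bool, True = high
    empty: np.ndarray  # (3**k,) bool, True = no training individuals
    train_overall_mean: float


@dataclass
class QmdrModel:
    """One locus combination's cross-validation summary."""

    loci: tuple[int, ...]
    snp_ids: tuple[str, ...]
    k: int
    fold_wins: int
    n_folds: int
    avg_testing_score: float
    empirical_p: float | None = None

    @property
    def cvc(self) -> float:
        return self.fold_wins / self.n_folds


def enumerate_combinations(p: int, k: int) -> list[tuple[int, ...]]:
    """All C(p, k) locus tuples in lexicographic order."""
    if not (1 <= k <= p):
        raise ValueError(f"order k={k} must satisfy 1 <= k <= p={p}")
    return list(itertools.combinations(range(p), k))


def _cell_index(geno_cols: np.ndarray) -> np.ndarray:
    """Base-3 cell id per individual; -1 where any locus is missing."""
    geno_cols = np.asarray(geno_cols)
    miss = np.any(geno_cols == MISSING, axis=1)
    cells = np.zeros(geno_cols.shape[0], dtype=np.int64)
    for j in range(geno_cols.shape[1]):
        cells = cells * 3 + np.where(geno_cols[:, j] == MISSING, 0, geno_cols[:, j])
    cells[miss] = -1
    return cells


def partition_cells(
    geno_cols: np.ndarray,
    pheno: np.ndarray,
    loci: tuple[int, ...] | None = None,
    tie_rule: str = "low",
    empty_cell_rule: str = "low",
) -> CellPartition:
    """Label each of the 3**k genotype cells high or low on training data.

    A cell is *high* iff its training mean strictly exceeds the overall
    training mean; exact ties follow ``tie_rule`` and empty cells follow
    ``empty_cell_rule`` (default low for both, so held-out individuals in
    them are always classified rather than dropped).
    """
    geno_cols = np.asarray(geno_cols)
    if geno_cols.ndim == 1:
        geno_cols = geno_cols[:, None]
    y = np.asarray(pheno, dtype=float)
    k = geno_cols.shape[1]
    m = 3**k
    cells = _cell_index(geno_cols)
    ok = cells >= 0
    if not ok.any():
        raise ValueError("all individuals missing at these loci")
    cnt = np.bincount(cells[ok], minlength=m)
    tot = np.bincount(cells[ok], weights=y[ok], minlength=m)
    overall = y[ok].mean()
    with np.errstate(invalid="ignore"):
        means = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    empty = cnt == 0
    label = np.zeros(m, dtype=bool)
    nonempty = ~empty
    if tie_rule == "low":
        label[nonempty] = means[nonempty] > overall
    else:
        label[nonempty] = means[nonempty] >= overall
    label[empty] = empty_cell_rule == "high"
    return CellPartition(
        loci=tuple(loci) if loci is not None else tuple(range(k)),
        cell_label=label,
        empty=empty,
        train_overall_mean=float(overall),
    )


def _t_from_groups(high: np.ndarray, low: np.ndarray, variant: str) -> float:
    """Two-sample t (high minus low); 0 when either group has < 2 members."""
    n1, n2 = len(high), len(low)
    if n1 < 2 or n2 < 2:
        return 0.0
    m1, m2 = high.mean(), low.mean()
    v1 = high.var(ddof=1)
    v2 = low.var(ddof=1)
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        denom = np.sqrt(v1 / n1 + v2 / n2)
    if denom == 0.0:
        return 0.0 if m1 == m2 else float(np.sign(m1 - m2) * np.inf)
    return float((m1 - m2) / denom)


def pooled_t_score(
    partition: CellPartition,
    geno_cols: np.ndarray,
    pheno: np.ndarray,
    variant: str = "pooled",
) -> float:
    """t-statistic of high vs low pooled groups under a fitted partition.

    Individuals are assigned to groups via the partition's cell labels;
    those with a missing genotype at any locus are excluded.  Positive
    values mean the high group's mean exceeds the low group's.
    """
    geno_cols = np.asarray(geno_cols)
    if geno_cols.ndim == 1:
        geno_cols = geno_cols[:, None]
    y = np.asarray(pheno, dtype=float)
    cells = _cell_index(geno_cols)
    ok = cells >= 0
    is_high = partition.cell_label[cells[ok]]
    yo = y[ok]
    return _t_from_groups(yo[is_high], yo[~is_high], variant)


# ---------------------------------------------------------------------------
# vectorised exhaustive CV search


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random near-equal fold labels 0..n_folds-1 for n individuals."""
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        fold_of[chunk] = f
    return fold_of


def _vector_t(n1, s1, q1, n2, s2, q2, variant: str) -> np.ndarray:
    """Two-sample t from per-group (count, sum, sum-of-squares) arrays."""
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = s1 / n1
        m2 = s2 / n2
        ssd1 = np.maximum(q1 - s1 * m1, 0.0)
        ssd2 = np.maximum(q2 - s2 * m2, 0.0)
        if variant == "pooled":
            sp2 = (ssd1 + ssd2) / (n1 + n2 - 2)
            denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            denom = np.sqrt(ssd1 / (n1 * (n1 - 1)) + ssd2 / (n2 * (n2 - 1)))
        t = (m1 - m2) / denom
        diff = m1 - m2
        t = np.where(denom == 0.0, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
    t[(n1 < 2) | (n2 < 2)] = 0.0
    return t


class _OrderSearch:
    """Precomputed cell indices for every order-k combination of one dataset.

    Genotypes are fixed across permutations, so the expensive part — the
    per-individual cell id for each of the C(p, k) combinations — is built
    once.  Each CV run then reduces to bincounts of the phenotype over
    (combination, cell) pairs.
    """

    def __init__(self, codes: np.ndarray, k: int):
        codes = np.asarray(codes)
        n, p = codes.shape
        self.n = n
        self.k = k
        self.combos = enumerate_combinations(p, k)
        combo_arr = np.array(self.combos)  # (K, k)
        self.K = len(self.combos)
        self.m = 3**k
        cells = np.zeros((n, self.K), dtype=np.int64)
        miss = np.zeros((n, self.K), dtype=bool)
        for j in range(k):
            col = codes[:, combo_arr[:, j]]
            miss |= col == MISSING
            cells = cells * 3 + np.where(col == MISSING, 0, col)
        cells[miss] = self.m  # dump cell for missing, excluded from stats
        self.flat = cells + np.arange(self.K, dtype=np.int64) * (self.m + 1)
        self.L = self.K * (self.m + 1)

    def cv(
        self,
        y: np.ndarray,
        fold_of: np.ndarray,
        config: QmdrConfig,
    ) -> tuple[np.ndarray, np.ndarray]:
        """One full CV pass: per-fold winning combination and testing score."""
        y = np.asarray(y, dtype=float)
        K, m, L = self.K, self.m, self.L
        fr = self.flat.ravel()
        yK = np.repeat(y, K)
        y2K = np.repeat(y * y, K)
        cnt_all = np.bincount(fr, minlength=L)
        sum_all = np.bincount(fr, weights=yK, minlength=L)
        ssq_all = np.bincount(fr, weights=y2K, minlength=L)

        n_folds = int(fold_of.max()) + 1
        winners = np.empty(n_folds, dtype=np.int64)
        test_scores = np.empty(n_folds)
        strict = config.tie_rule == "low"
        empty_high = config.empty_cell_rule == "high"

        for f in range(n_folds):
            te = fold_of == f
            ft = self.flat[te].ravel()
            yt = np.repeat(y[te], K)
            cnt_te = np.bincount(ft, minlength=L)
            sum_te = np.bincount(ft, weights=yt, minlength=L)
            ssq_te = np.bincount(ft, weights=yt * yt, minlength=L)

            cnt = (cnt_all - cnt_te).reshape(K, m + 1)[:, :m]
            s = (sum_all - sum_te).reshape(K, m + 1)[:, :m]
            q = (ssq_all - ssq_te).reshape(K, m + 1)[:, :m]

            tot_n = cnt.sum(axis=1)
            tot_s = s.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                overall = tot_s / tot_n
                cell_mean = s / np.maximum(cnt, 1)
            nonempty = cnt > 0
            if strict:
                high = nonempty & (cell_mean > overall[:, None])
            else:
                high = nonempty & (cell_mean >= overall[:, None])
            if empty_high:
                high |= ~nonempty

            n_h = np.einsum("ij,ij->i", cnt, high)
            s_h = np.einsum("ij,ij->i", s, high)
            q_h = np.einsum("ij,ij->i", q, high)
            t_tr = _vector_t(
                n_h, s_h, q_h, tot_n - n_h, tot_s - s_h, q.sum(axis=1) - q_h, config.t_variant
            )
            w = int(np.argmax(t_tr))  # ties -> first, i.e. lexicographically first tuple
            winners[f] = w

            cte = cnt_te.reshape(K, m + 1)[w, :m]
            ste = sum_te.reshape(K, m + 1)[w, :m]
            qte = ssq_te.reshape(K, m + 1)[w, :m]
            hw = high[w]
            nh = float((cte * hw).sum())
            sh = float((ste * hw).sum())
            qh = float((qte * hw).sum())
            test_scores[f] = _vector_t(
                np.array([nh]),
                np.array([sh]),
                np.array([qh]),
                np.array([cte.sum() - nh]),
                np.array([ste.sum() - sh]),
                np.array([qte.sum() - qh]),
                config.t_variant,
            )[0]
        return winners, test_scores


def _codes(genotypes: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.values, genotypes.snp_ids
    arr = np.asarray(genotypes)
    return arr, [f"snp{j + 1}" for j in range(arr.shape[1])]


def _aggregate(
    winners: np.ndarray,
    test_scores: np.ndarray,
    combos: list[tuple[int, ...]],
    snp_ids: list[str],
    k: int,
    n_folds: int,
) -> list[QmdrModel]:
    models = []
    for w in sorted(set(winners.tolist())):
        sel = winners == w
        loci = combos[w]
        models.append(
            QmdrModel(
                loci=loci,
                snp_ids=tuple(snp_ids[j] for j in loci),
                k=k,
                fold_wins=int(sel.sum()),
                n_folds=n_folds,
                avg_testing_score=float(test_scores[sel].mean()),
            )
        )
    models.sort(key=lambda m: (-m.fold_wins, -m.avg_testing_score, m.loci))
    return models


def run_cv(
    genotypes: GenotypeMatrix | np.ndarray,
    pheno: np.ndarray,
    k: int,
    config: QmdrConfig | None = None,
) -> list[QmdrModel]:
    """Exhaustive order-k QMDR search under cross-validation.

    Individuals are shuffled by ``config.rng_seed`` into near-equal folds;
    every fold's winner (maximum training score over all C(p, k)
    combinations) is recorded, and winners are aggregated into
    :class:`QmdrModel` records whose ``fold_wins`` sum to ``n_folds``.
    Empirical p-values are attached separately by
    :func:`permutation_pvalues`.
    """
    config = config or QmdrConfig()
    codes, snp_ids = _codes(genotypes)
    y = np.asarray(pheno, dtype=float)
    n = codes.shape[0]
    if n < config.n_folds:
        raise ValueError("fewer individuals than folds")
    search = _OrderSearch(codes, k)
    rng = np.random.default_rng(config.rng_seed)
    fold_of = _fold_assignment(n, config.n_folds, rng)
    winners, scores = search.cv(y, fold_of, config)
    return _aggregate(winners, scores, search.combos, snp_ids, k, config.n_folds)


def _empirical_p(observed: float, perm_scores: np.ndarray) -> float:
    """Add-one permutation p-value: (1 + #{perm >= obs}) / (B + 1)."""
    perm_scores = np.asarray(perm_scores, dtype=float)
    return float((1 + np.sum(perm_scores >= observed)) / (perm_scores.size + 1))


def permutation_pvalues(
    genotypes: GenotypeMatrix | np.ndarray,
    pheno: np.ndarray,
    k: int,
    config: QmdrConfig | None = None,
    models: list[QmdrModel] | None = None,
) -> list[QmdrModel]:
    """Attach empirical p-values by phenotype permutation.

    For each of B permutations the phenotype is shuffled (genotypes
    fixed), folds are re-drawn from the permutation RNG stream, the whole
    order-k search is re-run, and the permutation's best-model average
    testing score is recorded.  Every observed model is ranked against this
    common max-statistic null with the add-one estimator, so p-values are
    never exactly zero and are directly comparable across models of the
    same order.
    """
    config = config or QmdrConfig()
    codes, snp_ids = _codes(genotypes)
    y = np.asarray(pheno, dtype=float)
    if models is None:
        models = run_cv(genotypes, pheno, k, config)
    search = _OrderSearch(codes, k)
    n = codes.shape[0]
    prng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0x9E3779]))
    B = config.n_permutations
    perm_best = np.empty(B)
    for b in range(B):
        yp = prng.permutation(y)
        fold_of = _fold_assignment(n, config.n_folds, prng)
        winners, scores = search.cv(yp, fold_of, config)
        # best model of the permutation: max fold wins, tie -> max avg score
        wins = np.bincount(winners)
        cand = np.flatnonzero(wins == wins.max())
        best_score = -np.inf
        for c in cand:
            avg = scores[winners == c].mean()
            if avg > best_score:
                best_score = avg
        perm_best[b] = best_score
    return [
        replace(m, empirical_p=_empirical_p(m.avg_testing_score, perm_best)) for m in models
    ]


def best_model(models: list[QmdrModel]) -> QmdrModel:
    """Maximum-CVC model; ties broken by average testing score, then loci."""
    if not models:
        raise ValueError("no models to choose from")
    return min(models, key=lambda m: (-m.fold_wins, -m.avg_testing_score, m.loci))


def results_table(models_by_order: dict[int, list[QmdrModel]]) -> pd.DataFrame:
    """Flat report: order, loci, CVC as 'm/10', score, empirical p."""
    rows = []
    for k in sorted(models_by_order):
        for m in sorted(models_by_order[k], key=lambda x: (-x.fold_wins, -x.avg_testing_score)):
            rows.append(
                {
                    "order": k,
                    "loci": ",".join(m.snp_ids),
                    "cvc": f"{m.fold_wins}/{m.n_folds}",
                    "avg_testing_score": m.avg_testing_score,
                    "empirical_p": m.empirical_p,
                }
            )
    return pd.DataFrame(rows)
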