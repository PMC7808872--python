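"""QMDR: cell partitioning, t scores, CV search and permutation p-values."""

import numpy as np
import pytest
from scipy import stats

from epiclock.datatypes import GenotypeMatrix, SnpRecord
from epiclock.qmdr import (
    QmdrConfig,
    QmdrModel,
    _empirical_p,
    best_model,
    enumerate_combinations,
    partition_cells,
    permutation_pvalues,
    pooled_t_score,
    run_cv,
)


def test_combination_enumeration_counts_and_order():
    assert len(enumerate_combinations(17, 2)) == 136
    assert len(enumerate_combinations(17, 3)) == 680
    assert enumerate_combinations(3, 3) == [(0, 1, 2)]
    combos = enumerate_combinations(5, 2)
    assert combos == sorted(combos)
    with pytest.raises(ValueError):
        enumerate_combinations(4, 5)


def test_partition_all_ties_go_low():
    g = np.array([0, 1, 2, 0, 1, 2])
    part = partition_cells(g, np.full(6, 30.0))
    assert not part.cell_label.any()


def test_partition_single_locus_means():
    # cell means 35 / 30 / 25 against overall 30: high, low (tie), low
    g = np.repeat([0, 1, 2], 4)
    y = np.concatenate([np.full(4, 35.0), np.full(4, 30.0), np.full(4, 25.0)])
    part = partition_cells(g, y)
    assert list(part.cell_label) == [True, False, False]
    assert part.train_overall_mean == pytest.approx(30.0)


def test_partition_negation_swaps_labels(rng):
    g = rng.integers(0, 3, size=(200, 2))
    y = rng.normal(30, 6, size=200)  # continuous: exact ties have measure zero
    a = partition_cells(g, y)
    b = partition_cells(g, -y)
    occupied = ~a.empty
    assert np.array_equal(a.cell_label[occupied], ~b.cell_label[occupied])


def test_partition_empty_cells_follow_rule():
    g = np.array([0, 0, 2, 2])  # cell 1 never observed
    y = np.array([40.0, 41.0, 20.0, 21.0])
    low = partition_cells(g, y)
    assert low.empty[1] and not low.cell_label[1]
    high = partition_cells(g, y, empty_cell_rule="high")
    assert high.cell_label[1]


def test_t_score_known_groups():
    g = np.repeat([0, 2], 3)
    y = np.array([4.0, 5.0, 6.0, 1.0, 2.0, 3.0])
    part = partition_cells(g, y)
    t = pooled_t_score(part, g, y)
    # mean diff 3, pooled variance 1, se = sqrt(2/3)
    assert t == pytest.approx(3 * np.sqrt(1.5))
    assert t == pytest.approx(stats.ttest_ind(y[:3], y[3:], equal_var=True).statistic)


def test_t_score_degenerate_group_is_zero():
    g = np.zeros(6, dtype=int)
    y = np.arange(6.0)
    part = partition_cells(g, y)
    assert pooled_t_score(part, g, y) == 0.0


def test_t_score_location_invariant(rng):
    g = rng.integers(0, 3, size=150)
    y = rng.normal(30, 6, size=150)
    part = partition_cells(g, y)
    assert pooled_t_score(part, g, y + 100.0) == pytest.approx(
        pooled_t_score(part, g, y), abs=1e-9
    )


def test_t_score_matches_scipy_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(20, 80))
        g = rng.integers(0, 3, size=(n, 2))
        y = rng.normal(30, 6, size=n)
        part = partition_cells(g, y)
        cells = (g[:, 0] * 3 + g[:, 1]).astype(int)
        is_high = part.cell_label[cells]
        if is_high.sum() < 2 or (~is_high).sum() < 2:
            continue
        expected = stats.ttest_ind(y[is_high], y[~is_high], equal_var=True).statistic
        assert pooled_t_score(part, g, y) == pytest.approx(expected, abs=1e-12)


def test_welch_variant_matches_scipy(rng):
    g = rng.integers(0, 3, size=(120, 1))
    y = rng.normal(30, 6, size=120)
    part = partition_cells(g, y)
    is_high = part.cell_label[g[:, 0]]
    expected = stats.ttest_ind(y[is_high], y[~is_high], equal_var=False).statistic
    assert pooled_t_score(part, g, y, variant="welch") == pytest.approx(expected, abs=1e-12)


def _random_study(rng, n=200, p=5):
    vals = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    snps = [SnpRecord(f"s{j}", "G", "1", j + 1, ("A", "B")) for j in range(p)]
    gm = GenotypeMatrix(vals, snps, [f"i{i}" for i in range(n)])
    y = rng.normal(30, 6, size=n)
    return gm, y


def test_single_candidate_wins_every_fold(rng):
    gm, y = _random_study(rng, p=2)
    models = run_cv(gm, y, 2, QmdrConfig(rng_seed=3, n_permutations=1))
    assert len(models) == 1
    assert models[0].fold_wins == 10 and models[0].cvc == 1.0


def test_fold_wins_sum_to_fold_count(rng):
    gm, y = _random_study(rng)
    for k in (1, 2, 3):
        models = run_cv(gm, y, k, QmdrConfig(rng_seed=11, n_permutations=1))
        assert sum(m.fold_wins for m in models) == 10


def test_search_is_bit_reproducible(rng):
    gm, y = _random_study(rng)
    cfg = QmdrConfig(rng_seed=42, n_permutations=19)
    a = permutation_pvalues(gm, y, 2, cfg)
    b = permutation_pvalues(gm, y, 2, cfg)
    assert [(m.loci, m.fold_wins, m.avg_testing_score, m.empirical_p) for m in a] == [
        (m.loci, m.fold_wins, m.avg_testing_score, m.empirical_p) for m in b
    ]


def test_phenotype_negation_preserves_winners_and_scores(rng):
    gm, y = _random_study(rng)
    cfg = QmdrConfig(rng_seed=5, n_permutations=1)
    a = run_cv(gm, y, 2, cfg)
    b = run_cv(gm, -y, 2, cfg)
    assert [(m.loci, m.fold_wins) for m in a] == [(m.loci, m.fold_wins) for m in b]
    for ma, mb in zip(a, b):
        assert mb.avg_testing_score == pytest.approx(ma.avg_testing_score, abs=1e-9)


def test_missing_genotypes_excluded_per_tuple():
    # individual 0 is missing at locus 0 only: it must not affect the
    # (1,) model but must be absent from models containing locus 0
    rng = np.random.default_rng(0)
    vals = rng.integers(0, 3, size=(60, 2)).astype(np.int8)
    vals[0, 0] = -1
    snps = [SnpRecord(f"s{j}", "G", "1", j + 1, ("A", "B")) for j in range(2)]
    gm = GenotypeMatrix(vals, snps, [f"i{i}" for i in range(60)])
    y = rng.normal(30, 6, size=60)
    part0 = partition_cells(vals[:, [0]], y)
    # manual: partition on complete rows only
    ok = vals[:, 0] >= 0
    ref = partition_cells(vals[ok][:, [0]], y[ok])
    assert np.array_equal(part0.cell_label, ref.cell_label)
    assert part0.train_overall_mean == pytest.approx(ref.train_overall_mean)


def test_empirical_p_formula_bounds():
    assert _empirical_p(-5.0, np.full(19, 1.0)) == 1.0
    assert _empirical_p(10.0, np.zeros(999)) == pytest.approx(0.001)
    assert _empirical_p(0.5, np.array([0.4, 0.6, 0.5])) == pytest.approx(3 / 4)


def test_permutation_pvalues_attach_to_all_models(rng):
    gm, y = _random_study(rng, n=120, p=4)
    cfg = QmdrConfig(rng_seed=2, n_permutations=19)
    models = permutation_pvalues(gm, y, 2, cfg)
    B = cfg.n_permutations
    for m in models:
        assert m.empirical_p is not None
        assert 1 / (B + 1) <= m.empirical_p <= 1.0


def _model(loci, wins, score):
    return QmdrModel(
        loci=loci, snp_ids=tuple(f"s{j}" for j in loci), k=len(loci),
        fold_wins=wins, n_folds=10, avg_testing_score=score,
    )


def test_best_model_tiebreaks():
    models = [_model((0, 1), 8, 1.1), _model((0, 2), 1, 2.0), _model((1, 2), 1, 0.5)]
    assert best_model(models).loci == (0, 1)
    tie = [_model((0, 1), 5, 0.9), _model((0, 2), 5, 1.2)]
    assert best_model(tie).loci == (0, 2)
    lex = [_model((0, 2), 5, 1.0), _model((0, 1), 5, 1.0)]
    assert best_model(lex).loci == (0, 1)
    assert best_model([_model((3, 4), 10, 0.1)]).loci == (3, 4)
    with pytest.raises(ValueError):
        best_model([])


def test_config_validation():
    with pytest.raises(ValueError):
        QmdrConfig(n_folds=1)
    with pytest.raises(ValueError):
        QmdrConfig(n_permutations=0)
    with pytest.raises(ValueError):
        QmdrConfig(t_variant="student")
    with pytest.raises(ValueError):
        run_cv(np.zeros((30, 2), dtype=np.int8), np.zeros(30), 3)
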