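"""The synthetic-cohort generator: determinism, MAFs, planted effects."""

import numpy as np
import pytest

from epiclock.simulate import (
    SCENARIOS,
    EffectSpec,
    SimulationConfig,
    SnpSpec,
    make_fixture,
    panel_specs,
    pure_epistasis_offsets,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotype,
)
from epiclock.single_locus import fit_additive
from epiclock.snp_qc import genotype_counts, hwe_exact_test


def test_same_seed_gives_identical_datasets():
    a = make_fixture("null_cohort", rng_seed=77)
    b = make_fixture("null_cohort", rng_seed=77)
    assert np.array_equal(a.genotypes.values, b.genotypes.values)
    assert np.array_equal(a.phenotype, b.phenotype)
    assert a.covariates.equals(b.covariates)
    c = make_fixture("null_cohort", rng_seed=78)
    assert not np.array_equal(a.phenotype, c.phenotype)


def test_empirical_mafs_converge_to_spec(rng):
    specs = [SnpSpec(f"s{i}", "G", maf) for i, maf in enumerate([0.05, 0.2, 0.5])]
    config = SimulationConfig(n_individuals=10000, snp_specs=specs, rng_seed=4)
    gm = simulate_genotypes(config)
    for j, s in enumerate(specs):
        emp = gm.values[:, j].mean() / 2
        assert emp == pytest.approx(s.maf, abs=0.01)


def test_vanishing_maf_gives_monomorphic_column():
    specs = [SnpSpec("s0", "G", 1e-9)]
    gm = simulate_genotypes(SimulationConfig(n_individuals=200, snp_specs=specs, rng_seed=1))
    assert (gm.values == 0).all()


def test_invalid_maf_rejected():
    with pytest.raises(ValueError, match="maf"):
        SimulationConfig(snp_specs=[SnpSpec("s0", "G", 0.7)])


def test_heterozygote_excess_snp_fails_hwe():
    specs = [SnpSpec("bad", "G", 0.48, inbreeding=-0.9)]
    gm = simulate_genotypes(SimulationConfig(n_individuals=1000, snp_specs=specs, rng_seed=9))
    assert hwe_exact_test(*genotype_counts(gm.values[:, 0])) < 1e-6


def test_cohort_shape_matches_defaults():
    config = SimulationConfig(n_individuals=5000, rng_seed=3)
    rng = np.random.default_rng(config.rng_seed)
    cov = simulate_covariates(config, rng)
    gm = simulate_genotypes(config, rng)
    y = simulate_phenotype(gm, cov, EffectSpec(), rng)
    assert cov["sex"].mean() == pytest.approx(0.628, abs=0.03)
    assert (cov["age"] >= 18).all() and (cov["age"] <= 59).all()
    assert y.mean() == pytest.approx(30.7, abs=0.3)
    assert y.std(ddof=1) == pytest.approx(6.1, abs=0.3)


def test_noiseless_additive_effect_is_exact():
    specs = [SnpSpec("s0", "G", 0.4)]
    config = SimulationConfig(n_individuals=50, snp_specs=specs, rng_seed=2)
    rng = np.random.default_rng(2)
    cov = simulate_covariates(config, rng)
    gm = simulate_genotypes(config, rng)
    y = simulate_phenotype(
        gm, cov, EffectSpec(noise_sd=0.0, additive_betas={"s0": 1.0}), rng
    )
    assert np.allclose(y, 30.7 + gm.values[:, 0])


def test_covariate_effects_enter_linearly():
    config = SimulationConfig(n_individuals=40, snp_specs=[SnpSpec("s0", "G", 0.3)], rng_seed=6)
    rng = np.random.default_rng(6)
    cov = simulate_covariates(config, rng)
    gm = simulate_genotypes(config, rng)
    y = simulate_phenotype(gm, cov, EffectSpec(noise_sd=0.0, covariate_betas=(0.1, -2.0)), rng)
    expected = 30.7 + 0.1 * cov["age"].to_numpy() - 2.0 * cov["sex"].to_numpy()
    assert np.allclose(y, expected)


@pytest.mark.parametrize("mafs", [(0.5, 0.5), (0.459, 0.452), (0.3, 0.2, 0.4)])
def test_epistasis_offsets_have_silent_marginals(mafs):
    k = len(mafs)
    off = pure_epistasis_offsets(mafs, 3.0).reshape((3,) * k)
    probs = []
    for q in mafs:
        p = 1 - q
        probs.append(np.array([p * p, 2 * p * q, q * q]))
    for axis in range(k):
        w = np.ones((3,) * k)
        for a, pr in enumerate(probs):
            if a != axis:
                w = w * pr.reshape([3 if d == a else 1 for d in range(k)])
        marg = (off * w).sum(axis=tuple(a for a in range(k) if a != axis)) / w.sum(
            axis=tuple(a for a in range(k) if a != axis)
        )
        assert np.all(np.abs(marg) < 1e-10)
    assert np.max(np.abs(off)) > 1.0  # the interaction itself is not degenerate


def test_pure_epistasis_leaves_single_locus_silent():
    bundle = make_fixture("planted_pair", rng_seed=31)
    config = bundle.config
    # large-n check: marginal additive effects at the planted loci stay
    # within sampling noise of zero
    big = SimulationConfig(n_individuals=5000, snp_specs=config.snp_specs, rng_seed=31)
    rng = np.random.default_rng(31)
    cov = simulate_covariates(big, rng)
    gm = simulate_genotypes(big, rng)
    y = simulate_phenotype(gm, cov, bundle.effect_spec, rng)
    for snp_id in bundle.effect_spec.interaction[0]:
        res = fit_additive(y, gm.values[:, gm.index_of(snp_id)])
        assert abs(res.coefficient) <= 3 * res.se


def test_ld_block_genotypes_match_block_marginals():
    bundle = make_fixture("ld_gene_block")
    gm = bundle.genotypes
    cols = gm.genes()["BHLHB2"]
    # haplotypes (00,01,10,11) at (0.4,0.3,0.2,0.1): allele-1 frequency is
    # 0.3 at the first SNP and 0.4 at the second
    emp0 = gm.values[:, cols[0]].mean() / 2
    emp1 = gm.values[:, cols[1]].mean() / 2
    assert emp0 == pytest.approx(0.3, abs=0.03)
    assert emp1 == pytest.approx(0.4, abs=0.03)


def test_missingness_rate_applied():
    config = SimulationConfig(
        n_individuals=2000, snp_specs=panel_specs(), missing_rate=0.05, rng_seed=8
    )
    gm = simulate_genotypes(config)
    assert gm.missing_mask.mean() == pytest.approx(0.05, abs=0.01)


def test_unknown_scenario_lists_options():
    with pytest.raises(ValueError) as err:
        make_fixture("nope")
    for s in SCENARIOS:
        assert s in str(err.value)


def test_bounded_phenotype_stays_in_questionnaire_range():
    config = SimulationConfig(n_individuals=3000, rng_seed=5, bound_to_cs_range=True)
    rng = np.random.default_rng(5)
    cov = simulate_covariates(config, rng)
    gm = simulate_genotypes(config, rng)
    y = simulate_phenotype(gm, cov, EffectSpec(), rng, bound_to_cs_range=True)
    assert y.min() >= 13 and y.max() <= 55
    assert np.allclose(y, np.round(y))
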