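"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a candidate-gene chronotype study: ~19 tag SNPs in
eight clock genes with minor allele frequencies between roughly 0.05 and
0.5, a cohort of ~1,300 young adults (about 63% female, ages concentrated
in the 20s-30s), and a bounded quantitative morningness score with mean
~30.7 and SD ~6.1.  Ground-truth effects — additive per-allele shifts,
age/sex covariate effects, and k-locus cell-mean interaction offsets (in
particular *pure epistasis* patterns whose single-locus marginal means are
constant) — can be planted so every analysis stage has closed-loop
recovery tests.

Hardy-Weinberg violations are parameterised by an inbreeding-style
coefficient F acting on heterozygosity (negative F = heterozygote
excess); within-gene linkage disequilibrium can be induced by drawing
genotypes as sums of two haplotypes from specified block frequencies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, SnpRecord

# Tag-SNP panel of eight clock genes; MAFs typical of East Asian reference
# panels.  The first 17 are Hardy-Weinberg clean; the two PER1 SNPs are the
# panel's designated HWE violators (used only by scenarios that plant
# heterozygote excess, with MAF near 0.5 so extreme negative F is feasible).
CLOCK_GENE_PANEL: list[tuple[str, str, str, str, int, float]] = [
    # (gene, rsid, alleles, chromosome, position, maf)
    ("BHLHB2", "rs6442925", "CT", "3", 4972191, 0.047),
    ("BHLHB2", "rs2137947", "CT", "3", 4989276, 0.323),
    ("CLOCK", "rs1801260", "CT", "4", 55435202, 0.099),
    ("CLOCK", "rs3805148", "AC", "4", 55440643, 0.349),
    ("CLOCK", "rs12504300", "CG", "4", 55482360, 0.379),
    ("CLOCK", "rs4864542", "CG", "4", 55487920, 0.351),
    ("CLOCK", "rs12649507", "AG", "4", 55514317, 0.352),
    ("CSNK1E", "rs135745", "CG", "22", 38287631, 0.223),
    ("CSNK1E", "rs1534891", "CT", "22", 38299094, 0.093),
    ("CSNK1E", "rs2075984", "AC", "22", 38294883, 0.408),
    ("NR1D1", "rs2314339", "CT", "17", 40096959, 0.459),
    ("NR1D1", "rs2269457", "AG", "17", 40098436, 0.495),
    ("PER2", "rs2304672", "CG", "2", 238277948, 0.063),
    ("PER2", "rs2304669", "AG", "2", 238257022, 0.116),
    ("PER3", "rs228669", "AG", "1", 7809988, 0.257),
    ("TIMELESS", "rs4630333", "AG", "12", 56443632, 0.452),
    ("TIMELESS", "rs1082214", "AG", "12", 56452706, 0.095),
]
PER1_VIOLATOR_SNPS: list[tuple[str, str, str, str, int, float]] = [
    ("PER1", "rs2735611", "CT", "17", 8044280, 0.480),
    ("PER1", "rs885747", "CG", "17", 8045667, 0.500),
]


@dataclass
class SnpSpec:
    """How to draw one SNP: MAF plus an optional HWE distortion."""

    id: str
    gene: str
    maf: float
    chromosome: str = "1"
    position: int = 0
    alleles: tuple[str, str] = ("A", "B")
    inbreeding: float = 0.0  # F; negative values give heterozygote excess

    def genotype_probs(self) -> np.ndarray:
        """P(genotype = 0, 1, 2) under the inbreeding-distorted model."""
        q = self.maf
        p = 1.0 - q
        f = self.inbreeding
        probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
        probs = np.clip(probs, 0.0, None)
        return probs / probs.sum()


def panel_specs(include_violators: bool = False, violator_f: float = -0.9) -> list[SnpSpec]:
    """SnpSpecs for the built-in clock-gene panel (17 or 19 SNPs)."""
    rows = list(CLOCK_GENE_PANEL) + (list(PER1_VIOLATOR_SNPS) if include_violators else [])
    specs = []
    for gene, rsid, bases, chrom, pos, maf in rows:
        f = violator_f if gene == "PER1" else 0.0
        specs.append(
            SnpSpec(
                id=rsid,
                gene=gene,
                maf=maf,
                chromosome=chrom,
                position=pos,
                alleles=(bases[0], bases[1]),
                inbreeding=f,
            )
        )
    return specs


@dataclass
class SimulationConfig:
    """Cohort shape: who is simulated, before any phenotype effects."""

    n_individuals: int = 1293
    snp_specs: list[SnpSpec] = field(default_factory=panel_specs)
    ld_blocks: dict[str, tuple[list[tuple[int, ...]], list[float]]] | None = None
    sex_fraction_female: float = 0.628
    age_mean_male: float = 27.5
    age_sd_male: float = 8.3
    age_mean_female: float = 23.7
    age_sd_female: float = 3.5
    age_range: tuple[float, float] = (18.0, 59.0)
    missing_rate: float = 0.0
    bound_to_cs_range: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for s in self.snp_specs:
            if not (0.0 <= s.maf <= 0.5):
                raise ValueError(f"SNP {s.id}: maf {s.maf} outside [0, 0.5]")


@dataclass
class EffectSpec:
    """Ground truth for the phenotype model.

    phenotype = baseline + sum(additive beta * minor-allele count)
              + beta_age * age + beta_sex * sex(F=1)
              + interaction cell offset + N(0, noise_sd^2)
    """

    baseline_mean: float = 30.7
    noise_sd: float = 6.1
    additive_betas: dict[str, float] = field(default_factory=dict)
    covariate_betas: tuple[float, float] = (0.0, 0.0)  # (age, sex)
    interaction: tuple[tuple[str, ...], np.ndarray] | None = None  # (snp ids, 3**k offsets)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.interaction is not None:
            loci, offsets = self.interaction
            offsets = np.asarray(offsets, dtype=float).ravel()
            if offsets.size != 3 ** len(loci):
                raise ValueError("interaction offsets must have 3**k entries")
            self.interaction = (tuple(loci), offsets)

    def to_json(self) -> str:
        d = asdict(self)
        if self.interaction is not None:
            d["interaction"] = {
                "loci": list(self.interaction[0]),
                "offsets": self.interaction[1].tolist(),
            }
        return json.dumps(d, indent=2)


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """iid, sex (0=M, 1=F) and age drawn from the configured cohort shape."""
    n = config.n_individuals
    sex = (rng.random(n) < config.sex_fraction_female).astype(int)
    mean = np.where(sex == 1, config.age_mean_female, config.age_mean_male)
    sd = np.where(sex == 1, config.age_sd_female, config.age_sd_male)
    age = np.clip(rng.normal(mean, sd), *config.age_range)
    iids = [f"ind{i + 1:05d}" for i in range(n)]
    return pd.DataFrame({"iid": iids, "sex": sex, "age": np.round(age, 1)})


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw the genotype matrix.

    Independent SNPs are drawn from their (possibly inbreeding-distorted)
    genotype distribution; genes listed in ``ld_blocks`` are instead drawn
    as two haplotypes per individual from the block's haplotype
    frequencies, inducing within-gene LD while leaving other genes
    independent.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    n = config.n_individuals
    specs = config.snp_specs
    values = np.zeros((n, len(specs)), dtype=np.int8)

    ld_genes = set(config.ld_blocks or {})
    for j, s in enumerate(specs):
        if s.gene in ld_genes:
            continue
        values[:, j] = rng.choice(3, size=n, p=s.genotype_probs())

    gene_cols: dict[str, list[int]] = {}
    for j, s in enumerate(specs):
        gene_cols.setdefault(s.gene, []).append(j)
    for gene, (haps, freqs) in (config.ld_blocks or {}).items():
        cols = gene_cols[gene]
        haps_arr = np.array(haps, dtype=np.int8)
        if haps_arr.shape[1] != len(cols):
            raise ValueError(f"{gene}: haplotypes have {haps_arr.shape[1]} alleles "
                             f"for {len(cols)} panel SNPs")
        freqs = np.asarray(freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError(f"{gene}: haplotype frequencies must sum to 1")
        draw = rng.choice(len(haps_arr), size=(n, 2), p=freqs)
        values[:, cols] = haps_arr[draw[:, 0]] + haps_arr[draw[:, 1]]

    if config.missing_rate > 0:
        miss = rng.random(values.shape) < config.missing_rate
        values[miss] = -1

    snps = [
        SnpRecord(id=s.id, gene=s.gene, chromosome=s.chromosome,
                  position=s.position, alleles=s.alleles, maf=s.maf)
        for s in specs
    ]
    iids = [f"ind{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(values=values, snps=snps, iids=iids)


def pure_epistasis_offsets(mafs: tuple[float, ...], magnitude: float) -> np.ndarray:
    """Cell-mean offsets with no marginal (single-locus) signal.

    Starts from a k-dimensional checkerboard of +/- ``magnitude`` and
    projects out the grand mean and every single-locus main effect under
    the product Hardy-Weinberg cell distribution, so the conditional mean
    offset given any one locus's genotype is exactly zero — genuine
    epistasis with silent marginals.  At MAF 0.5 the checkerboard is
    already centred and survives unchanged.
    """
    k = len(mafs)
    shape = (3,) * k
    idx = np.indices(shape).sum(axis=0)
    table = magnitude * np.where(idx % 2 == 0, 1.0, -1.0)

    probs = []
    for q in mafs:
        p = 1.0 - q
        probs.append(np.array([p * p, 2 * p * q, q * q]))

    def _axis_mean(t: np.ndarray, axis: int) -> np.ndarray:
        w = np.ones(shape)
        for a, pr in enumerate(probs):
            if a != axis:
                w = w * pr.reshape([3 if d == a else 1 for d in range(k)])
        num = (t * w).sum(axis=tuple(a for a in range(k) if a != axis))
        den = w.sum(axis=tuple(a for a in range(k) if a != axis))
        return num / den

    grand_w = np.ones(shape)
    for a, pr in enumerate(probs):
        grand_w = grand_w * pr.reshape([3 if d == a else 1 for d in range(k)])
    table = table - (table * grand_w).sum()
    for axis in range(k):
        marg = _axis_mean(table, axis)
        table = table - marg.reshape([3 if d == axis else 1 for d in range(k)])
    # verify: all single-locus marginal means vanish
    for axis in range(k):
        assert np.all(np.abs(_axis_mean(table, axis)) < 1e-10)
    return table.ravel()


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    spec: EffectSpec,
    rng: np.random.Generator | int = 0,
    bound_to_cs_range: bool = False,
) -> np.ndarray:
    """Phenotype vector under the ground-truth effect model.

    Missing genotypes contribute no additive or interaction effect.  With
    ``bound_to_cs_range`` the result is rounded and clipped into [13, 55]
    (the questionnaire's support), which slightly shrinks the variance.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = genotypes.n_individuals
    y = np.full(n, spec.baseline_mean, dtype=float)

    for snp_id, beta in spec.additive_betas.items():
        g = genotypes.values[:, genotypes.index_of(snp_id)].astype(float)
        y += beta * np.where(g < 0, 0.0, g)

    b_age, b_sex = spec.covariate_betas
    y += b_age * np.asarray(covariates["age"], dtype=float)
    y += b_sex * np.asarray(covariates["sex"], dtype=float)

    if spec.interaction is not None:
        loci, offsets = spec.interaction
        cols = [genotypes.index_of(s) for s in loci]
        sub = genotypes.values[:, cols]
        complete = ~np.any(sub == -1, axis=1)
        cell = np.zeros(n, dtype=int)
        for j in range(len(cols)):
            cell = cell * 3 + np.where(sub[:, j] < 0, 0, sub[:, j])
        y[complete] += offsets[cell[complete]]

    y += rng.normal(0.0, spec.noise_sd, size=n)
    if bound_to_cs_range:
        y = np.clip(np.round(y), 13, 55)
    return y


@dataclass
class DatasetBundle:
    """One simulated study: genotypes, covariates, phenotype and its truth."""

    name: str
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    phenotype: np.ndarray
    effect_spec: EffectSpec
    config: SimulationConfig


SCENARIOS = ("null_cohort", "planted_pair", "planted_triple", "hwe_violators", "ld_gene_block")

# default seeds making each named scenario a fixed, reproducible dataset
_SCENARIO_SEEDS = {
    "null_cohort": 2020,
    "planted_pair": 2021,
    "planted_triple": 2022,
    "hwe_violators": 2023,
    "ld_gene_block": 2024,
}

PLANTED_PAIR = ("rs2314339", "rs4630333")
PLANTED_TRIPLE = ("rs2314339", "rs4630333", "rs228669")


def make_fixture(name: str, rng_seed: int | None = None) -> DatasetBundle:
    """Build one of the named, seeded study scenarios.

    * ``null_cohort`` — n=1293, the 17-SNP panel, no effects.
    * ``planted_pair`` — n=1000, pure-epistasis cell offsets of magnitude
      0.5 * noise SD at the NR1D1 x TIMELESS pair.
    * ``planted_triple`` — n=1000, magnitude 1.0 * noise SD at the
      NR1D1 x TIMELESS x PER3 triple.
    * ``hwe_violators`` — n=1000, 19 SNPs of which the two PER1 SNPs are
      drawn with inbreeding coefficient -0.9 (strong heterozygote excess).
    * ``ld_gene_block`` — n=1000, the BHLHB2 pair drawn from 2-SNP
      haplotypes with frequencies (0.4, 0.3, 0.2, 0.1).

    Passing ``rng_seed`` overrides the scenario's fixed default seed.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {', '.join(SCENARIOS)}")
    seed = _SCENARIO_SEEDS[name] if rng_seed is None else rng_seed
    effect = EffectSpec()

    if name == "null_cohort":
        config = SimulationConfig(n_individuals=1293, snp_specs=panel_specs(), rng_seed=seed)
    elif name == "hwe_violators":
        config = SimulationConfig(
            n_individuals=1000, snp_specs=panel_specs(include_violators=True), rng_seed=seed
        )
    elif name == "planted_pair":
        config = SimulationConfig(n_individuals=1000, snp_specs=panel_specs(), rng_seed=seed)
        mafs = tuple(s.maf for s in config.snp_specs if s.id in PLANTED_PAIR)
        effect = EffectSpec(
            interaction=(PLANTED_PAIR, pure_epistasis_offsets(mafs, 0.5 * 6.1))
        )
    elif name == "planted_triple":
        config = SimulationConfig(n_individuals=1000, snp_specs=panel_specs(), rng_seed=seed)
        mafs = tuple(s.maf for s in config.snp_specs if s.id in PLANTED_TRIPLE)
        effect = EffectSpec(
            interaction=(PLANTED_TRIPLE, pure_epistasis_offsets(mafs, 1.0 * 6.1))
        )
    else:  # ld_gene_block
        haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
        config = SimulationConfig(
            n_individuals=1000,
            snp_specs=panel_specs(),
            ld_blocks={"BHLHB2": (haps, [0.4, 0.3, 0.2, 0.1])},
            rng_seed=seed,
        )

    rng = np.random.default_rng(config.rng_seed)
    covariates = simulate_covariates(config, rng)
    genotypes = simulate_genotypes(config, rng)
    phenotype = simulate_phenotype(
        genotypes, covariates, effect, rng, bound_to_cs_range=config.bound_to_cs_range
    )
    return DatasetBundle(
        name=name,
        genotypes=genotypes,
        covariates=covariates,
        phenotype=phenotype,
        effect_spec=effect,
        config=config,
    )
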