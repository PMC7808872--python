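# Methods

This note records the statistical procedures, their assumptions, the
defaults and why, and what the synthetic-data tests do and do not show.

## Phenotype: the Composite Scale of Morningness

The CS total is the sum of 13 items, three on a 1–5 scale and ten on a
1–4 scale (total support 13–55; higher = morning preference). Published
versions of the instrument differ in *which* items are five-point, and
chronotype classes depend only on the total, so the scorer takes a
per-item scale declaration (default: items 1–3 five-point). Missing item
responses are rejected, not imputed. Class cut-offs are fixed: evening
≤ 26, intermediate 27–40, morning ≥ 41. Summary-table percentages are
rounded half-up to one decimal, matching the convention of printed cohort
tables (they therefore sum to 100.0 ± 0.1).

## Hardy–Weinberg QC

Genotypes are oriented so codes count the dataset's minor allele
(columns with coded-allele frequency > 0.5 are flipped); MAF and HWE use
per-SNP complete observations. The HWE test is the exact conditional
test: given the allele counts, the heterozygote count h follows
P(h) ∝ 2^h · n! / (n_AA! · h! · n_BB!), and the two-sided p-value sums
P over all admissible h (same parity) with P(h) ≤ P(h_obs). Weights are
evaluated as exact integers, so results agree with a rational-arithmetic
enumeration oracle to machine precision, and the test is symmetric in the
two homozygote classes. Monomorphic SNPs return p = 1 (nothing to test).
The filter threshold defaults to α = 0.05; both the test and threshold are
deliberate choices — the source analysis style does not pin them down, and
the exact test is the standard for candidate-gene sample sizes and MAFs.
Note the test is conservative: its null rejection rate sits at or below
the nominal level (the test suite checks the 0.5 %–6.5 % band at n = 300).

## Single-locus regression

OLS with genotype as a 0/1/2 minor-allele count — one coefficient per SNP
in CS units per minor allele. Model 1 is unadjusted; Model 2 adds age
(years, continuous) and sex (0 = male, 1 = female; configurable, only
signs depend on it). Missing genotypes/covariates are dropped listwise per
SNP. Degenerate designs (monomorphic SNPs) yield a flagged result rather
than an exception; a constant phenotype reports coefficient 0, t 0, p 1 by
convention. Raw p-values are reported without multiple-testing correction,
matching how such candidate-gene tables are conventionally presented.

## Haplotype association

Within each gene with ≥ 2 surviving SNPs, haplotype frequencies are
estimated by EM over diplotype resolutions: the E-step weights each
individual's compatible haplotype pairs by current frequencies (factor 2
for heterozygous pairs), the M-step re-estimates frequencies from expected
counts. Numerical conventions: uniform initialisation over compatible
haplotypes, convergence when the largest frequency change < 1e-6, 1,000
iteration cap, frequencies < 1e-10 pruned, and the log-likelihood is
asserted non-decreasing at every step. With fully unambiguous phases the
estimates equal direct counts exactly; a lone double heterozygote has a
flat likelihood between coupling and repulsion and the uniform start stays
at the symmetric stationary point — a documented property, not a defect.

Association is the PLINK-style quantitative omnibus: posterior-expected
dosages (each individual's rows sum to 2) for common haplotypes
(frequency ≥ 0.01), the most frequent omitted as reference, entered jointly
into OLS; the overall F with df_num = n_common − 1 tests all haplotype
effects at once. Phase uncertainty enters only through the expectation
(single-step dosages); collinear dosage columns are dropped with a warning
and the df reduced. Genes with fewer than two common haplotypes are
skipped.

## QMDR

For loci subset S (|S| = k ≤ 3 by default), training individuals are
binned into the 3^k genotype cells; a cell is *high* iff its training mean
phenotype strictly exceeds the overall training mean. Deterministic edge
rules, all configurable: an exact tie labels the cell low; an empty
training cell is labelled low so held-out individuals landing in it are
classified, never discarded; individuals missing a genotype at any locus
of S are excluded for S only. The score is the pooled-variance two-sample
t between the pooled high and low groups (Welch available), oriented so
high > low is positive; if either group has < 2 members the score is 0,
keeping the exhaustive search total.

Cross-validation: individuals are shuffled by the run seed into 10
near-equal folds; per fold the winner maximises the training score (ties →
lexicographically first tuple), and its testing score is the t on the
held-out fold using the training partition. Fold wins are aggregated into
models whose CVC = wins/10 (wins always sum to 10 per order) and whose
reported score is the average testing t over winning folds (a single-fold
winner's score is that one fold's t). The best model per order maximises
CVC, ties broken by score then lexicographic loci.

Permutation p-values: B = 1,000 by default. Each permutation shuffles the
phenotype, re-draws folds from the permutation RNG stream, re-runs the
entire order-k search, and records the permutation's best-model average
testing score. Every reported model of that order is ranked against this
common max-statistic null with the add-one estimator
p = (1 + #{perm ≥ obs}) / (B + 1), so p-values are never 0 and are
comparable across models of one order. Re-randomising folds per
permutation (rather than freezing the observed folds) makes the observed
best score exchangeable with the permutation scores, giving exactly
calibrated p-values under the null; the test suite verifies the rejection
rate empirically. QMDR is run unadjusted (no covariates inside the
search); the whole pipeline is bit-reproducible given data and seed.

The engine precomputes per-combination cell indices once per dataset and
reduces every CV pass to phenotype bincounts over (combination, cell)
pairs, so a full order-2 search over 17 SNPs at n = 500 with ~100
permutations runs in well under a second.

## Synthetic cohorts

The generator emulates the target study design: defaults are n = 1,293,
62.8 % female, age normal by sex (male 27.5 ± 8.3, female 23.7 ± 3.5)
clipped to [18, 59], phenotype baseline 30.7 with noise SD 6.1, and a
17-SNP clock-gene panel with MAFs from 0.047 to 0.495 (a 19-SNP variant
adds two PER1 SNPs reserved for HWE-violation scenarios). Genotypes are
two independent allele draws at the SNP's MAF; HWE violations use a
one-parameter inbreeding-style distortion of heterozygosity (F < 0 gives
heterozygote excess; probabilities are clipped at 0 and renormalised, so
extreme F needs MAF near 0.5 — the PER1 violators use 0.48/0.50 with
F = −0.9). Within-gene LD is induced by drawing two haplotypes per
individual from specified block frequencies.

Phenotypes are baseline + additive per-allele effects + covariate effects
+ interaction cell offset + Gaussian noise; an optional bound-to-CS-range
mode rounds and clips into [13, 55], which slightly shrinks the variance
(acknowledged; off by default). Pure-epistasis offsets start from a
k-dimensional ± magnitude checkerboard and project out the grand mean and
every single-locus main effect under the product HWE cell distribution, so
conditional means given any one locus are exactly zero — single-locus
regressions stay null while k-locus cell means differ. Named scenarios
(`null_cohort`, `planted_pair`, `planted_triple`, `hwe_violators`,
`ld_gene_block`) are fixed, internally seeded datasets; the planted pair
uses cell offsets of 0.5 × noise SD at the NR1D1 × TIMELESS pair and the
triple 1.0 × noise SD.

What the simulations do **not** emulate: genome-wide LD structure,
realistic clock-gene haplotype blocks, genotyping error, non-Gaussian
phenotype shape, or population stratification. Passing recovery and
calibration tests therefore demonstrates correctness of the algorithms
under their own assumptions, not robustness of the study design to those
real-data complications.

## Problem sizes used in the automated checks

The test suite runs calibration and power studies at deliberately modest
scale chosen to give tight binomial error bars while staying quick:
null p-value calibration uses 200 replicates of n = 500 with 17 SNPs and
B = 99 permutations of the order-2 search; epistasis power uses 20
replicates of the planted-pair scenario at n = 1,000; oracle-equivalence
checks use 100+ random small instances per statistic at 1e-10 tolerance.

## Known limitations

* Haplotype blocks are capped at 5 SNPs (diplotype enumeration is
  exponential in heterozygous sites); genes with more SNPs would need
  windowing, which is out of scope.
* The EM landscape can in principle have multiple modes; the deterministic
  uniform start makes runs reproducible but does not search for the global
  optimum.
* QMDR orders above 3 work but are untested at scale; the exhaustive
  search is O(C(p, k)) per fold and permutation.
* Empirical p-values inherit the granularity 1/(B+1); with the default
  B = 1,000 the smallest attainable p is ≈ 0.001.
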