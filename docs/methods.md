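# Methods

## Phenotype model

Seedling growth inhibition is defined per replicate pair as
`SGI = 100 * (CFM - TFM) / CFM` (percent), where CFM is the fresh mass of
the untreated control seedling and TFM the fresh mass of its
MAMP-treated partner. The control mass must be positive; negative SGI
(growth promotion) is permitted and SGI never exceeds 100. SGI is computed
per replicate pair first and then averaged per (genotype, MAMP variant) —
pairing is the experimental unit, so the per-pair ratio is the natural
observation. Cells backed by fewer than three replicate pairs are marked
unusable and excluded downstream.

A genotype is classified *insensitive* to a MAMP class (elf18 or flg22)
when the mean of its usable variant means within that class is strictly
below 15%. The boundary value 15.0 counts as sensitive ("less than 15%"
read strictly). The class mean uses every usable variant of the class,
including weakly perceived ones. Genotypes with no usable variant in a
class get an undefined flag and are excluded from class-level statements.

Correlation structure uses Pearson coefficients between genotype-mean SGI
vectors on the panel remaining after removing every genotype insensitive
to either class (natural receptor mutants would otherwise inflate
between-class similarity at the bottom of the scale). Observations are
pairwise-complete: each variant pair uses all genotypes with usable means
for both, which maximises n per pair rather than forcing a common listwise
subset. Confidence intervals are Fisher-z at 95%; a constant column makes
a correlation undefined and it is reported as missing rather than guessed.
Group comparisons between variant means use Welch's unequal-variance t
with Satterthwaite degrees of freedom.

## Mixed model

The quantitative-genetic model for a vector y of genotype-mean SGI over n
accessions is

    y = 1*mu + u + e,   u ~ N(0, sigma_a2 * K),   e ~ N(0, sigma_e2 * I).

K is a kinship matrix over accessions. The default is the
allele-frequency standardized form K = Z Z' / m, with Z the call matrix
centred by allele frequency and scaled by sqrt(p(1-p)) over the m
polymorphic SNPs; an identity-by-state variant (mean proportion of shared
alleles) is available for fidelity with older tooling, and the method used
is recorded in scan metadata. Missing calls are mean-imputed for the
kinship computation only; a ridge of 1e-6 goes on the diagonal when the
smallest eigenvalue is negative, so downstream factorisations are stable.

Genotypes use the inbred-line convention: accessions are homozygous, calls
are single allele counts in {0, 1}, and heterozygous VCF calls are
converted to missing (with a logged count) rather than treated as an
error. MAF is computed over non-missing calls; SNPs with MAF < 0.05 are
removed before scanning (mixed-model tests are positively biased for rare
alleles), with MAF exactly 0.05 retained and 0.05 <= MAF < 0.1 carried as
a "rare" flag into results.

### REML

With delta = sigma_e2 / sigma_a2, the restricted likelihood profiled over
sigma_a2 is a one-dimensional function of delta evaluated in the
eigenbasis of S K S, where S projects out the intercept. It is maximised
on a 100-point grid of log(delta) over [-10, 10] (natural log) and refined
by bounded scalar optimisation between the best grid point's neighbours;
the returned optimum therefore never falls below any grid value. The
spectral evaluation is tested against a dense brute-force restricted
likelihood (explicit determinants and inverses) to 1e-6 at n = 10.

Heritability is h2 = sigma_a2 / (sigma_a2 + sigma_e2) = 1 / (1 + delta).
Its confidence interval inverts the likelihood ratio over delta (all delta
within chi2_1(0.95)/2 of the maximum), mapped through 1/(1+delta); the
reported standard error is the CI width over 2*1.96. This profile CI has
asymptotic 95% coverage but is honest about boundary cases: intervals can
span nearly [0, 1] at desk-scale n, because a structured kinship whose
bulk eigenvalue spectrum is narrow (m >> n Balding–Nichols genotypes)
identifies delta weakly. A flat restricted likelihood — K = I exactly —
yields an `unidentifiable` flag and NaN components rather than an
arbitrary number.

### Association scan

The scan uses the EMMAX approximation: variance components are fitted once
under the intercept-only null and held fixed; each SNP is then tested by
generalised least squares under V = sigma_a2*K + sigma_e2*I, implemented
by rotating y, the intercept and all (mean-imputed) SNP vectors through
the eigenbasis of K and solving the 2x2 weighted normal equations
vectorised across SNPs. The SNP coefficient is referred to a t
distribution with n - 2 degrees of freedom (at these n the large-sample
normal reference would be indistinguishable beyond the third decimal; the
t reference is slightly conservative). An exact mode that refits delta per
SNP exists as a debugging aid; the approximation tracks it closely away
from extremely strong signals. Per-SNP n_used records non-missing calls.
Fixed effects are intercept-only (no covariates). Calibration is checked
three ways in the test suite: identity-kinship scans reproduce OLS
p-values to 1e-6 on log10 p; type-I error on permuted phenotypes is 5% ±2
points; and genomic inflation lambda_GC under structure confounding is
lower than naive OLS regression's.

## Peaks and genes

The tail rule takes the floor(n * 0.001) smallest p-values (203 SNPs from
the 203,498-marker panel the design emulates); ties at the cutoff break by
(chromosome, position) so the count is exact and deterministic. Tail SNPs
are clumped greedily: the unassigned SNP with the smallest p becomes an
apex and absorbs all unassigned tail SNPs within 15 kb on its chromosome;
windows extend ±15 kb around the apex, clipped to [1, chromosome length].
Overlapping windows are allowed and never merged — memberships partition
the tail. Genes whose bodies intersect a window are candidates. The
apex-to-gene distance is 0 when the apex lies inside the gene, positive
(gene start − apex) when the apex is upstream of the gene start, negative
when downstream of the gene end; only the magnitude and the zero case are
comparable across sign conventions. A gene hit by several peaks of one
trait is reported once with the smallest apex p. A gene-anchored window
utility (gene boundaries ±15 kb) anchors on the gene body, not its
midpoint.

## Resampling

**Circular-shift enrichment.** The observed statistic is the frequency of
a priori candidate genes among the deduplicated genes under a trait's peak
regions. The null slides all windows of a chromosome by a single uniform
offset with wrap-around (a window straddling the end splits in two), which
preserves peak count, window lengths and within-chromosome spacing — and
therefore the local gene-density structure the windows sample. With 100
permutations the empirical p is the fraction of permuted frequencies
greater than or equal to the observed one. Frequencies (not raw counts)
are compared, because the gene denominator changes under shifting.

**Shared peaks.** Two traits share a genomic region when 30 kb intervals
centred on their peak apexes intersect; counting matches peaks one-to-one
greedily by interval endpoint, so no peak is double-used and the count is
symmetric and bounded by the smaller peak list. The null reruns the entire
scan → tail → clump pipeline per trait on phenotypes shuffled
independently across accessions (destroying both genetics and inter-trait
correlation), and significance applies a Bonferroni threshold of
0.05/21 = 0.002 for the 21 pairs of seven variants.

**Empirical p-values** are r/n, so zero is attainable — required for
significance at 0.002 with 100 permutations; the (r+1)/(n+1) variant is
available by flag for users who prefer the positively biased but
never-zero convention.

**Mutant validation.** Each candidate gene's knockout line is compared to
its wild-type background by a two-sided Wilcoxon rank-sum test on SGI
replicates (minimum 3 per arm; the emulated design uses 12), with
Benjamini–Hochberg FDR across the whole batch and confirmation at
q ≤ 0.05. BH is the reproducible standard choice here; empirical-null FDR
estimators give similar decisions at these batch sizes but depend on
tuning. Effect direction comes from the median difference (+: stronger SGI
in the mutant).

## Synthetic study generator

The generator is first-class, tested code: its defaults define the study
conditions everything downstream is validated under.

* **Genotypes**: Balding–Nichols. Ancestral allele frequencies are uniform
  on (0.05, 0.95); each of 3 subpopulations draws its frequency from a
  Beta with mean p and variance fst·p(1−p) (fst = 0.1); accessions are
  assigned to subpopulations evenly and calls are haploid 0/1 draws. This
  is the minimal structure model that makes kinship correction matter; a
  Hudson-estimator check on simulated matrices recovers the target fst
  within ±0.03. The realized MAF spectrum includes sub-0.05 alleles, so
  the MAF filter is always exercised.
* **Genome**: 5 chromosomes × 2 Mb, 5,000 SNPs placed uniformly, 500
  non-overlapping genes of 3 kb tiled uniformly — a desk-scale genome that
  keeps every test and the acceptance run in seconds while preserving the
  real panel's shape (5 chromosomes, gene-dense annotation).
* **Traits**: seven MAMP variants, three elf18 and four flg22, each with a
  baseline SGI (38–50% for perceived variants), class-shared major loci
  (two per class, 8% SGI per alt allele) and a variant-specific locus
  (6%; 12% for elf18_DC, emulating a single large-effect receptor locus).
  One flg22 variant is barely perceived (baseline 6%, heritability 0),
  emulating a highly diverged peptide. Each causal gene acts through one
  tag SNP inside its body (the SNP nearest the gene midpoint; if the
  uniform draw left a causal gene empty, the nearest SNP is relocated into
  it so the tag-SNP precondition holds by construction).
* **Polygenic background**: drawn once per MAMP class as a multivariate
  normal with covariance proportional to the realized standardized kinship
  — so the REML model is correctly specified — and scaled per trait so
  that the kinship-captured share of genotype-mean variance equals the
  trait's `polygenic_h2` (default 0.29) given the major-locus and expected
  replicate-noise variances: v_poly = h2/(1−h2) · (v_major + v_env), with
  v_env = (100 − baseline)² · cv² / R from the mass model below. Sharing
  the draw within a class is what produces the strong within-class /
  weak between-class correlation block.
* **Loss of function**: 2/186 elf18 and 10/186 flg22 carriers (disjoint
  sets — no accession loses both classes); their true SGI for every
  variant of the affected class is uniform on (0, 10)%, leaving the other
  class untouched. Under default noise these fall below the 15% classifier
  threshold with high probability.
* **Masses**: control fresh mass is log-normal (median 15 mg, log-sd equal
  to the coefficient of variation 0.15); treated mass is
  CFM · (1 − SGI_true/100) · (1 + ε) with ε ~ N(0, 0.15), floored at 0;
  5 replicate pairs per genotype × variant (within the at-least-3 to ~20
  range such assays produce). The control mass cancels exactly in the
  per-pair SGI ratio, so replicate noise on SGI has standard deviation
  (100 − SGI_true) · cv.

What the generator does **not** emulate: linkage disequilibrium beyond
structure-induced correlation (no recombination maps), epistasis,
dominance (meaningless for inbred lines), genotyping error, shared
between-class genetic components (simulated between-class correlation is
~0, whereas real panels show a modest positive one), trial/batch effects,
and heteroscedasticity beyond the (100 − SGI) scaling. Passing tests
therefore demonstrate the statistics are implemented and calibrated
correctly under a correctly specified additive model — not that the
pipeline is robust to LD-driven tag-SNP ambiguity or batch structure in
real data.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive internally (GFF convention); BED is
  converted at the boundary and the conversion is its own inverse.
  Chromosome names match by exact string equality — no "chr" stripping.
* Readers sort SNPs by (chromosome, position) and reject duplicate
  positions and multi-allelic records; ordering is deterministic
  regardless of input row order.
* The missing-call sentinel propagates; imputation policy belongs to the
  consumer (kinship and scan mean-impute, and record per-SNP n_used).
* A SNP constant after filtering tests at p = 1 with a warning (a guard —
  it cannot occur after the MAF filter).
* Scan p-values are floored at the smallest positive float so p ∈ (0, 1].
* Tie-breaks are always by (chromosome, position) ascending, making tail
  selection and clumping order-independent and reproducible.
* All randomness flows through explicit numpy Generators; simulation
  functions derive independent streams from the config seed, so studies
  are reproducible end-to-end from one integer.

## Known limitations

* Variance-component estimates at n ≈ 186–300 with a Balding–Nichols
  kinship are individually noisy (per-trait ĥ² can hit the 0 or 1
  boundary); recovery holds on average over seeds, and the profile CI
  reports the uncertainty honestly.
* The EMMAX shortcut understates evidence slightly at very strong signals
  compared with per-SNP REML (available via the exact flag, at ~n-fold
  cost).
* The overlap null shuffles each trait independently, which destroys the
  inter-trait correlation along with the genetics; a null preserving
  phenotypic correlation while breaking genotype linkage would be stricter
  but is not what the 100-run randomized-phenotype design specifies.
* The shared-peak count depends on a matching convention; the one-to-one
  greedy-by-endpoint rule is symmetric and conservative, but other
  conventions (any-overlap counting) would give larger counts.
* Peak windows are purely positional (±15 kb); no LD-based clumping.
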