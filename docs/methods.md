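# Methods

This note documents the models implemented in `breedscan`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Conventions

Genomic coordinates are 1-based inclusive everywhere inside the
package; BED input/output converts at the boundary. Genotypes are
counts of the A1 allele in {0, 1, 2} with a dedicated missing sentinel
(−1), never 0, so missingness can never masquerade as homozygosity.
On-disk PLINK phenotype coding (2 = case, 1 = control, −9/0 = missing)
is translated to a categorical representation on load. Because a bare
4-column `.map` cannot record which allele the dosages count, the text
dialect writes two extra allele columns (A1 A2); readers accept both
the 4- and 6-column forms.

## Population-genetic primitives

**GRM.** Entry (j, k) of the relationship matrix averages
`(x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i))` over SNPs non-missing
in both samples, with `p_i` the sample allele frequency and
monomorphic SNPs excluded. Because frequencies are estimated within
the analyzed cohort, within-cohort off-diagonals center near zero;
cross-breed contrasts (e.g. comparing bottleneck strengths) should be
computed on a combined multi-breed dataset, which is what the tests
do. Missing genotypes are mean-imputed per SNP for GRM/PCA/LD only;
association testing handles missingness separately.

**Inbreeding.** `θ_j = 1 − H_obs,j / H_exp,j` with the expectation
`Σ_i 2 p_i (1 − p_i)` summed over SNPs non-missing in sample j.
Negative values (heterozygote excess) are reported as-is. This is the
heterozygosity-deficit estimator; which of the several
sample-frequency-corrected variants a given external tool reports is
not standardized, so the definition is stated here and labeled in
output.

**LD decay.** r² is the squared composite (genotype) correlation —
phase is never inferred anywhere in the pipeline, so haplotype-EM r²
would add machinery without changing any downstream decision. Pairs
within a maximum distance on the same chromosome are binned by
distance; `decay_distance` is the midpoint of the first bin whose mean
r² falls below the threshold (default 0.2). When LD stays above the
threshold across the whole measured range the decay distance is +inf —
deliberately comparable ("longer than anything measured") rather than
NaN, which is reserved for profiles with no usable pairs.

**Relatedness pruning.** Concordant-phenotype pairs with relatedness
above 0.25 are resolved greedily in descending relatedness, keeping
the younger case and the older control; discordant pairs are never
touched. The traversal order is the package's choice (the preference
rule itself does not determine one); ties break on sample id, and a
missing age sorts as oldest, which removes it first among cases and
shields it among controls. A post-condition assertion re-checks that
no concordant pair above threshold survives.

## Mixed-model association

Case/control status enters as a 0/1 trait in a linear mixed model —
the convention under which per-SNP odds ratios are reported from the
allele table rather than from the regression coefficient. REML
estimation profiles out the variance ratio λ = σ²g/σ²e after a
spectral decomposition of K (eigenvalues floored at zero), scanning a
41-point log-spaced grid plus the λ = 0 boundary and refining with
bounded 1-D optimization; the fit is therefore deterministic. The SE
of h² comes from the numeric curvature of the profile REML
log-likelihood at the optimum.

The per-SNP test holds Σ = σ²g K + σ²e I fixed (components are not
re-estimated per SNP), whitens phenotype, covariates, and dosages, and
applies an ordinary slope t-test in the whitened space. With σ²g = 0
this reduces to OLS exactly (verified to 1e-10 in the acceptance
suite). SNPs below MAF 0.05 are excluded; missing genotypes are
mean-imputed per SNP. The reported risk allele is the allele enriched
in cases; its odds ratio is the allelic OR from the case/control 2×2
allele table, a reproducible convention that is labeled as such in
output (regression-scale and allele-table ORs differ in general).

**Permutation envelope.** Phenotypes are permuted (kinship, rotation,
and covariates held fixed), the full scan re-run, and the sorted
−log10 p recorded per permutation; the envelope is the per-rank
2.5%/97.5% quantile band and the genome-wide threshold is the upper
envelope at rank 1. Coverage is calibrated by construction: a fresh
null scan exceeds the rank-1 upper envelope with probability ≈ 2.5%,
subject to quantile noise that shrinks with the number of
permutations (the calibration checks use 200–1,000 permutations; at
200 the conditional coverage can wander by a point or two). Fewer
than 100 permutations triggers a warning.

**Clumping.** Significant SNPs (default p < 0.0005) are visited by
ascending p, ties broken by (chromosome, position) so the output is
independent of input order. Stage 1 claims unclaimed significant SNPs
with r² > 0.2 within 5 Mb of the index; stage 2 spans the subset with
r² > 0.8 within 1 Mb. Claimed SNPs cannot seed new regions, and stage-1
member sets are disjoint across regions. An all-pairs brute-force
reference in the test suite pins the exact semantics.

**Regional variance explained** rebuilds the broad SNP set around each
peak (r² > 0.2 within 5 Mb, over *all* scanned SNPs, not only the
significant ones), constructs a GRM from those SNPs alone, and refits
the single-component REML; the result is the regional h² on the
observed 0/1 scale with a curvature SE. Fewer than 10 regional SNPs
warns.

**Genotype relative risk** is `exp(Σ_l c_l log OR_l)` over peak-SNP
risk-allele counts, normalized by the population mean; a missing
genotype drops that locus for that dog and the sum is rescaled to the
full locus count. Case/control separation is summarized by a
two-sided rank-sum test.

## Selection scans

Fixed regions are maximal runs of consecutive SNPs with within-breed
MAF < 0.05, reported when the first-to-last SNP span reaches 250 kb,
together with the fraction of the SNP-covered genome they occupy.

The RRV scan tiles each chromosome from position 1 in non-overlapping
150-kb windows, computes mean expected heterozygosity `2p(1−p)` per
window in the target breed and in each reference breed, and ranks
windows by the ratio target / panel-mean. Windows with fewer than 10
SNPs (default) are dropped. Both numerator and denominator are floored
at 1e-4 before dividing, so a window fixed in every breed scores ≈ 1
instead of 0 or infinity — the scan flags windows that are unusual *in
the target relative to the panel*, not windows that are degenerate
everywhere. The RRV set is the lowest `ceil(quantile × retained)`
windows (default quantile 1%), ties broken by coordinate. Expected
heterozygosity is the package's variability statistic; it is the
standard choice where a specific published windowing statistic is not
being reproduced, and the output labels it explicitly.

Fixation checks report each region's peak-SNP risk-allele frequency in
other breeds and flag frequencies strictly above 0.95.

## Gene-set enrichment

The statistic for a set is the number of query intervals overlapping
at least one set gene (each interval counted once — the interval-count
convention; counting genes instead would over-weight gene-dense
intervals). Null replicates place, for every query interval, a random
SNP-anchored window matched on physical length (±20%), contained SNP
count (±20%), and contained gene count (±1, widened proportionally
above 10 genes); placements start and end at SNP positions so SNP
density matching is meaningful on the same universe LD clumping
operates in. Matching tolerances relax stepwise (×1.5, warning) if an
interval has no admissible placement. Empirical p-values use the
add-one rule and can never be exactly zero; the experiment-wide
correction is the min-p permutation method sharing the same
replicates. Because the overlap statistic is a small integer, per-set
p-values are discrete; calibration checks use enough intervals and
dense enough gene sets that the null p distribution is close to
uniform (sparser designs make the add-one p conservative, which is the
safe direction).

Fisher combination is `X² = −2(ln p_GWAS + ln p_RRV)` against χ² with
4 df; zero inputs are clamped with a warning. The empirical background
combines each GWAS breed's enrichment p with the RRV enrichment p of
every *reference* breed, pooled over sets and pairs; an observed
(GWAS, own-RRV) combination is reported with its quantile in that pool
and flagged "inflated" beyond the 0.99 quantile, under which an
all-null analysis flags ≈ 1% of sets.

## Copy-number analysis

Gain/loss calls are threshold-and-run: at least 3 consecutive probes
with log2 tumor:reference ≥ 0.2 (gain) or ≤ −0.2 (loss), inclusive at
the boundary; segments span first-to-last probe position. Unsorted
probe tables are an error, not silently reordered — segmentation
semantics depend on order, and a silent sort would mask an upstream
problem. A "consistent with homozygous deletion" sub-threshold is not
implemented: no defensible cutoff presented itself, and guessing one
would contaminate the gain/loss calls that are well-defined.

Probe recurrence counts probes aberrant in *all* samples of a group
("up" = gained in all, "down" = lost in all, "any" = aberrant in all,
directions may mix); the null expectation is the product of the
per-sample aberrant fractions (independence), and the p-value is the
upper binomial tail at that expectation.

The stratified 2×2 machinery computes the Pearson chi-square (no
continuity correction — the convention that reproduces standard
printed replication p-values), the CMH statistic
`(Σ(a − E[a]))² / Σ Var[a]` with the hypergeometric variance, the
Mantel–Haenszel common OR, and the Breslow–Day homogeneity statistic
against that common OR (Tarone adjustment available behind a flag,
off by default). Note the algebraic fact that a single-stratum CMH is
`(N−1)/N` times the Pearson chi-square, not equal to it. Allele
counts for in-text cohorts given as (n, frequency) are reconstructed
as `round(2n·f)` with a self-consistency check that the reconstructed
count re-rounds to the printed frequency. Germline-to-somatic
association builds, per probe and peak SNP, breed-stratified 2×2
tables of allele counts among aberrant vs non-aberrant dogs and
applies the CMH test.

## Synthetic-data generator

Each breed is founded by drawing `2 × founders_per_breed` haplotypes
from a shared ancestral pool and then evolved by `generations` rounds
of random mating with crossover (constant 1e-8 per bp, no
interference). The ancestral pool itself is built by a
recombination-with-mutation copying chain: each haplotype copies a
template mosaic of earlier ones (switch rate 5e-8 per bp) and re-draws
alleles at a per-site mutation probability. That mutation probability
defaults to 0.2: at low values the copying chain behaves like a Pólya
urn and drifts pool frequencies to fixation (more than half of SNPs
below MAF 0.05 in a moderately bottlenecked breed), whereas 0.2 keeps
realized frequencies near their targets while leaving enough haplotype
sharing for the founder bottleneck to generate realistic long-range
LD — the quantity that actually matters downstream. Under the
defaults a strongly bottlenecked breed (20 founders) shows mean
pairwise r² above 0.2 out to megabase scale while a weak bottleneck
(200 founders) decays within ~100 kb, and multi-breed inbreeding
coefficients fall in the 0.1–0.5 range.

Risk loci, near-fixed regions, and low-variability windows are planted
in the founder pool per breed (risk alleles by Bernoulli draws at the
target frequency; fixed regions forced to the major allele;
low-variability windows re-drawn at frequency 0.01 by default), then
subjected to drift like everything else — so planted frequencies are
recovered within binomial-plus-drift error, not exactly. Phenotypes
follow a logistic model `P(case|g) = expit(α + Σ g_l log OR_l)` with α
solved so the expected case fraction matches the target prevalence;
ages are drawn with cases skewing younger (defaults 5 ± 2 vs 9 ± 2
years) to exercise the pruning rule. The planted effect used in power
checks is the one implied by the target case/control frequency
contrast (allelic OR ≈ 8 for a 0.14 vs 0.02 contrast); printed
per-locus ORs of ~1.2–1.8 alongside such contrasts are mutually
inconsistent and cannot drive a detectable signal at n ≈ 140.

CGH cohorts place probes on a regular grid (26 kb default), add
planted recurrent segments (+0.58 gain / −1.0 loss defaults) for
their carrier samples, Gaussian probe noise, and a chaotic background
of random segments (per-probe start probability, random direction and
length). Tumor purity, wave artifacts, and probe-specific response are
*not* modeled; noiseless recovery tests therefore show calling-logic
correctness, not robustness to real aCGH artifacts.

What passing tests on these simulations show — and what they do not:
the generator produces the *statistical structure* the methods assume
(relatedness, LD, fixation, logistic risk, recurrent CNAs), so
recovery and calibration results demonstrate internal correctness of
the machinery under those assumptions. Real breed data add
genotyping error, call-rate structure, age censoring, diagnostic
misclassification, and selection patterns none of which are emulated
here.

## Problem sizes and runtime

Test-suite and acceptance-script simulations use 1–2 chromosomes of
50 Mb, 400–4,500 SNPs, 60–500 samples, and 4–10 breeds; permutation
counts are 200–1,000 for envelopes and 3,000–10,000 for enrichment.
These sizes were chosen so that every stochastic check runs in seconds
while keeping each test's discriminating power (e.g. 20-seed recovery
rates, 500-replicate coverage estimates); the algorithms themselves
are vectorized and scale to array-type datasets (10⁵–10⁶ SNPs, a few
hundred samples) without modification.

## Known limitations

- The logistic phenotype model ignores age/sex effects on risk; sex
  enters the scan only as an optional covariate.
- Permutation envelopes assume exchangeability of phenotypes given the
  fixed kinship rotation; strong case/control imbalance with
  substructure not captured by K would violate this.
- Interval enrichment requires a SNP map dense enough to anchor
  matched placements; very gene-sparse chromosomes force tolerance
  relaxation (warned).
- The Breslow–Day statistic is unstable for strata with near-empty
  cells; such strata are dropped with the degrees of freedom reduced.
- X-chromosome dosage is not modeled; all scans treat chromosomes as
  autosomal.
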