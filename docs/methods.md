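# Methods

This note documents the statistical models behind `islandpop`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results bit-for-bit.

## Data model

Genotypes are counts of allele A per sample and SNP in {0, 1, 2} with −1
for missing, alongside sample metadata (island, herd) and marker metadata
(chromosome, 1-based bp position, allele codes). On PLINK text input the
count allele is the observed minor allele (ties broken lexicographically)
so that MAF filtering and expected heterozygosity share a consistent
reference; on binary input the BIM A1 allele is taken as the count allele.
All downstream statistics are invariant to which allele is counted except
for the sign of PCA loadings, which is fixed by convention (largest
loading positive).

## Synthetic cohorts

The generator emulates a two-population, herd-subdivided sampling design:
defaults are 307 + 117 samples in 18 + 6 herds, 40,000 SNPs on 26
autosomes totalling exactly 2,610 Mb (sheep-like length proportions), and
ancestral allele frequencies Uniform(0.05, 0.95).

- **Differentiation** follows a two-level Balding–Nichols hierarchy:
  island frequency ~ Beta(p(1−c)/c, (1−p)(1−c)/c) with c = `fst_island`
  (default 0.01, weak island differentiation), herd frequencies drawn the
  same way around their island frequency with c = `fst_herd` (default
  0.05, inside the 0.01–0.10 herd-pair range the design targets). The
  Beta draw has mean p and variance c·p(1−p), so c is recovered by the
  Weir–Cockerham estimator.
- **Admixture** is modelled at the allele-frequency level: a fraction of
  samples (default 0.25) draws genotypes from q·p_herd + (1−q)·p_other_island
  with own-island ancestry q ~ Uniform(0.5, 1). Tract-level admixture is
  deliberately not simulated; frequency-level mixing is sufficient for
  PCA/clustering behaviour and much simpler. Consequently the generator
  produces no admixture linkage disequilibrium.
- **Relatives** are produced by gene dropping: founder haplotypes are
  Bernoulli draws at the island frequencies; gametes follow a Markov
  crossover process with Haldane map and a uniform 1 cM/Mb rate (a
  standard, adequate approximation for IBD expectations). Supported
  relationships: duplicate, parent-offspring, full-sib, half-sib,
  first-cousin, first-cousin-once-removed, unrelated.
- **Autozygosity** is injected by forcing non-overlapping segments
  (uniform lengths, default 4–20 Mb) to homozygosity until a target
  genome fraction F is covered; heterozygotes inside a segment collapse
  to a random homozygote, mimicking copying one haplotype at unlinked
  loci. The recorded truth allows end-to-end f_ROH recovery tests.

Because loci are simulated independently given the frequency hierarchy,
background LD is absent: LD pruning on simulated data removes (almost)
nothing, and ROH false positives are rarer than on a real SNP array where
local LD creates chance homozygous stretches. Recovery tolerances
(f_ROH ±0.03, π̂ ±0.02, F_ST 15% relative) should therefore be read as
validating estimator correctness, not as field error bars for real data.

## Quality control

Order: sample call rate → marker call rate → MAF → HWE → LD pruning, with
each removed marker attributed to the first criterion it failed.
Thresholds are strict inequalities ("lower than 0.95/0.05"), so boundary
values are retained. The HWE exact test computes the conditional
distribution of the heterozygote count given allele counts by the
standard two-term recurrence and sums probabilities no larger than the
observed one (two-sided); monomorphic tables return p = 1. HWE is tested
on all samples pooled — the single-pass convention — which can exclude
markers for Wahlund reasons in structured cohorts; the report makes such
exclusions auditable. LD pruning computes genotype-count r² (composite
correlation; phase is unavailable) on pairwise-complete samples within
50-SNP windows advanced by 5; from an offending pair the lower-MAF member
is removed (tie: the later position), which keeps the more informative
marker. Removals are permanent across windows.

## Diversity and inbreeding

H_O is the heterozygote fraction among non-missing calls per locus and
group; H_E = 2p(1−p) without small-sample correction (a correction toggle
exists), matching the usual diversity-table convention. The
Brown–Forsythe test is one-way ANOVA on absolute deviations from group
medians, applied to per-locus H_O values grouped by island or herd (loci
are the replication unit). f_is uses expected homozygosity
1 − 2p(1−p)·2n/(2n−1) summed over the sample's called loci — the
method-of-moments estimator whose sign separates heterozygote excess
(negative) from deficit (positive).

ROH detection is the consecutive-runs method. A candidate run must start
and end on homozygous calls, contain at most one heterozygous and one
missing call, and have no inter-marker gap above 1 Mb; candidates below
25 SNPs or 1 Mb are dropped. Candidate runs are maximal (not extendable
without violating a constraint); two maximal runs can overlap around a
shared heterozygote, and overlaps are resolved greedily left to right so
reported segments never overlap. The scanner is verified against an
exhaustive O(n²) window oracle on small genomes. Run length is
end_bp − start_bp (the marker span; the off-by-one is immaterial at Mb
scale but stated here for exact tests). f_ROH divides summed lengths by
the marker-covered genome (2,610 Mb default) with classes [1,5), [5,20),
[20,∞) Mb, which partition the total exactly.

## Relatedness and structure

π̂ is estimated by the method of moments: observed IBS-state counts over
mutually non-missing loci with MAF ≥ 0.05 are equated to their
expectations given IBD state under Hardy–Weinberg at the cohort allele
frequencies; P0, P1, P2 are solved sequentially, negatives truncated to
zero and the triple renormalized. The original tool's small-sample bias
corrections are not applied — frequencies are treated as known — because
with cohort sizes in the hundreds the correction is negligible, as the
recovery suite shows (duplicate pairs are exactly 1 by construction:
every locus is IBS 2, forcing P0 = P1 = 0). Truncation induces a small
positive bias for nearly unrelated pairs (mean π̂ ≈ 0.01–0.03 at 5–20k
loci), visible in the fourth-degree recovery numbers.

The GRM is the variance-standardized cross-product averaged over
pairwise-complete loci; its diagonal has expectation 1 + f for an
individual with inbreeding f, and its off-diagonal mean carries the
classic −1/n bias from in-sample frequency estimation. PCA is the GRM
eigendecomposition (scores = eigenvectors × √eigenvalue, variance
fractions = eigenvalues / trace), equivalent up to scaling to an SVD of
the standardized genotype matrix. The similarity matrix is the Pearson
correlation of GRM rows; k-means (k = 2–8, 10 restarts, seed 17) runs on
similarity rows by default — the heatmap is what gets clustered — with a
switch for GRM rows, since the source convention is ambiguous.

## Differentiation

Weir–Cockerham (1984) two-population variance components a, b, c are
computed per locus from sample sizes, allele frequencies and observed
heterozygosity; loci with fewer than two genotyped samples in either
group, or monomorphic across both (zero denominator), are excluded. The
multilocus estimate is Σa/Σ(a+b+c) — the ratio of sums, which differs
from the mean of per-locus ratios and is asserted to differ in the test
suite. Bootstrap CIs resample loci with replacement (default 1000
replicates, 95% percentile interval), independently per group pair,
deterministic under seed. Nei (1972) D = −ln(J_xy/√(J_x·J_y)) uses
gene identities averaged over loci with defined frequencies in both
groups, clamped at 0 (sampling noise can push the raw value slightly
negative). Small herds are allowed with a warning; their distances are
upward-biased, a known small-sample artefact. The "overall" island
differentiation is reported both as island-vs-island θ and as the mean of
herd-pair θs, since either reading is defensible.

## Panel assignment

Per-SNP θ between the two islands ranks markers; the top 25/50/100/150
form candidate panels (monomorphic markers rank last). Panel genotypes
are mean-imputed, centred and standardized (a toggle disables scaling),
then reduced to 1/2/5/10 PCs. Assignment uses a normal-theory
discriminant with priors proportional to class size. "Linear discriminant
analysis assuming unequal variances" is self-contradictory: unequal
covariances imply the quadratic rule, so the default is the quadratic
(class-specific covariance) classifier with a pooled-covariance linear
switch. Covariances are unbiased (n−1) estimates; numerically singular
ones are ridge-regularized with a warning. Error rates come from
leave-one-out cross-validation, refitting the rule for every held-out
sample; the implementation is checked for exact equality against an
independent refit-per-sample oracle built on scipy multivariate normals.

Panel selection happens once on the full cohort before cross-validation
(the described sequence), which makes error estimates optimistically
biased — the selected SNPs have seen every sample. A `nested=True` mode
repeats the ranking inside every fold for an honest estimate; the default
reproduces the published protocol. The overall error rate equals the
size-weighted mean of per-class rates; when recomputing overall rates
from rounded published per-class rates, per-class counts are first
rounded back to integers (`integer_counts=True`), the only convention
under which the published rows are internally consistent.

## Problem sizes and determinism

The test and acceptance workloads are scaled to recover each parameter
comfortably: π̂ suites use ~20,000 loci and 100–200 pairs per
relationship; F_ST recovery uses 2×100 samples at 10,000 loci with
coverage checked over 50 simulations × 200 bootstrap replicates; ROH
recovery uses a 40,000-SNP genome. All randomness flows through
`numpy.random.Generator` objects seeded explicitly; pipelines rerun
byte-identically under a fixed seed.

## Known limitations

- Two islands only; the discriminant extends to more classes but the
  F_ST machinery is two-population.
- No VCF input, no sex chromosomes, no genotype-intensity processing.
- The generator has no background LD, no selection and no coalescent
  genealogy; admixture is frequency-level, not tract-level.
- Variational admixture inference, split-network construction and heatmap
  rendering are left to the dedicated external tools; the package only
  exports their inputs (PLINK binary, NEXUS distances).
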