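# islandpop

Population-genomic analysis of hierarchically sampled SNP-array cohorts —
two populations ("islands") subdivided into herds — covering genotype QC,
diversity and inbreeding estimation, relatedness and structure detection,
genetic differentiation, and the design of small discriminatory SNP panels
for origin assignment. The motivating use case is livestock conservation
genetics: deciding whether two island sheep populations are differentiated,
how inbred individual herds are, and how few markers suffice to assign an
animal to its island of origin.

Because cohorts like this are rarely public, the package ships a
first-class synthetic-genotype generator with known truth (differentiation
level, pedigree relationships, autozygous segments), so every estimator is
validated by recovery of simulated parameters.

## What it computes

- **QC** (`islandpop.qc`): sample call rate, marker call rate, MAF,
  Hardy–Weinberg exact test (Wigginton-style recurrence), and sliding-window
  LD pruning (r² on genotype counts; window 50, step 5, r² > 0.50).
  Thresholds follow strict "lower than" semantics.
- **Diversity and inbreeding** (`islandpop.diversity`): per-locus
  H_O and H_E = 2p(1−p) by group; Brown–Forsythe homogeneity-of-variance
  test; per-sample f_is = (O_hom − E_hom)/(L − E_hom) with the 2n/(2n−1)
  small-sample factor; runs of homozygosity by the consecutive-runs method
  (≥25 SNPs, ≥1 Mb, ≤1 heterozygote, ≤1 missing, gaps ≤1 Mb) and
  f_ROH = Σ ROH length / 2,610 Mb, overall and in [1,5), [5,20), ≥20 Mb
  classes.
- **Relatedness and structure** (`islandpop.relatedness`): method-of-moments
  IBD with π̂ = P(IBD=2) + ½·P(IBD=1); the variance-standardized GRM
  A(j,k) = Σ (x_j−2p)(x_k−2p)/(2p(1−p)) / M; Pearson similarity of GRM rows
  with k-means (k = 2–8); PCA as the GRM eigendecomposition.
- **Differentiation** (`islandpop.differentiation`): Weir–Cockerham (1984)
  θ from variance components a/(a+b+c), multilocus as a ratio of sums,
  with locus-bootstrap percentile CIs (default 1000 replicates, 95%);
  Nei (1972) D = −ln(J_xy/√(J_x·J_y)); NEXUS export of distance matrices
  for split-network viewers.
- **Panel assignment** (`islandpop.panel`): SNPs ranked by per-locus θ
  between islands; panels of 25/50/100/150 markers reduced to 1/2/5/10 PCs;
  normal-theory discriminant assignment (class-specific covariances, priors
  proportional to class size) with leave-one-out cross-validation over the
  16-cell grid.
- **Pipeline** (`islandpop.pipeline`, `popgen-pipeline` CLI): all stages
  from one TOML config, with a TSV report bundle and a deterministic seed.

## Worked example

```python
import numpy as np
from islandpop import SimConfig, simulate_dataset, wc_fst, grid_evaluate, pca
from islandpop.qc import run_qc

cfg = SimConfig(
    n_snps=5000,
    herd_sizes={"A": (30, 30, 30), "B": (30, 30)},
    fst_island=0.05, fst_herd=0.02,
    admixed_fraction=0.25, seed=42,
)
ds, truth = simulate_dataset(cfg)
ds_qc, report = run_qc(ds)
print("after QC:", ds_qc.n_samples, "samples x", ds_qc.n_snps, "SNPs")
_, theta = wc_fst(ds_qc, ds_qc.samples["island"], "A", "B")
print(f"island-vs-island Weir-Cockerham theta = {theta:.4f}")
res = pca(ds_qc, n_components=10)
print(f"PC1 variance fraction = {res.variance_fraction[0]:.3f}")
grid = grid_evaluate(ds_qc, panel_sizes=(25, 50), pc_counts=(1, 2))
print(grid[["panel_size", "fst_mean", "n_pcs",
            "error_A", "error_B", "overall_error"]].to_string(index=False))
```

Output:

```
after QC: 150 samples x 4765 SNPs
island-vs-island Weir-Cockerham theta = 0.0478
PC1 variance fraction = 0.054
 panel_size  fst_mean  n_pcs  error_A  error_B  overall_error
         25  0.351194      1 0.022222      0.0       0.013333
         25  0.351194      2 0.022222      0.0       0.013333
         50  0.320136      1 0.000000      0.0       0.000000
         50  0.320136      2 0.000000      0.0       0.000000
```

The simulated island differentiation (Balding–Nichols c = 0.05) is
recovered by the multilocus θ (0.0478); the top-25 panel already assigns
almost every sample to the right island, and 50 markers suffice for
error-free leave-one-out assignment in this cohort.

The same analysis runs from the shell:

```sh
popgen-pipeline run --config config.toml --out-dir results/
panel-assign --config config.toml --panel-sizes 25,50,100,150 --pcs 1,2,5,10
```

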