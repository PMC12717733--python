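# mbgp — multibreed genomic prediction with LD-block-wise covariances

`mbgp` implements genomic prediction across breeds for quantitative
traits, built around a multitrait blockwise BayesA model in which the
genetic (co)variance of SNP effects is specific to each
linkage-disequilibrium (LD) block of the genome. Pooling reference
animals from several breeds can lift prediction accuracy for small
populations, but marker effects only partially transfer across breeds;
letting every LD block carry its own cross-breed effect covariance
lets the model borrow strength where effects are shared and ignore
regions where they are not.

The package provides, as scikit-learn-style estimators:

- **`LDBlockPartitioner`** — partitions each chromosome into blocks
  from LD: for every candidate breakpoint k, the statistic
  `w_k = mean of Corr[M_i, M_j]^2` over dosage-column pairs spanning k
  within a window (`n_win = 50` SNPs) is computed on the merged panel,
  smoothed with a penalized cubic spline (R `smooth.spline`-style
  `spar = 0.2`), and every interior local minimum becomes a block
  boundary. A fixed-size strategy (100 SNPs/block) is the comparator.
- **`MbBayesAB`** — the multitrait blockwise BayesA Gibbs sampler:
  per-block effect covariance `G_i ~ IW(4 + p, B_i)` with
  phenotype-informed scales, residual `R_0 ~ IW(4 + p, R_p)`,
  missing own-breed phenotypes handled by data augmentation. The
  LD-based and fixed-size variants differ only in the block map
  supplied.
- **`STGBLUP` / `MTGBLUP`** — GBLUP baselines on the VanRaden genomic
  relationship matrix with joint-reference allele frequencies:
  single-trait (breeds pooled; exact spectral REML) and multitrait
  (one trait per breed; direct REML with analytic gradients).
- **`mbgp.simulate`** — a forward-in-time multibreed simulator
  (drift LD, hotspot-structured recombination maps, litter-based breed
  formation under divergent truncation selection, blockwise
  heterogeneous QTL correlations) with full truth tracking.
- **`mbgp.evaluate`** — stratified cross-validation, accuracy
  (Pearson correlation of GEBV with the target), unbiasedness (OLS
  slope of target on GEBV), paired t-tests, and population-structure
  statistics (LD-pattern consistency within 10 Mbp, allele-frequency
  correlation, Hudson's F_ST).

I/O covers PLINK 1 binary triplets (.bed/.bim/.fam), phenotype tables
with a stacked multibreed layout, and tab-separated block/GEBV/
posterior tables. A thin `mbgp` CLI exposes `simulate`, `partition`,
`fit` (methods `mbbayesab-ld | mbbayesab-fix | stgblup | mtgblup`) and
`evaluate`.

See `docs/methods.md` for the model details, numerical choices and
limitations.

## Worked example

Simulate a desk-scale two-breed dataset (2,000 SNPs; 600 breed-A and
300 breed-B individuals; 10 blocks with cross-breed effect correlation
0.8, the rest uncorrelated), hold out one five-fold validation fold,
and compare the blockwise model with pooled GBLUP:

```python
import numpy as np
from mbgp import MbBayesAB, STGBLUP
from mbgp import simulate as sim
from mbgp.evaluate import accuracy, make_cv_plan, unbiasedness

config, arch = sim.desk_two_breed(r_g_mean=0.8)
panel, pheno, truth = sim.simulate_dataset(config, arch, seed=7)

plan = make_cv_plan(pheno, k=5, repeats=1, seed=7)
val = plan.validation_indices(0, 0)          # 20% of each breed
masked = pheno.mask_samples(val)

bayes = MbBayesAB(blocks=truth.blocks, n_iter=3000, burn_in=1000,
                  thin=5, seed=7).fit(panel, masked)
gblup = STGBLUP().fit(panel, masked)

own = pheno.own_trait_index()
tbv = truth.tbv[np.arange(panel.n_samples), own]
for name, g in [("mbBayesAB-LD", bayes.gebv_[np.arange(len(own)), own]),
                ("STGBLUP", gblup.gebv_)]:
    for breed in ("A", "B"):
        vb = val[pheno.sample_breeds[val] == breed]
        print(f"{name:13s} breed {breed}: accuracy "
              f"{accuracy(g[vb], tbv[vb]):.3f}, slope "
              f"{unbiasedness(g[vb], tbv[vb]):.3f}")
```

Output from this exact script:

```
mbBayesAB-LD  breed A: accuracy 0.793, slope 1.490
mbBayesAB-LD  breed B: accuracy 0.552, slope 1.655
STGBLUP       breed A: accuracy 0.866, slope 1.157
STGBLUP       breed B: accuracy 0.666, slope 0.651
```

Accuracy is the correlation between predicted and true breeding values
of the held-out individuals; a slope above 1 means the GEBV spread is
shrunken (typical of the Bayesian models), below 1 inflated (typical
of GBLUP). `truth.blocks` holds the LD partition, and
`bayes.posterior_` carries posterior block covariances and per-block
cross-breed genetic correlations.

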