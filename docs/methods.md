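# Methods

This note documents the statistical models implemented in `mbgp`, the
numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## The prediction problem

Genomic prediction across breeds pools reference animals from several
populations to predict the genetic merit of candidates, which is most
attractive for breeds too small to support an accurate within-breed
evaluation. The difficulty is that marker effects are not exchangeable
across breeds: linkage-disequilibrium (LD) phase, allele frequencies
and QTL effects all differ. Treating the pooled data as one population
(single-trait GBLUP) assumes a cross-breed genetic correlation of 1
everywhere; treating the breeds as distinct correlated traits
(multitrait GBLUP) estimates one global correlation. The blockwise
model in this package lets the genetic (co)variance differ between LD
blocks of the genome, so regions where effects transfer across breeds
and regions where they do not are weighted differently.

## LD-block partitioning

For each chromosome of the merged (all-breeds) reference panel and
every candidate breakpoint SNP k, the statistic

    w_k = (1 / m_k) * sum over pairs (i, j) of Corr[M_i, M_j]^2

averages the squared Pearson correlation of dosage columns over all
pairs that span k (i <= k < j) with lag j - i at most `n_win` SNPs
(default 50); m_k counts the included pairs. Pairs involving a
monomorphic column are excluded (the correlation is undefined), and
w_k is missing when no pair remains. Low w_k means the SNPs on the two
sides of k are nearly unassociated, i.e. k sits at an LD-block
boundary.

The w curve is smoothed with a penalized cubic smoothing spline. The
penalty is parameterized on the familiar R `smooth.spline` `spar`
scale: lambda = r * 256^(3*spar - 1), with r = tr(X'X) / tr(Omega)
computed on the cubic B-spline basis with knots at the (rescaled to
[0, 1]) data points and Omega the Gram matrix of second derivatives.
With the same lambda, `scipy.interpolate.make_smoothing_spline`
reproduces R's fit to ~1e-4 on reference curves (a frozen R 4.3.3
reference is kept in the test suite); the residual difference is a
boundary effect of order 20/n in the ratio r and vanishes with n. The
default `spar = 0.2` applies light smoothing (effective df about 0.8 n,
matching R at any n); `lam` can be set directly instead. Missing w
values are bridged by fitting on the defined points only; fewer than 5
defined points triggers a pass-through with a warning (a cubic spline
basis needs 5 points).

Every strict interior local minimum of the smoothed curve becomes a
block boundary (block ends at the minimum SNP). A flat run lower than
both neighbours yields one breakpoint at the run's last index; the
first and last SNP never qualify. A fixed-size comparator cuts
consecutive runs of `block_size` SNPs (default 100) instead. Both
partitioners guarantee a gap-free, overlap-free tiling of each
chromosome, checked by `BlockMap.validate`.

## The blockwise multitrait BayesA model

The same trait recorded in p breeds is modeled as p distinct traits in
the stacked layout: every genotyped individual has p trait cells, of
which only the own-breed cell is observed. For block i with m_i SNPs,

    y_l = X b_l + sum_i sum_j z_ij a_ijl + e_l,
    a_ij ~ N(0, G_i),     G_i ~ IW(df, B_i),
    e    ~ N(0, I_n x R_0),   R_0 ~ IW(df, R_p),   df = 4 + p,

with phenotype-informed scale matrices

    B_i = h2 * P / [ s (df - 1) sum_{j in i} 2 p_j (1 - p_j) ],
    R_p = (1 - h2) * P / (df - 1),

where P = diag of per-breed phenotypic variances, p_j the merged-panel
allele frequency, s the number of blocks and h2 the prior heritability
(default 0.5, a moderately informative neutral value). Prior
covariances between breeds are zero (P is diagonal). Fixed effects are
a per-breed-trait population mean plus any supplied covariates (e.g.
sex), with a flat prior.

Gibbs updates run per cycle in a fixed order: impute missing
phenotypes, fixed effects, every block's SNP effects, every G_i, R_0.
Details:

- **Effect updates** are per-SNP p-variate draws from
  N[(m'm R0^-1 + G_i^-1)^-1 R0^-1 (E + m a_j')' m, (m'm R0^-1 + G_i^-1)^-1],
  with the residual matrix E updated incrementally so the adjusted
  response is never re-materialized. The current G_i draw provides the
  prior (co)variance of the block's effects — the standard
  hierarchical reading under which sampling G_i matters.
- **Marker coding.** Dosages are counted minor alleles on the merged
  panel; inside the sampler the columns are centered by twice the
  allele frequency. The intercept absorbs the offset, the model is
  unchanged up to reparameterization, and single-site Gibbs mixes far
  better because effects decorrelate from the mean. GEBVs are reported
  on the centered scale (a per-trait constant, irrelevant to
  correlation/regression scoring); `predict` centers new panels with
  the training frequencies.
- **Fixed effects** share one design across traits, so the conditional
  is matrix normal with row covariance (X'X)^-1 and column covariance
  R_0; rank-deficient designs raise an error naming the aliased
  columns.
- **Covariance updates** are inverse-Wishart draws via the Bartlett
  construction, batched over blocks; validated against the analytic IW
  mean and scipy's marginals.
- **Missing phenotypes** are data-augmented: the missing residual
  components are redrawn each cycle from their conditional normal
  given the observed components under e ~ N(0, R_0) (validation
  individuals, with no observed cell, get an unconditional draw), and
  the imputed phenotype is implicitly fixed + genetic + residual.
- **Residual covariance restriction.** In the stacked multibreed
  layout no individual observes two breed-traits, so the off-diagonal
  of R_0 carries no likelihood information. Left free, it performs a
  slow random walk through the augmented records (posterior
  conditional concentrated at the current value) and can drift to
  near-degenerate values. The default therefore restricts R_0 to its
  identifiable diagonal, each variance drawn from its univariate
  conditional; `residual_model="full"` restores the unrestricted
  update. The same identifiability argument fixes the MTGBLUP residual
  covariances at zero.
- **PD safeguards**: every scale matrix is symmetrized before
  factorization, one jitter of 1e-10 * trace is attempted, then the
  sampler raises. Stored draws are verified positive definite.
- **Reproducibility**: one `numpy.random.Generator` drives every
  stochastic step in a fixed documented order; the numba kernels are
  pure algebra on pre-drawn normals, so runs are bit-reproducible.

Chain defaults are 30,000 cycles, 20,000 burn-in, thinning 10 (1,000
stored samples). GEBVs are posterior means of the genetic values
accumulated across stored samples; the posterior-mean effects are also
stored for predicting external panels (the two differ only by
Monte-Carlo error). Posterior summaries include per-block genetic
correlations r_i = G_i[l,l'] / sqrt(G_i[l,l] G_i[l',l']).

The sampler's joint correctness is established by a successive-
conditional (Geweke-style) check on a tiny model (p = 2, 2 blocks x 3
SNPs, n = 12): alternating one Gibbs sweep with re-simulation of the
data leaves the prior marginals of G_i and R_0 invariant
(Kolmogorov-Smirnov p-values well above 0.01 at 50,000 draws, for
diagonal and off-diagonal elements alike, with and without missing
cells).

## GBLUP baselines

The GRM follows VanRaden: G = ZZ' / (2 sum p_j (1 - p_j)) with Z the
dosage matrix centered by twice the joint-reference allele frequency;
monomorphic SNPs contribute zero and are excluded from the
denominator. STGBLUP pools all breeds as one population with a single
mean; variance components come from exact spectral REML (the GRM
eigenbasis reduces the restricted likelihood to a 1-D profile in
sigma_a^2 / sigma_e^2), and GEBVs — including for phenotype-masked
validation individuals — come through the relationship rows. STGBLUP
is numerically equivalent to SNP-BLUP with matched shrinkage
(correlation > 0.999 in the tests).

MTGBLUP models a ~ N(0, G0 x G) with per-trait means and residual
covariances fixed at zero (unidentifiable, as above). (G0, diag R0)
maximize the observed-data restricted likelihood directly: L-BFGS-B on
a Cholesky (G0) / log (residual variances) parameterization with
analytic gradients from dNLL/dtheta = (tr(P V_k) - y'P V_k P y) / 2.
This route was chosen over EM-REML with average-information
acceleration because the quasi-Newton iteration on the unconstrained
scale is stable under the missing-by-design pattern (where AI steps
are fragile) and converges tightly enough that the p = 1 case matches
spectral REML to 1e-4 relative; accepted iterates are monotone in the
restricted likelihood and the path is exposed (`loglik_path_`).

## Synthetic data

The generator emulates a multibreed breeding design with full truth
tracking:

1. **History.** A random-mating population of size 100 (a conventional
   livestock effective population size) evolves 100 discrete
   generations; sites start in linkage equilibrium with U(0.05, 0.95)
   frequencies and LD accumulates by drift.
2. **Genetic map.** Per-gap map distances are gamma(0.2) draws
   renormalized to the chromosome length, so a small fraction of gaps
   (hotspots) carries most recombination — the mechanism behind
   haplotype-block structure; meiosis is a Poisson crossover process
   on that map (exactly the per-gap Haldane fractions, no
   interference).
3. **Breed formation.** Each breed samples founders from the history
   and breeds `gen` generations with litters of 8 and truncation
   selection (proportion 0.5) on an auxiliary polygenic phenotype
   (h2 = 0.3) — high, low, or random per breed — so breeds diverge in
   allele frequencies and LD. The per-generation population is three
   times the minimum needed, so the analyzed panel (two individuals
   per litter from the last three generations) samples few litters
   twice and prediction accuracy reflects LD rather than dense
   full-sibship.
4. **Panel.** The requested SNP count is selected evenly among sites
   segregating in the merged panel (1.75x sites are simulated so the
   target count survives ascertainment), then minor-allele coded.
5. **Architecture.** Blocks come from the LD partitioner on the merged
   panel. A configurable number of blocks carry one QTL each with
   independent effects per breed; a further set (default 10 blocks x
   10 QTLs) carries effects drawn from a correlation-r_b multivariate
   normal across the designated breed pair. In the 'identical'
   scenario r_b = r_g_mean for every block; in 'uniform', r_b ~
   U(-1, 1) location-shifted (with clipping, iterated to the fixed
   point) so the block mean equals r_g_mean exactly. Effects are
   scaled so each breed's realized genetic variance equals its h2
   target on a phenotypic variance of 1.
6. **Phenotypes.** y = breed mean + (TBV - within-breed mean TBV) +
   N(0, var(TBV)(1 - h2)/h2). Centering the genetic term makes the
   configured breed mean the breed's expected phenotype.

Presets encode the two study designs: `two_breed()` (A: 40
generations, high-phenotype selection, 3,000 individuals, h2 0.5, mean
1.0; B: 10 generations, random selection, 600 individuals, h2 0.3,
mean 0.5; 50,058 SNPs on 18 chromosomes) and `three_breed()` (600
individuals each; r_g between A and B only, blocks from the A+B merged
panel). `desk_two_breed()` is the scaled-down benchmark configuration
used throughout the tests: 2,000 SNPs on 3 chromosomes of 33 cM
(shrinking genome length rather than marker density, ~20 SNPs/cM as at
full scale, so per-SNP LD stays in the regime the method targets),
600 + 300 individuals, 150 uncorrelated + 10 correlated blocks (the
correlated component kept at 10 blocks x 10 QTLs; the uncorrelated
count is what a 2,000-SNP partition can host while keeping the
uncorrelated share of variance dominant, as at full scale).

A note on the structure statistics: the between-breed allele-frequency
correlation is computed, as everywhere in the package, on merged-panel
minor-allele frequencies over jointly segregating SNPs. With little
divergence it approaches 1 (shared history dominates; this is a test
invariant). Under the strongly diverged presets (Hudson F_ST above
~0.3 after 40 generations of closed truncation selection) the
minor-allele folding constrains the frequency cloud near the folding
boundary and the correlation can turn small or negative — a property
of the folded statistic at high divergence, not of the simulation
machinery.

What the generator does **not** emulate: mutation-drift equilibrium
site-frequency spectra, sex chromosomes, genotyping error, pedigree
recording, variable litter sizes, or the exact LD spectra of any
commercial simulator. Passing tests therefore show that the methods
behave correctly under a realistic drift + selection + hotspot-LD
regime, not that real-data accuracies are reproduced.

## Benchmark problem sizes and honest expectations

The package's behavioral checks run the two-breed benchmark at desk
scale: 2,000 SNPs, 600 + 300 individuals, 3,000-cycle chains (1,000
burn-in, thinning 5), one held-out fold of the five-fold geometry per
seed, 20 seeds; the acceptance script reports the same design at 6
seeds with all four models. At this scale the between-model accuracy
differences are small relative to per-fold sampling noise, and the
pooled GBLUP baseline — which benefits disproportionately from the
strong genomic relationships of small simulated populations — is a
harder target than at full scale: within-breed prediction beats pooled
STGBLUP for the small breed (as expected when most genetic variance
does not transfer across breeds), and the multitrait models pay a
finite-sample price for estimating thousands of block covariances.
The per-seed ordering tests between the Bayesian variants and STGBLUP
encode the full-scale expectation and are allowed to fail at desk
scale; the sampler itself is validated by the oracle and
joint-distribution layers, which are exact.

## Limitations

- Per-SNP single-site Gibbs trades the exact joint block draw for
  O(m_i p^3) cost; with very strong within-block LD, longer chains may
  be needed.
- The spar-to-penalty mapping matches R to a boundary effect of order
  20/n; block boundaries on chromosomes with under ~100 SNPs may
  differ from R's in edge cases.
- MTGBLUP assumes one GRM for all breeds (as do the Bayesian models);
  breed-specific GRMs are out of scope.
- The three-breed preset applies r_g between one breed pair only, with
  the third breed uncorrelated; general correlation structures over
  more than two breeds are exchangeable-only.
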