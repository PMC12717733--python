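"""Blockwise multitrait BayesA for multibreed genomic prediction.

The same trait recorded in p breeds is treated as p distinct,
genetically correlated traits. With the genome tiled into s blocks, the
model for the stacked phenotypes is

    y_l = X b_l + sum_i sum_{j in block i} z_ij a_ijl + e_l,

where the p-vector of SNP-j effects in block i is a_ij ~ N(0, G_i) with
a block-specific effect (co)variance G_i ~ IW(df, B_i), df = 4 + p, and
residuals e ~ N(0, I_n (x) R_0) with R_0 ~ IW(df, R_p). The scale
matrices are set from the phenotypes:

    B_i = h2 * P / [ s (df - 1) sum_{j in i} 2 p_j (1 - p_j) ],
    R_p = (1 - h2) * P / (df - 1),

with P the diagonal matrix of per-breed phenotypic variances, p_j the
merged-panel allele frequency and h2 a moderately informative prior
heritability (default 0.5). Fitting is by Gibbs sampling: each
individual observes its own breed-trait only, and the structurally
missing cells are data-augmented by drawing the missing residual
components from their conditional normal given the observed ones.

Block definitions come from :mod:`mbgp.partition`; the LD-based and the
fixed-size strategies differ only in the :class:`~mbgp.types.BlockMap`
supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr as _pivoted_qr
from sklearn.base import BaseEstimator

from ._kernels import update_block_effects
from .partition import partition_genome
from .types import BlockMap, GenotypePanel, PhenotypeTable

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorSummary",
    "build_priors",
    "inv_wishart_rvs",
    "inv_wishart_batch",
    "sample_fixed_effects",
    "sample_block_covariance",
    "sample_residual_covariance",
    "impute_missing_residuals",
    "run_gibbs",
    "compute_gebv",
    "MbBayesAB",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# priors and configuration
# ---------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Hyperparameters of the block-covariance and residual priors."""

    p: int                    # number of breeds / traits
    df: float                 # 4 + p
    h2: float                 # prior heritability
    P: np.ndarray             # (p, p) diagonal phenotypic-variance matrix
    B: np.ndarray             # (s, p, p) per-block IW scale matrices
    R_p: np.ndarray           # (p, p) residual IW scale


@dataclass
class McmcConfig:
    """Chain length bookkeeping. Defaults follow common practice for
    this model class: 30,000 cycles, 20,000 burn-in, thinning 10."""

    n_iter: int = 30_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSummary:
    """Posterior means/SDs of all model unknowns plus GEBVs.

    GEBVs are posterior means of the genetic values accumulated across
    stored samples (not recomputed from posterior-mean effects)."""

    n_stored: int
    trait_breeds: list
    b_mean: np.ndarray          # (q, p)
    b_sd: np.ndarray
    effect_mean: np.ndarray     # (m, p)
    G_mean: np.ndarray          # (s, p, p)
    G_sd: np.ndarray
    R0_mean: np.ndarray         # (p, p)
    R0_sd: np.ndarray
    block_corr_mean: np.ndarray  # (s, p, p), posterior mean correlations
    gebv_mean: np.ndarray       # (n, p)
    gebv_sd: np.ndarray
    sample_ids: np.ndarray = field(default=None)

    def gebv_frame(self) -> pd.DataFrame:
        rows = []
        for l, breed in enumerate(self.trait_breeds):
            for i in range(self.gebv_mean.shape[0]):
                rows.append((self.sample_ids[i], breed,
                             self.gebv_mean[i, l], self.gebv_sd[i, l]))
        return pd.DataFrame(rows, columns=["sample", "breed", "gebv",
                                           "gebv_sd"])


def build_priors(pheno: PhenotypeTable, panel: GenotypePanel,
                 blocks: BlockMap, h2_prior: float = 0.5) -> PriorSpec:
    """Phenotype-informed IW scale matrices for every block and for the
    residual covariance."""
    p = pheno.n_traits
    df = 4.0 + p
    variances = np.empty(p)
    for l in range(p):
        obs = pheno.values[:, l]
        obs = obs[np.isfinite(obs)]
        if len(obs) < 2 or np.var(obs) == 0:
            raise ValueError(
                f"breed-trait {pheno.trait_breeds[l]!r} has zero phenotypic "
                "variance (or fewer than 2 observed records)")
        variances[l] = np.var(obs, ddof=1)
    P = np.diag(variances)
    freq = panel.allele_freqs()
    het = 2.0 * freq * (1.0 - freq)
    s = blocks.n_blocks
    B = np.empty((s, p, p))
    for i, sl in enumerate(blocks.slices()):
        denom = het[sl].sum()
        if denom <= 0:
            raise ValueError(f"block {i} is entirely monomorphic")
        B[i] = h2_prior * P / (s * (df - 1.0) * denom)
    R_p = (1.0 - h2_prior) * P / (df - 1.0)
    return PriorSpec(p=p, df=df, h2=h2_prior, P=P, B=B, R_p=R_p)


# ---------------------------------------------------------------------
# elementary samplers (the full conditionals)
# ---------------------------------------------------------------------

def _chol_pd(A: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Cholesky with symmetrization and a single jitter attempt."""
    A = 0.5 * (A + A.T)
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(A) * np.eye(A.shape[0])
        try:
            return np.linalg.cholesky(A + jitter)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"{what} not positive definite even after jitter")


def inv_wishart_rvs(nu: float, S: np.ndarray, rng: np.random.Generator
                    ) -> np.ndarray:
    """One draw G ~ InverseWishart(nu, S) (mean S/(nu - p - 1)).

    Bartlett construction: G^-1 ~ Wishart(nu, S^-1)."""
    return inv_wishart_batch(np.array([float(nu)]), S[None], rng)[0]


def inv_wishart_batch(nu: np.ndarray, S: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Vectorized IW draws: one G_i ~ IW(nu_i, S_i) per batch entry."""
    s, p, _ = S.shape
    if np.any(nu <= p - 1):
        raise ValueError("inverse-Wishart requires nu > p - 1")
    S = 0.5 * (S + np.swapaxes(S, 1, 2))
    try:
        Ls = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        jit = (1e-10 * np.einsum("sii->s", S))[:, None, None] * np.eye(p)
        Ls = np.linalg.cholesky(S + jit)
    A = np.zeros((s, p, p))
    tri = np.tril_indices(p, k=-1)
    A[np.arange(s)[:, None],
      np.arange(p)[None, :],
      np.arange(p)[None, :]] = np.sqrt(
        rng.chisquare(nu[:, None] - np.arange(p)[None, :]))
    if len(tri[0]):
        A[:, tri[0], tri[1]] = rng.standard_normal((s, len(tri[0])))
    # with C = (Ls')^-1, C C' = S^-1 and G^-1 = C A A' C', so
    # G = (A^-1 Ls')' (A^-1 Ls')
    Binv = np.linalg.solve(A, np.swapaxes(Ls, 1, 2))
    return np.einsum("sji,sjk->sik", Binv, Binv)


def sample_fixed_effects(X: np.ndarray, ystar: np.ndarray, R0: np.ndarray,
                         rng: np.random.Generator | None,
                         names=None):
    """Draw the fixed-effect coefficient matrix from its conditional.

    The conditional is N[(X'R^-1 X)^-1 X'R^-1 y*, (X'R^-1 X)^-1] with
    R = I_n (x) R_0 and y* the phenotypes minus all genetic terms.
    Because every trait shares the same design X, the mean collapses to
    the per-trait GLS/OLS solution and the draw is matrix normal with
    row covariance (X'X)^-1 and column covariance R_0.

    Returns (mean, draw); with ``rng=None`` the draw equals the mean.
    """
    q = X.shape[1]
    if q == 0:
        z = np.zeros((0, ystar.shape[1]))
        return z, z
    if np.linalg.matrix_rank(X) < q:
        _, R, piv = _pivoted_qr(X, mode="economic", pivoting=True)
        tol = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        aliased = sorted(piv[np.abs(np.diag(R)) < tol])
        labels = ([names[i] for i in aliased] if names is not None
                  else aliased)
        raise ValueError(f"fixed-effect design is rank deficient; aliased "
                         f"columns: {labels}")
    XtX = X.T @ X
    mean = np.linalg.solve(XtX, X.T @ ystar)
    if rng is None:
        return mean, mean.copy()
    Lx = _chol_pd(np.linalg.inv(XtX), "fixed-effect covariance")
    Lr = _chol_pd(R0, "residual covariance")
    draw = mean + Lx @ rng.standard_normal(mean.shape) @ Lr.T
    return mean, draw


def sample_block_effects(E: np.ndarray, M: np.ndarray, mtm: np.ndarray,
                         a: np.ndarray, R0: np.ndarray, G_i: np.ndarray,
                         rng: np.random.Generator, block_id=None) -> None:
    """Gibbs-update all SNP effects of one block (in place).

    Effects are drawn one SNP at a time from the p-dimensional
    conditional N[(m'm R0^-1 + G_i^-1)^-1 R0^-1 m'y_adj, ...] with the
    residual matrix E updated incrementally."""
    z = rng.standard_normal(a.shape)
    R0inv = np.linalg.inv(0.5 * (R0 + R0.T))
    Ginv = np.linalg.inv(0.5 * (G_i + G_i.T))
    bad = update_block_effects(E, M, mtm, a, R0inv, Ginv, z)
    if bad >= 0:
        raise np.linalg.LinAlgError(
            f"non-PD conditional covariance at SNP {bad} of block {block_id}")


def sample_block_covariance(a_block: np.ndarray, B_i: np.ndarray,
                            df: float, rng: np.random.Generator
                            ) -> np.ndarray:
    """G_i ~ IW(df + m_i, sum_j a_ij a_ij' + B_i)."""
    m_i = a_block.shape[0]
    return inv_wishart_rvs(df + m_i, a_block.T @ a_block + B_i, rng)


def sample_residual_covariance(E: np.ndarray, R_p: np.ndarray,
                               df: float, rng: np.random.Generator,
                               diagonal: bool = False) -> np.ndarray:
    """R_0 ~ IW(df + n, sum_i e_i e_i' + R_p).

    With ``diagonal=True`` the residual covariance is restricted to its
    diagonal (each variance drawn from the univariate conditional).
    Under the stacked multibreed layout no individual observes two
    breed-traits, so the residual covariances between traits carry no
    likelihood information; left free they perform a slow random walk
    through the augmented records that can destabilize the rest of the
    chain, so the identifiable diagonal restriction is the default for
    multibreed fits."""
    n, p = E.shape
    if not diagonal:
        return inv_wishart_rvs(df + n, E.T @ E + R_p, rng)
    scale = (np.einsum("ij,ij->j", E, E) + np.diag(R_p))
    draws = inv_wishart_batch(np.full(p, df + n), scale[:, None, None],
                              rng)
    return np.diag(draws[:, 0, 0])


def _missing_groups(obs_mask: np.ndarray) -> list:
    """Group individuals by observed-trait pattern: (rows, obs, mis)."""
    patterns = {}
    for i in range(len(obs_mask)):
        patterns.setdefault(tuple(obs_mask[i]), []).append(i)
    groups = []
    for pat, idx in patterns.items():
        pat = np.asarray(pat)
        groups.append((np.asarray(idx), np.flatnonzero(pat),
                       np.flatnonzero(~pat)))
    return groups


def impute_missing_residuals(E: np.ndarray, obs_mask: np.ndarray,
                             R0: np.ndarray, rng: np.random.Generator,
                             groups: list | None = None) -> None:
    """Redraw the structurally missing residual components (in place).

    For each individual, e ~ N(0, R_0); the missing components are drawn
    from their conditional normal given the observed ones (individuals
    with no observed trait get an unconditional draw). The imputed
    phenotype is then implicitly fixed + genetic + drawn residual."""
    n, p = E.shape
    if groups is None:
        groups = _missing_groups(obs_mask)
    for idx, obs, mis in groups:
        if len(mis) == 0:
            continue
        if len(obs) == 0:
            L = _chol_pd(R0, "residual covariance")
            E[np.ix_(idx, mis)] = rng.standard_normal((len(idx), p)) @ L.T
            continue
        Roo = R0[np.ix_(obs, obs)]
        Rmo = R0[np.ix_(mis, obs)]
        K = Rmo @ np.linalg.inv(Roo)              # regression coefficients
        cond_mean = E[np.ix_(idx, obs)] @ K.T
        cond_cov = R0[np.ix_(mis, mis)] - K @ Rmo.T
        L = _chol_pd(cond_cov, "conditional residual covariance")
        E[np.ix_(idx, mis)] = (cond_mean +
                               rng.standard_normal((len(idx), len(mis))) @ L.T)


# ---------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------

def _design_matrix(pheno: PhenotypeTable):
    cols = [np.ones(len(pheno.sample_ids))]
    names = ["intercept"]
    if pheno.covariates is not None:
        for c in pheno.covariates.columns:
            cols.append(pheno.covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    return np.column_stack(cols), names


def run_gibbs(panel: GenotypePanel, pheno: PhenotypeTable,
              priors: PriorSpec, blocks: BlockMap,
              config: McmcConfig, intercept: bool = True,
              residual_model: str = "diagonal",
              block_order=None) -> PosteriorSummary:
    """Run the full Gibbs sampler and return posterior summaries.

    Per cycle the updates run in a fixed order: impute missing
    phenotypes -> fixed effects -> every block's SNP effects -> every
    block's G_i -> R_0. Identical seeds give identical output.

    ``intercept=False`` drops all fixed effects (used by the
    prior/posterior self-consistency checks on degenerate models).
    """
    rng = np.random.default_rng(config.seed)
    n, p = pheno.values.shape
    s = blocks.n_blocks
    if intercept:
        X, xnames = _design_matrix(pheno)
    else:
        X, xnames = np.zeros((n, 0)), []
    q = X.shape[1]
    obs_mask = pheno.observed_mask()

    logger.info(
        "Gibbs start: n=%d p=%d snps=%d blocks=%d (%s) | df=%.1f h2=%.2f | "
        "n_iter=%d burn_in=%d thin=%d seed=%s",
        n, p, panel.n_variants, s, blocks.method, priors.df, priors.h2,
        config.n_iter, config.burn_in, config.thin, config.seed)

    # marker columns are centered by twice the merged allele frequency:
    # the intercept absorbs the offset and the SNP-effect conditionals
    # decorrelate from the mean, which single-site Gibbs needs to mix
    freqs = panel.allele_freqs()
    Mfull = np.asfortranarray(panel.dosages - 2.0 * freqs,
                              dtype=np.float64)
    m = panel.n_variants
    starts = blocks.table["start"].to_numpy(dtype=np.int64)
    stops = blocks.table["stop"].to_numpy(dtype=np.int64)
    sizes = (stops - starts).astype(float)
    mtm = np.einsum("ij,ij->j", Mfull, Mfull)
    groups = _missing_groups(obs_mask)
    order = (np.arange(s) if block_order is None
             else np.asarray(block_order, dtype=np.int64))

    # initial state: effects zero; covariances start at magnitudes
    # consistent with the prior heritability split (total genetic
    # variance h2 * P, residual (1 - h2) * P) so burn-in is short
    a = np.zeros((m, p))
    het = 2.0 * panel.allele_freqs() * (1.0 - panel.allele_freqs())
    G = np.empty((s, p, p))
    for i in range(s):
        denom = max(het[starts[i]:stops[i]].sum(), 1e-12)
        G[i] = priors.h2 * priors.P / (s * denom)
    R0 = (1.0 - priors.h2) * priors.P + 1e-12 * np.eye(p)
    B = np.zeros((q, p))
    E = np.asfortranarray(np.where(obs_mask,
                                   np.nan_to_num(pheno.values), 0.0))
    if q > 0:
        col_mean = np.array([
            pheno.values[obs_mask[:, l], l].mean() if obs_mask[:, l].any()
            else 0.0 for l in range(p)])
        B[0] = col_mean
        E -= np.where(obs_mask, X @ B, 0.0)

    n_store = config.n_stored
    acc = {
        "b": np.zeros((q, p)), "b2": np.zeros((q, p)),
        "eff": np.zeros((panel.n_variants, p)),
        "G": np.zeros((s, p, p)), "G2": np.zeros((s, p, p)),
        "R0": np.zeros((p, p)), "R02": np.zeros((p, p)),
        "corr": np.zeros((s, p, p)),
        "g": np.zeros((n, p)), "g2": np.zeros((n, p)),
    }
    stored = 0

    from ._kernels import update_all_blocks

    for it in range(1, config.n_iter + 1):
        impute_missing_residuals(E, obs_mask, R0, rng, groups=groups)
        if q > 0:
            ystar = E + X @ B          # y - genetic part
            _, Bnew = sample_fixed_effects(X, ystar, R0, rng, names=xnames)
            E += X @ (B - Bnew)
            B = Bnew
        z = rng.standard_normal((m, p))
        R0inv = np.linalg.inv(0.5 * (R0 + R0.T))
        Ginv = np.linalg.inv(0.5 * (G + np.swapaxes(G, 1, 2)))
        bad_block, bad_snp = update_all_blocks(
            E, Mfull, mtm, a, starts[order], stops[order], R0inv,
            np.ascontiguousarray(Ginv[order]), z)
        if bad_block >= 0:
            raise np.linalg.LinAlgError(
                f"non-PD conditional covariance at SNP {bad_snp} of "
                f"block {bad_block} (iteration {it})")
        outer = a[:, :, None] * a[:, None, :]
        S = np.add.reduceat(outer, starts, axis=0) + priors.B
        G = inv_wishart_batch(priors.df + sizes, S, rng)
        R0 = sample_residual_covariance(E, priors.R_p, priors.df, rng,
                                        diagonal=residual_model == "diagonal")

        if not np.isfinite(E).all():
            raise FloatingPointError(f"sampler diverged at iteration {it}")
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            gmat = Mfull @ a
            np.linalg.cholesky(G)  # raises if any stored G_i is not PD
            _chol_pd(R0, "stored R0")
            acc["b"] += B
            acc["b2"] += B ** 2
            acc["eff"] += a
            acc["G"] += G
            acc["G2"] += G ** 2
            acc["R0"] += R0
            acc["R02"] += R0 ** 2
            d = np.sqrt(np.einsum("sii->si", G))
            acc["corr"] += G / d[:, :, None] / d[:, None, :]
            acc["g"] += gmat
            acc["g2"] += gmat ** 2
            stored += 1

    assert stored == n_store
    mean = {k: v / n_store for k, v in acc.items()}

    def _sd(m2, m):
        return np.sqrt(np.maximum(m2 - m ** 2, 0.0))

    return PosteriorSummary(
        n_stored=n_store,
        trait_breeds=list(pheno.trait_breeds),
        b_mean=mean["b"], b_sd=_sd(mean["b2"], mean["b"]),
        effect_mean=mean["eff"],
        G_mean=mean["G"], G_sd=_sd(mean["G2"], mean["G"]),
        R0_mean=mean["R0"], R0_sd=_sd(mean["R02"], mean["R0"]),
        block_corr_mean=mean["corr"],
        gebv_mean=mean["g"], gebv_sd=_sd(mean["g2"], mean["g"]),
        sample_ids=pheno.sample_ids,
    )


def compute_gebv(effect_mean: np.ndarray, panel: GenotypePanel
                 ) -> np.ndarray:
    """GEBVs from posterior-mean SNP effects: dosages @ effects.

    Applies to reference and validation individuals alike; for fit
    individuals this differs from the stored-sample posterior mean only
    by Monte-Carlo error."""
    if effect_mean.shape[0] != panel.n_variants:
        raise ValueError(
            f"effect table has {effect_mean.shape[0]} SNPs but panel has "
            f"{panel.n_variants}")
    return panel.dosages.astype(float) @ effect_mean


# ---------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------

class MbBayesAB(BaseEstimator):
    """Multibreed blockwise BayesA with heterogeneous block covariances.

    Parameters
    ----------
    blocks : BlockMap or None
        Precomputed block definitions. If None, the genome is
        partitioned at fit time with ``partition`` ("ld" for the
        LD/local-minima strategy, "fixed" for runs of ``block_size``).
    n_win, spar : LD-partitioning controls (see :mod:`mbgp.partition`).
    block_size : SNPs per block for the fixed strategy (default 100).
    h2_prior : prior heritability used in the scale matrices.
    n_iter, burn_in, thin, seed : MCMC settings.

    Attributes (after fit)
    ----------------------
    blocks_ : BlockMap used.
    priors_ : PriorSpec.
    posterior_ : PosteriorSummary (GEBVs, covariances, correlations).
    gebv_ : (n, p) posterior-mean genetic values for the fit panel.
    effects_ : (m, p) posterior-mean SNP effects.
    """

    def __init__(self, blocks: BlockMap | None = None,
                 partition: str = "ld", n_win: int = 50, spar: float = 0.2,
                 block_size: int = 100, h2_prior: float = 0.5,
                 n_iter: int = 30_000, burn_in: int = 20_000,
                 thin: int = 10, seed: int | None = None,
                 residual_model: str = "diagonal"):
        self.blocks = blocks
        self.partition = partition
        self.n_win = n_win
        self.spar = spar
        self.block_size = block_size
        self.h2_prior = h2_prior
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.residual_model = residual_model

    def fit(self, panel: GenotypePanel, pheno: PhenotypeTable
            ) -> "MbBayesAB":
        if self.blocks is not None:
            blocks = self.blocks
        else:
            blocks = partition_genome(panel, method=self.partition,
                                      n_win=self.n_win, spar=self.spar,
                                      block_size=self.block_size)
        blocks.validate(panel)
        self.blocks_ = blocks
        self.priors_ = build_priors(pheno, panel, blocks,
                                    h2_prior=self.h2_prior)
        config = McmcConfig(n_iter=self.n_iter, burn_in=self.burn_in,
                            thin=self.thin, seed=self.seed)
        self.posterior_ = run_gibbs(panel, pheno, self.priors_, blocks,
                                    config,
                                    residual_model=self.residual_model)
        self.breeds_ = list(pheno.trait_breeds)
        self.freqs_ = panel.allele_freqs()
        self.gebv_ = self.posterior_.gebv_mean
        self.effects_ = self.posterior_.effect_mean
        return self

    def predict(self, panel: GenotypePanel) -> np.ndarray:
        """GEBVs (n, p) for an arbitrary panel on the same SNP set,
        centered with the training panel's allele frequencies."""
        if panel.n_variants != self.effects_.shape[0]:
            raise ValueError("panel SNP set does not match fitted effects")
        return (panel.dosages - 2.0 * self.freqs_) @ self.effects_
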