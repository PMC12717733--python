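"""Cross-validation orchestration and performance / structure statistics.

Accuracy is the Pearson correlation between GEBVs and the scoring
target (true breeding values in simulations, pre-adjusted phenotypes
otherwise); unbiasedness is the ordinary-least-squares slope of the
target on the GEBVs (1 = unbiased, < 1 = inflated GEBV spread).
Population-structure statistics: cross-breed LD-pattern consistency
(correlation of pairwise r-squared within a bp window, "R10Mbp" at the
default 10 Mbp), allele-frequency correlation over jointly segregating
SNPs, and Hudson's F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .types import GenotypePanel, PhenotypeTable

__all__ = [
    "CvPlan",
    "make_cv_plan",
    "accuracy",
    "unbiasedness",
    "paired_ttest",
    "ld_consistency",
    "allele_freq_corr",
    "hudson_fst",
    "EvalResult",
    "run_benchmark",
]


# ---------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------

@dataclass
class CvPlan:
    """Stratified-by-breed fold assignments, shared across models."""

    folds: np.ndarray       # (repeats, n) fold id per individual
    k: int
    repeats: int
    seed: int | None

    def validation_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds[repeat] == fold)


def make_cv_plan(pheno: PhenotypeTable, k: int = 5, repeats: int = 5,
                 seed=None) -> CvPlan:
    """Random folds stratified within breed; per-breed fold sizes differ
    by at most one. The same plan is applied to every model."""
    rng = np.random.default_rng(seed)
    breeds = pheno.sample_breeds
    n = len(breeds)
    folds = np.empty((repeats, n), dtype=int)
    for breed in dict.fromkeys(breeds):
        idx = np.flatnonzero(breeds == breed)
        if len(idx) < k:
            raise ValueError(
                f"breed {breed!r} has {len(idx)} individuals; cannot make "
                f"{k} folds")
        for r in range(repeats):
            perm = rng.permutation(idx)
            folds[r, perm] = np.arange(len(idx)) % k
    return CvPlan(folds=folds, k=k, repeats=repeats, seed=seed)


# ---------------------------------------------------------------------
# performance statistics
# ---------------------------------------------------------------------

def accuracy(gebv, target) -> float:
    """Pearson correlation; NaN if either vector has zero variance."""
    gebv = np.asarray(gebv, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(gebv) != len(target) or len(gebv) < 3:
        raise ValueError("aligned vectors of length >= 3 required")
    if np.std(gebv) == 0 or np.std(target) == 0:
        return float("nan")
    return float(np.corrcoef(gebv, target)[0, 1])


def unbiasedness(gebv, target) -> float:
    """OLS slope of target on GEBV: cov(t, g) / var(g)."""
    gebv = np.asarray(gebv, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(gebv) != len(target) or len(gebv) < 3:
        raise ValueError("aligned vectors of length >= 3 required")
    vg = np.var(gebv)
    if vg == 0:
        return float("nan")
    return float(np.cov(target, gebv, ddof=0)[0, 1] / vg)


class PairedTTest(NamedTuple):
    t: float
    p: float
    degenerate: bool


def paired_ttest(a, b) -> PairedTTest:
    """Two-sided paired t-test on matched performance cells.

    Conventions for degenerate inputs: all differences zero -> p = 1
    (t = 0); constant non-zero differences -> p = 0 with the degenerate
    flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired vectors of length >= 2 required")
    d = a - b
    if np.all(d == 0):
        return PairedTTest(0.0, 1.0, True)
    if np.std(d) <= 1e-12 * max(abs(d.mean()), 1.0):
        return PairedTTest(np.inf if d[0] > 0 else -np.inf, 0.0, True)
    t, p = stats.ttest_rel(a, b)
    return PairedTTest(float(t), float(p), False)


# ---------------------------------------------------------------------
# population-structure statistics
# ---------------------------------------------------------------------

def _segregating(panel: GenotypePanel) -> np.ndarray:
    f = panel.allele_freqs()
    return (f > 0) & (f < 1)


def _r2_pairs(dosages: np.ndarray, pos: np.ndarray, window_bp: float):
    """Composite-LD r^2 (squared dosage correlation) for all SNP pairs
    closer than window_bp on one chromosome; returns (i, j, r2)."""
    M = dosages.astype(float)
    sd = M.std(axis=0)
    Z = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    C = (Z.T @ Z) / len(M)
    iu, ju = np.triu_indices(M.shape[1], k=1)
    close = (pos[ju] - pos[iu]) < window_bp
    return iu[close], ju[close], (C[iu[close], ju[close]]) ** 2


def ld_consistency(panel_a: GenotypePanel, panel_b: GenotypePanel,
                   window_bp: float = 10_000_000) -> float:
    """Correlation across breeds of pairwise r^2 within a bp window
    (R10Mbp at the default window). Only SNPs segregating in both
    panels contribute; panels must share the variant map."""
    if panel_a.n_variants != panel_b.n_variants:
        raise ValueError("panels must share the SNP set")
    shared = _segregating(panel_a) & _segregating(panel_b)
    va, vb = [], []
    for chrom in panel_a.chromosomes():
        sl = panel_a.chrom_slice(chrom)
        keep = shared[sl]
        if keep.sum() < 2:
            continue
        pos = panel_a.variants["pos"].to_numpy()[sl][keep]
        da = panel_a.dosages[:, sl][:, keep]
        db = panel_b.dosages[:, sl][:, keep]
        _, _, ra = _r2_pairs(da, pos, window_bp)
        _, _, rb = _r2_pairs(db, pos, window_bp)
        va.append(ra)
        vb.append(rb)
    if not va:
        raise ValueError("no SNP pairs within the window")
    va, vb = np.concatenate(va), np.concatenate(vb)
    if len(va) == 0:
        raise ValueError("no SNP pairs within the window")
    return float(np.corrcoef(va, vb)[0, 1])


def allele_freq_corr(panel_a: GenotypePanel, panel_b: GenotypePanel
                     ) -> float:
    """Pearson correlation of allele-frequency vectors over SNPs that
    segregate simultaneously in both panels."""
    if panel_a.n_variants != panel_b.n_variants:
        raise ValueError("panels must share the SNP set")
    keep = _segregating(panel_a) & _segregating(panel_b)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 jointly segregating SNPs")
    fa = panel_a.dosages[:, keep].mean(axis=0) / 2.0
    fb = panel_b.dosages[:, keep].mean(axis=0) / 2.0
    return float(np.corrcoef(fa, fb)[0, 1])


def hudson_fst(panel_a: GenotypePanel, panel_b: GenotypePanel) -> float:
    """Hudson's F_ST (ratio-of-averages estimator) between two panels."""
    pa = panel_a.allele_freqs()
    pb = panel_b.allele_freqs()
    na = 2.0 * panel_a.n_samples
    nb = 2.0 * panel_b.n_samples
    num = ((pa - pb) ** 2 - pa * (1 - pa) / (na - 1)
           - pb * (1 - pb) / (nb - 1))
    den = pa * (1 - pb) + pb * (1 - pa)
    keep = den > 0
    return float(num[keep].mean() / den[keep].mean())


# ---------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------

@dataclass
class EvalResult:
    """Per-cell scores plus helpers for aggregation and paired tests."""

    cells: pd.DataFrame  # model, breed, repeat, fold, accuracy, slope

    def aggregate(self) -> pd.DataFrame:
        def _agg(g):
            return pd.Series({
                "accuracy": g["accuracy"].mean(),
                "accuracy_se": g["accuracy"].std(ddof=1)
                / np.sqrt(len(g)),
                "slope": g["slope"].mean(),
                "slope_se": g["slope"].std(ddof=1) / np.sqrt(len(g)),
                "n_cells": len(g),
            })
        return (self.cells.groupby(["model", "breed"])
                .apply(_agg, include_groups=False).reset_index())

    def pairwise_pvalues(self, metric: str = "accuracy") -> pd.DataFrame:
        """Paired t-tests between models on matched (breed, repeat,
        fold) cells."""
        wide = self.cells.pivot_table(
            index=["breed", "repeat", "fold"], columns="model",
            values=metric, aggfunc="first")
        models = list(wide.columns)
        rows = []
        for i, ma in enumerate(models):
            for mb in models[i + 1:]:
                ok = wide[[ma, mb]].dropna()
                res = paired_ttest(ok[ma], ok[mb])
                rows.append((ma, mb, res.t, res.p, res.degenerate))
        return pd.DataFrame(rows, columns=["model_a", "model_b", "t", "p",
                                           "degenerate"])


def _own_gebv(estimator, pheno: PhenotypeTable) -> np.ndarray:
    """Normalize a fitted model's GEBVs to one value per individual
    (its own breed-trait column for multitrait models)."""
    g = np.asarray(estimator.gebv_)
    if g.ndim == 1:
        return g
    return g[np.arange(g.shape[0]), pheno.own_trait_index()]


def run_benchmark(panel: GenotypePanel, pheno: PhenotypeTable,
                  models: dict, plan: CvPlan, targets: np.ndarray,
                  validation_breeds=None, seed=None) -> EvalResult:
    """Cross-validated comparison of registered models.

    For every (repeat, fold): the validation individuals' phenotypes are
    masked, every model is fitted on the identical reference, and the
    validation individuals are scored per breed against ``targets``
    (own-breed true breeding value in simulations, or pre-adjusted
    phenotype). Stochastic models get a per-cell seed derived from
    ``seed`` so reruns are reproducible.
    """
    targets = np.asarray(targets, dtype=float)
    breeds = (list(dict.fromkeys(pheno.sample_breeds))
              if validation_breeds is None else list(validation_breeds))
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep in range(plan.repeats):
        for fold in range(plan.k):
            val = plan.validation_indices(rep, fold)
            masked = pheno.mask_samples(val)
            for name, proto in models.items():
                est = clone(proto)
                if "seed" in est.get_params():
                    sub = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                    est.set_params(seed=sub)
                est.fit(panel, masked)
                gebv = _own_gebv(est, pheno)
                for breed in breeds:
                    vb = val[pheno.sample_breeds[val] == breed]
                    if len(vb) < 3:
                        continue
                    rows.append((name, breed, rep, fold,
                                 accuracy(gebv[vb], targets[vb]),
                                 unbiasedness(gebv[vb], targets[vb])))
    return EvalResult(pd.DataFrame(
        rows, columns=["model", "breed", "repeat", "fold", "accuracy",
                       "slope"]))


def preadjusted_targets(panel: GenotypePanel, pheno: PhenotypeTable
                        ) -> np.ndarray:
    """Pre-adjusted phenotypes for real-style scoring: own-breed record
    minus the fixed-effect estimates of a single-trait model fitted once
    on the full data."""
    from .gblup import STGBLUP, _design

    st = STGBLUP().fit(panel, pheno)
    X = _design(pheno, np.arange(panel.n_samples))
    return pheno.own_values() - X @ st.b_
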