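"""GBLUP baselines: VanRaden GRM, REML variance components, BLUP GEBVs.

STGBLUP pools every breed into a single population with one genetic
variance (a ~ N(0, G sigma_a^2)); variance components come from exact
spectral REML (a single random effect permits working in the GRM's
eigenbasis, where the restricted likelihood is a cheap 1-D profile).

MTGBLUP treats the same trait in each breed as distinct traits,
a ~ N(0, G0 (x) G), with every individual observing exactly one trait
(missing by design). Residual covariances across breed-traits are not
identifiable under that pattern and are fixed at zero. (G0, diag R0)
are estimated by direct REML: the restricted log-likelihood of the
observed records is maximized by L-BFGS-B on a Cholesky/log
parameterization with analytic gradients, which is robust where
average-information iterations are fragile under missing-by-design.

Validation individuals are carried inside the GRM with their phenotypes
set missing and receive GEBVs through their relationship rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator

from .types import GenotypePanel, PhenotypeTable

__all__ = ["GRM", "build_grm", "STGBLUP", "MTGBLUP"]


@dataclass
class GRM:
    """VanRaden genomic relationship matrix.

    matrix = Z Z' / (2 sum p_j (1 - p_j)) with Z the dosage matrix
    column-centered by twice the joint-reference allele frequency.
    Monomorphic SNPs contribute zero and are excluded from the
    denominator.
    """

    matrix: np.ndarray
    freqs: np.ndarray
    denom: float


def build_grm(panel: GenotypePanel, freqs: np.ndarray | None = None) -> GRM:
    """GRM from the merged panel with joint-reference allele frequencies."""
    M = panel.dosages.astype(float)
    if freqs is None:
        freqs = M.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; GRM undefined")
    Z = M - 2.0 * freqs
    Z[:, ~poly] = 0.0
    denom = float(2.0 * np.sum(freqs[poly] * (1.0 - freqs[poly])))
    return GRM(matrix=(Z @ Z.T) / denom, freqs=freqs, denom=denom)


def _design(pheno: PhenotypeTable, rows: np.ndarray) -> np.ndarray:
    cols = [np.ones(len(rows))]
    if pheno.covariates is not None:
        for c in pheno.covariates.columns:
            cols.append(pheno.covariates[c].to_numpy(dtype=float)[rows])
    return np.column_stack(cols)


class STGBLUP(BaseEstimator):
    """Single-trait GBLUP over the pooled multibreed reference.

    Attributes (after fit): ``sigma_a2_``, ``sigma_e2_``, ``h2_``,
    ``loglik_``, ``b_``, ``gebv_`` (length-n vector, one genetic value
    per individual, validation individuals included).
    """

    def __init__(self, grm: GRM | None = None, jitter: float = 1e-8):
        self.grm = grm
        self.jitter = jitter

    def fit(self, panel: GenotypePanel, pheno: PhenotypeTable) -> "STGBLUP":
        grm = self.grm if self.grm is not None else build_grm(panel)
        self.grm_ = grm
        y_all = pheno.own_values()
        ref = np.flatnonzero(np.isfinite(y_all))
        if len(ref) < 3:
            raise ValueError("fewer than 3 observed phenotypes")
        y = y_all[ref]
        X = _design(pheno, ref)
        Gm = grm.matrix[np.ix_(ref, ref)] + self.jitter * np.eye(len(ref))

        d, U = np.linalg.eigh(Gm)
        d = np.maximum(d, 0.0)
        yt, Xt = U.T @ y, U.T @ X
        n, q = len(y), X.shape[1]

        def neg_restricted_ll(log_lam: float) -> float:
            lam = np.exp(log_lam)
            v = lam * d + 1.0
            Xv = Xt / v[:, None]
            XtVX = Xt.T @ Xv
            beta = np.linalg.solve(XtVX, Xv.T @ yt)
            r = yt - Xt @ beta
            rss = float(r @ (r / v))
            sigma_e2 = rss / (n - q)
            return 0.5 * ((n - q) * np.log(sigma_e2) + np.log(v).sum()
                          + np.linalg.slogdet(XtVX)[1] + (n - q))

        res = minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0),
                              method="bounded",
                              options={"xatol": 1e-10})
        if not res.success:
            raise RuntimeError(f"spectral REML failed: {res}")
        lam = float(np.exp(res.x))
        v = lam * d + 1.0
        Xv = Xt / v[:, None]
        XtVX = Xt.T @ Xv
        beta = np.linalg.solve(XtVX, Xv.T @ yt)
        r = yt - Xt @ beta
        sigma_e2 = float(r @ (r / v)) / (n - q)
        sigma_a2 = lam * sigma_e2

        self.b_ = beta
        self.sigma_e2_ = sigma_e2
        self.sigma_a2_ = sigma_a2
        self.h2_ = sigma_a2 / (sigma_a2 + sigma_e2)
        self.loglik_ = -float(res.fun) - 0.5 * (n - q) * np.log(2 * np.pi)
        # BLUP through the relationship rows: a_hat = sa2 G[:,ref] V^-1 r
        w = U @ (r / (sigma_a2 * d + sigma_e2))
        self.gebv_ = sigma_a2 * grm.matrix[:, ref] @ w
        self.reference_ = ref
        return self

    def predict(self, idx=None) -> np.ndarray:
        return self.gebv_ if idx is None else self.gebv_[np.asarray(idx)]


class MTGBLUP(BaseEstimator):
    """Multitrait GBLUP with each breed's trait distinct, a ~ N(0, G0 x G).

    Attributes (after fit): ``G0_`` (p x p genetic covariance), ``R0_``
    (diagonal residual covariance), ``genetic_correlation_`` (p x p),
    ``loglik_``, ``gebv_`` ((n, p) genetic value of every individual for
    every breed-trait), ``loglik_path_`` (accepted-iterate likelihoods,
    non-decreasing).
    """

    def __init__(self, grm: GRM | None = None, jitter: float = 1e-8,
                 max_iter: int = 200, tol: float = 1e-9):
        self.grm = grm
        self.jitter = jitter
        self.max_iter = max_iter
        self.tol = tol

    # -- restricted likelihood and gradient ----------------------------
    @staticmethod
    def _nll_grad(params, Gm, trait_of, y, X, p):
        ntri = p * (p + 1) // 2
        L = np.zeros((p, p))
        iu = np.tril_indices(p)
        L[iu] = params[:ntri]
        diag = np.arange(p)
        L[diag, diag] = np.exp(params[:ntri][_diag_pos(p)])
        G0 = L @ L.T
        sigma_e2 = np.exp(params[ntri:])
        n, q = len(y), X.shape[1]

        V = G0[np.ix_(trait_of, trait_of)] * Gm
        V[np.diag_indices_from(V)] += sigma_e2[trait_of]
        cf = np.linalg.cholesky(V)
        Vinv = np.linalg.inv(V)
        XtVinv = X.T @ Vinv
        XtVX = XtVinv @ X
        beta = np.linalg.solve(XtVX, XtVinv @ y)
        r = y - X @ beta
        Py = Vinv @ r
        nll = 0.5 * (2.0 * np.log(np.diag(cf)).sum()
                     + np.linalg.slogdet(XtVX)[1] + float(r @ Py))

        # P = Vinv - Vinv X (X'Vinv X)^-1 X' Vinv
        W = np.linalg.solve(XtVX, XtVinv)
        P = Vinv - XtVinv.T @ W

        # gradient wrt symmetric G0 entries and sigma_e2
        gG0 = np.zeros((p, p))
        ge = np.zeros(p)
        PyPy = np.outer(Py, Py)
        D = P - PyPy                      # tr(D V_k) / 2 is the gradient
        for a in range(p):
            ia = trait_of == a
            ge[a] = 0.5 * float(np.diag(D)[ia].sum())
            for b in range(a, p):
                ib = trait_of == b
                Vk = np.zeros_like(Gm)
                Vk[np.ix_(ia, ib)] = Gm[np.ix_(ia, ib)]
                if a != b:
                    Vk[np.ix_(ib, ia)] = Gm[np.ix_(ib, ia)]
                gG0[a, b] = gG0[b, a] = 0.5 * float(np.sum(D * Vk))
        # chain rule to Cholesky factor: with Gamma_ab = s_ab/2 (a != b),
        # Gamma_aa = s_aa, dNLL/dL = 2 Gamma L
        gL = (gG0 + np.diag(np.diag(gG0))) @ L
        gvec = np.zeros_like(params)
        tri = gL[iu].copy()
        tri[_diag_pos(p)] *= L[diag, diag]  # log-diag parameterization
        gvec[:ntri] = tri
        gvec[ntri:] = ge * sigma_e2
        return nll, gvec, (G0, sigma_e2, beta, Vinv, r, Py)

    def fit(self, panel: GenotypePanel, pheno: PhenotypeTable) -> "MTGBLUP":
        grm = self.grm if self.grm is not None else build_grm(panel)
        self.grm_ = grm
        p = pheno.n_traits
        own = pheno.own_trait_index()
        y_all = pheno.own_values()
        ref = np.flatnonzero(np.isfinite(y_all))
        y = y_all[ref]
        trait_of = own[ref]
        # per-trait fixed effects: trait intercepts (+ covariates per trait)
        base = _design(pheno, ref)
        X = np.zeros((len(ref), base.shape[1] * p))
        for l in range(p):
            rows = trait_of == l
            X[rows, l * base.shape[1]:(l + 1) * base.shape[1]] = base[rows]
        keep = np.abs(X).sum(axis=0) > 0
        X = X[:, keep]
        Gm = grm.matrix[np.ix_(ref, ref)] + self.jitter * np.eye(len(ref))

        # init from per-trait phenotypic variances split 50/50
        var0 = np.array([max(np.var(y[trait_of == l], ddof=1), 1e-8)
                         if (trait_of == l).sum() > 1 else 1.0
                         for l in range(p)])
        ntri = p * (p + 1) // 2
        x0 = np.zeros(ntri + p)
        L0 = np.diag(np.sqrt(0.5 * var0))
        tri0 = L0[np.tril_indices(p)]
        tri0[_diag_pos(p)] = np.log(np.diag(L0))
        x0[:ntri] = tri0
        x0[ntri:] = np.log(0.5 * var0)

        path = []
        cache = {}

        def fun(params):
            nll, g, _ = self._nll_grad(params, Gm, trait_of, y, X, p)
            cache[params.tobytes()] = nll
            return nll, g

        def cb(params):
            nll = cache.get(params.tobytes())
            if nll is None:
                nll = self._nll_grad(params, Gm, trait_of, y, X, p)[0]
            path.append(-nll)

        res = minimize(fun, x0, jac=True, method="L-BFGS-B", callback=cb,
                       options={"maxiter": self.max_iter, "ftol": 1e-14,
                                "gtol": self.tol})
        nll, _, (G0, sigma_e2, beta, Vinv, r, Py) = self._nll_grad(
            res.x, Gm, trait_of, y, X, p)
        self.converged_ = bool(res.success)
        self.loglik_ = -float(nll) - 0.5 * (len(y) - X.shape[1]) \
            * np.log(2 * np.pi)
        self.loglik_path_ = np.array(path)
        self.G0_ = G0
        self.R0_ = np.diag(sigma_e2)
        dsd = np.sqrt(np.diag(G0))
        self.genetic_correlation_ = G0 / np.outer(dsd, dsd)
        self.b_ = beta

        # GEBVs for every individual x breed-trait through the GRM rows
        n_all = grm.matrix.shape[0]
        gebv = np.empty((n_all, p))
        for l in range(p):
            wgt = G0[l, trait_of] * Py
            gebv[:, l] = grm.matrix[:, ref] @ wgt
        self.gebv_ = gebv
        self.reference_ = ref
        self.trait_breeds_ = list(pheno.trait_breeds)
        return self

    def predict(self, idx=None) -> np.ndarray:
        return self.gebv_ if idx is None else self.gebv_[np.asarray(idx)]


def _diag_pos(p: int) -> np.ndarray:
    """Positions of the diagonal entries inside tril_indices order."""
    iu = np.tril_indices(p)
    return np.flatnonzero(iu[0] == iu[1])
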