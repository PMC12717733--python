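"""Numba inner loops for the blockwise multitrait Gibbs sampler.

All randomness is pre-drawn outside (numpy Generator) so the kernels are
pure deterministic algebra; this keeps runs bit-reproducible with one
RNG stream. Matrices are tiny (p x p, p = number of breeds), so
Cholesky factorization and triangular solves are hand-rolled loops
rather than LAPACK calls. The residual matrix E and the dosage matrix
M should be Fortran-ordered so the per-trait/per-SNP inner loops run
over contiguous memory.
"""

import numba
import numpy as np

__all__ = ["update_block_effects", "update_all_blocks", "NUMBA_OK"]

NUMBA_OK = True


@numba.njit(cache=False, fastmath=True, inline="always")
def _snp_update(E, M, mtm, a, R0inv, Ginv, z, j, C, L, rhs, mean, anew):
    """Draw one SNP's p-vector effect from its full conditional
    N(C^-1 R0inv (E + m a_j')' m, C^-1), C = (m'm) R0inv + Ginv, and
    update the residuals E in place. Returns False on a non-PD C."""
    n, p = E.shape
    # m'(E + m a_j'): per-trait contiguous passes (E Fortran-ordered)
    for t in range(p):
        s = 0.0
        for i in range(n):
            s += M[i, j] * E[i, t]
        rhs[t] = s + mtm[j] * a[j, t]
    for t in range(p):
        s = 0.0
        for u in range(p):
            s += R0inv[t, u] * rhs[u]
        mean[t] = s
    for t in range(p):
        for u in range(p):
            C[t, u] = mtm[j] * R0inv[t, u] + Ginv[t, u]
    # Cholesky C = L L'
    for i in range(p):
        for k in range(i + 1):
            s = C[i, k]
            for u in range(k):
                s -= L[i, u] * L[k, u]
            if i == k:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, k] = s / L[k, k]
    # mean <- C^-1 (R0inv rhs): solve L v = mean, then L' mean = v
    for t in range(p):
        s = mean[t]
        for u in range(t):
            s -= L[t, u] * rhs[u]
        rhs[t] = s / L[t, t]
    for t in range(p - 1, -1, -1):
        s = rhs[t]
        for u in range(t + 1, p):
            s -= L[u, t] * mean[u]
        mean[t] = s / L[t, t]
    # draw: anew = mean + L'^{-1} z  (covariance C^-1)
    for t in range(p - 1, -1, -1):
        s = z[j, t]
        for u in range(t + 1, p):
            s -= L[u, t] * anew[u]
        anew[t] = s / L[t, t]
    # E <- E - m (anew + mean - a_j)'
    for t in range(p):
        anew[t] += mean[t]
        delta = anew[t] - a[j, t]
        a[j, t] = anew[t]
        for i in range(n):
            E[i, t] -= M[i, j] * delta
    return True


@numba.njit(cache=False, fastmath=True)
def update_block_effects(E, M, mtm, a, R0inv, Ginv, z):
    """One Gibbs pass over the SNPs of one block (arrays block-local).

    E is (n, p) residuals (y - Xb - all genetic terms), updated in
    place together with the (m_i, p) effects a. Returns the index of
    the first SNP whose conditional covariance was not positive
    definite, or -1 on success.
    """
    p = E.shape[1]
    C = np.empty((p, p))
    L = np.empty((p, p))
    rhs = np.empty(p)
    mean = np.empty(p)
    anew = np.empty(p)
    for j in range(M.shape[1]):
        if not _snp_update(E, M, mtm, a, R0inv, Ginv, z, j,
                           C, L, rhs, mean, anew):
            return j
    return -1


@numba.njit(cache=False, fastmath=True)
def update_all_blocks(E, M, mtm, a, starts, stops, R0inv, Ginv_all, z):
    """One Gibbs pass over every block's SNPs in one flat loop.

    ``M``/``a``/``z`` cover the whole genome; ``starts``/``stops`` give
    each block's SNP range and ``Ginv_all`` its current effect
    precision. Returns (block, snp) of the first non-PD conditional, or
    (-1, -1) on success."""
    p = E.shape[1]
    C = np.empty((p, p))
    L = np.empty((p, p))
    rhs = np.empty(p)
    mean = np.empty(p)
    anew = np.empty(p)
    for b in range(len(starts)):
        Ginv = Ginv_all[b]
        for j in range(starts[b], stops[b]):
            if not _snp_update(E, M, mtm, a, R0inv, Ginv, z, j,
                               C, L, rhs, mean, anew):
                return b, j - starts[b]
    return -1, -1
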