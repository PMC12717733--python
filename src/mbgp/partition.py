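"""LD-based genome partitioning into blocks.

For every candidate breakpoint SNP *k* on a chromosome, the statistic

    w_k = mean of Corr[M_i, M_j]^2 over all dosage-column pairs (i, j)
          that span k (i <= k < j) with lag j - i <= N_win

measures how strongly the SNPs on the two sides of *k* are still in LD:
w_k near 1 means *k* sits inside a tight LD block, w_k near 0 means the
association is broken there. The w curve is smoothed with a penalized
cubic smoothing spline (penalty expressed through the familiar R
``smooth.spline`` ``spar`` scale) and every strict interior local
minimum of the smoothed curve becomes a block boundary. A fixed-size
partitioner (consecutive runs of ``block_size`` SNPs) is provided as the
comparator strategy.

Partitioning always uses the merged (all-breeds) reference panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline
from sklearn.base import BaseEstimator

from .types import BlockMap, GenotypePanel

__all__ = [
    "WProfile",
    "compute_w",
    "smooth_w",
    "find_breakpoints",
    "partition_fixed",
    "partition_genome",
    "LDBlockPartitioner",
]


@dataclass
class WProfile:
    """Raw and smoothed w statistic along one chromosome.

    ``w[k]`` refers to the breakpoint candidate between SNP k and k+1
    (0-based); it is NaN where no valid spanning pair exists (e.g. all
    pairs involve monomorphic columns) and for the last SNP.
    """

    chrom: object
    w: np.ndarray
    w_smooth: np.ndarray | None
    n_win: int
    spar: float | None = None


def compute_w(panel: GenotypePanel, chrom, n_win: int = 50) -> WProfile:
    """w statistic for every candidate breakpoint on one chromosome.

    Pairs with an undefined Pearson correlation (a monomorphic column on
    the merged panel) are excluded from the average and the pair count
    m_k is decremented; if no pair remains, w_k is NaN.
    """
    if n_win < 1:
        raise ValueError("n_win must be >= 1")
    sl = panel.chrom_slice(chrom)
    M = panel.dosages[:, sl].astype(float)
    n, m = M.shape
    if m < 2:
        raise ValueError(f"chromosome {chrom!r} has fewer than 2 SNPs")

    Z = M - M.mean(axis=0)
    sd = Z.std(axis=0)
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(ok, Z / np.where(ok, sd, 1.0), np.nan)

    # c2[d-1, i] = squared correlation of columns i and i+d (NaN if invalid)
    wsum = np.zeros(m)
    wcnt = np.zeros(m, dtype=int)
    for d in range(1, min(n_win, m - 1) + 1):
        c = np.einsum("ni,ni->i", Z[:, :-d], Z[:, d:]) / n
        c2 = c * c  # NaN propagates from invalid columns
        valid = np.isfinite(c2)
        vals = np.where(valid, c2, 0.0)
        # pair (i, i+d) contributes to every k in [i, i+d-1]
        acc = np.zeros(m + 1)
        cnt = np.zeros(m + 1)
        np.add.at(acc, np.arange(m - d), vals)
        np.add.at(acc, np.arange(d, m), -vals)
        np.add.at(cnt, np.arange(m - d), valid.astype(float))
        np.add.at(cnt, np.arange(d, m), -valid.astype(float))
        wsum += np.cumsum(acc[:-1])
        wcnt += np.cumsum(cnt[:-1]).astype(int)
    with np.errstate(invalid="ignore"):
        w = np.where(wcnt > 0, wsum / np.maximum(wcnt, 1), np.nan)
    w[-1] = np.nan  # no pair spans beyond the last SNP
    return WProfile(chrom, w, None, n_win)


def _spar_to_lam(x01: np.ndarray, spar: float) -> float:
    """Map R smooth.spline's spar to the roughness penalty lambda.

    lambda = r * 256^(3 spar - 1) with r = tr(X'X) / tr(Omega) computed
    on the cubic B-spline basis with knots at the (rescaled) data points;
    Omega is the Gram matrix of second derivatives.
    """
    t = np.concatenate([[x01[0]] * 3, x01, [x01[-1]] * 3])
    nb = len(t) - 4
    X = BSpline.design_matrix(x01, t, 3)
    tr_x = float(X.multiply(X).sum())
    # tr(Omega) = sum_i int (B_i'')^2, each basis spans <= 4 intervals
    gx, gw = np.polynomial.legendre.leggauss(4)
    tr_om = 0.0
    coef = np.zeros(nb)
    for i in range(nb):
        coef[i] = 1.0
        d2 = BSpline(t, coef, 3).derivative(2)
        a, b = t[i], t[i + 4]
        knots = np.unique(t[(t >= a) & (t <= b)])
        for lo, hi in zip(knots[:-1], knots[1:]):
            pts = 0.5 * (hi - lo) * gx + 0.5 * (hi + lo)
            tr_om += 0.5 * (hi - lo) * float(np.sum(gw * d2(pts) ** 2))
        coef[i] = 0.0
    return tr_x / tr_om * 256.0 ** (3.0 * spar - 1.0)


def smooth_w(profile: WProfile, spar: float = 0.2,
             lam: float | None = None) -> WProfile:
    """Smooth the raw w curve with a penalized cubic smoothing spline.

    ``spar`` is mapped onto the spline penalty following the
    R ``smooth.spline`` convention; pass ``lam`` to set the penalty
    directly (on x rescaled to [0, 1]). Missing raw values are bridged:
    the spline is fitted on the defined points and evaluated everywhere.
    """
    w = profile.w
    m = len(w)
    defined = np.flatnonzero(np.isfinite(w))
    # a cubic smoothing spline needs 5 points; fewer -> pass-through
    if len(defined) < 5:
        warnings.warn(
            f"chromosome {profile.chrom!r}: only {len(defined)} defined w "
            "values; smoothing skipped (pass-through)", stacklevel=2)
        return WProfile(profile.chrom, w, w.copy(), profile.n_win, spar)
    x = defined.astype(float)
    x01 = (x - x[0]) / (x[-1] - x[0])
    if lam is None:
        lam = _spar_to_lam(x01, spar)
    spl = make_smoothing_spline(x01, w[defined], lam=lam)
    xs_all = (np.arange(m, dtype=float) - x[0]) / (x[-1] - x[0])
    smooth = spl(np.clip(xs_all, 0.0, 1.0))
    return WProfile(profile.chrom, w, smooth, profile.n_win, spar)


def _local_minima(y: np.ndarray) -> list[int]:
    """Strict interior local minima; a flat run lower than both
    neighbours yields its last index. Boundary points never qualify."""
    m = len(y)
    minima = []
    i = 1
    while i < m - 1:
        j = i
        while j + 1 < m and y[j + 1] == y[i]:
            j += 1
        if j < m - 1 and y[i - 1] > y[i] and y[j + 1] > y[j]:
            minima.append(j)
        i = j + 1
    return minima


def find_breakpoints(profile: WProfile, panel: GenotypePanel | None = None,
                     offset: int = 0) -> BlockMap:
    """Turn local minima of the smoothed w curve into a single-chromosome
    block map. A breakpoint at SNP k ends its block at k (inclusive).

    ``offset`` is the chromosome's global first-SNP index, so block
    indices are global when partitioning a multi-chromosome panel.
    """
    if profile.w_smooth is None:
        raise ValueError("smooth the profile before locating breakpoints")
    y = profile.w_smooth
    m = len(y)
    if panel is not None:
        offset = panel.chrom_slice(profile.chrom).start
    bps = _local_minima(y)
    edges = [0] + [k + 1 for k in bps] + [m]
    table = pd.DataFrame({
        "chrom": [profile.chrom] * (len(edges) - 1),
        "start": [offset + a for a in edges[:-1]],
        "stop": [offset + b for b in edges[1:]],
    })
    return BlockMap(table, method="ld",
                    params={"n_win": profile.n_win, "spar": profile.spar})


def partition_fixed(n_snps_per_chrom, block_size: int = 100) -> BlockMap:
    """Consecutive runs of ``block_size`` SNPs per chromosome; the final
    block holds the remainder. Blocks never cross chromosome boundaries.

    ``n_snps_per_chrom``: dict chrom -> SNP count (or list of counts).
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not isinstance(n_snps_per_chrom, dict):
        n_snps_per_chrom = {i: c for i, c in enumerate(n_snps_per_chrom)}
    rows = []
    offset = 0
    for chrom, m in n_snps_per_chrom.items():
        edges = list(range(0, m, block_size)) + [m]
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append((chrom, offset + a, offset + b))
        offset += m
    table = pd.DataFrame(rows, columns=["chrom", "start", "stop"])
    return BlockMap(table, method="fixed", params={"block_size": block_size})


def partition_genome(panel: GenotypePanel, method: str = "ld",
                     n_win: int = 50, spar: float = 0.2,
                     block_size: int = 100,
                     lam: float | None = None) -> BlockMap:
    """Partition every chromosome of the merged panel.

    ``method="ld"`` runs the w-statistic / smoothing / local-minima
    procedure per chromosome; ``method="fixed"`` cuts consecutive runs
    of ``block_size`` SNPs.
    """
    if method == "fixed":
        counts = {c: panel.chrom_slice(c).stop - panel.chrom_slice(c).start
                  for c in panel.chromosomes()}
        return partition_fixed(counts, block_size=block_size)
    if method != "ld":
        raise ValueError(f"unknown partition method {method!r}")
    maps = []
    for chrom in panel.chromosomes():
        prof = smooth_w(compute_w(panel, chrom, n_win=n_win),
                        spar=spar, lam=lam)
        maps.append(find_breakpoints(prof, panel=panel))
    return BlockMap.concat(maps, method="ld",
                           params={"n_win": n_win, "spar": spar})


class LDBlockPartitioner(BaseEstimator):
    """Genome partitioner with the scikit-learn estimator protocol.

    Parameters
    ----------
    method : "ld" or "fixed"
    n_win : int, window (in SNPs) limiting the pair lag for w_k
    spar : float, smoothing parameter on the R smooth.spline scale
    block_size : int, SNPs per block for the fixed strategy
    lam : float or None, direct roughness penalty override

    After :meth:`fit`, ``blocks_`` holds the :class:`BlockMap` and (for
    the LD method) ``profiles_`` the per-chromosome w profiles.
    """

    def __init__(self, method: str = "ld", n_win: int = 50,
                 spar: float = 0.2, block_size: int = 100,
                 lam: float | None = None):
        self.method = method
        self.n_win = n_win
        self.spar = spar
        self.block_size = block_size
        self.lam = lam

    def fit(self, panel: GenotypePanel, y=None) -> "LDBlockPartitioner":
        if self.method == "ld":
            self.profiles_ = {
                chrom: smooth_w(compute_w(panel, chrom, n_win=self.n_win),
                                spar=self.spar, lam=self.lam)
                for chrom in panel.chromosomes()
            }
            maps = [find_breakpoints(p, panel=panel)
                    for p in self.profiles_.values()]
            self.blocks_ = BlockMap.concat(
                maps, "ld", {"n_win": self.n_win, "spar": self.spar})
        else:
            self.blocks_ = partition_genome(panel, method=self.method,
                                            block_size=self.block_size)
        self.blocks_.validate(panel)
        return self

    def transform(self, panel: GenotypePanel) -> BlockMap:
        return self.blocks_
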