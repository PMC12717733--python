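"""w statistic, smoothing, breakpoint detection and block tiling."""

import numpy as np
import pandas as pd
import pytest

from mbgp.partition import (LDBlockPartitioner, WProfile, compute_w,
                            find_breakpoints, partition_fixed,
                            partition_genome, smooth_w)

from conftest import make_panel, random_panel


def brute_force_w(M, n_win):
    """Enumerate every spanning pair (i <= k < j, j - i <= n_win),
    Pearson-correlate the raw columns, square, and average."""
    n, m = M.shape
    w = np.full(m, np.nan)
    for k in range(m):
        vals = []
        for i in range(max(0, k - n_win + 1), k + 1):
            for j in range(k + 1, min(k + n_win, m - 1) + 1):
                if j - i > n_win:
                    continue
                if np.std(M[:, i]) == 0 or np.std(M[:, j]) == 0:
                    continue
                vals.append(np.corrcoef(M[:, i], M[:, j])[0, 1] ** 2)
        if vals:
            w[k] = np.mean(vals)
    return w


class TestComputeW:
    def test_identical_columns_give_w_one(self):
        col = [0, 1, 2, 1, 0, 1, 2, 1]
        panel = make_panel(np.tile(np.array(col)[:, None], (1, 5)))
        prof = compute_w(panel, "1", n_win=3)
        np.testing.assert_allclose(prof.w[:-1], 1.0, atol=1e-12)

    def test_matches_brute_force_on_fixed_matrix(self):
        M = np.array([
            [0, 1, 2, 0, 1, 2],
            [1, 2, 1, 0, 0, 1],
            [2, 2, 0, 1, 1, 0],
            [0, 0, 1, 2, 2, 1],
            [1, 1, 2, 2, 0, 0],
            [2, 0, 0, 1, 2, 2],
            [0, 2, 1, 1, 0, 1],
            [1, 0, 2, 0, 1, 2],
        ])
        prof = compute_w(make_panel(M), "1", n_win=2)
        np.testing.assert_allclose(prof.w, brute_force_w(M, 2), atol=1e-12)

    def test_zero_variance_column_pairs_excluded(self):
        M = np.array([
            [0, 1, 1, 2],
            [1, 1, 0, 1],
            [2, 1, 2, 0],
            [0, 1, 1, 2],
        ])  # column 1 monomorphic
        prof = compute_w(make_panel(M), "1", n_win=3)
        np.testing.assert_allclose(prof.w, brute_force_w(M, 3), atol=1e-12)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_on_random_fixtures(self, trial):
        rng = np.random.default_rng(500 + trial)
        m = int(rng.integers(10, 61))
        n = int(rng.integers(6, 25))
        n_win = int(rng.integers(1, 8))
        M = rng.binomial(2, rng.uniform(0.05, 0.95, m), size=(n, m))
        if trial % 2:
            M[:, int(rng.integers(0, m))] = 1  # monomorphic column
        prof = compute_w(make_panel(M), "1", n_win=n_win)
        np.testing.assert_allclose(prof.w, brute_force_w(M, n_win),
                                   atol=1e-12)

    def test_larger_window_never_undefines_w(self, rng):
        M = rng.binomial(2, 0.3, size=(12, 30))
        M[:, 5] = 0  # monomorphic
        small = compute_w(make_panel(M), "1", n_win=2).w
        large = compute_w(make_panel(M), "1", n_win=6).w
        assert not np.any(np.isfinite(small) & ~np.isfinite(large))

    def test_invariant_to_duplicating_individuals(self, rng):
        M = rng.binomial(2, 0.4, size=(9, 20))
        w1 = compute_w(make_panel(M), "1", n_win=4).w
        w2 = compute_w(make_panel(np.vstack([M, M])), "1", n_win=4).w
        np.testing.assert_allclose(w1, w2, atol=1e-10)


# smooth.spline(x, y, spar = 0.2, all.knots = TRUE) fit of the curve
# y = 0.5 + 0.25 sin(x/6) + 0.1 cos(x/2.1), x = 0..59 (independent
# reference computed with R 4.3.3)
_R_SMOOTH_REFERENCE = np.array([
    0.6004959083, 0.6296775533, 0.6397587167, 0.6340244005, 0.6218424355,
    0.6126766975, 0.6144820895, 0.6317916974, 0.6645513492, 0.7080280434,
    0.7537925677, 0.7915604691, 0.8114832090, 0.8063795579, 0.7734096185,
    0.7148168906, 0.6375702126, 0.5519813364, 0.4696010721, 0.4008568392,
    0.3529515251, 0.3284850948, 0.3250994355, 0.3362192688, 0.3527182829,
    0.3651341330, 0.3659343534, 0.3513245570, 0.3221929255, 0.2839780601,
    0.2454877810, 0.2169308983, 0.2076001271, 0.2237229738, 0.2669610372,
    0.3338948268, 0.4166127584, 0.5042780372, 0.5853301501, 0.6498369391,
    0.6914800087, 0.7087379302, 0.7050101430, 0.6876599341, 0.6661949957,
    0.6499954159, 0.6460989702, 0.6575400347, 0.6826143568, 0.7152349405,
    0.7463005050, 0.7657716426, 0.7649912994, 0.7387307721, 0.6865032124,
    0.6128492519, 0.5265006107, 0.4386696885, 0.3615550778, 0.3018082183,
])


class TestSmoothW:
    def test_constant_curve_reproduced(self):
        prof = smooth_w(WProfile("1", np.full(30, 0.5), None, 50))
        np.testing.assert_allclose(prof.w_smooth, 0.5, atol=1e-10)

    def test_linear_curve_reproduced(self):
        y = np.linspace(0.1, 0.9, 40)
        prof = smooth_w(WProfile("1", y, None, 50))
        np.testing.assert_allclose(prof.w_smooth, y, atol=1e-8)

    def test_matches_r_reference_curve(self):
        x = np.arange(60.0)
        y = 0.5 + 0.25 * np.sin(x / 6) + 0.1 * np.cos(x / 2.1)
        prof = smooth_w(WProfile("1", y, None, 50), spar=0.2)
        assert np.abs(prof.w_smooth - _R_SMOOTH_REFERENCE).max() < 5e-3

    def test_smoothing_improves_noisy_sinusoid(self):
        rng = np.random.default_rng(7)
        x = np.arange(200.0)
        clean = 0.5 + 0.3 * np.sin(x / 20)
        noisy = clean + rng.normal(0, 0.05, 200)
        prof = smooth_w(WProfile("1", noisy, None, 50), spar=0.5)
        assert (np.corrcoef(prof.w_smooth, clean)[0, 1]
                >= np.corrcoef(noisy, clean)[0, 1])

    def test_missing_values_bridged(self):
        y = np.linspace(0.2, 0.8, 25)
        y[[5, 6, 12]] = np.nan
        prof = smooth_w(WProfile("1", y, None, 50))
        assert np.isfinite(prof.w_smooth).all()

    def test_too_few_points_passthrough_with_warning(self):
        y = np.array([0.2, np.nan, 0.4, np.nan, np.nan])
        with pytest.warns(UserWarning, match="smoothing skipped"):
            prof = smooth_w(WProfile("1", y, None, 50))
        np.testing.assert_array_equal(prof.w_smooth, y)


class TestFindBreakpoints:
    def _profile(self, y):
        return WProfile("1", np.asarray(y, float),
                        np.asarray(y, float), 50, 0.2)

    def test_monotone_curve_single_block(self):
        bm = find_breakpoints(self._profile(np.linspace(0, 1, 15)))
        assert bm.n_blocks == 1
        assert bm.table.iloc[0]["start"] == 0
        assert bm.table.iloc[0]["stop"] == 15

    def test_v_shape_splits_at_minimum(self):
        y = np.abs(np.arange(21) - 10.0)
        bm = find_breakpoints(self._profile(y))
        assert bm.n_blocks == 2
        assert list(bm.table["start"]) == [0, 11]
        assert list(bm.table["stop"]) == [11, 21]

    def test_double_well_matches_exhaustive_scan(self):
        x = np.arange(40.0)
        y = np.minimum((x - 12) ** 2, (x - 30) ** 2 + 3)
        expected = [k for k in range(1, 39)
                    if y[k] < y[k - 1] and y[k] < y[k + 1]]
        bm = find_breakpoints(self._profile(y))
        assert list(bm.table["stop"][:-1] - 1) == expected

    def test_plateau_breaks_at_last_index(self):
        y = np.array([0.9, 0.5, 0.2, 0.2, 0.2, 0.6, 0.8])
        bm = find_breakpoints(self._profile(y))
        assert bm.n_blocks == 2
        assert bm.table.iloc[0]["stop"] == 5  # run ends at index 4

    def test_boundaries_never_breakpoints(self):
        y = np.array([0.0, 0.5, 0.4, 0.6, 0.1])  # ends are extreme lows
        bm = find_breakpoints(self._profile(y))
        assert bm.table.iloc[0]["start"] == 0
        assert bm.table.iloc[-1]["stop"] == 5
        assert bm.n_blocks == 2  # only the interior minimum at index 2


class TestPartitionFixed:
    @pytest.mark.parametrize("m,size,expected", [
        (250, 100, [100, 100, 50]),
        (50, 100, [50]),
        (300, 100, [100, 100, 100]),
    ])
    def test_single_chromosome_sizes(self, m, size, expected):
        bm = partition_fixed({"1": m}, block_size=size)
        assert list(bm.sizes()) == expected

    def test_blocks_never_cross_chromosomes(self):
        bm = partition_fixed({"1": 120, "2": 80}, block_size=100)
        assert list(bm.sizes()) == [100, 20, 80]
        assert list(bm.table["chrom"]) == ["1", "1", "2"]

    def test_block_count_arithmetic(self):
        sizes = {"1": 2311, "2": 1999, "3": 870, "4": 100, "5": 37}
        bm = partition_fixed(sizes, block_size=100)
        expected = sum(-(-m // 100) for m in sizes.values())
        assert bm.n_blocks == expected
        assert bm.sizes().sum() == sum(sizes.values())


class TestPartitionGenome:
    def test_ld_composition_per_chromosome(self, rng):
        panel = random_panel(rng, 30, 40, chrom=["1"] * 25 + ["2"] * 15)
        whole = partition_genome(panel, "ld", n_win=5)
        parts = []
        for chrom in ("1", "2"):
            prof = smooth_w(compute_w(panel, chrom, n_win=5))
            parts.append(find_breakpoints(prof, panel=panel))
        combined = pd.concat([p.table for p in parts], ignore_index=True)
        pd.testing.assert_frame_equal(whole.table, combined)

    def test_every_map_tiles_exactly(self, rng):
        for trial in range(5):
            chrom = (["1"] * int(rng.integers(5, 40))
                     + ["2"] * int(rng.integers(5, 40)))
            panel = random_panel(rng, 20, len(chrom), chrom=chrom)
            for method in ("ld", "fixed"):
                bm = partition_genome(panel, method, n_win=4, block_size=7)
                bm.validate(panel)

    def test_deterministic(self, rng):
        panel = random_panel(rng, 25, 30)
        a = partition_genome(panel, "ld", n_win=5)
        b = partition_genome(panel, "ld", n_win=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_estimator_interface(self, rng):
        panel = random_panel(rng, 25, 30)
        part = LDBlockPartitioner(n_win=5).fit(panel)
        assert part.blocks_.n_blocks >= 1
        assert part.get_params()["n_win"] == 5
        part2 = LDBlockPartitioner(method="fixed", block_size=8).fit(panel)
        assert (part2.blocks_.sizes() <= 8).all()
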