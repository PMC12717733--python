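"""Forward-in-time multibreed simulator with full truth tracking.

Emulates the classic breeding-program design: a random-mating
historical population accumulates drift LD over many discrete
generations; each breed then samples founders from it and undergoes its
own formation phase (litter structure, truncation selection on an
auxiliary phenotype — high, low, or none) so the breeds diverge in
allele frequency and LD pattern. Recombination follows a Haldane map
(per-gap recombination fractions from cM spacing, no interference). The
analyzed panel takes two individuals per litter from the last three
generations of every breed, and SNPs are ascertained to segregate in
the merged panel.

Trait architecture: a set of blocks (from the LD partitioner run on the
merged panel) carries one uncorrelated QTL each; a further small set of
blocks carries several QTLs per block whose effects are correlated
across breeds at a per-block r_b — either fixed at r_g_mean
('identical') or drawn from U(-1, 1) and location-adjusted so the mean
over blocks equals r_g_mean ('uniform'). Effects are scaled so every
breed's realized genetic variance equals its target h2 (phenotypic
variance 1), and phenotypes add a fixed breed mean and normal residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import BlockMap, GenotypePanel, PhenotypeTable

__all__ = [
    "BreedConfig",
    "ArchitectureConfig",
    "SimConfig",
    "TruthSet",
    "two_breed",
    "three_breed",
    "desk_scale",
    "simulate_genotypes",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "make_replicates",
]


@dataclass
class BreedConfig:
    """One breed's formation parameters.

    sel: 'phen/h' (truncation on high auxiliary phenotype), 'phen/l'
    (low), or 'rnd' (random). n_ind is the number of analyzed
    individuals drawn from the last three generations (2 per litter).
    """

    name: str
    gen: int            # breed-formation generations
    sel: str            # 'phen/h' | 'phen/l' | 'rnd'
    n_ind: int          # analyzed individuals
    h2: float           # analysis-trait heritability target
    mean: float         # fixed breed effect on the phenotype
    pop_size: int | None = None  # per-generation size (auto if None)


@dataclass
class ArchitectureConfig:
    """QTL architecture of the analysis trait."""

    n_uncorrelated: int = 300        # blocks with 1 independent QTL
    n_correlated: int = 10           # blocks with correlated QTLs
    qtl_per_correlated: int = 10
    r_g_mean: float = 0.8
    scenario: str = "identical"      # 'identical' | 'uniform'
    correlated_breeds: tuple | None = None  # breed pair sharing r_g


@dataclass
class SimConfig:
    """Full simulation design: history, map, breeds and seed scale."""

    breeds: list
    n_chrom: int = 18
    n_snps: int = 50_058
    chrom_length_cm: float = 100.0
    bp_per_cm: int = 1_000_000
    hist_size: int = 100             # Ne ~ 100, typical for livestock
    hist_generations: int = 100
    founders_per_breed: int = 100
    litter_size: int = 8
    selection_proportion: float = 0.5
    aux_h2: float = 0.3              # heritability of the selection trait
    # recombination clustering: per-gap map distances are drawn from a
    # gamma(shape) renormalized to the chromosome length, so a small
    # fraction of gaps (hotspots) carries most of the recombination --
    # the mechanism behind haplotype-block structure in real genomes.
    # shape -> infinity recovers a uniform map.
    recomb_shape: float = 0.2
    # simulate oversample * n_snps sites so that n_snps evenly spaced
    # SNPs can be selected among those segregating in the merged panel
    oversample: float = 1.75


@dataclass
class TruthSet:
    """Everything the simulator knows that a model must recover."""

    qtl_indices: np.ndarray          # global SNP indices with effects
    effects: np.ndarray              # (m, p) per-breed allele effects
    block_r: dict                    # block index -> true cross-breed r
    tbv: np.ndarray                  # (n, p) true breeding values
    breed_means: np.ndarray
    residual_variances: np.ndarray
    realized_h2: np.ndarray
    blocks: BlockMap | None = None


def two_breed() -> SimConfig:
    """Two breeds of unequal size, divergent selection histories."""
    return SimConfig(breeds=[
        BreedConfig("A", gen=40, sel="phen/h", n_ind=3000, h2=0.5, mean=1.0),
        BreedConfig("B", gen=10, sel="rnd", n_ind=600, h2=0.3, mean=0.5),
    ])


def three_breed() -> SimConfig:
    """Three equal-size breeds; r_g applies between A and B only."""
    return SimConfig(breeds=[
        BreedConfig("A", gen=70, sel="rnd", n_ind=600, h2=0.5, mean=1.5),
        BreedConfig("B", gen=40, sel="phen/h", n_ind=600, h2=0.4, mean=1.0),
        BreedConfig("C", gen=10, sel="phen/l", n_ind=600, h2=0.3, mean=0.5),
    ])


def desk_scale(config: SimConfig, n_snps: int = 2000, n_chrom: int = 3,
               n_ind=None) -> SimConfig:
    """Shrink a preset to desk scale (fewer SNPs / individuals)."""
    breeds = [replace(b) for b in config.breeds]
    if n_ind is not None:
        for b, n in zip(breeds, n_ind):
            b.n_ind = n
    return replace(config, breeds=breeds, n_snps=n_snps, n_chrom=n_chrom)


def desk_two_breed(r_g_mean: float = 0.8, scenario: str = "identical"):
    """Desk-scale two-breed benchmark: 2,000 SNPs, 600 + 300 analyzed
    individuals. The QTL architecture keeps 10 correlated blocks of 10
    QTLs and scales the uncorrelated-block count to what a 2,000-SNP
    partition can host while leaving the uncorrelated component the
    dominant share of genetic variance, as in the full-scale design.

    Returns (SimConfig, ArchitectureConfig).
    """
    config = desk_scale(two_breed(), n_snps=2000, n_chrom=3,
                        n_ind=(600, 300))
    # shrink genome length, not marker density: 2,000 SNPs over 3 x 33 cM
    # keeps ~20 SNPs/cM as in the full-scale panel, so per-SNP LD (and
    # hence block structure) stays in the regime the method targets
    config = replace(config, chrom_length_cm=33.0)
    arch = ArchitectureConfig(n_uncorrelated=150, n_correlated=10,
                              qtl_per_correlated=10, r_g_mean=r_g_mean,
                              scenario=scenario)
    return config, arch


# ---------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------

def _recomb_fractions(config: SimConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-gap recombination fraction across the concatenated genome.

    Gap map distances within a chromosome are gamma(recomb_shape) draws
    renormalized to the chromosome length (hotspot-structured map);
    Haldane then gives r = (1 - exp(-2d))/2 per gap. Gaps that cross a
    chromosome boundary recombine freely (r = 1/2), and entry 0 is 1/2
    so the starting haplotype of each gamete is random.
    """
    per = np.full(config.n_chrom, config.n_snps // config.n_chrom)
    per[:config.n_snps % config.n_chrom] += 1
    r = np.empty(config.n_snps)
    pos = 0
    for c in range(config.n_chrom):
        n_gaps = per[c] - 1
        gaps = rng.gamma(config.recomb_shape, 1.0, n_gaps)
        gaps *= (config.chrom_length_cm / 100.0) / gaps.sum()  # Morgans
        r[pos] = 0.5
        r[pos + 1:pos + per[c]] = 0.5 * (1.0 - np.exp(-2.0 * gaps))
        pos += per[c]
    return r


def _variant_frame(config: SimConfig) -> pd.DataFrame:
    per = np.full(config.n_chrom, config.n_snps // config.n_chrom)
    per[:config.n_snps % config.n_chrom] += 1
    rows = []
    for c in range(config.n_chrom):
        spacing = config.chrom_length_cm * config.bp_per_cm / per[c]
        for i in range(per[c]):
            rows.append((f"snp{c + 1}_{i + 1}", f"{c + 1}",
                         int((i + 0.5) * spacing) + 1))
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
    df["a1"], df["a2"] = "A", "B"
    return df


class _Meiosis:
    """Poisson crossover process (no interference) on the marker map.

    Equivalent to per-gap Haldane recombination fractions: the switch
    probability across a gap of d Morgans is P(odd crossovers) =
    (1 - e^{-2d})/2. Chromosomes segregate independently (random
    starting haplotype per chromosome).
    """

    def __init__(self, rgap: np.ndarray):
        # recover per-gap map distances from the Haldane fractions;
        # rgap == 0.5 marks a chromosome start
        self.starts = np.flatnonzero(rgap == 0.5)
        d = -0.5 * np.log1p(-2.0 * np.minimum(rgap, 0.49999999))
        d[self.starts] = 0.0
        self.cmap = np.cumsum(d)          # genetic position per SNP
        self.total = float(d.sum())
        self.m = len(rgap)
        self.chrom_of = np.searchsorted(self.starts, np.arange(self.m),
                                        side="right") - 1

    def gametes(self, H: np.ndarray, parents: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
        n_g = len(parents)
        k = rng.poisson(self.total, n_g)
        switches = np.zeros((n_g, self.m), dtype=np.int8)
        tot = int(k.sum())
        if tot:
            pos = rng.uniform(0.0, self.total, tot)
            snp = np.searchsorted(self.cmap, pos, side="left")
            row = np.repeat(np.arange(n_g), k)
            keep = snp < self.m
            np.add.at(switches, (row[keep], snp[keep]), 1)
        parity = np.cumsum(switches, axis=1, dtype=np.int8)
        phase = rng.integers(0, 2, (n_g, len(self.starts)), dtype=np.int8)
        hap = (parity + phase[:, self.chrom_of]) & 1
        return H[parents[:, None], hap, np.arange(self.m)[None, :]]


def _gametes(H: np.ndarray, parents: np.ndarray, rgap,
             rng: np.random.Generator) -> np.ndarray:
    """Meioses for each parent index: (len(parents), m) haplotypes."""
    if not isinstance(rgap, _Meiosis):
        rgap = _Meiosis(np.asarray(rgap))
    return rgap.gametes(H, parents, rng)


def _aux_phenotype(H: np.ndarray, beta: np.ndarray, h2: float,
                   rng: np.random.Generator) -> np.ndarray:
    g = (H[:, 0, :] + H[:, 1, :]).astype(float) @ beta
    vg = g.var()
    if vg == 0:
        return rng.standard_normal(len(g))
    return g + rng.normal(0.0, np.sqrt(vg * (1 - h2) / h2), len(g))


def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | int | None = None
                       ) -> GenotypePanel:
    """Run history + breed formation; return the merged analyzed panel."""
    rng = np.random.default_rng(rng)
    raw = replace(config,
                  n_snps=int(np.ceil(config.n_snps * config.oversample)))
    m = raw.n_snps
    rgap = _Meiosis(_recomb_fractions(raw, rng))

    # historical random mating with drift
    p0 = rng.uniform(0.05, 0.95, m)
    H = (rng.random((config.hist_size, 2, m)) < p0).astype(np.int8)
    for _ in range(config.hist_generations):
        sires = rng.integers(0, config.hist_size, config.hist_size)
        dams = rng.integers(0, config.hist_size, config.hist_size)
        H = np.stack([_gametes(H, sires, rgap, rng),
                      _gametes(H, dams, rgap, rng)], axis=1)

    beta_aux = rng.standard_normal(m)
    dosage_parts, sample_parts = [], []
    for breed in config.breeds:
        pop = breed.pop_size
        if pop is None:
            # several times the minimum (n_ind * litter_size / 6) so the
            # analyzed panel samples few litters twice: genotyped cohorts
            # are a modest fraction of the breeding population and GEBV
            # accuracy should come from LD, not dense full-sibship
            pop = int(np.ceil(breed.n_ind * config.litter_size / 6 * 3.0))
            pop = max(pop, 8 * config.litter_size)
        founders = rng.choice(
            config.hist_size,
            min(config.founders_per_breed, pop, config.hist_size),
            replace=False)
        Hb = H[founders]
        n_litters = max(pop // config.litter_size, 1)
        tail: list = []  # (litter ids, haplotypes) of last 3 generations
        for g in range(breed.gen):
            n_now = Hb.shape[0]
            n_sel = max(int(np.ceil(n_now * config.selection_proportion)), 2)
            if breed.sel == "rnd":
                sel = rng.permutation(n_now)[:n_sel]
            else:
                phen = _aux_phenotype(Hb, beta_aux, config.aux_h2, rng)
                order = np.argsort(phen)
                sel = order[-n_sel:] if breed.sel == "phen/h" else order[:n_sel]
            pairs = np.array([rng.choice(sel, 2, replace=False)
                              for _ in range(n_litters)])
            sires = np.repeat(pairs[:, 0], config.litter_size)
            dams = np.repeat(pairs[:, 1], config.litter_size)
            Hb = np.stack([_gametes(Hb, sires, rgap, rng),
                           _gametes(Hb, dams, rgap, rng)], axis=1)
            litter_id = np.repeat(np.arange(n_litters), config.litter_size)
            if g >= breed.gen - 3:
                tail.append((litter_id, Hb))

        chosen = []
        for litter_id, Hg in tail:
            for lit in np.unique(litter_id):
                members = np.flatnonzero(litter_id == lit)
                take = rng.choice(members, min(2, len(members)),
                                  replace=False)
                chosen.append(Hg[take])
        pool = np.concatenate(chosen, axis=0)
        if len(pool) < breed.n_ind:
            raise ValueError(
                f"breed {breed.name}: only {len(pool)} candidates from the "
                f"last three generations but n_ind={breed.n_ind}; increase "
                "pop_size or litter_size")
        keep = rng.choice(len(pool), breed.n_ind, replace=False)
        dos = (pool[keep, 0, :] + pool[keep, 1, :]).astype(np.int8)
        fixed = ((dos.min(axis=0) == dos.max(axis=0)).mean())
        if fixed > 0.5:
            warnings.warn(f"breed {breed.name}: {fixed:.0%} of SNPs fixed "
                          "within the breed", stacklevel=2)
        dosage_parts.append(dos)
        sample_parts.append(pd.DataFrame({
            "id": [f"{breed.name}_{i + 1}" for i in range(breed.n_ind)],
            "breed": breed.name,
        }))

    dosages = np.concatenate(dosage_parts, axis=0)
    variants = _variant_frame(raw)
    # ascertain: evenly distributed SNPs segregating in the merged panel
    freq = dosages.mean(axis=0) / 2.0
    seg = np.flatnonzero((freq > 0) & (freq < 1))
    if len(seg) > config.n_snps:
        pick = np.unique(np.linspace(0, len(seg) - 1,
                                     config.n_snps).round().astype(int))
        seg = seg[pick]
    dosages = dosages[:, seg]
    variants = variants.iloc[seg].reset_index(drop=True)
    freq = freq[seg]
    flip = freq > 0.5
    dosages[:, flip] = 2 - dosages[:, flip]
    samples = pd.concat(sample_parts, ignore_index=True)
    return GenotypePanel(dosages, variants, samples)


# ---------------------------------------------------------------------
# trait architecture
# ---------------------------------------------------------------------

def _block_correlations(arch: ArchitectureConfig,
                        rng: np.random.Generator) -> np.ndarray:
    if arch.scenario == "identical":
        return np.full(arch.n_correlated, float(arch.r_g_mean))
    if arch.scenario != "uniform":
        raise ValueError(f"unknown scenario {arch.scenario!r}")
    r = rng.uniform(-1.0, 1.0, arch.n_correlated)
    # location shift with clipping, iterated to its fixed point so the
    # mean over blocks equals r_g_mean exactly
    for _ in range(200):
        delta = arch.r_g_mean - r.mean()
        if abs(delta) < 1e-12:
            break
        r = np.clip(r + delta, -1.0, 1.0)
    return r


def _psd_sqrt(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    return vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0))) @ vecs.T


def assign_qtl_effects(panel: GenotypePanel, blocks: BlockMap,
                       arch: ArchitectureConfig, breed_cfgs,
                       rng: np.random.Generator | int | None = None):
    """Draw per-breed QTL effects over the block map.

    Returns ``(effects, qtl_indices, block_r)`` with ``effects`` an
    (m, p) matrix that is zero off the QTLs, scaled so each breed's
    realized genetic variance equals its h2 target (phenotypic variance
    1). Uncorrelated blocks carry one QTL with independent effects per
    breed; correlated blocks carry ``qtl_per_correlated`` QTLs whose
    effect vectors follow an exchangeable correlation r_b across the
    designated breed pair (all pairs when p = 2).
    """
    rng = np.random.default_rng(rng)
    p = len(breed_cfgs)
    m = panel.n_variants
    sizes = blocks.sizes()
    eligible = np.flatnonzero(sizes >= arch.qtl_per_correlated)
    if len(eligible) < arch.n_correlated:
        raise ValueError(
            f"only {len(eligible)} blocks hold >= {arch.qtl_per_correlated} "
            f"SNPs; {arch.n_correlated} correlated blocks requested")
    corr_blocks = rng.choice(eligible, arch.n_correlated, replace=False)
    rest = np.setdiff1d(np.arange(blocks.n_blocks), corr_blocks)
    if len(rest) < arch.n_uncorrelated:
        raise ValueError(
            f"only {len(rest)} blocks left for {arch.n_uncorrelated} "
            "uncorrelated QTL blocks")
    unc_blocks = rng.choice(rest, arch.n_uncorrelated, replace=False)

    names = [b.name for b in breed_cfgs]
    if arch.correlated_breeds is None:
        pair = tuple(range(p))
    else:
        pair = tuple(names.index(b) for b in arch.correlated_breeds)

    effects = np.zeros((m, p))
    qtl = []
    slices = blocks.slices()
    for b in unc_blocks:
        sl = slices[b]
        j = int(rng.integers(sl.start, sl.stop))
        effects[j] = rng.standard_normal(p)
        qtl.append(j)
    rs = _block_correlations(arch, rng)
    block_r = {}
    for b, r_b in zip(corr_blocks, rs):
        sl = slices[b]
        js = rng.choice(np.arange(sl.start, sl.stop),
                        arch.qtl_per_correlated, replace=False)
        C = np.eye(p)
        for a in pair:
            for c in pair:
                if a != c:
                    C[a, c] = r_b
        draws = rng.standard_normal((arch.qtl_per_correlated, p))
        effects[js] = draws @ _psd_sqrt(C).T
        qtl.extend(int(j) for j in js)
        block_r[int(b)] = float(r_b)

    # scale each breed's column so its realized genetic variance is h2
    for l, cfg in enumerate(breed_cfgs):
        idx = panel.breed_indices(cfg.name)
        tbv = panel.dosages[idx].astype(float) @ effects[:, l]
        v = tbv.var()
        if v == 0:
            raise ValueError(f"breed {cfg.name}: zero genetic variance")
        effects[:, l] *= np.sqrt(cfg.h2 / v)
    return effects, np.sort(np.array(qtl)), block_r


def simulate_phenotypes(panel: GenotypePanel, effects: np.ndarray,
                        breed_cfgs,
                        rng: np.random.Generator | int | None = None,
                        qtl_indices=None, block_r=None,
                        blocks: BlockMap | None = None):
    """Phenotype = breed mean + TBV + N(0, var(TBV)(1-h2)/h2)."""
    rng = np.random.default_rng(rng)
    M = panel.dosages.astype(float)
    tbv = M @ effects
    p = len(breed_cfgs)
    n = panel.n_samples
    values = np.full((n, p), np.nan)
    sig_e = np.empty(p)
    means = np.empty(p)
    real_h2 = np.empty(p)
    for l, cfg in enumerate(breed_cfgs):
        idx = panel.breed_indices(cfg.name)
        g = tbv[idx, l]
        vg = g.var()
        if vg == 0:
            raise ValueError(f"breed {cfg.name}: zero genetic variance")
        ve = vg * (1.0 - cfg.h2) / cfg.h2
        noise = (rng.normal(0.0, np.sqrt(ve), len(idx)) if ve > 0
                 else np.zeros(len(idx)))
        # the fixed breed effect is the breed's expected phenotype, so
        # the genetic term enters as its within-breed deviation
        values[idx, l] = cfg.mean + (g - g.mean()) + noise
        sig_e[l] = ve
        means[l] = cfg.mean
        real_h2[l] = vg / values[idx, l].var() if values[idx, l].var() else 1.0
    pheno = PhenotypeTable(values, [b.name for b in breed_cfgs],
                           panel.samples["id"].to_numpy(),
                           panel.samples["breed"].to_numpy())
    truth = TruthSet(
        qtl_indices=(np.array([], dtype=int) if qtl_indices is None
                     else np.asarray(qtl_indices)),
        effects=effects, block_r=block_r or {}, tbv=tbv,
        breed_means=means, residual_variances=sig_e,
        realized_h2=real_h2, blocks=blocks)
    return pheno, truth


def simulate_dataset(config: SimConfig, arch: ArchitectureConfig,
                     seed=None, n_win: int = 50, spar: float = 0.2):
    """Full pipeline: genotypes -> LD partition -> effects -> phenotypes.

    Returns (panel, pheno, truth); truth.blocks holds the block map the
    QTL architecture was drawn on.
    """
    from .partition import partition_genome

    rng = np.random.default_rng(seed)
    panel = simulate_genotypes(config, rng)
    blocks = partition_genome(panel, method="ld", n_win=n_win, spar=spar)
    effects, qtl, block_r = assign_qtl_effects(panel, blocks, arch,
                                               config.breeds, rng)
    pheno, truth = simulate_phenotypes(panel, effects, config.breeds, rng,
                                       qtl_indices=qtl, block_r=block_r,
                                       blocks=blocks)
    return panel, pheno, truth


def make_replicates(config: SimConfig, arch: ArchitectureConfig,
                    n_reps: int = 20, seed=None) -> list:
    """Independent replicates with seeds derived from a master seed."""
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    return [simulate_dataset(config, arch, seed=np.random.default_rng(s))
            for s in seeds]
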