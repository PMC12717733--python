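"""Core in-memory containers shared by every component.

The package works on three objects throughout: a :class:`GenotypePanel`
(minor-allele dosage matrix plus variant/sample metadata for one or more
breeds), a :class:`PhenotypeTable` in the stacked multibreed layout (the
same trait measured in each breed is treated as a distinct trait, observed
only for that breed's individuals), and a :class:`BlockMap` that tiles the
genome into contiguous, non-overlapping SNP blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "PhenotypeTable", "BlockMap"]


@dataclass
class GenotypePanel:
    """Coded genotypes for one or more breeds.

    Parameters
    ----------
    dosages : ndarray of shape (n_samples, n_variants), integer
        Minor-allele counts in {0, 1, 2}. The minor allele is defined on
        the merged (all-breeds) panel, so within a single breed a column
        may be majority-coded; that is accepted.
    variants : DataFrame with columns ``id, chrom, pos, a1, a2``
        One row per SNP, strictly ordered by (chrom, pos); ``pos`` is
        1-based bp; ``a1`` is the counted (merged-panel minor) allele.
    samples : DataFrame with columns ``id, breed`` (optionally ``sex``)
        One row per individual, aligned with ``dosages`` rows.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError(
                f"metadata shape mismatch: dosages {n}x{m}, "
                f"{len(self.samples)} samples, {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage out of {{0,1,2}} at sample "
                f"{self.samples['id'].iloc[i]!r}, SNP {self.variants['id'].iloc[j]!r}"
            )
        if self.samples["breed"].isna().any():
            missing = self.samples.loc[self.samples["breed"].isna(), "id"].tolist()
            raise ValueError(f"samples without a breed label: {missing}")
        chrom = self.variants["chrom"].to_numpy()
        pos = self.variants["pos"].to_numpy()
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(m)):
            raise ValueError("variants must be sorted by (chrom, pos)")

    # -- accessors ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def breeds(self) -> list:
        """Breed labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["breed"]))

    def breed_indices(self, breed) -> np.ndarray:
        return np.flatnonzero((self.samples["breed"] == breed).to_numpy())

    def subset_samples(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            self.dosages[idx], self.variants.copy(), self.samples.iloc[idx]
        )

    def subset_breed(self, breed) -> "GenotypePanel":
        return self.subset_samples(self.breed_indices(breed))

    def allele_freqs(self) -> np.ndarray:
        """Counted-allele frequency of each SNP on the merged panel."""
        return self.dosages.mean(axis=0) / 2.0

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.variants["chrom"]))

    def chrom_slice(self, chrom) -> slice:
        """Global variant-index slice covering one chromosome."""
        mask = (self.variants["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class PhenotypeTable:
    """Stacked multibreed phenotypes aligned to a :class:`GenotypePanel`.

    ``values[i, l]`` is individual *i*'s record for breed-trait *l*
    (``trait_breeds[l]``); exactly the own-breed cell is observed, all
    other cells are NaN (structurally missing, to be imputed by the
    sampler). Validation individuals may have every cell NaN.
    """

    values: np.ndarray  # (n, p) float, NaN = missing
    trait_breeds: list
    sample_ids: np.ndarray
    sample_breeds: np.ndarray
    covariates: pd.DataFrame | None = None  # extra fixed effects (e.g. sex)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        self.sample_breeds = np.asarray(self.sample_breeds)
        n, p = self.values.shape
        if p != len(self.trait_breeds):
            raise ValueError("values width must match trait_breeds")
        if len(self.sample_ids) != n or len(self.sample_breeds) != n:
            raise ValueError("sample metadata length mismatch")
        # no record may be observed outside the individual's own breed-trait
        col = {b: l for l, b in enumerate(self.trait_breeds)}
        own = np.array([col[b] for b in self.sample_breeds])
        obs = ~np.isnan(self.values)
        other = obs.copy()
        other[np.arange(n), own] = False
        if other.any():
            i = int(np.flatnonzero(other.any(axis=1))[0])
            raise ValueError(
                f"sample {self.sample_ids[i]!r} has an observed value for a "
                "breed-trait other than its own breed"
            )

    @property
    def n_traits(self) -> int:
        return len(self.trait_breeds)

    def own_trait_index(self) -> np.ndarray:
        col = {b: l for l, b in enumerate(self.trait_breeds)}
        return np.array([col[b] for b in self.sample_breeds])

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def own_values(self) -> np.ndarray:
        """Each individual's own-breed record (NaN if masked)."""
        return self.values[np.arange(len(self.sample_ids)), self.own_trait_index()]

    def mask_samples(self, idx) -> "PhenotypeTable":
        """Copy with the given individuals' records withheld (set NaN)."""
        vals = self.values.copy()
        vals[np.asarray(idx, dtype=np.intp)] = np.nan
        return PhenotypeTable(
            vals,
            list(self.trait_breeds),
            self.sample_ids,
            self.sample_breeds,
            None if self.covariates is None else self.covariates.copy(),
        )


@dataclass
class BlockMap:
    """Ordered, gap-free tiling of each chromosome into SNP blocks.

    ``table`` has one row per block with columns ``chrom, start, stop``
    where indices are **global** variant indices, 0-based half-open.
    Serialized files use 1-based inclusive indices (the io layer owns the
    conversion).
    """

    table: pd.DataFrame  # chrom, start, stop
    method: str = "ld"  # "ld" | "fixed"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    @property
    def n_blocks(self) -> int:
        return len(self.table)

    def sizes(self) -> np.ndarray:
        return (self.table["stop"] - self.table["start"]).to_numpy()

    def slices(self) -> list:
        return [slice(int(a), int(b)) for a, b in
                zip(self.table["start"], self.table["stop"])]

    def validate(self, panel: GenotypePanel) -> None:
        """Check the blocks tile the panel's chromosomes exactly."""
        if int(self.sizes().min(initial=1)) < 1:
            raise ValueError("empty block")
        covered = 0
        for chrom in panel.chromosomes():
            sl = panel.chrom_slice(chrom)
            sub = self.table[self.table["chrom"] == chrom]
            if len(sub) == 0:
                raise ValueError(f"chromosome {chrom!r} has no blocks")
            starts = sub["start"].to_numpy()
            stops = sub["stop"].to_numpy()
            if starts[0] != sl.start or stops[-1] != sl.stop:
                raise ValueError(f"blocks do not span chromosome {chrom!r}")
            if not np.array_equal(starts[1:], stops[:-1]):
                raise ValueError(f"blocks overlap or leave gaps on {chrom!r}")
            covered += int((stops - starts).sum())
        if covered != panel.n_variants:
            raise ValueError("blocks do not cover every SNP exactly once")

    @classmethod
    def concat(cls, maps, method: str, params: dict) -> "BlockMap":
        table = pd.concat([m.table for m in maps], ignore_index=True)
        return cls(table, method=method, params=params)
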