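"""Shared fixtures and small synthetic-data helpers."""

import numpy as np
import pandas as pd
import pytest

from mbgp.types import BlockMap, GenotypePanel, PhenotypeTable


def make_panel(dosages, chrom=None, breeds=None, pos=None) -> GenotypePanel:
    """Panel from a raw dosage array with minimal metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = []
        counters = {}
        for c in chrom:
            counters[c] = counters.get(c, 0) + 1
            pos.append(counters[c] * 1000)
    if breeds is None:
        breeds = ["X"] * n
    variants = pd.DataFrame({
        "id": [f"snp{j}" for j in range(m)], "chrom": chrom, "pos": pos,
        "a1": "A", "a2": "B",
    })
    samples = pd.DataFrame({
        "id": [f"ind{i}" for i in range(n)], "breed": breeds,
    })
    return GenotypePanel(dosages, variants, samples)


def random_panel(rng, n, m, breeds=None, maf_low=0.1, maf_high=0.9,
                 chrom=None) -> GenotypePanel:
    freqs = rng.uniform(maf_low, maf_high, m)
    d = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
    f = d.mean(axis=0) / 2
    flip = f > 0.5
    d[:, flip] = 2 - d[:, flip]
    return make_panel(d, breeds=breeds, chrom=chrom)


def stacked_pheno(panel: GenotypePanel, own_values) -> PhenotypeTable:
    """PhenotypeTable with each individual's own-breed value filled."""
    breeds = panel.breeds
    col = {b: l for l, b in enumerate(breeds)}
    values = np.full((panel.n_samples, len(breeds)), np.nan)
    for i, (v, b) in enumerate(zip(own_values, panel.samples["breed"])):
        values[i, col[b]] = v
    return PhenotypeTable(values, breeds, panel.samples["id"].to_numpy(),
                          panel.samples["breed"].to_numpy())


def single_block_map(panel: GenotypePanel) -> BlockMap:
    rows = []
    for c in panel.chromosomes():
        sl = panel.chrom_slice(c)
        rows.append((c, sl.start, sl.stop))
    return BlockMap(pd.DataFrame(rows, columns=["chrom", "start", "stop"]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
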