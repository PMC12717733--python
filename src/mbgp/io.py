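"""Reading and writing the standard on-disk formats.

PLINK 1 binary triplets (.bed/.bim/.fam, SNP-major), phenotype tables,
block-map files and tidy result tables. All downstream code consumes the
containers in :mod:`mbgp.types`; this module owns every format detail,
including the 0-based half-open (in memory) vs 1-based inclusive (on
disk) block index convention.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BlockMap, GenotypePanel, PhenotypeTable

__all__ = [
    "read_plink",
    "write_plink",
    "read_phenotypes",
    "write_blockmap",
    "read_blockmap",
    "write_gebv_table",
    "read_gebv_table",
    "write_posterior_covariances",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major

# 2-bit PLINK codes -> counted copies of allele A1; 3 marks a missing call
_CODE_TO_A1 = np.array([2, 3, 1, 0], dtype=np.uint8)
_A1_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}

# byte -> 4 dosages lookup, built once
_BYTE_LUT = np.empty((256, 4), dtype=np.uint8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_A1[(_b >> (2 * _k)) & 0b11]


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    return bim


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["fid", "id", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "id": str},
    )
    return fam


def read_plink(prefix, breed_map) -> GenotypePanel:
    """Read a PLINK 1 binary triplet into a :class:`GenotypePanel`.

    Parameters
    ----------
    prefix : path without extension; ``prefix.bed/.bim/.fam`` must exist.
    breed_map : DataFrame with columns ``id, breed`` (optionally ``sex``),
        or a path to a whitespace/CSV table with those columns. Breed
        labels come from this sidecar table, not the .fam family id.

    Dosages are re-coded so that the counted allele is the minor allele
    on the merged panel. Missing genotype calls are rejected with an
    error naming the SNP and sample.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"{prefix}{ext} not found")
    bim = _read_bim(prefix.with_suffix(".bim"))
    fam = _read_fam(prefix.with_suffix(".fam"))
    n, m = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK 1 .bed file")
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:]
    if len(body) != bpv * m:
        raise ValueError(f"{prefix}.bed has wrong size for {n} samples x {m} SNPs")
    geno = _BYTE_LUT[body.reshape(m, bpv)].reshape(m, bpv * 4)[:, :n]
    if (geno == 3).any():
        j, i = np.argwhere(geno == 3)[0]
        raise ValueError(
            f"missing genotype call at SNP {bim['id'].iloc[j]!r}, "
            f"sample {fam['id'].iloc[i]!r}; genotypes must be complete"
        )
    dosages = geno.T.astype(np.int8)  # (n, m), counts of A1

    if isinstance(breed_map, (str, os.PathLike)):
        breed_map = pd.read_csv(breed_map, sep=None, engine="python",
                                dtype={"id": str})
    breed_map = breed_map.copy()
    breed_map["id"] = breed_map["id"].astype(str)
    lookup = breed_map.set_index("id")
    unknown = [s for s in fam["id"] if s not in lookup.index]
    if unknown:
        raise ValueError(f"samples missing from breed_map: {unknown}")
    samples = pd.DataFrame({
        "id": fam["id"],
        "breed": lookup.loc[fam["id"], "breed"].to_numpy(),
    })
    if "sex" in breed_map.columns:
        samples["sex"] = lookup.loc[fam["id"], "sex"].to_numpy()

    # recode to merged-panel minor allele
    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        dosages = dosages.copy()
        dosages[:, flip] = 2 - dosages[:, flip]
        a1 = variants["a1"].to_numpy().copy()
        a2 = variants["a2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip], a1[flip].copy()
        variants["a1"], variants["a2"] = a1, a2

    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy()))
    variants = variants.iloc[order]
    dosages = dosages[:, order]
    return GenotypePanel(dosages, variants, samples)


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a panel as a PLINK 1 binary triplet (counted allele = A1)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = panel.variants
    pd.DataFrame({
        "chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"],
        "a1": v.get("a1", pd.Series(["A"] * len(v))),
        "a2": v.get("a2", pd.Series(["B"] * len(v))),
    }).to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    s = panel.samples
    sex = s["sex"] if "sex" in s.columns else 0
    pd.DataFrame({
        "fid": s["breed"], "id": s["id"], "father": 0, "mother": 0,
        "sex": sex, "pheno": -9,
    }).to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = panel.n_samples, panel.n_variants
    bpv = (n + 3) // 4
    codes = np.zeros((m, bpv * 4), dtype=np.uint8)
    d = panel.dosages.T  # (m, n)
    for dosage, code in _A1_TO_CODE.items():
        codes[:, :n][d == dosage] = code
    packed = (codes[:, 0::4] | (codes[:, 1::4] << 2)
              | (codes[:, 2::4] << 4) | (codes[:, 3::4] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_phenotypes(path, panel: GenotypePanel, trait: str,
                    covariates=(), missing: str = "NA") -> PhenotypeTable:
    """Read a phenotype table and build the stacked multibreed layout.

    The table (whitespace- or comma-delimited, with a header) must have
    an ``id`` column, the named ``trait`` column, and any requested
    covariate columns. Each individual's record fills its own breed-trait
    cell only; ``missing`` values are retained as NaN (to be imputed).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"id": str},
                     na_values=[missing], keep_default_na=False)
    if "id" not in df.columns or trait not in df.columns:
        raise ValueError(f"phenotype file must have 'id' and {trait!r} columns")
    ids = panel.samples["id"].astype(str)
    unknown = [s for s in df["id"] if s not in set(ids)]
    if unknown:
        raise ValueError(f"phenotype records for unknown samples: {unknown}")
    vals = pd.to_numeric(df[trait], errors="coerce")
    bad = vals.isna() & df[trait].notna()
    if bad.any():
        raise ValueError(
            f"non-numeric trait values (missing code is {missing!r}): "
            f"{df.loc[bad, trait].tolist()}"
        )

    breeds = panel.breeds
    col = {b: l for l, b in enumerate(breeds)}
    n = panel.n_samples
    values = np.full((n, len(breeds)), np.nan)
    row = pd.Series(np.arange(n), index=ids)
    for sid, val in zip(df["id"], vals):
        i = int(row[sid])
        values[i, col[panel.samples["breed"].iloc[i]]] = val
    cov = None
    if covariates:
        missing_cols = [c for c in covariates if c not in df.columns]
        if missing_cols:
            raise ValueError(f"covariate columns not found: {missing_cols}")
        cov = (df.set_index("id").loc[ids, list(covariates)]
               .reset_index(drop=True).astype(float))
    return PhenotypeTable(values, breeds, ids.to_numpy(),
                          panel.samples["breed"].to_numpy(), cov)


# -- result serialization ----------------------------------------------

def write_blockmap(blocks: BlockMap, path) -> None:
    """BED-like tab file; SNP indices are 1-based inclusive on disk."""
    out = pd.DataFrame({
        "chrom": blocks.table["chrom"],
        "start_snp": blocks.table["start"] + 1,
        "end_snp": blocks.table["stop"],
        "n_snps": blocks.sizes(),
        "method": blocks.method,
    })
    out.to_csv(path, sep="\t", index=False)


def read_blockmap(path) -> BlockMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    table = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start_snp"] - 1,
        "stop": df["end_snp"],
    })
    method = str(df["method"].iloc[0]) if len(df) else "ld"
    return BlockMap(table, method=method)


def write_gebv_table(gebv: pd.DataFrame, path) -> None:
    """Tidy GEBV table: sample, breed(-trait), gebv [, gebv_sd]."""
    gebv.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gebv_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "breed": str})


def write_posterior_covariances(block_cov: np.ndarray, trait_breeds,
                                path) -> None:
    """Per-block posterior (co)variances, long format.

    ``block_cov`` has shape (s, p, p); one output row per block per
    upper-triangle entry (p variances + p(p-1)/2 covariances).
    """
    s, p, _ = block_cov.shape
    rows = []
    for i in range(s):
        for a in range(p):
            for b in range(a, p):
                rows.append((i, trait_breeds[a], trait_breeds[b],
                             block_cov[i, a, b]))
    pd.DataFrame(rows, columns=["block", "trait_a", "trait_b", "value"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.17g")
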