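"""PLINK-format genotype i/o plus the pipeline's plain-text tables.

PED/MAP are the text formats (alleles coded 1/2, 0 = missing; MAP carries
chromosome, marker name, genetic position in cM and a base-pair position
derived at 1 cM ~ 1 Mb). BED/BIM/FAM is the standard binary companion
(SNP-major, magic bytes 0x6c 0x1b 0x01).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_bed",
    "read_bed",
    "write_pedigree_csv",
    "write_phenotype_csv",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit BED codes, SNP-major: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_FROM_DOSAGE = {0: 0b11, 1: 0b10, 2: 0b00, -1: 0b01}
_DOSAGE_FROM_CODE = np.array([2, -1, 1, 0], dtype=np.int8)


def _marker_frame(chrom: np.ndarray, pos_cM: np.ndarray, names=None) -> pd.DataFrame:
    names = (
        [f"snp{c + 1}_{i + 1}" for i, c in enumerate(chrom)] if names is None else list(names)
    )
    return pd.DataFrame(
        {
            "chrom": np.asarray(chrom) + 1,
            "name": names,
            "cM": np.asarray(pos_cM),
            "bp": np.round(np.asarray(pos_cM) * 1e6).astype(np.int64),
        }
    )


def write_ped_map(prefix, genotypes, chrom, pos_cM, fam: pd.DataFrame | None = None, names=None):
    """Write 0/1/2 dosages (missing = -1) as PED/MAP at ``prefix``.

    ``fam`` may provide columns fid, iid, father, mother, sex, phenotype;
    defaults are unrelated animals with unknown sex and missing phenotype.
    """
    prefix = Path(prefix)
    G = np.asarray(genotypes)
    n, m = G.shape
    _marker_frame(chrom, pos_cM, names).to_csv(
        prefix.with_suffix(".map"), sep="\t", header=False, index=False
    )
    if fam is None:
        fam = pd.DataFrame(
            {"fid": 1, "iid": np.arange(1, n + 1), "father": 0, "mother": 0, "sex": 0,
             "phenotype": -9}
        )
    # dosage k -> allele pair: 0 -> "2 2", 1 -> "1 2", 2 -> "1 1", missing -> "0 0"
    pair = {0: "2 2", 1: "1 2", 2: "1 1", -1: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for r in range(n):
            lead = " ".join(str(v) for v in fam.iloc[r].tolist())
            body = " ".join(pair[int(g)] for g in G[r])
            fh.write(f"{lead} {body}\n")


def read_ped_map(prefix):
    """Read PED/MAP back into (dosages, marker frame, fam frame)."""
    prefix = Path(prefix)
    marker = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None, names=["chrom", "name", "cM", "bp"]
    )
    fam_rows, geno_rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            fam_rows.append(parts[:6])
            alleles = np.array(parts[6:], dtype=np.int8).reshape(-1, 2)
            missing = (alleles == 0).any(axis=1)
            dosage = (alleles == 1).sum(axis=1).astype(np.int8)
            dosage[missing] = -1
            geno_rows.append(dosage)
    fam = pd.DataFrame(fam_rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"])
    return np.vstack(geno_rows), marker, fam


def write_bed(prefix, genotypes, chrom, pos_cM, fam: pd.DataFrame | None = None, names=None):
    """Write BED/BIM/FAM (SNP-major) for 0/1/2 dosages (missing = -1)."""
    prefix = Path(prefix)
    G = np.asarray(genotypes)
    n, m = G.shape
    marker = _marker_frame(chrom, pos_cM, names)
    bim = marker.assign(a1=1, a2=2)[["chrom", "name", "cM", "bp", "a1", "a2"]]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    if fam is None:
        fam = pd.DataFrame(
            {"fid": 1, "iid": np.arange(1, n + 1), "father": 0, "mother": 0, "sex": 0,
             "phenotype": -9}
        )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    lookup = np.zeros(4, dtype=np.uint8)
    for dosage, code in _CODE_FROM_DOSAGE.items():
        lookup[dosage % 4] = code  # -1 maps to index 3
    codes = lookup[G % 4]  # (n, m) of 2-bit codes
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for k in range(4):
        rows = np.arange(k, n, 4)
        packed[:, : len(rows)] |= codes[rows].T << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_bed(prefix):
    """Read BED/BIM/FAM into (dosages, marker frame, fam frame)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "name", "cM", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
    )
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK BED file")
    m, n = len(bim), len(fam)
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    dosages = np.empty((n, m), dtype=np.int8)
    for k in range(4):
        rows = np.arange(k, n, 4)
        codes = (body[:, : len(rows)] >> (2 * k)) & 0b11
        dosages[rows] = _DOSAGE_FROM_CODE[codes].T
    return dosages, bim, fam


def write_pedigree_csv(path, pedigree: pd.DataFrame):
    pedigree[["id", "sire", "dam", "sex", "generation"]].to_csv(path, index=False)


def write_phenotype_csv(path, pedigree: pd.DataFrame):
    pedigree[["id", "phenotype", "tbv"]].to_csv(path, index=False)
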