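"""Readers/writers for the PLINK 1 binary trio and GCTA binary GRM files.

The .bed codec follows the SNP-major PLINK 1 layout: a 3-byte magic
(0x6c, 0x1b, 0x01) then, per SNP, ceil(n/4) bytes packing four samples per
byte, lowest bits first. Two-bit codes: 00 = homozygous A1, 10 = heterozygous,
11 = homozygous A2, 01 = missing. Dosages count copies of the A1 allele.

The GCTA GRM triple is ``<prefix>.grm.bin`` (float32 lower triangle, row by
row including the diagonal), ``<prefix>.grm.N.bin`` (float32 SNP counts per
pair, same layout) and ``<prefix>.grm.id`` (FID IID lines).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_bed",
    "read_bed",
    "write_plink",
    "read_plink",
    "write_pheno",
    "read_pheno",
    "write_covar",
    "read_covar",
    "write_gcta_grm",
    "read_gcta_grm",
]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage (A1 count) -> 2-bit code; missing (-1) -> 01
_CODE_OF_DOSAGE = np.array([3, 2, 0], dtype=np.uint8)  # 0 -> 11, 1 -> 10, 2 -> 00
_DOSAGE_OF_CODE = np.array([2, -1, 1, 0], dtype=np.int8)

# 256 x 4 lookup: byte value -> 4 dosages
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _s in range(4):
        _BYTE_LUT[_b, _s] = _DOSAGE_OF_CODE[(_b >> (2 * _s)) & 0b11]


def write_bed(path: str | Path, dosages: np.ndarray) -> None:
    """Write an (n_samples, n_snps) dosage matrix as a SNP-major PLINK .bed."""
    d = np.asarray(dosages)
    if d.ndim != 2:
        raise ValueError("dosages must be 2-D (samples x SNPs)")
    if not np.isin(d, [-1, 0, 1, 2]).all():
        raise ValueError("dosages must be in {0,1,2} (-1 for missing)")
    n, m = d.shape
    codes = np.where(d < 0, 1, _CODE_OF_DOSAGE[np.clip(d, 0, 2)]).astype(np.uint8)
    n_pad = (-n) % 4
    if n_pad:
        codes = np.vstack([codes, np.zeros((n_pad, m), dtype=np.uint8)])
    # pack 4 samples/byte, sample-fastest within byte, SNP-major across bytes
    c = codes.T.reshape(m, -1, 4)  # (m, bytes_per_snp, 4)
    packed = (c[..., 0] | (c[..., 1] << 2) | (c[..., 2] << 4) | (c[..., 3] << 6)).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())


def read_bed(path: str | Path, n_samples: int, n_snps: int) -> np.ndarray:
    """Read a SNP-major PLINK .bed into an (n_samples, n_snps) int8 matrix (-1 missing)."""
    raw = Path(path).read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError(f"{path}: not a SNP-major PLINK 1 .bed file")
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * n_snps:
        raise ValueError(
            f"{path}: expected {bytes_per_snp * n_snps} data bytes, found {body.size}"
        )
    d = _BYTE_LUT[body.reshape(n_snps, bytes_per_snp)].reshape(n_snps, -1)
    return np.ascontiguousarray(d[:, :n_samples].T)


def write_plink(prefix: str | Path, genotypes, fam: pd.DataFrame | None = None) -> None:
    """Write a GenotypeMatrix as <prefix>.bed/.bim/.fam.

    ``fam`` may supply per-sample sex (0/1) and status (0/1); defaults write
    unknown sex and missing phenotype.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_bed(prefix.with_suffix(".bed"), genotypes.dosages)
    meta = genotypes.snp_meta
    bim = pd.DataFrame(
        {
            "chrom": meta["chrom"].astype(int),
            "snp_id": meta["snp_id"],
            "cm": 0,
            "pos_bp": meta["pos_bp"].astype(int),
            "a1": meta["a1"],
            "a2": meta["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    ids = list(genotypes.sample_ids)
    if fam is not None:
        sex_code = np.asarray(fam["sex"]).astype(int) + 1  # 0/1 -> 1/2
        pheno = np.asarray(fam["status"]).astype(int) + 1  # 0/1 -> 1/2
    else:
        sex_code = np.zeros(len(ids), dtype=int)
        pheno = np.full(len(ids), -9, dtype=int)
    fam_df = pd.DataFrame(
        {"fid": ids, "iid": ids, "pid": 0, "mid": 0, "sex": sex_code, "pheno": pheno}
    )
    fam_df.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path):
    """Read <prefix>.bed/.bim/.fam into a :class:`~snph2.simulate.GenotypeMatrix`.

    Allele frequencies in the returned metadata are the realized A1 sample
    frequencies (missing genotypes excluded).
    """
    from .simulate import GenotypeMatrix

    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    d = read_bed(prefix.with_suffix(".bed"), len(fam), len(bim))
    freq = np.where(d >= 0, d, np.nan)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(freq, axis=0) / 2.0
    meta = bim[["chrom", "snp_id", "pos_bp", "a1", "a2"]].copy()
    meta["allele_freq"] = p
    return GenotypeMatrix(dosages=d, snp_meta=meta, sample_ids=fam["iid"].tolist())


def write_pheno(path: str | Path, sample_ids, status) -> None:
    pd.DataFrame({"fid": sample_ids, "iid": sample_ids, "status": np.asarray(status).astype(int)}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_pheno(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, names=["fid", "iid", "status"], dtype={"fid": str, "iid": str})


def write_covar(path: str | Path, sample_ids, sex, age) -> None:
    pd.DataFrame(
        {"fid": sample_ids, "iid": sample_ids, "sex": np.asarray(sex).astype(int), "age": np.asarray(age)}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_covar(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=r"\s+", header=None, names=["fid", "iid", "sex", "age"], dtype={"fid": str, "iid": str}
    )


def write_truth_json(path: str | Path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def write_gcta_grm(prefix: str | Path, grm) -> None:
    """Write a Grm as the GCTA binary triple <prefix>.grm.bin/.grm.N.bin/.grm.id."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.values.shape[0]
    tril = np.tril_indices(n)
    lower = grm.values[tril].astype(np.float32)
    lower.tofile(str(prefix) + ".grm.bin")
    np.full(lower.shape, grm.n_snps, dtype=np.float32).tofile(str(prefix) + ".grm.N.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_gcta_grm(prefix: str | Path):
    """Read a GCTA binary GRM triple into a :class:`~snph2.relatedness.Grm`."""
    from .relatedness import Grm

    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    lower = np.fromfile(prefix + ".grm.bin", dtype=np.float32)
    if lower.size != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin: size does not match {n} samples")
    vals = np.zeros((n, n))
    tril = np.tril_indices(n)
    vals[tril] = lower
    vals = vals + np.tril(vals, -1).T
    counts = np.fromfile(prefix + ".grm.N.bin", dtype=np.float32)
    n_snps = int(round(float(counts[0]))) if counts.size else 0
    return Grm(values=vals, n_snps=n_snps, sample_ids=ids)
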