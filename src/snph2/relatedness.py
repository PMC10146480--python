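"""Genetic relatedness matrices, segment LD scores and LDMS stratification.

The GRM is the standard allele-frequency-standardized kernel

    A_jk = (1/M) Sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with ``p_i`` estimated from the analysed sample (cases and controls jointly)
and monomorphic SNPs dropped. For LD-and-MAF-stratified (LDMS) fits each SNP
is scored by its segment LD score — the sum of squared dosage correlations
with all SNPs within a fixed window (200 kb total, i.e. +/-100 kb around the
SNP) — then binned by a MAF split at 0.05 and LD-score quartiles within each
MAF group, and one GRM is built per bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import RegionSet
from .simulate import GenotypeMatrix

__all__ = [
    "Grm",
    "SnpStrata",
    "compute_grm",
    "segment_ld_scores",
    "make_ldms_strata",
    "exclude_regions",
]

logger = logging.getLogger(__name__)


@dataclass
class Grm:
    """A symmetric N x N relatedness matrix and the SNP count that built it.

    When built by :func:`compute_grm` the standardized genotype factor ``Z``
    (with ``values = Z Z' / n_snps``) is retained, which lets the REML engine
    obtain the kernel's spectrum from the much smaller M x M SNP Gram matrix
    when M < N.
    """

    values: np.ndarray
    n_snps: int
    sample_ids: list[str]
    factor: np.ndarray | None = field(default=None, repr=False)
    _spectrum: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if not np.isfinite(v).all():
            raise ValueError("GRM contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValueError("GRM is not symmetric within 1e-12")
        if len(self.sample_ids) != v.shape[0]:
            raise ValueError("sample_ids length does not match GRM dimension")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def spectrum(self, tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (descending, non-zero part only) and eigenvectors.

        Returns ``(d, U)`` with ``A ~= U diag(d) U'`` where ``d`` holds the
        eigenvalues above ``tol * max(d)``; omitted directions lie in the
        kernel's null space. Uses the SNP-factor route when cheaper. Cached.
        """
        if self._spectrum is not None:
            return self._spectrum
        n = self.n_samples
        if self.factor is not None and self.factor.shape[1] < n:
            Z = self.factor
            m = Z.shape[1]
            w, V = np.linalg.eigh(Z.T @ Z / self.n_snps)
            order = np.argsort(w)[::-1]
            w, V = w[order], V[:, order]
            keep = w > max(tol * max(w[0], 0.0), 0.0)
            w, V = w[keep], V[:, keep]
            U = (Z @ V) / np.sqrt(w * self.n_snps)
        else:
            w, U = np.linalg.eigh(self.values)
            order = np.argsort(w)[::-1]
            w, U = w[order], U[:, order]
            keep = w > tol * max(w[0], 0.0)
            w, U = w[keep], U[:, keep]
        self._spectrum = (w, U)
        return self._spectrum


def _standardize(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, allele-frequency-standardized dosages and the mask of polymorphic SNPs."""
    d = np.where(dosages >= 0, dosages, np.nan).astype(float)
    p = np.nanmean(d, axis=0) / 2.0
    het = 2 * p * (1 - p)
    poly = het > 0
    d = np.where(np.isnan(d), 2 * p, d)
    Z = (d[:, poly] - 2 * p[poly]) / np.sqrt(het[poly])
    return Z, poly


def compute_grm(
    G: GenotypeMatrix,
    snp_subset: Sequence[str] | None = None,
    keep_factor: bool = True,
) -> Grm:
    """GCTA-style GRM from (a subset of) a genotype matrix.

    Allele frequencies come from the analysed sample; monomorphic SNPs are
    excluded from the SNP count. Missing dosages (real data only) are
    mean-imputed before standardization.
    """
    if snp_subset is not None:
        G = G.subset_snps(snp_subset)
    Z, poly = _standardize(G.dosages)
    m = int(poly.sum())
    if m == 0:
        raise ValueError("no polymorphic SNPs remain after filtering; cannot build a GRM")
    values = (Z @ Z.T) / m
    return Grm(
        values=values,
        n_snps=m,
        sample_ids=list(G.sample_ids),
        factor=Z if keep_factor else None,
    )


def segment_ld_scores(G: GenotypeMatrix, segment_bp: int = 200_000) -> np.ndarray:
    """Segment-based LD score per SNP.

    ``ld_score(i) = Sum_j r^2(i, j)`` over SNPs j on the same chromosome with
    ``|pos_j - pos_i| <= segment_bp / 2`` (a sliding window of total width
    ``segment_bp`` centred on the SNP, including j = i, so every score is
    >= 1). r^2 is the squared Pearson correlation of mean-imputed dosages;
    monomorphic SNPs get score exactly 1.
    """
    d = np.where(G.dosages >= 0, G.dosages, np.nan).astype(float)
    p = np.nanmean(d, axis=0) / 2.0
    d = np.where(np.isnan(d), 2 * p, d)
    sd = d.std(axis=0)
    Z = np.zeros_like(d)
    ok = sd > 0
    Z[:, ok] = (d[:, ok] - d[:, ok].mean(axis=0)) / sd[ok]
    n = Z.shape[0]

    half = segment_bp / 2.0
    scores = np.ones(G.n_snps)
    chroms = G.snp_meta["chrom"].to_numpy()
    pos = G.snp_meta["pos_bp"].to_numpy()
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        cpos = pos[idx]
        if np.any(np.diff(cpos) < 0):
            raise ValueError(f"positions not sorted on chromosome {c}")
        lo = np.searchsorted(cpos, cpos - half, side="left")
        hi = np.searchsorted(cpos, cpos + half, side="right")
        for k, i in enumerate(idx):
            if not ok[i]:
                continue
            window = idx[lo[k] : hi[k]]
            window = window[ok[window]]
            r = (Z[:, window].T @ Z[:, i]) / n
            scores[i] = float(np.sum(r * r))
    return scores


@dataclass
class SnpStrata:
    """Assignment of every SNP to one LD-score x MAF stratum.

    ``table`` columns: snp_id, maf, ld_score, stratum_id (consecutive ints);
    ``definitions`` maps stratum_id -> (maf_group, ld_bin) with the quartile
    boundaries recorded in ``boundaries``.
    """

    table: pd.DataFrame
    definitions: dict[int, tuple[str, int]]
    boundaries: dict[str, np.ndarray]
    maf_split: float

    @property
    def n_strata(self) -> int:
        return len(self.definitions)

    def snp_ids(self, stratum_id: int) -> list[str]:
        return self.table.loc[self.table["stratum_id"] == stratum_id, "snp_id"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def make_ldms_strata(
    ld_scores: np.ndarray,
    mafs: np.ndarray,
    snp_ids: Sequence[str] | None = None,
    maf_split: float = 0.05,
    n_ld_bins: int = 4,
) -> SnpStrata:
    """Partition SNPs by MAF split then LD-score quartiles within each MAF group.

    Quartile boundaries use linear-interpolation quantiles of the group's own
    LD scores, with right-closed bins (a score equal to a boundary falls in
    the lower bin); with all-tied scores a group collapses into a single bin.
    Empty strata are dropped with a warning, and groups smaller than the bin
    count fall back to fewer bins.
    """
    ld_scores = np.asarray(ld_scores, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if ld_scores.shape != mafs.shape:
        raise ValueError("ld_scores and mafs must be aligned")
    m = ld_scores.size
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(m)]
    maf_group = np.where(np.minimum(mafs, 1 - mafs) <= maf_split, "low_maf", "high_maf")

    stratum = np.full(m, -1, dtype=int)
    definitions: dict[int, tuple[str, int]] = {}
    boundaries: dict[str, np.ndarray] = {}
    next_id = 0
    for grp in ("low_maf", "high_maf"):
        mask = maf_group == grp
        k = int(mask.sum())
        if k == 0:
            continue
        bins = min(n_ld_bins, k)
        if bins < n_ld_bins:
            logger.warning("MAF group %s has %d SNPs; using %d LD bins instead of %d", grp, k, bins, n_ld_bins)
        qs = np.quantile(ld_scores[mask], np.linspace(0, 1, bins + 1)[1:-1])
        boundaries[grp] = qs
        # right-closed: score <= boundary -> lower bin
        bin_ids = np.searchsorted(qs, ld_scores[mask], side="left")
        for b in range(bins):
            sel = np.flatnonzero(mask)[bin_ids == b]
            if sel.size == 0:
                logger.warning("dropping empty stratum (%s, LD bin %d)", grp, b)
                continue
            stratum[sel] = next_id
            definitions[next_id] = (grp, b)
            next_id += 1
    table = pd.DataFrame(
        {"snp_id": list(snp_ids), "maf": mafs, "ld_score": ld_scores, "stratum_id": stratum}
    )
    return SnpStrata(table=table, definitions=definitions, boundaries=boundaries, maf_split=maf_split)


def exclude_regions(
    snp_meta: pd.DataFrame,
    regions: RegionSet,
    flank_bp: int = 0,
) -> list[str]:
    """SNP ids whose position lies outside every region interval +/- flank.

    Containment is 1-based inclusive on both interval ends, so a SNP exactly
    at ``start - flank`` or ``end + flank`` is excluded.
    """
    hit = regions.contains(
        snp_meta["chrom"].to_numpy(), snp_meta["pos_bp"].to_numpy(), flank_bp=flank_bp
    )
    return snp_meta.loc[~hit, "snp_id"].tolist()
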