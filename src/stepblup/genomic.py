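"""Genotype QC and genomic relationship matrices for single-step GBLUP.

The single-step combined relationship matrix enters the mixed-model
equations only through its inverse,

    H^-1 = A^-1 + [0 0; 0 (w G + (1-w) A22)^-1 - A22^-1],   w = 0.95,

where G is VanRaden's (method 1) genomic relationship matrix computed
from centred SNP dosages and A22 is the pedigree relationship block of
the genotyped animals.  Blending G with a small share of A22 guarantees
an invertible genomic block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree, RelationshipMatrix, a_inverse, a_matrix


class GenomicError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix (animals x SNPs, entries 0/1/2, NaN = missing)."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray  # float array, NaN for missing

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise GenomicError("dosage matrix shape does not match ID lists")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def write_raw(self, path) -> None:
        """Write a PLINK .raw-style additive dosage table (whitespace-separated)."""
        df = pd.DataFrame(self.dosages, columns=list(self.snp_ids))
        df.insert(0, "IID", self.animal_ids)
        df.to_csv(path, sep=" ", index=False, na_rep="NA")


def read_raw(path: str | Path) -> GenotypeMatrix:
    """Read a PLINK .raw-style dosage table.

    The file must contain an ``IID`` column with animal IDs; other
    standard .raw metadata columns (FID, PAT, MAT, SEX, PHENOTYPE) are
    ignored when present, every remaining column is a SNP.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"IID": str})
    if "IID" not in df.columns:
        raise GenomicError("dosage table must contain an 'IID' column")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    snps = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(
        animal_ids=df["IID"].to_numpy(dtype=object),
        snp_ids=np.asarray(snps, dtype=object),
        dosages=df[snps].to_numpy(dtype=np.float64),
    )


@dataclass
class QCReport:
    """Per-filter removal bookkeeping for a genotype panel."""

    n_input_snps: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    n_input_animals: int
    n_removed_animals: int
    removed_call_rate: list = field(default_factory=list)
    removed_maf: list = field(default_factory=list)
    removed_hwe: list = field(default_factory=list)
    removed_animals: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Frequency of the dosage-coded allele per SNP, p_j = mean(dosage_j)/2.

    Missing entries are ignored in the mean.
    """
    with np.errstate(invalid="ignore"):
        return np.nanmean(geno.dosages, axis=0) / 2.0


def qc_filter(
    geno: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.01,
    max_hwe_dev: float = 0.15,
):
    """Apply the fixed QC cascade: call rate (SNP, then animal) -> MAF -> HWE.

    Allele frequencies are recomputed after each step.  The
    Hardy-Weinberg departure of a SNP is |observed heterozygote frequency
    - 2 p (1-p)|; SNPs exceeding ``max_hwe_dev`` are removed.  Returns
    the filtered panel and a :class:`QCReport`.  Missing dosages must be
    confined to low-call-rate rows/columns: if any remain after
    filtering, an error asks for external imputation.
    """
    dos = geno.dosages
    snp_keep = np.ones(geno.n_snps, dtype=bool)
    ani_keep = np.ones(geno.n_animals, dtype=bool)

    # 1a. SNP call rate
    snp_cr = 1.0 - np.mean(np.isnan(dos), axis=0)
    snp_keep = snp_cr >= min_call_rate
    removed_cr = list(geno.snp_ids[~snp_keep])
    # 1b. animal call rate on the surviving SNPs
    if snp_keep.any():
        ani_cr = 1.0 - np.mean(np.isnan(dos[:, snp_keep]), axis=1)
    else:
        ani_cr = np.zeros(geno.n_animals)
    ani_keep = ani_cr >= min_call_rate
    removed_animals = list(geno.animal_ids[~ani_keep])

    sub = dos[np.ix_(ani_keep, snp_keep)]
    ids_now = geno.snp_ids[snp_keep]

    # 2. MAF
    with np.errstate(invalid="ignore"):
        p = np.nanmean(sub, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf_ok = maf >= min_maf
    removed_maf = list(ids_now[~maf_ok])
    sub = sub[:, maf_ok]
    ids_now = ids_now[maf_ok]

    # 3. HWE heterozygote departure, frequencies recomputed post-MAF
    with np.errstate(invalid="ignore"):
        p = np.nanmean(sub, axis=0) / 2.0
        het = np.nanmean(sub == 1.0, axis=0)
    dev = np.abs(het - 2.0 * p * (1.0 - p))
    hwe_ok = dev <= max_hwe_dev
    removed_hwe = list(ids_now[~hwe_ok])
    sub = sub[:, hwe_ok]
    ids_now = ids_now[hwe_ok]

    if sub.shape[1] == 0:
        raise GenomicError("QC removed every SNP: empty panel")
    if np.isnan(sub).any():
        raise GenomicError(
            "missing dosages remain after QC; impute genotypes before analysis"
        )

    report = QCReport(
        n_input_snps=geno.n_snps,
        n_removed_call_rate=len(removed_cr),
        n_removed_maf=len(removed_maf),
        n_removed_hwe=len(removed_hwe),
        n_retained=int(sub.shape[1]),
        n_input_animals=geno.n_animals,
        n_removed_animals=len(removed_animals),
        removed_call_rate=[str(s) for s in removed_cr],
        removed_maf=[str(s) for s in removed_maf],
        removed_hwe=[str(s) for s in removed_hwe],
        removed_animals=[str(a) for a in removed_animals],
    )
    out = GenotypeMatrix(
        animal_ids=geno.animal_ids[ani_keep],
        snp_ids=ids_now,
        dosages=sub,
    )
    return out, report


def vanraden_g(geno: GenotypeMatrix, p: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    G = Z Z' / (2 sum_j p_j (1 - p_j)) with Z the dosage matrix centred
    column-wise by 2 p_j.  By default p is computed from the observed
    panel; pass base-population frequencies to override.
    """
    if np.isnan(geno.dosages).any():
        raise GenomicError("vanraden_g requires complete dosages (run QC first)")
    if p is None:
        p = allele_frequencies(geno)
    p = np.asarray(p, dtype=np.float64)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise GenomicError("all SNPs monomorphic: zero scaling denominator")
    Z = geno.dosages - 2.0 * p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(ids=geno.animal_ids.copy(), values=G, kind="G")


def blend(
    G: RelationshipMatrix, A22: RelationshipMatrix, w: float = 0.95
) -> RelationshipMatrix:
    """Gw = w G + (1-w) A22 (invertible for w < 1 when A22 is PD)."""
    if G.n != A22.n or not np.array_equal(G.ids, A22.ids):
        raise GenomicError("G and A22 must share the same animal ordering")
    if not (0.0 < w <= 1.0):
        raise GenomicError("blend weight must lie in (0, 1]")
    vals = w * G.dense() + (1.0 - w) * A22.dense()
    return RelationshipMatrix(ids=G.ids.copy(), values=vals, kind="G_blended")


@dataclass
class HInverseParts:
    """Ingredients of the single-step H^-1 assembly."""

    A_inv: RelationshipMatrix  # sparse, full pedigree
    A22: RelationshipMatrix  # dense, genotyped animals
    G: RelationshipMatrix  # dense, genotyped animals
    genotyped_index: np.ndarray  # positions of genotyped animals in pedigree order
    blend_weight: float = 0.95


def _inv_pd(M: np.ndarray, label: str) -> np.ndarray:
    from scipy.linalg import cho_factor, cho_solve

    try:
        c = cho_factor(M)
    except np.linalg.LinAlgError as exc:
        eigmin = float(np.linalg.eigvalsh(M).min())
        raise GenomicError(
            f"{label} is singular or indefinite (min eigenvalue {eigmin:.3e})"
        ) from exc
    return cho_solve(c, np.eye(M.shape[0]))


def h_inverse(parts: HInverseParts) -> RelationshipMatrix:
    """Assemble sparse H^-1 = A^-1 + scatter((wG + (1-w)A22)^-1 - A22^-1)."""
    n = parts.A_inv.n
    idx = np.asarray(parts.genotyped_index, dtype=np.int64)
    hinv = sp.csr_matrix(parts.A_inv.values, copy=True).astype(np.float64)
    if idx.size:
        Gw = blend(parts.G, parts.A22, parts.blend_weight)
        gw_inv = _inv_pd(Gw.dense(), "blended G")
        a22_inv = _inv_pd(parts.A22.dense(), "A22")
        corr = gw_inv - a22_inv
        corr = 0.5 * (corr + corr.T)
        rows = np.repeat(idx, idx.size)
        cols = np.tile(idx, idx.size)
        scatter = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
        hinv = (hinv + scatter.tocsr()).tocsr()
    return RelationshipMatrix(ids=parts.A_inv.ids.copy(), values=hinv, kind="H_inv")


def build_h_inverse(
    ped: Pedigree,
    geno: GenotypeMatrix,
    w: float = 0.95,
    p: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Convenience: A^-1, A22 and G from pedigree + genotypes, then H^-1."""
    ainv = a_inverse(ped)
    a22 = a_matrix(ped, subset=list(geno.animal_ids))
    G = vanraden_g(geno, p=p)
    parts = HInverseParts(
        A_inv=ainv,
        A22=a22,
        G=G,
        genotyped_index=ped.index_of(geno.animal_ids),
        blend_weight=w,
    )
    return h_inverse(parts)
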