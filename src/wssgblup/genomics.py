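"""Genotype handling: PLINK text I/O, quality control, G, G* and H^-1.

The genomic relationship matrix follows VanRaden's first method:

    G = Z D Z' / sum_i 2 p_i (1 - p_i)

with Z the column-centred dosage matrix (dosage - 2p) and D a diagonal
matrix of per-SNP weights (identity for the unweighted analysis).  The
single-step inverse combines the sparse pedigree inverse with a dense
correction on the genotyped block:

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

Frequencies p are observed counted-allele frequencies in the genotyped set
(not folded minor-allele frequencies): folding would flip centring signs
SNP by SNP.  A ``fold_maf`` switch exists for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import RelationshipMatrix

MISSING_DOSAGE = -9

AUTOSOMES_BTA = frozenset(str(c) for c in range(1, 30))


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    animal_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray          # per-SNP chromosome label (str)
    pos_bp: np.ndarray         # per-SNP 1-based position
    dosage: np.ndarray         # animals x SNPs, int8, {0,1,2,MISSING_DOSAGE}
    counted_allele: np.ndarray
    other_allele: np.ndarray

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING_DOSAGE

    def sorted_by_map(self) -> "GenotypeMatrix":
        """Return a copy with SNPs ordered by (chromosome, position)."""
        uniq = sorted(set(self.chrom), key=lambda c: (len(c), c))  # "2" before "10"
        rank = {c: k for k, c in enumerate(uniq)}
        order = np.lexsort((self.pos_bp, np.array([rank[c] for c in self.chrom])))
        return replace(
            self,
            snp_ids=[self.snp_ids[j] for j in order],
            chrom=self.chrom[order],
            pos_bp=self.pos_bp[order],
            dosage=self.dosage[:, order],
            counted_allele=self.counted_allele[order],
            other_allele=self.other_allele[order],
        )


@dataclass
class AlleleFrequencies:
    p: np.ndarray
    maf: np.ndarray
    two_pq_sum: float


@dataclass
class SnpWeights:
    d: np.ndarray
    iteration: int = 0

    @classmethod
    def identity(cls, n_snps: int) -> "SnpWeights":
        return cls(d=np.ones(n_snps), iteration=0)


@dataclass
class QCReport:
    n_snps_in: int
    n_animals_in: int
    n_snps_nonautosomal: int
    n_animals_low_callrate: int
    n_snps_low_maf: int
    n_snps_out: int
    n_animals_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "input_snps",
                    "input_animals",
                    "dropped_nonautosomal_snps",
                    "dropped_low_callrate_animals",
                    "dropped_low_maf_snps",
                    "output_snps",
                    "output_animals",
                ],
                "count": [
                    self.n_snps_in,
                    self.n_animals_in,
                    self.n_snps_nonautosomal,
                    self.n_animals_low_callrate,
                    self.n_snps_low_maf,
                    self.n_snps_out,
                    self.n_animals_out,
                ],
            }
        )


# ---------------------------------------------------------------------------
# PLINK text I/O


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK 6-column .ped + 4-column .map text files.

    The counted allele of each SNP is the first non-missing allele observed
    in file order (deterministic given the file).  ``0 0`` genotypes become
    missing dosages.
    """
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise GenotypeError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom.append(parts[0])
            snp_ids.append(parts[1])
            pos.append(int(parts[3]))
    n_snps = len(snp_ids)

    animal_ids: list[str] = []
    counted = np.array([""] * n_snps, dtype=object)
    other = np.array([""] * n_snps, dtype=object)
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            animal_ids.append(parts[1])
            alleles = np.array(parts[6:], dtype=object).reshape(n_snps, 2)
            dos = np.full(n_snps, MISSING_DOSAGE, dtype=np.int8)
            for j in range(n_snps):
                a1, a2 = alleles[j]
                if a1 == "0" or a2 == "0":
                    if a1 != a2:
                        raise GenotypeError(
                            f"{ped_path}:{ln}: half-missing genotype for SNP {snp_ids[j]}"
                        )
                    continue
                for a in (a1, a2):
                    if not counted[j]:
                        counted[j] = a
                    elif a != counted[j] and not other[j]:
                        other[j] = a
                    elif a != counted[j] and a != other[j]:
                        raise GenotypeError(
                            f"{ped_path}:{ln}: more than two alleles for SNP {snp_ids[j]}"
                        )
                dos[j] = int(a1 == counted[j]) + int(a2 == counted[j])
            rows.append(dos)
    dosage = np.vstack(rows) if rows else np.zeros((0, n_snps), dtype=np.int8)
    return GenotypeMatrix(
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        dosage=dosage,
        counted_allele=counted,
        other_allele=np.where(other == "", "N", other),
    ).sorted_by_map()


def write_plink_text(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write .ped/.map so that :func:`read_plink_text` round-trips."""
    with open(map_path, "w") as fh:
        for c, s, p in zip(g.chrom, g.snp_ids, g.pos_bp):
            fh.write(f"{c}\t{s}\t0\t{p}\n")
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(g.animal_ids):
            fields = ["FAM", str(aid), "0", "0", "0", "-9"]
            for j in range(g.n_snps):
                d = g.dosage[i, j]
                if d == MISSING_DOSAGE:
                    fields += ["0", "0"]
                else:
                    a, b = g.counted_allele[j], g.other_allele[j]
                    fields += [a] * int(d) + [b] * (2 - int(d))
            fh.write(" ".join(fields) + "\n")


def read_plink_raw(raw_path) -> GenotypeMatrix:
    """Read a PLINK .raw additive-dosage file (no map; positions 0)."""
    df = pd.read_csv(raw_path, sep=r"\s+")
    snp_cols = [c for c in df.columns if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
    dos = df[snp_cols].to_numpy(dtype=float)
    dosage = np.where(np.isnan(dos), MISSING_DOSAGE, dos).astype(np.int8)
    names, counted = [], []
    for c in snp_cols:
        name, _, allele = c.rpartition("_")
        names.append(name or c)
        counted.append(allele if name else "A")
    n = len(names)
    return GenotypeMatrix(
        animal_ids=[str(i) for i in df["IID"]],
        snp_ids=names,
        chrom=np.array(["0"] * n, dtype=object),
        pos_bp=np.arange(1, n + 1, dtype=np.int64),
        dosage=dosage,
        counted_allele=np.array(counted, dtype=object),
        other_allele=np.array(["N"] * n, dtype=object),
    )


# ---------------------------------------------------------------------------
# QC and frequencies


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """Observed counted-allele frequency per SNP over non-missing calls."""
    dos = g.dosage.astype(float)
    miss = g.missing_mask()
    dos[miss] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    maf = np.minimum(p, 1.0 - p)
    two_pq = 2.0 * p * (1.0 - p)
    return AlleleFrequencies(p=p, maf=maf, two_pq_sum=float(two_pq.sum()))


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    ind_callrate_min: float = 0.90,
    autosomes: frozenset[str] = AUTOSOMES_BTA,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard marker QC, in order.

    1. keep autosomal SNPs only;
    2. drop individuals with call rate below ``ind_callrate_min``;
    3. drop SNPs with minor allele frequency below ``maf_min`` (recomputed
       after the individual drop).
    """
    n_snps_in, n_animals_in = g.n_snps, g.n_animals

    auto = np.array([c in autosomes for c in g.chrom])
    n_nonauto = int((~auto).sum())
    g = _subset(g, snps=np.nonzero(auto)[0])

    callrate = 1.0 - g.missing_mask().mean(axis=1) if g.n_snps else np.ones(g.n_animals)
    keep_animals = np.nonzero(callrate >= ind_callrate_min)[0]
    n_lowcall = g.n_animals - keep_animals.size
    g = _subset(g, animals=keep_animals)

    freqs = allele_frequencies(g)
    keep_snps = np.nonzero(freqs.maf >= maf_min)[0]
    n_lowmaf = g.n_snps - keep_snps.size
    g = _subset(g, snps=keep_snps)

    if g.n_snps == 0:
        raise GenotypeError("QC removed all SNPs")
    report = QCReport(
        n_snps_in=n_snps_in,
        n_animals_in=n_animals_in,
        n_snps_nonautosomal=n_nonauto,
        n_animals_low_callrate=n_lowcall,
        n_snps_low_maf=n_lowmaf,
        n_snps_out=g.n_snps,
        n_animals_out=g.n_animals,
    )
    return g, report


def _subset(g: GenotypeMatrix, animals=None, snps=None) -> GenotypeMatrix:
    if snps is not None:
        g = replace(
            g,
            snp_ids=[g.snp_ids[j] for j in snps],
            chrom=g.chrom[snps],
            pos_bp=g.pos_bp[snps],
            dosage=g.dosage[:, snps],
            counted_allele=g.counted_allele[snps],
            other_allele=g.other_allele[snps],
        )
    if animals is not None:
        g = replace(
            g,
            animal_ids=[g.animal_ids[i] for i in animals],
            dosage=g.dosage[animals, :],
        )
    return g


def subset_animals(g: GenotypeMatrix, animal_ids: Sequence[str]) -> GenotypeMatrix:
    index = {a: i for i, a in enumerate(g.animal_ids)}
    try:
        rows = np.array([index[a] for a in animal_ids], dtype=np.int64)
    except KeyError as exc:
        raise GenotypeError(f"animal {exc.args[0]!r} not genotyped") from None
    return _subset(g, animals=rows)


# ---------------------------------------------------------------------------
# Z, G, H^-1


def center_dosages(
    g: GenotypeMatrix, f: AlleleFrequencies, fold_maf: bool = False
) -> np.ndarray:
    """Centred dosage matrix Z = dosage - 2p, missing imputed to the mean."""
    p = np.minimum(f.p, 1 - f.p) if fold_maf else f.p
    Z = g.dosage.astype(np.float64)
    Z[g.missing_mask()] = np.nan
    Z -= 2.0 * p
    return np.where(np.isnan(Z), 0.0, Z)


def build_G(
    Z: np.ndarray,
    f: AlleleFrequencies,
    weights: SnpWeights | None = None,
) -> RelationshipMatrix:
    """VanRaden genomic relationship G = Z D Z' / sum 2 p (1-p)."""
    if f.two_pq_sum <= 0:
        raise GenotypeError("sum of 2p(1-p) is not positive; run QC first")
    if weights is None:
        G = Z @ Z.T
        kind = "G"
    else:
        G = (Z * weights.d) @ Z.T
        kind = "G_weighted"
    G /= f.two_pq_sum
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(labels=[str(i) for i in range(Z.shape[0])], values=G, kind=kind)


def tune_G_to_A22(G: RelationshipMatrix, A22: RelationshipMatrix) -> RelationshipMatrix:
    """Rescale G so its mean diagonal and mean off-diagonal match A22.

    Compensates for computing allele frequencies from the observed genotyped
    set rather than the (unobservable) base population: solves
    ``a + b * mean(G) = mean(A22)`` on the diagonal and off-diagonal means
    and returns ``a + b * G``.
    """
    Gd = G.dense()
    Ad = A22.dense()
    n = Gd.shape[0]
    dg, da = float(np.trace(Gd)) / n, float(np.trace(Ad)) / n
    og = float(Gd.sum() - np.trace(Gd)) / max(n * (n - 1), 1)
    oa = float(Ad.sum() - np.trace(Ad)) / max(n * (n - 1), 1)
    b = (da - oa) / (dg - og)
    a = oa - b * og
    return RelationshipMatrix(list(G.labels), a + b * Gd, G.kind)


def blend_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, alpha: float = 0.05
) -> RelationshipMatrix:
    """Convex blend (1-alpha) G + alpha A22 for numerical invertibility."""
    if alpha == 0:
        return G
    values = (1.0 - alpha) * G.dense() + alpha * A22.dense()
    return RelationshipMatrix(labels=list(G.labels), values=values, kind=G.kind)


def _spd_inverse(M: np.ndarray, err: str) -> np.ndarray:
    import scipy.linalg as sla

    try:
        cf, _ = sla.cho_factor(M, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        raise GenotypeError(err) from None
    inv, info = sla.lapack.dpotri(cf, lower=1)
    if info != 0:
        raise GenotypeError(err)
    return np.tril(inv) + np.tril(inv, -1).T


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22: RelationshipMatrix,
    G_blended: RelationshipMatrix,
    genotyped_index: np.ndarray,
) -> RelationshipMatrix:
    """Single-step H^-1: sparse A^-1 plus (G^-1 - A22^-1) on genotyped rows/cols."""
    n = A_inv.n
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    if genotyped_index.size == 0:
        return RelationshipMatrix(list(A_inv.labels), A_inv.values.copy(), "H_inverse")
    G_inv = _spd_inverse(
        G_blended.dense(),
        "G is singular or indefinite; blend it with A22 (blend_G) first",
    )
    A22_inv = _spd_inverse(A22.dense(), "A22 is singular")
    corr = G_inv - A22_inv
    corr = 0.5 * (corr + corr.T)
    rows = np.repeat(genotyped_index, genotyped_index.size)
    cols = np.tile(genotyped_index, genotyped_index.size)
    H_inv = A_inv.values.tocoo() + sp.coo_matrix(
        (corr.ravel(), (rows, cols)), shape=(n, n)
    )
    return RelationshipMatrix(list(A_inv.labels), H_inv.tocsc(), "H_inverse")
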