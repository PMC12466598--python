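"""Synthetic herd generator.

Produces the data structures the single-step analysis consumes — a
multi-generation pedigree with half-sib families, gene-dropped SNP
genotypes, and phenotypes following the analysis model
y = mu + Xb + Za + Wc + e — with known ground truth, so that every stage of
the pipeline is testable without any external dataset.

Breeding values mix up to three parts, each scaled to its configured share
of the additive variance: a few "major" QTL with large effects, a
marker-based polygenic background (many genotyped SNPs with small random
effects), and a pedigree polygenic remainder generated by the
Mendelian-sampling recursion.  Loci segregate freely by default — a
planted QTL is itself a genotyped SNP, so window scans can localise it
without an LD model — but an optional blocked-LD mode adds within-block
linkage and founder allele correlation for tagging realism.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical configs produce identical data and
identical fixture files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix, subset_animals, write_plink_text
from .mixed_model import PhenotypeTable, afc_class_from_months
from .pedigree import MISSING, PedigreeTable, build_pedigree, compute_inbreeding

# plausible trait means and fixed-effect sizes (trait units); means are
# cosmetic — the analysis centres on variance structure, not location
TRAIT_PROFILES = {
    "AFC": {"mean": 40.0, "covariates": {}, "afc_class": False},
    "IC12": {"mean": 15.0, "covariates": {"F": 8.0}, "afc_class": True},
    "ACI": {"mean": 15.0, "covariates": {"F": 8.0}, "afc_class": True},
    "RE": {"mean": 80.0, "covariates": {"F": -30.0, "age_last_calving": 0.1}, "afc_class": True},
    "custom": {"mean": 0.0, "covariates": {}, "afc_class": False},
}


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic herd.

    Defaults give a desk-scale herd (~1,500 animals over 5 discrete
    generations, ~27% genotyped on an 800-SNP / 5-chromosome map, 160
    herd-year-season classes) with the AFC variance regime.
    """

    n_founders: int = 250
    n_generations: int = 5
    offspring_per_dam: float = 2.0
    n_snps: int = 800
    n_chromosomes: int = 5
    chrom_length_bp: int = 10_000_000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 10
    qtl_variance_fraction: float = 0.10
    n_major_qtl: int = 0                    # large-effect loci, scaled separately
    major_qtl_variance_fraction: float = 0.0
    sigma2_a: float = 6.29
    sigma2_hys: float = 15.90
    sigma2_e: float = 21.01
    n_hys_classes: int = 160
    genotyped_fraction: float = 0.27
    trait_profile: str = "AFC"
    sire_use_fraction: float = 0.2   # share of available males used per generation
    phenotype_all: bool = False      # record both sexes (calibration runs)
    ld_block_bp: int | None = None   # linkage-block size; None = free segregation
    ld_switch_prob: float = 0.02     # per-locus crossover within a block
    ld_founder_copy_prob: float = 0.8  # founder within-block allele correlation
    qtl_scale_population: str = "founders"  # or "all": population whose QTL
                                            # variance is pinned to the target
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_hys", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("qtl_variance_fraction", "genotyped_fraction", "major_qtl_variance_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.qtl_variance_fraction + self.major_qtl_variance_fraction > 1.0:
            raise ValueError("QTL variance fractions sum above 1")
        if self.trait_profile not in TRAIT_PROFILES:
            raise ValueError(f"unknown trait_profile {self.trait_profile!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["founder_maf_range"] = list(self.founder_maf_range)
        return d


@dataclass
class SimTruth:
    tbv: np.ndarray                    # per pedigree animal, pedigree order
    qtl_snp_indices: np.ndarray        # background QTL
    qtl_effects: np.ndarray            # allele-substitution effects, scaled
    major_qtl_indices: np.ndarray
    major_qtl_effects: np.ndarray
    hys_effects: np.ndarray            # per HYS class
    fixed_coefficients: dict
    mu: float
    h2_target: float

    def to_json(self) -> dict:
        return {
            "tbv": self.tbv.tolist(),
            "qtl_snp_indices": self.qtl_snp_indices.tolist(),
            "qtl_effects": self.qtl_effects.tolist(),
            "major_qtl_indices": self.major_qtl_indices.tolist(),
            "major_qtl_effects": self.major_qtl_effects.tolist(),
            "hys_effects": self.hys_effects.tolist(),
            "fixed_coefficients": self.fixed_coefficients,
            "mu": self.mu,
            "h2_target": self.h2_target,
        }


@dataclass
class SimData:
    """Bundle returned by :func:`simulate_herd`."""

    config: SimConfig
    ped: PedigreeTable
    genotypes_all: GenotypeMatrix      # every pedigree animal (truth-level)
    genotyped_ids: list[str]
    phenotypes: PhenotypeTable
    truth: SimTruth

    @property
    def genotypes(self) -> GenotypeMatrix:
        """The genotyped subset, as the analysis would see it."""
        return subset_animals(self.genotypes_all, self.genotyped_ids)


# ---------------------------------------------------------------------------
# Pedigree


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator) -> PedigreeTable:
    """Discrete-generation pedigree with half-sib families.

    Sex alternates within each cohort (so both sexes always exist); each
    generation's offspring draw a sire from a reused subset of the previous
    generation's males and a dam from its females, dams limited to
    ``offspring_per_dam`` on average by cohort sizing.
    """
    ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    generation: list[int] = []
    sex: list[str] = []  # alternating M/F within cohort

    def cohort(g: int, size: int, sire_pool: list[str], dam_pool: list[str]) -> list[str]:
        members = []
        for k in range(size):
            aid = f"G{g}_{k:05d}"
            ids.append(aid)
            generation.append(g)
            sex.append("M" if k % 2 == 0 else "F")
            if sire_pool:
                sires.append(str(rng.choice(sire_pool)))
                dams.append(str(rng.choice(dam_pool)))
            else:
                sires.append("")
                dams.append("")
            members.append(aid)
        return members

    current = cohort(0, cfg.n_founders, [], [])
    for g in range(1, cfg.n_generations + 1):
        males = [a for a, s in zip(current, sex[-len(current):]) if s == "M"]
        females = [a for a, s in zip(current, sex[-len(current):]) if s == "F"]
        if not males or not females:
            raise ValueError("cohort lost a sex; increase n_founders")
        n_active = max(1, int(round(len(males) * cfg.sire_use_fraction)))
        active_sires = list(rng.choice(males, size=n_active, replace=False))
        n_off = int(round(len(females) * cfg.offspring_per_dam))
        current = cohort(g, n_off, active_sires, females)

    meta = pd.DataFrame({"generation": generation, "sex": sex})
    ped = build_pedigree(ids, sires, dams, meta=meta)
    return compute_inbreeding(ped)


# ---------------------------------------------------------------------------
# Genotypes (gene dropping)


def simulate_genotypes(
    ped: PedigreeTable, cfg: SimConfig, rng: np.random.Generator
) -> tuple[GenotypeMatrix, list[str]]:
    """Gene-drop genotypes for every pedigree animal.

    Founder haplotype alleles are Bernoulli draws at per-SNP frequencies
    uniform on ``founder_maf_range``; descendants inherit one uniformly
    chosen allele per parent per locus (free segregation).  With
    ``ld_block_bp`` set, the parental-haplotype choice is instead made once
    per block of that physical size (complete linkage within a block up to
    ``ld_switch_prob`` crossovers per locus, free recombination between
    blocks), and founder alleles within a block copy the block anchor with
    probability ``ld_founder_copy_prob`` — a coarse LD model that lets
    window scans aggregate tagging SNPs around a causal one.  Returns the
    full matrix plus the sampled genotyped subset (stratified so every
    generation is represented).
    """
    n, S = ped.n, cfg.n_snps
    snps_per_chrom = np.full(cfg.n_chromosomes, S // cfg.n_chromosomes)
    snps_per_chrom[: S % cfg.n_chromosomes] += 1
    chrom, pos = [], []
    for c in range(cfg.n_chromosomes):
        k = int(snps_per_chrom[c])
        raw = np.sort(rng.choice(cfg.chrom_length_bp - 1, size=k, replace=False)) + 1
        chrom += [str(c + 1)] * k
        pos += raw.tolist()
    chrom_arr = np.array(chrom, dtype=object)
    pos_arr = np.array(pos, dtype=np.int64)

    if cfg.ld_block_bp:
        # block index, unique across chromosomes
        per_chrom_block = pos_arr // cfg.ld_block_bp
        chrom_num = np.array([int(c) for c in chrom_arr])
        n_block_per_chrom = cfg.chrom_length_bp // cfg.ld_block_bp + 1
        block = chrom_num * n_block_per_chrom + per_chrom_block
        _, block = np.unique(block, return_inverse=True)
    else:
        block = np.arange(S)  # every SNP its own block = free segregation
    n_blocks = int(block.max()) + 1

    p0 = rng.uniform(*cfg.founder_maf_range, size=S)

    def founder_haplotype() -> np.ndarray:
        fresh = (rng.random(S) < p0).astype(np.int8)
        if not cfg.ld_block_bp:
            return fresh
        anchor_allele = (rng.random(n_blocks) < p0[np.searchsorted(block, np.arange(n_blocks))])
        copy = rng.random(S) < cfg.ld_founder_copy_prob
        return np.where(copy, anchor_allele[block], fresh).astype(np.int8)

    def gamete(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        pick = (rng.random(n_blocks) < 0.5)[block]
        if cfg.ld_block_bp:
            pick = pick ^ (rng.random(S) < cfg.ld_switch_prob)
        return np.where(pick, h1, h2)

    hap1 = np.zeros((n, S), dtype=np.int8)
    hap2 = np.zeros((n, S), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == MISSING and d == MISSING:
            hap1[i] = founder_haplotype()
            hap2[i] = founder_haplotype()
        else:
            hap1[i] = gamete(hap1[s], hap2[s])
            hap2[i] = gamete(hap1[d], hap2[d])
    dosage = (hap1 + hap2).astype(np.int8)

    g = GenotypeMatrix(
        animal_ids=list(ped.ids),
        snp_ids=[f"snp{j:05d}" for j in range(S)],
        chrom=chrom_arr,
        pos_bp=pos_arr,
        dosage=dosage,
        counted_allele=np.array(["A"] * S, dtype=object),
        other_allele=np.array(["B"] * S, dtype=object),
    )

    gens = ped.meta["generation"].to_numpy() if ped.meta is not None else np.zeros(n, int)
    genotyped: list[str] = []
    for gval in np.unique(gens):
        members = np.nonzero(gens == gval)[0]
        k = max(1, int(round(members.size * cfg.genotyped_fraction)))
        chosen = rng.choice(members, size=k, replace=False)
        genotyped += [ped.ids[i] for i in np.sort(chosen)]
    return g, genotyped


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_phenotypes(
    ped: PedigreeTable,
    genotypes_all: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[PhenotypeTable, SimTruth]:
    """Phenotypes for all females, under the analysis model with known truth.

    Breeding value = planted-QTL part (scaled so its founder variance is
    ``qtl_variance_fraction * sigma2_a``) + pedigree polygenic part (scaled
    to the remainder).  Records carry HYS codes blocked within generation,
    the trait profile's covariates, and N(0, sigma2_e) residuals.
    """
    n = ped.n
    S = genotypes_all.n_snps
    founders = ped.is_founder()

    base = founders if cfg.qtl_scale_population == "founders" else np.ones(n, dtype=bool)

    def marker_part(idx: np.ndarray, var_target: float):
        """Scale random effects at `idx` so the base-population variance hits the target."""
        raw_eff = rng.normal(size=idx.size)
        raw = genotypes_all.dosage[:, idx].astype(float) @ raw_eff
        v0 = raw[base].var()
        scale = np.sqrt(var_target / v0) if v0 > 0 else 0.0
        return raw_eff * scale, (raw - raw[base].mean()) * scale

    # planted major QTL (large effects, separate variance share)
    poly_fraction = 1.0
    major_idx = np.zeros(0, dtype=np.int64)
    major_eff = np.zeros(0)
    major_part = np.zeros(n)
    if cfg.n_major_qtl > 0 and cfg.major_qtl_variance_fraction > 0 and cfg.sigma2_a > 0:
        major_idx = np.sort(rng.choice(S, size=min(cfg.n_major_qtl, S), replace=False))
        major_eff, major_part = marker_part(
            major_idx, cfg.major_qtl_variance_fraction * cfg.sigma2_a
        )
        poly_fraction -= cfg.major_qtl_variance_fraction

    # background QTL (marker-based polygenic share)
    q = min(cfg.n_qtl, S - major_idx.size)
    if q > 0 and cfg.qtl_variance_fraction > 0 and cfg.sigma2_a > 0:
        pool = np.setdiff1d(np.arange(S), major_idx)
        qtl_idx = np.sort(rng.choice(pool, size=q, replace=False))
        qtl_eff, qtl_part = marker_part(qtl_idx, cfg.qtl_variance_fraction * cfg.sigma2_a)
        poly_fraction -= cfg.qtl_variance_fraction
    else:
        qtl_idx = np.zeros(0, dtype=np.int64)
        qtl_eff = np.zeros(0)
        qtl_part = np.zeros(n)

    # residual polygenic part by Mendelian-sampling recursion
    s2_poly = max(poly_fraction, 0.0) * cfg.sigma2_a
    poly = np.zeros(n)
    F = ped.inbreeding if ped.inbreeding is not None else np.zeros(n)
    draws = rng.normal(size=n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == MISSING and d == MISSING:
            poly[i] = draws[i] * np.sqrt(s2_poly)
        else:
            pa = 0.0
            fs = fd = 0.0
            k = 0
            if s != MISSING:
                pa += poly[s]
                fs = F[s]
                k += 1
            if d != MISSING:
                pa += poly[d]
                fd = F[d]
                k += 1
            pa *= 0.5
            msv = (1.0 - 0.25 * k) - 0.25 * (fs + fd)  # 0.5/0.75/1 minus inbreeding term
            poly[i] = pa + draws[i] * np.sqrt(max(msv, 0.0) * s2_poly)
    tbv = major_part + qtl_part + poly

    # phenotyped animals: all females
    sexes = ped.meta["sex"].to_numpy() if ped.meta is not None else np.array(["F"] * n)
    gens = ped.meta["generation"].to_numpy() if ped.meta is not None else np.zeros(n, int)
    pheno_idx = np.arange(n) if cfg.phenotype_all else np.nonzero(sexes == "F")[0]
    n_rec = pheno_idx.size

    # HYS classes blocked within generation (contemporary groups)
    n_cls = min(cfg.n_hys_classes, n_rec)
    gen_vals = np.unique(gens[pheno_idx])
    cls_per_gen = np.full(len(gen_vals), n_cls // len(gen_vals))
    cls_per_gen[: n_cls % len(gen_vals)] += 1
    hys_code = np.zeros(n_rec, dtype=np.int64)
    offset = 0
    for gi, gval in enumerate(gen_vals):
        mask = np.nonzero(gens[pheno_idx] == gval)[0]
        k = max(1, int(cls_per_gen[gi]))
        hys_code[mask] = offset + (np.arange(mask.size) * k) // max(mask.size, 1)
        offset += k
    n_cls_actual = int(hys_code.max()) + 1
    hys_eff = rng.normal(scale=np.sqrt(cfg.sigma2_hys), size=n_cls_actual)

    profile = TRAIT_PROFILES[cfg.trait_profile]
    mu = profile["mean"]
    coeffs = dict(profile["covariates"])
    df = pd.DataFrame({"animal": [ped.ids[i] for i in pheno_idx]})
    df["hys"] = hys_code
    fixed_part = np.zeros(n_rec)
    if "F" in coeffs:
        df["F"] = F[pheno_idx]
        fixed_part += coeffs["F"] * df["F"].to_numpy()
    if "age_last_calving" in coeffs:
        df["age_last_calving"] = rng.normal(100.0, 15.0, size=n_rec).round(1)
        fixed_part += coeffs["age_last_calving"] * df["age_last_calving"].to_numpy()
    if profile["afc_class"]:
        afc_months = rng.normal(35.0, 5.0, size=n_rec)
        df["afc_class"] = afc_class_from_months(afc_months)
        class_eff = {1: 0.0, 2: 0.6, 3: 1.2}
        coeffs["afc_class"] = class_eff
        fixed_part += np.array([class_eff[c] for c in df["afc_class"]])

    resid = rng.normal(scale=np.sqrt(cfg.sigma2_e), size=n_rec)
    df["value"] = mu + fixed_part + tbv[pheno_idx] + hys_eff[hys_code] + resid

    denom = cfg.sigma2_a + cfg.sigma2_hys + cfg.sigma2_e
    truth = SimTruth(
        tbv=tbv,
        qtl_snp_indices=qtl_idx,
        qtl_effects=qtl_eff,
        major_qtl_indices=major_idx,
        major_qtl_effects=major_eff,
        hys_effects=hys_eff,
        fixed_coefficients=coeffs,
        mu=mu,
        h2_target=cfg.sigma2_a / denom if denom > 0 else 0.0,
    )
    return PhenotypeTable(data=df, trait=cfg.trait_profile), truth


# ---------------------------------------------------------------------------
# Orchestration and fixtures


def simulate_herd(cfg: SimConfig) -> SimData:
    """Full generator run: pedigree, genotypes, phenotypes, truth."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    genotypes_all, genotyped_ids = simulate_genotypes(ped, cfg, rng)
    phenotypes, truth = simulate_phenotypes(ped, genotypes_all, cfg, rng)
    return SimData(
        config=cfg,
        ped=ped,
        genotypes_all=genotypes_all,
        genotyped_ids=genotyped_ids,
        phenotypes=phenotypes,
        truth=truth,
    )


def write_fixtures(sim: SimData, out_dir) -> dict[str, Path]:
    """Write pedigree CSV, PLINK .ped/.map, phenotype CSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.csv",
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
        "config": out / "sim_config.json",
    }
    frame = sim.ped.to_frame()
    if sim.ped.meta is not None:
        frame = pd.concat([frame.reset_index(drop=True),
                           sim.ped.meta.reset_index(drop=True)], axis=1)
    frame.to_csv(paths["pedigree"], index=False)
    write_plink_text(sim.genotypes, paths["ped"], paths["map"])
    sim.phenotypes.to_csv(paths["phenotypes"])
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth.to_json(), fh)
    with open(paths["config"], "w") as fh:
        json.dump(sim.config.to_dict(), fh, indent=1)
    return paths
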