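"""Frozen study designs for parameter-recovery and scan-calibration runs.

These configurations define the synthetic herds used to check that the
pipeline recovers what it should: REML heritability under the four fertility
variance regimes, detection of a planted 8%-variance QTL, and the absence of
systematic window signal under a purely polygenic null.  They are fixed
study conditions, shared between the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .mixed_model import SingleStepModel, TraitModelSpec, VarianceComponents, fit_ssgreml
from .simulate import SimConfig, simulate_herd
from .wssgwas import run_wssgblup, scan_windows

# variance regimes per fertility trait: (sigma2_a, sigma2_hys, sigma2_e)
TRAIT_REGIMES = {
    "AFC": (6.29, 15.90, 21.01),
    "IC12": (3.65, 2.49, 8.90),
    "ACI": (2.91, 1.45, 6.26),
    "RE": (53.38, 73.79, 133.94),
}


def recovery_config(trait: str, seed: int) -> SimConfig:
    """Heritability-recovery herd: ~3,000 animals over 5 generations, ~800
    genotyped on a 1,200-SNP map, 300 HYS classes, fully marker-based
    additive architecture (the generative model the H matrix assumes)."""
    s2a, s2h, s2e = TRAIT_REGIMES[trait]
    return SimConfig(
        n_founders=500,
        n_generations=5,
        n_snps=1200,
        n_chromosomes=5,
        n_hys_classes=300,
        genotyped_fraction=0.27,
        phenotype_all=True,
        n_qtl=1200,
        qtl_variance_fraction=1.0,
        trait_profile=trait,
        sigma2_a=s2a,
        sigma2_hys=s2h,
        sigma2_e=s2e,
        seed=seed,
    )


def recovery_replicate(trait: str, seed: int, tol: float = 1e-6) -> float:
    """One replicate: simulate, run single-step AI-REML, return estimated h2."""
    sim = simulate_herd(recovery_config(trait, seed))
    vc, _ = fit_ssgreml(
        TraitModelSpec.for_trait(trait), sim.phenotypes, sim.ped, sim.genotypes,
        tol=tol,
    )
    return vc.h2


def power_config(seed: int) -> SimConfig:
    """Planted-QTL detection herd: 3,000 animals, all genotyped and
    recorded, one major QTL at 8% of additive variance over a marker-based
    polygenic background, ACI variance regime."""
    s2a, s2h, s2e = TRAIT_REGIMES["ACI"]
    return SimConfig(
        n_founders=200,
        n_generations=3,
        offspring_per_dam=4.0,
        n_snps=1000,
        n_chromosomes=10,
        chrom_length_bp=25_000_000,
        n_hys_classes=30,
        n_qtl=1000,
        qtl_variance_fraction=0.92,
        n_major_qtl=1,
        major_qtl_variance_fraction=0.08,
        genotyped_fraction=1.0,
        phenotype_all=True,
        trait_profile="ACI",
        sigma2_a=s2a,
        sigma2_hys=s2h,
        sigma2_e=s2e,
        qtl_scale_population="all",
        seed=seed,
    )


def power_replicate(seed: int, n_iterations: int = 2) -> bool:
    """True when the planted QTL's window tops the selected-window list."""
    cfg = power_config(seed)
    sim = simulate_herd(cfg)
    vc = VarianceComponents(cfg.sigma2_a, cfg.sigma2_hys, cfg.sigma2_e)
    spec = TraitModelSpec.for_trait("ACI")
    model = SingleStepModel(spec, sim.phenotypes, sim.ped, sim.genotypes)
    hist = run_wssgblup(
        spec, sim.phenotypes, sim.ped, sim.genotypes,
        n_iterations=n_iterations, vc=vc, model=model,
    )
    qi = sim.truth.major_qtl_indices[0]
    _, selected = scan_windows(
        model.Z_centered, hist[-1].effects, sim.genotypes, vc.sigma2_a
    )
    if not selected:
        return False
    top = selected[0]
    return bool(top.snp_start <= qi < top.snp_stop)


def null_config(seed: int) -> SimConfig:
    """Purely polygenic null herd: ~500 animals, 1,000 SNPs, no planted QTL."""
    s2a, s2h, s2e = TRAIT_REGIMES["ACI"]
    return SimConfig(
        n_founders=125,
        n_generations=3,
        n_snps=1000,
        n_chromosomes=5,
        chrom_length_bp=25_000_000,
        n_hys_classes=20,
        n_qtl=0,
        qtl_variance_fraction=0.0,
        genotyped_fraction=1.0,
        phenotype_all=True,
        trait_profile="ACI",
        sigma2_a=s2a,
        sigma2_hys=s2h,
        sigma2_e=s2e,
        seed=seed,
    )


def null_replicate(seed: int, n_iterations: int = 2):
    """Return (top-window chromosome, effective SNP count of final weights)."""
    cfg = null_config(seed)
    sim = simulate_herd(cfg)
    vc = VarianceComponents(cfg.sigma2_a, cfg.sigma2_hys, cfg.sigma2_e)
    spec = TraitModelSpec.for_trait("ACI")
    model = SingleStepModel(spec, sim.phenotypes, sim.ped, sim.genotypes)
    hist = run_wssgblup(
        spec, sim.phenotypes, sim.ped, sim.genotypes,
        n_iterations=n_iterations, vc=vc, model=model,
    )
    results, _ = scan_windows(
        model.Z_centered, hist[-1].effects, sim.genotypes, vc.sigma2_a
    )
    top = max(results, key=lambda r: r.pct_variance)
    d = hist[-1].weights.d
    n_eff = float(d.sum() ** 2 / (d**2).sum())
    return top.chrom, n_eff


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
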