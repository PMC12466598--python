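"""Weighted single-step GWAS: back-solved SNP effects and the window scan.

Plants one QTL carrying 10% of the additive variance, runs two weighting
iterations, scans 1-Mb sliding windows, and checks that the top selected
window contains the QTL.
"""

import numpy as np

from wssgblup import SimConfig, TraitModelSpec, VarianceComponents, simulate_herd
from wssgblup.mixed_model import SingleStepModel
from wssgblup.wssgwas import run_wssgblup, scan_windows, windows_to_frame

cfg = SimConfig(
    n_founders=150, n_generations=3, offspring_per_dam=4.0,
    n_snps=600, n_chromosomes=6, chrom_length_bp=20_000_000,
    n_hys_classes=25, genotyped_fraction=1.0, phenotype_all=True,
    n_qtl=600, qtl_variance_fraction=0.9,
    n_major_qtl=1, major_qtl_variance_fraction=0.1,
    qtl_scale_population="all",
    sigma2_a=2.91, sigma2_hys=1.45, sigma2_e=6.26, trait_profile="ACI",
    seed=5,
)
sim = simulate_herd(cfg)
vc = VarianceComponents(cfg.sigma2_a, cfg.sigma2_hys, cfg.sigma2_e)
spec = TraitModelSpec.for_trait("ACI")

model = SingleStepModel(spec, sim.phenotypes, sim.ped, sim.genotypes)
history = run_wssgblup(spec, sim.phenotypes, sim.ped, sim.genotypes,
                       n_iterations=2, vc=vc, model=model)
for h in history:
    print(f"iteration {h.iteration}: max SNP weight {h.weights.d.max():.1f}")

results, selected = scan_windows(model.Z_centered, history[-1].effects,
                                 sim.genotypes, vc.sigma2_a)
print(f"\n{len(selected)} windows above 1% of additive variance; top 5:")
print(windows_to_frame(selected).head(5).to_string(index=False))

qtl = sim.truth.major_qtl_indices[0]
top = selected[0]
print(f"\nplanted QTL at SNP {qtl} "
      f"({'inside' if top.snp_start <= qtl < top.snp_stop else 'outside'} the top window)")

# Iteration 1 is plain single-step GBLUP; the second iteration reweights
# SNPs by their estimated variance 2*a^2*p(1-p), which sharpens the QTL
# window's share well above the polygenic background.
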