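# wssgblup

Weighted single-step GBLUP and window-based GWAS for pedigreed populations
with a genotyped subset — the evaluation machinery used for low-heritability
traits such as beef-cattle female fertility (age at first calving, calving
intervals, reproductive efficiency), where phenotypes are plentiful but only
a minority of animals carry SNP genotypes.

## The model

The univariate animal model is

    y = mu + X b + Z a + W c + e

with fixed covariates/factors `b` (inbreeding, age at last calving,
age-at-first-calving class, depending on the trait), additive genetic
effects `a ~ N(0, H sigma2_a)`, a herd-year-season contemporary-group effect
`c ~ N(0, I sigma2_hys)`, and residuals `e ~ N(0, I sigma2_e)`.
Heritability is `h2 = sigma2_a / (sigma2_a + sigma2_hys + sigma2_e)`.

`H` blends the pedigree numerator relationship matrix `A` with the VanRaden
genomic matrix `G = ZZ' / sum_i 2 p_i (1 - p_i)` (Z: centred dosages).  Only
its inverse is ever formed:

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

Variance components come from EM/AI-REML on Henderson's mixed-model
equations.  SNP effects are back-solved from the genotyped animals' GEBVs,

    a_hat = D Z' (Z D Z')^-1 u_g,      sigma2_u,i = 2 a_hat_i^2 p_i (1 - p_i),

and the per-SNP variances become the diagonal weights `D` of the next
iteration's weighted genomic matrix `G* = Z D Z' / sum 2p(1-p)`.  The GWAS
scan slides a 1-Mb window one SNP at a time and reports the variance (across
genotyped animals) of each window's summed genetic value as a percentage of
the additive variance; windows above 1% are selected.

A synthetic herd generator (multi-generation pedigree, gene-dropped
genotypes, optional linkage blocks, planted QTL, HYS structure) makes the
whole pipeline testable end to end with no external data.

## Worked example

```python
import wssgblup as w

# a small herd: 3 generations, half genotyped, one strong QTL
cfg = w.SimConfig(n_founders=100, n_generations=3, offspring_per_dam=4.0,
                  n_snps=500, n_chromosomes=5, n_hys_classes=20,
                  n_qtl=500, qtl_variance_fraction=0.9,
                  n_major_qtl=1, major_qtl_variance_fraction=0.1,
                  genotyped_fraction=1.0, phenotype_all=True,
                  trait_profile="ACI", sigma2_a=2.91, sigma2_hys=1.45,
                  sigma2_e=6.26, qtl_scale_population="all", seed=7)
sim = w.simulate_herd(cfg)

spec = w.TraitModelSpec.for_trait("ACI")
vc, sol = w.fit_ssgreml(spec, sim.phenotypes, sim.ped, sim.genotypes)
print(f"h2 = {vc.h2:.3f}")

hist = w.run_wssgblup(spec, sim.phenotypes, sim.ped, sim.genotypes,
                      n_iterations=2, vc=vc)
from wssgblup.wssgwas import scan_windows
from wssgblup.mixed_model import SingleStepModel
m = SingleStepModel(spec, sim.phenotypes, sim.ped, sim.genotypes)
results, selected = scan_windows(m.Z_centered, hist[-1].effects,
                                 sim.genotypes, vc.sigma2_a)
top = selected[0]
qtl = sim.truth.major_qtl_indices[0]
print(f"top window chr{top.chrom}:{top.start_bp}-{top.end_bp} "
      f"explains {top.pct_variance:.2f}% (QTL inside: "
      f"{top.snp_start <= qtl < top.snp_stop})")
```

Output:

```
h2 = 0.293
top window chr4:2918989-3918989 explains 8.12% (QTL inside: True)
```

`h2` is the REML heritability estimate (simulated value 0.274 here); the
last line reports the 1-Mb window explaining the largest share of additive
genetic variance after one weighting iteration — it contains the planted
QTL, whose simulated share was 10%.

More narrative scripts live in `examples/`:

* `01_simulate_herd.py` — generate a herd and write pedigree/PLINK/phenotype files
* `02_qc_and_grm.py` — marker QC and genomic/pedigree relationship matrices
* `03_ssgreml_heritability.py` — variance components and GEBVs by single-step REML
* `04_wssgwas_scan.py` — weighted iterations and the 1-Mb window scan
* `05_full_pipeline.py` — the YAML-configured end-to-end pipeline

There is also a CLI: `wssgwas run --config cfg.yaml` (subcommands
`simulate`, `qc`, `reml`, `scan`, `annotate`).

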