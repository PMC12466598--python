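# Methods

This note documents the statistical machinery, the numerical choices, what
the synthetic herds do and do not emulate, and the designs used by the test
suite and the reproduction script.

## Model and estimation

The trait model is a univariate animal model
`y = mu + Xb + Za + Wc + e` with three variance components: additive
genetic `sigma2_a` (relationship `A`, `G` or the combined `H`),
herd-year-season `sigma2_hys` (identity covariance across HYS classes), and
residual `sigma2_e`.  Heritability is defined against the sum of all three.
Trait profiles fix the fixed-effect structure: age at first calving (AFC)
keeps only the overall mean; the interval traits (IC12, ACI) add the
inbreeding covariate and a 3-level AFC class (<30, [30,36), >=36 months);
reproductive efficiency (RE) further adds age at last calving.  Fixed
factors are dummy-coded with the first level dropped.

### Pedigree machinery

* Inbreeding: Meuwissen–Luo ancestor-tracing recursion, O(depth) per
  animal.  An animal may have a single known parent; the Mendelian-sampling
  variance is then `0.75 − 0.25 F_known` (`0.5 − 0.25(F_s+F_d)` with both,
  1 with none).
* `A^-1`: Henderson's rules with those `d_i`; stored sparse.
* `A22` (genotyped block): never forms dense `A`; one sparse LU of `A^-1`,
  then one solve per genotyped animal.
* A dense tabular-`A` oracle exists for pedigrees up to 2,000 animals and
  is used only for testing (`A · A^-1 = I`, `diag(A) − 1 = F`).

### Genomic machinery

* Dosages count the per-SNP "counted allele" (first allele observed in the
  PLINK text file — deterministic given the file).  QC order: keep
  autosomes (1–29), drop individuals with call rate < 0.90, drop SNPs with
  MAF < 0.01 recomputed after the individual drop.
* Centring and the `G` divisor use the observed counted-allele frequency,
  not folded MAF — folding would flip centring signs SNP by SNP.  A
  `fold_maf` switch exists for sensitivity analysis.  Missing dosages are
  mean-imputed (centred value 0).
* `G` is blended with `A22` as `(1−alpha)G + alpha A22`, `alpha = 0.05` by
  default, purely for invertibility; `alpha = 0` disables it.  No scale
  tuning of `G` to `A22` is applied by default; `tune_G_to_A22` (matching
  the mean diagonal and mean off-diagonal) is available by flag.
* `H^-1` adds the dense `G^-1 − A22^-1` correction onto the genotyped
  rows/columns of sparse `A^-1`.  Inverses use Cholesky + `dpotri`.

### REML

EM updates with average-information acceleration:

* per iterate, the mixed-model coefficient matrix (lambda form) is built
  densely, Cholesky-factorised, and inverted with `dpotri`; EM updates use
  `u'K^-1 u + sigma2_e tr(K^-1 C^uu)` (and analogues), the residual update
  uses `(y'y − sol'rhs)/(n − rank X)`;
* exact first derivatives come from the trace identities on the same
  quantities, and the AI matrix from three extra solves with the existing
  factorisation; the Newton step is taken unless it explodes (>100× total
  variance) — proposals below zero are clamped to a floor of `1e-6` of the
  total variance;
* a component resting on that floor leaves the AI parameter set (its
  variance ratio would poison the AI matrix) and re-enters as soon as its
  score turns positive;
* convergence: maximum absolute component change relative to the *total*
  variance < `1e-8` (default), so boundary components converge too.
  Standard errors are read from the inverse AI matrix at the optimum.

Dense algebra bounds the practical problem size at a few thousand pedigree
animals — the scale this package targets.  The MME solver itself offers
sparse LU, dense Cholesky (chosen automatically once the genotyped block
dominates) and Jacobi-preconditioned CG.

### Weighted iterations and the window scan

Iteration 1 is plain single-step GBLUP/REML (`D = I`).  Variance components
are estimated once and held fixed in later iterations — re-weighting
re-estimates GEBVs and SNP effects, not components.  Weights are
`d_i ∝ 2 a_hat_i^2 p_i(1−p_i)`, normalised to mean 1 each iteration (an
optional ceiling guards against weight collapse; a warning fires when the
effective number of weighted SNPs drops below 5).  The default is 2
iterations: this weighting scheme is known to overfit beyond 2–3.

Windows slide one SNP at a time; a window is the run of consecutive SNPs on
one chromosome within < 1 Mb of its left anchor, reported as
`[anchor, anchor + 1 Mb)`.  The window percentage is the population
variance (denominator `n`, for determinism; `n−1` by flag) of
`sum_j Z_ij a_hat_j` over genotyped animals, divided by the REML
`sigma2_a` — so percentages need not sum to 100 (a `Var(Z a_hat)`
denominator is available by flag).  Selection is strictly `> 1%`.
Only genotyped animals enter the back-solve and the scan.

## The synthetic herd generator

The generator emulates the data structure the analysis assumes: a
multi-generation herd with half-sib families (sires reused across dams),
gene-dropped SNP genotypes, a large categorical HYS effect blocked within
generation, trait-profile covariates, and additive values with known truth.
Defaults give ~1,500 animals, 800 SNPs on 5 chromosomes (~16 SNPs/Mb), 160
HYS classes, 27% genotyped.

Additive architecture: a configurable mix of (i) "major" QTL with their own
variance share, (ii) a marker-based background (`n_qtl` SNPs with random
effects), and (iii) a pedigree polygenic remainder via the
Mendelian-sampling recursion.  Marker parts are rescaled so their empirical
variance in the base population (founders by default, the whole herd with
`qtl_scale_population="all"`) hits the configured share.

Loci segregate freely by default — there is no linkage map beyond physical
positions.  An optional blocked-LD mode draws the parental-haplotype choice
once per physical block (with a small per-locus crossover probability) and
correlates founder alleles within a block, giving tagging SNPs around a
causal locus.  Real genomes differ in ways the generator does not attempt:
no mutation, no selection, no realistic allele-frequency spectrum or LD
decay, records pre-cleaned (no culling or missingness process).  Passing
tests therefore demonstrate correctness of the estimation machinery under
its own assumptions, not robustness to real-data pathologies.

Sex alternates within each cohort; phenotypes go to all females by default,
or to every animal with `phenotype_all=True` (used in calibration runs,
where doubling the record count matters more than the cosmetic sex label).
All randomness flows from one integer seed; fixture files are byte-stable
under a fixed seed.

## Calibration designs (`wssgblup.calibration`)

* **Heritability recovery** — four variance regimes
  (6.29/15.90/21.01, 3.65/2.49/8.90, 2.91/1.45/6.26, 53.38/73.79/133.94;
  simulated h2 0.146/0.243/0.274/0.204): 500 founders × 5 generations
  (3,000 animals, all recorded), 1,200 SNPs, 300 HYS classes, 27%
  genotyped (~810), fully marker-based additive architecture.  The marker-based
  architecture is the generative model the `H` matrix assumes; simulating
  the polygenic part from the pedigree instead makes `G` a noisy proxy of
  the true covariance and visibly attenuates `sigma2_a` under `H` (and
  inflates it under `A`) — both architectures are available, but recovery
  is calibrated under the matched one.  Ten replicates per regime; the
  mean estimated h2 is compared at ±0.03.
* **Planted-QTL power** — 200 founders × 3 generations (3,000 animals, all
  genotyped and recorded), 1,000 SNPs on 10 × 25 Mb chromosomes, one major
  QTL at 8% of additive variance over a marker background, ACI regime,
  components fixed at truth, 2 weighting iterations; the QTL window should
  top the selected list in ≥ 90% of 20 replicates.  Power is strongly
  size-dependent (≈80% at 1,500–2,250 animals); this herd size is the
  smallest that cleared the bar in design pilots.
* **Null calibration** — same scan on a purely polygenic ~500-animal herd:
  the top window's chromosome should be uniform (chi-square p > 0.01) and
  SNP weights tame (max < 10 in ≥ 90% of replicates).

Problem sizes are the package's chosen desk scale: large enough for
acceptably small Monte-Carlo error (recovery SD per replicate ≈ 0.02–0.04
on the h2 scale, so the 10-replicate mean carries a standard error near
0.01), small enough to run on a single CPU in minutes.

## Known limitations

* Dense REML internals cap the pedigree at a few thousand animals; a
  sparse-trace (Takahashi/selected-inverse) implementation would be needed
  for herdbook scale.
* Single-trait models only; no dominance, repeatability or random
  regression.
* The QC stage implements the standard marker filters only — no
  array-hardware metrics, no imputation beyond mean fill, no LD pruning.
* Gene annotation is a generic window–BED interval overlap; no external
  genome resources are consulted.
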