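"""Weighted single-step GWAS: SNP back-solving, weighting, window scan.

From the GEBVs of the genotyped animals, allele-substitution effects are
back-solved as

    a_hat = D Z' (Z D Z')^-1 u_g

with Z the centred dosages and D the diagonal SNP-weight matrix (identity
in the first iteration).  Each SNP's variance contribution
2 a_hat_i^2 p_i (1 - p_i) becomes its weight in the next iteration's
weighted genomic matrix G* = Z D Z' / sum 2p(1-p).  The association scan
slides a 1-Mb window one SNP at a time and reports, per window, the
variance across genotyped animals of the window's summed genetic value as
a percentage of the total additive genetic variance; windows above 1% are
selected.  Only genotyped animals enter the back-solve and the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .genomics import AlleleFrequencies, GenotypeMatrix, SnpWeights
from .mixed_model import (
    MMESolution,
    PhenotypeTable,
    SingleStepModel,
    TraitModelSpec,
    VarianceComponents,
)
from .pedigree import PedigreeTable

logger = logging.getLogger(__name__)

WINDOW_BP = 1_000_000
SELECT_THRESHOLD_PCT = 1.0


class GwasError(ValueError):
    pass


@dataclass
class SnpEffects:
    a_hat: np.ndarray
    var_u: np.ndarray | None = None
    iteration: int = 1


@dataclass
class WindowResult:
    chrom: str
    start_bp: int
    end_bp: int          # exclusive
    snp_start: int       # index into the post-QC map
    snp_stop: int        # exclusive
    pct_variance: float

    @property
    def n_snps(self) -> int:
        return self.snp_stop - self.snp_start


# ---------------------------------------------------------------------------
# Back-solving and weights


def backsolve_snp_effects(
    Z: np.ndarray,
    weights: SnpWeights | None,
    u_g: np.ndarray,
    ZDZt: np.ndarray | None = None,
    iteration: int = 1,
) -> SnpEffects:
    """Back-solve SNP effects from genotyped-animal GEBVs.

    ``ZDZt`` may be supplied as the blended G* times sum 2p(1-p) to keep
    the system invertible; otherwise it is formed directly from Z and D and
    must be non-singular.
    """
    if Z.shape[0] != len(u_g):
        raise GwasError("rows of Z must align with u_g")
    d = weights.d if weights is not None else np.ones(Z.shape[1])
    if ZDZt is None:
        ZDZt = (Z * d) @ Z.T
    try:
        cf = sla.cho_factor(ZDZt, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        raise GwasError(
            "Z D Z' is singular; pass a blended-G-scaled ZDZt (see blend_G)"
        ) from None
    t = sla.cho_solve(cf, u_g, check_finite=False)
    a_hat = d * (Z.T @ t)
    return SnpEffects(a_hat=a_hat, iteration=iteration)


def snp_variances(effects: SnpEffects, f: AlleleFrequencies) -> SnpEffects:
    """Per-SNP variance of effect: 2 a_hat^2 p (1-p)."""
    effects.var_u = 2.0 * effects.a_hat**2 * f.p * (1.0 - f.p)
    return effects


def update_weights(effects: SnpEffects, ceiling: float | None = None) -> SnpWeights:
    """SNP weights proportional to effect variances, normalized to mean 1."""
    if effects.var_u is None:
        raise GwasError("call snp_variances before update_weights")
    d = effects.var_u.astype(float).copy()
    if d.mean() <= 0:
        return SnpWeights(d=np.ones_like(d), iteration=effects.iteration)
    d /= d.mean()
    if ceiling is not None:
        for _ in range(20):  # cap and renormalize until stable
            d = np.minimum(d, ceiling)
            d /= d.mean()
            if d.max() <= ceiling * (1 + 1e-9):
                break
    return SnpWeights(d=d, iteration=effects.iteration)


# ---------------------------------------------------------------------------
# Windows


def define_windows(
    chrom: np.ndarray, pos_bp: np.ndarray, span_bp: int = WINDOW_BP
) -> list[tuple[int, int]]:
    """Sliding windows: one per left-anchor SNP, spanning < span_bp.

    Returns ``(start, stop)`` index pairs (stop exclusive) of consecutive
    SNPs on the same chromosome with pos - pos_anchor < span_bp.  Requires
    the map sorted by (chromosome, position).
    """
    windows: list[tuple[int, int]] = []
    n = len(pos_bp)
    start_of_chrom = 0
    for j in range(n):
        if j and chrom[j] != chrom[j - 1]:
            start_of_chrom = j
        # bound of this chromosome
        stop_of_chrom = start_of_chrom
        while stop_of_chrom < n and chrom[stop_of_chrom] == chrom[j]:
            stop_of_chrom += 1
        stop = j + int(np.searchsorted(pos_bp[j:stop_of_chrom], pos_bp[j] + span_bp, side="left"))
        windows.append((j, stop))
    return windows


def window_variance(
    Z: np.ndarray,
    effects: SnpEffects,
    windows: list[tuple[int, int]],
    sigma2_a: float,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    span_bp: int = WINDOW_BP,
    ddof: int = 0,
) -> list[WindowResult]:
    """Percentage of additive variance per window.

    For window w, the genetic value of animal i is
    g_i = sum_{j in w} Z_ij a_hat_j; the window explains
    var(g) / sigma2_a * 100 percent of the additive variance (population
    variance, denominator n, by default).
    """
    if sigma2_a <= 0:
        raise GwasError("sigma2_a must be positive")
    # cumulative Z a per SNP prefix lets each window variance come from a
    # prefix difference: g_w = cum[:, stop] - cum[:, start]
    contrib = Z * effects.a_hat
    cum = np.concatenate(
        [np.zeros((Z.shape[0], 1)), np.cumsum(contrib, axis=1)], axis=1
    )
    out = []
    for start, stop in windows:
        g = cum[:, stop] - cum[:, start]
        v = float(np.var(g, ddof=ddof))
        out.append(
            WindowResult(
                chrom=str(chrom[start]),
                start_bp=int(pos_bp[start]),
                end_bp=int(pos_bp[start]) + span_bp,
                snp_start=start,
                snp_stop=stop,
                pct_variance=v / sigma2_a * 100.0,
            )
        )
    return out


def select_windows(
    results: list[WindowResult],
    threshold_pct: float = SELECT_THRESHOLD_PCT,
    merge: bool = False,
) -> list[WindowResult]:
    """Windows strictly above the threshold, sorted by percentage descending."""
    kept = [w for w in results if w.pct_variance > threshold_pct]
    kept.sort(key=lambda w: (-w.pct_variance, w.chrom, w.start_bp))
    if merge:
        kept = _merge_windows(kept)
    return kept


def _merge_windows(selected: list[WindowResult]) -> list[WindowResult]:
    by_pos = sorted(selected, key=lambda w: (w.chrom, w.start_bp))
    merged: list[WindowResult] = []
    for w in by_pos:
        if merged and merged[-1].chrom == w.chrom and w.start_bp < merged[-1].end_bp:
            prev = merged[-1]
            merged[-1] = WindowResult(
                chrom=prev.chrom,
                start_bp=prev.start_bp,
                end_bp=max(prev.end_bp, w.end_bp),
                snp_start=prev.snp_start,
                snp_stop=max(prev.snp_stop, w.snp_stop),
                pct_variance=max(prev.pct_variance, w.pct_variance),
            )
        else:
            merged.append(w)
    merged.sort(key=lambda w: -w.pct_variance)
    return merged


def windows_to_frame(results: list[WindowResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in results],
            "start_bp": [w.start_bp for w in results],
            "end_bp": [w.end_bp for w in results],
            "n_snps": [w.n_snps for w in results],
            "pct_variance": [w.pct_variance for w in results],
        }
    )
    df["rank"] = df["pct_variance"].rank(ascending=False, method="first").astype(int)
    return df


def annotate_windows(
    selected: list[WindowResult], intervals: pd.DataFrame
) -> pd.DataFrame:
    """Overlap selected windows with BED-style intervals (any overlap >= 1 bp).

    ``intervals`` needs columns chrom/start/end/name (BED half-open,
    0-based start); window coordinates are treated as half-open as well.
    """
    rows = []
    for w in selected:
        hits = intervals[
            (intervals["chrom"].astype(str) == w.chrom)
            & (intervals["start"] < w.end_bp)
            & (intervals["end"] > w.start_bp)
        ]
        for _, iv in hits.iterrows():
            rows.append(
                {
                    "chrom": w.chrom,
                    "window_start": w.start_bp,
                    "window_end": w.end_bp,
                    "pct_variance": w.pct_variance,
                    "feature": iv["name"],
                    "feature_start": iv["start"],
                    "feature_end": iv["end"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "window_start", "window_end", "pct_variance",
            "feature", "feature_start", "feature_end",
        ],
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Iterative weighted analysis


@dataclass
class WssIteration:
    iteration: int
    vc: VarianceComponents
    solution: MMESolution
    effects: SnpEffects
    weights: SnpWeights


def run_wssgblup(
    spec: TraitModelSpec,
    phenotypes: PhenotypeTable,
    ped: PedigreeTable,
    genotypes: GenotypeMatrix,
    n_iterations: int = 2,
    vc: VarianceComponents | None = None,
    vc_init: VarianceComponents | None = None,
    blend_alpha: float = 0.05,
    reml_tol: float = 1e-8,
    weight_ceiling: float | None = None,
    model: SingleStepModel | None = None,
    verbose: bool = False,
) -> list[WssIteration]:
    """Iterative weighted single-step analysis.

    Iteration 1 runs with D = I; variance components are estimated by REML
    there (unless ``vc`` fixes them) and held constant in later iterations,
    which rebuild G* from the previous weights, re-solve the equations,
    and re-back-solve SNP effects.  Returns the full trajectory.  A
    prebuilt :class:`SingleStepModel` may be passed to reuse its matrices.
    """
    if n_iterations < 1:
        raise GwasError("n_iterations must be >= 1")
    if model is None:
        model = SingleStepModel(spec, phenotypes, ped, genotypes, blend_alpha=blend_alpha)
    if model.genotypes is None or model.Z_centered is None:
        raise GwasError("run_wssgblup requires genotypes")
    weights = SnpWeights.identity(model.genotypes.n_snps)
    history: list[WssIteration] = []
    for it in range(1, n_iterations + 1):
        w_used = weights if it > 1 else None
        Gb = model.G_star(w_used)
        K = model.K_inv(G_blended=Gb)
        if it == 1 and vc is None:
            vc = model.reml(init=vc_init, tol=reml_tol, K_inv=K, verbose=verbose)
        sol = model.solve(vc, K_inv=K)
        u_g = model.gebv_genotyped(sol)
        ZDZt = Gb.dense() * model.freqs.two_pq_sum
        eff = backsolve_snp_effects(
            model.Z_centered,
            weights if it > 1 else None,
            u_g,
            ZDZt=ZDZt,
            iteration=it,
        )
        eff = snp_variances(eff, model.freqs)
        new_weights = update_weights(eff, ceiling=weight_ceiling)
        n_eff = float((new_weights.d.sum() ** 2) / max((new_weights.d**2).sum(), 1e-300))
        if n_eff < 5:
            logger.warning(
                "iteration %d: SNP weight mass concentrated on ~%.1f SNPs", it, n_eff
            )
        if verbose:
            print(
                f"wssGBLUP iteration {it}: h2={vc.h2:.4f} "
                f"max weight={new_weights.d.max():.2f} effective SNPs={n_eff:.0f}"
            )
        history.append(
            WssIteration(iteration=it, vc=vc, solution=sol, effects=eff, weights=new_weights)
        )
        weights = new_weights
    return history


def scan_windows(
    model_Z: np.ndarray,
    effects: SnpEffects,
    genotypes: GenotypeMatrix,
    sigma2_a: float,
    span_bp: int = WINDOW_BP,
    threshold_pct: float = SELECT_THRESHOLD_PCT,
) -> tuple[list[WindowResult], list[WindowResult]]:
    """Convenience: window scan + selection on a fitted iteration."""
    windows = define_windows(genotypes.chrom, genotypes.pos_bp, span_bp)
    results = window_variance(
        model_Z, effects, windows, sigma2_a, genotypes.chrom, genotypes.pos_bp, span_bp
    )
    return results, select_windows(results, threshold_pct)
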