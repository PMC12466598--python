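"""Henderson's mixed-model equations and REML for the three-component model.

The univariate animal model is

    y = mu + X b + Z a + W c + e

with a ~ N(0, K sigma2_a) for K the pedigree (A), genomic (G) or combined
single-step (H) relationship matrix, c ~ N(0, I sigma2_hys) the
herd-year-season contemporary-group effect, and e ~ N(0, I sigma2_e).
Heritability is defined on the full phenotypic variance,
h2 = sigma2_a / (sigma2_a + sigma2_hys + sigma2_e).

Variance components are estimated by REML: EM updates with
average-information (AI) acceleration, falling back to EM whenever an AI
step leaves the parameter space.  All trace terms come from the inverse of
the mixed-model coefficient matrix, which at the problem sizes this package
targets is handled densely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.sparse.linalg import splu, cg

from .pedigree import PedigreeTable, RelationshipMatrix, build_A_inverse, compute_inbreeding, extract_A22
from .genomics import (
    GenotypeMatrix,
    SnpWeights,
    allele_frequencies,
    blend_G,
    build_G,
    build_H_inverse,
    center_dosages,
    subset_animals,
    tune_G_to_A22,
)

TRAITS = ("AFC", "IC12", "ACI", "RE")

# age-at-first-calving class boundaries, months
AFC_CLASS_EDGES = (30.0, 36.0)


class ModelError(ValueError):
    pass


def afc_class_from_months(afc_months) -> np.ndarray:
    """Classify age at first calving into 3 classes: <30, [30,36), >=36."""
    a = np.asarray(afc_months, dtype=float)
    return (np.digitize(a, AFC_CLASS_EDGES) + 1).astype(np.int64)


@dataclass
class TraitModelSpec:
    """Fixed-effect profile per fertility trait.

    AFC keeps only the overall mean (no inbreeding covariate and no
    age-at-first-calving class, which would be the trait itself); the
    interval traits add the inbreeding covariate and the 3-level AFC class;
    RE additionally adjusts for age at last calving.
    """

    trait: str
    fixed_covariates: list[str] = field(default_factory=list)
    fixed_factors: list[str] = field(default_factory=list)
    include_hys: bool = True

    @classmethod
    def for_trait(cls, trait: str) -> "TraitModelSpec":
        trait = trait.upper()
        if trait == "AFC":
            return cls(trait, [], [])
        if trait in ("IC12", "ACI"):
            return cls(trait, ["F"], ["afc_class"])
        if trait == "RE":
            return cls(trait, ["F", "age_last_calving"], ["afc_class"])
        raise ModelError(f"unknown trait {trait!r}; use TraitModelSpec directly for custom models")


@dataclass
class PhenotypeTable:
    """One record per row: animal id, trait value, HYS code, covariates."""

    data: pd.DataFrame
    trait: str = "custom"

    @classmethod
    def read_csv(cls, path, trait: str = "custom") -> "PhenotypeTable":
        df = pd.read_csv(path)
        df["animal"] = df["animal"].astype(str)
        return cls(data=df, trait=trait)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def n_records(self) -> int:
        return len(self.data)


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_hys: float
    sigma2_e: float
    se: dict | None = None
    n_iter: int = 0
    converged: bool = True

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_hys + self.sigma2_e)

    def to_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_hys": self.sigma2_hys,
            "sigma2_e": self.sigma2_e,
            "h2": self.h2,
            "se": self.se,
            "n_iter": self.n_iter,
        }


@dataclass
class Designs:
    X: np.ndarray              # n_records x p
    Z: sp.csr_matrix           # n_records x n_ped
    W: sp.csr_matrix | None    # n_records x n_hys (None if no HYS term)
    y: np.ndarray
    x_names: list[str]
    hys_levels: list
    animal_codes: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_ped(self) -> int:
        return self.Z.shape[1]

    @property
    def n_hys(self) -> int:
        return 0 if self.W is None else self.W.shape[1]


@dataclass
class MMESystem:
    C: sp.csr_matrix
    rhs: np.ndarray
    p: int
    n_ped: int
    n_hys: int
    x_names: list[str]
    hys_levels: list


@dataclass
class MMESolution:
    b: pd.Series
    u: np.ndarray
    c: pd.Series
    convergence: float


# ---------------------------------------------------------------------------
# Design matrices


def build_design(
    spec: TraitModelSpec, phenotypes: PhenotypeTable, ped: PedigreeTable
) -> Designs:
    """Build X (fixed), Z (animal incidence) and W (HYS incidence).

    Fixed factors are dummy-coded with the first (sorted) level dropped;
    column order is intercept, covariates (spec order), then factor dummies.
    Raises if X is rank-deficient beyond the intercept.
    """
    df = phenotypes.data
    if "value" not in df.columns or "animal" not in df.columns:
        raise ModelError("phenotype table needs 'animal' and 'value' columns")
    y = df["value"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ModelError("missing trait values in phenotype table")
    n = len(df)

    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in spec.fixed_covariates:
        if cov not in df.columns:
            raise ModelError(f"covariate {cov!r} missing from phenotype table")
        cols.append(df[cov].to_numpy(dtype=float))
        names.append(cov)
    for fac in spec.fixed_factors:
        if fac not in df.columns:
            raise ModelError(f"factor {fac!r} missing from phenotype table")
        levels = sorted(pd.unique(df[fac]))
        for lev in levels[1:]:
            cols.append((df[fac] == lev).to_numpy(dtype=float))
            names.append(f"{fac}={lev}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = sla.qr(X, pivoting=True, mode="economic")
        aliased = [names[j] for j in piv[rank:]]
        raise ModelError(f"fixed-effect design is rank deficient; aliased columns: {aliased}")

    animal_codes = ped.codes(df["animal"].astype(str).tolist())
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), animal_codes)), shape=(n, ped.n)
    )

    W = None
    hys_levels: list = []
    if spec.include_hys:
        if "hys" not in df.columns:
            raise ModelError("phenotype table needs an 'hys' column for the HYS term")
        hys_levels = sorted(pd.unique(df["hys"]))
        level_of = {h: k for k, h in enumerate(hys_levels)}
        w_idx = np.array([level_of[h] for h in df["hys"]], dtype=np.int64)
        W = sp.csr_matrix(
            (np.ones(n), (np.arange(n), w_idx)), shape=(n, len(hys_levels))
        )
    return Designs(X=X, Z=Z, W=W, y=y, x_names=names, hys_levels=hys_levels, animal_codes=animal_codes)


# ---------------------------------------------------------------------------
# MME assembly and solving


def assemble_mme(
    designs: Designs, K_inv: RelationshipMatrix | sp.spmatrix, vc: VarianceComponents
) -> MMESystem:
    """Assemble the sparse symmetric mixed-model equations.

    C = [[X'X, X'Z, X'W], [Z'X, Z'Z + K^-1 la, Z'W], [W'X, W'Z, W'W + I lc]]
    with la = sigma2_e/sigma2_a and lc = sigma2_e/sigma2_hys.
    """
    if vc.sigma2_a <= 0 or vc.sigma2_e <= 0:
        raise ModelError("variance components must be positive")
    Kv = K_inv.values if isinstance(K_inv, RelationshipMatrix) else K_inv
    Kv = sp.csr_matrix(Kv)
    X, Z, W, y = designs.X, designs.Z, designs.W, designs.y
    la = vc.sigma2_e / vc.sigma2_a
    Xs = sp.csr_matrix(X)
    blocks = [[Xs.T @ Xs, Xs.T @ Z], [Z.T @ Xs, Z.T @ Z + la * Kv]]
    rhs = [X.T @ y, Z.T @ y]
    if W is not None:
        if vc.sigma2_hys <= 0:
            raise ModelError("sigma2_hys must be positive when the HYS term is present")
        lc = vc.sigma2_e / vc.sigma2_hys
        blocks[0].append(Xs.T @ W)
        blocks[1].append(Z.T @ W)
        blocks.append([W.T @ Xs, W.T @ Z, W.T @ W + lc * sp.identity(W.shape[1], format="csr")])
        rhs.append(W.T @ y)
    C = sp.bmat(blocks, format="csr")
    return MMESystem(
        C=C,
        rhs=np.concatenate(rhs),
        p=X.shape[1],
        n_ped=Z.shape[1],
        n_hys=0 if W is None else W.shape[1],
        x_names=list(designs.x_names),
        hys_levels=list(designs.hys_levels),
    )


def solve_mme(
    system: MMESystem,
    method: str = "direct",
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> MMESolution:
    """Solve the assembled equations directly (sparse LU) or by Jacobi-PCG."""
    C, rhs = system.C, system.rhs
    if method == "direct":
        # dense Cholesky beats sparse LU once the genotyped block dominates
        density = C.nnz / max(C.shape[0] ** 2, 1)
        if density > 0.02 and C.shape[0] <= 20_000:
            try:
                x = sla.cho_solve(
                    sla.cho_factor(C.toarray(), lower=True, check_finite=False), rhs,
                    check_finite=False,
                )
            except np.linalg.LinAlgError:
                x = splu(C.tocsc()).solve(rhs)
        else:
            x = splu(C.tocsc()).solve(rhs)
    elif method == "pcg":
        d = C.diagonal()
        M = sp.diags(1.0 / np.where(d != 0, d, 1.0))
        x, info = cg(C, rhs, M=M, rtol=tol, maxiter=max_iter)
        if info != 0:
            res = np.linalg.norm(C @ x - rhs, np.inf) / max(np.linalg.norm(rhs, np.inf), 1e-300)
            raise ModelError(f"PCG did not converge in {max_iter} iterations (residual {res:.2e})")
    else:
        raise ModelError(f"unknown solve method {method!r}")
    resid = np.linalg.norm(C @ x - rhs, np.inf) / max(np.linalg.norm(rhs, np.inf), 1e-300)
    p, q, m = system.p, system.n_ped, system.n_hys
    return MMESolution(
        b=pd.Series(x[:p], index=system.x_names),
        u=x[p : p + q],
        c=pd.Series(x[p + q : p + q + m], index=system.hys_levels),
        convergence=float(resid),
    )


# ---------------------------------------------------------------------------
# REML


class RemlError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory


def reml_estimate(
    designs: Designs,
    K_inv: RelationshipMatrix | sp.spmatrix,
    init: VarianceComponents,
    algorithm: str = "ai",
    max_iter: int = 200,
    tol: float = 1e-8,
    verbose: bool = False,
) -> VarianceComponents:
    """REML variance components by EM with optional AI acceleration.

    Each iterate assembles the mixed-model coefficient matrix at the current
    variance ratios, inverts it (dense Cholesky), and computes EM updates

        sigma2_a' = (u' K^-1 u + sigma2_e tr(K^-1 C^uu)) / n_ped
        sigma2_hys' = (c'c + sigma2_e tr(C^cc)) / n_hys
        sigma2_e' = (y'y - sol'rhs) / (n - rank X)

    with C^uu, C^cc blocks of the inverse coefficient matrix.  ``ai`` uses
    these to form exact first derivatives and takes a Newton step with the
    average-information matrix, reverting to the EM update whenever the step
    leaves the parameter space.  Convergence: max relative change < tol.
    """
    if algorithm not in ("em", "ai"):
        raise ModelError(f"unknown REML algorithm {algorithm!r}")
    Kv = K_inv.values if isinstance(K_inv, RelationshipMatrix) else K_inv
    Kv = sp.csr_matrix(Kv)
    X, Z, W, y = designs.X, designs.Z, designs.W, designs.y
    n, p = X.shape
    q = Z.shape[1]
    m = 0 if W is None else W.shape[1]
    has_hys = W is not None
    rank_x = int(np.linalg.matrix_rank(X))

    # dense cross-product base; the lambda terms are added per iteration
    Zd = Z  # keep sparse for products
    base_dim = p + q + m
    C0 = np.zeros((base_dim, base_dim))
    C0[:p, :p] = X.T @ X
    XtZ = X.T @ Zd.toarray() if q <= 4000 else (Zd.T @ sp.csr_matrix(X)).T.toarray()
    C0[:p, p : p + q] = XtZ
    C0[p : p + q, :p] = XtZ.T
    ZtZ = (Zd.T @ Zd).toarray()
    C0[p : p + q, p : p + q] = ZtZ
    if has_hys:
        XtW = X.T @ W.toarray()
        ZtW = (Zd.T @ W).toarray()
        C0[:p, p + q :] = XtW
        C0[p + q :, :p] = XtW.T
        C0[p : p + q, p + q :] = ZtW
        C0[p + q :, p : p + q] = ZtW.T
        C0[p + q :, p + q :] = (W.T @ W).toarray()
    rhs = np.concatenate(
        [X.T @ y, Zd.T @ y] + ([W.T @ y] if has_hys else [])
    )
    yty = float(y @ y)
    K_dense = Kv.toarray()

    theta = np.array(
        [init.sigma2_a, init.sigma2_hys if has_hys else 0.0, init.sigma2_e]
    )
    if theta[0] <= 0 or theta[2] <= 0 or (has_hys and theta[1] <= 0):
        raise ModelError("initial variance components must be positive")

    trajectory = []
    ai_cov = None
    for it in range(1, max_iter + 1):
        s2a, s2h, s2e = theta
        la = s2e / s2a
        C = C0.copy()
        C[p : p + q, p : p + q] += la * K_dense
        if has_hys:
            lc = s2e / s2h
            idx = np.arange(p + q, base_dim)
            C[idx, idx] += lc
        cf = sla.cho_factor(C, lower=True, check_finite=False)
        sol = sla.cho_solve(cf, rhs, check_finite=False)
        Cinv, info = sla.lapack.dpotri(cf[0], lower=1)
        if info != 0:
            raise RemlError(f"dpotri failed with info={info}", trajectory=trajectory)
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T

        u = sol[p : p + q]
        chat = sol[p + q :] if has_hys else np.zeros(0)
        uKu = float(u @ (Kv @ u))
        T_a = float(np.sum(K_dense * Cinv[p : p + q, p : p + q]))
        T_c = float(np.trace(Cinv[p + q :, p + q :])) if has_hys else 0.0

        em = np.array(
            [
                (uKu + s2e * T_a) / q,
                ((chat @ chat) + s2e * T_c) / m if has_hys else 0.0,
                (yty - sol @ rhs) / (n - rank_x),
            ]
        )
        new = em.copy()
        used = "em"
        if algorithm == "ai":
            # exact scores from the trace identities
            score = np.zeros(3)
            score[0] = -0.5 * ((q - la * T_a) / s2a - uKu / s2a**2)
            if has_hys:
                score[1] = -0.5 * ((m - lc * T_c) / s2h - (chat @ chat) / s2h**2)
            trP = (
                n - rank_x - (q - la * T_a) - ((m - lc * T_c) if has_hys else 0.0)
            ) / s2e
            e_hat = y - X @ sol[:p] - Zd @ u - (W @ chat if has_hys else 0.0)
            r = e_hat / s2e
            score[2] = -0.5 * (trP - float(r @ r))

            f_by_comp = {0: (Zd @ u) / s2a, 2: r}
            if has_hys:
                f_by_comp[1] = (W @ chat) / s2h
            # components resting on the zero boundary leave the AI update
            # (their huge variance ratios poison the AI matrix) unless the
            # score pushes them back into the interior
            floor = 1e-6 * theta.sum()
            idx_all = [0, 1, 2] if has_hys else [0, 2]
            active = [i for i in idx_all if theta[i] > 5 * floor or score[i] > 0]
            if active:
                fs = [f_by_comp[i] for i in active]
                Pf = []
                for f in fs:
                    mf = np.concatenate(
                        [X.T @ f, Zd.T @ f] + ([W.T @ f] if has_hys else [])
                    )
                    sf = sla.cho_solve(cf, mf, check_finite=False)
                    Pf.append(
                        (f - X @ sf[:p] - Zd @ sf[p : p + q]
                         - (W @ sf[p + q :] if has_hys else 0.0)) / s2e
                    )
                k = len(fs)
                AI = np.zeros((k, k))
                for i in range(k):
                    for j in range(i, k):
                        AI[i, j] = AI[j, i] = 0.5 * float(fs[i] @ Pf[j])
                try:
                    delta = np.linalg.solve(AI, score[active])
                    cand = np.maximum(theta[active] + delta, floor)
                    if np.all(np.isfinite(cand)) and np.all(cand < 100 * theta.sum()):
                        new = theta.copy()
                        new[active] = cand
                        for i in idx_all:
                            if i not in active:
                                new[i] = min(theta[i], floor)
                        used = "ai"
                        if len(active) == len(idx_all):
                            ai_cov = np.linalg.inv(AI)
                except np.linalg.LinAlgError:
                    pass

        # change relative to total variance, so a component shrinking to the
        # boundary still converges
        change = np.max(np.abs(new - theta)) / max(new.sum(), 1e-300)
        trajectory.append((it, used, tuple(theta), change))
        if verbose:
            print(f"  REML iter {it:3d} [{used}] "
                  f"s2a={new[0]:.5g} s2hys={new[1]:.5g} s2e={new[2]:.5g} change={change:.2e}")
        theta = new
        if change < tol:
            se = None
            if ai_cov is not None:
                d = np.sqrt(np.clip(np.diag(ai_cov), 0, None))
                if has_hys:
                    se = {"sigma2_a": d[0], "sigma2_hys": d[1], "sigma2_e": d[2]}
                else:
                    se = {"sigma2_a": d[0], "sigma2_e": d[1]}
            return VarianceComponents(
                sigma2_a=float(theta[0]),
                sigma2_hys=float(theta[1]),
                sigma2_e=float(theta[2]),
                se=se,
                n_iter=it,
                converged=True,
            )
    raise RemlError(
        f"REML did not converge in {max_iter} iterations "
        f"(last change {trajectory[-1][3]:.2e})",
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# Single-step orchestration


class SingleStepModel:
    """Holds the assembled single-step machinery for one trait analysis.

    Prepares the pedigree inverse, the genotyped-block matrices and the
    design matrices once; exposes REML and MME solving under arbitrary SNP
    weights so the weighted iterations reuse the same structures.
    """

    def __init__(
        self,
        spec: TraitModelSpec,
        phenotypes: PhenotypeTable,
        ped: PedigreeTable,
        genotypes: GenotypeMatrix | None = None,
        blend_alpha: float = 0.05,
        tune_G: bool = False,
        fold_maf: bool = False,
    ):
        if ped.inbreeding is None:
            compute_inbreeding(ped)
        self.spec = spec
        self.ped = ped
        self.designs = build_design(spec, phenotypes, ped)
        self.A_inv = build_A_inverse(ped)
        self.blend_alpha = blend_alpha
        self.tune_G = tune_G
        self.genotypes = genotypes
        if genotypes is not None:
            in_ped = set(ped.ids)
            self.genotyped_ids = [a for a in genotypes.animal_ids if a in in_ped]
            if len(self.genotyped_ids) < genotypes.n_animals:
                genotypes = subset_animals(genotypes, self.genotyped_ids)
                self.genotypes = genotypes
            self.genotyped_index = ped.codes(self.genotyped_ids)
            self.freqs = allele_frequencies(genotypes)
            self.Z_centered = center_dosages(genotypes, self.freqs, fold_maf=fold_maf)
            self.A22 = extract_A22(ped, self.genotyped_ids, A_inv=self.A_inv)
        else:
            self.genotyped_ids = []
            self.genotyped_index = np.zeros(0, dtype=np.int64)
            self.freqs = None
            self.Z_centered = None
            self.A22 = None

    def G_star(self, weights: SnpWeights | None = None) -> RelationshipMatrix | None:
        if self.genotypes is None:
            return None
        G = build_G(self.Z_centered, self.freqs, weights=weights)
        G.labels = list(self.genotyped_ids)
        if self.tune_G:
            G = tune_G_to_A22(G, self.A22)
        return blend_G(G, self.A22, self.blend_alpha)

    def K_inv(
        self,
        weights: SnpWeights | None = None,
        G_blended: RelationshipMatrix | None = None,
    ) -> RelationshipMatrix:
        if self.genotypes is None:
            return self.A_inv
        Gb = G_blended if G_blended is not None else self.G_star(weights)
        return build_H_inverse(self.A_inv, self.A22, Gb, self.genotyped_index)

    def reml(
        self,
        init: VarianceComponents | None = None,
        weights: SnpWeights | None = None,
        algorithm: str = "ai",
        max_iter: int = 200,
        tol: float = 1e-8,
        K_inv: RelationshipMatrix | None = None,
        verbose: bool = False,
    ) -> VarianceComponents:
        if init is None:
            vy = float(np.var(self.designs.y))
            third = vy / 3.0 if self.designs.W is not None else vy / 2.0
            init = VarianceComponents(third, third if self.designs.W is not None else 0.0, third)
        if K_inv is None:
            K_inv = self.K_inv(weights)
        return reml_estimate(
            self.designs, K_inv, init,
            algorithm=algorithm, max_iter=max_iter, tol=tol, verbose=verbose,
        )

    def solve(
        self,
        vc: VarianceComponents,
        weights: SnpWeights | None = None,
        method: str = "direct",
        K_inv: RelationshipMatrix | None = None,
    ) -> MMESolution:
        if K_inv is None:
            K_inv = self.K_inv(weights)
        system = assemble_mme(self.designs, K_inv, vc)
        return solve_mme(system, method=method)

    def gebv_genotyped(self, solution: MMESolution) -> np.ndarray:
        return solution.u[self.genotyped_index]


def fit_ssgreml(
    spec: TraitModelSpec,
    phenotypes: PhenotypeTable,
    ped: PedigreeTable,
    genotypes: GenotypeMatrix | None = None,
    vc_init: VarianceComponents | None = None,
    blend_alpha: float = 0.05,
    algorithm: str = "ai",
    tol: float = 1e-8,
    verbose: bool = False,
) -> tuple[VarianceComponents, MMESolution]:
    """Single-step GREML: REML components plus GEBVs for all pedigree animals.

    Without genotypes this reduces exactly to pedigree BLUP/REML.
    """
    model = SingleStepModel(spec, phenotypes, ped, genotypes, blend_alpha=blend_alpha)
    vc = model.reml(init=vc_init, algorithm=algorithm, tol=tol, verbose=verbose)
    sol = model.solve(vc)
    return vc, sol
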