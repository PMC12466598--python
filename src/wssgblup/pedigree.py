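"""Pedigree handling: parsing, ordering, inbreeding and relationship matrices.

The numerator relationship matrix A encodes expected additive relatedness
between animals given the pedigree; its diagonal is 1 + F where F is the
inbreeding coefficient.  Single-step evaluation needs three derived objects:

* a dense "tabular" A for small pedigrees (test oracle only),
* the sparse inverse A^-1 built directly from pedigree structure via
  Henderson's rules with Meuwissen-Luo inbreeding,
* the dense sub-block A22 for the genotyped animals, obtained without ever
  forming the full dense A.

Animals are referenced externally by string ids and internally by dense
0..n-1 integer codes assigned at parse time in topological order (every
parent precedes its offspring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

MISSING = -1

DEFAULT_ORACLE_CAP = 2000


class PedigreeError(ValueError):
    pass


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree with integer-coded parents.

    ``ids[i]`` is the external id of the animal with code ``i``; ``sire[i]``
    and ``dam[i]`` are parent codes or :data:`MISSING`.  Parents always have
    smaller codes than their offspring.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    inbreeding: np.ndarray | None = None
    meta: pd.DataFrame | None = None
    _code: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._code:
            self._code = {a: i for i, a in enumerate(self.ids)}
        if len(self._code) != len(self.ids):
            raise PedigreeError("duplicate animal ids after coding")

    @property
    def n(self) -> int:
        return len(self.ids)

    def code(self, animal_id: str) -> int:
        try:
            return self._code[animal_id]
        except KeyError:
            raise PedigreeError(f"unknown animal id: {animal_id!r}") from None

    def codes(self, animal_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.code(a) for a in animal_ids], dtype=np.int64)

    def is_founder(self) -> np.ndarray:
        return (self.sire == MISSING) & (self.dam == MISSING)

    def validate(self) -> None:
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = np.nonzero(par >= np.arange(self.n))[0]
            if bad.size:
                raise PedigreeError(
                    f"pedigree not topologically sorted: {name} of "
                    f"{self.ids[bad[0]]!r} does not precede it"
                )

    def to_frame(self) -> pd.DataFrame:
        def name(c: int) -> str:
            return "" if c == MISSING else self.ids[c]

        df = pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [name(c) for c in self.sire],
                "dam": [name(c) for c in self.dam],
            }
        )
        if self.inbreeding is not None:
            df["F"] = self.inbreeding
        return df


@dataclass
class RelationshipMatrix:
    """Labelled symmetric relationship matrix (dense or sparse)."""

    labels: list[str]
    values: np.ndarray | sp.spmatrix
    kind: str

    @property
    def n(self) -> int:
        return len(self.labels)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def to_tsv(self, path) -> None:
        if sp.issparse(self.values):
            coo = self.values.tocoo()
            pd.DataFrame(
                {"row": coo.row, "col": coo.col, "value": coo.data}
            ).to_csv(path, sep="\t", index=False)
        else:
            pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
                path, sep="\t"
            )


# ---------------------------------------------------------------------------
# Parsing and ordering


def _normalize_parent(value, missing_tokens: set[str]) -> str:
    s = "" if value is None else str(value).strip()
    if s in missing_tokens or s.lower() in {"na", "nan", "none"}:
        return ""
    return s


def read_pedigree(
    path,
    id_columns: tuple[str, str, str] = ("animal", "sire", "dam"),
    missing_tokens: Sequence[str] = ("", "0"),
) -> PedigreeTable:
    """Read a pedigree CSV and return a topologically sorted table.

    Parents referenced but never listed as animals are added as founders.
    Unknown parents (empty, ``0``, ``NA`` by default) become the missing
    sentinel.  Raises on duplicate ids or cycles.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in id_columns:
        if col not in df.columns:
            raise PedigreeError(f"pedigree file lacks column {col!r}")
    a_col, s_col, d_col = id_columns
    animals = [str(a).strip() for a in df[a_col]]
    dup = pd.Series(animals)
    if dup.duplicated().any():
        raise PedigreeError(f"duplicate animal id: {dup[dup.duplicated()].iloc[0]!r}")
    missing = set(missing_tokens)
    sires = [_normalize_parent(v, missing) for v in df[s_col]]
    dams = [_normalize_parent(v, missing) for v in df[d_col]]
    meta_cols = [c for c in df.columns if c not in id_columns]
    meta = df[meta_cols] if meta_cols else None
    return build_pedigree(animals, sires, dams, meta=meta)


def build_pedigree(
    animals: Sequence[str],
    sires: Sequence[str],
    dams: Sequence[str],
    meta: pd.DataFrame | None = None,
) -> PedigreeTable:
    """Assemble a :class:`PedigreeTable` from parallel id lists.

    Missing parents are the empty string.  Performs founder completion,
    topological sort (Kahn on parent->offspring edges) and cycle detection.
    """
    known = set(animals)
    if len(known) != len(animals):
        seen: set[str] = set()
        for a in animals:
            if a in seen:
                raise PedigreeError(f"duplicate animal id: {a!r}")
            seen.add(a)
    parent_of = {a: (s, d) for a, s, d in zip(animals, sires, dams)}
    extra = []
    for s, d in zip(sires, dams):
        for p in (s, d):
            if p and p not in known:
                known.add(p)
                extra.append(p)
                parent_of[p] = ("", "")
    all_ids = extra + list(animals)

    children: dict[str, list[str]] = {a: [] for a in all_ids}
    indeg = {a: 0 for a in all_ids}
    for a in all_ids:
        s, d = parent_of[a]
        for p in {p for p in (s, d) if p}:
            children[p].append(a)
            indeg[a] += 1
    order: list[str] = []
    queue = [a for a in all_ids if indeg[a] == 0]
    while queue:
        nxt: list[str] = []
        for a in queue:
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) != len(all_ids):
        cyc = _find_cycle(parent_of, [a for a in all_ids if indeg[a] > 0])
        raise PedigreeError(f"pedigree cycle detected: {' -> '.join(cyc)}")

    code = {a: i for i, a in enumerate(order)}
    sire_arr = np.full(len(order), MISSING, dtype=np.int64)
    dam_arr = np.full(len(order), MISSING, dtype=np.int64)
    for a in order:
        s, d = parent_of[a]
        if s:
            sire_arr[code[a]] = code[s]
        if d:
            dam_arr[code[a]] = code[d]
    if meta is not None:
        meta = meta.copy()
        meta.index = list(animals)
        meta = meta.reindex(order)
    return PedigreeTable(ids=order, sire=sire_arr, dam=dam_arr, meta=meta)


def _find_cycle(parent_of: dict[str, tuple[str, str]], candidates: list[str]) -> list[str]:
    start = candidates[0]
    seen: list[str] = []
    node = start
    while node not in seen:
        seen.append(node)
        s, d = parent_of[node]
        node = s if s in candidates or s == node else d
        if not node:  # pragma: no cover - defensive
            return seen
    return seen[seen.index(node):] + [node]


# ---------------------------------------------------------------------------
# Inbreeding (Meuwissen & Luo)


def compute_inbreeding(ped: PedigreeTable) -> PedigreeTable:
    """Fill inbreeding coefficients with the Meuwissen-Luo algorithm.

    Works animal by animal, tracing each animal's ancestor list with
    accumulated contributions L and the within-family variances d; cost is
    proportional to pedigree depth per animal.  Idempotent.
    """
    ped.validate()
    n = ped.n
    F = np.zeros(n)
    # d_i in the L'DL decomposition of A, filled lazily as F becomes known
    sire, dam = ped.sire, ped.dam

    def dval(i: int) -> float:
        s, d = sire[i], dam[i]
        fs = F[s] if s != MISSING else 0.0
        fd = F[d] if d != MISSING else 0.0
        k = int(s != MISSING) + int(d != MISSING)
        return 0.5 - 0.25 * (fs + fd) if k == 2 else (0.75 - 0.25 * (fs + fd) if k == 1 else 1.0)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s == MISSING or d == MISSING:
            F[i] = 0.0
            continue
        # accumulate L contributions over the ancestor closure of i
        L: dict[int, float] = {i: 1.0}
        aii = 0.0
        for anc in range(i, -1, -1):
            coef = L.pop(anc, 0.0)
            if coef == 0.0:
                continue
            aii += coef * coef * dval(anc)
            for p in (sire[anc], dam[anc]):
                if p != MISSING:
                    L[p] = L.get(p, 0.0) + 0.5 * coef
        F[i] = aii - 1.0
    ped.inbreeding = F
    return ped


# ---------------------------------------------------------------------------
# Relationship matrices


def build_A_tabular(ped: PedigreeTable, oracle_cap: int = DEFAULT_ORACLE_CAP) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular recursion.

    a_ij = (a_{j,s(i)} + a_{j,d(i)}) / 2 for j < i and
    a_ii = 1 + a_{s(i),d(i)} / 2.  Intended as a small-pedigree oracle.
    """
    n = ped.n
    if n > oracle_cap:
        raise PedigreeError(
            f"pedigree has {n} animals, above the dense-oracle cap {oracle_cap}; "
            "use build_A_inverse / extract_A22 instead"
        )
    ped.validate()
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if i:
            row = np.zeros(i)
            if s != MISSING:
                row += 0.5 * A[s, :i]
            if d != MISSING:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s != MISSING and d != MISSING else 0.0)
    return RelationshipMatrix(labels=list(ped.ids), values=A, kind="A")


def mendelian_variances(ped: PedigreeTable) -> np.ndarray:
    """Per-animal Mendelian-sampling variances d_i given parental inbreeding."""
    if ped.inbreeding is None:
        compute_inbreeding(ped)
    F = ped.inbreeding
    fs = np.where(ped.sire != MISSING, F[np.clip(ped.sire, 0, None)], 0.0)
    fd = np.where(ped.dam != MISSING, F[np.clip(ped.dam, 0, None)], 0.0)
    nk = (ped.sire != MISSING).astype(int) + (ped.dam != MISSING).astype(int)
    d = np.where(
        nk == 2,
        0.5 - 0.25 * (fs + fd),
        np.where(nk == 1, 0.75 - 0.25 * (fs + fd), 1.0),
    )
    return d


def build_A_inverse(ped: PedigreeTable) -> RelationshipMatrix:
    """Sparse A^-1 via Henderson's rules with inbreeding accounted for.

    For each animal i with Mendelian-sampling variance d_i, add 1/d_i on
    (i,i), -1/(2 d_i) on (i,parent), and 1/(4 d_i) on each (parent,parent)
    pair of the known parents.
    """
    ped.validate()
    d = mendelian_variances(ped)
    n = ped.n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    idx = np.arange(n)
    inv_d = 1.0 / d

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=np.float64))

    add(idx, idx, inv_d)
    for par in (ped.sire, ped.dam):
        m = par != MISSING
        add(idx[m], par[m], -0.5 * inv_d[m])
        add(par[m], idx[m], -0.5 * inv_d[m])
        add(par[m], par[m], 0.25 * inv_d[m])
    both = (ped.sire != MISSING) & (ped.dam != MISSING)
    add(ped.sire[both], ped.dam[both], 0.25 * inv_d[both])
    add(ped.dam[both], ped.sire[both], 0.25 * inv_d[both])

    Ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    return RelationshipMatrix(labels=list(ped.ids), values=Ainv, kind="A_inverse")


def extract_A22(
    ped: PedigreeTable,
    genotyped_ids: Sequence[str],
    A_inv: RelationshipMatrix | None = None,
) -> RelationshipMatrix:
    """Dense A restricted to the genotyped animals, without forming full A.

    Solves A^-1 x = e_j for each genotyped animal j using one sparse LU
    factorization, and keeps the genotyped rows of x.  Row/column order
    follows ``genotyped_ids``.
    """
    g_idx = ped.codes(genotyped_ids)
    if A_inv is None:
        A_inv = build_A_inverse(ped)
    lu = splu(A_inv.values.tocsc())
    rhs = np.zeros((ped.n, len(g_idx)))
    rhs[g_idx, np.arange(len(g_idx))] = 1.0
    cols = lu.solve(rhs)
    A22 = cols[g_idx, :]
    A22 = 0.5 * (A22 + A22.T)
    return RelationshipMatrix(labels=[str(a) for a in genotyped_ids], values=A22, kind="A22")
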