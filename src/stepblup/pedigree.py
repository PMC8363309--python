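"""Pedigree handling and numerator relationship matrices.

A pedigree is stored in topological order (every parent precedes its
offspring) with parents encoded as integer indices and ``-1`` for an
unknown parent.  Unknown parents are treated as unrelated, non-inbred
founders.  On top of that ordering the module computes inbreeding
coefficients (Meuwissen & Luo style back-tracing), the numerator
relationship matrix A by the tabular method, its sparse inverse by
Henderson's rules with inbreeding-aware Mendelian-sampling variances,
subset blocks (A22), and cohort relationship summaries used by the LR
validation method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit

UNKNOWN = -1
#: strings read as "parent unknown" in pedigree CSV files
UNKNOWN_TOKENS = {"", "0", "NA", "na", ".", "nan", "None"}

VALID_SEXES = {"male", "female", "steer"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, dangling parent, ...)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids : object ndarray of original animal IDs, in internal order
    sire, dam : int ndarrays of parent indices (``-1`` = unknown)
    birth_year : int ndarray
    sex : object ndarray of {'male','female','steer'} or None
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    sex: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        """Map original IDs to internal indices (raises on unknown IDs)."""
        try:
            return np.asarray([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal ID not in pedigree: {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        sentinel = np.concatenate([self.ids, np.asarray(["0"], dtype=object)])
        out = pd.DataFrame(
            {
                "animal": self.ids,
                "sire": sentinel[self.sire],
                "dam": sentinel[self.dam],
                "birth_year": self.birth_year,
            }
        )
        if self.sex is not None:
            out["sex"] = self.sex
        return out

    def write(self, path) -> None:
        """Write the pedigree CSV dialect (unknown parent encoded as '0')."""
        self.to_frame().to_csv(path, index=False)


def _toposort(n: int, sire: np.ndarray, dam: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Kahn topological order over the parent->offspring DAG.

    Returns a permutation `order` such that parents precede offspring.
    Raises PedigreeError naming one animal on a cycle.
    """
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    order = []
    while queue:
        nxt = []
        for i in queue:
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) < n:
        stuck = int(np.flatnonzero(indeg > 0)[0])
        raise PedigreeError(
            f"pedigree contains a cycle involving animal {ids[stuck]!r}"
        )
    return np.asarray(order, dtype=np.int64)


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Validate and topologically order a pedigree data frame.

    Expected columns: animal, sire, dam, birth_year and optionally sex.
    Unknown parents may be encoded as '0', empty, NA or '.'.
    """
    required = {"animal", "sire", "dam", "birth_year"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree is missing columns: {sorted(missing)}")

    def _clean(col):
        return np.asarray(
            [None if (pd.isna(v) or str(v).strip() in UNKNOWN_TOKENS) else str(v).strip()
             for v in col],
            dtype=object,
        )

    animals = np.asarray([str(v).strip() for v in df["animal"]], dtype=object)
    if len(set(animals)) != len(animals):
        dup = pd.Series(animals)
        offenders = sorted(dup[dup.duplicated()].unique().tolist())
        raise PedigreeError(f"duplicate animal IDs: {offenders[:10]}")
    sires = _clean(df["sire"])
    dams = _clean(df["dam"])
    lookup = {a: i for i, a in enumerate(animals)}

    dangling = sorted(
        {p for p in np.concatenate([sires, dams]) if p is not None and p not in lookup}
    )
    if dangling:
        raise PedigreeError(
            f"parent IDs absent from the animal column: {dangling[:10]}"
        )

    n = len(animals)
    sire_ix = np.asarray([lookup[p] if p is not None else UNKNOWN for p in sires])
    dam_ix = np.asarray([lookup[p] if p is not None else UNKNOWN for p in dams])
    for i in range(n):
        if sire_ix[i] == i or dam_ix[i] == i:
            raise PedigreeError(
                f"pedigree contains a cycle involving animal {animals[i]!r}"
            )

    order = _toposort(n, sire_ix, dam_ix, animals)
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    remap = np.concatenate([rank, [UNKNOWN]])  # remap[-1] handles UNKNOWN

    birth_year = np.asarray(df["birth_year"], dtype=np.int64)[order]
    sex = None
    if "sex" in df.columns:
        sex = np.asarray([str(v) for v in df["sex"]], dtype=object)[order]
        bad = sorted(set(sex) - VALID_SEXES)
        if bad:
            raise PedigreeError(f"invalid sex codes: {bad}")
    return Pedigree(
        ids=animals[order],
        sire=remap[sire_ix][order],
        dam=remap[dam_ix][order],
        birth_year=birth_year,
        sex=sex,
    )


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV (columns animal,sire,dam,birth_year[,sex])."""
    df = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    return pedigree_from_frame(df)


# ---------------------------------------------------------------------------
# inbreeding and relationship matrices
# ---------------------------------------------------------------------------

@njit(cache=True)
def _inbreeding_kernel(sire, dam):  # pragma: no cover - exercised via wrapper
    """Meuwissen & Luo back-tracing; w seeded at the parents of each animal."""
    n = sire.shape[0]
    F = np.zeros(n)
    d = np.zeros(n)
    w = np.zeros(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        fs = F[s] if s >= 0 else -1.0
        fm = F[m] if m >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fm)
        if s < 0 or m < 0:
            F[i] = 0.0
            continue
        for j in range(i):
            w[j] = 0.0
        w[s] += 0.5
        w[m] += 0.5
        aii = d[i]
        top = s if s > m else m
        for j in range(top, -1, -1):
            if w[j] != 0.0:
                aii += w[j] * w[j] * d[j]
                sj, mj = sire[j], dam[j]
                if sj >= 0:
                    w[sj] += 0.5 * w[j]
                if mj >= 0:
                    w[mj] += 0.5 * w[j]
        F[i] = aii - 1.0
    return F, d


def inbreeding_coefficients(ped: Pedigree, with_d: bool = False):
    """Per-animal inbreeding coefficients F (founder convention F=0).

    F_i = 0.5 * a(sire_i, dam_i); an animal with an unknown parent has F=0.
    When ``with_d`` is true, the Mendelian-sampling variance scale
    d_i = 0.5 - 0.25 (F_s + F_d) (with F=-1 for unknown parents) is also
    returned; it feeds Henderson's inverse rules.
    """
    F, d = _inbreeding_kernel(
        ped.sire.astype(np.int64), ped.dam.astype(np.int64)
    )
    return (F, d) if with_d else F


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix keyed by animal IDs."""

    ids: np.ndarray
    values: object  # dense ndarray or scipy sparse
    kind: str  # A | A_inv | A22 | A22_inv | G | G_blended | H_inv

    @property
    def n(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)


@njit(cache=True)
def _tabular_a(sire, dam):  # pragma: no cover
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, m = sire[i], dam[i]
        asd = A[s, m] if (s >= 0 and m >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if m >= 0:
                val += 0.5 * A[j, m]
            A[i, j] = val
            A[j, i] = val
    return A


_DENSE_LIMIT = 4000


def a_matrix(ped: Pedigree, subset=None) -> RelationshipMatrix:
    """Numerator relationship matrix A (tabular method), or its A22 block.

    ``subset`` is a list of original animal IDs; the block is the
    restriction of the full-pedigree A to those animals (computed on the
    whole pedigree first, never on a pruned one).  For large pedigrees the
    block is obtained from sparse solves with A^-1 instead of the dense
    tabular recursion.
    """
    if subset is None:
        A = _tabular_a(ped.sire.astype(np.int64), ped.dam.astype(np.int64))
        return RelationshipMatrix(ids=ped.ids.copy(), values=A, kind="A")

    idx = ped.index_of(subset)
    if ped.n <= _DENSE_LIMIT:
        A = _tabular_a(ped.sire.astype(np.int64), ped.dam.astype(np.int64))
        block = A[np.ix_(idx, idx)]
    else:
        # A e_j columns via solves with the sparse inverse (Colleau's trick)
        ainv = a_inverse(ped)
        lu = sp.linalg.splu(ainv.values.tocsc())
        rhs = np.zeros((ped.n, len(idx)))
        rhs[idx, np.arange(len(idx))] = 1.0
        cols = lu.solve(rhs)
        block = cols[idx, :]
        block = 0.5 * (block + block.T)
    return RelationshipMatrix(
        ids=np.asarray(subset, dtype=object), values=block, kind="A22"
    )


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A^-1 by Henderson's rules with inbreeding-aware Mendelian
    sampling variances (alpha_i = 1/d_i, d from computed parental F)."""
    _, d = inbreeding_coefficients(ped, with_d=True)
    alpha = 1.0 / d
    n = ped.n
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        a = alpha[i]
        s, m = int(ped.sire[i]), int(ped.dam[i])
        add(i, i, a)
        for p in (s, m):
            if p >= 0:
                add(p, i, -0.5 * a)
                add(i, p, -0.5 * a)
                add(p, p, 0.25 * a)
        if s >= 0 and m >= 0:
            add(s, m, 0.25 * a)
            add(m, s, 0.25 * a)
    ainv = sp.coo_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(n, n)
    ).tocsr()
    return RelationshipMatrix(ids=ped.ids.copy(), values=ainv, kind="A_inv")


@dataclass
class CohortSummary:
    """Average inbreeding and pairwise relationship of a focal cohort."""

    mean_inbreeding: float  # Fbar
    mean_pairwise_relationship: float  # 2*fbar, mean off-diagonal of A
    cohort_ids: np.ndarray


def cohort_summary(a_focal: RelationshipMatrix) -> CohortSummary:
    """Fbar = mean(diag)-1 and 2fbar = mean off-diagonal of the focal A block."""
    A = a_focal.dense()
    n = A.shape[0]
    if n < 2:
        raise ValueError("cohort must contain at least two animals")
    fbar = float(np.mean(np.diag(A)) - 1.0)
    off = (A.sum() - np.trace(A)) / (n * (n - 1))
    return CohortSummary(
        mean_inbreeding=fbar,
        mean_pairwise_relationship=float(off),
        cohort_ids=a_focal.ids.copy(),
    )
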