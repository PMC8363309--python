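"""Mixed-model equations for single- and multi-trait animal models.

The model per trait is y = Xb + Zu + e with Var(u) = G0 (x) K and
Var(e) determined by the residual covariance R0 applied per animal over
its observed traits (records may be missing trait-wise; each animal's
residual weight is the inverse of the observed-trait submatrix of R0).
K is the pedigree relationship matrix A or the single-step matrix H,
supplied through its sparse inverse.

Henderson's equations are assembled with the solution vector ordered as
[b_1, ..., b_t, u_1, ..., u_t]; the random block adds G0^-1 (x) K^-1.
Small systems are solved directly (sparse LU); large multi-trait
single-step systems use a Jacobi-preconditioned conjugate gradient whose
matvec exploits the Kronecker structure of the random block instead of
materializing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree, RelationshipMatrix

TRAITS_8 = ["YW", "UBFT", "UEMA", "UIMF", "BFT", "CW", "EMA", "MS"]
CARCASS_TRAITS = ["BFT", "CW", "EMA", "MS"]
ULTRASOUND_TRAITS = ["UBFT", "UEMA", "UIMF"]


class ModelError(ValueError):
    pass


@dataclass
class PhenotypeTable:
    """Per-animal multi-trait records.

    ``data`` has one row per animal with an ``animal`` column, one column
    per trait (NaN = unrecorded) and the fixed-effect / covariate columns
    the model spec refers to.
    """

    data: pd.DataFrame
    traits: list

    def __post_init__(self):
        if "animal" not in self.data.columns:
            raise ModelError("phenotype table needs an 'animal' column")
        if self.data["animal"].duplicated().any():
            raise ModelError("one row per animal expected (duplicate animal IDs)")

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(data=self.data.copy(), traits=list(self.traits))

    def observed(self, trait: str) -> pd.Series:
        return self.data[trait].notna()

    def n_records(self, trait: str) -> int:
        return int(self.observed(trait).sum())

    def write(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class TraitModel:
    """Fixed part of one trait's model: categorical factors + covariates."""

    factors: list = field(default_factory=list)
    covariates: list = field(default_factory=list)


@dataclass
class ModelSpec:
    traits: list
    trait_models: dict  # trait -> TraitModel
    relationship_source: str = "A_inv"  # or "H_inv"
    multi_trait: bool = True

    def __post_init__(self):
        if self.relationship_source not in ("A_inv", "H_inv"):
            raise ModelError("relationship_source must be 'A_inv' or 'H_inv'")
        for tr in self.traits:
            self.trait_models.setdefault(tr, TraitModel())

    @property
    def model_tag(self) -> str:
        st = "MT" if self.multi_trait else "ST"
        k = "ssGBLUP" if self.relationship_source == "H_inv" else "BLUP"
        return f"{st}-{k}"

    def single_trait(self, trait: str) -> "ModelSpec":
        return ModelSpec(
            traits=[trait],
            trait_models={trait: self.trait_models[trait]},
            relationship_source=self.relationship_source,
            multi_trait=False,
        )


@dataclass
class DesignBundle:
    """Animal-indexed design for one trait (zero rows for unrecorded animals)."""

    trait: str
    Xa: sp.csr_matrix  # n_pedigree x p, row i = fixed-effect row of animal i
    ya: np.ndarray  # n_pedigree, 0.0 where unrecorded
    obs: np.ndarray  # bool mask over pedigree animals
    columns: list  # fixed-effect column names (intercept first)


def build_design(
    pheno: PhenotypeTable, spec: ModelSpec, trait: str, ped: Pedigree
) -> DesignBundle:
    """One-trait design: intercept + drop-first dummies + covariates.

    Records with a missing trait value are excluded; factor levels are
    taken from the included records only (sorted for determinism), so a
    level seen only in excluded rows is silently dropped.
    """
    tm = spec.trait_models[trait]
    df = pheno.data.loc[pheno.observed(trait)]
    if df.empty:
        raise ModelError(f"no records for trait {trait!r}")
    animal_idx = ped.index_of(df["animal"].to_numpy())
    if len(np.unique(animal_idx)) != len(animal_idx):
        raise ModelError(f"duplicate records per animal for trait {trait!r}")

    nrec = len(df)
    cols: list[np.ndarray] = [np.ones(nrec)]
    names: list[str] = ["intercept"]
    for fac in tm.factors:
        levels = sorted(pd.unique(df[fac]).tolist())
        for lev in levels[1:]:  # reference (first) level dropped
            cols.append((df[fac] == lev).to_numpy(dtype=np.float64))
            names.append(f"{fac}[{lev}]")
    for cov in tm.covariates:
        v = df[cov].to_numpy(dtype=np.float64)
        if np.isnan(v).any():
            raise ModelError(f"covariate {cov!r} has missing values in records of {trait!r}")
        cols.append(v)
        names.append(cov)

    X = np.column_stack(cols)
    Xa = sp.csr_matrix(
        (X.ravel(), (np.repeat(animal_idx, X.shape[1]), np.tile(np.arange(X.shape[1]), nrec))),
        shape=(ped.n, X.shape[1]),
    )
    ya = np.zeros(ped.n)
    ya[animal_idx] = df[trait].to_numpy(dtype=np.float64)
    obs = np.zeros(ped.n, dtype=bool)
    obs[animal_idx] = True
    return DesignBundle(trait=trait, Xa=Xa, ya=ya, obs=obs, columns=names)


def residual_weights(obs_matrix: np.ndarray, R0: np.ndarray) -> np.ndarray:
    """Per-animal residual precision weights under trait-wise missingness.

    For each animal, the inverse of the observed-trait submatrix of R0 is
    scattered into a t x t matrix; returns W of shape (n, t, t) with
    W[i, k, l] = 0 unless traits k and l are both observed on animal i.
    """
    n, t = obs_matrix.shape
    W = np.zeros((n, t, t))
    patterns, inverse = np.unique(obs_matrix, axis=0, return_inverse=True)
    for g, pat in enumerate(patterns):
        if not pat.any():
            continue
        o = np.flatnonzero(pat)
        Einv = np.linalg.inv(R0[np.ix_(o, o)])
        members = inverse == g
        block = np.zeros((t, t))
        block[np.ix_(o, o)] = Einv
        W[members] = block
    return W


@dataclass
class MMESystem:
    """Assembled mixed-model equations.

    ``lhs_data`` holds the data (X'R^-1X-style) part; the random-effect
    prior G0^-1 (x) K^-1 is kept implicit through ``G0inv`` and ``Kinv``
    so large systems never materialize the Kronecker product.
    """

    traits: list
    lhs_data: sp.csr_matrix
    rhs: np.ndarray
    G0inv: np.ndarray
    Kinv: sp.csr_matrix
    n_animals: int
    fixed_offsets: dict  # trait -> (start, stop) in the solution vector
    u_offset: int  # start of the breeding-value block
    fixed_columns: dict  # trait -> column names

    @property
    def n_equations(self) -> int:
        return self.lhs_data.shape[0]

    def u_slice(self, k: int) -> slice:
        N = self.n_animals
        return slice(self.u_offset + k * N, self.u_offset + (k + 1) * N)

    def materialize(self) -> sp.csr_matrix:
        """Full sparse LHS including the Kronecker random block."""
        t, N = len(self.traits), self.n_animals
        M = self.n_equations
        kron_u = sp.kron(sp.csr_matrix(self.G0inv), self.Kinv, format="coo")
        pad = sp.coo_matrix(
            (kron_u.data, (kron_u.row + self.u_offset, kron_u.col + self.u_offset)),
            shape=(M, M),
        )
        return (self.lhs_data + pad.tocsr()).tocsr()

    def matvec(self, x: np.ndarray) -> np.ndarray:
        out = self.lhs_data @ x
        t, N = len(self.traits), self.n_animals
        U = x[self.u_offset:].reshape(t, N)
        out[self.u_offset:] += (self.G0inv @ (self.Kinv @ U.T).T).ravel()
        return out

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.lhs_data.diagonal()).copy()
        kd = np.outer(np.diag(self.G0inv), self.Kinv.diagonal()).ravel()
        d[self.u_offset:] += kd
        return d


def _check_pd(M: np.ndarray, label: str) -> np.ndarray:
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        raise ModelError(f"{label} is not positive definite") from None
    return np.linalg.inv(M)


def assemble_mme(designs: list, vc, Kinv: RelationshipMatrix | sp.spmatrix) -> MMESystem:
    """Henderson MME for the traits in ``designs`` (order defines G0/R0 order).

    ``vc`` is anything exposing G0 and R0 (t x t arrays); ``Kinv`` is the
    sparse inverse relationship matrix over the full pedigree.
    """
    G0 = np.atleast_2d(np.asarray(vc.G0, dtype=np.float64))
    R0 = np.atleast_2d(np.asarray(vc.R0, dtype=np.float64))
    t = len(designs)
    if G0.shape != (t, t) or R0.shape != (t, t):
        raise ModelError("variance component dimensions do not match trait count")
    G0inv = _check_pd(G0, "G0")
    _check_pd(R0, "R0")
    K = Kinv.values if isinstance(Kinv, RelationshipMatrix) else Kinv
    K = sp.csr_matrix(K)
    N = K.shape[0]
    for d in designs:
        if d.Xa.shape[0] != N:
            raise ModelError("design and relationship matrix dimensions differ")

    obs = np.column_stack([d.obs for d in designs])
    W = residual_weights(obs, R0)  # (N, t, t)

    p = [d.Xa.shape[1] for d in designs]
    FF = [[None] * t for _ in range(t)]
    FU = [[None] * t for _ in range(t)]
    UU = [[None] * t for _ in range(t)]
    rhs_f = []
    rhs_u = []
    Y = np.column_stack([d.ya for d in designs])
    for k in range(t):
        rf = np.zeros(p[k])
        ru = np.zeros(N)
        for l in range(t):
            w = W[:, k, l]
            Dw = sp.diags(w)
            XkT = designs[k].Xa.T
            FF[k][l] = (XkT @ Dw @ designs[l].Xa).tocsr()
            FU[k][l] = (XkT @ Dw).tocsr()
            UU[k][l] = sp.diags(w).tocsr()
            rf += XkT @ (w * Y[:, l])
            ru += w * Y[:, l]
        rhs_f.append(rf)
        rhs_u.append(ru)

    lhs_data = sp.bmat(
        [[FF[k][l] for l in range(t)] + [FU[k][l] for l in range(t)] for k in range(t)]
        + [[FU[l][k].T for l in range(t)] + [UU[k][l] for l in range(t)] for k in range(t)],
        format="csr",
    )
    rhs = np.concatenate(rhs_f + rhs_u)

    fixed_offsets = {}
    pos = 0
    for k, d in enumerate(designs):
        fixed_offsets[d.trait] = (pos, pos + p[k])
        pos += p[k]
    return MMESystem(
        traits=[d.trait for d in designs],
        lhs_data=lhs_data,
        rhs=rhs,
        G0inv=G0inv,
        Kinv=K,
        n_animals=N,
        fixed_offsets=fixed_offsets,
        u_offset=pos,
        fixed_columns={d.trait: d.columns for d in designs},
    )


_DIRECT_NNZ_BUDGET = 2_000_000


def solve_mme(
    sys: MMESystem,
    method: str = "auto",
    tol: float = 1e-10,
    maxiter: int = 20000,
) -> np.ndarray:
    """Solve the MME; residual norm ||lhs x - rhs|| / ||rhs|| <= tol.

    ``auto`` picks a direct sparse LU when materializing the system stays
    cheap and conjugate gradients (Jacobi preconditioner, implicit
    Kronecker matvec) otherwise.
    """
    t = len(sys.traits)
    if method == "auto":
        est_nnz = sys.lhs_data.nnz + t * t * sys.Kinv.nnz
        # multi-trait Kronecker systems suffer severe LU fill-in; keep the
        # direct path for compact (mostly single-trait) systems only
        method = (
            "direct"
            if est_nnz <= _DIRECT_NNZ_BUDGET and sys.n_equations <= 6000
            else "pcg"
        )

    if method == "direct":
        full = sys.materialize().tocsc()
        try:
            lu = spla.splu(full)
        except RuntimeError as exc:
            raise ModelError(f"direct factorization failed: {exc}") from exc
        x = lu.solve(sys.rhs)
    elif method == "pcg":
        M = sys.n_equations
        op = spla.LinearOperator((M, M), matvec=sys.matvec, dtype=np.float64)
        d = sys.diagonal()
        d[d <= 0] = 1.0
        prec = spla.LinearOperator((M, M), matvec=lambda v: v / d, dtype=np.float64)
        x, info = spla.cg(op, sys.rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=prec)
        if info != 0:
            raise ModelError(
                f"PCG did not converge within {maxiter} iterations (info={info})"
            )
    else:
        raise ModelError(f"unknown solver method {method!r}")

    rnorm = np.linalg.norm(sys.matvec(x) - sys.rhs)
    bnorm = np.linalg.norm(sys.rhs)
    if bnorm > 0 and rnorm / bnorm > max(tol * 100, 1e-8):
        raise ModelError(
            f"solution residual {rnorm / bnorm:.2e} exceeds tolerance"
        )
    return x


@dataclass
class EvaluationResult:
    """EBVs for every pedigree animal plus fixed-effect solutions."""

    ebv: pd.DataFrame  # index: animal ID, columns: traits
    fixed_solutions: dict  # trait -> pd.Series of fixed-effect estimates
    model_tag: str
    scenario_tag: str = "whole"

    def write(self, path) -> None:
        long = self.ebv.reset_index(names="animal").melt(
            id_vars="animal", var_name="trait", value_name="ebv"
        )
        long["model_tag"] = self.model_tag
        long["scenario_tag"] = self.scenario_tag
        long.to_csv(path, index=False, float_format="%.10g")


def evaluate(
    pheno: PhenotypeTable,
    spec: ModelSpec,
    vc,
    Kinv: RelationshipMatrix | sp.spmatrix,
    ped: Pedigree,
    scenario_tag: str = "whole",
    method: str = "auto",
    tol: float = 1e-8,
) -> EvaluationResult:
    """Run build -> assemble -> solve and collect EBVs for all animals.

    For a single-trait spec each trait is solved in its own system with
    the corresponding diagonal entries of G0/R0 (covariances assumed
    zero), matching the classical ST-BLUP convention.
    """
    G0 = np.atleast_2d(np.asarray(vc.G0, dtype=np.float64))
    R0 = np.atleast_2d(np.asarray(vc.R0, dtype=np.float64))
    t = len(spec.traits)
    ebv = np.zeros((ped.n, t))
    fixed: dict = {}

    class _VC:
        def __init__(self, G0, R0):
            self.G0, self.R0 = G0, R0

    if spec.multi_trait:
        designs = [build_design(pheno, spec, tr, ped) for tr in spec.traits]
        system = assemble_mme(designs, _VC(G0, R0), Kinv)
        x = solve_mme(system, method=method, tol=tol)
        for k, tr in enumerate(spec.traits):
            ebv[:, k] = x[system.u_slice(k)]
            a, b = system.fixed_offsets[tr]
            fixed[tr] = pd.Series(x[a:b], index=system.fixed_columns[tr])
    else:
        for k, tr in enumerate(spec.traits):
            d = build_design(pheno, spec, tr, ped)
            system = assemble_mme(
                [d], _VC(G0[k : k + 1, k : k + 1], R0[k : k + 1, k : k + 1]), Kinv
            )
            x = solve_mme(system, method=method, tol=tol)
            ebv[:, k] = x[system.u_slice(0)]
            a, b = system.fixed_offsets[tr]
            fixed[tr] = pd.Series(x[a:b], index=system.fixed_columns[tr])

    return EvaluationResult(
        ebv=pd.DataFrame(ebv, index=pd.Index(ped.ids, name="animal"), columns=spec.traits),
        fixed_solutions=fixed,
        model_tag=spec.model_tag,
        scenario_tag=scenario_tag,
    )
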