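"""Bayesian variance-component estimation by Gibbs sampling.

Multi-trait animal model y = Xb + Zu + e, Var(u) = G0 (x) K,
Var(e) = R0 (x) I, sampled with the classical scheme:

* location effects (fixed effects and breeding values) by single-site
  Gauss-Seidel sampling from their scalar full conditionals, swept once
  per iteration (compiled with numba);
* trait-wise missing records by data augmentation: missing residuals are
  drawn from their conditional normal given the observed residuals of the
  same animal, which restores complete-data conjugacy (missing records
  carry an arbitrary fixed reference-level design row, which leaves the
  observed-data posterior untouched);
* G0 from inverse-Wishart(prior + U' K^-1 U, prior df + n_animals) and
  R0 from inverse-Wishart(prior + E'E, prior df + n_augmented-records).

Priors default to minimal degrees of freedom (t + 1) with scale set to
half the observed phenotypic variances, a near-flat choice whose weight
is negligible against thousands of records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy.stats import invwishart

from .linear_model import ModelSpec, PhenotypeTable, build_design
from .pedigree import Pedigree, RelationshipMatrix


class GibbsError(RuntimeError):
    pass


@dataclass
class GibbsConfig:
    """Chain settings.

    Defaults are the desk-scale chain (20,000 iterations, 5,000 burn-in,
    thinning 10); production-scale settings (e.g. 550,000 / 50,000 / 50)
    are plain configuration.
    """

    n_iterations: int = 20000
    burn_in: int = 5000
    thinning: int = 10
    seed: int = 0
    prior_df: int | None = None  # default: t + 1
    prior_scale_g: np.ndarray | None = None
    prior_scale_r: np.ndarray | None = None

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must be < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class GibbsChain:
    """Retained (thinned, post burn-in) draws."""

    traits: list
    G0_draws: np.ndarray  # (ndraws, t, t)
    R0_draws: np.ndarray  # (ndraws, t, t)
    bv_draws: np.ndarray | None  # (ndraws, n_store, t)
    store_ids: np.ndarray | None
    config: GibbsConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.G0_draws.shape[0]

    def h2_draws(self) -> np.ndarray:
        g = np.diagonal(self.G0_draws, axis1=1, axis2=2)
        r = np.diagonal(self.R0_draws, axis1=1, axis2=2)
        return g / (g + r)

    def write(self, path) -> None:
        """Columnar chain file: one row per retained draw."""
        t = len(self.traits)
        cols = {}
        for i in range(t):
            for j in range(i, t):
                cols[f"G0[{self.traits[i]},{self.traits[j]}]"] = self.G0_draws[:, i, j]
                cols[f"R0[{self.traits[i]},{self.traits[j]}]"] = self.R0_draws[:, i, j]
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


@njit(cache=True)
def _gibbs_sweep(Bp, Bi, Bx, blB, Kp, Ki, Kx, blK, r0flat, g0flat, rhs, theta, z):
    """One Gauss-Seidel sampling sweep over all location equations.

    The coefficient matrix is C = sum_kl R0inv[kl]*B_kl + G0inv[kl]*K_kl;
    B and K are stored once in CSR form with a per-entry trait-pair label
    so only the scalar scales change between iterations.
    """
    M = rhs.shape[0]
    for i in range(M):
        acc = 0.0
        diag = 0.0
        for e in range(Bp[i], Bp[i + 1]):
            j = Bi[e]
            v = r0flat[blB[e]] * Bx[e]
            if j == i:
                diag += v
            else:
                acc += v * theta[j]
        for e in range(Kp[i], Kp[i + 1]):
            j = Ki[e]
            v = g0flat[blK[e]] * Kx[e]
            if j == i:
                diag += v
            else:
                acc += v * theta[j]
        mu = (rhs[i] - acc) / diag
        theta[i] = mu + z[i] / np.sqrt(diag)


def _entry_labels(C: sp.csr_matrix, offsets: np.ndarray, t: int) -> np.ndarray:
    """Trait-pair label k*t+l for every stored entry of the global CSR."""
    rows = np.repeat(
        np.arange(C.shape[0]), np.diff(C.indptr).astype(np.int64)
    )
    k = np.searchsorted(offsets, rows, side="right") - 1
    l = np.searchsorted(offsets, C.indices, side="right") - 1
    return (k * t + l).astype(np.int64)


def _augmented_designs(pheno, spec, ped):
    """Per-trait animal-indexed designs with reference rows for the
    augmented (missing) records of otherwise-phenotyped animals."""
    designs = [build_design(pheno, spec, tr, ped) for tr in spec.traits]
    any_obs = np.zeros(ped.n, dtype=bool)
    for d in designs:
        any_obs |= d.obs
    Xf = []
    for d in designs:
        X = d.Xa.tolil(copy=True)
        fill = np.flatnonzero(any_obs & ~d.obs)
        for i in fill:
            X[i, 0] = 1.0  # intercept-only reference row
        Xf.append(X.tocsr())
    return designs, Xf, any_obs


def gibbs_sample(
    pheno: PhenotypeTable,
    spec: ModelSpec,
    Kinv: RelationshipMatrix | sp.spmatrix,
    cfg: GibbsConfig,
    ped: Pedigree,
    store_bv_ids=None,
) -> GibbsChain:
    """Run the Gibbs sampler and return the thinned post burn-in chain.

    ``store_bv_ids`` restricts breeding-value draw storage to a declared
    subset of animals (needed by the equilibrium genetic variance).
    """
    rng = np.random.default_rng(cfg.seed)
    traits = list(spec.traits)
    t = len(traits)
    K = Kinv.values if isinstance(Kinv, RelationshipMatrix) else Kinv
    K = sp.csr_matrix(K).astype(np.float64)
    N = K.shape[0]

    designs, Xf, any_obs = _augmented_designs(pheno, spec, ped)
    P = np.flatnonzero(any_obs)
    nP = P.size
    if nP == 0:
        raise GibbsError("no phenotyped animals")
    obs = np.column_stack([d.obs for d in designs])  # (N, t)
    Yobs = np.column_stack([d.ya for d in designs])  # zeros where unobserved
    p = [X.shape[1] for X in Xf]
    Mk = [pk + N for pk in p]
    offsets = np.concatenate([[0], np.cumsum(Mk)]).astype(np.int64)
    Mtot = int(offsets[-1])

    # --- static coefficient structures -------------------------------------
    Dp = sp.diags(any_obs.astype(np.float64)).tocsr()
    Bblocks = []
    for k in range(t):
        row = []
        for l in range(t):
            XkT = Xf[k].T
            row.append(
                sp.bmat(
                    [[XkT @ Dp @ Xf[l], XkT @ Dp], [(Xf[l].T @ Dp).T, Dp]],
                    format="csr",
                )
            )
        Bblocks.append(row)
    B = sp.bmat(Bblocks, format="csr")
    B.sum_duplicates()
    blB = _entry_labels(B, offsets[:-1], t)

    Kblocks = [
        [
            sp.bmat(
                [
                    [sp.csr_matrix((p[k], p[l])), sp.csr_matrix((p[k], N))],
                    [sp.csr_matrix((N, p[l])), K],
                ],
                format="csr",
            )
            for l in range(t)
        ]
        for k in range(t)
    ]
    Kg = sp.bmat(Kblocks, format="csr")
    Kg.sum_duplicates()
    blK = _entry_labels(Kg, offsets[:-1], t)

    # missing patterns over phenotyped animals
    patterns, pat_inverse = np.unique(obs[P], axis=0, return_inverse=True)
    pat_members = [P[pat_inverse == g] for g in range(len(patterns))]

    # --- priors and starting values ----------------------------------------
    vp = np.array(
        [np.var(Yobs[designs[k].obs, k], ddof=1) if designs[k].obs.sum() > 1 else 1.0
         for k in range(t)]
    )
    nu0 = cfg.prior_df if cfg.prior_df is not None else t + 1
    # half the observed phenotypic covariance matrix (pairwise complete,
    # clipped to PD): prior scale and starting values.  Using the full
    # matrix rather than its diagonal matters: a diagonal scale centres
    # the implied prior correlation at zero, which measurably shrinks
    # genetic correlations when they are weakly identified.
    Cp = np.diag(vp).astype(np.float64)
    for k in range(t):
        for l in range(k + 1, t):
            both = obs[:, k] & obs[:, l]
            if both.sum() > 2:
                c = np.cov(Yobs[both, k], Yobs[both, l], ddof=1)[0, 1]
                lim = 0.95 * np.sqrt(vp[k] * vp[l])
                Cp[k, l] = Cp[l, k] = np.clip(c, -lim, lim)
    w, Q = np.linalg.eigh(Cp)
    Cp = (Q * np.maximum(w, 1e-6 * vp.max())) @ Q.T
    S0g = cfg.prior_scale_g if cfg.prior_scale_g is not None else 0.5 * Cp
    S0r = cfg.prior_scale_r if cfg.prior_scale_r is not None else 0.5 * Cp
    G0 = 0.5 * Cp
    R0 = 0.5 * Cp
    theta = np.zeros(Mtot)
    Yc = Yobs.copy()  # completed data, zeros off P

    store_idx = None
    if store_bv_ids is not None:
        store_idx = ped.index_of(store_bv_ids)

    n_keep = (cfg.n_iterations - cfg.burn_in) // cfg.thinning
    G0_draws = np.empty((n_keep, t, t))
    R0_draws = np.empty((n_keep, t, t))
    bv_draws = (
        np.empty((n_keep, len(store_idx), t)) if store_idx is not None else None
    )

    u_view = [slice(offsets[k] + p[k], offsets[k + 1]) for k in range(t)]
    b_view = [slice(offsets[k], offsets[k] + p[k]) for k in range(t)]

    kept = 0
    for it in range(cfg.n_iterations):
        G0inv = np.linalg.inv(G0)
        R0inv = np.linalg.inv(R0)

        # conditional means for phenotyped animals, all traits
        mean = np.zeros((N, t))
        for k in range(t):
            mean[:, k] = Xf[k] @ theta[b_view[k]] + theta[u_view[k]]

        # augmentation: sample missing residuals | observed residuals
        Eobs = Yobs[P] - mean[P]
        E = Eobs.copy()
        for g, pat in enumerate(patterns):
            mem = pat_members[g]
            if pat.all() or not mem.size:
                continue
            o = np.flatnonzero(pat)
            m = np.flatnonzero(~pat)
            Roo_inv = np.linalg.inv(R0[np.ix_(o, o)])
            beta = Roo_inv @ R0[np.ix_(o, m)]
            schur = R0[np.ix_(m, m)] - R0[np.ix_(m, o)] @ beta
            schur = 0.5 * (schur + schur.T)
            try:
                L = np.linalg.cholesky(schur)
            except np.linalg.LinAlgError as exc:
                raise GibbsError(
                    f"non-PD conditional residual covariance at iteration {it}"
                ) from exc
            loc = np.searchsorted(P, mem)
            e_obs = Eobs[loc][:, o]
            e_mis = e_obs @ beta + rng.standard_normal((mem.size, m.size)) @ L.T
            E[np.ix_(loc, m)] = e_mis
        comp = mean[P] + E
        comp[obs[P]] = Yobs[P][obs[P]]  # exact observed values, no fp drift
        Yc[P] = comp

        # rhs for the location sweep
        V = Yc @ R0inv
        rhs = np.empty(Mtot)
        for k in range(t):
            rhs[b_view[k]] = Xf[k].T @ V[:, k]
            rhs[u_view[k]] = V[:, k]
        z = rng.standard_normal(Mtot)
        _gibbs_sweep(
            B.indptr, B.indices, B.data, blB,
            Kg.indptr, Kg.indices, Kg.data, blK,
            R0inv.ravel(), G0inv.ravel(), rhs, theta, z,
        )

        # variance components
        U = np.column_stack([theta[u_view[k]] for k in range(t)])
        Sg = U.T @ (K @ U)
        Sg = 0.5 * (Sg + Sg.T)
        try:
            G0 = invwishart.rvs(df=nu0 + N, scale=S0g + Sg, random_state=rng)
        except np.linalg.LinAlgError as exc:
            raise GibbsError(f"non-PD G0 scale at iteration {it}") from exc
        G0 = np.atleast_2d(G0)

        for k in range(t):
            mean[:, k] = Xf[k] @ theta[b_view[k]] + theta[u_view[k]]
        Ecur = Yc[P] - mean[P]
        Sr = Ecur.T @ Ecur
        Sr = 0.5 * (Sr + Sr.T)
        try:
            R0 = invwishart.rvs(df=nu0 + nP, scale=S0r + Sr, random_state=rng)
        except np.linalg.LinAlgError as exc:
            raise GibbsError(f"non-PD R0 scale at iteration {it}") from exc
        R0 = np.atleast_2d(R0)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            G0_draws[kept] = G0
            R0_draws[kept] = R0
            if bv_draws is not None:
                bv_draws[kept] = U[store_idx]
            kept += 1

    chain = GibbsChain(
        traits=traits,
        G0_draws=G0_draws[:kept],
        R0_draws=R0_draws[:kept],
        bv_draws=bv_draws[:kept] if bv_draws is not None else None,
        store_ids=np.asarray(store_bv_ids, dtype=object) if store_bv_ids is not None else None,
        config=cfg,
    )
    chain.diagnostics = _chain_diagnostics(chain)
    return chain


def _chain_diagnostics(chain: GibbsChain) -> dict:
    """Geweke-style first/last segment Z and crude effective sample size
    for the heritability traces (logged, never gated on)."""
    out = {}
    h2 = chain.h2_draws()
    n = h2.shape[0]
    for k, tr in enumerate(chain.traits):
        x = h2[:, k]
        a = x[: max(n // 10, 1)]
        b = x[n // 2:]
        denom = np.sqrt(np.var(a, ddof=1) / len(a) + np.var(b, ddof=1) / len(b))
        z = float((a.mean() - b.mean()) / denom) if denom > 0 else 0.0
        rho1 = 0.0
        if n > 2 and np.var(x) > 0:
            rho1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
        ess = n * (1 - rho1) / (1 + rho1) if abs(rho1) < 1 else float(n)
        out[tr] = {"geweke_z": z, "ess_h2": float(max(ess, 1.0))}
    return out


def hdi(draws: np.ndarray, prob: float = 0.95) -> tuple:
    """Shortest interval containing ``prob`` of the draws (quantile scan)."""
    x = np.sort(np.asarray(draws, dtype=np.float64))
    n = len(x)
    if n == 0:
        raise ValueError("empty draw vector")
    m = max(int(np.ceil(prob * n)), 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


@dataclass
class VarianceComponents:
    """Posterior summaries of a Gibbs chain (or fixed known components)."""

    traits: list
    G0: np.ndarray
    R0: np.ndarray
    heritability: np.ndarray | None = None
    genetic_correlation: np.ndarray | None = None
    phenotypic_correlation: np.ndarray | None = None
    hdi95: dict = field(default_factory=dict)

    @classmethod
    def known(cls, traits, G0, R0) -> "VarianceComponents":
        G0 = np.atleast_2d(np.asarray(G0, dtype=np.float64))
        R0 = np.atleast_2d(np.asarray(R0, dtype=np.float64))
        g, r = np.diag(G0), np.diag(R0)
        sg = np.sqrt(np.outer(g, g))
        P0 = G0 + R0
        sp_ = np.sqrt(np.outer(np.diag(P0), np.diag(P0)))
        return cls(
            traits=list(traits),
            G0=G0,
            R0=R0,
            heritability=g / (g + r),
            genetic_correlation=np.divide(G0, sg, out=np.zeros_like(G0), where=sg > 0),
            phenotypic_correlation=np.divide(P0, sp_, out=np.zeros_like(P0), where=sp_ > 0),
        )

    def diagonal_subset(self) -> "VarianceComponents":
        """Zero all covariances (the single-trait model assumption)."""
        return VarianceComponents.known(
            self.traits, np.diag(np.diag(self.G0)), np.diag(np.diag(self.R0))
        )

    def to_json(self, path) -> None:
        obj = {
            "traits": list(self.traits),
            "G0": self.G0.tolist(),
            "R0": self.R0.tolist(),
            "heritability": None if self.heritability is None else self.heritability.tolist(),
            "genetic_correlation": None
            if self.genetic_correlation is None
            else self.genetic_correlation.tolist(),
            "phenotypic_correlation": None
            if self.phenotypic_correlation is None
            else self.phenotypic_correlation.tolist(),
            "hdi95": {k: list(v) for k, v in self.hdi95.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def _corr_draws(cov_draws: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diagonal(cov_draws, axis1=1, axis2=2))
    return cov_draws / (d[:, :, None] * d[:, None, :])


def posterior_summary(chain: GibbsChain) -> VarianceComponents:
    """Posterior means and 95% HDIs of variances, h2, r_g and r_p."""
    if chain.n_draws == 0:
        raise GibbsError("empty chain: nothing retained after burn-in/thinning")
    t = len(chain.traits)
    G0 = chain.G0_draws.mean(axis=0)
    R0 = chain.R0_draws.mean(axis=0)
    h2d = chain.h2_draws()
    rg_d = _corr_draws(chain.G0_draws)
    rp_d = _corr_draws(chain.G0_draws + chain.R0_draws)
    out = VarianceComponents(
        traits=list(chain.traits),
        G0=G0,
        R0=R0,
        heritability=h2d.mean(axis=0),
        genetic_correlation=rg_d.mean(axis=0),
        phenotypic_correlation=rp_d.mean(axis=0),
    )
    for k, tr in enumerate(chain.traits):
        out.hdi95[f"h2[{tr}]"] = hdi(h2d[:, k])
        out.hdi95[f"G0[{tr},{tr}]"] = hdi(chain.G0_draws[:, k, k])
        out.hdi95[f"R0[{tr},{tr}]"] = hdi(chain.R0_draws[:, k, k])
        for l in range(k + 1, t):
            tr2 = chain.traits[l]
            out.hdi95[f"r_g[{tr},{tr2}]"] = hdi(rg_d[:, k, l])
            out.hdi95[f"r_p[{tr},{tr2}]"] = hdi(rp_d[:, k, l])
    return out


def equilibrium_genetic_variance(chain: GibbsChain, focal_ids) -> np.ndarray:
    """Equilibrium genetic variance sigma2_u_inf per trait.

    Per retained draw, the empirical variance (n-1 divisor) of the sampled
    breeding values across the focal animals; returned as the posterior
    mean per trait.  Under selection this shrinks below the base additive
    variance, which is exactly what the LR accuracy denominator needs.
    """
    if chain.bv_draws is None or chain.store_ids is None:
        raise GibbsError(
            "breeding-value draws were not stored; rerun gibbs_sample with store_bv_ids"
        )
    stored = {a: i for i, a in enumerate(chain.store_ids)}
    try:
        idx = np.asarray([stored[a] for a in focal_ids], dtype=np.int64)
    except KeyError as exc:
        raise GibbsError(
            f"focal animal {exc.args[0]!r} has no stored breeding-value draws"
        ) from None
    draws = chain.bv_draws[:, idx, :]  # (ndraws, nfocal, t)
    if draws.shape[1] < 2:
        return np.zeros(draws.shape[2])
    return draws.var(axis=1, ddof=1).mean(axis=0)
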