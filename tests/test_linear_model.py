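"""Design matrices, MME assembly/solvers and the evaluation wrapper."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import stepblup as sb
from stepblup.linear_model import (
    MMESystem,
    ModelError,
    assemble_mme,
    build_design,
    solve_mme,
)

from conftest import random_pedigree_frame


class VC:
    def __init__(self, G0, R0):
        self.G0, self.R0 = np.atleast_2d(G0), np.atleast_2d(R0)


def make_pheno(ped, rng, traits=("tA", "tB"), miss=(0.0, 0.0), factors=True):
    data = pd.DataFrame({"animal": list(ped.ids)})
    for tr, m in zip(traits, miss):
        y = rng.normal(10, 2, ped.n)
        y[rng.random(ped.n) < m] = np.nan
        data[tr] = y
    if factors:
        data["cg"] = rng.integers(0, 3, ped.n)
        data["age"] = rng.normal(0, 1, ped.n)
    return sb.PhenotypeTable(data=data, traits=list(traits))


def dense_mme_oracle(designs, G0, R0, A):
    """Record-level GLS construction of Henderson's equations (dense)."""
    N = A.shape[0]
    G0, R0 = np.atleast_2d(G0), np.atleast_2d(R0)
    p = [d.Xa.shape[1] for d in designs]
    off = np.concatenate([[0], np.cumsum(p)])
    M = off[-1] + len(designs) * N
    recs = [(i, k) for k, d in enumerate(designs) for i in np.flatnonzero(d.obs)]
    W = np.zeros((len(recs), M))
    y = np.zeros(len(recs))
    for r, (i, k) in enumerate(recs):
        W[r, off[k]:off[k] + p[k]] = designs[k].Xa[i].toarray()
        W[r, off[-1] + k * N + i] = 1.0
        y[r] = designs[k].ya[i]
    Rbig = np.zeros((len(recs), len(recs)))
    for r1, (i1, k1) in enumerate(recs):
        for r2, (i2, k2) in enumerate(recs):
            if i1 == i2:
                Rbig[r1, r2] = R0[k1, k2]
    Rinv = np.linalg.inv(Rbig)
    lhs = W.T @ Rinv @ W
    lhs[off[-1]:, off[-1]:] += np.kron(np.linalg.inv(G0), np.linalg.inv(A))
    return np.linalg.solve(lhs, W.T @ Rinv @ y)


class TestBuildDesign:
    def test_one_factor_one_hot_with_reference(self, trio_pedigree, rng):
        data = pd.DataFrame(
            {"animal": ["1", "2", "3"], "t": [1.0, 2.0, 3.0], "cg": [0, 1, 1],
             "age": [0.1, -0.2, 0.3]}
        )
        pheno = sb.PhenotypeTable(data=data, traits=["t"])
        spec = sb.ModelSpec(traits=["t"], trait_models={"t": sb.TraitModel(["cg"], ["age"])})
        d = build_design(pheno, spec, "t", trio_pedigree)
        assert d.columns == ["intercept", "cg[1]", "age"]
        X = d.Xa.toarray()[trio_pedigree.index_of(["1", "2", "3"])]
        assert np.allclose(X[:, 0], 1.0)
        assert np.allclose(X[:, 1], [0, 1, 1])  # level 0 is the reference
        assert np.allclose(X[:, 2], [0.1, -0.2, 0.3])

    def test_covariate_only_model(self, trio_pedigree):
        data = pd.DataFrame({"animal": ["1", "2"], "t": [1.0, 2.0], "age": [1.0, 2.0]})
        pheno = sb.PhenotypeTable(data=data, traits=["t"])
        spec = sb.ModelSpec(traits=["t"], trait_models={"t": sb.TraitModel([], ["age"])})
        d = build_design(pheno, spec, "t", trio_pedigree)
        assert d.columns == ["intercept", "age"]

    def test_level_counts_match(self, small_random_pedigree, rng):
        ped = small_random_pedigree
        pheno = make_pheno(ped, rng, traits=("t",), miss=(0.3,))
        spec = sb.ModelSpec(traits=["t"], trait_models={"t": sb.TraitModel(["cg"], [])})
        d = build_design(pheno, spec, "t", ped)
        df = pheno.data[pheno.data["t"].notna()]
        X = d.Xa.toarray()[ped.index_of(df["animal"])]
        for j, name in enumerate(d.columns[1:], start=1):
            lev = int(name.split("[")[1][:-1])
            assert X[:, j].sum() == (df["cg"] == lev).sum()

    def test_animal_not_in_pedigree(self, trio_pedigree):
        data = pd.DataFrame({"animal": ["99"], "t": [1.0]})
        pheno = sb.PhenotypeTable(data=data, traits=["t"])
        spec = sb.ModelSpec(traits=["t"], trait_models={"t": sb.TraitModel()})
        with pytest.raises(KeyError):
            build_design(pheno, spec, "t", trio_pedigree)


class TestAssembleSolve:
    def test_two_unrelated_animals_closed_form(self, trio_pedigree):
        # mean + animal, h2 = 0.5: EBV = 0.5 (y - ybar) for two founders
        data = pd.DataFrame({"animal": ["1", "2"], "t": [4.0, 8.0]})
        pheno = sb.PhenotypeTable(data=data, traits=["t"])
        spec = sb.ModelSpec(traits=["t"], trait_models={"t": sb.TraitModel()})
        res = sb.evaluate(pheno, spec, VC(1.0, 1.0), sb.a_inverse(trio_pedigree),
                          trio_pedigree, method="direct")
        assert res.ebv.loc["1", "t"] == pytest.approx(0.5 * (4 - 6))
        assert res.ebv.loc["2", "t"] == pytest.approx(0.5 * (8 - 6))

    def test_dense_oracle_multitrait_missing(self, rng):
        ped = sb.pedigree_from_frame(random_pedigree_frame(40, rng))
        pheno = make_pheno(ped, rng, miss=(0.3, 0.5))
        spec = sb.ModelSpec(
            traits=["tA", "tB"],
            trait_models={"tA": sb.TraitModel(["cg"], ["age"]), "tB": sb.TraitModel(["cg"], [])},
        )
        G0 = np.array([[2.0, 0.8], [0.8, 1.0]])
        R0 = np.array([[3.0, 0.5], [0.5, 2.0]])
        designs = [build_design(pheno, spec, t, ped) for t in spec.traits]
        system = assemble_mme(designs, VC(G0, R0), sb.a_inverse(ped))
        x = solve_mme(system, method="direct")
        oracle = dense_mme_oracle(designs, G0, R0, sb.a_matrix(ped).dense())
        assert np.abs(x - oracle).max() < 1e-6

    def test_direct_and_pcg_agree(self, rng):
        ped = sb.pedigree_from_frame(random_pedigree_frame(50, rng))
        pheno = make_pheno(ped, rng, miss=(0.2, 0.2))
        spec = sb.ModelSpec(
            traits=["tA", "tB"],
            trait_models={"tA": sb.TraitModel(["cg"], []), "tB": sb.TraitModel(["cg"], [])},
        )
        designs = [build_design(pheno, spec, t, ped) for t in spec.traits]
        system = assemble_mme(
            designs, VC(np.eye(2) + 0.5, np.eye(2) * 2.0), sb.a_inverse(ped)
        )
        xd = solve_mme(system, method="direct")
        xp = solve_mme(system, method="pcg", tol=1e-12)
        assert np.abs(xd - xp).max() < 1e-6

    def test_identity_system_returns_rhs(self):
        rhs = np.array([1.0, -2.0, 3.0])
        system = MMESystem(
            traits=["t"], lhs_data=sp.identity(3, format="csr"), rhs=rhs,
            G0inv=np.zeros((1, 1)), Kinv=sp.csr_matrix((3, 3)), n_animals=3,
            fixed_offsets={}, u_offset=0, fixed_columns={},
        )
        assert np.allclose(solve_mme(system, method="pcg", tol=1e-12), rhs)

    def test_nonpd_variances_rejected(self, trio_pedigree, rng):
        pheno = make_pheno(trio_pedigree, rng, traits=("tA", "tB"))
        spec = sb.ModelSpec(
            traits=["tA", "tB"],
            trait_models={"tA": sb.TraitModel(), "tB": sb.TraitModel()},
        )
        designs = [build_design(pheno, spec, t, trio_pedigree) for t in spec.traits]
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ModelError, match="positive definite"):
            assemble_mme(designs, VC(bad, np.eye(2)), sb.a_inverse(trio_pedigree))


class TestEvaluate:
    def test_mt_with_zero_covariances_equals_st(self, rng):
        ped = sb.pedigree_from_frame(random_pedigree_frame(60, rng))
        pheno = make_pheno(ped, rng, miss=(0.2, 0.4))
        tm = {"tA": sb.TraitModel(["cg"], []), "tB": sb.TraitModel(["cg"], [])}
        mt = sb.ModelSpec(traits=["tA", "tB"], trait_models=tm, multi_trait=True)
        st = sb.ModelSpec(traits=["tA", "tB"], trait_models=tm, multi_trait=False)
        vc = VC(np.diag([2.0, 1.0]), np.diag([3.0, 2.0]))
        ainv = sb.a_inverse(ped)
        r_mt = sb.evaluate(pheno, mt, vc, ainv, ped, method="direct")
        r_st = sb.evaluate(pheno, st, vc, ainv, ped, method="direct")
        assert np.allclose(r_mt.ebv.to_numpy(), r_st.ebv.to_numpy(), atol=1e-8)
        assert r_mt.model_tag == "MT-BLUP" and r_st.model_tag == "ST-BLUP"

    def test_st_blup_recovers_positive_accuracy(self):
        from stepblup.synthetic import (
            FactorSpec, SimulationConfig, TraitSim, simulate,
        )

        cfg = SimulationConfig(
            traits=[TraitSim("T", h2=0.4, sigma_p=10.0, factors=[FactorSpec("cg", 5)])],
            r_g=np.eye(1), r_e=np.eye(1),
            n_founders=500, n_generations=4, n_males_per_gen=250, n_snps=20,
        )
        ds = simulate(cfg, seed=5)
        spec = sb.ModelSpec(
            traits=["T"], trait_models={"T": sb.TraitModel(["cg"], [])}, multi_trait=False
        )
        res = sb.evaluate(ds.phenotypes, spec, VC(ds.G0, ds.R0),
                          sb.a_inverse(ds.pedigree), ds.pedigree)
        r = np.corrcoef(res.ebv["T"], ds.true_bv["T"])[0, 1]
        assert r > 0.5

    def test_genomic_ebv_differ_from_parent_average(self):
        # genotyped focal animals without phenotypes: H gives within-family
        # deviations that A cannot
        from stepblup.synthetic import hanwoo_like_preset
        from stepblup.lr_validation import FocalSet, make_partial
        from stepblup.varcomp import VarianceComponents

        ds = hanwoo_like_preset(scale=0.02, seed=9)
        vc = VarianceComponents.known(ds.config.trait_names, ds.G0, ds.R0)
        masked = make_partial(ds.phenotypes, FocalSet(ids=ds.focal_ids), "birth")
        ainv = sb.a_inverse(ds.pedigree)
        hinv = sb.build_h_inverse(ds.pedigree, ds.genotypes)
        spec_a = sb.ModelSpec(traits=ds.model_spec.traits,
                              trait_models=ds.model_spec.trait_models)
        res_a = sb.evaluate(masked, spec_a, vc, ainv, ds.pedigree)
        res_h = sb.evaluate(masked, spec_a, vc, hinv, ds.pedigree)
        focal_geno = [a for a in ds.focal_ids if a in set(ds.genotypes.animal_ids)]
        assert len(focal_geno) > 10
        da = res_a.ebv.loc[focal_geno, "CW"].to_numpy()
        dh = res_h.ebv.loc[focal_geno, "CW"].to_numpy()
        assert np.std(dh - da) > 1e-3
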