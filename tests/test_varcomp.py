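"""Gibbs variance-component estimation: determinism, parameter recovery,
posterior summaries and the equilibrium genetic variance."""

import numpy as np
import pytest

import stepblup as sb
from stepblup.varcomp import GibbsChain, GibbsError, hdi
from stepblup.synthetic import (
    FactorSpec,
    RecordingRule,
    SimulationConfig,
    TraitSim,
    TruncationSelection,
    simulate,
)


def univariate_config(h2=0.5, n_per_gen=400, gens=5, selection=None,
                      sire_fraction=0.2, recording="everyone"):
    # both-sex recording and many sire families: the informative design for
    # estimator-recovery studies, so the check measures the estimator rather
    # than the mating plan (n_records = 2 x n_per_gen x gens for 'everyone')
    return SimulationConfig(
        traits=[TraitSim("T", h2=h2, sigma_p=10.0,
                         recording=RecordingRule(recording),
                         factors=[FactorSpec("cg", 8)])],
        r_g=np.eye(1), r_e=np.eye(1),
        n_founders=2 * n_per_gen, n_generations=gens, n_males_per_gen=n_per_gen,
        sire_fraction=sire_fraction, n_snps=20, architecture="pedigree",
        selection=selection,
    )


@pytest.fixture(scope="module")
def univariate_chain():
    """Shared chain: h2=0.5 trait, 2,000 phenotyped animals."""
    ds = simulate(univariate_config(n_per_gen=200), seed=11)
    gc = sb.GibbsConfig(n_iterations=5000, burn_in=1500, thinning=5, seed=3)
    chain = sb.gibbs_sample(
        ds.phenotypes, ds.model_spec, sb.a_inverse(ds.pedigree), gc, ds.pedigree,
        store_bv_ids=list(ds.focal_ids),
    )
    return ds, chain


class TestSampler:
    def test_seeded_chain_is_reproducible(self):
        ds = simulate(univariate_config(n_per_gen=60, gens=3), seed=2)
        gc = sb.GibbsConfig(n_iterations=300, burn_in=50, thinning=2, seed=7)
        ainv = sb.a_inverse(ds.pedigree)
        c1 = sb.gibbs_sample(ds.phenotypes, ds.model_spec, ainv, gc, ds.pedigree)
        c2 = sb.gibbs_sample(ds.phenotypes, ds.model_spec, ainv, gc, ds.pedigree)
        assert np.array_equal(c1.G0_draws, c2.G0_draws)
        assert np.array_equal(c1.R0_draws, c2.R0_draws)

    def test_univariate_h2_recovery(self, univariate_chain):
        ds, chain = univariate_chain
        vc = sb.posterior_summary(chain)
        assert vc.heritability[0] == pytest.approx(0.5, abs=0.05)

    def test_bivariate_genetic_correlation_recovery(self):
        rg = 0.8
        cfg = SimulationConfig(
            traits=[
                TraitSim("T1", h2=0.4, sigma_p=5.0, factors=[FactorSpec("cg1", 6)]),
                TraitSim("T2", h2=0.5, sigma_p=8.0, factors=[FactorSpec("cg2", 6)]),
            ],
            r_g=np.array([[1, rg], [rg, 1]]),
            r_e=np.array([[1, 0.2], [0.2, 1]]),
            n_founders=700, n_generations=5, n_males_per_gen=350,
            n_snps=20, architecture="pedigree",
        )
        ds = simulate(cfg, seed=31)
        gc = sb.GibbsConfig(n_iterations=6000, burn_in=1500, thinning=5, seed=13)
        chain = sb.gibbs_sample(
            ds.phenotypes, ds.model_spec, sb.a_inverse(ds.pedigree), gc, ds.pedigree
        )
        vc = sb.posterior_summary(chain)
        assert vc.genetic_correlation[0, 1] == pytest.approx(rg, abs=0.07)

    def test_posterior_ratio_matches_reml_oracle(self):
        """Flat-ish priors, balanced univariate data: posterior mean of the
        variance ratio within 10% of a dense REML point estimate."""
        ds = simulate(univariate_config(n_per_gen=250, gens=4), seed=17)
        ped = ds.pedigree
        gc = sb.GibbsConfig(n_iterations=6000, burn_in=1500, thinning=5, seed=23)
        chain = sb.gibbs_sample(ds.phenotypes, ds.model_spec, sb.a_inverse(ped),
                                gc, ped)
        lam_post = float(
            np.mean(chain.G0_draws[:, 0, 0] / (chain.G0_draws[:, 0, 0] + chain.R0_draws[:, 0, 0]))
        )

        # independent dense REML on the phenotyped animals' marginal model
        from scipy.optimize import minimize_scalar

        df = ds.phenotypes.data
        idx = ped.index_of(df["animal"])
        A = sb.a_matrix(ped).dense()[np.ix_(idx, idx)]
        y = df["T"].to_numpy()
        X = np.column_stack([np.ones(len(y))] +
                            [(df["cg"] == l).to_numpy(float) for l in sorted(df["cg"].unique())[1:]])
        w, Q = np.linalg.eigh(A)
        yq, Xq = Q.T @ y, Q.T @ X

        def neg_reml(logit):
            h2 = 1 / (1 + np.exp(-logit))
            d = h2 * w + (1 - h2)  # V / sigma_p^2 eigenvalues
            Xd = Xq / d[:, None]
            XtVX = Xq.T @ Xd
            beta = np.linalg.solve(XtVX, Xd.T @ yq)
            r = yq - Xq @ beta
            n, p = len(y), X.shape[1]
            quad = float(r @ (r / d))
            s2 = quad / (n - p)
            ll = -0.5 * (np.sum(np.log(d)) + (n - p) * np.log(s2)
                         + np.linalg.slogdet(XtVX)[1])
            return -ll

        res = minimize_scalar(neg_reml, bounds=(-4, 4), method="bounded")
        h2_reml = 1 / (1 + np.exp(-res.x))
        assert lam_post == pytest.approx(h2_reml, rel=0.10)


class TestSummary:
    def _chain(self, G0_draws, R0_draws, bv=None, ids=None):
        return GibbsChain(
            traits=["T"], G0_draws=np.asarray(G0_draws, float).reshape(-1, 1, 1),
            R0_draws=np.asarray(R0_draws, float).reshape(-1, 1, 1),
            bv_draws=bv, store_ids=ids, config=sb.GibbsConfig(n_iterations=10, burn_in=0),
        )

    def test_constant_chain(self):
        vc = sb.posterior_summary(self._chain([2.0] * 5, [6.0] * 5))
        assert vc.G0[0, 0] == pytest.approx(2.0)
        assert vc.heritability[0] == pytest.approx(0.25)

    def test_two_draw_mean_is_midpoint(self):
        vc = sb.posterior_summary(self._chain([1.0, 3.0], [1.0, 1.0]))
        assert vc.G0[0, 0] == pytest.approx(2.0)

    def test_empty_chain_rejected(self):
        with pytest.raises(GibbsError, match="empty"):
            sb.posterior_summary(self._chain([], []))

    def test_hdi_matches_bruteforce_scan(self, rng):
        draws = rng.gamma(2.0, 1.0, size=400)
        lo, hi = hdi(draws, 0.9)
        # brute force over all contiguous windows of sorted draws
        x = np.sort(draws)
        m = int(np.ceil(0.9 * len(x)))
        widths = [(x[i + m] - x[i], x[i], x[i + m]) for i in range(len(x) - m)]
        bw, blo, bhi = min(widths)
        assert (lo, hi) == (pytest.approx(blo), pytest.approx(bhi))
        inside = np.mean((draws >= lo) & (draws <= hi))
        assert inside >= 0.9


class TestEquilibriumVariance:
    def test_constant_equal_bvs_zero(self):
        chain = GibbsChain(
            traits=["T"], G0_draws=np.ones((1, 1, 1)), R0_draws=np.ones((1, 1, 1)),
            bv_draws=np.full((1, 5, 1), 3.14), store_ids=np.array(list("abcde"), dtype=object),
            config=sb.GibbsConfig(n_iterations=10, burn_in=0),
        )
        assert sb.equilibrium_genetic_variance(chain, list("abcde"))[0] == pytest.approx(0.0)

    def test_missing_storage_instructs(self, univariate_chain):
        ds, chain = univariate_chain
        bare = GibbsChain(traits=chain.traits, G0_draws=chain.G0_draws,
                          R0_draws=chain.R0_draws, bv_draws=None, store_ids=None,
                          config=chain.config)
        with pytest.raises(GibbsError, match="store_bv_ids"):
            sb.equilibrium_genetic_variance(bare, ["a"])

    def test_unselected_near_base_variance(self, univariate_chain):
        ds, chain = univariate_chain
        eq = sb.equilibrium_genetic_variance(chain, list(ds.focal_ids))[0]
        # focal-cohort variance is slightly below sigma2_u through relatedness
        assert eq == pytest.approx(ds.G0[0, 0], rel=0.35)

    def test_selection_shrinks_equilibrium_variance(self):
        """Strong truncation of sires on a phenotypic index (Bulmer effect):
        the selected cohort's genetic variance drops below the unselected
        cohort's, and the Gibbs-based sigma2_u_inf stays below the base
        additive variance."""
        kw = dict(n_per_gen=600, gens=6, sire_fraction=0.05)
        base = simulate(univariate_config(**kw), seed=42)
        sel = simulate(
            univariate_config(selection=TruncationSelection(proportion=0.08), **kw),
            seed=42,
        )
        v_base = np.var(base.true_bv.loc[base.focal_ids, "T"], ddof=1)
        v_sel = np.var(sel.true_bv.loc[sel.focal_ids, "T"], ddof=1)
        assert v_sel < v_base
        gc = sb.GibbsConfig(n_iterations=2500, burn_in=800, thinning=5, seed=9)
        chain = sb.gibbs_sample(
            sel.phenotypes, sel.model_spec, sb.a_inverse(sel.pedigree), gc,
            sel.pedigree, store_bv_ids=list(sel.focal_ids),
        )
        eq = sb.equilibrium_genetic_variance(chain, list(sel.focal_ids))[0]
        assert eq < sel.G0[0, 0]

    def test_selected_sires_beat_cohort_mean(self):
        from stepblup.synthetic import simulate_pedigree
        cfg = univariate_config(n_per_gen=200, gens=3,
                                selection=TruncationSelection(proportion=0.2))
        rng = np.random.default_rng(1)
        ped, bv, _ = simulate_pedigree(cfg, rng, G0=np.array([[50.0]]),
                                       R0=np.array([[50.0]]))
        sires = np.unique(ped.sire[ped.sire >= 0])
        non_founder_sires = sires[ped.birth_year[sires] > cfg.base_year]
        cohort = np.isin(ped.birth_year, ped.birth_year[non_founder_sires])
        male = np.isin(ped.sex, ["male", "steer"])
        assert bv[non_founder_sires, 0].mean() > bv[cohort & male, 0].mean()
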