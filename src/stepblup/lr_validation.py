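"""LR (partial/whole) validation of genetic evaluations.

The method compares breeding values estimated from the complete data
("whole", u_w) with those from a dataset in which the focal animals'
phenotypes are masked ("partial", u_p).  For the focal cohort it reports

* accuracy  rho = cov(u_w, u_p) / ((1 + Fbar + 2 fbar) sigma2_u_inf),
* bias      mu  = mean(u_p) - mean(u_w)    (0 when unbiased),
* dispersion b  = cov(u_w, u_p) / var(u_p) (1 without over/under-dispersion),

where Fbar and 2 fbar are the cohort's average inbreeding and average
pairwise relationship and sigma2_u_inf the equilibrium genetic variance.
As printed, rho is a covariance over a variance and therefore lives on a
squared-accuracy scale; ``square_root=True`` returns its square root,
and the sign of the 2 fbar term is switchable (some published forms of
the method subtract it).  Covariances and variances use the n-1 divisor.

Two masking stages reflect when an evaluation is run: at *birth* the
focal animals contribute no phenotypes at all; at *yearling* their
yearling weight and ultrasound records are kept and only the carcass
records (slaughter traits) are masked.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .linear_model import (
    CARCASS_TRAITS,
    EvaluationResult,
    PhenotypeTable,
    evaluate,
)
from .pedigree import CohortSummary, Pedigree, a_matrix, cohort_summary

STAGES = ("birth", "yearling")


class ValidationError(ValueError):
    pass


@dataclass
class FocalSet:
    ids: np.ndarray
    rule: str = ""

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        if self.ids.size == 0:
            raise ValidationError("focal set is empty")


def focal_last_cohorts(ped: Pedigree, n_years: int = 2, recorded: np.ndarray | None = None) -> FocalSet:
    """Focal cohort: animals born in the last ``n_years`` birth years."""
    mask = np.ones(ped.n, dtype=bool) if recorded is None else recorded
    years = np.unique(ped.birth_year[mask])
    take = years[-n_years:]
    return FocalSet(
        ids=ped.ids[mask & np.isin(ped.birth_year, take)],
        rule=f"birth_year in {sorted(take.tolist())}",
    )


def make_partial(
    pheno: PhenotypeTable, focal: FocalSet, stage: str,
    carcass_traits=CARCASS_TRAITS,
) -> PhenotypeTable:
    """Mask focal phenotypes for a validation stage.

    ``birth`` masks every trait of focal animals; ``yearling`` masks only
    the carcass traits, keeping the focal animals' yearling weight and
    ultrasound records.  Non-focal rows are returned untouched.
    """
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = pheno.copy()
    hit = out.data["animal"].isin(set(focal.ids.tolist()))
    if stage == "birth":
        cols = list(pheno.traits)
    else:
        cols = [tr for tr in pheno.traits if tr in carcass_traits]
    out.data.loc[hit, cols] = np.nan
    return out


def _aligned(u_w, u_p):
    u_w = np.asarray(u_w, dtype=np.float64)
    u_p = np.asarray(u_p, dtype=np.float64)
    if u_w.shape != u_p.shape or u_w.ndim != 1:
        raise ValidationError("whole/partial EBV vectors must be aligned 1-d arrays")
    if u_w.size < 2:
        raise ValidationError("need at least two focal animals")
    return u_w, u_p


def lr_accuracy(
    u_w, u_p, cohort: CohortSummary, sigma2_u_inf: float,
    square_root: bool = False, f_term_sign: int = +1,
) -> float:
    """rho = cov(u_w, u_p) / ((1 + Fbar +/- 2 fbar) sigma2_u_inf)."""
    u_w, u_p = _aligned(u_w, u_p)
    denom = (
        1.0 + cohort.mean_inbreeding
        + f_term_sign * cohort.mean_pairwise_relationship
    ) * sigma2_u_inf
    if denom <= 0:
        raise ValidationError(f"non-positive accuracy denominator ({denom:.3e})")
    rho = float(np.cov(u_w, u_p, ddof=1)[0, 1] / denom)
    return float(np.sqrt(rho)) if square_root else rho


def lr_bias(u_w, u_p) -> float:
    """mu = mean(u_p) - mean(u_w)."""
    u_w, u_p = _aligned(u_w, u_p)
    return float(np.mean(u_p) - np.mean(u_w))


def lr_dispersion(u_w, u_p) -> float:
    """b = cov(u_w, u_p) / var(u_p), the slope of u_w regressed on u_p."""
    u_w, u_p = _aligned(u_w, u_p)
    v = np.var(u_p, ddof=1)
    if v <= 0:
        raise ValidationError("partial EBVs have zero variance")
    return float(np.cov(u_w, u_p, ddof=1)[0, 1] / v)


@dataclass
class RelativeGain:
    ratio: float
    gain: float  # ratio - 1


def relative_gain(rho_ref: float, rho_other: float) -> RelativeGain:
    """Accuracy ratio rho_ref / rho_other and the gain (ratio - 1)."""
    if rho_other == 0:
        raise ValidationError("reference accuracy is zero")
    r = rho_ref / rho_other
    return RelativeGain(ratio=float(r), gain=float(r - 1.0))


@dataclass
class LRReport:
    """Tidy per (trait, model, scenario) LR statistics + cohort constants."""

    table: pd.DataFrame  # columns: trait, model_tag, scenario, rho, rho_sqrt, mu, b
    cohort: CohortSummary
    sigma2_u_inf: dict  # trait -> equilibrium genetic variance
    gains: pd.DataFrame | None = None  # pairwise accuracy ratios per trait/scenario
    evaluations: list | None = None  # EvaluationResult objects when kept

    def write(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def constants_json(self) -> dict:
        return {
            "mean_inbreeding": self.cohort.mean_inbreeding,
            "mean_pairwise_relationship": self.cohort.mean_pairwise_relationship,
            "n_focal": int(len(self.cohort.cohort_ids)),
            "sigma2_u_inf": {k: float(v) for k, v in self.sigma2_u_inf.items()},
        }


def run_validation(
    ped: Pedigree,
    pheno: PhenotypeTable,
    models: list,
    scenarios: list,
    focal: FocalSet,
    vc,
    kinv_map: dict,
    sigma2_u_inf: dict | None = None,
    reference_tag: str = "MT-ssGBLUP",
    solver_tol: float = 1e-8,
    carcass_traits=CARCASS_TRAITS,
    keep_evaluations: bool = False,
) -> LRReport:
    """Whole vs partial evaluations for every model x masking stage.

    ``models`` are ModelSpec objects; ``vc`` holds the (t x t) G0/R0 used
    by every evaluator (multi-trait as estimated, single-trait with
    covariances zeroed); ``kinv_map`` maps relationship_source ->
    RelationshipMatrix.  ``sigma2_u_inf`` defaults to the diagonal of G0
    (no-selection equilibrium); pass the Gibbs-based per-trait estimates
    to account for selection.
    """
    focal_idx = ped.index_of(focal.ids)
    cs = cohort_summary(a_matrix(ped, subset=list(focal.ids)))
    traits = list(models[0].traits)
    if sigma2_u_inf is None:
        G0 = np.atleast_2d(np.asarray(vc.G0))
        sigma2_u_inf = {tr: float(G0[k, k]) for k, tr in enumerate(traits)}

    partials = {
        stage: make_partial(pheno, focal, stage, carcass_traits=carcass_traits)
        for stage in scenarios
    }

    rows = []
    acc = {}
    kept = [] if keep_evaluations else None
    # single-trait systems depend only on that trait's records, which are
    # often identical across datasets (e.g. a carcass trait sees the same
    # records at the birth and yearling stages); cache those solves
    st_cache: dict = {}

    def _fingerprint(table: PhenotypeTable, trait: str) -> tuple:
        col = table.data[trait]
        m = col.notna().to_numpy()
        return (
            trait,
            hash(tuple(table.data.loc[m, "animal"])),
            hash(col[m].to_numpy().tobytes()),
        )

    def _evaluate(table, spec, svc, kinv, tag):
        if spec.multi_trait:
            return evaluate(table, spec, svc, kinv, ped, scenario_tag=tag, tol=solver_tol)
        cols = {}
        fixed = {}
        for k, tr in enumerate(spec.traits):
            key = (spec.model_tag, _fingerprint(table, tr))
            if key not in st_cache:
                sub = evaluate(
                    table, spec.single_trait(tr),
                    _single_vc(svc, k), kinv, ped, scenario_tag=tag, tol=solver_tol,
                )
                st_cache[key] = (sub.ebv[tr], sub.fixed_solutions[tr])
            cols[tr], fixed[tr] = st_cache[key]
        ebv = pd.DataFrame(cols, index=pd.Index(ped.ids, name="animal"))
        return EvaluationResult(
            ebv=ebv[list(spec.traits)], fixed_solutions=fixed,
            model_tag=spec.model_tag, scenario_tag=tag,
        )

    for spec in models:
        svc = vc if spec.multi_trait else _diagonal_vc(vc)
        kinv = kinv_map[spec.relationship_source]
        whole = _evaluate(pheno, spec, svc, kinv, "whole")
        if kept is not None:
            kept.append(whole)
        for stage in scenarios:
            part = _evaluate(partials[stage], spec, svc, kinv, f"partial_{stage}")
            if kept is not None:
                kept.append(part)
            for tr in spec.traits:
                u_w = whole.ebv[tr].to_numpy()[focal_idx]
                u_p = part.ebv[tr].to_numpy()[focal_idx]
                rho = lr_accuracy(u_w, u_p, cs, sigma2_u_inf[tr])
                rows.append(
                    {
                        "trait": tr,
                        "model_tag": spec.model_tag,
                        "scenario": stage,
                        "rho": rho,
                        "rho_sqrt": float(np.sqrt(max(rho, 0.0))),
                        "mu": lr_bias(u_w, u_p),
                        "b": lr_dispersion(u_w, u_p),
                    }
                )
                acc[(tr, spec.model_tag, stage)] = rho

    table = pd.DataFrame(rows)
    gain_rows = []
    tags = [m.model_tag for m in models]
    if reference_tag in tags:
        for tr, stage in product(traits, scenarios):
            for tag in tags:
                if tag == reference_tag:
                    continue
                key_ref = (tr, reference_tag, stage)
                key_i = (tr, tag, stage)
                if key_ref in acc and key_i in acc and acc[key_i] > 0:
                    g = relative_gain(acc[key_ref], acc[key_i])
                    gain_rows.append(
                        {
                            "trait": tr,
                            "scenario": stage,
                            "model_tag": tag,
                            "reference": reference_tag,
                            "ratio": g.ratio,
                            "gain": g.gain,
                        }
                    )
    gains = pd.DataFrame(gain_rows) if gain_rows else None
    return LRReport(
        table=table, cohort=cs, sigma2_u_inf=sigma2_u_inf, gains=gains,
        evaluations=kept,
    )


def _single_vc(vc, k: int):
    from .varcomp import VarianceComponents

    G0 = np.atleast_2d(np.asarray(vc.G0))
    R0 = np.atleast_2d(np.asarray(vc.R0))
    traits = list(getattr(vc, "traits", range(G0.shape[0])))
    return VarianceComponents.known(
        [traits[k]], G0[k : k + 1, k : k + 1], R0[k : k + 1, k : k + 1]
    )


def _diagonal_vc(vc):
    from .varcomp import VarianceComponents

    G0 = np.atleast_2d(np.asarray(vc.G0))
    R0 = np.atleast_2d(np.asarray(vc.R0))
    traits = getattr(vc, "traits", [f"t{i}" for i in range(G0.shape[0])])
    return VarianceComponents.known(traits, np.diag(np.diag(G0)), np.diag(np.diag(R0)))
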