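"""End-to-end study orchestration.

A *study* is: obtain data (synthetic preset or files on disk), QC the
genotypes, estimate variance components (Gibbs) or take them as given,
evaluate breeding values under the requested models, and validate every
model x masking stage with the LR method.  All stage outputs are plain
CSV/JSON files in the output directory plus a run manifest; all
randomness flows from one root seed split per stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomic import (
    GenotypeMatrix,
    HInverseParts,
    h_inverse,
    qc_filter,
    read_raw,
    vanraden_g,
)
from .linear_model import ModelSpec, PhenotypeTable, TraitModel
from .lr_validation import FocalSet, run_validation
from .pedigree import Pedigree, a_inverse, a_matrix, read_pedigree
from .synthetic import hanwoo_like_preset
from .varcomp import (
    GibbsConfig,
    VarianceComponents,
    equilibrium_genetic_variance,
    gibbs_sample,
    posterior_summary,
)

log = logging.getLogger("stepblup")

MODEL_TAGS = ("ST-BLUP", "MT-BLUP", "ST-ssGBLUP", "MT-ssGBLUP")


class StudyError(RuntimeError):
    pass


@dataclass
class StudyConfig:
    """Configuration of a full study run."""

    out: str = "study_out"
    seed: int = 1
    scale: float = 0.05
    data_dir: str | None = None  # load files instead of simulating
    models: tuple = MODEL_TAGS
    scenarios: tuple = ("birth", "yearling")
    vc_mode: str = "gibbs"  # or "given" (generating truth / vc.json)
    gibbs: dict = field(default_factory=dict)  # GibbsConfig overrides
    qc: dict = field(default_factory=dict)  # qc_filter overrides
    solver_tol: float = 1e-8
    blend_weight: float = 0.95
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.models or not self.scenarios:
            raise StudyError("need at least one model and one scenario")
        bad = [m for m in self.models if m not in MODEL_TAGS]
        if bad:
            raise StudyError(f"unknown model tags: {bad}")
        bad = [s for s in self.scenarios if s not in ("birth", "yearling")]
        if bad:
            raise StudyError(f"unknown scenarios: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("_comment", None)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        return cls(**raw)


def _stage_seeds(root: int, n: int = 8) -> list:
    ss = np.random.SeedSequence(root)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def spec_for_tag(tag: str, base: ModelSpec) -> ModelSpec:
    st, kind = tag.split("-")
    return ModelSpec(
        traits=list(base.traits),
        trait_models={tr: base.trait_models[tr] for tr in base.traits},
        relationship_source="H_inv" if kind == "ssGBLUP" else "A_inv",
        multi_trait=(st == "MT"),
    )


def write_model_spec(spec: ModelSpec, path) -> None:
    obj = {
        "traits": list(spec.traits),
        "trait_models": {
            tr: {"factors": tm.factors, "covariates": tm.covariates}
            for tr, tm in spec.trait_models.items()
        },
    }
    Path(path).write_text(json.dumps(obj, indent=2))


def read_model_spec(path) -> ModelSpec:
    obj = json.loads(Path(path).read_text())
    return ModelSpec(
        traits=obj["traits"],
        trait_models={
            tr: TraitModel(factors=tm["factors"], covariates=tm["covariates"])
            for tr, tm in obj["trait_models"].items()
        },
    )


@dataclass
class StudyData:
    """Everything the evaluation stages consume."""

    ped: Pedigree
    pheno: PhenotypeTable
    geno: GenotypeMatrix
    base_spec: ModelSpec
    focal: FocalSet
    vc_true: VarianceComponents | None = None


def simulate_stage(cfg: StudyConfig, outdir: Path, seed: int) -> StudyData:
    ds = hanwoo_like_preset(scale=cfg.scale, seed=seed)
    ds.write(outdir / "data")
    write_model_spec(ds.model_spec, outdir / "data" / "model_spec.json")
    vc = VarianceComponents.known(ds.config.trait_names, ds.G0, ds.R0)
    vc.to_json(outdir / "data" / "vc_true.json")
    log.info("simulate: %d pedigree animals, %d genotyped, %d SNPs (seed=%d)",
             ds.pedigree.n, ds.genotypes.n_animals, ds.genotypes.n_snps, seed)
    return StudyData(
        ped=ds.pedigree,
        pheno=ds.phenotypes,
        geno=ds.genotypes,
        base_spec=ds.model_spec,
        focal=FocalSet(ids=ds.focal_ids, rule="last two birth-year cohorts"),
        vc_true=vc,
    )


def load_stage(data_dir: Path) -> StudyData:
    ped = read_pedigree(data_dir / "pedigree.csv")
    spec = read_model_spec(data_dir / "model_spec.json")
    pheno = PhenotypeTable(
        data=pd.read_csv(data_dir / "phenotypes.csv", dtype={"animal": str}),
        traits=spec.traits,
    )
    geno = read_raw(data_dir / "genotypes.raw")
    focal_df = pd.read_csv(data_dir / "focal_animals.csv", dtype={"animal": str})
    vc = None
    vc_path = data_dir / "vc_true.json"
    if vc_path.exists():
        obj = json.loads(vc_path.read_text())
        vc = VarianceComponents.known(obj["traits"], np.array(obj["G0"]), np.array(obj["R0"]))
    return StudyData(
        ped=ped, pheno=pheno, geno=geno, base_spec=spec,
        focal=FocalSet(ids=focal_df["animal"].to_numpy(dtype=object)),
        vc_true=vc,
    )


def build_kinv_map(data: StudyData, cfg: StudyConfig, outdir: Path) -> dict:
    ainv = a_inverse(data.ped)
    kinv = {"A_inv": ainv}
    if any(m.endswith("ssGBLUP") for m in cfg.models):
        geno, report = qc_filter(data.geno, **cfg.qc)
        report.to_json(outdir / "qc_report.json")
        log.info("qc: kept %d of %d SNPs", report.n_retained, report.n_input_snps)
        a22 = a_matrix(data.ped, subset=list(geno.animal_ids))
        G = vanraden_g(geno)
        kinv["H_inv"] = h_inverse(
            HInverseParts(
                A_inv=ainv, A22=a22, G=G,
                genotyped_index=data.ped.index_of(geno.animal_ids),
                blend_weight=cfg.blend_weight,
            )
        )
    return kinv


def variance_stage(data: StudyData, cfg: StudyConfig, kinv_map: dict,
                   outdir: Path, seed: int):
    """Variance components for the evaluators + sigma2_u_inf per trait."""
    if cfg.vc_mode == "given":
        if data.vc_true is None:
            raise StudyError("vc_mode 'given' but no vc_true.json available")
        vc = data.vc_true
        sigma2 = None
        log.info("varcomp: using supplied variance components")
    elif cfg.vc_mode == "gibbs":
        gc = GibbsConfig(**{"seed": seed, **cfg.gibbs})
        spec = ModelSpec(
            traits=data.base_spec.traits,
            trait_models=data.base_spec.trait_models,
            relationship_source="A_inv",
            multi_trait=True,
        )
        chain = gibbs_sample(
            data.pheno, spec, kinv_map["A_inv"], gc, data.ped,
            store_bv_ids=list(data.focal.ids),
        )
        chain.write(outdir / "gibbs_chain.csv")
        vc = posterior_summary(chain)
        vc.to_json(outdir / "varcomp.json")
        eq = equilibrium_genetic_variance(chain, list(data.focal.ids))
        sigma2 = {tr: float(eq[k]) for k, tr in enumerate(spec.traits)}
        log.info("varcomp: gibbs chain of %d retained draws (seed=%d)",
                 chain.n_draws, seed)
        for tr, diag in chain.diagnostics.items():
            log.info("varcomp: %s geweke_z=%.2f ess=%.0f", tr,
                     diag["geweke_z"], diag["ess_h2"])
    else:
        raise StudyError(f"unknown vc_mode {cfg.vc_mode!r}")
    return vc, sigma2


def run_study(cfg: StudyConfig) -> dict:
    """Run the full study; returns the manifest dictionary."""
    logging.basicConfig(level=cfg.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "stages": {},
        "outputs": [],
    }

    def _stage(name, fn):
        t0 = time.perf_counter()
        res = fn()
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"seconds": round(dt, 3)}
        log.info("stage %s finished in %.2fs", name, dt)
        return res

    try:
        if cfg.data_dir is not None:
            data = _stage("load", lambda: load_stage(Path(cfg.data_dir)))
        else:
            data = _stage("simulate", lambda: simulate_stage(cfg, outdir, seeds[0]))
        kinv_map = _stage("relationships", lambda: build_kinv_map(data, cfg, outdir))
        vc, sigma2 = _stage(
            "varcomp", lambda: variance_stage(data, cfg, kinv_map, outdir, seeds[1])
        )
        models = [spec_for_tag(tag, data.base_spec) for tag in cfg.models]

        def _validate():
            report = run_validation(
                data.ped, data.pheno, models, list(cfg.scenarios), data.focal,
                vc, kinv_map, sigma2_u_inf=sigma2, solver_tol=cfg.solver_tol,
                keep_evaluations=True,
            )
            return report

        report = _stage("validate", _validate)
        report.write(outdir / "lr_report.csv")
        if report.gains is not None:
            report.gains.to_csv(outdir / "relative_gains.csv", index=False,
                                float_format="%.10g")
        (outdir / "lr_constants.json").write_text(
            json.dumps(report.constants_json(), indent=2)
        )
        for ev in report.evaluations or []:
            ev.write(outdir / f"ebv_{ev.model_tag}_{ev.scenario_tag}.csv")
    except Exception:
        log.exception("study failed; partial outputs preserved in %s", outdir)
        raise

    manifest["outputs"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
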