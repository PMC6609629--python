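"""End-to-end pipeline orchestration.

Ties the stages together in the order the analysis runs them:
simulate (or load) -> DEG-list intersection -> signature discovery ->
classifier training -> transfer evaluation -> survival association ->
enrichment. Every intermediate artifact is persisted as JSON/TSV and a
single ``run_report.json`` summarizes the run. All randomness flows from
one seed through stage-keyed substreams, so identical configs reproduce
byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import evaluate_on_cohort, train_stratification_model
from .data_model import (
    ExpressionMatrix,
    SampleAnnotation,
    differential_expression,
    quantile_normalize,
    read_annotation_table,
    read_expression_table,
    standardize_genes,
)
from .enrichment import nes_permutation_test
from .intersect import GeneList, intersect_gene_lists
from .signature import PruneConfig, discover_signature
from .simulate import (
    DEGSpec,
    SimulationConfig,
    hotpam_like_config,
    simulate_deg_lists,
    simulate_expression_cohort,
    simulate_survival_times,
)
from .survival import cox_backward_select, dichotomize_expression, log_rank_test

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a full pipeline run.

    ``expression_path``/``annotation_path`` load a real cohort; when absent
    the synthetic preset generates both the training and an independent
    transfer cohort from ``seed``-derived substreams.
    """

    seed: int = 0
    out_dir: str = "pipeline_out"
    expression_path: str | None = None
    annotation_path: str | None = None
    stages: tuple[str, ...] = (
        "simulate",
        "intersect",
        "discover",
        "train",
        "evaluate",
        "survival",
        "enrichment",
    )
    deg_spec: tuple[int, int, int, float] = (536, 2677, 87, 0.8)
    k_extreme: int | None = None
    min_size: int = 2
    epsilon: float = 1e-6
    paper_strict: bool = False
    prune_metric: str = "t"
    n_perm: int = 200
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "deg_spec" in raw:
            raw["deg_spec"] = tuple(raw["deg_spec"])
        return cls(**raw)


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order, persisting every artifact.

    Returns the run report (also written to ``run_report.json``). A stage
    that needs a missing upstream artifact fails fast with a clear message;
    artifacts written before a failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_echo = asdict(cfg)
    cfg_echo.pop("out_dir")  # keep artifacts byte-identical across output paths
    report: dict = {"version": __version__, "seed": cfg.seed, "config": cfg_echo, "stages": {}}
    state: dict = {}

    def require(key: str, needed_by: str):
        if key not in state:
            raise RuntimeError(
                f"stage {needed_by!r} needs artifact {key!r}; enable the stage that produces it"
            )
        return state[key]

    try:
        if "simulate" in cfg.stages and cfg.expression_path is None:
            sim_cfg = hotpam_like_config(seed=cfg.seed)
            study = simulate_expression_cohort(sim_cfg)
            ann = simulate_survival_times(sim_cfg, study)
            study = replace(study, annotation=ann)
            transfer_cfg = hotpam_like_config(seed=cfg.seed + 1_000_003)
            transfer = simulate_expression_cohort(transfer_cfg)
            study.write(out / "study")
            transfer.write(out / "transfer_study")
            state["study"], state["transfer"] = study, transfer
            state["panel"] = GeneList.from_iterable("panel", study.signature_panel())
            report["stages"]["simulate"] = {
                "n_samples": study.expression.n_samples,
                "n_genes": study.expression.n_genes,
            }
        elif cfg.expression_path is not None:
            expr = read_expression_table(cfg.expression_path)
            ann = read_annotation_table(cfg.annotation_path)
            study = type("L", (), {})()  # lightweight holder for loaded cohorts
            from .simulate import SimulatedStudy

            state["study"] = SimulatedStudy(expr, ann, {"roles": {}}, hotpam_like_config(cfg.seed))
            state["panel"] = GeneList.from_iterable("panel", expr.gene_ids)
            report["stages"]["load"] = {"n_samples": expr.n_samples, "n_genes": expr.n_genes}

        if "intersect" in cfg.stages:
            a, b = simulate_deg_lists(DEGSpec(*cfg.deg_spec), seed=cfg.seed)
            rep = intersect_gene_lists(
                GeneList.from_iterable("proximal_degs", a.genes),
                GeneList.from_iterable("knockdown_degs", b.genes),
            )
            _dump(rep.to_dict(), out / "intersection.json")
            report["stages"]["intersect"] = {
                "size_a": rep.size_a,
                "size_b": rep.size_b,
                "size_intersection": rep.size_intersection,
            }

        if "discover" in cfg.stages:
            study = require("study", "discover")
            std = standardize_genes(study.expression)
            prune_cfg = PruneConfig(
                min_size=cfg.min_size,
                epsilon=cfg.epsilon,
                metric=cfg.prune_metric,
                paper_strict=cfg.paper_strict,
                k_extreme=cfg.k_extreme,
            )
            signature, disc_report = discover_signature(
                std, study.annotation, require("panel", "discover"), prune_cfg
            )
            _dump(signature.to_dict(), out / "signature.json")
            _dump(disc_report, out / "discovery_report.json")
            state["signature"], state["std"] = signature, std
            report["stages"]["discover"] = {
                "n_genes": len(signature.genes),
                "variance_explained_0": signature.final_variance_explained,
                "auc": signature.final_separation.auc,
            }

        if "train" in cfg.stages:
            study = require("study", "train")
            signature = require("signature", "train")
            model, train_report = train_stratification_model(
                require("std", "train"), study.annotation, list(signature.genes), cohort="training"
            )
            model.to_json(out / "model.json")
            _dump(train_report.to_dict(), out / "training_evaluation.json")
            state["model"] = model
            report["stages"]["train"] = {
                "genes": sorted(model.coefficients),
                "aic": model.aic,
                "threshold": model.threshold,
                "balanced_accuracy": train_report.balanced_accuracy,
                "auc": train_report.auc,
                "resubstitution": model.resubstitution,
            }

        if "evaluate" in cfg.stages:
            transfer = require("transfer", "evaluate")
            model = require("model", "evaluate")
            rep = evaluate_on_cohort(
                model, standardize_genes(transfer.expression), transfer.annotation
            )
            _dump(rep.to_dict(), out / "transfer_evaluation.json")
            report["stages"]["evaluate"] = rep.to_dict()

        if "survival" in cfg.stages:
            study = require("study", "survival")
            signature = require("signature", "survival")
            surv = study.annotation.survival("os")
            rows = {}
            for gene in signature.genes:
                groups = dichotomize_expression(study.expression, gene).loc[surv.index]
                lr = log_rank_test(surv["time"], surv["event"], groups)
                rows[gene] = {"chi_square": lr.chi_square, "p": lr.p_value}
            data = surv.copy()
            for gene in signature.genes:
                v = study.expression.values.loc[gene, surv.index]
                data[gene] = (v - v.mean()) / v.std(ddof=1)
            cox, trace = cox_backward_select(data, list(signature.genes), alpha=cfg.alpha)
            _dump(
                {
                    "log_rank": rows,
                    "cox_final": {} if cox is None else cox.table.to_dict(orient="index"),
                    "trace": trace,
                },
                out / "survival.json",
            )
            report["stages"]["survival"] = {
                "n_genes_tested": len(rows),
                "cox_covariates": [] if cox is None else cox.covariates,
            }

        if "enrichment" in cfg.stages:
            study = require("study", "enrichment")
            signature = require("signature", "enrichment")
            res = nes_permutation_test(
                study.expression,
                study.annotation,
                set(signature.genes),
                class_a="metastatic",
                class_b="primary",
                n_perm=cfg.n_perm,
                seed=np.random.default_rng(np.random.SeedSequence([cfg.seed, 99])),
            )
            enr = {
                "es": res.es,
                "nes": res.nes,
                "nominal_p": res.nominal_p,
                "n_permutations": res.n_permutations,
                "set_size": res.set_size,
            }
            _dump(enr, out / "enrichment.json")
            report["stages"]["enrichment"] = enr
    except Exception as exc:
        report["error"] = {"stage": "unknown", "message": str(exc)}
        _dump(report, out / "run_report.json")
        raise
    _dump(report, out / "run_report.json")
    return report
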