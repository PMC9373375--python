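"""End-to-end orchestration: simulate -> ccf -> enrich -> assoc -> survival.

Each stage consumes the previous stage's TSVs and writes its own under the
run's output directory; the run closes with a manifest mapping every file
to its SHA-256 checksum plus a run.log recording per-stage record counts
and skip reasons, so cohort attrition is auditable. Reruns with the same
config and seed produce byte-identical TSVs (floats are formatted at 6
significant digits).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import ccf as ccf_mod
from . import enrichment as enrich_mod
from . import survival as surv_mod
from .io import CohortBundle, clinical_frame, read_cohort
from .simulate import config_from_dict, simulate_cohort, write_cohort

FLOAT_FMT = "%.6g"

log = logging.getLogger("clonarch")


@dataclass
class PipelineConfig:
    out_dir: str = "clonarch_out"
    #: when None, the four input paths must be given instead
    simulation: dict | None = None
    maf: str | None = None
    seg: str | None = None
    purity: str | None = None
    clinical: str | None = None
    stages: dict = field(
        default_factory=lambda: {
            "ccf": True, "enrich": True, "assoc": True, "survival": True
        }
    )
    subclonal_ccf: float = 0.9
    p_subclonal: float = 0.5
    ci_level: float = 0.95
    grid_size: int = 100
    n_perm: int = 1000
    min_patients: int = 5
    bootstrap_b: int = 1000
    both_rule: str = "clonal-dominant"
    seed: int = 7


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a pipeline YAML; reports every violation at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    violations: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            violations.append(f"unknown config key '{key}'")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})

    for name in ("subclonal_ccf", "p_subclonal", "ci_level"):
        v = getattr(cfg, name)
        if not (isinstance(v, (int, float)) and 0.0 < v < 1.0):
            violations.append(f"{name} must be in (0,1), got {v}")
    for name in ("n_perm", "min_patients", "bootstrap_b", "grid_size"):
        v = getattr(cfg, name)
        if not (isinstance(v, int) and v >= 1):
            violations.append(f"{name} must be a positive integer, got {v}")
    if not isinstance(cfg.seed, int):
        violations.append(f"seed must be an integer, got {cfg.seed!r}")
    if cfg.simulation is None:
        for name in ("maf", "seg", "purity", "clinical"):
            p = getattr(cfg, name)
            if p is None:
                violations.append(f"either 'simulation' or input path '{name}' is required")
            elif not Path(p).exists():
                violations.append(f"input path '{name}' does not exist: {p}")
    else:
        try:
            config_from_dict({**cfg.simulation, "seed": cfg.simulation.get("seed", cfg.seed)})
        except (TypeError, ValueError) as exc:
            violations.append(f"invalid simulation config: {exc}")
    if violations:
        return None, violations
    return cfg, []


def write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep="NA")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _setup_log(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    return handler


def run_ccf_stage(bundle: CohortBundle, cfg: PipelineConfig, out: Path) -> ccf_mod.CohortCalls:
    grid = ccf_mod.ccf_grid(cfg.grid_size)
    calls = ccf_mod.call_cohort(
        bundle,
        subclonal_ccf=cfg.subclonal_ccf,
        p_threshold=cfg.p_subclonal,
        ci_level=cfg.ci_level,
        grid=grid,
    )
    write_tsv(calls.calls, out / "calls.tsv")
    write_tsv(ccf_mod.gene_summary_frame(calls.gene_summaries), out / "gene_summary.tsv")
    write_tsv(calls.patient_architecture, out / "patient_architecture.tsv")
    write_tsv(calls.skip_report, out / "skip_report.tsv")
    log.info(
        "ccf: %d mutations classified (%d clonal, %d subclonal), %d skipped",
        len(calls.calls),
        int((calls.calls["label"] == "clonal").sum()),
        int((calls.calls["label"] == "subclonal").sum()),
        len(calls.skip_report),
    )
    return calls


def run_survival_stage(
    categories: pd.DataFrame, clin: pd.DataFrame, cfg: PipelineConfig, out: Path
) -> None:
    scan = surv_mod.gene_survival_scan(categories, clin, min_patients=cfg.min_patients)
    km = pd.DataFrame([r.__dict__ for r in scan])
    write_tsv(km, out / "km_logrank.tsv")

    prognostic = [
        r.gene for r in scan
        if r.eligible and r.p_overall is not None and r.p_overall < 0.05
    ]
    log.info("survival: %d eligible genes with 3-group log-rank p < 0.05", len(prognostic))
    model = clin[["os_time", "os_event"]].copy()
    age = pd.to_numeric(clin["age"], errors="coerce")
    model["age_high"] = (age >= age.median()).astype(float).where(age.notna())
    model["sex_male"] = (clin["sex"] == "male").astype(float).where(clin["sex"].notna())
    model["site_left"] = (
        (clin["tumour_site"] == "left-sided").astype(float).where(clin["tumour_site"].notna())
    )
    model["msi"] = (clin["msi_status"] == "MSI").astype(float).where(clin["msi_status"].notna())
    for col, name, cut in (
        ("ajcc_stage", "stage34", 2),
        ("t_stage", "t34", 2),
        ("n_stage", "n12", 0),
        ("m_stage", "m1", 0),
    ):
        v = pd.to_numeric(clin[col], errors="coerce")
        model[name] = (v > cut).astype(float).where(v.notna())
    groups: dict[str, list[str]] = {}
    for g in prognostic:
        dummies = surv_mod.clonality_dummies(categories, g)
        model = model.join(dummies)
        groups[g] = list(dummies.columns)
    covariates = [c for c in model.columns if c not in ("os_time", "os_event")]
    if not covariates:
        return
    write_tsv(
        surv_mod.cox_univariate(model, covariates, groups=groups).summary.reset_index(
            names="covariate"
        ),
        out / "cox_univariate.tsv",
    )
    write_tsv(
        surv_mod.cox_fit(model, covariates, ph_diagnostic=True).summary.reset_index(
            names="covariate"
        ),
        out / "cox_multivariate.tsv",
    )
    step = surv_mod.stepwise_backward(model, covariates, groups=groups)
    write_tsv(step.summary.reset_index(names="covariate"), out / "cox_stepwise.tsv")
    boot = surv_mod.bootstrap_stability(
        model, covariates, B=cfg.bootstrap_b, seed=cfg.seed, groups=groups
    )
    write_tsv(
        boot.summary.reset_index(names="covariate"), out / "bootstrap_inclusion.tsv"
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns the manifest dict (also written)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(out)
    manifest: dict = {"stages": {}, "files": {}, "seed": cfg.seed}
    try:
        if cfg.simulation is not None:
            sim_cfg = config_from_dict(
                {**cfg.simulation, "seed": cfg.simulation.get("seed", cfg.seed)}
            )
            bundle, truth = simulate_cohort(sim_cfg)
            write_cohort(bundle, truth, out)
            log.info(
                "simulate: %d patients, %d mutations", sim_cfg.n_patients, len(bundle.mutations)
            )
            manifest["stages"]["simulate"] = "ok"
        else:
            bundle, reports = read_cohort(cfg.maf, cfg.seg, cfg.purity, cfg.clinical)
            for name, rep in reports.items():
                log.info("read %s: %d rows, %d kept, %d skipped", name, rep.n_rows,
                         rep.n_kept, rep.n_skipped)
            manifest["stages"]["simulate"] = "skipped"

        calls = None
        if cfg.stages.get("ccf", True):
            calls = run_ccf_stage(bundle, cfg, out)
            manifest["stages"]["ccf"] = "ok"
        else:
            manifest["stages"]["ccf"] = "skipped"

        if cfg.stages.get("enrich", True) and calls is not None and len(calls.calls):
            results = enrich_mod.enrichment_from_calls(
                calls.calls, n_perm=cfg.n_perm, seed=cfg.seed
            )
            write_tsv(enrich_mod.enrichment_frame(results), out / "enrichment.tsv")
            log.info("enrich: %d genes tested", len(results))
            manifest["stages"]["enrich"] = "ok"
        else:
            manifest["stages"]["enrich"] = "skipped"

        if calls is not None and len(calls.calls) and (
            cfg.stages.get("assoc", True) or cfg.stages.get("survival", True)
        ):
            clin = clinical_frame(bundle.clinical)
            categories = assoc_mod.patient_gene_category(
                calls.calls, list(clin.index), rule=cfg.both_rule
            )

            if cfg.stages.get("assoc", True):
                results, matrix = assoc_mod.association_scan(
                    categories, clin, min_patients=cfg.min_patients, seed=cfg.seed
                )
                write_tsv(assoc_mod.association_frame(results), out / "associations.tsv")
                write_tsv(
                    matrix.reset_index(names="gene"), out / "neglog2p_matrix.tsv"
                )
                burden_rows = []
                counts = {
                    "clonal": calls.calls[calls.calls["label"] == "clonal"]
                    .groupby("sample").size().reindex(clin.index, fill_value=0),
                    "subclonal": calls.calls[calls.calls["label"] == "subclonal"]
                    .groupby("sample").size().reindex(clin.index, fill_value=0),
                }
                for var, grouping in assoc_mod.binarize_clinical(clin).items():
                    for kind, cnt in counts.items():
                        for method in ("t-test", "wilcoxon"):
                            p, ok = assoc_mod.burden_compare(cnt, grouping, method)
                            burden_rows.append(
                                {"variable": var, "count_type": kind, "method": method,
                                 "p_value": p, "evaluable": ok}
                            )
                write_tsv(pd.DataFrame(burden_rows), out / "burden_tests.tsv")
                mt = assoc_mod.mutation_type_vs_clonality(calls.calls, "indel")
                mt += assoc_mod.mutation_type_vs_clonality(calls.calls, "nonsense")
                write_tsv(assoc_mod.association_frame(mt), out / "mutation_type_tests.tsv")
                log.info("assoc: %d gene x variable tests", len(results))
                manifest["stages"]["assoc"] = "ok"
            else:
                manifest["stages"]["assoc"] = "skipped"

            if cfg.stages.get("survival", True):
                run_survival_stage(categories, clin, cfg, out)
                manifest["stages"]["survival"] = "ok"
            else:
                manifest["stages"]["survival"] = "skipped"
        else:
            manifest["stages"].setdefault("assoc", "skipped")
            manifest["stages"].setdefault("survival", "skipped")
    except Exception as exc:
        manifest["failed"] = f"stage error: {exc}"
        log.error("pipeline halted: %s", exc)
        _finalize(out, manifest)
        log.removeHandler(handler)
        handler.close()
        raise
    _finalize(out, manifest)
    log.removeHandler(handler)
    handler.close()
    return manifest


def _finalize(out: Path, manifest: dict) -> None:
    for f in sorted(out.glob("*.tsv")):
        manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
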