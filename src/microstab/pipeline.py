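"""End-to-end pipeline: simulate -> qc -> normalize -> diversity -> cst ->
stability -> symptoms -> associate, with a JSON manifest and a plain-text
report.

Every stage writes its outputs as TSV/CSV under the run directory; the
manifest records parameters, seeds, package version and per-stage sample
counts so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import microstab
from microstab import associations, community, diversity, qc, simulate, stability, symptoms
from microstab.tables import GenusCountTable, MetadataTable, align_tables

STAGES = ["simulate", "qc", "normalize", "diversity", "cst",
          "stability", "symptoms", "associate"]


@dataclass
class PipelineConfig:
    """Parameters of a full run; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "microstab_run"
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    qc_threshold: float | None = None  # None -> max blank yield
    css_quantile: float = 0.5
    k: int | str = 7  # number of community types, or 'auto'
    n_perm: int = 999
    persistence_scheme: str = "methods"
    glm_mode: str = "full"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    tables: dict[str, pd.DataFrame]


def _stage_error(stage: str, exc: Exception) -> RuntimeError:
    return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": microstab.__version__,
        "seed": config.seed,
        "stages": {},
        "parameters": {
            "qc_threshold": config.qc_threshold,
            "css_quantile": config.css_quantile,
            "k": config.k,
            "n_perm": config.n_perm,
            "persistence_scheme": config.persistence_scheme,
            "glm_mode": config.glm_mode,
        },
    }
    tables: dict[str, pd.DataFrame] = {}

    # -- simulate ---------------------------------------------------------
    try:
        sim_cfg = simulate.SimConfig(**{"seed": config.seed, **config.sim})
        study = simulate.generate_cohort(sim_cfg)
        study.write(outdir / "synthetic")
        manifest["stages"]["simulate"] = {
            "n_samples": len(study.counts.samples),
            "n_blanks": len(study.blanks.samples),
            "n_subjects": len(study.truth),
            "seed": sim_cfg.seed,
        }
    except Exception as exc:  # pragma: no cover - defensive
        raise _stage_error("simulate", exc)

    # -- qc ---------------------------------------------------------------
    try:
        filtered, report = qc.qc_screen(
            study.counts, study.blanks, threshold=config.qc_threshold
        )
        qc_frame = report.to_frame()
        qc_frame.to_csv(outdir / "qc_report.tsv", sep="\t")
        report.contaminants.to_csv(outdir / "qc_contaminants.tsv", sep="\t")
        tables["qc"] = qc_frame
        manifest["stages"]["qc"] = {
            "threshold": report.threshold,
            "n_in": len(study.counts.samples),
            "n_out": len(filtered.samples),
            "n_excluded": len(report.excluded),
            "mean_coverage": float(report.coverage.mean()),
        }
    except Exception as exc:
        raise _stage_error("qc", exc)

    # -- normalize --------------------------------------------------------
    try:
        norm = diversity.css_normalize(filtered, quantile=config.css_quantile)
        norm.data.to_csv(outdir / "css_normalized.tsv", sep="\t")
        manifest["stages"]["normalize"] = {
            "quantile": config.css_quantile,
            "n_samples": norm.data.shape[1],
        }
    except Exception as exc:
        raise _stage_error("normalize", exc)

    # -- diversity --------------------------------------------------------
    try:
        alpha = diversity.alpha_diversity_table(filtered, tree=study.tree)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        rel = norm.relative_abundance()
        dm = diversity.distance_matrix(norm, metric="braycurtis")
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            outdir / "bray_curtis.tsv", sep="\t"
        )
        tables["alpha"] = alpha
        manifest["stages"]["diversity"] = {
            "metrics": diversity.ALPHA_METRICS, "beta_metric": "braycurtis",
        }
    except Exception as exc:
        raise _stage_error("diversity", exc)

    # -- community typing -------------------------------------------------
    try:
        assignment = community.assign_community_types(rel, k=config.k)
        meta = study.metadata.data.loc[assignment.labels.index]
        summary = community.characterize_cts(
            rel, assignment.labels, cohorts=meta["cohort"]
        )
        assignment.labels.rename("CT").to_csv(outdir / "ct_labels.tsv", sep="\t")
        summary.to_csv(outdir / "ct_summary.tsv", sep="\t")
        tables["ct_summary"] = summary
        tables["ct_labels"] = assignment.labels.to_frame("CT")
        manifest["stages"]["cst"] = {"k": assignment.k, "method": assignment.method}
    except Exception as exc:
        raise _stage_error("cst", exc)

    # -- stability --------------------------------------------------------
    try:
        aligned = align_tables(filtered, study.metadata)
        stab = stability.stability_table(rel, filtered.sample_index)
        subj_cohort = (
            aligned.metadata.data.groupby("subject")["cohort"].first()
        )
        stab["cohort"] = subj_cohort.reindex(stab.index)
        stab.to_csv(outdir / "stability.tsv", sep="\t")
        tables["stability"] = stab
        kw = stability.compare_stability_groups(
            stab["overall_stability"], stab["cohort"]
        )
        manifest["stages"]["stability"] = {
            "n_subjects": len(stab), "kw_cohort_p": kw["p"],
        }
    except Exception as exc:
        raise _stage_error("stability", exc)

    # -- symptoms ---------------------------------------------------------
    try:
        panel = study.symptoms
        presence = symptoms.presence_table(panel)
        persistence = symptoms.persistence_table(
            presence, panel["subject"], scheme=config.persistence_scheme
        )
        presence.to_csv(outdir / "symptom_presence.tsv", sep="\t")
        persistence.to_csv(outdir / "symptom_persistence.tsv", sep="\t")
        meta_all = study.metadata.data
        prevalence = symptoms.symptom_prevalence(
            presence, meta_all["cohort"], meta_all["timepoint"], "T0"
        )
        prevalence.to_csv(outdir / "symptom_prevalence_T0.tsv", sep="\t")
        tables["persistence"] = persistence
        tables["prevalence_T0"] = prevalence
        manifest["stages"]["symptoms"] = {
            "n_subjects": len(persistence),
            "scheme": config.persistence_scheme,
        }
    except Exception as exc:
        raise _stage_error("symptoms", exc)

    # -- associations -----------------------------------------------------
    try:
        meta = aligned.metadata.data
        perm = associations.permanova(
            dm, meta.loc[list(dm.ids), ["cohort"]],
            n_perm=config.n_perm, seed=config.seed,
        )
        perm.to_csv(outdir / "permanova.tsv", sep="\t")
        covars = pd.DataFrame({
            "cohort": subj_cohort.reindex(stab.index),
            "age": meta.groupby("subject")["age"].first().reindex(stab.index),
            "BMI": meta.groupby("subject")["BMI"].first().reindex(stab.index),
            "race": meta.groupby("subject")["race"].first().reindex(stab.index),
            "intercourse_4w": meta.groupby("subject")["intercourse_4w"]
            .mean().reindex(stab.index),
        })
        glm_tables = {}
        for metric in ["overall_stability", "resistance", "resilience"]:
            glm = associations.forward_aic_glm(
                stab[metric], covars, mode=config.glm_mode
            )
            glm.to_csv(outdir / f"glm_{metric}.tsv", sep="\t")
            glm_tables[metric] = glm
        tables["permanova"] = perm
        tables["glm"] = glm_tables
        manifest["stages"]["associate"] = {
            "permanova_cohort_p": float(perm.loc["cohort", "p"]),
            "n_perm": config.n_perm,
            "glm_mode": config.glm_mode,
        }
    except Exception as exc:
        raise _stage_error("associate", exc)

    manifest["n_stages"] = len(manifest["stages"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(outdir=outdir, manifest=manifest, tables=tables)


def render_report(result: PipelineResult) -> str:
    """Human-readable plain-text summary of a pipeline run."""
    m = result.manifest
    lines = [
        "microstab pipeline report",
        "=" * 30,
        f"version {m['version']}  seed {m['seed']}  stages {m['n_stages']}",
        "",
    ]
    for stage in STAGES:
        info = m["stages"].get(stage)
        if info is None:
            lines.append(f"[{stage}] not run")
            continue
        pairs = ", ".join(f"{k}={v}" for k, v in info.items())
        lines.append(f"[{stage}] {pairs}")
    if "ct_summary" in result.tables:
        lines += ["", "Community types:",
                  result.tables["ct_summary"][["n", "pct_of_total"]].to_string()]
    if "stability" in result.tables:
        stab = result.tables["stability"]
        med = stab.groupby("cohort")["overall_stability"].median()
        lines += ["", "Median overall stability (ABC) by cohort:", med.to_string()]
    if "persistence" in result.tables:
        lines += ["", f"Persistence rows: {len(result.tables['persistence'])}"]
    return "\n".join(lines) + "\n"
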