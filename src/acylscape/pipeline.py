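"""End-to-end orchestration: simulate -> quantify -> call -> classify ->
differential -> proportions -> enrichment -> report.

The pipeline is a pure function of its configuration: stage products
are passed in memory, summary tables are written as TSV, and a
machine-readable ``report.json`` records per-stage counts, the config
hash, the seed, and the package version — two runs with the same
config produce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    changed_set_overlap,
    diff_expression,
    diff_modification,
    diurnal_classification,
)
from .enrichment import combination_enrichment, gene_set_enrichment
from .genomic_io import MARKS, read_gene_sets
from .integration import (
    acylation_proportions,
    change_correlation,
    expression_by_category,
    proportion_change,
    total_acylation_by_category,
)
from .marks import call_marked_genes, classify_combinations, marginal_counts
from .quantify import compute_tpm
from .synthetic import CONDITIONS, TREATMENTS, SimulationConfig, simulate

log = logging.getLogger("acylscape")


class PipelineError(RuntimeError):
    """A stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class Thresholds:
    """Every decision threshold of the analysis, in one place."""

    mod_fc: float = 1.5
    epsilon: float = 1.0
    de_fc: float = 4.0
    de_fdr: float = 0.05
    diurnal_fc: float = 2.0
    diurnal_fdr: float = 0.05
    diurnal_min_comparisons: int = 3
    enrich_alpha: float = 0.01
    go_fdr: float = 0.05

    def __post_init__(self):
        for name in ("mod_fc", "epsilon", "de_fc", "de_fdr", "diurnal_fc", "diurnal_fdr", "enrich_alpha", "go_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class RunConfig:
    outdir: str = "acylscape_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    gene_sets_path: str | None = None  # optional term -> gene TSV

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        thr = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(simulation=sim, thresholds=thr, **raw)
        cfg.simulation.seed = cfg.seed
        return cfg

    def validate(self) -> None:
        if self.gene_sets_path is not None and not Path(self.gene_sets_path).exists():
            raise FileNotFoundError(
                f"configured gene_sets_path does not exist: {self.gene_sets_path}"
            )

    def hash(self) -> str:
        """Digest of the analytic configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _replicate_tpm(samples, annotation, mark) -> pd.DataFrame:
    """Gene x replicate body-TPM frame for one mark."""
    cols = [
        compute_tpm(samples[(mark, rep)].track, annotation, "body").matrix
        for rep in (1, 2)
    ]
    return pd.concat(cols, axis=1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on a simulated study; returns the report dict."""
    config.validate()
    config.simulation.seed = config.seed
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "stages": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        name = stage("simulate")
        annotation, truth, chip, expression = simulate(config.simulation)
        report["stages"][name] = {"n_genes": len(annotation)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", exc) from exc

    try:
        name = stage("quantify")
        tpm: dict[str, dict[str, pd.DataFrame]] = {}
        for cond in CONDITIONS:
            tpm[cond] = {m: _replicate_tpm(chip[cond], annotation, m) for m in MARKS}
            for m in MARKS:
                tpm[cond][m].to_csv(outdir / f"tpm.{m}.body.{cond}.tsv", sep="\t")
        report["stages"][name] = {
            "mean_body_tpm_control": {
                m: float(tpm["control"][m].mean(axis=1).mean()) for m in MARKS
            }
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("quantify", exc) from exc

    try:
        name = stage("call_marks")
        statuses = {
            m: call_marked_genes(
                chip["control"][(m, 1)].peaks, chip["control"][(m, 2)].peaks, annotation
            )
            for m in MARKS
        }
        profile = classify_combinations(*[statuses[m] for m in MARKS])
        venn = marginal_counts(profile)
        status_df = pd.DataFrame({m: statuses[m].marked for m in MARKS})
        status_df.to_csv(outdir / "mark_status.tsv", sep="\t")
        profile.labels.to_frame().to_csv(outdir / "combinations.tsv", sep="\t")
        with open(outdir / "venn_counts.json", "w") as fh:
            json.dump(
                {
                    "category_counts": venn["category_counts"],
                    "totals": venn["totals"],
                    "triple": venn["triple"],
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        report["stages"][name] = {
            "category_counts": venn["category_counts"],
            "totals": venn["totals"],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("call_marks", exc) from exc

    try:
        name = stage("differential")
        diffmod: dict[str, dict[str, pd.DataFrame]] = {}
        diffexpr: dict[str, pd.DataFrame] = {}
        counts = {}
        for treat in TREATMENTS:
            diffmod[treat] = {}
            for m in MARKS:
                res = diff_modification(
                    tpm["control"][m], tpm[treat][m], thr.mod_fc, thr.epsilon
                )
                res.to_csv(outdir / f"diffmod.{m}.{treat}.tsv", sep="\t")
                diffmod[treat][m] = res
            de = diff_expression(
                expression.counts["control"],
                expression.counts[treat],
                thr.de_fc,
                thr.de_fdr,
            )
            de.to_csv(outdir / f"diffexpr.{treat}.tsv", sep="\t")
            diffexpr[treat] = de
            counts[treat] = {
                "de_up": int((de["call"] == "up").sum()),
                "de_down": int((de["call"] == "down").sum()),
                **{
                    f"mod_{m}_{d}": int((diffmod[treat][m]["call"] == d).sum())
                    for m in MARKS
                    for d in ("up", "down")
                },
            }
            changed = {
                m: set(
                    diffmod[treat][m].index[diffmod[treat][m]["call"] != "unchanged"]
                )
                for m in MARKS
            }
            changed_set_overlap(changed).to_csv(
                outdir / f"changed_overlap.{treat}.tsv", sep="\t"
            )
        diurnal = diurnal_classification(
            expression.timepoint_counts,
            thr.diurnal_fc,
            thr.diurnal_fdr,
            thr.diurnal_min_comparisons,
        )
        diurnal.table.to_csv(outdir / "diurnal.tsv", sep="\t")
        report["stages"][name] = {
            **counts,
            "n_diurnal": int(diurnal.table["diurnal"].sum()),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("differential", exc) from exc

    try:
        name = stage("proportions")
        props = {}
        for cond in CONDITIONS:
            props[cond] = acylation_proportions(
                *[tpm[cond][m].mean(axis=1) for m in MARKS]
            )
            props[cond].table.to_csv(outdir / f"proportions.{cond}.tsv", sep="\t")
        prop_summary = {}
        correlations = {}
        for treat in TREATMENTS:
            delta, summary = proportion_change(
                props["control"], props[treat], diffexpr[treat]
            )
            delta.to_csv(outdir / f"proportion_change.{treat}.tsv", sep="\t")
            summary.to_csv(outdir / f"proportion_change_summary.{treat}.tsv", sep="\t", index=False)
            prop_summary[treat] = summary.to_dict("records")
            correlations[treat] = {
                m: change_correlation(diffexpr[treat], diffmod[treat][m])
                for m in MARKS
            }
        cat_expr = expression_by_category(
            expression.fpkm["control"].mean(axis=1), profile
        )
        cat_expr.to_csv(outdir / "category_expression.tsv", sep="\t")
        total_acylation_by_category(
            *[tpm["control"][m].mean(axis=1) for m in MARKS], profile
        ).to_csv(outdir / "category_total_acylation.tsv", sep="\t")
        report["stages"][name] = {
            "change_correlation": correlations,
            "proportion_change_summary": prop_summary,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("proportions", exc) from exc

    try:
        name = stage("enrichment")
        enr_report = {}
        for treat in TREATMENTS:
            up = set(diffexpr[treat].index[diffexpr[treat]["call"] == "up"])
            if up:
                enr = combination_enrichment(profile, up, thr.enrich_alpha)
                enr.to_csv(outdir / f"enrichment.up_{treat}.tsv", sep="\t")
                enr_report[f"up_{treat}"] = enr["significant"].sum().item()
        dgenes = diurnal.diurnal_genes
        if dgenes:
            enr = combination_enrichment(profile, dgenes, thr.enrich_alpha)
            enr.to_csv(outdir / "enrichment.diurnal.tsv", sep="\t")
            enr_report["diurnal"] = enr["significant"].sum().item()
        if config.gene_sets_path:
            sets = read_gene_sets(config.gene_sets_path)
            universe = set(annotation.gene_ids)
            for treat in TREATMENTS:
                up = set(diffexpr[treat].index[diffexpr[treat]["call"] == "up"])
                if up:
                    gse = gene_set_enrichment(sets, up, universe, thr.go_fdr)
                    gse.to_csv(outdir / f"go_enrichment.up_{treat}.tsv", sep="\t")
        report["stages"][name] = {"n_significant_categories": enr_report}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("enrichment", exc) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", outdir / "report.json")
    return report
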