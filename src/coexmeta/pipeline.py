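"""End-to-end orchestration: QC -> association -> selection -> prioritization.

``run_pipeline`` ties the stages together on file inputs described by a
:class:`PipelineConfig`, writes every stage's table plus a machine-readable
run manifest (parameters, seed, per-stage counts), and returns the in-memory
results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .association import SeedAssociationMeta
from .clinical import dichotomize_expression, summarize_cohort, survival_by_group
from .enrichment import hypergeom_enrich, prioritize_targets, read_gmt
from .permutation import PermutationFDRSelector
from .qc import run_batch_qc

logger = logging.getLogger("coexmeta")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """File paths and parameters for a full pipeline run."""

    expression_paths: list[str]
    probe_map_path: str
    output_dir: str
    gene_sets_path: str | None = None
    interactions_path: str | None = None
    clinical_path: str | None = None
    exclusion_sets: list[str] = field(default_factory=lambda: ["BCR_SIGNALING"])
    seed_gene: str = "MS4A1"
    qc_threshold: float = 0.8
    qc_score_mode: str = "profiles"
    top_k: int = 500
    perms: int = 1000
    fdr: float = 0.01
    confidence: float = 0.99
    two_sided: bool = False
    level: str = "probe"
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.expression_paths:
            raise ValueError("no expression files configured")
        for p in [*self.expression_paths, self.probe_map_path]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for p in (self.gene_sets_path, self.interactions_path, self.clinical_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 < self.fdr < 1 or not 0 < self.confidence < 1:
            raise ValueError("fdr and confidence must lie in (0, 1)")
        if not -1 <= self.qc_threshold <= 1:
            raise ValueError("qc_threshold must lie in [-1, 1]")
        if self.perms < 1 or self.top_k < 1:
            raise ValueError("perms and top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"].append({"stage": name, **counts})
    logger.info("stage %s: %s", name, counts)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run dedup -> QC -> association -> permutation FDR -> enrichment ->
    prioritization -> (optional) clinical stats; write stage TSVs + manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": config.to_dict(), "stages": []}
    results: dict = {}

    try:
        # --- read inputs ---------------------------------------------------
        batches = [cio.read_expression(p) for p in config.expression_paths]
        probe_map = cio.read_probe_map(config.probe_map_path)
        _stage(manifest, "read", n_batches=len(batches),
               n_samples=sum(b.n_samples for b in batches),
               n_probes=len(probe_map))

        # --- QC (dedup + PCqc outliers), per batch -------------------------
        clean_batches = []
        qc_tables = []
        for b in batches:
            clean, report = run_batch_qc(b, threshold=config.qc_threshold,
                                         score_mode=config.qc_score_mode)
            clean_batches.append(clean)
            t = report.table.copy()
            t.insert(1, "batch", b.batch_id)
            t["pc1_variance_fraction"] = report.pc1_variance_fraction
            qc_tables.append(t)
        qc_table = pd.concat(qc_tables, ignore_index=True)
        qc_table.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        _stage(manifest, "qc",
               n_in=sum(b.n_samples for b in batches),
               n_kept=sum(b.n_samples for b in clean_batches),
               n_removed=int((~qc_table["kept"]).sum()))

        # --- association meta-analysis -------------------------------------
        meta = SeedAssociationMeta(seed_gene=config.seed_gene, top_k=config.top_k,
                                   level=config.level).fit(clean_batches, probe_map)
        meta.table_.to_csv(outdir / "association.tsv", sep="\t", index=False)
        meta.top_.to_csv(outdir / "association_top.tsv", sep="\t", index=False)
        negative = meta.table_[meta.table_["statistic"] < 0].copy()
        negative.to_csv(outdir / "association_negative.tsv", sep="\t", index=False)
        _stage(manifest, "association", n_features=len(meta.table_),
               top_k=len(meta.top_), n_unique_genes=meta.n_unique_genes_)
        results["meta"] = meta

        # --- permutation FDR selection --------------------------------------
        selector = PermutationFDRSelector(
            n_permutations=config.perms, fdr=config.fdr,
            confidence=config.confidence, two_sided=config.two_sided,
            random_state=config.rng_seed,
        ).fit(meta)
        sel = selector.selection_
        sel_table = meta.table_[~meta.table_["is_seed"]].copy()
        sel_table["selected"] = sel_table["probe_id"].isin(set(sel.selected))
        sel_table["t_star"] = sel.threshold
        sel_table["fdr"] = sel.fdr
        sel_table["confidence"] = sel.confidence
        sel_table["n_permutations"] = sel.n_permutations
        sel_table["rng_seed"] = config.rng_seed
        sel_table.to_csv(outdir / "selection.tsv", sep="\t", index=False)
        selected_genes = list(dict.fromkeys(
            sel_table.loc[sel_table["selected"], "gene_symbol"]
        ))
        _stage(manifest, "selection", n_selected_probes=sel.n_selected,
               n_selected_genes=len(selected_genes),
               threshold=sel.threshold)
        results["selector"] = selector
        results["selected_genes"] = selected_genes

        # --- enrichment -----------------------------------------------------
        universe = sorted(set(meta.table_["gene_symbol"]) - {config.seed_gene})
        exclusions = None
        if config.gene_sets_path:
            collection = read_gmt(config.gene_sets_path)
            enrich = hypergeom_enrich(selected_genes, collection, universe)
            enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            _stage(manifest, "enrichment", n_sets=len(collection),
                   n_query=len(selected_genes), n_universe=len(universe))
            results["enrichment"] = enrich
            from .enrichment import GeneSetCollection
            exclusions = GeneSetCollection()
            for name in config.exclusion_sets:
                if name in collection.sets:
                    exclusions.add(name, collection[name])

        # --- prioritization ---------------------------------------------------
        if config.interactions_path:
            interactions = cio.read_interactions(config.interactions_path)
            targets = prioritize_targets(selected_genes, interactions, exclusions)
            targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
            _stage(manifest, "prioritization", n_with_interaction=len(targets),
                   n_excluded=int(targets["excluded"].sum()) if len(targets) else 0,
                   n_retained=int((~targets["excluded"]).sum()) if len(targets) else 0)
            results["targets"] = targets

        # --- clinical stats ----------------------------------------------------
        if config.clinical_path:
            clin = cio.read_clinical(config.clinical_path)
            summary = summarize_cohort(clin, fields=("arm", "coo"))
            summary.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
            if "group" not in clin.columns and "expression" in clin.columns:
                clin["group"] = dichotomize_expression(clin["expression"].to_numpy())
            if "group" in clin.columns and {"arm", "coo"}.issubset(clin.columns):
                surv = survival_by_group(clin)
                surv.to_csv(outdir / "survival.tsv", sep="\t", index=False)
                results["survival"] = surv
                _stage(manifest, "clinical", n_patients=len(clin),
                       n_strata=len(surv))
            else:
                _stage(manifest, "clinical", n_patients=len(clin), n_strata=0)
            results["cohort_summary"] = summary

    except Exception as exc:
        manifest["failed_stage"] = type(exc).__name__
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    results["manifest"] = manifest
    return results
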