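"""End-to-end orchestration: tables in, regulation/cluster tables out.

``run_all`` wires the stages in their fixed order — parse, iRT
normalization, quality/localization filters, channel cross-filter,
technical averaging, missingness filter, stability selection, kinetic
scaling, embedding, density-peak clustering, optional enrichment — and
records a manifest of seeds, surviving row counts and output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering, enrichment, mq_io, preprocess, regulation
from .core import DesignTable, KineticsMatrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_all", "process_channel"]


@dataclass
class PipelineConfig:
    """Single configuration for a full run; defaults follow the study."""

    site_table: str = ""
    protein_table: Optional[str] = None
    design: str = ""
    irt: Optional[str] = None
    dataset: Optional[str] = None
    out_dir: str = "results"
    # thresholds
    pep_max: float = 0.01
    loc_min: float = 0.75
    min_conditions: int = 3
    min_reps_per_condition: int = 2
    # imputation
    impute_c: float = 0.3
    base_seed: int = 0
    # regulation
    n_iter: int = 200
    alpha: float = 0.05
    fc_min: float = 1.75
    frac_min: float = 0.9
    min_pair_points: int = 2
    # clustering
    perplexity: float = 12.0
    tsne_seed: int = 0
    dc_quantile: float = 0.02
    center_sd: float = 1.5
    # enrichment (optional inputs)
    annotations: Optional[str] = None
    kinase_annotations: Optional[str] = None
    expressed_kinases: Optional[str] = None
    neighborhood_radius: float = 4.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def regulation_params(self) -> regulation.RegulationParams:
        return regulation.RegulationParams(
            n_iter=self.n_iter,
            alpha=self.alpha,
            log2_fc_min=float(np.log2(self.fc_min)),
            frac_min=self.frac_min,
            min_pair_points=self.min_pair_points,
            base_seed=self.base_seed,
            impute_c=self.impute_c,
        )


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def log_count(self, stage: str, n: int) -> None:
        self.counts[stage] = int(n)
        logger.info("%s: %d rows", stage, n)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.manifest = manifest


def process_channel(
    records,
    design: DesignTable,
    cfg: PipelineConfig,
    enrichment_name: str,
    irt: Optional[pd.DataFrame],
    manifest: Optional[RunManifest] = None,
) -> KineticsMatrix:
    """Raw records -> iRT-normalized, filtered, tech-averaged matrix."""
    matrix = mq_io.build_kinetics_matrix(
        records, design, dataset=cfg.dataset, enrichment=enrichment_name
    )
    if manifest:
        manifest.log_count(f"{enrichment_name}/parsed", matrix.n_sites)
    if irt is not None:
        matrix = preprocess.irt_normalize(matrix, irt)
    return matrix


def _finish_channel(matrix: KineticsMatrix, cfg: PipelineConfig, manifest, tag: str):
    matrix = preprocess.average_tech_replicates(matrix)
    matrix = preprocess.missingness_filter(
        matrix, cfg.min_conditions, cfg.min_reps_per_condition
    )
    if manifest:
        manifest.log_count(f"{tag}/missingness_filtered", matrix.n_sites)
    return matrix


def run_all(cfg: PipelineConfig) -> RunManifest:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        seeds={"base_seed": cfg.base_seed, "tsne_seed": cfg.tsne_seed},
    )
    t0 = time.time()
    stage = "parse"
    try:
        design = DesignTable.from_file(cfg.design)
        irt = pd.read_csv(cfg.irt, sep="\t") if cfg.irt else None
        records = mq_io.parse_site_table(cfg.site_table, design)
        manifest.log_count("parsed_records", len(records))

        stage = "filter"
        records = preprocess.quality_filter(records, cfg.pep_max)
        manifest.log_count("quality_filtered", len(records))
        records = preprocess.localization_filter(records, cfg.loc_min)
        manifest.log_count("localization_filtered", len(records))

        stage = "channels"
        enrichments = set(
            design.subset(dataset=cfg.dataset).df["enrichment"]
        ) & {"TiO2", "pY_IP"}
        channels: dict[str, KineticsMatrix] = {}
        for e in sorted(enrichments):
            recs = [r for r in records if _seen_in_channel(r, design, cfg.dataset, e)]
            if recs:
                channels[e] = process_channel(recs, design, cfg, e, irt, manifest)
        if "TiO2" in channels and "pY_IP" in channels:
            channels["TiO2"], channels["pY_IP"] = preprocess.enrichment_cross_filter(
                channels["TiO2"], channels["pY_IP"]
            )
            for e in ("TiO2", "pY_IP"):
                manifest.log_count(f"{e}/cross_filtered", channels[e].n_sites)

        stage = "regulation"
        params = cfg.regulation_params()
        results = {}
        matrices = {}
        for e, m in channels.items():
            m = _finish_channel(m, cfg, manifest, e)
            matrices[e] = m
            res = regulation.stability_select(m, params)
            regulation.condition_direction(res)
            results[e] = res
            manifest.log_count(f"{e}/regulated", len(res.regulated_ids))
            p = out / f"regulation_{e}.tsv"
            res.to_frame().to_csv(p, sep="\t", index=False)
            manifest.outputs[f"regulation_{e}"] = str(p)
        manifest.timings["regulation_s"] = round(time.time() - t0, 2)

        stage = "clustering"
        scaled_parts = []
        for e, m in matrices.items():
            reg = results[e].regulated_ids
            if not reg:
                continue
            model = preprocess.fit_imputation_model(m, cfg.impute_c, cfg.base_seed)
            imputed = preprocess.impute_missing(m, model)
            normed = preprocess.replicate_normalize(imputed)
            scaled_parts.append(clustering.scale_kinetics(normed, reg))
        if scaled_parts:
            scaled = pd.concat(scaled_parts)
            perp = min(cfg.perplexity, max(2.0, (len(scaled) - 1) / 3.0))
            coords = clustering.embed_2d(scaled, cfg.tsne_seed, perp)
            cmap = clustering.density_peak_cluster(
                coords, cfg.dc_quantile, cfg.center_sd
            )
            summaries = clustering.cluster_summaries(cmap, scaled)
            manifest.counts["n_clusters"] = int(cmap.n_clusters)
            for name, df in [
                ("clusters", cmap.table.reset_index()),
                ("cluster_summaries", summaries),
            ]:
                p = out / f"{name}.tsv"
                df.to_csv(p, sep="\t", index=False)
                manifest.outputs[name] = str(p)
            payload = {
                "sites": {
                    s: {
                        "kinetic": [float(v) for v in scaled.loc[s]],
                        "cluster": int(cmap.table.loc[s, "cluster"]),
                    }
                    for s in scaled.index
                },
                "timepoints_s": [int(c) for c in scaled.columns],
            }
            p = out / "kinetics.json"
            with open(p, "w") as fh:
                json.dump(payload, fh)
            manifest.outputs["kinetics_json"] = str(p)

            stage = "enrichment"
            if cfg.annotations:
                ann = enrichment.AnnotationSet.from_table(
                    cfg.annotations, scaled.index, kind="keyword_site"
                )
                labels = cmap.table["cluster"]
                rows = []
                for cl in sorted(labels.unique()):
                    scope = labels.index[labels == cl]
                    rows += enrichment.hypergeom_enrich(
                        scope, ann, enrichment.KEYWORD_SITE_THRESHOLDS, str(cl)
                    )
                p = out / "cluster_enrichment.tsv"
                enrichment.results_frame(rows).to_csv(p, sep="\t", index=False)
                manifest.outputs["cluster_enrichment"] = str(p)
                local = enrichment.local_embedding_enrichment(
                    coords, ann, cfg.neighborhood_radius
                )
                p = out / "local_enrichment.tsv"
                local.to_csv(p, sep="\t", index=False)
                manifest.outputs["local_enrichment"] = str(p)
            if cfg.kinase_annotations and cfg.expressed_kinases:
                kin = enrichment.AnnotationSet.from_table(
                    cfg.kinase_annotations, scaled.index, kind="kinase_substrate"
                )
                expressed = [
                    l.strip()
                    for l in Path(cfg.expressed_kinases).read_text().splitlines()
                    if l.strip()
                ]
                prof = enrichment.kinase_activity_profile(
                    cmap.table["cluster"], kin, expressed
                )
                p = out / "kinase_enrichment.tsv"
                prof["p"].to_csv(p, sep="\t")
                manifest.outputs["kinase_enrichment"] = str(p)

        stage = "proteins"
        if cfg.protein_table:
            prot = mq_io.parse_protein_table(cfg.protein_table, design)
            prot = preprocess.quality_filter(prot, pep_max=1.0)
            pm = mq_io.build_protein_matrix(prot, design, dataset=cfg.dataset)
            if irt is not None:
                pm = preprocess.irt_normalize(pm, irt)
            pm = _finish_channel(pm, cfg, manifest, "protein")
            pres = regulation.protein_regulation(
                pm, regulation.RegulationParams.protein_defaults(
                    n_iter=cfg.n_iter, base_seed=cfg.base_seed, impute_c=cfg.impute_c
                )
            )
            manifest.log_count("protein/regulated", len(pres.regulated_ids))
            p = out / "regulation_proteins.tsv"
            pres.to_frame().to_csv(p, sep="\t", index=False)
            manifest.outputs["regulation_proteins"] = str(p)
    except Exception as exc:  # abort with stage name and manifest-so-far
        raise StageError(stage, manifest, exc) from exc

    manifest.timings["total_s"] = round(time.time() - t0, 2)
    manifest.write(out / "manifest.json")
    return manifest


def _seen_in_channel(record, design: DesignTable, dataset, enrichment_name: str) -> bool:
    runs = set(design.subset(dataset=dataset, enrichment=enrichment_name).runs)
    return any(r in runs for r in record.raw_intensity)
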