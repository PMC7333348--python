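"""Synthetic-data benchmarks: recovery and null-calibration experiments.

These run the full pipeline on generated data and score it against the
generator's ground truth — the package's built-in way of checking that
the regulation calls and kinetic clusters behave as designed before
pointing it at real quantification tables.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional

import pandas as pd

from . import clustering, mq_io, preprocess, regulation
from . import simulate as sim

__all__ = ["run_synthetic_pipeline", "recovery_benchmark", "null_benchmark"]


def run_synthetic_pipeline(
    cfg: sim.GeneratorConfig,
    n_iter: int = 200,
    base_seed: int = 0,
    tsne_seed: int = 0,
    cluster: bool = True,
    workdir: Optional[str] = None,
):
    """Generate tables, push them through the full analysis, score vs truth.

    Goes through the on-disk TSV round trip so the parsing layer is part
    of every benchmark. Returns (metrics dict, extras dict).
    """
    ds = sim.generate(cfg)
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        paths = ds.write(td)
        design = ds.design_table()
        records = mq_io.parse_site_table(paths["sites"], design)
        irt = pd.read_csv(paths["irt"], sep="\t")
    records = preprocess.quality_filter(records)
    records = preprocess.localization_filter(records)

    channels = {}
    for e in ("TiO2", "pY_IP"):
        runs = set(design.subset(enrichment=e).runs)
        recs = [r for r in records if any(run in runs for run in r.raw_intensity)]
        if recs:
            m = mq_io.build_kinetics_matrix(recs, design, enrichment=e)
            channels[e] = preprocess.irt_normalize(m, irt)
    if "TiO2" in channels and "pY_IP" in channels:
        channels["TiO2"], channels["pY_IP"] = preprocess.enrichment_cross_filter(
            channels["TiO2"], channels["pY_IP"]
        )

    params = regulation.RegulationParams(n_iter=n_iter, base_seed=base_seed)
    calls = []
    scaled_parts = []
    n_tested = 0
    for e, m in channels.items():
        m = preprocess.average_tech_replicates(m)
        m = preprocess.missingness_filter(m)
        if m.n_sites < 2:
            continue
        n_tested += m.n_sites
        res = regulation.stability_select(m, params)
        calls += res.calls
        if cluster and res.regulated_ids:
            model = preprocess.fit_imputation_model(m, seed=base_seed)
            imputed = preprocess.impute_missing(m, model)
            normed = preprocess.replicate_normalize(imputed)
            scaled_parts.append(clustering.scale_kinetics(normed, res.regulated_ids))

    cmap = None
    if cluster and scaled_parts:
        scaled = pd.concat(scaled_parts)
        perp = min(12.0, max(2.0, (len(scaled) - 1) / 3.0))
        coords = clustering.embed_2d(scaled, seed=tsne_seed, perplexity=perp)
        cmap = clustering.density_peak_cluster(coords)

    metrics = sim.truth_eval(calls, cmap, ds.truth)
    metrics["n_tested"] = n_tested
    if cmap is not None:
        metrics["n_clusters"] = cmap.n_clusters
    return metrics, {"calls": calls, "cluster_map": cmap, "dataset": ds}


def recovery_benchmark(seed: int, n_sites: int = 2000, n_iter: int = 200) -> dict:
    """Sensitivity/FDR/cluster recovery under the default study conditions."""
    cfg = sim.GeneratorConfig(n_sites=n_sites, seed=seed)
    metrics, _ = run_synthetic_pipeline(
        cfg, n_iter=n_iter, base_seed=seed + 1, tsne_seed=seed + 2
    )
    return metrics

def null_benchmark(seed: int, n_sites: int = 500, n_iter: int = 50) -> dict:
    """Fraction of i.i.d. null sites called regulated (type-I calibration)."""
    cfg = sim.GeneratorConfig(
        n_sites=n_sites, seed=seed, frac_regulated=0.0, bio_sd=0.3
    )
    metrics, _ = run_synthetic_pipeline(
        cfg, n_iter=n_iter, base_seed=seed + 1, cluster=False
    )
    metrics["null_regulated_fraction"] = (
        metrics["n_called"] / metrics["n_tested"] if metrics["n_tested"] else 0.0
    )
    return metrics
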