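"""Normalization, filtering and left-censored imputation of kinetics.

Stage order is fixed: iRT normalization on run-level intensities, then
identification-quality and localization filters, the cross-channel
residue filter, technical-replicate averaging, the missingness filter,
and finally (once per stability iteration) imputation of poorly covered
conditions followed by between-replicate normalization.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DesignTable, ImputationModel, KineticsMatrix, SiteRecord

logger = logging.getLogger(__name__)

__all__ = [
    "irt_normalize",
    "quality_filter",
    "localization_filter",
    "enrichment_cross_filter",
    "average_tech_replicates",
    "missingness_filter",
    "fit_imputation_model",
    "impute_missing",
    "replicate_normalize",
]


def irt_offsets(irt: pd.DataFrame, runs: Sequence[str]) -> pd.Series:
    """Per-run log2 offsets from spiked-in iRT standard intensities.

    ``irt`` is long-format with columns (run_id, peptide, intensity).
    The offset of run r is the median over iRT peptides of the deviation
    of log2 intensity from that peptide's cross-run mean — robust to a
    single aberrant standard. Runs without any iRT observation get
    offset 0 with a warning.
    """
    need = {"run_id", "peptide", "intensity"}
    if not need.issubset(irt.columns):
        raise ValueError(f"iRT table must have columns {sorted(need)}")
    irt = irt[irt["intensity"] > 0].copy()
    irt["log2"] = np.log2(irt["intensity"])
    dev = irt["log2"] - irt.groupby("peptide")["log2"].transform("mean")
    off = dev.groupby(irt["run_id"]).median()
    out = pd.Series(0.0, index=list(runs), name="irt_offset")
    covered = off.index.intersection(out.index)
    out.loc[covered] = off.loc[covered]
    missing = [r for r in runs if r not in set(covered)]
    if missing:
        logger.warning("no iRT observations for runs %s; offset 0 used", missing)
    return out


def irt_normalize(matrix: KineticsMatrix, irt: pd.DataFrame) -> KineticsMatrix:
    """Subtract per-run iRT offsets from every cell (instrument variation)."""
    off = irt_offsets(irt, matrix.data.columns)
    data = matrix.data.sub(off, axis=1)
    return matrix.replace(data=data, stage="irt_normalized", irt_offsets=off)


def quality_filter(records: Iterable, pep_max: float = 0.01) -> list:
    """Drop contaminant/reverse entries and PSMs with PEP above threshold."""
    return [
        r
        for r in records
        if not r.is_contaminant and not r.is_reverse and r.pep <= pep_max
    ]


def _loc_class(p: float) -> int:
    if p > 0.75:
        return 1
    if p > 0.50:
        return 2
    if p > 0.25:
        return 3
    return 4


def localization_filter(
    records: Iterable[SiteRecord], loc_min: float = 0.75
) -> list[SiteRecord]:
    """Keep sites localized with probability >= loc_min in >= 1 replicate.

    Every record (kept or not) is annotated with its localization class:
    1 for > 75%, 2 for (50%, 75%], 3 for (25%, 50%], 4 for <= 25%.
    """
    kept = []
    for r in records:
        r.loc_class = _loc_class(r.max_localization)
        if r.max_localization >= loc_min:
            kept.append(r)
    return kept


def enrichment_cross_filter(
    matrix_tio2: KineticsMatrix, matrix_pyip: KineticsMatrix
) -> tuple[KineticsMatrix, KineticsMatrix]:
    """Residue cross-filter between the TiO2 and pY-IP channels.

    pS/pT rows are removed from the pY-IP matrix; pY rows that were
    quantified in the (filtered) pY-IP matrix are removed from the TiO2
    matrix. A pY never quantified in the pY-IP stays in TiO2 — removal
    is conditional on pY-IP quantification.
    """
    py_keep = matrix_pyip.site_meta["residue_class"] == "Y"
    pyip = matrix_pyip.subset(matrix_pyip.site_meta.index[py_keep], stage="filtered")
    py_keys = set(pyip.site_meta["site_key"])
    tio2_meta = matrix_tio2.site_meta
    drop = (tio2_meta["residue_class"] == "Y") & tio2_meta["site_key"].isin(py_keys)
    tio2 = matrix_tio2.subset(tio2_meta.index[~drop], stage="filtered")
    return tio2, pyip


def average_tech_replicates(matrix: KineticsMatrix) -> KineticsMatrix:
    """Average log2 intensities of technical MS replicates.

    The mean is taken over the present technical replicates of each
    (site, bio_rep, condition); the cell is missing only if all of them
    are missing.
    """
    if matrix.is_tech_averaged:
        raise ValueError("matrix is already tech-averaged")
    rep_cond = matrix.design.rep_cond_of_run()
    t = matrix.data.T
    t.index = pd.MultiIndex.from_tuples(
        [rep_cond[r] for r in matrix.data.columns], names=["bio_rep", "timepoint_s"]
    )
    data = t.groupby(level=["bio_rep", "timepoint_s"]).mean().T
    return matrix.replace(data=data, stage="tech_averaged")


def observed_counts(matrix: KineticsMatrix) -> pd.DataFrame:
    """Per (site, condition) count of observed biological replicates."""
    if not matrix.is_tech_averaged:
        raise ValueError("requires a tech-averaged matrix")
    return matrix.data.notna().T.groupby(level="timepoint_s").sum().T


def missingness_filter(
    matrix: KineticsMatrix, min_conditions: int = 3, min_reps_per_condition: int = 2
) -> KineticsMatrix:
    """Keep sites detected in >= 3 conditions with >= 2 replicates each."""
    counts = observed_counts(matrix)
    ok = (counts >= min_reps_per_condition).sum(axis=1) >= min_conditions
    return matrix.subset(matrix.data.index[ok], stage="filtered")


def fit_imputation_model(
    matrix: KineticsMatrix, c: float = 0.3, seed: int = 0
) -> ImputationModel:
    """Estimate (q05, sigma) from all observed log2 intensities."""
    vals = matrix.data.to_numpy(dtype=float)
    obs = vals[np.isfinite(vals)]
    if obs.size < 2:
        raise ValueError("too few observed values to fit an imputation model")
    q05 = float(np.quantile(obs, 0.05))
    sigma = float(np.std(obs, ddof=1))
    model = ImputationModel(q05=q05, sigma=sigma, c=c, seed=seed)
    if not q05 < float(np.median(obs)):
        raise ValueError("degenerate matrix: 5% quantile not below the median")
    return model


def impute_missing(
    matrix: KineticsMatrix,
    model: ImputationModel,
    seed: Optional[int] = None,
) -> KineticsMatrix:
    """Fill poorly covered conditions with low-intensity draws.

    A (site, condition) with 0 or 1 observed replicate values gets every
    missing design-valid cell replaced by an independent draw from
    Normal(q05, c * sigma). Conditions with >= 2 observed values are
    untouched. Imputed cells are flagged in the mask.
    """
    arr, reps, conds, valid = matrix.to_array()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    present = np.isfinite(arr)
    counts = present.sum(axis=1)  # (site, cond)
    needs = counts <= 1  # conditions to fill
    fill = needs[:, None, :] & ~present & valid[None, :, :]
    draws = rng.normal(model.q05, model.draw_sd, size=int(fill.sum()))
    out = arr.copy()
    out[fill] = draws
    return KineticsMatrix.from_array(
        out, reps, conds, matrix, stage="imputed", imputed=fill
    )


def _replicate_normalize_array(arr: np.ndarray) -> np.ndarray:
    """Mean-center each replicate's kinetic per site, restore grand mean."""
    with np.errstate(invalid="ignore"):
        rep_mean = np.nanmean(arr, axis=2, keepdims=True)  # (site, rep, 1)
        grand = np.nanmean(arr, axis=(1, 2), keepdims=True)
    out = arr - rep_mean + grand
    return out


def replicate_normalize(matrix: KineticsMatrix) -> KineticsMatrix:
    """Remove per-replicate offsets while preserving the absolute scale."""
    arr, reps, conds, _valid = matrix.to_array()
    out = _replicate_normalize_array(arr)
    imp = None
    if matrix.imputed is not None:
        imp = matrix.imputed.to_numpy().reshape(arr.shape)
    return KineticsMatrix.from_array(
        out, reps, conds, matrix, stage="replicate_normalized", imputed=imp
    )
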