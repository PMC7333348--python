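"""Synthetic MaxQuant-like phosphoproteomic time courses with ground truth.

The generator emulates the data-generating situation of an antibody-
stimulation TCR time course: 6 stimulation conditions (0-600 s), 4
biological replicates measured in 3 technical MS runs each, a TiO2
(pS/pT-dominated) and a pY-IP enrichment channel, log-normal baseline
intensities with per-run offsets recoverable from spiked-in iRT
standards, intensity-dependent (MNAR) dropout, PEP and localization-
probability columns, contaminant rows, and 13 kinetic response
archetypes for the regulated fraction. Output tables are parseable by
:mod:`phosphokin.mq_io` and ship with a per-site ground truth for
sensitivity/FDR/cluster-recovery evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import adjusted_rand_score

from .core import DesignTable

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "make_archetypes",
    "generate",
    "truth_eval",
    "expected_missing_rate",
    "ARCHETYPE_NAMES",
]

TIMEPOINTS = (0, 15, 30, 120, 300, 600)

# 13 kinetic templates (unit maximum). Up-regulated shapes start at 0 and
# peak later; dephosphorylation shapes peak at t = 0 and decay, so that
# adding log2(effect) * template to a flat baseline yields decreasing
# phosphorylation relative to the unstimulated point. Anchor values are
# fixed constants; between sampled times the curve is piecewise-linear in
# log time.
_ARCHETYPES = np.array(
    [
        [0.00, 1.00, 0.70, 0.35, 0.20, 0.15],  # transient, peak 15 s
        [0.00, 0.55, 1.00, 0.60, 0.30, 0.20],  # transient, peak 30 s
        [0.00, 1.00, 0.95, 0.80, 0.75, 0.70],  # early peak, sustained
        [0.00, 0.85, 1.00, 1.00, 0.95, 0.95],  # early peak, stable
        [0.00, 0.30, 0.60, 1.00, 0.60, 0.35],  # mid peak (120 s), then down
        [0.00, 0.30, 0.60, 1.00, 0.95, 0.90],  # mid peak (120 s), maintained
        [0.00, 0.20, 0.40, 0.70, 1.00, 0.95],  # gradual rise, sustained
        [0.00, 0.10, 0.25, 0.50, 0.75, 1.00],  # gradual, still rising at 600 s
        [1.00, 0.45, 0.25, 0.10, 0.10, 0.10],  # fast deep dephosphorylation
        [1.00, 0.70, 0.50, 0.35, 0.30, 0.30],  # fast shallow dephosphorylation
        [1.00, 0.95, 0.85, 0.55, 0.25, 0.10],  # delayed dephosphorylation
        [1.00, 0.90, 0.80, 0.60, 0.45, 0.30],  # gradual dephosphorylation
        [1.00, 1.00, 0.95, 0.85, 0.60, 0.35],  # late dephosphorylation
    ]
)
ARCHETYPE_NAMES = tuple(f"A{i + 1}" for i in range(13))
_DOWN = {8, 9, 10, 11, 12}


def make_archetypes() -> pd.DataFrame:
    """The 13 named kinetic templates (rows) over the 6 time points."""
    return pd.DataFrame(_ARCHETYPES.copy(), index=list(ARCHETYPE_NAMES), columns=list(TIMEPOINTS))


@dataclass
class GeneratorConfig:
    """Study conditions emulated by the generator.

    Noise scales are log2 units. ``missing_midpoint``/``missing_slope``
    parameterize the MNAR dropout: P(missing) =
    logistic(-slope * (log2 intensity - midpoint)), i.e. left-censoring
    that motivates low-quantile imputation. Defaults reproduce roughly
    20% global missingness under the default intensity distribution.
    """

    n_sites: int = 2000
    frac_regulated: float = 0.10
    effect_range: tuple[float, float] = (2.0, 8.0)  # linear fold change at peak
    baseline_log2_mean: float = 21.0
    baseline_log2_sd: float = 2.5
    rep_offset_sd: float = 0.25
    bio_sd: float = 0.25
    tech_sd: float = 0.15
    run_offset_sd: float = 0.30
    missing_midpoint: float = 18.0
    missing_slope: float = 0.7
    n_bio_reps: int = 4
    n_pyip_reps: int = 3  # pY-IP done in a subset of the experiments
    n_tech_reps: int = 3
    conditions: tuple[int, ...] = TIMEPOINTS
    n_irt_peptides: int = 11
    irt_noise_sd: float = 0.05
    contaminant_fraction: float = 0.02
    frac_high_pep: float = 0.02
    frac_poor_localization: float = 0.05
    residue_probs: tuple[float, float, float] = (0.81, 0.155, 0.035)  # S, T, Y
    py_in_tio2_prob: float = 0.30
    st_in_pyip_prob: float = 0.02
    p_multi2: float = 0.10
    dataset: str = "CD4"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_regulated <= 1:
            raise ValueError("frac_regulated must be in [0, 1]")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        for name in ("rep_offset_sd", "bio_sd", "tech_sd", "run_offset_sd", "irt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pyip_reps > self.n_bio_reps:
            raise ValueError("n_pyip_reps cannot exceed n_bio_reps")


@dataclass
class SyntheticDataset:
    """Generated tables plus ground truth, writable as plain TSVs."""

    site_table: pd.DataFrame
    protein_table: pd.DataFrame
    design: pd.DataFrame
    irt: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig

    def design_table(self) -> DesignTable:
        return DesignTable(self.design)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("sites", self.site_table),
            ("proteins", self.protein_table),
            ("design", self.design),
            ("irt", self.irt),
            ("truth", self.truth),
        ]:
            p = outdir / f"{name}.tsv"
            # %.17g guarantees exact float64 round-trip through the text file
            df.to_csv(p, sep="\t", index=False, float_format="%.17g")
            paths[name] = p
        return paths


def _interp_archetypes(conditions: Sequence[int]) -> np.ndarray:
    """Archetype values at arbitrary time points (linear in log time)."""
    t_ref = np.array(TIMEPOINTS, dtype=float)
    t = np.asarray(conditions, dtype=float)
    lt_ref = np.log1p(t_ref)
    lt = np.log1p(t)
    return np.vstack([np.interp(lt, lt_ref, row) for row in _ARCHETYPES])


def expected_missing_rate(config: GeneratorConfig) -> float:
    """Missingness implied by the logistic MNAR model, by numeric integration.

    Exact for frac_regulated = 0, where log2 intensities are Normal with
    variance = baseline^2 + rep_offset^2 + bio^2 + tech^2 + run_offset^2.
    """
    sd = math.sqrt(
        config.baseline_log2_sd ** 2
        + config.rep_offset_sd ** 2
        + config.bio_sd ** 2
        + config.tech_sd ** 2
        + config.run_offset_sd ** 2
    )
    x = np.linspace(config.baseline_log2_mean - 8 * sd, config.baseline_log2_mean + 8 * sd, 4001)
    dens = stats.norm.pdf(x, config.baseline_log2_mean, sd)
    drop = expit(-config.missing_slope * (x - config.missing_midpoint))
    return float(np.trapezoid(dens * drop, x))


def _make_design(config: GeneratorConfig) -> pd.DataFrame:
    reps = [chr(ord("A") + i) for i in range(config.n_bio_reps)]
    rows = []
    for enrich, enr_reps, n_tech in [
        ("TiO2", reps, config.n_tech_reps),
        ("pY_IP", reps[: config.n_pyip_reps], config.n_tech_reps),
        ("preenrich", reps, config.n_tech_reps),
    ]:
        for rep in enr_reps:
            for t in config.conditions:
                for k in range(1, n_tech + 1):
                    rows.append(
                        {
                            "run_id": f"{rep}_{enrich}_{t}s_r{k}",
                            "dataset": config.dataset,
                            "enrichment": enrich,
                            "bio_rep": rep,
                            "timepoint_s": t,
                            "tech_rep": k,
                        }
                    )
    return pd.DataFrame(rows)


def generate(config: Optional[GeneratorConfig] = None) -> SyntheticDataset:
    """Generate the site/protein/design/iRT tables and ground truth."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    S = config.n_sites
    conds = list(config.conditions)
    C = len(conds)
    reps = [chr(ord("A") + i) for i in range(config.n_bio_reps)]
    R = len(reps)

    design = _make_design(config)
    phospho_design = design[design["enrichment"].isin(["TiO2", "pY_IP"])]

    # --- per-site identity -------------------------------------------------
    residues = rng.choice(np.array(["S", "T", "Y"]), size=S, p=config.residue_probs)
    mult = np.where(rng.random(S) < config.p_multi2, 2, 1)
    n_reg = int(round(config.frac_regulated * S))
    regulated = np.zeros(S, dtype=bool)
    regulated[rng.permutation(S)[:n_reg]] = True
    arch_idx = np.full(S, -1)
    arch_idx[regulated] = rng.integers(0, len(_ARCHETYPES), size=regulated.sum())
    lo, hi = config.effect_range
    log2_eff = np.zeros(S)
    log2_eff[regulated] = rng.uniform(math.log2(lo), math.log2(hi), size=regulated.sum())

    arch_curves = _interp_archetypes(conds)
    shift = np.zeros((S, C))
    shift[regulated] = log2_eff[regulated, None] * arch_curves[arch_idx[regulated]]

    n_proteins = max(1, S // 3)
    protein_idx = rng.integers(0, n_proteins, size=S)
    accessions = np.array([f"P{70000 + i}" for i in range(n_proteins)])
    genes = np.array([f"Gene{i}" for i in range(n_proteins)])

    is_y = residues == "Y"
    in_tio2 = ~is_y | (rng.random(S) < config.py_in_tio2_prob)
    in_pyip = is_y | (rng.random(S) < config.st_in_pyip_prob)

    # --- noise components --------------------------------------------------
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, S)
    rep_off = rng.normal(0, config.rep_offset_sd, (S, R))
    bio = rng.normal(0, config.bio_sd, (S, R, C))
    run_ids = list(design["run_id"])
    run_off = rng.normal(0, config.run_offset_sd, len(run_ids))
    run_off_by_id = dict(zip(run_ids, run_off))

    rep_ix = {r: i for i, r in enumerate(reps)}
    cond_ix = {c: i for i, c in enumerate(conds)}

    # --- site intensities per phospho run ----------------------------------
    p_runs = list(phospho_design.itertuples())
    vals = np.full((S, len(p_runs)), np.nan)
    for j, run in enumerate(p_runs):
        ri, ci = rep_ix[run.bio_rep], cond_ix[run.timepoint_s]
        x = (
            baseline
            + shift[:, ci]
            + rep_off[:, ri]
            + bio[:, ri, ci]
            + run_off_by_id[run.run_id]
            + rng.normal(0, config.tech_sd, S)
        )
        channel = in_tio2 if run.enrichment == "TiO2" else in_pyip
        x[~channel] = np.nan
        vals[:, j] = x
    drop_p = expit(-config.missing_slope * (vals - config.missing_midpoint))
    dropped = rng.random(vals.shape) < drop_p
    vals[dropped] = np.nan

    # --- localization probabilities & PEP ----------------------------------
    poor_loc = rng.random(S) < config.frac_poor_localization
    loc = 0.75 + 0.25 * rng.beta(2.0, 1.0, (S, R))
    loc[poor_loc] = 0.74 * rng.beta(5.0, 2.0, (int(poor_loc.sum()), R))
    pep = rng.exponential(0.002, S).clip(max=0.01)
    high_pep = rng.random(S) < config.frac_high_pep
    pep[high_pep] = rng.uniform(0.011, 0.05, int(high_pep.sum()))

    # --- site table rows ----------------------------------------------------
    site_ids = np.array([f"s{i:05d}" for i in range(S)])
    table = {
        "id": site_ids,
        "Proteins": accessions[protein_idx],
        "Gene names": genes[protein_idx],
        "Amino acid": residues,
        "Position": np.arange(1, S + 1),
        "PEP": pep,
        "Reverse": "",
        "Potential contaminant": "",
    }
    for ri, rep in enumerate(reps):
        table[f"Localization prob {rep}"] = loc[:, ri]
    for k in (1, 2):
        sel = mult == k
        for j, run in enumerate(p_runs):
            col = np.zeros(S)
            col[sel] = np.where(np.isnan(vals[sel, j]), 0.0, np.power(2.0, vals[sel, j]))
            table[f"Intensity {run.run_id}___{k}"] = col
    site_table = pd.DataFrame(table)

    # contaminant rows: flagged, junk intensities, excluded from truth
    n_con = int(round(config.contaminant_fraction * S))
    if n_con:
        con = site_table.sample(n=n_con, random_state=int(rng.integers(2**31))).copy()
        con["id"] = [f"c{i:04d}" for i in range(n_con)]
        con["Proteins"] = [f"CON__Q{i:05d}" for i in range(n_con)]
        con["Potential contaminant"] = "+"
        con["Position"] = np.arange(S + 1, S + n_con + 1)
        site_table = pd.concat([site_table, con], ignore_index=True)

    # --- protein table -------------------------------------------------------
    pre_runs = [r for r in design.itertuples() if r.enrichment == "preenrich"]
    p_base = rng.normal(23.0, 1.5, n_proteins)
    p_rep_off = rng.normal(0, config.rep_offset_sd, (n_proteins, R))
    lfq = np.full((n_proteins, len(pre_runs)), np.nan)
    for j, run in enumerate(pre_runs):
        ri = rep_ix[run.bio_rep]
        x = (
            p_base
            + p_rep_off[:, ri]
            + run_off_by_id[run.run_id]
            + rng.normal(0, config.tech_sd, n_proteins)
        )
        lfq[:, j] = x
    p_drop = expit(-config.missing_slope * (lfq - config.missing_midpoint))
    lfq[rng.random(lfq.shape) < p_drop] = np.nan
    uniq = 2 + rng.poisson(6, n_proteins)
    uniq[rng.random(n_proteins) < 0.05] = 1
    protein_table = pd.DataFrame(
        {
            "id": [f"pg{i:05d}" for i in range(n_proteins)],
            "Majority protein IDs": accessions,
            "Gene names": genes,
            "Unique peptides": uniq,
            "iBAQ": np.power(2.0, p_base - 5.0),
            "Reverse": "",
            "Potential contaminant": "",
        }
    )
    for j, run in enumerate(pre_runs):
        protein_table[f"LFQ intensity {run.run_id}"] = np.where(
            np.isnan(lfq[:, j]), 0.0, np.power(2.0, lfq[:, j])
        )

    # --- iRT standards: recoverable per-run offsets --------------------------
    irt_base = rng.uniform(18.0, 24.0, config.n_irt_peptides)
    irt_rows = []
    for run_id in run_ids:
        noise = rng.normal(0, config.irt_noise_sd, config.n_irt_peptides)
        for p in range(config.n_irt_peptides):
            irt_rows.append(
                {
                    "run_id": run_id,
                    "peptide": f"iRT{p + 1:02d}",
                    "intensity": float(2.0 ** (irt_base[p] + run_off_by_id[run_id] + noise[p])),
                }
            )
    irt = pd.DataFrame(irt_rows)

    truth = pd.DataFrame(
        {
            "site_id": [f"{s}_M{m}" for s, m in zip(site_ids, mult)],
            "regulated": regulated,
            "archetype": [ARCHETYPE_NAMES[a] if a >= 0 else "" for a in arch_idx],
            "peak_fc": np.power(2.0, log2_eff),
            "direction": [
                ("down" if a in _DOWN else "up") if r else ""
                for a, r in zip(arch_idx, regulated)
            ],
            "residue": residues,
        }
    )
    return SyntheticDataset(
        site_table=site_table,
        protein_table=protein_table,
        design=design,
        irt=irt,
        truth=truth,
        config=config,
    )


def truth_eval(
    calls,
    cluster_map,
    truth: pd.DataFrame,
) -> dict:
    """Confusion metrics of regulation calls and cluster recovery vs truth.

    ``calls`` is a list of RegulationCall (or a StabilityResult);
    ``cluster_map`` a ClusterMap (or None to skip the ARI). Regulated
    truth sites never tested (lost to upstream filters) count as missed.
    """
    if hasattr(calls, "calls"):
        calls = calls.calls
    pred = {c.site_id: bool(c.regulated) for c in calls}
    truth_reg = dict(zip(truth["site_id"], truth["regulated"]))
    tp = [s for s, r in pred.items() if r and truth_reg.get(s, False)]
    fp = [s for s, r in pred.items() if r and not truth_reg.get(s, False)]
    n_true = int(truth["regulated"].sum())
    sensitivity = len(tp) / n_true if n_true else float("nan")
    fdr = len(fp) / (len(tp) + len(fp)) if (tp or fp) else 0.0

    per_arch = {}
    reg_truth = truth[truth["regulated"]]
    for arch, grp in reg_truth.groupby("archetype"):
        per_arch[arch] = float(np.mean([pred.get(s, False) for s in grp["site_id"]]))

    ari = float("nan")
    if cluster_map is not None:
        labels = cluster_map.table["cluster"] if hasattr(cluster_map, "table") else cluster_map
        arch_of = dict(zip(truth["site_id"], truth["archetype"]))
        common = [s for s in labels.index if s in set(tp)]
        if len(common) >= 2:
            ari = float(
                adjusted_rand_score(
                    [arch_of[s] for s in common], [labels[s] for s in common]
                )
            )
    return {
        "sensitivity": float(sensitivity),
        "fdr": float(fdr),
        "n_true_regulated": n_true,
        "n_called": int(sum(pred.values())),
        "n_true_positive": len(tp),
        "ari": ari,
        "per_archetype_recall": per_arch,
    }
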