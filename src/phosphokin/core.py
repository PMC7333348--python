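"""Core domain containers shared across the pipeline.

The analysis revolves around three objects: per-phosphosite quantification
records parsed from MaxQuant-dialect tables (:class:`SiteRecord`,
:class:`ProteinRecord`), the run design mapping each MS run to its
experimental coordinates (:class:`DesignTable`), and the site-by-run
log2-intensity grid carried through preprocessing
(:class:`KineticsMatrix`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

ENRICHMENTS = ("preenrich", "TiO2", "pY_IP")

#: Processing stages of a KineticsMatrix, in pipeline order.
STAGES = (
    "raw",
    "irt_normalized",
    "tech_averaged",
    "filtered",
    "imputed",
    "replicate_normalized",
)

DESIGN_COLUMNS = ("run_id", "dataset", "enrichment", "bio_rep", "timepoint_s", "tech_rep")


@dataclass
class SiteRecord:
    """One quantified phosphosite form: a (site, multiplicity) pair.

    Mono- and multi-phosphorylated forms of the same residue are kept as
    independent records because their regulation kinetics can differ.
    ``raw_intensity`` holds linear MS intensities per run; absent runs are
    simply missing from the mapping (MaxQuant writes 0 for
    not-quantified, which the parser drops).
    """

    site_id: str
    protein_ids: list[str]
    gene_name: str
    positions: list[int]
    residues: list[str]
    multiplicity: int
    localization_prob: dict[str, float]
    pep: float
    is_contaminant: bool
    is_reverse: bool
    raw_intensity: dict[str, float]
    loc_class: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.residues):
            raise ValueError(
                f"site {self.site_id}: positions and residues differ in length"
            )
        if self.multiplicity < 1:
            raise ValueError(f"site {self.site_id}: multiplicity must be >= 1")
        bad = {r for r in self.residues} - {"S", "T", "Y"}
        if bad:
            raise ValueError(f"site {self.site_id}: unexpected residues {bad}")
        for run, v in self.raw_intensity.items():
            if v < 0:
                raise ValueError(f"site {self.site_id}: negative intensity in {run}")

    @property
    def residue_class(self) -> str:
        """'Y' if any residue of the form is a phosphotyrosine, else 'ST'."""
        return "Y" if "Y" in self.residues else "ST"

    @property
    def max_localization(self) -> float:
        return max(self.localization_prob.values(), default=0.0)

    @property
    def site_key(self) -> str:
        """Canonical cross-dataset join key: accession_residue+position_Mk.

        Uses the leading accession; MaxQuant protein-group ambiguity is
        deliberately collapsed.
        """
        acc = self.protein_ids[0] if self.protein_ids else "NA"
        rp = ";".join(f"{r}{p}" for r, p in zip(self.residues, self.positions))
        return f"{acc}_{rp}_M{self.multiplicity}"


@dataclass
class ProteinRecord:
    """One MaxQuant protein group with LFQ intensities per run."""

    group_id: str
    accessions: list[str]
    gene_name: str
    unique_peptides: int
    lfq_intensity: dict[str, float]
    is_contaminant: bool
    is_reverse: bool
    ibaq: Optional[float] = None
    pep: float = 0.0

    def __post_init__(self) -> None:
        if self.unique_peptides < 0:
            raise ValueError(f"protein {self.group_id}: unique_peptides < 0")
        for run, v in self.lfq_intensity.items():
            if v < 0:
                raise ValueError(f"protein {self.group_id}: negative LFQ in {run}")


class DesignTable:
    """Run design: run_id -> (dataset, enrichment, bio_rep, timepoint_s, tech_rep).

    The optional ``intensity_column`` column maps a MaxQuant intensity
    column base name to the run, for files whose headers do not embed the
    run id directly.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        df = df.copy()
        df["run_id"] = df["run_id"].astype(str)
        df["bio_rep"] = df["bio_rep"].astype(str)
        df["timepoint_s"] = df["timepoint_s"].astype(int)
        df["tech_rep"] = df["tech_rep"].astype(int)
        if df["run_id"].duplicated().any():
            dup = df.loc[df["run_id"].duplicated(), "run_id"].iloc[0]
            raise ValueError(f"duplicate run_id in design: {dup}")
        bad = set(df["enrichment"]) - set(ENRICHMENTS)
        if bad:
            raise ValueError(f"unknown enrichment values: {sorted(bad)}")
        if (df["tech_rep"] < 1).any():
            raise ValueError("tech_rep must be >= 1")
        if df.empty:
            raise ValueError("design table is empty")
        self.df = df

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignTable":
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        return cls(pd.read_csv(path, sep=sep))

    @property
    def runs(self) -> list[str]:
        return list(self.df["run_id"])

    @property
    def bio_reps(self) -> list[str]:
        return sorted(self.df["bio_rep"].unique())

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.df["timepoint_s"].unique())

    def subset(self, dataset: Optional[str] = None, enrichment: Optional[str] = None) -> "DesignTable":
        df = self.df
        if dataset is not None:
            df = df[df["dataset"] == dataset]
        if enrichment is not None:
            df = df[df["enrichment"] == enrichment]
        if df.empty:
            raise ValueError(
                f"empty design selection (dataset={dataset!r}, enrichment={enrichment!r})"
            )
        return DesignTable(df)

    def column_to_run(self) -> dict[str, str]:
        """Map intensity-column base name -> run_id (defaults to identity)."""
        if "intensity_column" in self.df.columns:
            return dict(zip(self.df["intensity_column"].astype(str), self.df["run_id"]))
        return {r: r for r in self.df["run_id"]}

    def rep_cond_of_run(self) -> dict[str, tuple[str, int]]:
        return {
            r.run_id: (r.bio_rep, r.timepoint_s)
            for r in self.df.itertuples()
        }

    def valid_rep_conds(self) -> set[tuple[str, int]]:
        """(bio_rep, timepoint) combinations that have at least one run."""
        return set(zip(self.df["bio_rep"], self.df["timepoint_s"]))

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class KineticsMatrix:
    """Site x run (or site x (bio_rep, condition)) grid of log2 intensities.

    ``data`` holds log2-transformed intensities with NaN for missing.
    Before technical-replicate averaging the columns are run ids; after,
    they are a (bio_rep, timepoint_s) MultiIndex. The pipeline is
    monotone: filters drop rows, imputation fills cells, normalizations
    shift values — a present cell never becomes missing.
    """

    data: pd.DataFrame
    design: DesignTable
    stage: str
    site_meta: pd.DataFrame
    imputed: Optional[pd.DataFrame] = None
    irt_offsets: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite log2 intensities in matrix")

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def is_tech_averaged(self) -> bool:
        return isinstance(self.data.columns, pd.MultiIndex)

    def n_present(self) -> int:
        return int(self.data.notna().to_numpy().sum())

    def subset(self, site_ids: Sequence[str], stage: Optional[str] = None) -> "KineticsMatrix":
        site_ids = [s for s in self.data.index if s in set(site_ids)]
        return dataclasses.replace(
            self,
            data=self.data.loc[site_ids],
            site_meta=self.site_meta.loc[site_ids],
            imputed=None if self.imputed is None else self.imputed.loc[site_ids],
            stage=stage or self.stage,
        )

    def replace(self, **kw) -> "KineticsMatrix":
        return dataclasses.replace(self, **kw)

    def to_array(self) -> tuple[np.ndarray, list[str], list[int], np.ndarray]:
        """Return (values[site, rep, cond], reps, conds, valid[rep, cond]).

        Only meaningful on tech-averaged matrices; ``valid`` marks
        (rep, cond) combinations that exist in the design — cells outside
        it are structurally absent, not just missing.
        """
        if not self.is_tech_averaged:
            raise ValueError("to_array requires a tech-averaged matrix")
        reps = self.design.bio_reps
        conds = self.design.timepoints
        cols = pd.MultiIndex.from_product([reps, conds], names=["bio_rep", "timepoint_s"])
        wide = self.data.reindex(columns=cols)
        arr = wide.to_numpy(dtype=float).reshape(self.n_sites, len(reps), len(conds))
        valid = np.zeros((len(reps), len(conds)), dtype=bool)
        combos = self.design.valid_rep_conds()
        for i, r in enumerate(reps):
            for j, c in enumerate(conds):
                valid[i, j] = (r, c) in combos
        return arr, reps, conds, valid

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        reps: Sequence[str],
        conds: Sequence[int],
        template: "KineticsMatrix",
        stage: str,
        imputed: Optional[np.ndarray] = None,
    ) -> "KineticsMatrix":
        cols = pd.MultiIndex.from_product([reps, conds], names=["bio_rep", "timepoint_s"])
        data = pd.DataFrame(
            arr.reshape(arr.shape[0], -1), index=template.data.index, columns=cols
        )
        imp = None
        if imputed is not None:
            imp = pd.DataFrame(
                imputed.reshape(arr.shape[0], -1), index=template.data.index, columns=cols
            )
        return cls(
            data=data,
            design=template.design,
            stage=stage,
            site_meta=template.site_meta,
            imputed=imp,
            irt_offsets=template.irt_offsets,
        )


@dataclass
class ImputationModel:
    """Left-censored imputation model for MNAR missingness.

    Draws replacement values from Normal(q05, c * sigma) where ``q05`` is
    the 5% quantile and ``sigma`` the standard deviation of all observed
    log2 intensities of the matrix. ``c`` shrinks the spread of the
    draws; c = 1 reproduces a literal full-dataset-sd draw.
    """

    q05: float
    sigma: float
    c: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("imputation model requires sigma > 0")

    @property
    def draw_sd(self) -> float:
        return self.c * self.sigma
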