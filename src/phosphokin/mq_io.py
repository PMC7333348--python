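"""Readers for MaxQuant-dialect site/protein tables and the run design.

The site table follows the ``Phospho (STY)Sites.txt`` dialect: one row
per site, intensity columns ``Intensity <run>___k`` where ``k`` is the
multiplicity (number of phosphates on the quantified peptide form), PEP
and per-replicate localization-probability columns, and ``+`` markers
for contaminant/reverse entries. Zero intensities are
absence-of-quantification and map to missing. Each multiplicity is
expanded into its own :class:`~phosphokin.core.SiteRecord` so that mono-
and multi-phosphorylated forms are analysed independently.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DesignTable, KineticsMatrix, ProteinRecord, SiteRecord

__all__ = [
    "parse_site_table",
    "parse_protein_table",
    "build_kinetics_matrix",
    "DesignTable",
    "SiteRecord",
    "ProteinRecord",
]

_MULT_RE = re.compile(r"^(?P<base>.+?)___(?P<mult>\d+)$")
LOC_PREFIX = "Localization prob "


def _split_list(cell, cast=str) -> list:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return [cast(tok) for tok in str(cell).split(";") if tok != ""]


def _flag(cell) -> bool:
    return str(cell).strip() == "+"


def _intensity_columns(
    columns: Sequence[str], pattern: str, design: DesignTable
) -> dict[tuple[str, int], str]:
    """Resolve ``(run_id, multiplicity) -> column name`` via the design.

    ``pattern`` is e.g. ``"Intensity {run}"``; a ``___k`` suffix denotes
    the multiplicity and is optional (absent means multiplicity 1).
    """
    prefix = pattern.split("{run}")[0]
    col_to_run = design.column_to_run()
    known_runs = set(design.runs)
    out: dict[tuple[str, int], str] = {}
    for col in columns:
        if not col.startswith(prefix):
            continue
        body = col[len(prefix):]
        m = _MULT_RE.match(body)
        base, mult = (m.group("base"), int(m.group("mult"))) if m else (body, 1)
        run = col_to_run.get(base, base)
        if run not in known_runs:
            raise ValueError(
                f"intensity column {col!r} does not resolve to a run in the design"
            )
        out[(run, mult)] = col
    if not out:
        raise ValueError(f"no intensity columns matching pattern {pattern!r}")
    return out


def parse_site_table(
    path: str | Path,
    design: DesignTable,
    intensity_pattern: str = "Intensity {run}",
    loc_prefix: str = LOC_PREFIX,
) -> list[SiteRecord]:
    """Parse a phosphosite table into one record per (site, multiplicity)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, low_memory=False,
                     float_precision="round_trip")
    icols = _intensity_columns(df.columns, intensity_pattern, design)
    mults = sorted({m for (_, m) in icols})
    loc_cols = {c[len(loc_prefix):]: c for c in df.columns if c.startswith(loc_prefix)}

    records: list[SiteRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        loc = {}
        for rep, col in loc_cols.items():
            v = rowd[col]
            if pd.isna(v):
                continue
            try:
                v = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"malformed localization probability at row {idx}, column {col!r}"
                )
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"localization probability outside [0, 1] at row {idx}, column {col!r}"
                )
            loc[rep] = v
        try:
            pep = float(rowd.get("PEP", 0.0))
        except (TypeError, ValueError):
            raise ValueError(f"malformed PEP at row {idx}")
        for mult in mults:
            intens = {}
            for (run, m), col in icols.items():
                if m != mult:
                    continue
                v = rowd[col]
                v = 0.0 if pd.isna(v) else float(v)
                if v > 0:  # MaxQuant zero-as-missing convention
                    intens[run] = v
            records.append(
                SiteRecord(
                    site_id=f"{rowd['id']}_M{mult}",
                    protein_ids=_split_list(rowd.get("Proteins")),
                    gene_name=str(rowd.get("Gene names", "")),
                    positions=_split_list(rowd.get("Position"), int),
                    residues=_split_list(rowd.get("Amino acid")),
                    multiplicity=mult,
                    localization_prob=dict(loc),
                    pep=pep,
                    is_contaminant=_flag(rowd.get("Potential contaminant", "")),
                    is_reverse=_flag(rowd.get("Reverse", "")),
                    raw_intensity=intens,
                )
            )
    _check_unique([r.site_id for r in records], "site_id")
    return records


def parse_protein_table(
    path: str | Path,
    design: DesignTable,
    intensity_pattern: str = "LFQ intensity {run}",
) -> list[ProteinRecord]:
    """Parse a ``proteinGroups.txt``-dialect table into protein records."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, low_memory=False,
                     float_precision="round_trip")
    icols = _intensity_columns(df.columns, intensity_pattern, design)
    records: list[ProteinRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        intens = {}
        for (run, _m), col in icols.items():
            v = rowd[col]
            v = 0.0 if pd.isna(v) else float(v)
            if v > 0:
                intens[run] = v
        ibaq = rowd.get("iBAQ")
        records.append(
            ProteinRecord(
                group_id=str(rowd["id"]),
                accessions=_split_list(rowd.get("Majority protein IDs")),
                gene_name=str(rowd.get("Gene names", "")),
                unique_peptides=int(rowd.get("Unique peptides", 0)),
                lfq_intensity=intens,
                is_contaminant=_flag(rowd.get("Potential contaminant", "")),
                is_reverse=_flag(rowd.get("Reverse", "")),
                ibaq=None if ibaq is None or pd.isna(ibaq) else float(ibaq),
            )
        )
    _check_unique([r.group_id for r in records], "group_id")
    return records


def _check_unique(ids: list[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i}")
        seen.add(i)


def _site_meta(records: Sequence[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_key": [r.site_key for r in records],
            "residues": [";".join(r.residues) for r in records],
            "residue_class": [r.residue_class for r in records],
            "positions": [";".join(map(str, r.positions)) for r in records],
            "protein": [r.protein_ids[0] if r.protein_ids else "" for r in records],
            "gene_name": [r.gene_name for r in records],
            "multiplicity": [r.multiplicity for r in records],
            "loc_class": [r.loc_class for r in records],
        },
        index=pd.Index([r.site_id for r in records], name="site_id"),
    )


def build_kinetics_matrix(
    records: Sequence[SiteRecord],
    design: DesignTable,
    dataset: Optional[str] = None,
    enrichment: Optional[str] = None,
) -> KineticsMatrix:
    """Assemble the site x run log2-intensity grid for one channel.

    Rows are ordered by site_id; a site with no intensity in any selected
    run yields an all-missing row (removed later by the missingness
    filter, not here).
    """
    sel = design.subset(dataset=dataset, enrichment=enrichment)
    if not records:
        raise ValueError("no records to build a kinetics matrix from")
    records = sorted(records, key=lambda r: r.site_id)
    runs = sel.runs
    arr = np.full((len(records), len(runs)), np.nan)
    run_ix = {r: j for j, r in enumerate(runs)}
    for i, rec in enumerate(records):
        for run, v in rec.raw_intensity.items():
            j = run_ix.get(run)
            if j is not None:
                arr[i, j] = np.log2(v)
    data = pd.DataFrame(
        arr, index=pd.Index([r.site_id for r in records], name="site_id"), columns=runs
    )
    return KineticsMatrix(
        data=data, design=sel, stage="raw", site_meta=_site_meta(records)
    )


def build_protein_matrix(
    records: Sequence[ProteinRecord],
    design: DesignTable,
    dataset: Optional[str] = None,
    enrichment: str = "preenrich",
) -> KineticsMatrix:
    """Site-matrix analogue for protein LFQ intensities (rows = groups)."""
    sel = design.subset(dataset=dataset, enrichment=enrichment)
    if not records:
        raise ValueError("no protein records")
    records = sorted(records, key=lambda r: r.group_id)
    runs = sel.runs
    arr = np.full((len(records), len(runs)), np.nan)
    run_ix = {r: j for j, r in enumerate(runs)}
    for i, rec in enumerate(records):
        for run, v in rec.lfq_intensity.items():
            j = run_ix.get(run)
            if j is not None:
                arr[i, j] = np.log2(v)
    data = pd.DataFrame(
        arr, index=pd.Index([r.group_id for r in records], name="site_id"), columns=runs
    )
    meta = pd.DataFrame(
        {
            "site_key": [r.accessions[0] if r.accessions else r.group_id for r in records],
            "residues": "",
            "residue_class": "protein",
            "positions": "",
            "protein": [r.accessions[0] if r.accessions else "" for r in records],
            "gene_name": [r.gene_name for r in records],
            "multiplicity": 0,
            "loc_class": None,
            "unique_peptides": [r.unique_peptides for r in records],
        },
        index=pd.Index([r.group_id for r in records], name="site_id"),
    )
    return KineticsMatrix(data=data, design=sel, stage="raw", site_meta=meta)
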