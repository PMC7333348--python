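"""Hypergeometric over-representation of annotation and kinase sets.

Enrichment is tested per scope (a kinetic cluster, or the neighborhood
of an annotated site in the 2D embedding) against a fixed universe —
the set of all units under test (e.g. all TCR-regulated sites). The
upper-tail P(X >= k) convention is used throughout; no across-term
multiple-testing correction is applied, matching the thresholds used to
gate the figures this reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.spatial.distance import cdist

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "EnrichmentThresholds",
    "hypergeom_enrich",
    "local_embedding_enrichment",
    "kinase_activity_profile",
    "KEYWORD_SITE_THRESHOLDS",
    "KINASE_THRESHOLDS",
    "KEYWORD_PROTEIN_THRESHOLDS",
]


@dataclass(frozen=True)
class EnrichmentThresholds:
    p_max: float
    fc_min: float
    k_min: int


#: keyword terms vs sites per kinetic cluster
KEYWORD_SITE_THRESHOLDS = EnrichmentThresholds(p_max=0.01, fc_min=2.0, k_min=2)
#: kinase-substrate sets per cluster
KINASE_THRESHOLDS = EnrichmentThresholds(p_max=0.05, fc_min=2.0, k_min=2)
#: keyword terms at the protein level
KEYWORD_PROTEIN_THRESHOLDS = EnrichmentThresholds(p_max=0.05, fc_min=1.5, k_min=2)


@dataclass
class AnnotationSet:
    """term -> annotated units, restricted to a universe of tested units."""

    terms: dict[str, frozenset]
    universe: frozenset
    kind: str = "keyword_site"

    def __post_init__(self) -> None:
        self.terms = {
            t: frozenset(u) & self.universe for t, u in self.terms.items()
        }
        self.terms = {t: u for t, u in self.terms.items() if u}
        if not self.terms:
            raise ValueError("no annotation term overlaps the universe")

    @classmethod
    def from_table(
        cls, table: pd.DataFrame | str | Path, universe: Iterable, kind: str = "keyword_site"
    ) -> "AnnotationSet":
        """Build from a two-column (term, unit) table or TSV path."""
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t")
        term_col, unit_col = table.columns[:2]
        terms: dict[str, set] = {}
        for t, u in zip(table[term_col], table[unit_col]):
            terms.setdefault(str(t), set()).add(str(u))
        return cls(
            terms={t: frozenset(u) for t, u in terms.items()},
            universe=frozenset(map(str, universe)),
            kind=kind,
        )

    def restrict_terms(self, allowed: Iterable) -> "AnnotationSet":
        """Keep only terms whose name is in ``allowed`` (e.g. expressed kinases)."""
        allowed = set(map(str, allowed))
        kept = {t: u for t, u in self.terms.items() if t in allowed}
        if not kept:
            raise ValueError("no annotation terms left after restriction")
        return AnnotationSet(terms=kept, universe=self.universe, kind=self.kind)


@dataclass
class EnrichmentResult:
    term: str
    scope: str
    k: int  # annotated in scope
    n: int  # scope size
    K: int  # annotated in universe
    N: int  # universe size
    fold_change: float
    p: float
    enriched: bool


def hypergeom_enrich(
    scope_units: Iterable,
    annotation: AnnotationSet,
    thresholds: EnrichmentThresholds = KEYWORD_SITE_THRESHOLDS,
    scope_label: str = "scope",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of every term intersecting the scope."""
    scope = frozenset(map(str, scope_units))
    if not scope <= annotation.universe:
        raise ValueError("scope is not a subset of the annotation universe")
    N = len(annotation.universe)
    n = len(scope)
    out = []
    for term, units in sorted(annotation.terms.items()):
        K = len(units)
        k = len(units & scope)
        if k == 0:
            continue
        fold = (k / n) / (K / N)
        p = float(hypergeom.sf(k - 1, N, K, n))
        out.append(
            EnrichmentResult(
                term=term,
                scope=scope_label,
                k=k,
                n=n,
                K=K,
                N=N,
                fold_change=fold,
                p=p,
                enriched=(
                    p <= thresholds.p_max
                    and fold >= thresholds.fc_min
                    and k >= thresholds.k_min
                ),
            )
        )
    out.sort(key=lambda r: r.p)
    return out


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def local_embedding_enrichment(
    coords: pd.DataFrame,
    annotation: AnnotationSet,
    radius: float = 4.0,
    thresholds: EnrichmentThresholds = KEYWORD_SITE_THRESHOLDS,
) -> pd.DataFrame:
    """Neighborhood enrichment around each annotated site in the embedding.

    For every site carrying a term, the scope is the set of sites within
    Euclidean distance ``radius`` of it (the anchor included) in the
    t-SNE coordinates; the term's representation in that scope is tested
    against the full embedded set. The per-anchor p-value is the
    transparency weight used when highlighting terms on the map.
    """
    ids = [str(i) for i in coords.index]
    if not set(ids) <= annotation.universe:
        raise ValueError("embedding contains sites outside the annotation universe")
    X = coords[["x", "y"]].to_numpy(dtype=float)
    D = cdist(X, X)
    N = len(annotation.universe)
    rows = []
    pos = {s: i for i, s in enumerate(ids)}
    for term, units in sorted(annotation.terms.items()):
        K = len(units)
        for anchor in sorted(units & set(ids)):
            within = np.where(D[pos[anchor]] <= radius)[0]
            scope = {ids[i] for i in within}
            k = len(units & scope)
            n = len(scope)
            p = float(hypergeom.sf(k - 1, N, K, n))
            fold = (k / n) / (K / N)
            rows.append(
                {
                    "term": term,
                    "anchor": anchor,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "fold_change": fold,
                    "p": p,
                    "enriched": (
                        p <= thresholds.p_max
                        and fold >= thresholds.fc_min
                        and k >= thresholds.k_min
                    ),
                }
            )
    return pd.DataFrame(rows)


def kinase_activity_profile(
    cluster_labels: pd.Series,
    kinase_annotation: AnnotationSet,
    expressed_kinases: Iterable,
    thresholds: EnrichmentThresholds = KINASE_THRESHOLDS,
) -> dict[str, pd.DataFrame]:
    """Cluster x kinase substrate-enrichment matrices.

    ``cluster_labels`` maps site_id -> cluster label. Kinase sets are
    restricted to kinases present in the supplied expressed-protein
    list before testing. Returns wide matrices 'p', 'fold_change' and
    'enriched' (clusters as rows, kinases as columns; NaN where a kinase
    has no substrate in a cluster).
    """
    ann = kinase_annotation.restrict_terms(expressed_kinases)
    clusters = sorted(cluster_labels.unique())
    kinases = sorted(ann.terms)
    p = pd.DataFrame(np.nan, index=clusters, columns=kinases)
    fold = pd.DataFrame(np.nan, index=clusters, columns=kinases)
    enr = pd.DataFrame(False, index=clusters, columns=kinases)
    for cl in clusters:
        scope = cluster_labels.index[cluster_labels == cl]
        for r in hypergeom_enrich(scope, ann, thresholds, scope_label=str(cl)):
            p.loc[cl, r.term] = r.p
            fold.loc[cl, r.term] = r.fold_change
            enr.loc[cl, r.term] = r.enriched
    return {"p": p, "fold_change": fold, "enriched": enr}
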