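"""Cross-dataset comparison of independently processed phosphoproteomes.

Two datasets (e.g. CD4+ and OT-I CD8+ T cells) are each taken through
the full pipeline separately; this module joins them on a canonical
site key (leading accession + residue/position + multiplicity), counts
identification/regulation overlaps, and correlates per-site kinetics
over the shared stimulation conditions.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import KineticsMatrix
from .preprocess import replicate_normalize

logger = logging.getLogger(__name__)

__all__ = ["mean_normalize", "overlap", "per_site_correlation"]


def mean_normalize(matrix: KineticsMatrix) -> pd.DataFrame:
    """One kinetic per site: replicate-centered values averaged per condition.

    Each biological replicate's kinetic is centered on its mean
    intensity (grand mean restored), then the replicates are averaged at
    each condition. Works on the imputed matrix so every retained site
    yields a complete or near-complete 6-point kinetic.
    """
    normed = replicate_normalize(matrix)
    arr, reps, conds, _ = normed.to_array()
    with np.errstate(invalid="ignore"):
        means = np.nanmean(arr, axis=1)
    return pd.DataFrame(means, index=matrix.data.index, columns=conds)


def overlap(sets_a: Mapping[str, set], sets_b: Mapping[str, set]) -> pd.DataFrame:
    """Euler counts per stratum (e.g. 'identified', 'regulated').

    ``sets_a``/``sets_b`` map stratum name -> set of site keys.
    """
    rows = []
    for stratum in sorted(set(sets_a) | set(sets_b)):
        a = set(sets_a.get(stratum, set()))
        b = set(sets_b.get(stratum, set()))
        rows.append(
            {
                "stratum": stratum,
                "a_only": len(a - b),
                "b_only": len(b - a),
                "shared": len(a & b),
            }
        )
    return pd.DataFrame(rows)


def per_site_correlation(
    kinetics_a: pd.DataFrame,
    kinetics_b: pd.DataFrame,
    min_shared: int = 4,
) -> pd.Series:
    """Pearson r of the two datasets' kinetics per shared site.

    Only sites with values in both datasets for at least ``min_shared``
    conditions are eligible; zero-variance kinetics are omitted with a
    logged reason. Indexes must be comparable site keys.
    """
    shared_conds = [c for c in kinetics_a.columns if c in set(kinetics_b.columns)]
    shared_sites = kinetics_a.index.intersection(kinetics_b.index)
    out = {}
    for s in shared_sites:
        a = kinetics_a.loc[s, shared_conds].to_numpy(dtype=float)
        b = kinetics_b.loc[s, shared_conds].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_shared:
            continue
        a, b = a[ok], b[ok]
        if np.std(a) == 0 or np.std(b) == 0:
            logger.info("site %s omitted: zero variance on one side", s)
            continue
        out[s] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out, name="pearson_r", dtype=float)
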