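"""TCR-regulation calls by stability selection over repeated imputation.

Each of ``n_iter`` iterations redraws the left-censored imputed values,
re-normalizes replicates, and runs a one-way fixed-effects ANOVA with
Tukey's HSD post hoc per site. A site passes an iteration iff the ANOVA
p <= alpha and at least one pair of time points has (i) more than
``min_pair_points`` observed (non-imputed) replicate values on each
side, (ii) Tukey-adjusted p <= alpha, and (iii) |fold change| at or
above the threshold. A site is called regulated when the fraction of
passing iterations reaches ``frac_min`` (0.9 by default, over 200
iterations).

The Tukey machinery is vectorized across sites: significance is decided
against studentized-range critical values per residual df, and exact
tail probabilities are computed with a Gauss-Legendre quadrature of the
studentized range distribution (validated against scipy's
implementation, which is too slow to call per site per iteration).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import ImputationModel, KineticsMatrix
from .preprocess import (
    _replicate_normalize_array,
    fit_imputation_model,
    observed_counts,
)

__all__ = [
    "RegulationParams",
    "PairwiseResult",
    "RegulationCall",
    "StabilityResult",
    "studentized_range_sf",
    "anova_tukey",
    "stability_select",
    "condition_direction",
    "protein_regulation",
]

LOG2_FC_SITES = math.log2(1.75)


# ---------------------------------------------------------------------------
# Studentized range distribution
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _quad_nodes(k: int, df: int) -> tuple:
    """Precompute quadrature nodes for the studentized range CDF."""
    # outer: s = sigma_hat/sigma ~ sqrt(chi2_df / df); support effectively
    # within (0, hi) where hi covers the upper tail even for small df
    hi = 1.0 + 10.0 / math.sqrt(df)
    xs, ws = np.polynomial.legendre.leggauss(72)
    s = 0.5 * hi * (xs + 1.0)
    w_s = 0.5 * hi * ws
    logc = 0.5 * df * math.log(df) - gammaln(df / 2.0) - (df / 2.0 - 1.0) * math.log(2.0)
    dens = np.exp(logc + (df - 1.0) * np.log(s) - df * s * s / 2.0)
    # inner: z grid for the range probability
    zx, zw = np.polynomial.legendre.leggauss(96)
    z = 8.0 * zx
    w_z = 8.0 * zw
    phi = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    Phi = stats.norm.cdf(z)
    return s, w_s * dens, z, w_z * phi, Phi


def studentized_range_sf(q, k: int, df: int) -> np.ndarray:
    """Upper tail P(Q > q) of the studentized range, vectorized over q.

    ``k`` is the number of groups and ``df`` the residual degrees of
    freedom of the pooled variance estimate.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    s, ws_dens, z, wz_phi, Phi = _quad_nodes(int(k), int(df))
    out = np.empty_like(q)
    for lo in range(0, q.size, 2048):
        qq = q[lo : lo + 2048]
        x = qq[:, None] * s[None, :]  # (m, ns)
        # P(range of k std normals <= x) = k * int phi(z) [Phi(z)-Phi(z-x)]^{k-1} dz
        diff = Phi[None, None, :] - stats.norm.cdf(z[None, None, :] - x[:, :, None])
        np.clip(diff, 0.0, None, out=diff)
        inner = k * np.einsum("j,msj->ms", wz_phi, diff ** (k - 1))
        np.clip(inner, 0.0, 1.0, out=inner)
        out[lo : lo + 2048] = 1.0 - inner @ ws_dens
    np.clip(out, 0.0, 1.0, out=out)
    out[q <= 0] = 1.0
    return out


@functools.lru_cache(maxsize=None)
def _q_crit(alpha: float, k: int, df: int) -> float:
    """Critical studentized-range value (bisection on the quadrature sf)."""
    lo, hi = 1e-6, 60.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if studentized_range_sf(mid, k, df)[0] > alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Vectorized one-way ANOVA + Tukey over a (site, rep, cond) array
# ---------------------------------------------------------------------------

def _anova_arrays(arr: np.ndarray):
    """Per-site one-way ANOVA on (site, rep, cond) values with NaN missing.

    Returns (F, dfb, dfw, means, n_per_cond, msw). Degenerate sites
    (all values equal, zero within-variance) get F = 0 by convention.
    """
    present = np.isfinite(arr)
    n = present.sum(axis=1)  # (site, cond)
    with np.errstate(invalid="ignore"):
        m = np.nanmean(np.where(present, arr, np.nan), axis=1)  # (site, cond)
    N = n.sum(axis=1)
    k = (n > 0).sum(axis=1)
    grand = np.nansum(np.where(present, arr, 0.0), axis=(1, 2)) / np.maximum(N, 1)
    ssb = np.nansum(n * (m - grand[:, None]) ** 2, axis=1)
    resid = np.where(present, arr - m[:, None, :], 0.0)
    ssw = (resid ** 2).sum(axis=(1, 2))
    dfb = np.maximum(k - 1, 1)
    dfw = np.maximum(N - k, 1)
    msw = ssw / dfw
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / msw
    F = np.where(ssw <= 0, np.where(ssb <= 0, 0.0, np.inf), F)
    return F, dfb, dfw, m, n, msw


def _pairs(n_cond: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n_cond), 2))


def _tukey_q(m: np.ndarray, n: np.ndarray, msw: np.ndarray, pairs) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-Kramer q statistics and log2 fold changes for all pairs.

    fc[s, p] = mean(t_j) - mean(t_i) for pair p = (i, j) with i < j.
    """
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    fc = m[:, j] - m[:, i]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(msw[:, None] / 2.0 * (1.0 / n[:, i] + 1.0 / n[:, j]))
        q = np.abs(fc) / se
    q = np.where(se == 0, np.where(np.abs(fc) > 0, np.inf, 0.0), q)
    return q, fc


def _sf_by_df(q: np.ndarray, k: int, dfw: np.ndarray) -> np.ndarray:
    """studentized_range_sf with per-site df, grouped by unique df."""
    out = np.empty_like(q, dtype=float)
    for df in np.unique(dfw):
        sel = dfw == df
        out[sel] = studentized_range_sf(q[sel].ravel(), k, int(df)).reshape(
            out[sel].shape
        )
    return out


# ---------------------------------------------------------------------------
# Public single-site API
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    """One Tukey contrast between two conditions."""

    pair: tuple[int, int]  # (t_i, t_j), timepoints in seconds
    log2_fc: float  # mean(t_j) - mean(t_i)
    tukey_p: float
    n_i: int
    n_j: int


def anova_tukey(
    site_values: Mapping[int, Sequence[float]],
) -> tuple[float, list[PairwiseResult]]:
    """One-way ANOVA with Tukey HSD for a single site.

    ``site_values`` maps condition (time point) -> list of log2 values.
    Requires at least two conditions with >= 2 values. If every value is
    identical (F = 0/0) the convention p = 1 applies.
    """
    conds = sorted(site_values)
    groups = [np.asarray(site_values[c], dtype=float) for c in conds]
    if sum(len(g) >= 2 for g in groups) < 2:
        raise ValueError("need at least 2 conditions with >= 2 values each")
    rmax = max(len(g) for g in groups)
    arr = np.full((1, rmax, len(conds)), np.nan)
    for ci, g in enumerate(groups):
        arr[0, : len(g), ci] = g
    F, dfb, dfw, m, n, msw = _anova_arrays(arr)
    if np.isinf(F[0]):
        p = 0.0
    elif F[0] == 0 and msw[0] == 0:
        p = 1.0
    else:
        p = float(stats.f.sf(F[0], dfb[0], dfw[0]))
    pairs = _pairs(len(conds))
    q, fc = _tukey_q(m, n, msw, pairs)
    k = int((n[0] > 0).sum())
    tp = np.where(
        np.isinf(q[0]), 0.0, studentized_range_sf(np.where(np.isfinite(q[0]), q[0], 0.0), k, int(dfw[0]))
    )
    results = [
        PairwiseResult(
            pair=(conds[i], conds[j]),
            log2_fc=float(fc[0, pi]),
            tukey_p=float(tp[pi]),
            n_i=int(n[0, i]),
            n_j=int(n[0, j]),
        )
        for pi, (i, j) in enumerate(pairs)
    ]
    return p, results


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------

@dataclass
class RegulationParams:
    """Thresholds of the stability-selection procedure.

    ``log2_fc_min`` is log2(1.75) for phosphosites and 1.0 for proteins;
    ``min_pair_points`` is the strict lower bound on observed
    (non-imputed) replicate values per side of a pair ("more than 2
    points per condition").
    """

    n_iter: int = 200
    alpha: float = 0.05
    log2_fc_min: float = LOG2_FC_SITES
    frac_min: float = 0.9
    min_pair_points: int = 2
    base_seed: int = 0
    impute_c: float = 0.3

    @classmethod
    def protein_defaults(cls, **kw) -> "RegulationParams":
        kw.setdefault("log2_fc_min", 1.0)
        return cls(**kw)


@dataclass
class RegulationCall:
    """Stability-selection outcome for one site."""

    site_id: str
    stability_fraction: float
    regulated: bool
    n_iterations: int
    best_pair: Optional[PairwiseResult]
    direction: dict[int, str] = field(default_factory=dict)


@dataclass
class StabilityResult:
    """Calls plus the per-pair iteration summaries needed downstream."""

    calls: list[RegulationCall]
    conditions: list[int]
    pairs: list[tuple[int, int]]  # condition index pairs
    median_fc: np.ndarray  # (site, pair)
    median_tukey_p: np.ndarray  # (site, pair)
    pair_sig_frac: np.ndarray  # fraction of iterations with tukey p <= alpha
    obs_counts: np.ndarray  # (site, cond) observed replicate values
    params: RegulationParams
    site_ids: list[str]

    @property
    def regulated_ids(self) -> list[str]:
        return [c.site_id for c in self.calls if c.regulated]

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable per-site table (one row per site)."""
        rows = []
        for s, call in enumerate(self.calls):
            row = {
                "site_id": call.site_id,
                "stability_fraction": call.stability_fraction,
                "regulated": call.regulated,
                "n_iterations": call.n_iterations,
            }
            if call.best_pair is not None:
                row["best_pair"] = f"{call.best_pair.pair[0]}-{call.best_pair.pair[1]}"
                row["best_pair_log2_fc"] = call.best_pair.log2_fc
                row["best_pair_tukey_p"] = call.best_pair.tukey_p
            for pi, (i, j) in enumerate(self.pairs):
                tag = f"{self.conditions[i]}-{self.conditions[j]}"
                row[f"log2_fc[{tag}]"] = self.median_fc[s, pi]
                row[f"tukey_p[{tag}]"] = self.median_tukey_p[s, pi]
            for t, lab in call.direction.items():
                row[f"direction[{t}]"] = lab
            rows.append(row)
        return pd.DataFrame(rows)


def stability_select(
    matrix: KineticsMatrix,
    params: Optional[RegulationParams] = None,
    model: Optional[ImputationModel] = None,
) -> StabilityResult:
    """Run the repeated impute -> normalize -> ANOVA/Tukey selection.

    ``matrix`` is the filtered, tech-averaged matrix *before* imputation;
    each iteration draws fresh replacement values (seeded
    ``base_seed + iteration``), so a site with no missing cells gives
    identical results in every iteration.
    """
    params = params or RegulationParams()
    if params.n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if model is None:
        model = fit_imputation_model(matrix, c=params.impute_c, seed=params.base_seed)
    arr, reps, conds, valid = matrix.to_array()
    S = arr.shape[0]
    present = np.isfinite(arr)
    obs_n = present.sum(axis=1)  # (site, cond) observed values
    needs = obs_n <= 1
    fill = needs[:, None, :] & ~present & valid[None, :, :]
    n_fill = int(fill.sum())
    pairs = _pairs(len(conds))
    P = len(pairs)

    pass_count = np.zeros(S, dtype=int)
    sig_pair_count = np.zeros((S, P), dtype=int)
    fc_store = np.empty((params.n_iter, S, P), dtype=np.float32)
    q_store = np.empty((params.n_iter, S, P), dtype=np.float32)

    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    pair_obs_ok = (obs_n[:, i_idx] > params.min_pair_points) & (
        obs_n[:, j_idx] > params.min_pair_points
    )

    for it in range(params.n_iter):
        rng = np.random.default_rng(params.base_seed + it)
        vals = arr.copy()
        if n_fill:
            vals[fill] = rng.normal(model.q05, model.draw_sd, size=n_fill)
        vals = _replicate_normalize_array(vals)
        F, dfb, dfw, m, n, msw = _anova_arrays(vals)
        with np.errstate(invalid="ignore"):
            anova_sig = np.where(
                np.isinf(F), True, stats.f.sf(np.where(np.isfinite(F), F, 0.0), dfb, dfw) <= params.alpha
            )
        q, fc = _tukey_q(m, n, msw, pairs)
        # per-df critical values; dfw is iteration-invariant (fill pattern fixed)
        qcrit = np.empty(S)
        k_groups = (n > 0).sum(axis=1)
        for df in np.unique(dfw):
            sel = dfw == df
            kk = int(k_groups[sel][0])
            qcrit[sel] = _q_crit(params.alpha, kk, int(df))
        tukey_sig = q >= qcrit[:, None]
        pair_pass = tukey_sig & pair_obs_ok & (np.abs(fc) >= params.log2_fc_min)
        pass_count += (anova_sig & pair_pass.any(axis=1)).astype(int)
        sig_pair_count += tukey_sig.astype(int)
        fc_store[it] = fc
        q_store[it] = q

    median_fc = np.median(fc_store, axis=0)
    median_q = np.median(q_store.astype(float), axis=0)
    _, _, dfw, _, n, _ = _anova_arrays(
        np.where(fill, 0.0, np.where(present, arr, np.nan))
    )
    k = len(conds)
    median_p = _sf_by_df(np.where(np.isfinite(median_q), median_q, 0.0), k, dfw)
    median_p = np.where(np.isinf(median_q), 0.0, median_p)
    sig_frac = sig_pair_count / params.n_iter
    frac = pass_count / params.n_iter

    calls = []
    for s, site in enumerate(matrix.sites):
        usable = np.where(pair_obs_ok[s])[0]
        cand = usable if usable.size else np.arange(P)
        order = sorted(
            cand, key=lambda pi: (median_p[s, pi], -abs(median_fc[s, pi]))
        )
        pi = order[0]
        i, j = pairs[pi]
        best = PairwiseResult(
            pair=(conds[i], conds[j]),
            log2_fc=float(median_fc[s, pi]),
            tukey_p=float(median_p[s, pi]),
            n_i=int(obs_n[s, i]),
            n_j=int(obs_n[s, j]),
        )
        calls.append(
            RegulationCall(
                site_id=site,
                stability_fraction=float(frac[s]),
                regulated=bool(frac[s] >= params.frac_min),
                n_iterations=params.n_iter,
                best_pair=best,
            )
        )
    return StabilityResult(
        calls=calls,
        conditions=list(conds),
        pairs=pairs,
        median_fc=median_fc,
        median_tukey_p=median_p,
        pair_sig_frac=sig_frac,
        obs_counts=obs_n,
        params=params,
        site_ids=list(matrix.sites),
    )


def condition_direction(result: StabilityResult) -> pd.DataFrame:
    """Per (site, condition) up/down/none labels vs the unstimulated point.

    A condition is 'up' when the median-iteration log2 fold change vs
    t = 0 reaches the threshold and the Tukey contrast is significant in
    >= frac_min of iterations; 'down' symmetrically.
    """
    conds = result.conditions
    base = 0
    if base not in conds:
        raise ValueError("no unstimulated (t = 0) condition present")
    b = conds.index(base)
    out = {}
    for pi, (i, j) in enumerate(result.pairs):
        if i != b:
            continue
        t = conds[j]
        fc = result.median_fc[:, pi]
        stable = result.pair_sig_frac[:, pi] >= result.params.frac_min
        lab = np.where(
            stable & (fc >= result.params.log2_fc_min),
            "up",
            np.where(stable & (fc <= -result.params.log2_fc_min), "down", "none"),
        )
        out[t] = lab
    df = pd.DataFrame(out, index=result.site_ids)
    for s, call in enumerate(result.calls):
        call.direction = {t: df.iloc[s][t] for t in df.columns}
    return df


def protein_regulation(
    matrix: KineticsMatrix,
    params: Optional[RegulationParams] = None,
    min_unique_peptides: int = 2,
) -> StabilityResult:
    """Stability selection on protein LFQ kinetics.

    Same machinery as for sites with |log2 FC| >= 1; protein groups with
    fewer than 2 unique peptides are removed before testing.
    """
    params = params or RegulationParams.protein_defaults()
    if "unique_peptides" in matrix.site_meta.columns:
        ok = matrix.site_meta["unique_peptides"] >= min_unique_peptides
        matrix = matrix.subset(matrix.site_meta.index[ok])
    return stability_select(matrix, params)
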