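"""Co-essentiality mapping against a query gene.

Two genes are co-essential when their fitness-effect profiles correlate
across many cell lines, suggesting shared function.  The screen ranks
all genes by Pearson correlation with the query, converts r to a
two-sided p-value via the t transform, controls the FDR with
Benjamini–Hochberg, and derives the correlation cutoff from the elbow
("inflection point") of the descending ranked-coefficient curve.  A gene
passes when its BH-adjusted p-value is < alpha and its coefficient
strictly exceeds the elbow threshold.

Because genes syntenic with the query (same chromosome) inflate
correlations, the screen optionally drops a chromosome *before* BH
adjustment and threshold detection, mirroring the recommended
non-syntenic re-analysis.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FitnessScreen
from .errors import DegenerateCurveError, InputError, QueryLookupError

MIN_SHARED_LINES = 30


def pearson_profile(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p between two fitness profiles.

    Missing entries are removed pairwise; at least 3 complete pairs and
    non-zero variance in both vectors are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("profiles differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InputError(f"only {n} complete pairs; need >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance makes the correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    p = _r_to_p(np.array([r]), n)[0]
    return r, float(p)


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of Pearson r via the t-distribution transform."""
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    return np.clip(p, 0.0, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def inflection_threshold(r_sorted_desc) -> float:
    """Elbow of a descending ranked-coefficient curve (kneedle-style).

    Both axes are min-max scaled; the threshold is the coefficient at
    the index maximising perpendicular distance from the chord joining
    the first and last points.  Distance ties break toward the larger
    coefficient (the more conservative cutoff).
    """
    r = np.asarray(r_sorted_desc, dtype=float)
    if r.ndim != 1 or len(r) < 3:
        raise InputError("need a 1-D descending vector of length >= 3")
    if np.any(np.diff(r) > 0):
        raise InputError("coefficients must be sorted descending")
    x = np.linspace(0.0, 1.0, len(r))
    span = r[0] - r[-1]
    if span == 0:
        raise DegenerateCurveError("flat curve has no elbow")
    y = (r - r[-1]) / span
    # distance from chord y = 1 - x, up to the constant 1/sqrt(2)
    d = np.abs(x + y - 1.0)
    if np.max(d) <= 1e-12:
        raise DegenerateCurveError("curve is linear; all chord distances ~ 0")
    best = int(np.flatnonzero(d >= np.max(d) - 1e-12)[0])  # earliest index = larger r
    return float(r[best])


@dataclass
class ScreenResult:
    """Ranked co-essentiality table plus the detected threshold."""

    rows: pd.DataFrame  # columns: gene, r, p, q, chrom, passes (sorted by r desc)
    threshold: float
    query: str


def coessential_screen(
    screen: FitnessScreen,
    query: str,
    exclude_chrom: Optional[str] = None,
    alpha: float = 0.05,
    min_shared: int = MIN_SHARED_LINES,
) -> ScreenResult:
    """Screen every gene's fitness profile against the query gene's.

    Genes on ``exclude_chrom`` are dropped before BH adjustment and
    threshold detection.  Genes with fewer than ``min_shared`` complete
    line pairs are reported with r = NaN and excluded from BH and the
    threshold.  The query's self-correlation is excluded from threshold
    detection and never flagged as passing.
    """
    if query not in screen.genes:
        raise QueryLookupError(query)
    fit = screen.fitness
    if exclude_chrom is not None:
        keep = screen.chrom.loc[fit.index] != str(exclude_chrom)
        if query in fit.index[~keep]:
            raise InputError(f"query {query!r} lies on excluded chromosome {exclude_chrom}")
        fit = fit.loc[keep]

    X = fit.to_numpy(dtype=float)
    q_vec = screen.fitness.loc[query].to_numpy(dtype=float)
    q_ok = ~np.isnan(q_vec)

    n_genes = X.shape[0]
    r = np.full(n_genes, np.nan)
    n_shared = np.zeros(n_genes, dtype=int)
    row_nan = np.isnan(X).any(axis=1)
    dense = ~row_nan & q_ok.all()
    if dense.any():
        sub = X[dense]
        qs = q_vec
        qc = qs - qs.mean()
        sc = sub - sub.mean(axis=1, keepdims=True)
        denom = np.sqrt((sc**2).sum(axis=1) * (qc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r[dense] = (sc @ qc) / denom
        n_shared[dense] = len(qs)
    for i in np.flatnonzero(~dense):
        xi = X[i]
        keep = ~(np.isnan(xi) | np.isnan(q_vec))
        n_shared[i] = int(keep.sum())
        if n_shared[i] >= min_shared and np.ptp(xi[keep]) > 0 and np.ptp(q_vec[keep]) > 0:
            r[i] = np.corrcoef(xi[keep], q_vec[keep])[0, 1]
    r = np.clip(r, -1.0, 1.0)
    r[n_shared < min_shared] = np.nan

    rows = pd.DataFrame(
        {
            "gene": fit.index,
            "r": r,
            "chrom": screen.chrom.loc[fit.index].to_numpy(),
            "n": n_shared,
        }
    )
    valid = rows["r"].notna()
    p = np.full(n_genes, np.nan)
    # per-gene n can differ under missingness; use each gene's own df
    for n_val in np.unique(rows.loc[valid, "n"]):
        m = valid.to_numpy() & (rows["n"].to_numpy() == n_val)
        p[m] = _r_to_p(rows.loc[m, "r"].to_numpy(), int(n_val))
    rows["p"] = p
    q = np.full(n_genes, np.nan)
    q[valid.to_numpy()] = bh_adjust(rows.loc[valid, "p"].to_numpy())
    rows["q"] = q

    non_self = rows["gene"] != query
    r_rank = np.sort(rows.loc[valid & non_self, "r"].to_numpy())[::-1]
    threshold = inflection_threshold(r_rank)

    rows["passes"] = (
        valid & non_self & (rows["q"] < alpha) & (rows["r"] > threshold)
    )
    rows = rows.sort_values("r", ascending=False, kind="mergesort").reset_index(drop=True)
    return ScreenResult(rows=rows[["gene", "r", "p", "q", "chrom", "n", "passes"]],
                        threshold=threshold, query=query)
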