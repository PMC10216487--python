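"""In silico synthetic-lethality screening with a permutation null.

For every gene, lethality probabilities (0 = knockout tolerated,
1 = knockout lethal) are compared between a small mutant cell-line
group and a large control group with a two-sided Mann–Whitney U test.
Because the mutant group is tiny (two lines in the motivating design),
per-gene permutation of the labels exhausts its few distinct
arrangements; instead the raw p-values are adjusted against a null pool
built by shuffling group labels across lines and collecting the
re-computed p-values across *all* genes and permutations.  The add-one
(Phipson–Smyth) estimate

    p_adj(g) = (1 + #{null p <= p_obs(g)}) / (1 + #null draws)

never returns zero and is monotone in the observed p-value.

A gene is called a synthetic-lethal (SL) interactor when its adjusted
p-value is < 0.05, the larger group median exceeds 0.5, and the mutant
median exceeds the control median; the mirrored configuration is an
alleviating interaction.  The signed interaction score
``sign(median_mut - median_wt) * -log10(p_adj)`` ranks hits.
"""
from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigError, InputError

EXACT_PRODUCT_LIMIT = 400       # min(n)·max(n) bound for the untied exact branch
ENUM_LIMIT = 100_000            # C(n+m, min) bound for the tied enumeration branch


def mw_test(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Small untied samples use the exact distribution; small tied samples
    use exhaustive enumeration of label assignments (two-sided p as
    twice the smaller tail, capped at 1); everything else uses the
    tie-corrected normal approximation with continuity correction.
    Returns ``(U, p)`` with U counted for sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    small = min(a.size, b.size) * max(a.size, b.size) <= EXACT_PRODUCT_LIMIT
    if ties and comb(a.size + b.size, min(a.size, b.size)) <= ENUM_LIMIT:
        return _mw_exact_enum(a, b)
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _u_stat(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def _mw_exact_enum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exhaustive permutation distribution of U, tie-aware."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    na = len(a)
    u_obs = _u_stat(a, b)
    us = np.array(
        [
            _u_stat(pooled[list(idx)], np.delete(pooled, list(idx)))
            for idx in combinations(range(n), na)
        ]
    )
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return u_obs, float(min(1.0, 2.0 * min(lo, hi)))


def _rank_matrix(leth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks per gene (rows) and the per-gene tie-correction term."""
    ranks = stats.rankdata(leth, axis=1)
    n = leth.shape[1]
    tie_term = np.zeros(leth.shape[0])
    for i in range(leth.shape[0]):
        _, counts = np.unique(leth[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    return ranks, tie_term / (n * (n - 1.0))


def _u_to_p(u: np.ndarray, n1: int, n2: int, tie_term: np.ndarray) -> np.ndarray:
    """Vectorised two-sided normal-approximation p with tie correction.

    Matches scipy's asymptotic method (continuity correction included).
    ``u`` may be genes × permutations; ``tie_term`` broadcasts per gene.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u - mu) - 0.5) / sigma
    p = 2.0 * stats.norm.sf(np.maximum(z, 0.0))
    p = np.where(sigma == 0, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def _mutant_mask(lines: Sequence[str], groups: Mapping[str, str],
                 mutant_group: str, control_group: str) -> tuple[np.ndarray, np.ndarray]:
    g = np.array([groups.get(l) for l in lines], dtype=object)
    mut = g == mutant_group
    ctl = g == control_group
    if mut.sum() < 2 or ctl.sum() < 2:
        raise InputError(
            f"need >= 2 lines per group; got {int(mut.sum())} {mutant_group!r} "
            f"and {int(ctl.sum())} {control_group!r}"
        )
    return mut, ctl


def screen_pvalues(
    leth: pd.DataFrame,
    groups: Mapping[str, str],
    mutant_group: str = "HomDel",
    control_group: str = "WT",
) -> pd.DataFrame:
    """Observed per-gene U statistics, p-values and group medians.

    Uses the tie-corrected normal approximation for every gene so that
    the observed p-values are exchangeable with the permutation null
    pool built by :func:`perm_adjust`.
    """
    mut, ctl = _mutant_mask(leth.columns, groups, mutant_group, control_group)
    sub = leth.loc[:, mut | ctl]
    mut_sub = mut[mut | ctl]
    X = sub.to_numpy(dtype=float)
    ranks, tie_term = _rank_matrix(X)
    n1 = int(mut_sub.sum())
    n2 = X.shape[1] - n1
    u = ranks[:, mut_sub].sum(axis=1) - n1 * (n1 + 1) / 2.0
    p = _u_to_p(u, n1, n2, tie_term)
    return pd.DataFrame(
        {
            "gene": leth.index,
            "u_stat": u,
            "p_raw": p,
            "median_mut": np.median(X[:, mut_sub], axis=1),
            "median_wt": np.median(X[:, ~mut_sub], axis=1),
        }
    ).set_index("gene", drop=False)


def perm_adjust(
    p_obs: np.ndarray,
    leth: pd.DataFrame,
    groups: Mapping[str, str],
    n_perm: int,
    seed: int,
    mutant_group: str = "HomDel",
    control_group: str = "WT",
) -> np.ndarray:
    """Permutation-pool adjustment of observed p-values.

    Group labels are shuffled across the mutant + control lines
    ``n_perm`` times; each permutation recomputes every gene's
    Mann–Whitney p, and all null p-values are pooled across genes and
    permutations.  Returns the add-one empirical tail probability of
    each observed p in that pool.
    """
    if n_perm < 100:
        raise ConfigError(f"n_perm={n_perm} < 100 gives an unstable null tail")
    p_obs = np.asarray(p_obs, dtype=float)
    mut, ctl = _mutant_mask(leth.columns, groups, mutant_group, control_group)
    sub = leth.loc[:, mut | ctl]
    X = sub.to_numpy(dtype=float)
    n_lines = X.shape[1]
    n1 = int(mut.sum())
    n2 = n_lines - n1

    ranks, tie_term = _rank_matrix(X)
    rng = np.random.default_rng(seed)
    # permute the smaller group's label: |U - mu| is the same whichever group
    # is selected, so the null pool is exactly invariant under a label swap
    n_sel = min(n1, n2)
    sel = np.zeros((n_lines, n_perm))
    for j in range(n_perm):
        sel[rng.permutation(n_lines)[:n_sel], j] = 1.0
    rank_sums = ranks @ sel                      # genes × permutations
    u_null = rank_sums - n_sel * (n_sel + 1) / 2.0
    p_null = _u_to_p(u_null, n_sel, n_lines - n_sel, tie_term[:, None])

    pool = np.sort(p_null, axis=None)
    counts = np.searchsorted(pool, p_obs, side="right")
    return (1.0 + counts) / (1.0 + pool.size)


def call_interactors(
    rows: pd.DataFrame,
    essential_list: Iterable[str] = (),
    nonessential_list: Iterable[str] = (),
    alpha: float = 0.05,
    median_floor: float = 0.5,
) -> pd.DataFrame:
    """Drop known (non)essential genes and call SL/alleviating interactors.

    ``rows`` needs columns gene, p_adj, median_mut, median_wt.  A gene
    is ``SL`` when p_adj < alpha, the larger median exceeds
    ``median_floor``, and the mutant median is the larger one;
    ``alleviating`` mirrors the direction; ``none`` otherwise.
    """
    drop = set(essential_list) | set(nonessential_list)
    out = rows.loc[~rows["gene"].isin(drop)].copy()
    sig = (out["p_adj"] < alpha) & (
        np.maximum(out["median_mut"], out["median_wt"]) > median_floor
    )
    call = np.where(
        sig & (out["median_mut"] > out["median_wt"]), "SL",
        np.where(sig & (out["median_wt"] > out["median_mut"]), "alleviating", "none"),
    )
    out["call"] = call
    out["interaction_score"] = interaction_score(
        out["median_mut"].to_numpy(), out["median_wt"].to_numpy(), out["p_adj"].to_numpy()
    )
    return out


def interaction_score(median_mut, median_wt, p_adj):
    """Signed significance: ``sign(median_mut - median_wt) * -log10(p_adj)``."""
    return np.sign(np.asarray(median_mut) - np.asarray(median_wt)) * (
        -np.log10(np.asarray(p_adj, dtype=float))
    )


def sl_screen(
    leth: pd.DataFrame,
    groups: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    mutant_group: str = "HomDel",
    control_group: str = "WT",
    essential_list: Iterable[str] = (),
    nonessential_list: Iterable[str] = (),
) -> pd.DataFrame:
    """Full screen: observed tests, permutation adjustment, interactor calls."""
    rows = screen_pvalues(leth, groups, mutant_group, control_group)
    rows["p_adj"] = perm_adjust(
        rows["p_raw"].to_numpy(), leth, groups, n_perm, seed, mutant_group, control_group
    )
    rows = call_interactors(rows, essential_list, nonessential_list)
    return rows.sort_values("interaction_score", ascending=False, kind="mergesort")


def jaccard_term_clusters(term_sets: Mapping[str, Iterable], k: int) -> dict[str, int]:
    """Average-linkage clustering of annotation terms by Jaccard distance.

    Terms with identical member sets always co-cluster for any k below
    the number of distinct sets.  Returns term -> cluster id (1..k).
    """
    terms = sorted(term_sets)
    sets = [frozenset(term_sets[t]) for t in terms]
    if any(not s for s in sets):
        raise InputError("every term set must be non-empty")
    if k > len(terms):
        raise InputError(f"k={k} exceeds number of terms ({len(terms)})")
    if k < 1:
        raise InputError("k must be positive")
    if len(terms) == 1:
        return {terms[0]: 1}
    n = len(terms)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jac = len(sets[i] & sets[j]) / len(sets[i] | sets[j])
            dist[i, j] = dist[j, i] = 1.0 - jac
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                      t=k, criterion="maxclust")
    return dict(zip(terms, (int(c) for c in labels)))
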