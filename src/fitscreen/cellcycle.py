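"""Cell-cycle phase assignment and phase-stratified DE filtering.

Single cells are scored for the five classical expression-programme
phases (G1/S, S, G2, G2/M, M/G1) from marker gene sets: each gene is
z-scored across cells, a cell's phase score is the mean z over that
phase's markers, and the assigned phase is the strict unique positive
maximum — cells with no positive score or a tied maximum stay
``UNASSIGNED``.  This is the standard marker-score assignment used with
the Whitfield phase gene sets; the strict-unique-positive filter stands
in for the reference implementation's default filtering criteria and is
pluggable.

Differential-expression results computed per phase (by an external
negative-binomial model) are filtered by the conventional thresholds:
adjusted p < 0.05 and linear fold-change > 1.5.  Genes the DE model
declined to test (adjusted p of NA, e.g. below an expression filter)
are labelled ``NC`` (not calculated) rather than non-significant.
"""
from __future__ import annotations

from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

PHASES = ("G1_S", "S", "G2", "G2_M", "M_G1")
UNASSIGNED = "UNASSIGNED"
FC_THRESHOLD = 1.5
LOG2_FC_THRESHOLD = float(np.log2(FC_THRESHOLD))


def _strict_unique_positive_max(scores: np.ndarray, phases: Sequence[str]) -> str:
    """Default assignment filter: strict unique argmax, and it must be > 0."""
    top = scores.max()
    if top <= 0:
        return UNASSIGNED
    winners = np.flatnonzero(scores >= top - 1e-12)
    if len(winners) != 1:
        return UNASSIGNED
    return phases[winners[0]]


def score_phases(
    norm_expr: pd.DataFrame,
    marker_sets: Mapping[str, Sequence[str]],
    assign: Optional[Callable[[np.ndarray, Sequence[str]], str]] = None,
) -> pd.DataFrame:
    """Score cells (rows) for each phase and assign the winning phase.

    ``norm_expr`` is a cells × genes matrix of normalised expression
    (normalisation itself is upstream of this package).  Returns a
    DataFrame indexed by cell with one score column per phase plus an
    ``assigned`` column.
    """
    phases = list(marker_sets)
    present: dict[str, list[str]] = {}
    for phase in phases:
        genes = [g for g in marker_sets[phase] if g in norm_expr.columns]
        if not genes:
            raise ConfigError(f"phase {phase!r} has no marker genes in the matrix")
        present[phase] = genes

    X = norm_expr.to_numpy(dtype=float)
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (X - mu) / sd, 0.0)
    zdf = pd.DataFrame(z, index=norm_expr.index, columns=norm_expr.columns)

    out = pd.DataFrame(index=norm_expr.index)
    for phase in phases:
        out[phase] = zdf[present[phase]].mean(axis=1)
    assign = assign or _strict_unique_positive_max
    score_mat = out[phases].to_numpy()
    out["assigned"] = [assign(score_mat[i], phases) for i in range(len(out))]
    return out


def de_filter(rows: pd.DataFrame, alpha: float = 0.05,
              fc_threshold: float = FC_THRESHOLD) -> pd.DataFrame:
    """Label DE rows UP / DOWN / NS / NC.

    ``rows`` needs columns gene, log2fc, p_adj (NaN where the model did
    not test the gene).  The fold-change threshold is applied on the
    linear scale, i.e. ``|log2fc| > log2(fc_threshold)``.  Idempotent
    and row-order invariant.
    """
    out = rows.copy()
    log2_thr = np.log2(fc_threshold)
    p = out["p_adj"].to_numpy(dtype=float)
    lfc = out["log2fc"].to_numpy(dtype=float)
    nc = np.isnan(p)
    sig = ~nc & (p < alpha) & (np.abs(lfc) > log2_thr)
    out["status"] = np.select(
        [nc, sig & (lfc > 0), sig & (lfc < 0)],
        ["NC", "UP", "DOWN"],
        default="NS",
    )
    return out


def phase_counts(assignments: pd.DataFrame) -> dict[str, int]:
    """Cells per assigned phase, excluding UNASSIGNED."""
    if len(assignments) == 0:
        return {}
    counts = assignments["assigned"].value_counts()
    return {
        phase: int(n) for phase, n in counts.items() if phase != UNASSIGNED
    }
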