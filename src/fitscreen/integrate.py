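"""Cross-evidence integration across assays.

Each assay contributes a gene set — co-essentiality, the SL screen,
top-K co-expression, IP-MS detections in each cell-line background,
ChIP binding — and the evidence table records, per gene, which assays
support it.  ``high_confidence`` is always derived (detected by IP-MS
in both backgrounds), never supplied.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError, InputError

EVIDENCE_FLAGS = (
    "coessential",
    "sl",
    "coexpressed_topK",
    "ipms_hek",
    "ipms_nha",
    "high_confidence",
    "chip_bound",
)
_SUPPLIABLE = frozenset(EVIDENCE_FLAGS) - {"high_confidence"}


def topk_coexpressed(z: Mapping[str, float], k: int) -> set[str]:
    """The k genes with the largest co-expression z-scores.

    Boundary ties break lexicographically by gene symbol, so exactly k
    genes are always returned.
    """
    if k <= 0:
        raise InputError(f"k must be positive, got {k}")
    if k > len(z):
        raise InputError(f"k={k} exceeds number of genes ({len(z)})")
    ranked = sorted(z, key=lambda g: (-z[g], g))
    return set(ranked[:k])


def replicate_support(
    detections: Mapping[str, Iterable[str]], min_reps: int
) -> set[str]:
    """Genes detected in at least ``min_reps`` replicates."""
    if min_reps > len(detections):
        raise InputError(
            f"min_reps={min_reps} exceeds number of replicates ({len(detections)})"
        )
    counts: dict[str, int] = {}
    for genes in detections.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    return {g for g, n in counts.items() if n >= min_reps}


def evidence_table(sources: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Wide per-gene evidence table over the union of all source sets.

    ``sources`` maps a flag name (any suppliable member of
    :data:`EVIDENCE_FLAGS`) to its gene set.  ``high_confidence`` is
    derived as ``ipms_hek AND ipms_nha``.  Order-invariant and
    idempotent; one row per gene, sorted by symbol.
    """
    unknown = set(sources) - _SUPPLIABLE
    if unknown:
        raise ConfigError(
            f"unknown or non-suppliable source name(s): {sorted(unknown)}"
        )
    sets = {name: set(genes) for name, genes in sources.items()}
    universe = sorted(set().union(*sets.values())) if sets else []
    table = pd.DataFrame(index=pd.Index(universe, name="gene"))
    for flag in EVIDENCE_FLAGS:
        if flag == "high_confidence":
            continue
        table[flag] = [g in sets.get(flag, set()) for g in universe]
    table["high_confidence"] = table["ipms_hek"] & table["ipms_nha"]
    return table[list(EVIDENCE_FLAGS)]
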