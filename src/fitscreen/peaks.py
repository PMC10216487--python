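"""Interval-set operations on ChIP-seq peak sets.

Coordinates are strictly 0-based half-open (BED convention): the peak
``[100, 200)`` covers bases 100..199, and abutting intervals such as
``[100, 200)`` / ``[200, 300)`` do not overlap.  Overlap is counted per
query peak — a query overlapping three subject peaks contributes one —
matching how replicate-supported and cross-factor peak counts are
reported in practice.

Significance of an overlap of ``k`` of ``n_a`` query peaks with a set of
``n_b`` subject peaks is assessed with an upper-tail hypergeometric test
over a finite population of ``total_test`` testable sites (250,000 by
default, a recommendation for stem-cell genomes).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import InputError, ParseError

DEFAULT_TOTAL_TEST = 250_000


@dataclass(frozen=True, order=True)
class Peak:
    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )


@dataclass(frozen=True)
class OverlapTest:
    n_a: int
    n_b: int
    k: int
    total_test: int
    p: float


def _by_chrom(peaks: Iterable[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """chrom -> (starts sorted, prefix-max of ends in start order)."""
    grouped: dict[str, list[Peak]] = {}
    for p in peaks:
        grouped.setdefault(p.chrom, []).append(p)
    out = {}
    for chrom, ps in grouped.items():
        ps.sort(key=lambda p: (p.start, p.end))
        starts = np.array([p.start for p in ps])
        ends = np.maximum.accumulate(np.array([p.end for p in ps]))
        out[chrom] = (starts, ends)
    return out


def _overlaps_any(index: dict, peak: Peak) -> bool:
    if peak.chrom not in index:
        return False
    starts, prefix_max_end = index[peak.chrom]
    # candidates are subject peaks starting before the query's end
    i = int(np.searchsorted(starts, peak.end, side="left"))
    return i > 0 and prefix_max_end[i - 1] > peak.start


def replicate_intersect(rep1: Sequence[Peak], rep2: Sequence[Peak]) -> list[Peak]:
    """Peaks of ``rep1`` with at least one base of overlap in ``rep2``."""
    index = _by_chrom(rep2)
    return [p for p in rep1 if _overlaps_any(index, p)]


def overlap_count(a: Sequence[Peak], b: Sequence[Peak]) -> int:
    """Number of ``a`` peaks overlapping ``b`` (each counted once)."""
    return len(replicate_intersect(a, b))


def hypergeom_overlap(
    n_a: int, n_b: int, k: int, total_test: int = DEFAULT_TOTAL_TEST
) -> OverlapTest:
    """Upper-tail hypergeometric probability of observing >= k overlaps.

    Models the ``n_a`` query peaks as draws without replacement from a
    population of ``total_test`` sites of which ``n_b`` are subject-bound:
    ``p = P(X >= k)`` for X ~ Hypergeom(total_test, n_b, n_a).
    """
    if k > min(n_a, n_b):
        raise InputError(f"overlap k={k} exceeds min(n_a={n_a}, n_b={n_b})")
    if min(n_a, n_b, k) < 0:
        raise InputError("counts must be non-negative")
    if max(n_a, n_b) > total_test:
        raise InputError("peak-set sizes exceed total_test population")
    p = float(hypergeom.sf(k - 1, total_test, n_b, n_a))
    return OverlapTest(n_a=n_a, n_b=n_b, k=k, total_test=total_test, p=p)


def overlap_test(
    a: Sequence[Peak], b: Sequence[Peak], total_test: int = DEFAULT_TOTAL_TEST
) -> OverlapTest:
    """Convenience wrapper: count per-query overlaps then test them."""
    return hypergeom_overlap(len(a), len(b), overlap_count(a, b), total_test)
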