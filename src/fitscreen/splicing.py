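"""Splicing-entropy scoring and replicate-based differential-splicing calls.

Works on PSI (proportion-spliced-in, Ψ ∈ [0, 1]) event tables in the
eight-type vocabulary of splice-graph quantifiers: core exon (CE),
alternative acceptor/donor (AA/AD), alternative first/last exon
(AF/AL), retained intron (RI), and tandem transcription start / end
sites (TS/TE).

* Isoform complexity is summarised by the Shannon entropy (bits) of an
  isoform-usage vector; an event with entropy > 1.5 bits (more than
  three effectively expressed isoforms) is "high entropy".
* A differential-splicing call compares mean Ψ between two conditions;
  since the upstream quantifier's posterior probability is not
  available here, the call's confidence is a replicate-bootstrap
  sign-stability probability: the fraction of within-condition
  resamples whose ΔΨ keeps the observed sign.  An event is significant
  when |ΔΨ| > 0.1 and probability > 0.9 (both strict).
* Significant TS/TE events are classified as lengthening or shortening
  the corresponding UTR from the node's position relative to the coding
  region in transcription direction: increased usage of the proximal
  (coding-side) terminal node shortens the UTR.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

EVENT_TYPES = ("CE", "AA", "AD", "AF", "AL", "RI", "TS", "TE")
UTR_TYPES = ("TS", "TE")
HIGH_ENTROPY_THRESHOLD = 1.5
DPSI_THRESHOLD = 0.1
PROB_THRESHOLD = 0.9


@dataclass(frozen=True)
class SplicingEvent:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    etype: str
    psi_by_rep: Mapping[tuple[str, int], float]

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise InputError(f"unknown event type {self.etype!r}")
        if self.strand not in {"+", "-"}:
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        for key, psi in self.psi_by_rep.items():
            if not 0.0 <= psi <= 1.0:
                raise InputError(f"Ψ={psi} outside [0, 1] for replicate {key}")

    @property
    def node(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def conditions(self) -> list[str]:
        return sorted({cond for cond, _ in self.psi_by_rep})

    def psi_vector(self, condition: str) -> np.ndarray:
        reps = sorted(r for c, r in self.psi_by_rep if c == condition)
        return np.array([self.psi_by_rep[(condition, r)] for r in reps])


@dataclass(frozen=True)
class DiffCall:
    event: SplicingEvent
    dpsi: float
    probability: float
    significant: bool
    utr_direction: str = "not_applicable"


def entropy(usage) -> float:
    """Shannon entropy in bits of an isoform-usage vector.

    The vector must be non-negative and sum to 1 within 1e-9; zero
    entries contribute nothing (0·log 0 = 0).  Bounded by
    [0, log2(len(usage))].
    """
    u = np.asarray(usage, dtype=float)
    if np.any(u < 0):
        raise InputError("usage proportions must be non-negative")
    if abs(u.sum() - 1.0) > 1e-9:
        raise InputError(f"usage proportions sum to {u.sum()!r}, not 1")
    nz = u[u > 0]
    return float(-np.sum(nz * np.log2(nz)))


def classify_high_entropy(e: float, threshold: float = HIGH_ENTROPY_THRESHOLD) -> bool:
    """True iff the entropy score strictly exceeds the threshold."""
    if e < 0:
        raise InputError("entropy scores are non-negative")
    return e > threshold


def diff_splice(
    event: SplicingEvent,
    n_boot: int = 1000,
    seed: int = 0,
    condition_a: Optional[str] = None,
    condition_b: Optional[str] = None,
    dpsi_threshold: float = DPSI_THRESHOLD,
    prob_threshold: float = PROB_THRESHOLD,
) -> DiffCall:
    """Differential-splicing call for one event.

    ΔΨ = mean Ψ(B) − mean Ψ(A); conditions default to the event's two
    condition labels in sorted order.  The probability is the fraction
    of ``n_boot`` within-condition replicate resamples (with
    replacement) whose ΔΨ is non-zero with the same sign as the
    observed ΔΨ; a zero observed ΔΨ has probability 0.  Deterministic
    given the seed.
    """
    conds = event.conditions()
    if condition_a is None or condition_b is None:
        if len(conds) != 2:
            raise InputError(
                f"event has conditions {conds}; specify condition_a/condition_b"
            )
        condition_a, condition_b = conds
    a = event.psi_vector(condition_a)
    b = event.psi_vector(condition_b)
    if a.size < 2 or b.size < 2:
        raise InputError("need >= 2 replicates per condition")

    dpsi = float(b.mean() - a.mean())
    if dpsi == 0.0:
        prob = 0.0
    else:
        rng = np.random.default_rng(seed)
        ia = rng.integers(0, a.size, size=(n_boot, a.size))
        ib = rng.integers(0, b.size, size=(n_boot, b.size))
        deltas = b[ib].mean(axis=1) - a[ia].mean(axis=1)
        prob = float(np.mean((np.sign(deltas) == np.sign(dpsi)) & (deltas != 0)))
    significant = abs(dpsi) > dpsi_threshold and prob > prob_threshold
    return DiffCall(event=event, dpsi=dpsi, probability=prob, significant=significant)


def _tx_coord(pos: float, strand: str) -> float:
    """Map a genomic coordinate to a transcription-direction axis."""
    return pos if strand == "+" else -pos


def utr_direction(
    call: DiffCall,
    gene_span: tuple[int, int],
    strand: Optional[str] = None,
    sibling_nodes: Sequence[tuple[int, int]] = (),
) -> DiffCall:
    """Classify a significant TS/TE call as UTR lengthening or shortening.

    ``gene_span`` is the gene's (start, end) on genomic coordinates;
    ``sibling_nodes`` are the (start, end) coordinates of the gene's
    other terminal nodes of the same type (the node itself may be
    included).  A node is *proximal* when it lies nearer the coding
    region than the midrange of its sibling set — for TE nodes the
    coding region is 5′-ward (earlier in transcription), for TS nodes it
    is 3′-ward.  Increased usage (ΔΨ > 0) of a proximal node shortens
    the UTR; of a distal node, lengthens it; ΔΨ < 0 mirrors the call.
    On the − strand smaller genomic coordinates are 3′-ward, handled by
    working on a transcription-direction axis.

    Without siblings the gene span decides: a node more than its own
    length away from the transcription-direction span end (for TE; span
    start for TS) is proximal.  Events of any other type come back
    ``not_applicable`` without error.
    """
    ev = call.event
    if ev.etype not in UTR_TYPES:
        return replace(call, utr_direction="not_applicable")
    strand = strand or ev.strand
    if call.dpsi == 0.0:
        return replace(call, utr_direction="not_applicable")

    mid = _tx_coord((ev.start + ev.end) / 2.0, strand)
    span_lo, span_hi = sorted(gene_span)
    t5 = _tx_coord(span_lo if strand == "+" else span_hi, strand)  # transcription start side
    t3 = _tx_coord(span_hi if strand == "+" else span_lo, strand)  # transcription end side

    sibs = [_tx_coord((s + e) / 2.0, strand) for s, e in sibling_nodes]
    if mid not in sibs:
        sibs.append(mid)
    if len(sibs) > 1:
        midrange = (min(sibs) + max(sibs)) / 2.0
        if ev.etype == "TE":
            proximal = mid < midrange  # earlier poly-A, nearer the coding region
        else:
            proximal = mid > midrange  # later TSS, nearer the coding region
        if mid == midrange:  # equidistant pair collapses to the span rule
            proximal = _span_rule(ev, mid, t5, t3)
    else:
        proximal = _span_rule(ev, mid, t5, t3)

    shortened = (call.dpsi > 0) == proximal
    return replace(call, utr_direction="shortened" if shortened else "lengthened")


def _span_rule(ev: SplicingEvent, mid: float, t5: float, t3: float) -> bool:
    node_len = ev.end - ev.start
    if ev.etype == "TE":
        return (t3 - mid) > node_len
    return (mid - t5) > node_len


def compare_entropy_distributions(e_a, e_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test on entropy scores."""
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    if e_a.size == 0 or e_b.size == 0:
        raise InputError("both entropy samples must be non-empty")
    res = stats.ks_2samp(e_a, e_b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def tally_events(calls: Sequence[DiffCall]) -> pd.DataFrame:
    """Count significant calls by (event type, UTR direction).

    Returns a DataFrame indexed by (type, direction) with columns
    ``n_events`` and ``n_genes`` (distinct genes).  Non-TS/TE types
    tally under direction ``not_applicable``.
    """
    buckets: dict[tuple[str, str], list[str]] = {}
    for call in calls:
        if not call.significant:
            continue
        key = (call.event.etype, call.utr_direction)
        buckets.setdefault(key, []).append(call.event.gene)
    rows = [
        {"type": t, "direction": d, "n_events": len(genes), "n_genes": len(set(genes))}
        for (t, d), genes in sorted(buckets.items())
    ]
    return pd.DataFrame(rows, columns=["type", "direction", "n_events", "n_genes"])


def events_from_psi_tables(
    table_a: pd.DataFrame, table_b: pd.DataFrame,
    cond_a: str = "A", cond_b: str = "B",
) -> list[SplicingEvent]:
    """Assemble :class:`SplicingEvent` objects from two replicate Ψ tables.

    Tables need columns gene, node (``chrom:start-end``), strand, type,
    rep, psi, as written by :func:`fitscreen.simkit.sim_psi_tables` or
    read from a Whippet-dialect TSV.
    """
    merged: dict[tuple, dict] = {}
    for cond, table in ((cond_a, table_a), (cond_b, table_b)):
        for row in table.itertuples(index=False):
            chrom, span = str(row.node).rsplit(":", 1)
            start_s, end_s = span.split("-")
            key = (row.gene, chrom, int(start_s), int(end_s), row.strand, row.type)
            merged.setdefault(key, {})[(cond, int(row.rep))] = float(row.psi)
    return [
        SplicingEvent(gene=g, chrom=c, start=s, end=e, strand=st, etype=t,
                      psi_by_rep=psis)
        for (g, c, s, e, st, t), psis in merged.items()
    ]
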