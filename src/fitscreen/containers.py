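"""Shared in-memory containers for screen-level data.

A :class:`FitnessScreen` bundles the two matrices a DepMap-style
genome-wide CRISPR knockout screen provides — per-gene fitness-effect
scores (negative = knockout reduces viability) and lethality
probabilities (0 = dispensable, 1 = essential for that line) — together
with a gene → chromosome map used by the synteny filter.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError


@dataclass
class FitnessScreen:
    """Genes × cell-lines fitness matrices plus a chromosome map.

    Parameters
    ----------
    fitness
        DataFrame indexed by gene symbol, one column per cell line,
        holding fitness-effect scores.
    lethality
        Same shape/labels as ``fitness``; lethality probabilities in [0, 1].
    chrom
        Series mapping gene symbol to chromosome identifier (string).
    """

    fitness: pd.DataFrame
    lethality: pd.DataFrame
    chrom: pd.Series

    def __post_init__(self) -> None:
        if not self.fitness.index.equals(self.lethality.index):
            raise InputError("fitness and lethality matrices disagree on genes")
        if not self.fitness.columns.equals(self.lethality.columns):
            raise InputError("fitness and lethality matrices disagree on cell lines")
        missing = self.fitness.index.difference(self.chrom.index)
        if len(missing):
            raise InputError(f"chromosome map missing {len(missing)} genes, e.g. {missing[0]!r}")
        lo, hi = self.lethality.min().min(), self.lethality.max().max()
        if lo < 0 or hi > 1:
            raise InputError("lethality probabilities must lie in [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.fitness.index

    @property
    def lines(self) -> pd.Index:
        return self.fitness.columns
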