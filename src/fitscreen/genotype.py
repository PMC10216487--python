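"""Cell-line genotype grouping from variant and copy-number calls.

Lines carrying alterations in a query tumour-suppressor gene are
partitioned into four groups by severity:

``HomDel``
    any homozygous deleterious variant, or a deep copy-number loss;
``T_HetDel``
    potentially trans-heterozygous — two or more heterozygous
    deleterious variants, or one such variant combined with partial
    copy-number loss;
``HetDel``
    a single heterozygous deleterious variant, or partial copy-number
    loss alone;
``WT``
    no qualifying alteration.

"Deleterious" defaults to the protein-truncating consequence classes
and is configurable (e.g. to admit damaging missense calls).  Variants
may additionally be annotated as exclusive to the long (L) isoform of
the gene; a homozygous-deleterious line whose every deleterious variant
is L-exclusive keeps the ``HomDel`` label but is flagged ``l_only``,
since the short isoform may retain activity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import InputError, ParseError

CONSEQUENCES = frozenset(
    {"frameshift", "nonsense", "splice_site", "start_loss", "stop_loss",
     "missense", "silent", "other"}
)
DEFAULT_DELETERIOUS = frozenset(
    {"frameshift", "nonsense", "splice_site", "start_loss", "stop_loss"}
)
ZYGOSITIES = frozenset({"hom", "het"})
REGIONS = frozenset({"shared", "L_exclusive", "other"})
GROUPS = ("HomDel", "T_HetDel", "HetDel", "WT")


@dataclass(frozen=True)
class VariantCall:
    line_id: str
    gene: str
    consequence: str
    zygosity: str
    region: str = "shared"
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ParseError(
                f"unknown consequence {self.consequence!r} for line {self.line_id!r}"
            )
        if self.zygosity not in ZYGOSITIES:
            raise ParseError(
                f"unknown zygosity {self.zygosity!r} for line {self.line_id!r}"
            )
        if self.region not in REGIONS:
            raise ParseError(
                f"unknown region {self.region!r} for line {self.line_id!r}"
            )


@dataclass(frozen=True)
class CopyNumberCall:
    line_id: str
    gene: str
    cn_class: str

    def __post_init__(self) -> None:
        if self.cn_class not in {"neutral", "partial_loss", "deep_loss"}:
            raise ParseError(
                f"unknown cn_class {self.cn_class!r} for line {self.line_id!r}"
            )


@dataclass(frozen=True)
class GroupLabel:
    line_id: str
    group: str
    l_only: bool = False


def is_deleterious(v: VariantCall, rules: Iterable[str] = DEFAULT_DELETERIOUS) -> bool:
    """True iff the variant's consequence class is in ``rules``."""
    rules = frozenset(rules)
    if not rules:
        raise InputError("deleterious-consequence rule set must be non-empty")
    return v.consequence in rules


def classify_line(
    variants: Sequence[VariantCall],
    cn: Optional[CopyNumberCall] = None,
    rules: Iterable[str] = DEFAULT_DELETERIOUS,
) -> GroupLabel:
    """Assign one of the four genotype groups to a single cell line."""
    line_ids = {v.line_id for v in variants} | ({cn.line_id} if cn is not None else set())
    if len(line_ids) > 1:
        raise InputError(f"calls mix line ids: {sorted(line_ids)}")
    if not line_ids:
        raise InputError("no calls supplied; cannot determine line id")
    line_id = line_ids.pop()

    dels = [v for v in variants if is_deleterious(v, rules)]
    hom_dels = [v for v in dels if v.zygosity == "hom"]
    het_dels = [v for v in dels if v.zygosity == "het"]
    cn_class = cn.cn_class if cn is not None else "neutral"

    if hom_dels or cn_class == "deep_loss":
        l_only = bool(dels) and all(v.region == "L_exclusive" for v in dels) and cn_class != "deep_loss"
        return GroupLabel(line_id, "HomDel", l_only=l_only)
    partial = cn_class == "partial_loss"
    if len(het_dels) >= 2 or (len(het_dels) >= 1 and partial):
        return GroupLabel(line_id, "T_HetDel")
    if len(het_dels) == 1 or partial:
        return GroupLabel(line_id, "HetDel")
    return GroupLabel(line_id, "WT")


def annotate_isoform_region(
    v: VariantCall,
    shared_intervals: Sequence[tuple[int, int]],
    L_only_intervals: Sequence[tuple[int, int]],
) -> VariantCall:
    """Tag a variant as shared vs long-isoform-exclusive.

    Intervals are 0-based half-open on the same coordinate system as the
    variant position.  A position falling only in the L-only intervals is
    ``L_exclusive``; anywhere in the shared intervals it is ``shared``.
    A position outside both interval sets is flagged with a warning and
    tagged ``other``.
    """
    if v.position is None:
        raise InputError(f"variant for line {v.line_id!r} lacks a position")
    pos = v.position
    in_shared = any(s <= pos < e for s, e in shared_intervals)
    in_l = any(s <= pos < e for s, e in L_only_intervals)
    if in_shared:
        return replace(v, region="shared")
    if in_l:
        return replace(v, region="L_exclusive")
    warnings.warn(
        f"position {pos} of variant in line {v.line_id!r} falls outside both "
        "isoform interval sets; region set to 'other'",
        stacklevel=2,
    )
    return replace(v, region="other")


def classify_table(
    variants: pd.DataFrame,
    cn: Optional[pd.DataFrame] = None,
    rules: Iterable[str] = DEFAULT_DELETERIOUS,
) -> pd.DataFrame:
    """Classify every line in a MAF-like variant table.

    ``variants`` needs columns line_id, gene, consequence, zygosity and
    optionally region/position; ``cn`` needs line_id, gene, cn_class.
    Lines appearing only in ``cn`` are classified from copy number alone.
    Returns a DataFrame with columns line_id, group, l_only.
    """
    cn_by_line: dict[str, CopyNumberCall] = {}
    if cn is not None:
        for row in cn.itertuples(index=False):
            call = CopyNumberCall(str(row.line_id), str(row.gene), str(row.cn_class))
            if call.line_id in cn_by_line:
                raise InputError(f"multiple copy-number calls for line {call.line_id!r}")
            cn_by_line[call.line_id] = call

    var_by_line: dict[str, list[VariantCall]] = {}
    for row in variants.itertuples(index=False):
        v = VariantCall(
            line_id=str(row.line_id),
            gene=str(row.gene),
            consequence=str(row.consequence),
            zygosity=str(row.zygosity),
            region=str(getattr(row, "region", "shared")),
            position=int(row.position) if getattr(row, "position", None) is not None else None,
        )
        var_by_line.setdefault(v.line_id, []).append(v)

    records = []
    for line_id in sorted(set(var_by_line) | set(cn_by_line)):
        label = classify_line(
            var_by_line.get(line_id, []), cn_by_line.get(line_id), rules
        )
        records.append((label.line_id, label.group, label.l_only))
    return pd.DataFrame(records, columns=["line_id", "group", "l_only"])
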