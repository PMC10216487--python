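"""Readers and writers for the dialects the pipeline consumes and emits.

Formats covered:

* DepMap-dialect CSV — first column ``SYMBOL (entrez_id)``, one column
  per cell line;
* MAF-like variant TSV and copy-number TSV;
* MatrixMarket counts (``matrix.mtx`` + ``barcodes.tsv`` +
  ``features.tsv``) for single-cell count matrices;
* BED6, 0-based half-open;
* Whippet-dialect PSI TSV (gene, node ``chrom:start-end``, strand,
  type, condition, rep, psi);
* two-column marker-set TSV (phase, gene) and plain gene-list text;
* a YAML simulation config for :class:`fitscreen.simkit.SimConfig`.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .errors import ParseError
from .peaks import Peak
from .simkit import SimConfig

_DEPMAP_COL = re.compile(r"^(?P<symbol>\S+)\s+\((?P<entrez>\d+)\)$")


def write_depmap_csv(df: pd.DataFrame, path, entrez_ids: Mapping[str, int] | None = None) -> None:
    """Write a genes × lines matrix with DepMap-style gene labels."""
    out = df.copy()
    out.index = [
        f"{g} ({entrez_ids[g] if entrez_ids else i + 1})"
        for i, g in enumerate(df.index)
    ]
    out.index.name = "gene"
    out.to_csv(path)


def read_depmap_csv(path) -> pd.DataFrame:
    """Read a DepMap-dialect CSV back to a symbol-indexed matrix."""
    df = pd.read_csv(path, index_col=0)
    symbols = []
    for label in df.index:
        m = _DEPMAP_COL.match(str(label))
        if not m:
            raise ParseError(f"gene label {label!r} is not 'SYMBOL (id)'")
        symbols.append(m.group("symbol"))
    df.index = pd.Index(symbols, name="gene")
    return df


def write_maf(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"line_id", "gene", "consequence", "zygosity"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"variant table missing columns {sorted(missing)}")
    return df


def write_counts_mtx(counts: pd.DataFrame, outdir) -> None:
    """Write a cells × genes count matrix as MTX + barcodes/features TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # MTX convention stores genes (features) as rows
    mmwrite(str(outdir / "matrix.mtx"), csr_matrix(counts.to_numpy().T))
    (outdir / "barcodes.tsv").write_text("\n".join(counts.index) + "\n")
    (outdir / "features.tsv").write_text("\n".join(counts.columns) + "\n")


def read_counts_mtx(outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    mat = mmread(str(outdir / "matrix.mtx")).toarray().T
    barcodes = (outdir / "barcodes.tsv").read_text().splitlines()
    features = (outdir / "features.tsv").read_text().splitlines()
    return pd.DataFrame(mat, index=barcodes, columns=features)


def write_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t0\t.\n")


def read_bed(path) -> list[Peak]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            out.append(Peak(fields[0], start, end, name))
    return out


def write_psi(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_psi(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "node", "strand", "type", "rep", "psi"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"PSI table missing columns {sorted(missing)}")
    return df


def read_marker_sets(path) -> dict[str, list[str]]:
    """Two-column TSV (phase, gene) → phase → gene list."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'phase<TAB>gene'")
            sets.setdefault(parts[0], []).append(parts[1])
    return sets


def read_gene_list(path) -> list[str]:
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def load_sim_config(path) -> SimConfig:
    """Build a :class:`SimConfig` from a declarative YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return SimConfig(
            n_genes=int(raw["n_genes"]),
            n_lines=int(raw["n_lines"]),
            group_sizes=dict(raw["group_sizes"]),
            planted_coessential=tuple(
                (tuple(int(g) for g in module["genes"]), float(module["rho"]))
                for module in raw.get("planted_coessential", [])
            ),
            planted_sl=tuple(
                (int(item["gene"]), float(item["delta"]))
                for item in raw.get("planted_sl", [])
            ),
            noise_sd=float(raw.get("noise_sd", 1.0)),
            seed=int(raw.get("seed", 0)),
            mutant_groups=tuple(raw.get("mutant_groups", ("HomDel",))),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed simulation config {path}: {exc}") from exc
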