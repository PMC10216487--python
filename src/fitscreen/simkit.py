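"""Synthetic-data generators with planted, recoverable ground truth.

Every downstream stage of the pipeline has a generator here that plants
the statistical structure that stage is meant to recover:

* :func:`sim_fitness_screen` — a genes × cell-lines fitness matrix with
  Gaussian background, co-essential modules sharing a latent factor
  (pairwise correlation ≈ ρ), and a lethality-probability matrix with
  group-specific shifts planted for synthetic-lethal genes in mutant
  lines.
* :func:`sim_mutation_table` — variant and copy-number calls that
  round-trip through :func:`fitscreen.genotype.classify_line` to the
  intended genotype group for every line.
* :func:`sim_phase_counts` — negative-binomial single-cell counts with
  each cell's true-phase marker genes boosted.
* :func:`sim_psi_tables` — replicate Ψ tables with planted ΔΨ.
* :func:`sim_peak_sets` — paired BED-style interval sets with an exact
  number of overlapping pairs.

Determinism: each generator is a pure function of its arguments
including the seed.  Per-element substreams are derived by feeding
``(seed, stream-tag, element-index)`` into :class:`numpy.random.SeedSequence`,
so enlarging a simulation leaves previously generated elements unchanged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import FitnessScreen
from .errors import ConfigError
from .peaks import Peak

PHASES = ("G1_S", "S", "G2", "G2_M", "M_G1")
GROUPS = ("HomDel", "T_HetDel", "HetDel", "WT")
CHROMS = tuple(str(c) for c in range(1, 23))

# stream tags keep substreams for different purposes disjoint
_STREAM_GENE_NOISE = 1
_STREAM_LATENT = 2
_STREAM_MUTATION = 3
_STREAM_PHASE = 4
_STREAM_PSI = 5
_STREAM_PEAKS = 6


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


@dataclass(frozen=True)
class SimConfig:
    """Declarative description of one synthetic fitness screen.

    Parameters
    ----------
    n_genes, n_lines
        Matrix dimensions.
    group_sizes
        Genotype-group → number of lines; must sum to ``n_lines``.
    planted_coessential
        Sequence of ``(gene_indices, rho)`` modules.  Genes in a module
        share a latent factor with loading sqrt(rho); at the default
        ``noise_sd`` of 1 the expected pairwise Pearson r equals rho.
    planted_sl
        Sequence of ``(gene_index, delta_median)`` synthetic-lethal
        plants: the gene's lethality probability is shifted upward by
        ``delta_median`` in every line of the mutant groups.
    noise_sd
        Scale of the per-gene idiosyncratic Gaussian noise.
    mutant_groups
        Group labels whose lines receive the planted lethality shifts.
    logistic_slope, background_median_p
        Lethality probability is ``expit(-slope * fitness + logit(p0))``;
        a background gene (median fitness 0) thus has median lethality
        ``p0`` (default 0.05, so planted shifts of up to ~0.9 stay in
        range without clipping).
    """

    n_genes: int
    n_lines: int
    group_sizes: Mapping[str, int]
    planted_coessential: Sequence[tuple[Sequence[int], float]] = ()
    planted_sl: Sequence[tuple[int, float]] = ()
    noise_sd: float = 1.0
    seed: int = 0
    mutant_groups: Sequence[str] = ("HomDel",)
    logistic_slope: float = 2.0
    background_median_p: float = 0.05

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_lines < 1:
            raise ConfigError("n_genes and n_lines must be positive")
        if sum(self.group_sizes.values()) != self.n_lines:
            raise ConfigError(
                f"group_sizes sum to {sum(self.group_sizes.values())}, expected n_lines={self.n_lines}"
            )
        if any(size < 0 for size in self.group_sizes.values()):
            raise ConfigError("group sizes must be non-negative")
        for genes, rho in self.planted_coessential:
            if not 0 < rho <= 1:
                raise ConfigError(f"planted correlation rho={rho} outside (0, 1]")
            for g in genes:
                if not 0 <= g < self.n_genes:
                    raise ConfigError(f"planted co-essential gene index {g} out of range")
        for g, delta in self.planted_sl:
            if not 0 <= g < self.n_genes:
                raise ConfigError(f"planted SL gene index {g} out of range")
            if not 0 < delta <= 1:
                raise ConfigError(f"planted SL shift {delta} outside (0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.planted_sl:
            unknown = set(self.mutant_groups) - set(self.group_sizes)
            if unknown:
                raise ConfigError(f"mutant_groups {sorted(unknown)} absent from group_sizes")


@dataclass
class SimTruth:
    """Ground truth planted by a generator call."""

    coessential_genes: set = field(default_factory=set)
    sl_genes: set = field(default_factory=set)
    line_groups: dict = field(default_factory=dict)
    phase_of_cell: dict = field(default_factory=dict)
    true_dpsi: dict = field(default_factory=dict)


def gene_symbol(i: int) -> str:
    return f"G{i:05d}"


def line_id(i: int) -> str:
    return f"LINE{i:04d}"


def line_groups(cfg: SimConfig) -> dict[str, str]:
    """Deterministic line → group assignment: groups fill in declared order."""
    out: dict[str, str] = {}
    i = 0
    for group, size in cfg.group_sizes.items():
        for _ in range(size):
            out[line_id(i)] = group
            i += 1
    return out


def sim_fitness_screen(cfg: SimConfig) -> tuple[FitnessScreen, SimTruth]:
    """Simulate a fitness screen with planted co-essential and SL structure."""
    cfg.validate()
    genes = [gene_symbol(i) for i in range(cfg.n_genes)]
    lines = [line_id(i) for i in range(cfg.n_lines)]
    groups = line_groups(cfg)

    # module membership: gene index -> (module index, rho)
    membership: dict[int, tuple[int, float]] = {}
    for m, (module_genes, rho) in enumerate(cfg.planted_coessential):
        for g in module_genes:
            if g in membership:
                raise ConfigError(f"gene index {g} planted in more than one module")
            membership[g] = (m, rho)

    latents = {
        m: _rng(cfg.seed, _STREAM_LATENT, m).standard_normal(cfg.n_lines)
        for m in range(len(cfg.planted_coessential))
    }

    fitness = np.empty((cfg.n_genes, cfg.n_lines))
    for g in range(cfg.n_genes):
        eps = _rng(cfg.seed, _STREAM_GENE_NOISE, g).standard_normal(cfg.n_lines)
        if g in membership:
            m, rho = membership[g]
            fitness[g] = np.sqrt(rho) * latents[m] + np.sqrt(1.0 - rho) * cfg.noise_sd * eps
        else:
            fitness[g] = cfg.noise_sd * eps

    leth = expit(-cfg.logistic_slope * fitness + logit(cfg.background_median_p))

    mutant_cols = np.array([groups[l] in set(cfg.mutant_groups) for l in lines])
    clipped = 0
    for g, delta in cfg.planted_sl:
        shifted = leth[g, mutant_cols] + delta
        clipped += int(np.sum(shifted > 1))
        leth[g, mutant_cols] = np.clip(shifted, 0.0, 1.0)
    if clipped:
        warnings.warn(
            f"planted lethality shifts clipped {clipped} probabilities to 1.0",
            stacklevel=2,
        )

    chrom = pd.Series([CHROMS[i % len(CHROMS)] for i in range(cfg.n_genes)], index=genes)
    screen = FitnessScreen(
        fitness=pd.DataFrame(fitness, index=genes, columns=lines),
        lethality=pd.DataFrame(leth, index=genes, columns=lines),
        chrom=chrom,
    )
    truth = SimTruth(
        coessential_genes={gene_symbol(g) for g in membership},
        sl_genes={gene_symbol(g) for g, _ in cfg.planted_sl},
        line_groups=groups,
    )
    return screen, truth


def sim_mutation_table(
    cfg: SimConfig, gene: str = "CIC", gene_length: int = 5000
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Emit variant + copy-number tables realising each line's intended group.

    The construction alternates between the alternative routes into each
    group so both arms of every classification rule are exercised:
    HomDel lines get one homozygous frameshift; T-HetDel lines alternate
    between two het nonsense variants and one het variant plus partial
    copy loss; HetDel lines alternate between a single het frameshift
    and partial copy loss alone; WT lines get at most a silent passenger.
    Every line receives a copy-number row so the cohort is recoverable
    from the tables alone.
    """
    cfg.validate()
    groups = line_groups(cfg)
    rng = _rng(cfg.seed, _STREAM_MUTATION)
    var_rows = []
    cn_rows = []
    for i, (lid, group) in enumerate(groups.items()):
        cn_class = "neutral"
        positions = rng.integers(0, gene_length, size=2)
        if group == "HomDel":
            var_rows.append((lid, gene, "frameshift", "hom", "shared", int(positions[0])))
        elif group == "T_HetDel":
            if i % 2 == 0:
                var_rows.append((lid, gene, "nonsense", "het", "shared", int(positions[0])))
                var_rows.append((lid, gene, "nonsense", "het", "shared", int(positions[1])))
            else:
                var_rows.append((lid, gene, "frameshift", "het", "shared", int(positions[0])))
                cn_class = "partial_loss"
        elif group == "HetDel":
            if i % 2 == 0:
                var_rows.append((lid, gene, "frameshift", "het", "shared", int(positions[0])))
            else:
                cn_class = "partial_loss"
        elif group == "WT":
            if i % 2 == 0:
                var_rows.append((lid, gene, "silent", "het", "shared", int(positions[0])))
        else:
            raise ConfigError(f"unknown genotype group {group!r}")
        cn_rows.append((lid, gene, cn_class))

    variants = pd.DataFrame(
        var_rows,
        columns=["line_id", "gene", "consequence", "zygosity", "region", "position"],
    )
    cn = pd.DataFrame(cn_rows, columns=["line_id", "gene", "cn_class"])
    truth = SimTruth(line_groups=groups)
    return variants, cn, truth


def sim_phase_counts(
    n_cells: int,
    marker_sets: Mapping[str, Sequence[str]],
    boost: float,
    seed: int,
    background_mean: float = 1.0,
    nb_size: float = 10.0,
    n_background_genes: int = 50,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phase-structured single-cell counts.

    Background counts are negative binomial with mean ``background_mean``
    and size (inverse-dispersion) ``nb_size``; the marker genes of each
    cell's true phase have their mean multiplied by ``boost``.  True
    phases cycle deterministically over cells.
    """
    if boost <= 1:
        warnings.warn(
            f"boost={boost} <= 1 leaves no recoverable phase signal", stacklevel=2
        )
    phases = list(marker_sets)
    if not phases:
        raise ConfigError("marker_sets must name at least one phase")
    marker_genes = sorted({g for genes in marker_sets.values() for g in genes})
    genes = marker_genes + [f"BG{i:04d}" for i in range(n_background_genes)]
    cells = [f"CELL{i:05d}" for i in range(n_cells)]
    true_phase = {cells[i]: phases[i % len(phases)] for i in range(n_cells)}

    mean = np.full((n_cells, len(genes)), background_mean)
    gene_pos = {g: j for j, g in enumerate(genes)}
    for i, cell in enumerate(cells):
        for g in marker_sets[true_phase[cell]]:
            mean[i, gene_pos[g]] = background_mean * boost

    rng = _rng(seed, _STREAM_PHASE)
    p = nb_size / (nb_size + mean)
    counts = rng.negative_binomial(nb_size, p)
    df = pd.DataFrame(counts, index=cells, columns=genes)
    return df, SimTruth(phase_of_cell=true_phase)


def sim_psi_tables(
    events: Sequence[Mapping],
    n_reps: int,
    true_dpsi: Mapping[str, float],
    dispersion: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate Ψ tables for two conditions with planted ΔΨ.

    Each event mapping needs keys ``gene, chrom, start, end, strand,
    type, psi`` (the condition-A mean Ψ).  Condition B's mean is
    ``psi + true_dpsi[event_id]`` where the event id is
    ``"gene:chrom:start-end"``; events absent from ``true_dpsi`` get
    ΔΨ = 0.  Per-replicate Ψ is Beta-distributed around the condition
    mean with concentration ``1/dispersion``; ``dispersion = 0`` emits
    the mean exactly.
    """
    if dispersion < 0:
        raise ConfigError("dispersion must be non-negative")
    if n_reps < 1:
        raise ConfigError("n_reps must be positive")
    rows_a, rows_b = [], []
    for k, ev in enumerate(events):
        eid = f"{ev['gene']}:{ev['chrom']}:{ev['start']}-{ev['end']}"
        psi_a = float(ev["psi"])
        dpsi = float(true_dpsi.get(eid, 0.0))
        psi_b = psi_a + dpsi
        if not (0 <= psi_a <= 1 and 0 <= psi_b <= 1):
            raise ConfigError(
                f"event {eid}: Ψ={psi_a} with ΔΨ={dpsi} leaves [0, 1]"
            )
        rng = _rng(seed, _STREAM_PSI, k)
        for cond, mean_psi, rows in (("A", psi_a, rows_a), ("B", psi_b, rows_b)):
            for rep in range(1, n_reps + 1):
                if dispersion == 0:
                    psi = mean_psi
                else:
                    kappa = 1.0 / dispersion
                    m = min(max(mean_psi, 1e-9), 1 - 1e-9)
                    psi = float(rng.beta(m * kappa, (1 - m) * kappa))
                rows.append(
                    (ev["gene"], f"{ev['chrom']}:{ev['start']}-{ev['end']}",
                     ev["strand"], ev["type"], cond, rep, psi)
                )
    cols = ["gene", "node", "strand", "type", "condition", "rep", "psi"]
    return pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols)


def sim_peak_sets(
    n_a: int,
    n_b: int,
    n_shared: int,
    genome_size: int,
    min_gap: int,
    seed: int,
    peak_length: int = 200,
    overlap_bp: int = 50,
) -> tuple[list[Peak], list[Peak]]:
    """Two peak sets with exactly ``n_shared`` overlapping pairs.

    Shared pairs overlap by ``overlap_bp`` bases; all other peaks (and
    pair blocks) are separated by at least ``min_gap`` bases on a single
    chromosome.  Raises :class:`ConfigError` if the layout cannot fit in
    ``genome_size``.
    """
    if n_shared > min(n_a, n_b):
        raise ConfigError("n_shared exceeds one of the set sizes")
    if overlap_bp >= peak_length:
        raise ConfigError("overlap_bp must be smaller than peak_length")
    n_blocks = n_shared + (n_a - n_shared) + (n_b - n_shared)
    pair_span = 2 * peak_length - overlap_bp
    needed = (
        n_shared * pair_span
        + (n_a - n_shared + n_b - n_shared) * peak_length
        + max(n_blocks - 1, 0) * min_gap
    )
    if needed > genome_size:
        raise ConfigError(
            f"cannot pack {n_a}+{n_b} peaks ({needed} bp incl. gaps) into genome of {genome_size} bp"
        )
    slack = genome_size - needed
    rng = _rng(seed, _STREAM_PEAKS)
    # distribute spare room over the gaps (and the leading offset) at random
    extra = rng.multinomial(slack, np.ones(n_blocks + 1) / (n_blocks + 1)) if n_blocks else [slack]

    a_peaks: list[Peak] = []
    b_peaks: list[Peak] = []
    pos = int(extra[0])
    block = 0
    for i in range(n_shared):
        a_peaks.append(Peak("chr1", pos, pos + peak_length, f"a_shared_{i}"))
        b_start = pos + peak_length - overlap_bp
        b_peaks.append(Peak("chr1", b_start, b_start + peak_length, f"b_shared_{i}"))
        pos = b_start + peak_length + min_gap
        block += 1
        pos += int(extra[block])
    for i in range(n_a - n_shared):
        a_peaks.append(Peak("chr1", pos, pos + peak_length, f"a_only_{i}"))
        pos += peak_length + min_gap
        block += 1
        pos += int(extra[block])
    for i in range(n_b - n_shared):
        b_peaks.append(Peak("chr1", pos, pos + peak_length, f"b_only_{i}"))
        pos += peak_length + min_gap
        block += 1
        pos += int(extra[block])
    return a_peaks, b_peaks
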