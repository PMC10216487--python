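# Methods

`fitscreen` implements an in silico genetic-interaction analysis suite
around genome-wide CRISPR knockout fitness screens, together with the
companion analyses such a study typically layers on top (single-cell
cell-cycle phase scoring, ChIP peak-overlap testing, differential
splicing on PSI tables, and cross-assay evidence integration).  Every
stage has a synthetic-data generator with planted, recoverable ground
truth, so the statistical guarantees of each method can be tested
without any external download.

## Fitness screens and the synthetic world

A screen is a pair of genes × cell-lines matrices: *fitness-effect
scores* (negative = knockout reduces viability) and *lethality
probabilities* in [0, 1] (1 = the knockout is essential for that line).

`simkit.sim_fitness_screen` draws background fitness as standard
Gaussian noise scaled by `noise_sd` (default 1). A planted co-essential
module shares a latent factor across its genes:

    x_g = sqrt(rho) * f + sqrt(1 - rho) * noise_sd * eps_g

so the expected pairwise Pearson correlation within the module is
`rho / (rho + (1 - rho) * noise_sd**2)`, which equals `rho` exactly at
the default `noise_sd = 1`, and 1 at `rho = 1` for any noise level
(the idiosyncratic term has zero loading there).

Lethality probability is a logistic transform of fitness,

    p = expit(-k * fitness + logit(p0))

with slope `k = 2` and `p0 = 0.05`, so a background gene's median
lethality sits at 0.05 — screens treat probabilities near 1 as
essential, and most knockouts are tolerated, so the background mass
belongs near 0.  Synthetic-lethal plants add a constant `delta` to the
gene's probability in every mutant-group line, clipping into [0, 1]
with a warning rather than rejecting (a warning is the honest signal
that the planted effect saturated).

Determinism: every generator is a pure function of its arguments
including the seed.  Per-gene substreams come from
`SeedSequence((seed, stream_tag, gene_index))`, so enlarging `n_genes`
reproduces the existing genes bit-for-bit.

## Genotype groups

Cell lines are partitioned by alteration severity into HomDel
(any homozygous deleterious variant or deep copy loss), T-HetDel
(two or more heterozygous deleterious variants, or one plus partial
copy loss), HetDel (a single het deleterious variant or partial copy
loss alone), and WT.  "Deleterious" defaults to the protein-truncating
classes {frameshift, nonsense, splice_site, start_loss, stop_loss} and
is configurable — the predicate is declared, not inferred, since no
canonical list exists.  Copy-number status is consumed as a pre-made
categorical call; thresholding raw ratios is out of scope.  A line
whose only homozygous deleterious variants are exclusive to the long
isoform keeps HomDel but carries an `l_only` flag, since the short
isoform may retain activity.

## Co-essentiality screen

For a query gene, Pearson correlations of fitness profiles are computed
against every other gene (pairwise-complete over missing values, with a
declared minimum of 30 shared lines; genes below it report r = NA and
are excluded from multiple testing).  P-values come from the two-sided
t transform of r; FDR control is Benjamini–Hochberg.

The correlation cutoff is the *elbow* of the descending
ranked-coefficient curve: after min-max scaling both axes, the
coefficient at the index with maximum perpendicular distance to the
chord joining the first and last points (the kneedle construction).
Distance ties break toward the larger coefficient — the more
conservative cutoff.  An exactly linear curve has no elbow and raises
a degenerate-curve error.  The query's self-correlation (r = 1) is
excluded from elbow detection so the chord is not anchored at the
trivial maximum, and the query is never reported as passing.  Other
elbow operationalisations exist; thresholds from other toolchains
should therefore be compared with tolerance, not for equality.

The synteny filter drops all genes on a chromosome *before* BH
adjustment and elbow detection, mirroring the recommended non-syntenic
re-analysis for queries whose neighbours correlate for positional
rather than functional reasons.

## Synthetic-lethality screen

Per gene, lethality probabilities are compared between a small mutant
group and a large control group with a two-sided Mann–Whitney U test.
Design choices that the source material leaves open, declared here:

* **Sidedness** — two-sided, with the direction recovered from the
  group medians (the screen reports both lethal and alleviating
  interactions, and the interaction score is signed).
* **Null construction** — with a mutant group of two lines out of ~560,
  per-gene label permutations exhaust after a few thousand distinct
  assignments, so the null pools re-computed p-values across *all*
  genes and permutations.  Labels are shuffled across lines; the
  smaller group's label is the one permuted, making the null pool (and
  hence every downstream call) exactly invariant under swapping the
  mutant/control designation.
* **Adjustment** — the add-one (Phipson–Smyth) estimate
  `p_adj = (1 + #{null <= p_obs}) / (1 + #null)`, bounded below by
  1/(pool+1) and monotone in the observed p.
* **Consistency** — the screen's observed p-values and the permutation
  null both use the same vectorised tie-corrected normal approximation
  (ranks are computed once per gene; a permutation only re-sums them),
  so observed and null p-values are exchangeable under the null.  The
  standalone `mw_test` additionally offers exact branches for small
  inputs: the exact distribution when there are no ties, and full
  enumeration of label assignments when there are.

A gene is called **SL** when `p_adj < 0.05`, the larger group median
exceeds 0.5, and the mutant median is the larger one; the mirrored
pattern is **alleviating**.  Known essential/non-essential genes are
dropped from calling when lists are supplied.  The interaction score is
`sign(median_mut - median_wt) * -log10(p_adj)` (the source figure is
described but no formula is printed; this is the natural signed
significance and is documented as this package's choice).

Note an intended interaction between the call rule and the synthetic
world: over a 0.05 background median, a planted shift of +0.4 lands at
~0.45 — highly significant, but below the absolute-median floor of 0.5,
so it is *correctly* not called SL.  Planted effects must clear
`0.5 - background` to be callable; the power guarantees in the test
suite plant 0.55.

## Cell-cycle phase scoring and DE filtering

Each gene is z-scored across cells; a cell's phase score is the mean z
over the phase's marker genes; the assigned phase is the strict unique
positive maximum, else UNASSIGNED.  The strict-unique-positive filter
is a declared stand-in for the reference tool's default filtering (the
assignment callable is pluggable).  DE statistics themselves come from
an external model; `de_filter` applies adjusted p < 0.05 and linear
fold-change > 1.5 (as `|log2fc| > log2 1.5`), and maps an NA adjusted
p to NC ("not calculated") — a gene the model declined to test is not
the same as a non-significant one.

## Peak overlaps

BED semantics are strictly 0-based half-open; abutting peaks do not
overlap.  Replicate intersection keeps query peaks with ≥ 1 bp overlap
in the other replicate; cross-set overlap is counted per query peak
(a query overlapping three subject peaks counts once).  Significance is
the upper-tail hypergeometric probability of ≥ k overlapping peaks when
n_a query peaks are drawn from a population of `total_test` testable
sites containing n_b subject peaks; `total_test` defaults to 250,000.
The sweep implementation (sorted starts + prefix-max of ends) is
cross-checked against `bedtools intersect -u` in the test suite.

## Differential splicing

Events carry the eight-type vocabulary CE/AA/AD/AF/AL/RI/TS/TE and
per-replicate Ψ values.  ΔΨ is the difference of condition mean Ψ.
The upstream quantifier's posterior probability is not reproducible
from a PSI table, so the confidence here is a declared stand-in: the
fraction of within-condition replicate bootstrap resamples whose ΔΨ is
non-zero with the observed sign.  Significance uses the strict printed
thresholds |ΔΨ| > 0.1 and probability > 0.9; boundary values fail.

Entropy of an isoform-usage vector is Shannon entropy in bits, bounded
by log2(number of isoforms); an event is high-entropy above 1.5 bits
(more than three effectively expressed isoforms; uniform usage of three
gives log2 3 ≈ 1.585).  Distribution comparisons use the two-sample
two-sided Kolmogorov–Smirnov test with the asymptotic p-value.

**UTR direction.**  For tandem TS/TE events, increased usage of the
terminal node nearer the coding region shortens the corresponding UTR.
Coordinates are mapped to a transcription-direction axis (on the −
strand, smaller genomic coordinates are 3′-ward), and a node is
*proximal* when it lies nearer the coding region than the midrange of
its sibling terminal nodes of the same type — for TE nodes the coding
region is 5′-ward, for TS nodes 3′-ward.  A single-call signature
cannot binarise proximal/distal from one node, so `utr_direction`
accepts the sibling node coordinates (available from any PSI table);
without them, it falls back to the gene span: a node more than its own
length away from the transcription-direction span end (TE; span start
for TS) is proximal.  `ΔΨ = 0` yields `not_applicable`.

**Replicate noise.**  `sim_psi_tables` draws per-replicate Ψ from a
Beta distribution with concentration 1/dispersion around the condition
mean (dispersion 0 emits the mean exactly).  The default dispersion of
0.01 corresponds to a per-replicate s.d. of ≈ 0.05 at Ψ = 0.4 —
already generous relative to biological-replicate PSI variability for
quantifiable events, which is typically a few percent.  A limitation
worth stating plainly: the significance rule thresholds *raw* |ΔΨ|, so
its null behaviour depends on replicate noise.  The ≤ 10 % null
significant-call rate verified in the test suite holds when replicate
noise is below the ΔΨ threshold scale; at per-replicate s.d. ≳ 0.1 the
raw-ΔΨ rule is not calibrated (on real data, the upstream tool's
posterior-probability filter absorbs that role).

## Evidence integration

Top-K co-expression selection breaks boundary ties lexicographically so
exactly K genes always return.  Replicate support keeps genes detected
in ≥ `min_reps` replicate experiments.  The evidence table takes named
gene sets (co-essential, SL, top-K co-expressed, IP-MS per background,
ChIP-bound) and derives `high_confidence` as detection in both IP-MS
backgrounds; it can never be supplied directly.

## What a green test does and does not establish

The generators emulate the *statistical shape* of the real inputs —
background correlation, planted effect sizes, replicate noise, overlap
counts by construction — not their biological texture: no linkage/
synteny-driven correlation beyond the planted modules, no mutation
signatures, no read-level artefacts, no gene-length or expression-
dependent detection bias.  Recovery of planted truth therefore
validates the inference machinery (calibration, power, determinism,
bookkeeping), not the biological conclusions of any particular dataset.
Reproducing published full-data numbers additionally requires the
original public releases (fitness matrices, mutation calls, PSI tables)
as inputs.
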