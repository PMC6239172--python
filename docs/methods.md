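# Methods

## Coordinate model

All internal coordinates are 0-based half-open. 1-based coordinates
appear only at the GFF3 reader (input convention) and the TSV report
writer, giving a single conversion point in each direction. "Upstream"
is strand-aware throughout: smaller coordinates on +, larger on −.
Offset conventions for motif work: offset −1 is the base immediately
upstream of the anchor (TSS or start codon); the TSS base itself is +1
(there is no offset 0).

## TSS determination

The caller mirrors the standard differential-RNA-seq logic. Raw
5′-end counts are divided by median-of-ratios size factors
s_j = median over rows i of k_ij / (Π_j k_ij)^{1/m}, rows containing a
zero excluded. For dRNA-seq libraries the count table is built from
genomic bins (default 100 bp). The bin width matters: the normalization
is meant to equalize apparent gene-body coverage between treated and
untreated libraries, so the median bin must be dominated by the
processed-end background, not by TSS spikes; at 100 bp roughly one bin
in ten contains a spike and the median is background-driven. Gene-level
tables (e.g. from a companion RNA-seq experiment) can be supplied
instead.

Candidate positions (normalized density ≥ `min_density`, default 5.0 —
the floor is a package choice, configurable) are chained into initial
clusters when consecutive gaps are ≤ 300 bp, then split into
sub-clusters wherever two adjacent peaks have population SD ≥ 15. For
two points the population SD is half the gap, so the rule is gap < 30
bp; the SD flavor (population vs sample) is not canonical, and we chose
the literal two-point population reading. Each sub-cluster is
represented by its densest member, ties broken toward the most upstream
position for determinism.

A representative is kept if (d₊ + c)/(d₋ + c) ≥ 2 at its exact
position, with pseudocount c = 1.0 normalized units guarding against
zero untreated background while penalizing low-coverage spikes; a
window-summed ratio is available (`ratio_halfwidth`). A condition-level
TSS requires representatives from both replicates within ±4 bp —
reusing the only positional tolerance the merging step defines, since
no separate reproducibility window is canonical — and takes the
position and density of the denser replicate. Per-condition lists merge
greedily: seed at the densest unmerged TSS, absorb everything within
±4 bp on the same strand, union the condition labels. Greedy
density-first seeding makes the merge deterministic and idempotent;
for chains wider than the window (e.g. 100/104/108) the seed absorbs
both neighbours, which is the intended collapse.

## Classification and 5′-UTRs

Gene windows span offsets 1…299 upstream and 0…100 downstream of the
start codon (inclusive; both bounds configurable). A TSS inside several
windows goes to the gene with the nearest start codon, ties to the
lexicographically smaller gene id — same-strand tandem or
divergently-arranged gene pairs are the cases where this fires.
Precedence is gene-start window (P/S) > internal > antisense >
intergenic; antisense requires overlap of the gene body itself with no
flank. Per gene the densest window TSS is primary, the rest secondary,
so categories partition the TSS set and each gene has at most one P.

Leaders shorter than 10 nt are flagged leaderless: a ribosome-binding
site cannot fit in a shorter leader, and 10 nt is the conventional
boundary in primary-transcriptome studies. Lengths ≤ 0 (TSS at or
downstream of the start codon) give an empty leader sequence.

## Promoter and SD scanning

Elements are localized by mismatch-tolerant scanning against fixed
consensus sequences inside their biologically allowed ranges: TATAAT
fully within [−20,−5], TTGACA within [−36,−23] (≤1 mismatch by
default), AGGAGG within [−20,−5] of the start codon (≥4/6 identities).
Ties prefer fewer mismatches, then the 3′-most position. The spacer is
the gap in bp between the −35 box end and the −10 box start; canonical
σ70 promoters sit near 17 bp. Consensus-anchored scanning was chosen
over de novo discovery because the consensus and ranges are known and
the scan is exactly testable by enumeration; the SD identity threshold
and window are package defaults, not canonical values.

## RNA folding

The built-in engine minimizes the sum of base-pair energies (GC/CG
−3.0, AU/UA −2.0, GU/UG −1.0 kcal/mol) over nested structures with a
minimum loop of 3 unpaired bases — a Nussinov-style dynamic program
with energies in place of pair counts. The model is deliberately
simple: no stacking context, dangles, bulge or multiloop penalties, and
no temperature dependence (the temperature field is metadata only).
This keeps an exhaustive enumeration oracle feasible — the DP is
verified exactly against it over the full hexamer space and random
12-mers — and preserves the ordering property the leader analysis
needs (hairpin-bearing leaders score far below unstructured ones). It
does not reproduce absolute free energies of a nearest-neighbor
thermodynamic folder, and it systematically over-pairs random sequence,
so group contrasts are smaller than a Turner-model folder would give;
an external engine (e.g. an `RNAfold` binary) can be plugged into
`utr_mfe_table` where absolute energies matter. Traceback prefers
pairing the leftmost base with its smallest admissible partner, making
reported structures deterministic; energies are sums of small integers
so float comparisons are exact.

## Differential expression and grouping

The differential stage is a transparent per-gene negative-binomial Wald
test: log2FC is the log-ratio of mean normalized counts (pseudocount
1); the NB variance μ + αμ² uses a method-of-moments dispersion from
the pooled within-group variance, floored at 0; the log-scale Wald
statistic is referred to a t distribution with Welch-Satterthwaite
degrees of freedom. The t reference is a small-sample correction: with
four replicates per group the plug-in variance makes a normal reference
anticonservative (≈11% of null genes below p = 0.05 in NB simulation),
while the Welch-t reference restores ≈5.7%. No dispersion shrinkage or
outlier handling is attempted — the package's focus is the downstream
grouping, and the DE stage is swappable for any tool producing
per-gene log2FC and p. Benjamini-Hochberg adjustment and the DEG filter
(padj < 0.01, |log2FC| > 1, in ≥1 contrast by default; set
`min_contrasts=2` to require multiple conditions) follow.

Grouping is best-of-restarts Lloyd K-means over the genes × contrasts
log2FC matrix, with the SSE (elbow) curve reported; k can be fixed or
picked by the maximum-distance-to-chord heuristic. Group metrics
(leader length, ΔG) are summarized by median and linearly interpolated
quartiles and compared with the Wilcoxon-Mann-Whitney test — exact by
the U null distribution for tie-free samples with n+m ≤ 16, otherwise
the normal approximation with tie and continuity corrections. The
attenuator read-through ratio is mean gene-body coverage over mean
leader coverage (≈1 read-through, ≪1 premature termination; undefined
and flagged when the leader has zero coverage).

## Synthetic data: what it emulates, and what it does not

The generator plants everything the analysis is supposed to find.
Genomes alternate gene strands with ≥400 bp intergenic gaps; each gene
gets a TSS at Uniform[20,150] nt upstream, TATAAT inside [−20,−5],
TTGACA 17±1 bp further upstream, AGGAGG at −12…−10 from the start
codon, and 20% of genes form 2–4-gene operons. 5′-end profiles use
Poisson spikes — appropriate for sparse single-position counts and
analytically tractable — of mean depth×enrichment (RPP+, with 80/10/10
positional jitter over ±1 bp, motivated by the near-single-base
precision the ±4 bp merge window implies) versus depth (RPP−), over a
uniform processed-end background within transcribed spans (halved in
RPP+); each library carries its own depth factor from [0.7, 1.4] so the
normalization has work to do. Count matrices are NB with log-normal
base means and planted blocks: "C1-like" genes up 4-fold under the two
autotrophic conditions only, "C7-like" genes up 4-fold in all three
non-reference conditions (the pattern of genes induced by both
autotrophy and cold), the rest null; library size factors are drawn
from [0.5, 2]. Leader sets pair hairpin-planted sequences (GC-biased
perfect-complement stems) with their mononucleotide shuffles.

Defaults used in the benchmarks: 200 genes / ~530 kb for TSS recovery
(the smallest layout holding 200 planted TSSs under the spacing
invariant), enrichment 8×, depth 50, two replicates; 2000 null and 500
planted genes at dispersion 0.05 for calibration; 100 leaders per
structure class. These sizes give stable statistics while keeping every
benchmark in seconds.

What the simulation does not model: sequencing error and read-level
artifacts, mappability, transcript 3′ structure and termination,
RNase-generated processed-end hotspots, overlapping transcription
units, and condition-dependent TSS usage (every planted TSS is active
in every condition). Passing the benchmarks therefore demonstrates the
correctness of the algorithms under their stated assumptions, not
performance on real libraries, where background structure and
mapping artifacts dominate error.

## Numerical and degenerate-input choices

Median-of-ratios requires at least one all-positive row and raises
otherwise. Density ties break toward the most upstream position;
classification ties toward the nearest, then lexicographically smaller,
gene. Empty TSS sets produce header-only tables and zero counts. Genes
with all-zero counts are excluded from testing (NaN propagated, BH
applied to the finite subset). TSSs within 2 bp of a contig edge are
excluded from context profiling, and windows truncated by an edge are
skipped in promoter scanning, each with a warning. The folding length
guard (18 nt) bounds the enumeration oracle; K-means restarts default
to 10 with a fixed seed.
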