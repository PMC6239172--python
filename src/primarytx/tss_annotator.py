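"""Positional classification of TSSs and 5'-UTR extraction.

Merged TSSs are classified into five categories by their position
relative to annotated genes: primary (P, the highest-density TSS in a
gene's start-codon window), secondary (S, other TSSs in the same
window), internal (I, inside a gene body on the same strand), antisense
(A, inside a gene body on the opposite strand) and intergenic (N).
Primary TSSs define per-gene 5'-UTRs (leaders), from which start-codon
usage, TSS nucleotide context and operon assignment follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome_io import GeneFeature, Genome, OperonModel, revcomp
from .tss_caller import TssRecord

log = logging.getLogger(__name__)

# start-codon window: offsets 1..UPSTREAM_SPAN upstream and 0..DOWNSTREAM_SPAN
# downstream of the start codon's first base (strand-aware, inclusive)
UPSTREAM_SPAN = 299
DOWNSTREAM_SPAN = 100
LEADERLESS_MAX = 10  # leaders shorter than this many nt count as leaderless


@dataclass
class UtrRecord:
    """Per-gene 5'-UTR derived from its primary TSS.

    ``length`` is the signed strand-aware distance from the TSS to the
    first base of the start codon (positive = leader length in nt);
    ``sequence`` is the transcribed leader as RNA (empty when length <= 0).
    """

    gene_id: str
    tss_position: int
    length: int
    sequence: str
    leader_status: str  # "leader" or "leaderless"
    start_codon: str
    sd_hit: tuple[int, str] | None = None


def _window_contains(gene: GeneFeature, pos: int,
                     upstream: int = UPSTREAM_SPAN, downstream: int = DOWNSTREAM_SPAN) -> bool:
    sc = gene.start_codon_pos
    if gene.strand == "+":
        return sc - upstream <= pos <= sc + downstream
    return sc - downstream <= pos <= sc + upstream


def classify_tss(
    total_tss: list[TssRecord],
    genes: list[GeneFeature],
    upstream: int = UPSTREAM_SPAN,
    downstream: int = DOWNSTREAM_SPAN,
) -> list[TssRecord]:
    """Assign each TSS exactly one category P/S/I/A/N (classification in place).

    A TSS falling into the windows of several genes goes to the gene with
    the nearest start codon (ties to the lexicographically smaller gene
    id). Precedence: gene-start window (P/S) > internal > antisense >
    intergenic. Per gene, the highest-density window TSS is primary;
    the rest are secondary.
    """
    by_gene: dict[str, list[TssRecord]] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    unassigned: list[TssRecord] = []

    for tss in total_tss:
        candidates = [
            g
            for g in genes
            if g.replicon == tss.replicon
            and g.strand == tss.strand
            and _window_contains(g, tss.position, upstream, downstream)
        ]
        if candidates:
            best = min(
                candidates,
                key=lambda g: (abs(tss.position - g.start_codon_pos), g.gene_id),
            )
            by_gene.setdefault(best.gene_id, []).append(tss)
        else:
            unassigned.append(tss)

    for gene_id, group in by_gene.items():
        gene = gene_by_id[gene_id]
        upstream_key = (
            (lambda t: t.position) if gene.strand == "+" else (lambda t: -t.position)
        )
        group.sort(key=lambda t: (-t.density, upstream_key(t)))
        group[0].category = "P"
        group[0].gene_id = gene_id
        for t in group[1:]:
            t.category = "S"
            t.gene_id = gene_id

    for tss in unassigned:
        same = opposite = None
        for g in genes:
            if g.replicon != tss.replicon or not (g.start <= tss.position < g.end):
                continue
            if g.strand == tss.strand:
                same = same or g
            else:
                opposite = opposite or g
        if same is not None:
            tss.category, tss.gene_id = "I", same.gene_id
        elif opposite is not None:
            tss.category, tss.gene_id = "A", opposite.gene_id
        else:
            tss.category, tss.gene_id = "N", None
    return total_tss


def extract_5utr(
    primary_tss: TssRecord,
    gene: GeneFeature,
    genome: Genome,
    leaderless_max: int = LEADERLESS_MAX,
) -> UtrRecord:
    """5'-UTR of a gene from its primary TSS.

    Leaders shorter than ``leaderless_max`` nt are flagged leaderless (a
    ribosome cannot engage a Shine-Dalgarno site in so short a leader);
    non-positive lengths give an empty sequence.
    """
    if primary_tss.category != "P" or primary_tss.gene_id != gene.gene_id:
        raise ValueError(f"TSS at {primary_tss.position} is not primary for {gene.gene_id}")
    sc = gene.start_codon_pos
    if gene.strand == "+":
        length = sc - primary_tss.position
        seq = genome.fetch(gene.replicon, primary_tss.position, sc, "+") if length > 0 else ""
        codon = genome.fetch(gene.replicon, sc, sc + 3, "+")
    else:
        length = primary_tss.position - sc
        seq = genome.fetch(gene.replicon, sc + 1, primary_tss.position + 1, "-") if length > 0 else ""
        codon = genome.fetch(gene.replicon, sc - 2, sc + 1, "-")
    return UtrRecord(
        gene_id=gene.gene_id,
        tss_position=primary_tss.position,
        length=length,
        sequence=seq.replace("T", "U"),
        leader_status="leader" if length >= leaderless_max else "leaderless",
        start_codon=codon,
    )


def start_codon_usage(utrs: list[UtrRecord]) -> dict[tuple[str, str], int]:
    """Counts of start codons {ATG, GTG, TTG, other} x {leader, leaderless}."""
    counts: dict[tuple[str, str], int] = {}
    for u in utrs:
        codon = u.start_codon if u.start_codon in ("ATG", "GTG", "TTG") else "other"
        key = (codon, u.leader_status)
        counts[key] = counts.get(key, 0) + 1
    return counts


CONTEXT_OFFSETS = (-2, -1, 1, 2, 3)  # +1 is the TSS base; there is no offset 0


def tss_context_profile(tss_set: list[TssRecord], genome: Genome):
    """Per-position base frequencies over the -2..+3 nucleotide context of TSSs.

    Returns (frequencies, n_used): frequencies maps each offset in
    CONTEXT_OFFSETS to {base: fraction} summing to 1. TSSs within 2 bp
    of a contig edge are excluded with a warning.
    """
    counts = {o: {b: 0 for b in "ACGT"} for o in CONTEXT_OFFSETS}
    n_used = 0
    for tss in tss_set:
        length = genome.lengths[tss.replicon]
        if tss.position - 2 < 0 or tss.position + 3 > length:
            log.warning("TSS at %s:%d within 2 bp of contig edge; excluded",
                        tss.replicon, tss.position)
            continue
        window = genome.replicons[tss.replicon][tss.position - 2 : tss.position + 3]
        if tss.strand == "-":
            window = revcomp(window)
        for offset, base in zip(CONTEXT_OFFSETS, window):
            if base in counts[offset]:
                counts[offset][base] += 1
        n_used += 1
    freqs = {}
    for offset, bases in counts.items():
        total = sum(bases.values())
        freqs[offset] = {b: (c / total if total else 0.0) for b, c in bases.items()}
    return freqs, n_used


def assign_tss_to_operons(
    classified_tss: list[TssRecord],
    operons: list[OperonModel],
    genes: list[GeneFeature] | None = None,
) -> dict[str, dict]:
    """Map operons to the P/S TSSs of their first gene.

    An operon with at least one such TSS is flagged "TSS-validated",
    otherwise "coverage-only" (kept on the strength of its expression
    evidence alone). When ``genes`` is given, operons referencing a gene
    absent from the annotation raise a ValueError.
    """
    by_gene: dict[str, list[TssRecord]] = {}
    for t in classified_tss:
        if t.category in ("P", "S") and t.gene_id:
            by_gene.setdefault(t.gene_id, []).append(t)
    known = {g.gene_id for g in genes} if genes is not None else None
    out: dict[str, dict] = {}
    for op in operons:
        if not op.gene_ids:
            raise ValueError(f"operon {op.operon_id} has no members")
        if known is not None:
            missing = [g for g in op.gene_ids if g not in known]
            if missing:
                raise ValueError(f"operon {op.operon_id} references unknown genes {missing}")
        first = op.gene_ids[0]
        tss = by_gene.get(first, [])
        out[op.operon_id] = {
            "first_gene": first,
            "tss": tss,
            "status": "TSS-validated" if tss else "coverage-only",
        }
    return out
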