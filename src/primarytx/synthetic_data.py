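"""Synthetic genomes, 5'-end profiles, count matrices and UTR sets with ground truth.

The generators emulate the statistical structure the analysis assumes:
primary 5' ends enriched in the RPP+ library at true TSSs over a
processed-end background, biological replicate noise, library-depth
differences, condition-dependent expression blocks (including a group
up-regulated in three of four conditions, as acetogenesis genes are
under autotrophic and cold growth), canonical promoter boxes and
Shine-Dalgarno motifs planted upstream of each TSS, and leader
sequences with controllable hairpin content. Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import EndProfile, GeneFeature, Genome, OperonModel, revcomp

CONDITIONS = ("H20", "A20", "H10", "A10")  # heterotrophic/autotrophic x 20C/10C
REFERENCE_CONDITION = "H20"

BASES = np.array(list("ACGT"))


@dataclass
class TrueTss:
    gene_id: str
    replicon: str
    strand: str
    position: int
    utr_length: int
    category: str = "P"


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators; sufficient to score every stage."""

    tss: list[TrueTss] = field(default_factory=list)
    promoters: dict[str, dict] = field(default_factory=dict)  # gene -> element offsets
    expression_groups: dict[str, str] = field(default_factory=dict)  # gene -> group
    utr_classes: dict[str, str] = field(default_factory=dict)  # seq id -> class
    transcribed_spans: list[tuple[str, str, int, int]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tss": [asdict(t) for t in self.tss],
                    "promoters": self.promoters,
                    "expression_groups": self.expression_groups,
                    "utr_classes": self.utr_classes,
                    "transcribed_spans": [list(s) for s in self.transcribed_spans],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tss=[TrueTss(**t) for t in d["tss"]],
            promoters=d["promoters"],
            expression_groups=d["expression_groups"],
            utr_classes=d["utr_classes"],
            transcribed_spans=[tuple(s) for s in d["transcribed_spans"]],
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _plant(seq: list[str], pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = list(motif)


def generate_genome_annotation(
    n_genes: int,
    replicon_length: int,
    seed: int,
    gene_length: tuple[int, int] = (600, 1200),
    intergenic_min: int = 400,
    operon_fraction: float = 0.2,
    replicon_id: str = "chr",
):
    """Random genome with planted genes, TSSs, promoter boxes and SD motifs.

    Genes alternate strands down the replicon with >= intergenic_min bp
    gaps; each gene gets one true TSS at Uniform[20,150] nt upstream of
    its start codon, a TATAAT box whose 6-mer sits inside TSS offsets
    [-20,-5], a TTGACA box 17+/-1 bp further upstream, and an AGGAGG
    Shine-Dalgarno at -12..-10 from the start codon. About
    ``operon_fraction`` of genes are grouped into 2-4-gene operons.

    Returns (Genome, [GeneFeature], [OperonModel], SyntheticTruth).
    """
    rng = np.random.default_rng(seed)
    mean_len = sum(gene_length) / 2
    # each gene consumes its body, its upstream TSS/promoter region and a gap
    if n_genes * (mean_len + intergenic_min + 200) > replicon_length:
        raise ValueError(
            f"capacity exceeded: {n_genes} genes do not fit in {replicon_length} bp"
        )
    seq = list(_random_seq(rng, replicon_length))
    genes: list[GeneFeature] = []
    truth = SyntheticTruth()

    cursor = intergenic_min + 200
    for i in range(n_genes):
        glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
        utr_len = int(rng.integers(20, 151))
        strand = "+" if i % 2 == 0 else "-"
        start = cursor
        end = start + glen
        if end + intergenic_min + 200 > replicon_length:
            raise ValueError("capacity exceeded while placing genes")
        gene_id = f"g{i + 1:04d}"
        genes.append(GeneFeature(gene_id, replicon_id, strand, start, end))

        sc = start if strand == "+" else end - 1
        tss = sc - utr_len if strand == "+" else sc + utr_len
        # element offsets relative to the TSS / start codon (first base)
        m10_off = int(rng.integers(-12, -9))        # in {-12,-11,-10}
        spacer = int(rng.integers(16, 19))          # 17 +/- 1
        m35_off = m10_off - spacer - 6
        sd_off = int(rng.integers(-12, -9))

        if strand == "+":
            _plant(seq, start, "ATG")
            _plant(seq, tss + m10_off, "TATAAT")
            _plant(seq, tss + m35_off, "TTGACA")
            _plant(seq, sc + sd_off, "AGGAGG")
        else:
            # element first base at offset o sits at genome position tss - o
            # and extends downstream-in-genome to tss - o - 5
            _plant(seq, end - 3, revcomp("ATG"))
            _plant(seq, tss - m10_off - 5, revcomp("TATAAT"))
            _plant(seq, tss - m35_off - 5, revcomp("TTGACA"))
            _plant(seq, sc - sd_off - 5, revcomp("AGGAGG"))

        truth.tss.append(TrueTss(gene_id, replicon_id, strand, tss, utr_len))
        truth.promoters[gene_id] = {
            "minus10_offset": m10_off,
            "minus35_offset": m35_off,
            "sd_offset": sd_off,
            "spacer": spacer,
        }
        truth.transcribed_spans.append(
            (replicon_id, strand, start - utr_len if strand == "+" else start,
             end if strand == "+" else end + utr_len)
        )
        cursor = end + intergenic_min + 200

    # group ~operon_fraction of genes into same-strand 2-4-member operons
    operons: list[OperonModel] = []
    n_operon_genes = int(round(operon_fraction * n_genes))
    idx = 0
    op_i = 0
    while n_operon_genes >= 2 and idx < n_genes - 1:
        size = int(rng.integers(2, 5))
        members = [g for g in genes[idx : idx + size * 2] if g.strand == genes[idx].strand][:size]
        if len(members) >= 2:
            op_i += 1
            ordered = sorted(
                members,
                key=lambda g: g.start_codon_pos if g.strand == "+" else -g.start_codon_pos,
            )
            operons.append(
                OperonModel(
                    f"op{op_i:03d}",
                    tuple(g.gene_id for g in ordered),
                    members[0].strand,
                    replicon_id,
                )
            )
            n_operon_genes -= len(members)
        idx += size * 2

    genome = Genome({replicon_id: "".join(seq)})
    return genome, genes, operons, truth


def simulate_end_profiles(
    truth: SyntheticTruth,
    depth: float = 50.0,
    enrichment: float = 8.0,
    replicates: int = 2,
    seed: int = 0,
    conditions=CONDITIONS,
    background_rate: float = 2.0,
    background_per_span: int = 20,
    jitter: tuple[float, float, float] = (0.8, 0.1, 0.1),
    scale_range: tuple[float, float] = (0.7, 1.4),
) -> list[EndProfile]:
    """Simulate stranded 5'-end count profiles for RPP+/RPP- library pairs.

    RPP- libraries carry a processed-end background (Poisson(background_
    rate) counts at positions uniform within transcribed spans) plus
    Poisson(depth) at true TSSs; RPP+ libraries carry Poisson(depth x
    enrichment) at true TSSs with positional jitter (80% exact, 10% each
    +/-1 bp by default) plus a halved background leak. Each library gets
    its own depth-scaling factor drawn from ``scale_range`` so that
    size-factor normalization has real work to do. Draws are independent
    per condition and replicate.
    """
    if enrichment <= 1:
        raise ValueError("enrichment must be > 1")
    rng = np.random.default_rng(seed)
    profiles: list[EndProfile] = []
    exact, up, down = jitter
    for condition in conditions:
        for replicate in range(1, replicates + 1):
            for treatment in ("RPP+", "RPP-"):
                scale = rng.uniform(*scale_range)
                counts: dict[tuple[str, str, int], float] = {}

                def add(key, value):
                    if value > 0:
                        counts[key] = counts.get(key, 0.0) + value

                for t in truth.tss:
                    if treatment == "RPP+":
                        lam = depth * enrichment * scale
                        total = rng.poisson(lam)
                        n_up, n_down = rng.binomial(total, up), 0
                        if total - n_up > 0:
                            n_down = rng.binomial(total - n_up, down / (exact + down))
                        n_exact = total - n_up - n_down
                        shift = 1 if t.strand == "+" else -1
                        add((t.replicon, t.strand, t.position), float(n_exact))
                        add((t.replicon, t.strand, t.position - shift), float(n_up))
                        add((t.replicon, t.strand, t.position + shift), float(n_down))
                    else:
                        add(
                            (t.replicon, t.strand, t.position),
                            float(rng.poisson(depth * scale)),
                        )
                bg_rate = background_rate * (0.5 if treatment == "RPP+" else 1.0)
                for replicon, strand, lo, hi in truth.transcribed_spans:
                    positions = rng.integers(lo, hi, size=background_per_span)
                    for pos in positions:
                        add((replicon, strand, int(pos)), float(rng.poisson(bg_rate * scale)))
                profiles.append(
                    EndProfile(
                        library_id=f"{condition}_r{replicate}_{'p' if treatment == 'RPP+' else 'm'}",
                        condition=condition,
                        replicate=replicate,
                        treatment=treatment,
                        counts=counts,
                    )
                )
    return profiles


def simulate_count_matrix(
    truth: SyntheticTruth,
    conditions=CONDITIONS,
    n_reps: int = 4,
    dispersion: float = 0.05,
    seed: int = 0,
    n_genes: int | None = None,
    fold_change: float = 4.0,
    group_sizes: dict[str, int] | None = None,
    base_mean_log: tuple[float, float] = (np.log(200.0), 1.0),
):
    """NB count matrix with planted condition-responsive expression blocks.

    Gene base means are log-normal. "C1-like" genes are up ``fold_change``-
    fold in the autotrophic conditions only (A20, A10); "C7-like" genes
    are up in all three non-reference conditions (A20, H10, A10),
    mirroring genes induced by both autotrophy and cold; the rest are
    null. Library size factors are drawn from [0.5, 2].

    Returns (counts DataFrame genes x libraries, design DataFrame,
    truth updated with expression_groups).
    """
    rng = np.random.default_rng(seed)
    if REFERENCE_CONDITION not in conditions:
        raise ValueError(f"conditions must include the reference {REFERENCE_CONDITION}")
    sizes = group_sizes or {"C1-like": 60, "C7-like": 120, "null": 320}
    if n_genes is not None:
        sizes = dict(sizes)
        sizes["null"] = max(0, n_genes - sizes["C1-like"] - sizes["C7-like"])
    gene_ids = []
    groups = []
    for group, size in sizes.items():
        for _ in range(size):
            gene_ids.append(f"x{len(gene_ids) + 1:04d}")
            groups.append(group)
    truth.expression_groups = dict(zip(gene_ids, groups))

    up_in = {
        "C1-like": {"A20", "A10"},
        "C7-like": {"A20", "H10", "A10"},
        "null": set(),
    }
    base = rng.lognormal(base_mean_log[0], base_mean_log[1], len(gene_ids))
    libraries = []
    design_rows = []
    columns = {}
    r = 1.0 / dispersion
    for condition in conditions:
        for rep in range(1, n_reps + 1):
            lib = f"{condition}_r{rep}"
            libraries.append(lib)
            sf = rng.uniform(0.5, 2.0)
            design_rows.append({"library": lib, "condition": condition, "replicate": rep,
                                "true_size_factor": sf})
            mu = np.array(
                [
                    base[i] * (fold_change if condition in up_in[groups[i]] else 1.0)
                    for i in range(len(gene_ids))
                ]
            ) * sf
            columns[lib] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(columns, index=gene_ids)
    design = pd.DataFrame(design_rows).set_index("library")
    return counts, design, truth


def generate_structured_utrs(
    n_per_class: int,
    stem_len: int = 6,
    loop_len: int = 4,
    seed: int = 0,
    total_length: int = 30,
    gc_bias: float = 0.8,
):
    """Leader sequence sets with and without a planted hairpin.

    Structured sequences embed a perfect-complement GC-biased stem of
    ``stem_len`` around a ``loop_len`` loop inside a random core; the
    unstructured class consists of mononucleotide shuffles of the same
    sequences (identical length and base composition, hairpin destroyed).

    Returns (structured list, shuffled list) of RNA strings.
    """
    if stem_len < 3 or loop_len < 3:
        raise ValueError("stem_len and loop_len must each be >= 3")
    rng = np.random.default_rng(seed)
    hairpin_len = 2 * stem_len + loop_len
    if total_length < hairpin_len:
        raise ValueError("total_length too short for the requested hairpin")
    rna = np.array(list("ACGU"))
    p_stem = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    structured, shuffled = [], []
    for _ in range(n_per_class):
        flank = total_length - hairpin_len
        left = int(rng.integers(0, flank + 1))
        stem = "".join(rng.choice(rna, size=stem_len, p=p_stem))
        loop = "".join(rng.choice(rna, size=loop_len))
        core = stem + loop + "".join(comp[b] for b in reversed(stem))
        seq = (
            "".join(rng.choice(rna, size=left))
            + core
            + "".join(rng.choice(rna, size=flank - left))
        )
        structured.append(seq)
        shuffled.append("".join(rng.permutation(list(seq))))
    return structured, shuffled
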