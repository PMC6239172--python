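"""Readers/writers for external formats and the shared coordinate model.

All internal coordinates are 0-based half-open. The only places 1-based
coordinates appear are the GFF3 reader (input convention) and the TSV
report writer (output convention for humans), so there is a single
conversion point in each direction.

"Upstream" is always strand-aware: smaller coordinates on the + strand,
larger coordinates on the - strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

VALID_BASES = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Replicon sequences keyed by id; alphabet {A,C,G,T,N}."""

    replicons: dict[str, str]

    def __post_init__(self) -> None:
        for rid, seq in self.replicons.items():
            if not seq:
                raise FormatError(f"replicon {rid!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"replicon {rid!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {rid: len(seq) for rid, seq in self.replicons.items()}

    def fetch(self, replicon: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the given strand (reverse-complemented for -)."""
        seq = self.replicons[replicon][start:end]
        return revcomp(seq) if strand == "-" else seq


@dataclass(frozen=True)
class GeneFeature:
    """An annotated ORF (or operon member) in 0-based half-open coordinates."""

    gene_id: str
    replicon: str
    strand: str
    start: int
    end: int
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start},{self.end}) for {self.gene_id}")

    @property
    def start_codon_pos(self) -> int:
        """0-based genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class EndProfile:
    """Sparse per-position read 5'-end counts for one sequencing library.

    ``counts`` maps (replicon, strand, 0-based position) -> count; zero
    entries are never stored. ``treatment`` distinguishes the
    5'-pyrophosphatase-treated library (RPP+, primary 5'-PPP ends
    ligatable and hence enriched) from the untreated one (RPP-).
    Counts are raw integers as parsed, and become float densities after
    size-factor normalization.
    """

    library_id: str
    condition: str
    replicate: int
    treatment: str  # "RPP+" or "RPP-"
    counts: dict[tuple[str, str, int], float] = field(default_factory=dict)

    def positions(self, replicon: str, strand: str) -> list[int]:
        return sorted(
            p for (r, s, p) in self.counts if r == replicon and s == strand
        )


@dataclass(frozen=True)
class OperonModel:
    """A co-transcribed gene cluster; members ordered 5'->3' in transcription direction."""

    operon_id: str
    gene_ids: tuple[str, ...]
    strand: str
    replicon: str


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a Genome (uppercased, U mapped to T)."""
    replicons: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in records:
        if rec.id in replicons:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has non-IUPAC characters {sorted(bad)}"
            )
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} is empty")
        replicons[rec.id] = seq
    return Genome(replicons)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in genome.replicons.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff3_attributes(col9: str) -> dict[str, str]:
    out = {}
    for item in col9.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path, genome: Genome) -> list[GeneFeature]:
    """Read CDS-like features from GFF3 (1-based inclusive) into 0-based half-open.

    The gene id is taken from the ID attribute, falling back to locus_tag.
    Records on unknown replicons, with end < start, or out of genome
    bounds raise a FormatError naming the offending line.
    """
    feats: list[GeneFeature] = []
    lengths = genome.lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            replicon, _source, ftype, start1, end1, _score, strand, _frame, attrs = cols
            if replicon not in lengths:
                raise FormatError(f"{path}:{lineno}: unknown replicon {replicon!r}")
            try:
                start1i, end1i = int(start1), int(end1)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1i < start1i:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            start, end = start1i - 1, end1i  # to 0-based half-open
            if start < 0 or end > lengths[replicon]:
                raise FormatError(f"{path}:{lineno}: feature outside replicon bounds")
            attrd = _gff3_attributes(attrs)
            gene_id = attrd.get("ID") or attrd.get("locus_tag")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing ID/locus_tag attribute")
            feats.append(
                GeneFeature(
                    gene_id=gene_id,
                    replicon=replicon,
                    strand=strand,
                    start=start,
                    end=end,
                    kind=ftype,
                )
            )
    return feats


def write_gff3(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features back out as GFF3 (round-trips read_gff3 exactly)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.replicon}\tprimarytx\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.gene_id}\n"
            )


def _read_bedgraph(path: str | Path, strand: str, counts: dict, lengths: Mapping[str, int] | None) -> None:
    seen_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            replicon, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative count {value}")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty or inverted interval")
            if start < seen_end.get(replicon, 0):
                raise FormatError(
                    f"{path}:{lineno}: overlapping or unsorted intervals on one strand"
                )
            seen_end[replicon] = end
            if lengths is not None and (replicon not in lengths or end > lengths[replicon]):
                raise FormatError(f"{path}:{lineno}: interval outside replicon bounds")
            if value == 0:
                continue
            for pos in range(start, end):
                counts[(replicon, strand, pos)] = value


def read_bedgraph_pair(
    plus_path: str | Path,
    minus_path: str | Path,
    library_id: str,
    condition: str,
    replicate: int,
    treatment: str,
    genome: Genome | None = None,
) -> EndProfile:
    """Read one stranded bedGraph pair into a sparse EndProfile.

    bedGraph intervals are 0-based half-open; values are 5'-end counts.
    Intervals are expanded to per-position counts; zero-valued intervals
    are dropped. Note bedGraph requires sorted, non-overlapping intervals
    per strand; overlaps are a format error.
    """
    counts: dict[tuple[str, str, int], float] = {}
    lengths = genome.lengths if genome is not None else None
    _read_bedgraph(plus_path, "+", counts, lengths)
    _read_bedgraph(minus_path, "-", counts, lengths)
    return EndProfile(
        library_id=library_id,
        condition=condition,
        replicate=replicate,
        treatment=treatment,
        counts=counts,
    )


def write_bedgraph_pair(profile: EndProfile, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write an EndProfile as <prefix>.plus.bedgraph / <prefix>.minus.bedgraph."""
    prefix = Path(path_prefix)
    paths = (prefix.with_suffix(".plus.bedgraph"), prefix.with_suffix(".minus.bedgraph"))
    for strand, out in zip("+-", paths):
        items = sorted(
            ((r, p, v) for (r, s, p), v in profile.counts.items() if s == strand)
        )
        with open(out, "w") as fh:
            for r, p, v in items:
                val = int(v) if float(v).is_integer() else v
                fh.write(f"{r}\t{p}\t{p + 1}\t{val}\n")
    return paths


TSS_TSV_COLUMNS = [
    "tss_id",
    "replicon",
    "position",
    "strand",
    "category",
    "gene_id",
    "density",
    "enrichment",
    "conditions",
    "label",
]


def write_tss_outputs(tss_set, path_prefix: str | Path) -> dict[str, Path]:
    """Write a classified TSS set as TSV (1-based positions), BED6 and a JSON summary.

    The TSV mirrors the role of a per-TSS supplementary table; the BED
    track uses 0-based starts, name=category and a density-scaled score.
    """
    prefix = Path(path_prefix)
    tsv_path = prefix.with_suffix(".tss.tsv")
    bed_path = prefix.with_suffix(".tss.bed")
    json_path = prefix.with_suffix(".tss.summary.json")
    tss_list = list(tss_set)
    max_density = max((t.density for t in tss_list), default=1.0) or 1.0
    counts = {c: 0 for c in "PSIAN"}
    with open(tsv_path, "w") as tsv, open(bed_path, "w") as bed:
        tsv.write("\t".join(TSS_TSV_COLUMNS) + "\n")
        for i, t in enumerate(tss_list, 1):
            cat = t.category or "N"
            counts[cat] = counts.get(cat, 0) + 1
            tss_id = getattr(t, "tss_id", None) or f"TSS{i:05d}"
            tsv.write(
                "\t".join(
                    [
                        tss_id,
                        t.replicon,
                        str(t.position + 1),  # 1-based for reporting
                        t.strand,
                        cat,
                        t.gene_id or ".",
                        f"{t.density:.4f}",
                        f"{t.enrichment:.4f}",
                        ",".join(sorted(t.conditions)),
                        getattr(t, "label", "") or ".",
                    ]
                )
                + "\n"
            )
            score = int(round(1000 * t.density / max_density))
            bed.write(
                f"{t.replicon}\t{t.position}\t{t.position + 1}\t{cat}\t{score}\t{t.strand}\n"
            )
    with open(json_path, "w") as fh:
        json.dump({"n_tss": len(tss_list), "categories": counts}, fh, indent=1)
    return {"tsv": tsv_path, "bed": bed_path, "summary": json_path}
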