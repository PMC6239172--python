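"""Promoter -10/-35 box and Shine-Dalgarno motif localization.

Elements are found by mismatch-tolerant scanning against the canonical
sigma-70 consensus sequences (TATAAT for the -10 box, TTGACA for the
-35 box) inside their biologically allowed offset ranges relative to
the TSS, and against the AGGAGG Shine-Dalgarno consensus relative to
the start codon. This consensus-anchored approach localizes the known
elements rather than discovering motifs de novo.

Offset convention: offset -1 is the base immediately upstream of the
TSS (or start codon for SD); an element's offset is that of its first
(5'-most) base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome_io import Genome
from .tss_annotator import UtrRecord

log = logging.getLogger(__name__)

MINUS10_CONSENSUS = "TATAAT"
MINUS35_CONSENSUS = "TTGACA"
SD_CONSENSUS = "AGGAGG"

# allowed offset span [lo, hi] that the whole element must lie within
MINUS10_RANGE = (-20, -5)
MINUS35_RANGE = (-36, -23)
SD_RANGE = (-20, -5)


@dataclass
class ScanConfig:
    max_mismatches: int = 1       # for -10/-35 boxes
    sd_min_identities: int = 4    # of the 6 SD consensus positions
    width: int = 50               # upstream window width, nt


@dataclass(frozen=True)
class PromoterHit:
    tss_id: str | None
    element: str                # minus10 | minus35 | SD
    matched_sequence: str
    offset: int                 # first base, relative to TSS (boxes) or start codon (SD)
    mismatches: int
    spacer: int | None = None   # bp between -35 box end and -10 box start


def extract_upstream_windows(
    tss_set, genome: Genome, width: int = 50
) -> dict[str, str]:
    """Strand-aware windows covering offsets -width..-1 upstream of each TSS.

    TSSs closer than ``width`` to a contig edge are skipped with a warning.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    out: dict[str, str] = {}
    for tss in tss_set:
        length = genome.lengths[tss.replicon]
        tss_id = tss.tss_id or f"{tss.replicon}:{tss.position}:{tss.strand}"
        if tss.strand == "+":
            if tss.position - width < 0:
                log.warning("TSS %s too close to contig edge; window skipped", tss_id)
                continue
            out[tss_id] = genome.fetch(tss.replicon, tss.position - width, tss.position, "+")
        else:
            if tss.position + 1 + width > length:
                log.warning("TSS %s too close to contig edge; window skipped", tss_id)
                continue
            out[tss_id] = genome.fetch(tss.replicon, tss.position + 1, tss.position + 1 + width, "-")
    return out


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _best_match(window: str, width: int, consensus: str,
                offset_range: tuple[int, int], max_mm: int):
    """Best consensus match whose k-mer lies fully inside offset_range.

    Window index i corresponds to offset i - width (last char = -1).
    Ties: fewer mismatches, then the 3'-most (largest) offset.
    """
    k = len(consensus)
    if len(window) < k:
        raise ValueError(f"window shorter than element ({len(window)} < {k})")
    lo, hi = offset_range
    best = None
    # scanning 5'->3'; >= on ties keeps the 3'-most offset
    for start in range(max(lo, -width), hi - k + 2):
        i = start + width
        if i < 0 or i + k > len(window):
            continue
        mm = _mismatches(window[i : i + k], consensus)
        if mm <= max_mm and (best is None or mm <= best[0]):
            if best is None or mm < best[0] or start > best[1]:
                best = (mm, start, window[i : i + k])
    return best


def scan_promoter_elements(
    window: str,
    config: ScanConfig | None = None,
    tss_id: str | None = None,
) -> list[PromoterHit]:
    """Locate the -10 and -35 boxes in one upstream window.

    The -10 box is the best <=max_mismatches match to TATAAT lying fully
    within offsets [-20,-5]; the -35 box the best match to TTGACA within
    [-36,-23]. When both are found the spacer (bp between the -35 box
    end and the -10 box start) is reported on the -10 hit; canonical
    sigma-70 promoters have a spacer of about 17 bp.
    """
    config = config or ScanConfig()
    width = len(window)
    hits: list[PromoterHit] = []
    m10 = _best_match(window, width, MINUS10_CONSENSUS, MINUS10_RANGE, config.max_mismatches)
    m35 = _best_match(window, width, MINUS35_CONSENSUS, MINUS35_RANGE, config.max_mismatches)
    spacer = None
    if m10 and m35:
        minus35_end = m35[1] + len(MINUS35_CONSENSUS) - 1
        spacer = m10[1] - minus35_end - 1
    if m35:
        hits.append(PromoterHit(tss_id, "minus35", m35[2], m35[1], m35[0]))
    if m10:
        hits.append(PromoterHit(tss_id, "minus10", m10[2], m10[1], m10[0], spacer=spacer))
    return hits


def scan_sd_motif(
    utr: UtrRecord, config: ScanConfig | None = None
) -> PromoterHit | None:
    """Best Shine-Dalgarno (AGGAGG) match in a leader, or None.

    Requires >= sd_min_identities of the 6 consensus positions, with the
    6-mer fully inside offsets [-20,-5] from the start codon. Ties go to
    the match closest to the start codon (3'-most).
    """
    config = config or ScanConfig()
    seq = utr.sequence.replace("U", "T")
    length = len(seq)
    if length < 5:
        return None
    k = len(SD_CONSENSUS)
    lo, hi = SD_RANGE
    best = None
    for start in range(max(lo, -length), hi - k + 2):
        i = start + length
        if i < 0 or i + k > length:
            continue
        ident = k - _mismatches(seq[i : i + k], SD_CONSENSUS)
        if best is None or ident > best[0] or (ident == best[0] and start > best[1]):
            best = (ident, start, seq[i : i + k])
    if best is None or best[0] < config.sd_min_identities:
        return None
    return PromoterHit(
        tss_id=utr.gene_id,
        element="SD",
        matched_sequence=best[2],
        offset=best[1],
        mismatches=k - best[0],
    )
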