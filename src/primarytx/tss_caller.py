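"""dRNA-seq TSS determination workflow.

The caller follows the classic differential-RNA-seq logic: 5'-end read
positions are normalized by median-of-ratios size factors, candidate
peaks are clustered (300-bp chaining, then sub-clustering wherever the
standard deviation of two adjacent peaks is < 15, i.e. a gap < 30 bp),
one representative per sub-cluster is kept, and a representative is
accepted as a TSS when its RPP+/RPP- density ratio is at least twofold
and it is reproduced by both biological replicates within a small
positional window. Per-condition TSS lists are finally merged within
+/-4 bp into a total set labelled constitutive / conditional / specific.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import EndProfile

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass
class TssCallerConfig:
    """Tunables of the TSS determination workflow (units: bp and normalized counts)."""

    cluster_gap: int = 300          # max gap chaining candidates into an initial cluster
    pair_sd_max: float = 15.0       # SD threshold for adjacent-pair sub-clustering
    enrichment_min: float = 2.0     # min RPP+/RPP- density ratio
    merge_window: int = 4           # +/- bp for cross-condition merging
    min_density: float = 5.0        # candidate floor, normalized units
    pseudocount: float = 1.0        # added to both ratio terms
    replicate_window: int = 4       # +/- bp for replicate reproducibility
    ratio_halfwidth: int = 0        # half-width of the window summed for the ratio

    @classmethod
    def from_file(cls, path) -> "TssCallerConfig":
        """Load from a flat key=value text file; unknown keys rejected."""
        kwargs = {}
        fields = cls.__dataclass_fields__
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = type(fields[key].default)(value.strip())
        return cls(**kwargs)


@dataclass(frozen=True)
class TssCandidate:
    replicon: str
    strand: str
    position: int
    density: float
    library_id: str


@dataclass
class TssRecord:
    """A called transcription start site."""

    replicon: str
    strand: str
    position: int
    density: float
    enrichment: float
    conditions: set[str] = field(default_factory=set)
    category: str | None = None  # one of P,S,I,A,N once classified
    gene_id: str | None = None
    label: str | None = None     # constitutive / conditional / specific
    tss_id: str | None = None


def compute_size_factors(count_table: np.ndarray, library_ids=None) -> dict:
    """Median-of-ratios size factors from a rows x libraries raw count table.

    s_j = median over rows i of k_ij / (prod_j k_ij)^(1/m), where rows
    containing any zero are excluded (their geometric mean is degenerate).
    """
    k = np.asarray(count_table, dtype=float)
    if k.ndim != 2 or k.shape[1] < 1:
        raise NormalizationError("count table must be 2-D (rows x libraries)")
    if library_ids is None:
        library_ids = list(range(k.shape[1]))
    positive = np.all(k > 0, axis=1)
    if not positive.any():
        raise NormalizationError("no row with all-positive counts; cannot normalize")
    kp = k[positive]
    log_geomean = np.mean(np.log(kp), axis=1)
    ratios = kp / np.exp(log_geomean)[:, None]
    s = np.median(ratios, axis=0)
    return dict(zip(library_ids, s))


def normalize_profile(profile: EndProfile, size_factors: dict) -> EndProfile:
    """Divide every count by the library's size factor (sparsity preserved)."""
    if profile.library_id not in size_factors:
        raise NormalizationError(f"no size factor for library {profile.library_id!r}")
    s = size_factors[profile.library_id]
    return replace(
        profile, counts={key: v / s for key, v in profile.counts.items()}
    )


def profile_count_table(profiles: list[EndProfile], bin_size: int = 100):
    """Bin-level count matrix over a set of libraries, for size-factor estimation.

    Returns (matrix rows=bins x cols=libraries, library_ids). Bins with
    no reads in any library are dropped; bins with a zero in any single
    library are later excluded by the median-of-ratios itself. The
    default 100-bp bins keep the median bin dominated by gene-body
    (processed-end background) signal rather than by TSS spikes, which
    is the point of the normalization: treated and untreated libraries
    should appear equally covered within genes.
    """
    library_ids = [p.library_id for p in profiles]
    index: dict[tuple[str, int], int] = {}
    rows: list[np.ndarray] = []
    for j, prof in enumerate(profiles):
        for (replicon, _strand, pos), v in prof.counts.items():
            key = (replicon, pos // bin_size)
            i = index.get(key)
            if i is None:
                i = index[key] = len(rows)
                rows.append(np.zeros(len(profiles)))
            rows[i][j] += v
    if not rows:
        raise NormalizationError("no counts in any library")
    return np.vstack(rows), library_ids


def detect_candidates(norm_profile: EndProfile, min_density: float = 5.0) -> list[TssCandidate]:
    """Positions with normalized density >= min_density, sorted by (replicon, strand, position)."""
    out = [
        TssCandidate(r, s, p, d, norm_profile.library_id)
        for (r, s, p), d in norm_profile.counts.items()
        if d >= min_density and d > 0
    ]
    out.sort(key=lambda c: (c.replicon, c.strand, c.position))
    return out


def _upstream_key(strand: str):
    # for ties: most upstream = smallest position on +, largest on -
    return (lambda c: c.position) if strand == "+" else (lambda c: -c.position)


def cluster_candidates(candidates: list[TssCandidate], cluster_gap: int = 300,
                       pair_sd_max: float = 15.0) -> list[tuple[list[TssCandidate], TssCandidate]]:
    """Cluster candidates and pick one representative per sub-cluster.

    Initial clusters chain candidates with consecutive gaps <= cluster_gap.
    Within a cluster, two adjacent peaks a,b stay in one sub-cluster iff
    the population SD of {a,b} (= |a-b|/2) is < pair_sd_max, i.e. the gap
    is < 2*pair_sd_max. The representative is the member with highest
    density (ties broken toward the most upstream position, strand-aware).

    Returns a list of (members, representative); input must be sorted by
    (replicon, strand, position) and all on one replicon/strand.
    """
    if not candidates:
        return []
    replicon, strand = candidates[0].replicon, candidates[0].strand
    prev = None
    for c in candidates:
        if (c.replicon, c.strand) != (replicon, strand):
            raise ValueError("cluster_candidates expects a single replicon/strand")
        if prev is not None and c.position < prev:
            raise ValueError("candidates must be sorted by position")
        prev = c.position

    # initial 300-bp chains, then adjacent-pair SD sub-chains
    subclusters: list[list[TssCandidate]] = []
    current = [candidates[0]]
    for c in candidates[1:]:
        gap = c.position - current[-1].position
        within_initial = gap <= cluster_gap
        pair_sd = gap / 2.0
        if within_initial and pair_sd < pair_sd_max:
            current.append(c)
        else:
            subclusters.append(current)
            current = [c]
    subclusters.append(current)

    upstream = _upstream_key(strand)
    out = []
    for members in subclusters:
        rep = min(members, key=lambda c: (-c.density, upstream(c)))
        out.append((members, rep))
    return out


def enrichment_ratio(
    position: tuple[str, str, int],
    rpp_plus_norm: EndProfile,
    rpp_minus_norm: EndProfile,
    pseudocount: float = 1.0,
    halfwidth: int = 0,
) -> float:
    """(d+ + c) / (d- + c) at the representative position.

    With halfwidth > 0 the densities are summed over +/-halfwidth bp.
    """
    replicon, strand, pos = position

    def density(profile: EndProfile) -> float:
        return sum(
            profile.counts.get((replicon, strand, p), 0.0)
            for p in range(pos - halfwidth, pos + halfwidth + 1)
        )

    return (density(rpp_plus_norm) + pseudocount) / (density(rpp_minus_norm) + pseudocount)


def _replicate_representatives(
    plus: EndProfile, minus: EndProfile, config: TssCallerConfig
) -> list[TssCandidate]:
    """Enriched sub-cluster representatives for one RPP+/RPP- replicate pair."""
    reps: list[TssCandidate] = []
    cands = detect_candidates(plus, config.min_density)
    for (replicon, strand), group in _group_by_track(cands):
        for _members, rep in cluster_candidates(group, config.cluster_gap, config.pair_sd_max):
            ratio = enrichment_ratio(
                (replicon, strand, rep.position), plus, minus,
                config.pseudocount, config.ratio_halfwidth,
            )
            if ratio >= config.enrichment_min:
                reps.append(rep)
    return reps


def _group_by_track(candidates: list[TssCandidate]):
    groups: dict[tuple[str, str], list[TssCandidate]] = {}
    for c in candidates:
        groups.setdefault((c.replicon, c.strand), []).append(c)
    return sorted(groups.items())


def call_condition_tss(
    profiles: list[EndProfile],
    size_factors: dict,
    config: TssCallerConfig | None = None,
) -> list[TssRecord]:
    """Call TSSs for one condition from its RPP+/RPP- replicate pairs.

    Each replicate pair independently yields enriched representatives; a
    condition TSS requires representatives from both replicates within
    +/-replicate_window bp, and takes the position and density of the
    higher-density replicate representative. With a single replicate the
    reproducibility filter is skipped (with a warning).
    """
    config = config or TssCallerConfig()
    conditions = {p.condition for p in profiles}
    if len(conditions) != 1:
        raise ValueError(f"profiles span multiple conditions: {sorted(conditions)}")
    condition = conditions.pop()

    pairs: dict[int, dict[str, EndProfile]] = {}
    for p in profiles:
        pairs.setdefault(p.replicate, {})[p.treatment] = p
    rep_candidates: dict[int, list[TssCandidate]] = {}
    enrich_lookup: dict[tuple[int, str, str, int], float] = {}
    for replicate, by_treatment in sorted(pairs.items()):
        if "RPP+" not in by_treatment or "RPP-" not in by_treatment:
            raise ValueError(f"replicate {replicate} lacks an RPP+/RPP- partner")
        plus = normalize_profile(by_treatment["RPP+"], size_factors)
        minus = normalize_profile(by_treatment["RPP-"], size_factors)
        reps = _replicate_representatives(plus, minus, config)
        rep_candidates[replicate] = reps
        for r in reps:
            enrich_lookup[(replicate, r.replicon, r.strand, r.position)] = enrichment_ratio(
                (r.replicon, r.strand, r.position), plus, minus,
                config.pseudocount, config.ratio_halfwidth,
            )

    replicates = sorted(rep_candidates)
    if len(replicates) == 1:
        warnings.warn(
            f"condition {condition}: single replicate; reproducibility filter skipped",
            stacklevel=2,
        )
        chosen = [(r, enrich_lookup[(replicates[0], r.replicon, r.strand, r.position)])
                  for r in rep_candidates[replicates[0]]]
    else:
        # pair representatives across the two replicates within the window
        chosen = []
        first, second = replicates[0], replicates[1]
        used: set[int] = set()
        others = rep_candidates[second]
        for a in rep_candidates[first]:
            best = None
            for idx, b in enumerate(others):
                if idx in used or (b.replicon, b.strand) != (a.replicon, a.strand):
                    continue
                d = abs(b.position - a.position)
                if d <= config.replicate_window and (best is None or d < best[0]):
                    best = (d, idx, b)
            if best is None:
                continue
            used.add(best[1])
            b = best[2]
            winner, w_rep = (a, first) if a.density >= b.density else (b, second)
            chosen.append(
                (winner, enrich_lookup[(w_rep, winner.replicon, winner.strand, winner.position)])
            )

    return [
        TssRecord(
            replicon=r.replicon,
            strand=r.strand,
            position=r.position,
            density=r.density,
            enrichment=ratio,
            conditions={condition},
        )
        for r, ratio in sorted(chosen, key=lambda t: (t[0].replicon, t[0].strand, t[0].position))
    ]


def merge_tss_sets(
    tss_lists: list[list[TssRecord]],
    merge_window: int = 4,
    n_conditions: int | None = None,
) -> list[TssRecord]:
    """Merge per-condition TSS lists into the total set within +/-merge_window bp.

    Greedy: seed at the unmerged TSS of highest density, absorb every TSS
    within the window on the same strand/replicon, union the condition
    labels, repeat. Output is labelled constitutive (all conditions),
    conditional (>=2) or specific (1).
    """
    pool = [replace(t, conditions=set(t.conditions)) for lst in tss_lists for t in lst]
    all_conditions = {c for t in pool for c in t.conditions}
    total = n_conditions if n_conditions is not None else len(all_conditions)
    # deterministic seeding order: density desc, then coordinates
    order = sorted(
        range(len(pool)),
        key=lambda i: (-pool[i].density, pool[i].replicon, pool[i].strand, pool[i].position),
    )
    merged: list[TssRecord] = []
    taken = [False] * len(pool)
    for i in order:
        if taken[i]:
            continue
        seed = pool[i]
        taken[i] = True
        conditions = set(seed.conditions)
        for j in range(len(pool)):
            if taken[j]:
                continue
            t = pool[j]
            if (
                t.replicon == seed.replicon
                and t.strand == seed.strand
                and abs(t.position - seed.position) <= merge_window
            ):
                taken[j] = True
                conditions |= t.conditions
        n = len(conditions)
        label = "constitutive" if total and n == total else ("conditional" if n >= 2 else "specific")
        merged.append(replace(seed, conditions=conditions, label=label))
    merged.sort(key=lambda t: (t.replicon, t.strand, t.position))
    for i, t in enumerate(merged, 1):
        t.tss_id = f"TSS{i:05d}"
    return merged
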