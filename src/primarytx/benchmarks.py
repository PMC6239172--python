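"""End-to-end benchmarks scoring every pipeline stage against planted truth.

Each function generates its own inputs from a seed, runs the relevant
stage of the package, and measures recovery of the planted signal:
TSS-caller recall/precision, classification of positional archetypes,
agreement of the folding dynamic program with exhaustive enumeration,
size-factor recovery, calibration of the differential test, exactness
of the rank-sum test, expression-group recovery, and the folding-energy
contrast between hairpin-bearing and shuffled leaders.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .genome_io import GeneFeature, Genome
from .tss_caller import (
    TssRecord,
    call_condition_tss,
    compute_size_factors,
    merge_tss_sets,
    profile_count_table,
)
from .tss_annotator import classify_tss
from .rna_folding import brute_force_fold, fold_mfe, score_structure
from .expression_stats import (
    adjust_fdr,
    adjusted_rand_score,
    kmeans_cluster,
    rank_sum_exact_enumeration,
    rank_sum_test,
    select_deg,
    test_differential_expression,
)
from .synthetic_data import (
    SyntheticTruth,
    generate_genome_annotation,
    generate_structured_utrs,
    simulate_count_matrix,
    simulate_end_profiles,
)


def tss_recovery(
    seed: int,
    n_genes: int = 200,
    depth: float = 50.0,
    enrichment: float = 8.0,
    replicates: int = 2,
    tolerance: int = 2,
) -> dict:
    """Recall/precision of the condition-level TSS caller on planted TSSs."""
    genome, genes, _, truth = generate_genome_annotation(
        n_genes, int(n_genes * 2600 + 10000), seed
    )
    profiles = simulate_end_profiles(
        truth, depth=depth, enrichment=enrichment, replicates=replicates,
        seed=seed + 1, conditions=("H20",),
    )
    table, lib_ids = profile_count_table(profiles)
    sf = compute_size_factors(table, lib_ids)
    called = call_condition_tss(profiles, sf)
    true_set = [(t.replicon, t.strand, t.position) for t in truth.tss]
    called_set = [(t.replicon, t.strand, t.position) for t in called]

    def near(a, pool):
        return any(a[0] == b[0] and a[1] == b[1] and abs(a[2] - b[2]) <= tolerance for b in pool)

    recall = sum(near(t, called_set) for t in true_set) / len(true_set)
    precision = (
        sum(near(c, true_set) for c in called_set) / len(called_set) if called_set else 0.0
    )
    return {"recall": recall, "precision": precision,
            "n_true": len(true_set), "n_called": len(called_set)}


def _archetype_case() -> tuple[Genome, list[GeneFeature], dict[str, TssRecord]]:
    """One unambiguous instance of each positional category, plus the
    equidistant two-gene tie."""
    rng = np.random.default_rng(0)
    seq = list("".join(rng.choice(list("ACGT"), size=20000)))
    for pos in (1000, 12000, 12200):
        seq[pos : pos + 3] = list("ATG")
    seq[5997:6000] = list("CAT")
    genome = Genome({"chr": "".join(seq)})
    genes = [
        GeneFeature("g1", "chr", "+", 1000, 2000),
        GeneFeature("g2", "chr", "-", 5000, 6000),
        GeneFeature("g5", "chr", "+", 12000, 12150),
        GeneFeature("g6", "chr", "+", 12200, 12800),
    ]

    def tss(position, strand="+", density=10.0):
        return TssRecord("chr", strand, position, density, 5.0, {"H20"})

    cases = {
        "P": tss(950, density=100.0),
        "S": tss(940, density=40.0),
        "I": tss(1500, density=20.0),
        "A": tss(1500, "-", density=20.0),
        "N": tss(9000, density=20.0),
        "tie": tss(12100, density=60.0),
    }
    return genome, genes, cases


def classification_archetypes() -> dict:
    """Fraction of archetype relations classified as planted (expects 6/6)."""
    _, genes, cases = _archetype_case()
    classify_tss(list(cases.values()), genes)
    expected = {"P": ("P", "g1"), "S": ("S", "g1"), "I": ("I", "g1"),
                "A": ("A", "g1"), "N": ("N", None), "tie": ("P", "g5")}
    correct = sum(
        (cases[k].category, cases[k].gene_id) == v for k, v in expected.items()
    )
    return {"n_correct": correct, "n_cases": len(expected)}


def folding_oracle(seed: int, n_random: int = 200, random_len: int = 12) -> dict:
    """Agreement of the folding DP with exhaustive enumeration.

    Covers all 4^6 hexamers plus random 12-mers; agreement requires the
    exact MFE and a structure that re-scores to it.
    """
    rng = np.random.default_rng(seed)
    sequences = ["".join(p) for p in itertools.product("ACGU", repeat=6)]
    sequences += [
        "".join(rng.choice(list("ACGU"), size=random_len)) for _ in range(n_random)
    ]
    agree = 0
    for seq in sequences:
        dp = fold_mfe(seq)
        bf = brute_force_fold(seq)
        ok = (
            dp.mfe == bf.mfe
            and score_structure(seq, dp.structure) == dp.mfe
            and score_structure(seq, bf.structure) == bf.mfe
        )
        agree += ok
    return {"n_sequences": len(sequences), "n_agree": agree,
            "agreement": agree / len(sequences)}


def normalization_recovery(seed: int, factors=(0.5, 1.0, 2.0), n_rows: int = 300) -> dict:
    """Size-factor ratio recovery for exactly depth-scaled Poisson columns."""
    rng = np.random.default_rng(seed)
    base = rng.poisson(100, size=n_rows).astype(float)
    table = base[:, None] * np.asarray(factors)[None, :]
    sf = compute_size_factors(table)
    s = np.array([sf[j] for j in range(len(factors))])
    ratios = s / s[0]
    expected = np.asarray(factors) / factors[0]
    return {"max_ratio_error": float(np.max(np.abs(ratios - expected))),
            "n_rows": n_rows}


def statistical_calibration(seed: int, n_null: int = 2000, n_planted: int = 500,
                            dispersion: float = 0.05) -> dict:
    """Null FDR control and planted fold-change recovery of the NB Wald test."""
    rng = np.random.default_rng(seed)
    r = 1.0 / dispersion

    def nb(mu, n):
        return rng.negative_binomial(r, r / (r + mu[:, None]), size=(len(mu), n))

    mu0 = rng.lognormal(np.log(200), 1, n_null)
    null_counts = pd.DataFrame(
        nb(mu0, 8), columns=[f"l{i}" for i in range(8)]
    )
    sf = {c: 1.0 for c in null_counts.columns}
    table = test_differential_expression(
        null_counts, sf, [f"l{i}" for i in range(4)], [f"l{i}" for i in range(4, 8)]
    )
    padj = adjust_fdr(table["p"])
    frac_sig = float(np.nanmean(padj < 0.01))

    mu1 = rng.lognormal(np.log(200), 1, n_planted)
    planted = pd.DataFrame(
        np.hstack([nb(mu1, 3), nb(4 * mu1, 3)]), columns=[f"m{i}" for i in range(6)]
    )
    sf2 = {c: 1.0 for c in planted.columns}
    t2 = test_differential_expression(
        planted, sf2, [f"m{i}" for i in range(3)], [f"m{i}" for i in range(3, 6)]
    )
    return {"null_frac_padj_below_0.01": frac_sig,
            "planted_median_log2fc": float(t2["log2FC"].median()),
            "n_null": n_null, "n_planted": n_planted}


def rank_sum_oracle(max_total: int = 10) -> dict:
    """Exact rank-sum p vs enumeration over every tie-free split with n+m <= max_total."""
    worst = 0.0
    n_checked = 0
    for total in range(2, max_total + 1):
        for n in range(1, total):
            values = list(range(1, total + 1))
            for x_idx in itertools.combinations(range(total), n):
                x = [values[i] for i in x_idx]
                y = [values[i] for i in range(total) if i not in x_idx]
                _, p = rank_sum_test(x, y)
                worst = max(worst, abs(p - rank_sum_exact_enumeration(x, y)))
                n_checked += 1
    _, p_example = rank_sum_test([1, 2], [3, 4])
    return {"max_abs_error": worst, "n_checked": n_checked,
            "p_two_vs_two": float(p_example)}


def grouping_recovery(seed: int) -> dict:
    """Recovery of planted C1-like/C7-like blocks by DEG selection + K-means."""
    counts, design, truth = simulate_count_matrix(SyntheticTruth(), seed=seed)
    sf = compute_size_factors(counts.to_numpy(), list(counts.columns))
    results = {}
    ref = [c for c in counts.columns if design.loc[c, "condition"] == "H20"]
    for cond in ("A20", "H10", "A10"):
        cols = [c for c in counts.columns if design.loc[c, "condition"] == cond]
        t = test_differential_expression(counts, sf, ref, cols)
        t["padj"] = adjust_fdr(t["p"])
        results[cond] = t
    degs = sorted(select_deg(results))
    fc = pd.DataFrame({c: t["log2FC"] for c, t in results.items()}).loc[degs]
    labels, _ = kmeans_cluster(fc, [2], seed=seed, select_k=2)
    truth_labels = [truth.expression_groups[g] for g in degs]
    return {"ari": float(adjusted_rand_score(truth_labels, labels)),
            "n_deg": len(degs)}


def mfe_group_contrast(seed: int, n_per_class: int = 100) -> dict:
    """Folding-energy contrast between hairpin-planted and shuffled leaders."""
    structured, shuffled = generate_structured_utrs(n_per_class, stem_len=6, seed=seed)
    mfe_s = [fold_mfe(s).mfe for s in structured]
    mfe_u = [fold_mfe(s).mfe for s in shuffled]
    _, p = rank_sum_test(mfe_s, mfe_u, alternative="less")
    return {"median_structured": float(np.median(mfe_s)),
            "median_shuffled": float(np.median(mfe_u)),
            "p_less": float(p), "n_per_class": n_per_class}


def merge_semantics() -> dict:
    """The +/-4 bp chain collapses to its density seed; merging is idempotent."""
    def tss(position, density, condition):
        return TssRecord("chr", "+", position, density, 5.0, {condition})

    chain = [tss(100, 10.0, "A"), tss(104, 50.0, "B"), tss(108, 20.0, "C")]
    merged = merge_tss_sets([chain], n_conditions=3)
    twice = merge_tss_sets([merged], n_conditions=3)
    idempotent = [
        (t.position, sorted(t.conditions)) for t in merged
    ] == [(t.position, sorted(t.conditions)) for t in twice]
    return {"chain_n_merged": len(merged),
            "chain_position": merged[0].position if merged else -1,
            "idempotent": bool(idempotent)}
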