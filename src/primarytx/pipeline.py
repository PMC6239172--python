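"""End-to-end orchestration: simulate -> call TSS -> classify -> UTR/fold/promoter -> express.

A single RunConfig drives every stage; each run directory gets the
stage outputs plus a manifest recording the parameters actually used,
so a rerun with the same config and seed is bit-identical for the
deterministic stages. Failures in the optional analysis stages
(folding, promoter scanning) are logged and do not abort the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .genome_io import (
    Genome,
    write_bedgraph_pair,
    write_fasta,
    write_gff3,
    write_tss_outputs,
)
from .tss_caller import (
    TssCallerConfig,
    call_condition_tss,
    compute_size_factors,
    merge_tss_sets,
    profile_count_table,
)
from .tss_annotator import (
    assign_tss_to_operons,
    classify_tss,
    extract_5utr,
    start_codon_usage,
    tss_context_profile,
)
from .promoter_sd import ScanConfig, extract_upstream_windows, scan_promoter_elements, scan_sd_motif
from .rna_folding import EnergyParams, utr_mfe_table
from .expression_stats import (
    adjust_fdr,
    kmeans_cluster,
    select_deg,
    test_differential_expression,
)
from .synthetic_data import (
    CONDITIONS,
    REFERENCE_CONDITION,
    generate_genome_annotation,
    simulate_count_matrix,
    simulate_end_profiles,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of a pipeline run."""

    seed: int = 7
    out_dir: str = "run"
    # simulation
    n_genes: int = 60
    replicon_length: int = 160_000
    depth: float = 50.0
    enrichment: float = 8.0
    replicates: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    # TSS calling
    caller: TssCallerConfig = field(default_factory=TssCallerConfig)
    sf_bin_size: int = 100
    # expression
    n_reps_expression: int = 4
    dispersion: float = 0.05
    fdr_max: float = 0.01
    fc_min: float = 1.0
    min_contrasts: int = 1
    kmeans_k: int | None = 3
    kmeans_restarts: int = 10

    def validate(self) -> None:
        problems = []
        for name in ("depth", "enrichment", "replicon_length", "n_genes"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.caller.enrichment_min <= 0 or self.caller.min_density < 0:
            problems.append("caller thresholds must be positive")
        if REFERENCE_CONDITION not in self.conditions:
            problems.append(f"conditions must include {REFERENCE_CONDITION}")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic-data pipeline; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": _config_dict(config),
        "stages": {},
    }

    # --- simulate ---------------------------------------------------------
    genome, genes, operons, truth = generate_genome_annotation(
        config.n_genes, config.replicon_length, config.seed
    )
    write_fasta(genome, out / "genome.fasta")
    write_gff3(genes, out / "annotation.gff3")
    profiles = simulate_end_profiles(
        truth,
        depth=config.depth,
        enrichment=config.enrichment,
        replicates=config.replicates,
        seed=config.seed + 1,
        conditions=config.conditions,
    )
    for p in profiles:
        write_bedgraph_pair(p, out / p.library_id)
    truth.to_json(out / "truth.json")
    manifest["stages"]["simulate"] = {
        "n_genes": config.n_genes,
        "n_libraries": len(profiles),
    }

    # --- TSS calling ------------------------------------------------------
    per_condition = []
    for condition in config.conditions:
        cond_profiles = [p for p in profiles if p.condition == condition]
        table, lib_ids = profile_count_table(cond_profiles, config.sf_bin_size)
        sf = compute_size_factors(table, lib_ids)
        per_condition.append(call_condition_tss(cond_profiles, sf, config.caller))
    total = merge_tss_sets(
        per_condition, config.caller.merge_window, n_conditions=len(config.conditions)
    )
    manifest["stages"]["call_tss"] = {
        "per_condition": {c: len(t) for c, t in zip(config.conditions, per_condition)},
        "total": len(total),
    }

    # --- classification, UTRs --------------------------------------------
    classify_tss(total, genes)
    paths = write_tss_outputs(total, out / "run")
    gene_by_id = {g.gene_id: g for g in genes}
    utrs = [
        extract_5utr(t, gene_by_id[t.gene_id], genome)
        for t in total
        if t.category == "P"
    ]
    pd.DataFrame(
        [
            {
                "gene_id": u.gene_id,
                "tss_position": u.tss_position + 1,
                "length": u.length,
                "leader_status": u.leader_status,
                "start_codon": u.start_codon,
                "sequence": u.sequence,
            }
            for u in utrs
        ]
    ).to_csv(out / "utrs.tsv", sep="\t", index=False)
    context, n_context = tss_context_profile(total, genome)
    operon_map = assign_tss_to_operons(total, operons, genes)
    codon_usage = start_codon_usage(utrs)
    manifest["stages"]["classify"] = {
        "categories": {c: sum(t.category == c for t in total) for c in "PSIAN"},
        "n_utrs": len(utrs),
        "n_operons_validated": sum(
            1 for v in operon_map.values() if v["status"] == "TSS-validated"
        ),
        "context_n": n_context,
        "start_codons": {f"{k[0]}/{k[1]}": v for k, v in codon_usage.items()},
    }
    with open(out / "tss_context.json", "w") as fh:
        json.dump({str(k): v for k, v in context.items()}, fh, indent=1)

    # --- optional stages: folding and promoter scanning -------------------
    for stage, fn in (("fold", _stage_fold), ("promoter", _stage_promoter)):
        try:
            manifest["stages"][stage] = fn(out, total, utrs, genome)
        except Exception as exc:  # optional stages must not abort the run
            log.warning("optional stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"error": str(exc)}

    # --- expression -------------------------------------------------------
    counts, design, truth = simulate_count_matrix(
        truth,
        conditions=config.conditions,
        n_reps=config.n_reps_expression,
        dispersion=config.dispersion,
        seed=config.seed + 2,
    )
    counts.to_csv(out / "counts.tsv", sep="\t")
    sf = compute_size_factors(counts.to_numpy(), list(counts.columns))
    results = {}
    reference_cols = [c for c in counts.columns if design.loc[c, "condition"] == REFERENCE_CONDITION]
    for condition in config.conditions:
        if condition == REFERENCE_CONDITION:
            continue
        cols = [c for c in counts.columns if design.loc[c, "condition"] == condition]
        table = test_differential_expression(counts, sf, reference_cols, cols)
        table["padj"] = adjust_fdr(table["p"])
        results[f"{REFERENCE_CONDITION}:{condition}"] = table
    degs = select_deg(results, config.fc_min, config.fdr_max, config.min_contrasts)
    fc = pd.DataFrame({name: t["log2FC"] for name, t in results.items()}).loc[sorted(degs)]
    labels, sse = kmeans_cluster(
        fc, range(2, min(12, len(degs))), config.kmeans_restarts, config.seed,
        select_k=config.kmeans_k,
    )
    deg_table = pd.concat(
        {name: t for name, t in results.items()}, axis=1
    )
    deg_table.to_csv(out / "deg.tsv", sep="\t")
    labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    pd.Series(sse, name="sse").rename_axis("k").to_csv(out / "sse.tsv", sep="\t")
    manifest["stages"]["express"] = {"n_deg": len(degs), "k": int(labels.nunique())}

    # --- summary ----------------------------------------------------------
    with open(paths["summary"]) as fh:
        tss_summary = json.load(fh)
    summary = {"tss": tss_summary, "n_deg": len(degs)}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def _stage_fold(out: Path, total, utrs, genome) -> dict:
    table = utr_mfe_table(utrs, EnergyParams(), engine="builtin")
    table.to_csv(out / "mfe.tsv", sep="\t", index=False)
    folded = table["mfe"].notna()
    return {"n_folded": int(folded.sum()), "median_mfe": float(table.loc[folded, "mfe"].median())}


def _stage_promoter(out: Path, total, utrs, genome) -> dict:
    windows = extract_upstream_windows(total, genome, width=50)
    scan_cfg = ScanConfig()
    rows = []
    for tss_id, window in windows.items():
        for hit in scan_promoter_elements(window, scan_cfg, tss_id):
            rows.append(dataclasses.asdict(hit))
    for u in utrs:
        hit = scan_sd_motif(u, scan_cfg)
        if hit is not None:
            rows.append(dataclasses.asdict(hit))
    pd.DataFrame(
        rows, columns=["tss_id", "element", "matched_sequence", "offset", "mismatches", "spacer"]
    ).to_csv(out / "promoters.tsv", sep="\t", index=False)
    n10 = sum(1 for r in rows if r["element"] == "minus10")
    n35 = sum(1 for r in rows if r["element"] == "minus35")
    nsd = sum(1 for r in rows if r["element"] == "SD")
    return {"n_windows": len(windows), "minus10": n10, "minus35": n35, "sd": nsd}


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["conditions"] = list(config.conditions)
    return d
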