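"""End-to-end pipeline runner over the synthetic fixtures.

``run_pipeline`` executes simulate -> methylation -> insertions ->
DE/signatures -> GSEA -> single-cell QC as configured, writing every
stage's outputs plus a manifest (seeds, parameters, per-file sha256
checksums).  The run is a pure function of its config: rerunning with the
same config reproduces identical checksums.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import de, gsea, insertions, io, methylation, scqc, simulate

logger = logging.getLogger("nanoliver")

DEMO_CONFIG: dict = {
    "seed": 1,
    "genome": {"length": 20_000, "gc_fraction": 0.45, "n_promoters": 4},
    "methylome": {
        "promoter_open_prob": 0.85,
        "background_open_prob": 0.15,
        "cpg_meth_prob": 0.7,
    },
    "calls": {
        "coverage": 12,
        "llr_mean_effect": 4.0,
        "llr_sd": 1.0,
        "contamination_fraction": 0.05,
        "read_length": 4000,
        "threshold": 2.0,
        "min_coverage": 4,
        "flank": 1500,
    },
    "insertions": {
        "n_loci": 3,
        "support_per_locus": 4,
        "n_native_reads": 2,
        "n_background_reads": 8,
        "min_dual_len": 30,
        "cluster_radius": 50,
        "min_support": 2,
    },
    "bulk": {
        "n_genes": 1500,
        "n_samples_per_group": 3,
        "de_fraction": 0.1,
        "lfc_scale": 3.0,
        "dispersion_scale": 0.05,
        "n_perm": 200,
    },
    "sc": {"n_cells": 400, "lowq_fraction": 0.1},
}


def _preflight(config: dict, outdir: Path) -> None:
    for key in ("seed", "genome", "calls", "bulk", "sc"):
        if key not in config:
            raise ValueError(f"config missing required section {key!r}")
    outdir.mkdir(parents=True, exist_ok=True)


def run_pipeline(config: dict, outdir) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    config = copy.deepcopy(config)
    outdir = Path(outdir)
    _preflight(config, outdir)
    seed = int(config["seed"])
    t0 = time.time()
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        logger.info("wrote %s", path)
        return path

    header = {"seed": seed, "config_hash": _config_hash(config)}

    # --- stage 1: genome + methylome + call table -------------------------
    g = config["genome"]
    genome = simulate.make_genome(
        g["length"], g["gc_fraction"], g["n_promoters"], seed=seed
    )
    methylome = simulate.simulate_methylome(genome, seed=seed + 1, **config["methylome"])
    ccfg = config["calls"]
    sim_cfg = simulate.SimulationConfig(
        seed=seed + 2,
        coverage=ccfg["coverage"],
        llr_mean_effect=ccfg["llr_mean_effect"],
        llr_sd=ccfg["llr_sd"],
        contamination_fraction=ccfg["contamination_fraction"],
        read_length=ccfg["read_length"],
    )
    calls, read_truth = simulate.simulate_call_table(methylome, sim_cfg)
    emit("genome.fasta", lambda p: io.write_fasta({genome.name: genome.sequence}, p))
    emit(
        "tss.bed",
        lambda p: io.write_bed6(
            pd.DataFrame(
                {
                    "chrom": genome.name,
                    "start": [t for t, _ in genome.tss_list],
                    "end": [t + 1 for t, _ in genome.tss_list],
                    "name": [f"gene_{i}" for i in range(len(genome.tss_list))],
                    "strand": [s for _, s in genome.tss_list],
                }
            ),
            p,
            header_fields=header,
        ),
    )
    emit("calls.tsv", lambda p: io.write_call_table(calls, p, header_fields=header))

    # --- stage 2: methylation analysis ------------------------------------
    called = methylation.call_table(calls, threshold=ccfg["threshold"])
    kept, dropped = methylation.filter_contaminant_reads(called)
    summaries = methylation.aggregate_sites(kept, min_coverage=ccfg["min_coverage"])
    summaries = methylation.smooth_track(summaries)
    tss_df = pd.DataFrame(
        {
            "gene": [f"gene_{i}" for i in range(len(genome.tss_list))],
            "chrom": genome.name,
            "tss": [t for t, _ in genome.tss_list],
        }
    )
    promoters = methylation.promoter_profile(summaries, tss_df, flank=ccfg["flank"])
    emit(
        "site_summaries.tsv",
        lambda p: io.write_counts_tsv(summaries.set_index("pos"), p, header_fields=header),
    )
    for ctx in ("GCH", "HCG"):
        sub = summaries[summaries["context"] == ctx].sort_values("pos")
        emit(
            f"track_{ctx}.wig",
            lambda p, sub=sub, ctx=ctx: io.write_wiggle(
                sub, p, value_column="smoothed_level", track_name=ctx, header_fields=header
            ),
        )
    emit(
        "promoter_profile.tsv",
        lambda p: io.write_counts_tsv(promoters.set_index("gene"), p, header_fields=header),
    )

    # --- stage 3: insertion mapping ---------------------------------------
    icfg = config.get("insertions")
    if icfg:
        constructs = simulate.make_constructs(genome, seed=seed + 3)
        reads, ins_truth = simulate.simulate_insertion_reads(
            genome,
            constructs,
            n_loci=icfg["n_loci"],
            support_per_locus=icfg["support_per_locus"],
            n_native_reads=icfg["n_native_reads"],
            n_background_reads=icfg["n_background_reads"],
            seed=seed + 4,
        )
        tagged = insertions.find_construct_reads(reads, constructs)
        events, unanchored = insertions.locate_insertions(
            reads,
            tagged,
            genome.sequence,
            constructs,
            chrom=genome.name,
            min_dual_len=icfg["min_dual_len"],
            cluster_radius=icfg["cluster_radius"],
            min_support=icfg["min_support"],
        )
        events_df = pd.DataFrame(
            {
                "chrom": [e.chrom for e in events],
                "position": [e.position for e in events],
                "construct": [e.construct for e in events],
                "support": [e.support for e in events],
                "status": [e.status for e in events],
            }
        )
        emit("insertion_reads.fasta", lambda p: io.write_fasta(reads, p))
        emit(
            "insertion_events.tsv",
            lambda p: io.write_counts_tsv(
                events_df.set_index("position"), p, header_fields=header
            ),
        )
        accepted = events_df[events_df["status"] == insertions.STATUS_ACCEPTED]
        emit(
            "insertions_accepted.bed",
            lambda p: io.write_bed6(
                pd.DataFrame(
                    {
                        "chrom": accepted["chrom"],
                        "start": accepted["position"],
                        "end": accepted["position"] + 1,
                        "name": accepted["construct"],
                        "score": accepted["support"],
                    }
                ),
                p,
                header_fields=header,
            ),
        )

    # --- stage 4: bulk DE, signatures, GSEA -------------------------------
    bcfg = config["bulk"]
    bulk_cfg = simulate.SimulationConfig(
        seed=seed + 5,
        n_genes=bcfg["n_genes"],
        n_samples_per_group=bcfg["n_samples_per_group"],
        de_fraction=bcfg["de_fraction"],
        lfc_scale=bcfg["lfc_scale"],
        dispersion_scale=bcfg["dispersion_scale"],
    )
    counts, bulk_truth, _ = simulate.simulate_counts_bulk(bulk_cfg)
    groups = ["A"] * bcfg["n_samples_per_group"] + ["B"] * bcfg["n_samples_per_group"]
    stats_tab = de.nb_wald_test(counts, groups)
    hcc_sig = de.build_hcc_signature(stats_tab)
    ranked = gsea.rank_genes(stats_tab)
    planted_up = set(bulk_truth.index[(bulk_truth["true_log2fc"] > 0)])
    gene_sets = {"PLANTED_UP": planted_up}
    if hcc_sig.up_genes:
        gene_sets["HCC_UP"] = hcc_sig.up_genes
    results = gsea.permutation_test(ranked, gene_sets, n_perm=bcfg["n_perm"], seed=seed + 6)
    emit("bulk_counts.tsv", lambda p: io.write_counts_tsv(counts, p, header_fields=header))
    emit("de_stats.tsv", lambda p: io.write_counts_tsv(stats_tab, p, header_fields=header))
    emit(
        "signatures.gmt",
        lambda p: io.write_gmt(
            {"HCC_UP": sorted(hcc_sig.up_genes), "HCC_DOWN": sorted(hcc_sig.down_genes)}, p
        ),
    )
    emit(
        "gsea_results.tsv",
        lambda p: io.write_counts_tsv(
            gsea.results_table(results).set_index("name"), p, header_fields=header
        ),
    )

    # --- stage 5: single-cell QC and cell cycle ---------------------------
    scfg = config["sc"]
    sc_cfg = simulate.SimulationConfig(
        seed=seed + 7, n_cells=scfg["n_cells"], lowq_fraction=scfg["lowq_fraction"]
    )
    markers = simulate.default_phase_markers()
    sc_counts, sc_truth = simulate.simulate_counts_sc(sc_cfg, markers)
    metrics = scqc.cell_metrics(sc_counts)
    metrics["mapped_reads"] = sc_truth["mapped_reads"]
    metrics["sample_class"] = "HFL_CMT"
    kept_cells, excluded = scqc.qc_filter(metrics)
    filtered = scqc.gene_filter(sc_counts.loc[kept_cells])
    filtered = scqc.downsample_cells(filtered, n=500, seed=seed + 8)
    normalized = scqc.lognormalize(filtered)
    phases = scqc.cell_cycle_scores(normalized, markers)
    emit(
        "sc_qc_excluded.tsv",
        lambda p: excluded.to_csv(p, sep="\t", index=False),
    )
    emit(
        "sc_phase_scores.tsv",
        lambda p: io.write_counts_tsv(phases, p, header_fields=header),
    )

    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "elapsed_seconds": round(time.time() - t0, 2),
        "n_dropped_contaminant_reads": len(dropped),
        "files": {p.name: io.file_checksum(p) for p in sorted(written)},
    }
    # elapsed time is run metadata, not content: keep it out of the hashable part
    io.write_manifest(manifest, outdir / "manifest.json")
    return manifest


def _config_hash(config: dict) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
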