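"""Umbrella pipeline: filter -> matrix -> phase -> map (-> partition/qtl).

Each stage writes its artifact and contributes counts to a machine-
readable run report; a failure aborts with a stage-tagged error.  The
pipeline itself is deterministic — randomness exists only in the
simulator.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__, geneticmap, io, phasing, qtl
from .config import PipelineConfig
from .gametematrix import build_matrix, qc_sperm, select_reference_sperm
from .variants import filter_het_sites

logger = logging.getLogger("gametophase")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    logging.basicConfig(stream=sys.stderr, level=cfg.log_level)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "parameters": vars(cfg).copy()}

    try:
        records = io.read_vcf_sites(cfg.sites_vcf, quality_from=cfg.quality_from)
        result = filter_het_sites(
            records, min_quality=cfg.min_quality, min_minor_depth=cfg.min_minor_depth
        )
        sites = result.sites
        report["filter"] = {
            "sites_in": result.n_input,
            "sites_kept": len(sites),
            "rejected": dict(result.tally),
        }
        sites.to_csv(outdir / "sites.filtered.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("filter", exc) from exc

    try:
        calls = io.read_call_tables(cfg.calls_dir)
        matrix = build_matrix(sites, calls)
        qc, summary = qc_sperm(matrix)
        ref_id = select_reference_sperm(qc)
        report["matrix"] = {
            **summary,
            "reference_sperm": ref_id,
            "mismatched_calls": matrix.mismatch_count,
        }
        io.write_matrix_tsv(matrix, outdir / "matrix.tsv")
        qc.to_csv(outdir / "sperm_qc.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("matrix", exc) from exc

    try:
        bin_map, markers, correction, marker_report = phasing.phase_pipeline(
            matrix,
            ref_id,
            window=cfg.window,
            min_support=cfg.min_support,
            consensus_fraction=cfg.consensus_fraction,
            tolerance_bp=cfg.tolerance_bp,
            min_population=cfg.min_population,
            interval_bp=cfg.interval_bp,
            min_event_spacing_bp=cfg.min_event_spacing_bp,
            min_marker_confidence=cfg.min_marker_confidence,
        )
        counts, mean_xo = phasing.count_crossovers(bin_map)
        report["phase"] = {
            **marker_report,
            "n_bins": bin_map.n_bins,
            "n_reference_crossovers": sum(len(v) for v in correction.reference_positions.values()),
            "mean_crossovers_per_sperm": mean_xo,
        }
        io.write_bin_map(bin_map, outdir / "binmap")
        io.write_markers(markers, outdir / "markers.tsv")
        counts.to_csv(outdir / "crossover_counts.tsv", sep="\t")
    except Exception as exc:
        raise StageError("phase", exc) from exc

    try:
        gmap = geneticmap.build_genetic_map(bin_map)
        gmap.to_csv(outdir / "genetic_map.tsv", sep="\t", index=False)
        summary_df = geneticmap.map_summary(gmap)
        summary_df.to_csv(outdir / "map_summary.tsv", sep="\t", index=False)
        report["map"] = {
            "total_cM": float(summary_df.iloc[-1]["length_cM"]),
            "n_bins": int(summary_df.iloc[-1]["n_bins"]),
        }
    except Exception as exc:
        raise StageError("map", exc) from exc

    if cfg.reads and cfg.reference_fasta:
        try:
            from .readbin import index_markers, partition_reads

            reference = io.read_reference_fasta(cfg.reference_fasta)
            probes = index_markers(markers, reference, flank_bp=cfg.flank_bp)
            g0, g1, table, part_report = partition_reads(
                io.read_seqs(cfg.reads), probes, min_margin=cfg.min_margin
            )
            table.to_csv(outdir / "read_assignments.tsv", sep="\t", index=False)
            report["partition"] = part_report
        except Exception as exc:
            raise StageError("partition", exc) from exc

    if cfg.phenotypes:
        try:
            pheno = pd.read_csv(cfg.phenotypes, sep="\t")
            cof = qtl.select_cofactors(bin_map, pheno, max_cofactors=cfg.max_cofactors)
            scan = qtl.interval_scan(
                bin_map, gmap, pheno,
                walk_cM=cfg.walk_cm, window_cM=cfg.window_cm,
                cofactors=cof, threshold=cfg.lod_threshold,
            )
            scan.positions.to_csv(outdir / "qtl_scan.tsv", sep="\t", index=False)
            scan.intervals.to_csv(outdir / "qtl_intervals.tsv", sep="\t", index=False)
            peak = scan.peak
            report["qtl"] = {
                "n_intervals": len(scan.intervals),
                "peak_lod": float(peak["lod"]) if peak is not None else None,
                "cofactors": [bin_map.bins["bin_id"].iat[b] for b in cof],
            }
        except Exception as exc:
            raise StageError("qtl", exc) from exc

    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
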