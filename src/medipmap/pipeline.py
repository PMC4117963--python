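"""End-to-end report assembly: simulate (or load) inputs, then run CGI
scanning, peak annotation, density, metaprofile, CGI summary, DMR calling,
TSS clustering and chromosome correlation, writing TSVs plus a manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cgi import scan_cgi
from .cluster import build_tss_matrix, correlate_chromosome_stats, kmeans_profiles
from .density import (
    annotate_peaks,
    cgi_methylation_summary,
    gene_body_profile,
    methylation_density,
)
from .dmr import call_dmrs, dmrs_to_bed, records_to_frame, significant, summarize_dmrs
from .genemodel import derive_features
from .io import read_bed, read_fasta, read_gff, write_bed
from .qc import filter_fastq_pair
from .simulate import SimConfig, simulate_study


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full analysis described by ``config``; returns the
    manifest (also written to ``outdir/manifest.json``).

    Config keys: ``simulate`` (SimConfig fields; presence triggers
    simulation), ``inputs`` (paths: genome, genes, repeats, peaks_a,
    peaks_b, reads_a, reads_b, fastq pairs), ``qc`` (enabled flag +
    thresholds), ``cgi``, ``annotate``, ``dmr`` (alpha, min_fold),
    ``cluster`` (k, seed, window, bin_width).  Every stage logs counts
    in/out into the manifest; any failure aborts with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": config,
        "stages": [],
        "inputs": {},
    }
    stages = manifest["stages"]

    def stage(name: str, **info):
        stages.append({"name": name, **info})

    current = "setup"
    try:
        if "simulate" in config:
            current = "simulate"
            sim_cfg = SimConfig(seed=seed, **(config.get("simulate") or {}))
            simdir = outdir / "sim"
            truth = simulate_study(sim_cfg, simdir)
            inputs = {
                "genome": simdir / "genome.fa",
                "genes": simdir / "genes.gff",
                "repeats": simdir / "repeats.bed",
                "peaks_a": simdir / f"{sim_cfg.sample_names[0]}.peaks.bed",
                "peaks_b": simdir / f"{sim_cfg.sample_names[1]}.peaks.bed",
                "reads_a": simdir / f"{sim_cfg.sample_names[0]}.reads.bed",
                "reads_b": simdir / f"{sim_cfg.sample_names[1]}.reads.bed",
            }
            stage("simulate", n_cgis=len(truth.cgis), n_dmrs_planted=len(truth.dmrs))
        else:
            inputs = {k: Path(v) for k, v in config["inputs"].items()}

        manifest["inputs"] = {k: _sha256(Path(v)) for k, v in inputs.items()}

        if config.get("qc", {}).get("enabled"):
            current = "qc"
            rep = filter_fastq_pair(
                inputs["fastq_1"], inputs["fastq_2"], outdir / "qc"
            )
            stage("qc", total=rep.total_pairs, kept=rep.kept_pairs)

        current = "load"
        genome = read_fasta(inputs["genome"])
        genes = read_gff(inputs["genes"])
        repeats = read_bed(inputs["repeats"], genome.index)
        peaks_a = read_bed(inputs["peaks_a"], genome.index)
        peaks_b = read_bed(inputs["peaks_b"], genome.index)
        reads_a = read_bed(inputs["reads_a"], genome.index)
        reads_b = read_bed(inputs["reads_b"], genome.index)
        annotation = derive_features(genes, genome.index, repeats=repeats)

        current = "cgi_scan"
        cgis = scan_cgi(genome)
        write_bed([c.interval for c in cgis], outdir / "cgi.bed")
        stage("cgi_scan", n_islands=len(cgis))

        current = "annotate"
        _, row = annotate_peaks(peaks_a, annotation)
        row.to_frame().T.to_csv(outdir / "table1.tsv", sep="\t", index=False)
        stage("annotate", n_peaks=int(row["total_peaks"]))

        current = "density"
        prof = methylation_density(peaks_a, annotation)
        prof.to_series().round(6).to_frame("density").to_csv(
            outdir / "density.tsv", sep="\t"
        )
        stage("density", n_classes=len(prof.densities))

        current = "metaprofile"
        meta = gene_body_profile(peaks_a, genes)
        meta.to_frame().round(6).to_csv(outdir / "metaprofile.tsv", sep="\t", index=False)
        stage("metaprofile", n_genes=meta.n_genes, n_skipped=meta.n_skipped)

        current = "cgi_summary"
        summ = cgi_methylation_summary(cgis, peaks_a, annotation)
        summ.to_series().to_frame("value").to_csv(outdir / "table2.tsv", sep="\t")
        stage(
            "cgi_summary",
            methylated=summ.total_methylated,
            total=summ.total_cgis,
            percent=summ.percent_methylated,
        )

        current = "dmr"
        dmr_cfg = config.get("dmr", {})
        records = call_dmrs(
            peaks_a,
            peaks_b,
            reads_a,
            reads_b,
            alpha=float(dmr_cfg.get("alpha", 0.05)),
            min_fold=float(dmr_cfg.get("min_fold", 2.0)),
        )
        records_to_frame(records).round(6).to_csv(
            outdir / "dmr_full.tsv", sep="\t", index=False
        )
        write_bed(dmrs_to_bed(records), outdir / "dmr.bed")
        sig = significant(records)
        dmr_summary = summarize_dmrs(records, annotation)
        with open(outdir / "dmr_summary.json", "w") as fh:
            json.dump(dmr_summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        stage("dmr", n_tested=len(records), n_dmrs=len(sig))

        current = "cluster"
        cl_cfg = config.get("cluster", {})
        sig_ivs = [r.interval for r in sig] or [r.interval for r in records]
        matrix = build_tss_matrix(
            sig_ivs,
            genes,
            window=int(cl_cfg.get("window", 5000)),
            bin_width=int(cl_cfg.get("bin_width", 100)),
        )
        result = kmeans_profiles(
            matrix, k=int(cl_cfg.get("k", 5)), seed=int(cl_cfg.get("seed", seed))
        )
        result.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        stage("cluster", k=result.k, inertia=round(result.inertia, 6))

        current = "correlate"
        corr = correlate_chromosome_stats(peaks_a, genome.index, genes)
        with open(outdir / "correlation.json", "w") as fh:
            json.dump({k: round(v, 6) if isinstance(v, float) else v for k, v in corr.items()}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        stage("correlate", **{k: round(v, 4) if isinstance(v, float) else v for k, v in corr.items()})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
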