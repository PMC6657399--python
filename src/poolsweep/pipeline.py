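"""End-to-end pipeline: ingest -> QC -> scan -> region calling -> reports.

`run_pipeline` is deterministic for a fixed config and inputs: the region
report and BED output are byte-identical across reruns, and the JSON
manifest records the configuration, input checksums and per-stage counts
(no wall-clock fields, so it is reproducible too; timings go to the log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .region_calling import annotate_regions, filter_regions, merge_windows
from .snp_qc import QcConfig, run_qc
from .sweep_scan import ScanConfig, extract_outliers, scan
from .types import ContigSpec
from . import variant_io

log = logging.getLogger("poolsweep")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one scan run needs.

    Exactly one of ``sync_path`` / ``vcf_path`` must be set; ``groups`` maps
    VCF sample names to 'A' (selected) or 'B' (control).
    """

    out_dir: str
    sync_path: str | None = None
    vcf_path: str | None = None
    groups: dict = field(default_factory=dict)
    contig_lengths_path: str | None = None
    genes_path: str | None = None
    gene_name_attr: str = "Name"
    qc: QcConfig = field(default_factory=QcConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    max_gap: int = 0
    min_region_length: int = 0

    def __post_init__(self) -> None:
        if (self.sync_path is None) == (self.vcf_path is None):
            raise ValueError("set exactly one of sync_path / vcf_path")


def read_contig_lengths(path) -> list[ContigSpec]:
    """Read 'contig<TAB>length' lines (e.g. the first two .fai columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(ContigSpec(f[0], int(f[1])))
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    log.info("stage %s ...", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full scan and write all reports; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "poolsweep",
        "version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("qc", "scan")},
            "qc": asdict(config.qc),
            "scan": asdict(config.scan),
        },
        "inputs": {},
        "counts": {},
        "outputs": {},
    }

    t = _stage("ingest")
    try:
        if config.sync_path is not None:
            manifest["inputs"]["sync"] = _sha256(config.sync_path)
            sites, skip_log = variant_io.read_sync_counts(config.sync_path)
        else:
            manifest["inputs"]["vcf"] = _sha256(config.vcf_path)
            sites, skip_log = variant_io.read_vcf_counts(
                config.vcf_path, config.groups
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'ingest' failed: {exc}") from exc
    manifest["counts"]["sites_ingested"] = int(len(sites))
    manifest["counts"]["sites_skipped"] = dict(skip_log)
    log.info("ingest: %d sites (%.2fs)", len(sites), time.perf_counter() - t)

    t = _stage("qc")
    try:
        sites = sites.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
        sites, qc_report = run_qc(sites, config.qc)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'qc' failed: {exc}") from exc
    manifest["counts"]["qc"] = qc_report.to_dict()
    (out / "qc_report.txt").write_text(qc_report.to_text())
    manifest["outputs"]["qc_report"] = "qc_report.txt"
    log.info("qc: %d sites retained (%.2fs)", len(sites), time.perf_counter() - t)

    t = _stage("scan")
    try:
        contigs = None
        if config.contig_lengths_path is not None:
            manifest["inputs"]["contig_lengths"] = _sha256(config.contig_lengths_path)
            contigs = read_contig_lengths(config.contig_lengths_path)
        windows = scan(sites, config.scan, contigs=contigs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'scan' failed: {exc}") from exc
    variant_io.write_window_track(windows, out / "windows.tsv")
    variant_io.write_bedgraph(windows, "z_fst", out / "z_fst.bedgraph")
    variant_io.write_bedgraph(windows, "z_hp_ratio", out / "z_hp_ratio.bedgraph")
    manifest["outputs"]["windows"] = "windows.tsv"
    manifest["counts"]["windows_total"] = int(len(windows))
    manifest["counts"]["windows_retained"] = int((~windows["discarded"]).sum()) if len(windows) else 0
    log.info("scan: %d windows (%.2fs)", len(windows), time.perf_counter() - t)

    t = _stage("call-regions")
    try:
        outliers = extract_outliers(windows, config.scan.z_cutoff)
        regions = merge_windows(outliers, config.max_gap) if len(outliers) else []
        regions = filter_regions(regions, config.min_region_length)
        if config.genes_path is not None:
            manifest["inputs"]["genes"] = _sha256(config.genes_path)
            genes = variant_io.read_gene_intervals(
                config.genes_path, config.gene_name_attr
            )
            regions = annotate_regions(regions, genes)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'call-regions' failed: {exc}") from exc
    variant_io.write_regions_bed(regions, out / "regions.bed", out / "regions.tsv")
    manifest["outputs"]["regions_bed"] = "regions.bed"
    manifest["outputs"]["regions_report"] = "regions.tsv"
    manifest["counts"]["outlier_windows"] = int(len(outliers))
    manifest["counts"]["regions"] = len(regions)
    log.info("call-regions: %d regions (%.2fs)", len(regions), time.perf_counter() - t)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
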