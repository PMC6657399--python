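"""Convenience drivers for simulation-based evaluation of the scan.

Used by the analysis scripts and the acceptance checks: run the in-memory
pipeline (simulate -> QC -> scan -> region calling) on one seeded
configuration and measure recovery of the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .region_calling import filter_regions, merge_windows
from .snp_qc import QcConfig, QcReport, run_qc
from .sweep_scan import ScanConfig, extract_outliers, scan
from .synthetic import SimConfig, simulate_sites
from .types import SweepRegion, SweepTruth


@dataclass
class SimCallResult:
    sites: pd.DataFrame
    qc_sites: pd.DataFrame
    qc_report: QcReport
    windows: pd.DataFrame
    outliers: pd.DataFrame
    regions: list[SweepRegion]
    truth: list[SweepTruth]


def simulate_and_call(
    sim_config: SimConfig,
    qc_config: QcConfig = QcConfig(),
    scan_config: ScanConfig = ScanConfig(),
    max_gap: int = 0,
    min_region_length: int = 0,
) -> SimCallResult:
    """Simulate one genome and run QC -> scan -> region calling in memory.

    The scan's haploid sample sizes are taken from the simulation config so
    the estimator correction matches the generating pools.
    """
    scan_config = replace(
        scan_config,
        haploids_a=sim_config.haploids_a,
        haploids_b=sim_config.haploids_b,
    )
    sites, truth = simulate_sites(sim_config)
    qc_sites, qc_report = run_qc(sites, qc_config)
    windows = scan(qc_sites, scan_config, contigs=list(sim_config.contigs))
    outliers = extract_outliers(windows, scan_config.z_cutoff)
    regions = merge_windows(outliers, max_gap) if len(outliers) else []
    regions = filter_regions(regions, min_region_length)
    return SimCallResult(sites, qc_sites, qc_report, windows, outliers, regions, truth)


def regions_overlapping_truth(
    regions: Sequence[SweepRegion], truth: Sequence[SweepTruth]
) -> list[SweepRegion]:
    """Regions overlapping any planted sweep interval by >= 1 bp."""
    return [
        r for r in regions
        if any(
            r.contig == t.contig and r.start <= t.end and t.start <= r.end
            for t in truth
        )
    ]


def recovery_rate(
    base_config: SimConfig, seeds: Sequence[int], **call_kwargs
) -> tuple[float, float]:
    """(recovery fraction, mean false-positive regions) across seeds.

    A seed counts as recovered when at least one called region overlaps a
    planted sweep; regions overlapping no truth interval count as false
    positives (for a null config every region is a false positive).
    """
    hits = 0
    fp_total = 0
    for seed in seeds:
        res = simulate_and_call(replace(base_config, seed=seed), **call_kwargs)
        on_truth = regions_overlapping_truth(res.regions, res.truth)
        if res.truth and on_truth:
            hits += 1
        fp_total += len(res.regions) - len(on_truth)
    frac = hits / len(seeds) if base_config.sweeps else float("nan")
    return frac, fp_total / len(seeds)
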