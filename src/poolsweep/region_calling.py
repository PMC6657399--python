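"""Merge dual-outlier windows into candidate sweep regions and annotate genes.

Overlapping-or-abutting outlier windows on the same contig merge into one
region (the 10-kb step makes contiguous signal overlap by construction);
``max_gap`` > 0 additionally bridges short gaps. Region bounds are the outer
edges of the member windows, and each region carries the maxima of the
member Z-scores. Genes are attached on >= 1 bp interval overlap.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .types import GeneInterval, SweepRegion


def merge_windows(outlier_windows: pd.DataFrame, max_gap: int = 0) -> list[SweepRegion]:
    """Merge sorted outlier windows into regions (1-based inclusive bounds)."""
    if len(outlier_windows) == 0:
        return []
    df = outlier_windows
    keys = list(zip(df["contig"], df["start"]))
    if keys != sorted(keys):
        raise ValueError("outlier windows must be sorted by (contig, start)")
    regions: list[SweepRegion] = []
    cur = None  # [contig, start, end, n, max_zfst, max_zhp]
    for row in df.itertuples(index=False):
        if cur is not None and row.contig == cur[0] and row.start <= cur[2] + 1 + max_gap:
            cur[2] = max(cur[2], row.end)
            cur[3] += 1
            cur[4] = max(cur[4], row.z_fst)
            cur[5] = max(cur[5], row.z_hp_ratio)
        else:
            if cur is not None:
                regions.append(SweepRegion(*cur[:3], cur[3], cur[4], cur[5]))
            cur = [row.contig, int(row.start), int(row.end), 1,
                   float(row.z_fst), float(row.z_hp_ratio)]
    regions.append(SweepRegion(*cur[:3], cur[3], cur[4], cur[5]))
    return regions


def annotate_regions(
    regions: Sequence[SweepRegion], gene_intervals: Iterable[GeneInterval]
) -> list[SweepRegion]:
    """Attach genes overlapping each region by >= 1 bp, sorted by position."""
    trees: dict[str, IntervalTree] = {}
    for g in gene_intervals:
        # intervaltree is half-open; [start, end] inclusive -> [start, end+1)
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end + 1, g)
    out = []
    warned: set[str] = set()
    for r in regions:
        tree = trees.get(r.contig)
        if tree is None:
            if r.contig not in warned:
                warnings.warn(
                    f"no gene intervals for contig {r.contig}; "
                    "region left unannotated"
                )
                warned.add(r.contig)
            genes: tuple[str, ...] = ()
        else:
            hits = sorted(tree.overlap(r.start, r.end + 1),
                          key=lambda iv: (iv.begin, iv.end))
            genes = tuple(iv.data.gene_name for iv in hits)
        out.append(SweepRegion(r.contig, r.start, r.end, r.n_windows,
                               r.max_z_fst, r.max_z_hp_ratio, genes))
    return out


def filter_regions(
    regions: Sequence[SweepRegion], min_length: int = 0
) -> list[SweepRegion]:
    """Keep regions whose length (end - start + 1) is >= min_length."""
    return [r for r in regions if r.length >= min_length]
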