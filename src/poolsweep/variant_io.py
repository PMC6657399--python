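"""Reading and writing pooled variant data and interval tracks.

Readers produce the per-site, per-group allele-count table the scan operates
on (see :mod:`poolsweep.types`). Two input routes are supported: VCF with
per-sample allele depths (``AD``), from which per-group counts are summed over
the samples assigned to each group, and a popoolation2-style "sync" table with
per-group colon-separated base counts. Writers emit BED, bedGraph and
tab-delimited region/window reports.

Internal coordinates are 1-based inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

import os
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import GeneInterval, SITE_COLUMNS, SweepRegion

SYNC_BASES = "ATCGN"  # sixth sync column is deletions


def read_vcf_counts(
    path: str | os.PathLike,
    group_assignment: Mapping[str, str],
) -> tuple[pd.DataFrame, Counter]:
    """Read biallelic SNPs from a VCF into per-group allele counts.

    Parameters
    ----------
    path
        VCF file with a per-sample ``AD`` (allelic depth) FORMAT field.
    group_assignment
        Maps every sample name in the file to ``"A"`` (selected group) or
        ``"B"`` (control group).

    Returns
    -------
    (sites, skip_log)
        Site table plus a counter of skipped records by reason
        (``multiallelic``, ``non_snp``, ``zero_group_depth``).

    Notes
    -----
    Major/minor orientation is decided once from the pooled (A+B) counts,
    ties resolved toward the reference allele. Sites with zero total depth
    in either group are dropped (both scan statistics are undefined there).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in group_assignment:
            raise ValueError(f"sample {s!r} in VCF has no group assignment")
    bad = {s: g for s, g in group_assignment.items() if g not in ("A", "B")}
    if bad:
        raise ValueError(f"group labels must be 'A' or 'B': {bad}")
    in_a = np.array([group_assignment[s] == "A" for s in samples])
    in_b = ~in_a

    rows: list[tuple] = []
    skip_log: Counter = Counter()
    for rec in vcf:
        if len(rec.ALT) != 1:
            skip_log["multiallelic"] += 1
            continue
        if not rec.is_snp:
            skip_log["non_snp"] += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} lacks the AD allele-depth field"
            )
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative sentinels
        a_ref, a_alt = int(ad[in_a, 0].sum()), int(ad[in_a, 1].sum())
        b_ref, b_alt = int(ad[in_b, 0].sum()), int(ad[in_b, 1].sum())
        if a_ref + a_alt == 0 or b_ref + b_alt == 0:
            skip_log["zero_group_depth"] += 1
            continue
        # orientation on pooled counts; tie goes to the reference allele
        if a_alt + b_alt > a_ref + b_ref:
            row = (rec.CHROM, rec.POS, rec.QUAL, a_alt, a_ref, b_alt, b_ref)
        else:
            row = (rec.CHROM, rec.POS, rec.QUAL, a_ref, a_alt, b_ref, b_alt)
        rows.append(row)
    return pd.DataFrame(rows, columns=SITE_COLUMNS), skip_log


def read_sync_counts(
    path: str | os.PathLike,
    *,
    max_third_allele_frac: float = 0.0,
    default_qual: float = 60.0,
) -> tuple[pd.DataFrame, Counter]:
    """Read a sync-style pool-seq count table into per-group allele counts.

    Expected columns (tab-delimited): contig, 1-based position, reference
    base, then one ``A:T:C:G:N:del`` count field per group (group A first,
    group B second). The two most frequent bases over both groups define the
    biallelic pair; monomorphic sites and sites where remaining bases exceed
    ``max_third_allele_frac`` of the total are skipped. Sync files carry no
    site quality, so ``default_qual`` is assigned.
    """
    rows: list[tuple] = []
    skip_log: Counter = Counter()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-delimited columns, "
                    f"got {len(fields)}"
                )
            contig, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                counts = [
                    [int(x) for x in col.split(":")] for col in fields[3:5]
                ]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed count field") from exc
            if any(len(c) != 6 for c in counts):
                raise ValueError(f"{path}:{lineno}: count fields need 6 values")
            ga, gb = (np.array(c[:5], dtype=np.int64) for c in counts)
            pooled = ga + gb
            if pooled.sum() == 0 or ga.sum() == 0 or gb.sum() == 0:
                skip_log["zero_group_depth"] += 1
                continue
            order = np.argsort(-pooled, kind="stable")
            top2 = [i for i in order[:2]]
            rest = int(pooled[order[2:]].sum())
            if pooled[top2[1]] == 0:
                skip_log["monomorphic"] += 1
                continue
            if rest > max_third_allele_frac * pooled.sum():
                skip_log["multiallelic"] += 1
                continue
            maj, mnr = top2
            # tie on pooled counts: prefer the reference base as major
            if pooled[maj] == pooled[mnr] and ref in SYNC_BASES:
                ref_i = SYNC_BASES.index(ref)
                if mnr == ref_i:
                    maj, mnr = mnr, maj
            rows.append(
                (contig, int(pos_s), default_qual,
                 int(ga[maj]), int(ga[mnr]), int(gb[maj]), int(gb[mnr]))
            )
    return pd.DataFrame(rows, columns=SITE_COLUMNS), skip_log


def write_sync_counts(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a site table as a two-group sync file.

    Base identities are not tracked internally, so the major allele is
    written as ``A`` (also the reference base) and the minor allele as ``C``.
    """
    with open(path, "w") as fh:
        for row in sites.itertuples(index=False):
            ga = f"{row.a_major}:0:{row.a_minor}:0:0:0"
            gb = f"{row.b_major}:0:{row.b_minor}:0:0:0"
            fh.write(f"{row.contig}\t{row.pos}\tA\t{ga}\t{gb}\n")


def _check_sorted_regions(regions: Sequence[SweepRegion]) -> None:
    keys = [(r.contig, r.start) for r in regions]
    if keys != sorted(keys):
        raise ValueError("regions must be sorted by (contig, start)")


def write_regions_bed(
    regions: Sequence[SweepRegion],
    path: str | os.PathLike,
    report_path: str | os.PathLike | None = None,
) -> None:
    """Write candidate regions as BED plus a tab-delimited region report.

    BED lines are 0-based half-open; the score column carries the region's
    max Z(FST) clipped to [0, 1000]. The companion report mirrors the shape
    of a published sweep-region table: Chr, Start, End (1-based inclusive),
    the two Z maxima, and the comma-joined candidate genes.
    """
    _check_sorted_regions(regions)
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            score = min(max(r.max_z_fst, 0.0), 1000.0)
            fh.write(
                f"{r.contig}\t{r.start - 1}\t{r.end}\tsweep_{i:03d}\t{score:g}\t.\n"
            )
    if report_path is not None:
        write_region_report(regions, report_path)


def write_region_report(
    regions: Sequence[SweepRegion], path: str | os.PathLike
) -> None:
    """Write the region report (1-based inclusive bounds)."""
    _check_sorted_regions(regions)
    with open(path, "w") as fh:
        fh.write("Chr\tStart\tEnd\tMax_Z_FST\tMax_Z_HP_ratio\tCandidate_genes\n")
        for r in regions:
            genes = ", ".join(r.genes)
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.max_z_fst:.6f}\t"
                f"{r.max_z_hp_ratio:.6f}\t{genes}\n"
            )


def read_regions_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read a BED file back to 1-based inclusive (contig, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out


def read_gene_intervals(
    path: str | os.PathLike, name_attr: str = "Name"
) -> list[GeneInterval]:
    """Read gene intervals from GFF3 or BED (chosen by file extension).

    GFF3: ``gene`` features only, gene name taken from the ``name_attr``
    attribute (falling back to ``ID``). BED: name column 4. Returned
    coordinates are 1-based inclusive.
    """
    import pyranges as pr

    p = str(path)
    if p.endswith((".gff", ".gff3")):
        df = pr.read_gff3(p).df
        df = df[df["Feature"] == "gene"]
        if name_attr in df.columns:
            names = df[name_attr].fillna(df.get("ID", pd.Series(index=df.index)))
        else:
            names = df["ID"]
    elif p.endswith(".bed"):
        df = pr.read_bed(p).df
        names = df["Name"] if "Name" in df.columns else df.index.astype(str)
    else:
        raise ValueError(f"unrecognised gene-interval format: {p}")
    out = [
        GeneInterval(str(c), int(s) + 1, int(e), str(n))
        for c, s, e, n in zip(df["Chromosome"], df["Start"], df["End"], names)
    ]
    out.sort(key=lambda g: (g.contig, g.start))
    return out


def write_window_track(windows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the per-window statistic track as tab-delimited text."""
    cols = [
        "contig", "start", "end", "n_sites", "hp_a", "hp_b",
        "ln_hp_ratio", "fst", "z_fst", "z_hp_ratio", "discarded",
    ]
    windows.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")


def write_bedgraph(
    windows: pd.DataFrame, stat: str, path: str | os.PathLike
) -> None:
    """Write one window statistic as bedGraph (0-based half-open)."""
    kept = windows[~windows["discarded"]]
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{stat}"\n')
        for row in kept.itertuples(index=False):
            val = getattr(row, stat)
            if pd.isna(val):
                continue
            fh.write(f"{row.contig}\t{row.start - 1}\t{row.end}\t{val:.6g}\n")
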