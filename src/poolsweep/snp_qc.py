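"""SNP retention filters for pooled variant calls.

Three filters, applied in a fixed order:

1. **quality** — drop sites whose Phred-scaled quality implies a sequencing
   error rate above ``max_error_rate`` (default 1%, i.e. qual < 20);
2. **spacing** — drop every member of any cluster of SNPs closer than
   ``min_spacing`` bp (default 5 bp); clustered calls signal local
   misalignment, so the whole cluster is removed by default;
3. **depth** — drop sites whose total read depth in either group falls
   outside [``depth_low_factor``, ``depth_high_factor``] times that group's
   mean depth (defaults 1/3 and 2, inclusive bounds).

The group mean depth for the depth filter is computed on the set that
survives the spacing filter, so the depth criterion never depends on sites
already rejected as artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import validate_sites


@dataclass(frozen=True)
class QcConfig:
    max_error_rate: float = 0.01
    min_spacing: int = 5
    depth_low_factor: float = 1.0 / 3.0
    depth_high_factor: float = 2.0
    spacing_mode: str = "remove_all"  # or "keep_first"
    missing_qual_policy: str = "drop"  # or "keep"

    def __post_init__(self) -> None:
        if not 0.0 < self.max_error_rate < 1.0:
            raise ValueError("max_error_rate must lie in (0, 1)")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be >= 0")
        if not 0.0 < self.depth_low_factor < self.depth_high_factor:
            raise ValueError("require 0 < depth_low_factor < depth_high_factor")


@dataclass
class QcReport:
    """Per-filter attribution of dropped sites (first failing filter wins)."""

    n_input: int = 0
    n_fail_quality: int = 0
    n_fail_spacing: int = 0
    n_fail_depth: int = 0
    n_retained: int = 0
    n_missing_qual: int = 0
    mean_depth_a: float = float("nan")
    mean_depth_b: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_fail_quality": self.n_fail_quality,
            "n_fail_spacing": self.n_fail_spacing,
            "n_fail_depth": self.n_fail_depth,
            "n_retained": self.n_retained,
            "n_missing_qual": self.n_missing_qual,
            "mean_depth_a": self.mean_depth_a,
            "mean_depth_b": self.mean_depth_b,
        }

    def to_text(self) -> str:
        d = self.to_dict()
        return "\n".join(f"{k}\t{v}" for k, v in d.items()) + "\n"


def _check_sorted(sites: pd.DataFrame) -> None:
    if len(sites) < 2:
        return
    contigs = sites["contig"].to_numpy()
    pos = sites["pos"].to_numpy()
    same = contigs[1:] == contigs[:-1]
    if (pos[1:][same] < pos[:-1][same]).any():
        raise ValueError("sites must be sorted by (contig, pos)")
    # contig blocks must be contiguous
    seen: set = set()
    last = None
    for c in contigs:
        if c != last:
            if c in seen:
                raise ValueError("sites must be sorted by (contig, pos)")
            seen.add(c)
            last = c


def filter_quality(
    sites: pd.DataFrame,
    max_error_rate: float = 0.01,
    missing_qual_policy: str = "drop",
) -> pd.DataFrame:
    """Retain sites with Phred error probability 10^(-qual/10) <= max_error_rate."""
    qual = sites["qual"].to_numpy(dtype=float)
    err = np.power(10.0, -qual / 10.0)
    keep = err <= max_error_rate
    missing = np.isnan(qual)
    keep[missing] = missing_qual_policy == "keep"
    return sites[keep]


def filter_spacing(
    sites: pd.DataFrame, min_spacing: int = 5, mode: str = "remove_all"
) -> pd.DataFrame:
    """Remove SNP clusters spaced closer than ``min_spacing`` bp.

    ``remove_all`` drops every member of a cluster (a site survives only if
    all same-contig neighbours are at distance >= min_spacing);
    ``keep_first`` greedily keeps the first member of each cluster.
    """
    _check_sorted(sites)
    if min_spacing == 0 or len(sites) < 2:
        return sites
    contigs = sites["contig"].to_numpy()
    pos = sites["pos"].to_numpy(dtype=np.int64)
    if mode == "remove_all":
        gap = np.diff(pos)
        close = (gap < min_spacing) & (contigs[1:] == contigs[:-1])
        keep = np.ones(len(sites), dtype=bool)
        keep[1:] &= ~close
        keep[:-1] &= ~close
        return sites[keep]
    if mode == "keep_first":
        keep = np.ones(len(sites), dtype=bool)
        last_kept = -np.inf
        last_contig = None
        for i, (c, p) in enumerate(zip(contigs, pos)):
            if c != last_contig:
                last_contig, last_kept = c, p
                continue
            if p - last_kept < min_spacing:
                keep[i] = False
            else:
                last_kept = p
        return sites[keep]
    raise ValueError(f"unknown spacing mode {mode!r}")


def group_depths(sites: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Total per-site read depth for group A and group B."""
    da = (sites["a_major"] + sites["a_minor"]).to_numpy(dtype=np.int64)
    db = (sites["b_major"] + sites["b_minor"]).to_numpy(dtype=np.int64)
    return da, db


def filter_depth(
    sites: pd.DataFrame,
    depth_low_factor: float = 1.0 / 3.0,
    depth_high_factor: float = 2.0,
) -> tuple[pd.DataFrame, float, float]:
    """Retain sites whose depth lies within factor bounds of the group mean.

    Mean depth is computed per group over the input sites; a site survives
    only if its depth satisfies the (inclusive) bounds in *both* groups.
    Returns the retained sites and the two group means.
    """
    if len(sites) == 0:
        raise ValueError("depth filter needs a non-empty site table")
    da, db = group_depths(sites)
    mean_a, mean_b = float(da.mean()), float(db.mean())
    keep = (
        (da >= depth_low_factor * mean_a) & (da <= depth_high_factor * mean_a)
        & (db >= depth_low_factor * mean_b) & (db <= depth_high_factor * mean_b)
    )
    return sites[keep], mean_a, mean_b


def run_qc(sites: pd.DataFrame, config: QcConfig = QcConfig()) -> tuple[pd.DataFrame, QcReport]:
    """Apply quality -> spacing -> depth filters and report attribution."""
    validate_sites(sites)
    _check_sorted(sites)
    report = QcReport(n_input=len(sites))
    report.n_missing_qual = int(sites["qual"].isna().sum())

    after_q = filter_quality(sites, config.max_error_rate, config.missing_qual_policy)
    report.n_fail_quality = len(sites) - len(after_q)

    after_s = filter_spacing(after_q, config.min_spacing, config.spacing_mode)
    report.n_fail_spacing = len(after_q) - len(after_s)

    after_d, mean_a, mean_b = filter_depth(
        after_s, config.depth_low_factor, config.depth_high_factor
    )
    report.n_fail_depth = len(after_s) - len(after_d)
    report.mean_depth_a, report.mean_depth_b = mean_a, mean_b
    report.n_retained = len(after_d)
    return after_d.reset_index(drop=True), report
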