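"""Core domain types for the pool-seq sweep scan.

Sites are carried as a pandas DataFrame with one row per biallelic SNP and
columns ``SITE_COLUMNS``; the :class:`SiteCounts` tuple exists for building
small inputs by hand. Coordinates are 1-based inclusive throughout; only the
BED writers convert to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import pandas as pd

#: Column order of a site table. a_* = selected group (group A), b_* = control
#: (group B); major/minor orientation is decided once on pooled (A+B) counts.
SITE_COLUMNS = ["contig", "pos", "qual", "a_major", "a_minor", "b_major", "b_minor"]


class SiteCounts(NamedTuple):
    """One biallelic site with per-group major/minor read counts."""

    contig: str
    pos: int
    qual: float
    a_major: int
    a_minor: int
    b_major: int
    b_minor: int


class ContigSpec(NamedTuple):
    """A contig name and its length in bp."""

    contig: str
    length: int


class GeneInterval(NamedTuple):
    """A gene with 1-based inclusive coordinates."""

    contig: str
    start: int
    end: int
    gene_name: str


def sites_frame(sites: Sequence[SiteCounts]) -> pd.DataFrame:
    """Build a site table from individual :class:`SiteCounts` records."""
    df = pd.DataFrame(list(sites), columns=SITE_COLUMNS)
    if len(df) == 0:
        df = pd.DataFrame({c: pd.Series(dtype="int64") for c in SITE_COLUMNS})
        df["contig"] = df["contig"].astype(str)
        df["qual"] = df["qual"].astype(float)
    return df


def validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    """Check a site table's schema and invariants; returns the table."""
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    if len(df):
        counts = df[["a_major", "a_minor", "b_major", "b_minor"]]
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative allele counts")
        if (df["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
    return df


@dataclass(frozen=True)
class SweepRegion:
    """A merged candidate sweep region with per-region Z maxima and genes."""

    contig: str
    start: int  # 1-based inclusive
    end: int
    n_windows: int
    max_z_fst: float
    max_z_hp_ratio: float
    genes: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SweepTruth:
    """Ground-truth planted sweep interval (simulator output)."""

    contig: str
    start: int
    end: int
    het_reduction: float = 0.1
    divergence_shift: float = 0.3

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("sweep start must be < end")
        if not 0.0 <= self.het_reduction <= 1.0:
            raise ValueError("het_reduction must lie in [0, 1]")


@dataclass
class QpcrSample:
    """One qPCR sample: replicate Ct values for target and reference genes."""

    sample_id: str
    group: str  # "selected" or "control"
    stage_mm: float  # fetal length in mm
    target_cts: list[float] = field(default_factory=list)
    reference_cts: list[float] = field(default_factory=list)


class FoldChange(NamedTuple):
    """Relative expression of one sample via 2^-ddCt."""

    sample_id: str
    delta_ct: float
    delta_delta_ct: float
    fold: float
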