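"""Windowed pooled-heterozygosity / FST genome scan.

The scan slides fixed-size windows (default 50 kb, 10-kb step) along each
contig and computes, per window and per group, the pooled heterozygosity

    HP = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))**2

where the sums of major/minor allele read counts run over the SNPs in the
window, together with a window FST aggregated as a ratio of per-site sums
(Hudson-type two-population estimator by default). The log HP ratio is
oriented control/selected, so positive values mean heterozygosity loss in
the selected group. Both window statistics are Z-transformed genome-wide and
windows exceeding the cutoff in *both* statistics (default Z > 5) are the
dual-outlier candidates passed to region merging.

Windows with fewer than ``min_sites`` informative SNPs (default 10) are
flagged ``discarded`` and excluded from the Z-transformation and from
outlier extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ContigSpec, validate_sites

WINDOW_COLUMNS = [
    "contig", "start", "end", "n_sites", "hp_a", "hp_b",
    "ln_hp_ratio", "fst", "z_fst", "z_hp_ratio", "discarded",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    haploids_a / haploids_b are the numbers of distinct chromosomes sampled
    per group (pool count x individuals per pool x ploidy); they enter the
    Hudson estimator's finite-sample correction. Defaults reflect 40 and 20
    pools of 10 diploid individuals.
    """

    window_size: int = 50_000
    step: int = 10_000
    min_sites: int = 10
    z_cutoff: float = 5.0
    hp_floor: float = 1e-4
    fst_estimator: str = "hudson"
    haploids_a: int = 800
    haploids_b: int = 400

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if self.z_cutoff <= 0 or self.hp_floor <= 0:
            raise ValueError("z_cutoff and hp_floor must be positive")
        if self.fst_estimator not in ("hudson", "wright_mean"):
            raise ValueError(f"unknown fst_estimator {self.fst_estimator!r}")


def pooled_heterozygosity(sites: pd.DataFrame, group: str) -> float:
    """Pooled heterozygosity 2ab/(a+b)^2 over the given sites for one group.

    ``a`` and ``b`` are the summed major and minor allele read counts.
    Returns NaN (undefined) when the group has no reads at all, which is
    distinct from the value 0 produced by fixation (b = 0 with a > 0).
    """
    if len(sites) == 0:
        raise ValueError("pooled heterozygosity needs at least one site")
    g = group.lower()
    if g not in ("a", "b"):
        raise ValueError("group must be 'A' or 'B'")
    a = float(sites[f"{g}_major"].sum())
    b = float(sites[f"{g}_minor"].sum())
    return _hp(np.array(a), np.array(b)).item()


def _hp(major_sum: np.ndarray, minor_sum: np.ndarray) -> np.ndarray:
    tot = major_sum + minor_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = 2.0 * major_sum * minor_sum / (tot * tot)
    return np.where(tot > 0, hp, np.nan)


def snp_fst(
    a_major, a_minor, b_major, b_minor,
    estimator: str = "hudson",
    haploids_a: int = 800,
    haploids_b: int = 400,
):
    """Per-site FST numerator and denominator (vectorised).

    Allele frequencies are read-count fractions of the minor allele. The
    default ``hudson`` estimator subtracts the finite-sample variance terms
    p_i(1-p_i)/(n_i - 1); per-site numerators may therefore be negative.
    ``wright_mean`` is the uncorrected variance-standardised form
    (p1-p2)^2 / (4 pbar (1-pbar)). Window values are meant to be formed as
    ratio of sums, never as means of per-site ratios.
    """
    a_major = np.asarray(a_major, dtype=float)
    a_minor = np.asarray(a_minor, dtype=float)
    b_major = np.asarray(b_major, dtype=float)
    b_minor = np.asarray(b_minor, dtype=float)
    da, db = a_major + a_minor, b_major + b_minor
    if (da == 0).any() or (db == 0).any():
        raise ValueError("snp_fst requires nonzero depth in both groups")
    p1 = a_minor / da
    p2 = b_minor / db
    if estimator == "hudson":
        if haploids_a <= 1 or haploids_b <= 1:
            raise ValueError("haploid sample sizes must exceed 1")
        # correction terms grouped so group relabelling is exactly symmetric
        num = (p1 - p2) ** 2 - (
            p1 * (1 - p1) / (haploids_a - 1) + p2 * (1 - p2) / (haploids_b - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    elif estimator == "wright_mean":
        pbar = 0.5 * (p1 + p2)
        num = (p1 - p2) ** 2
        den = 4.0 * pbar * (1.0 - pbar)
    else:
        raise ValueError(f"unknown fst estimator {estimator!r}")
    return num, den


def window_fst(
    sites: pd.DataFrame,
    estimator: str = "hudson",
    haploids_a: int = 800,
    haploids_b: int = 400,
) -> float:
    """Ratio-of-sums window FST; NaN when the summed denominator is zero."""
    if len(sites) == 0:
        raise ValueError("window_fst needs at least one site")
    num, den = snp_fst(
        sites["a_major"], sites["a_minor"], sites["b_major"], sites["b_minor"],
        estimator=estimator, haploids_a=haploids_a, haploids_b=haploids_b,
    )
    den_sum = float(np.sum(den))
    if den_sum == 0.0:
        return float("nan")
    return float(np.sum(num)) / den_sum


def make_windows(
    contigs: Sequence[ContigSpec], window_size: int, step: int
) -> pd.DataFrame:
    """Sliding window frames (1-based inclusive), fully inside each contig.

    Starts are 1, 1+step, ...; a window is emitted only if it fits entirely,
    giving floor((L - W)/S) + 1 windows for L >= W and none otherwise.
    """
    rows = []
    for contig, length in contigs:
        if length < window_size:
            continue
        starts = np.arange(1, length - window_size + 2, step, dtype=np.int64)
        for s in starts:
            rows.append((contig, int(s), int(s + window_size - 1)))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def z_transform(values) -> np.ndarray:
    """Standardise to mean 0 / sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("z_transform needs at least two values")
    if not np.isfinite(x).all():
        raise ValueError("z_transform requires finite values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("z_transform undefined for zero dispersion")
    return (x - x.mean()) / sd


def scan(
    sites: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
    contigs: Sequence[ContigSpec] | None = None,
) -> pd.DataFrame:
    """Compute the full window table with genome-wide Z-scores.

    ``sites`` must be QC-filtered and sorted by (contig, pos). When contig
    lengths are not supplied they are inferred from the largest observed
    position per contig. Window sums use prefix sums, so the result is
    bit-identical to recomputing every window from scratch.
    """
    validate_sites(sites)
    if contigs is None:
        lengths = sites.groupby("contig", sort=True)["pos"].max()
        contigs = [ContigSpec(str(c), int(l)) for c, l in lengths.items()]
    frames = make_windows(contigs, config.window_size, config.step)
    if len(frames) == 0:
        return pd.DataFrame(columns=WINDOW_COLUMNS)

    out_parts = []
    by_contig = dict(tuple(sites.groupby("contig", sort=False)))
    for contig, fr in frames.groupby("contig", sort=False):
        sub = by_contig.get(contig)
        starts = fr["start"].to_numpy()
        ends = fr["end"].to_numpy()
        n = len(fr)
        if sub is None or len(sub) == 0:
            part = pd.DataFrame({
                "contig": contig, "start": starts, "end": ends,
                "n_sites": np.zeros(n, dtype=int),
                "hp_a": np.nan, "hp_b": np.nan,
                "ln_hp_ratio": np.nan, "fst": np.nan,
            })
            out_parts.append(part)
            continue
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if (np.diff(pos) < 0).any():
            raise ValueError("sites must be sorted by position within contig")
        cols = {}
        for c in ("a_major", "a_minor", "b_major", "b_minor"):
            cols[c] = np.concatenate(
                [[0], np.cumsum(sub[c].to_numpy(dtype=np.int64))]
            )
        num, den = snp_fst(
            sub["a_major"], sub["a_minor"], sub["b_major"], sub["b_minor"],
            estimator=config.fst_estimator,
            haploids_a=config.haploids_a, haploids_b=config.haploids_b,
        )
        cnum = np.concatenate([[0.0], np.cumsum(num)])
        cden = np.concatenate([[0.0], np.cumsum(den)])

        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="right")
        n_sites = (i1 - i0).astype(int)

        def wsum(pref):
            return pref[i1] - pref[i0]

        hp_a = _hp(wsum(cols["a_major"]).astype(float),
                   wsum(cols["a_minor"]).astype(float))
        hp_b = _hp(wsum(cols["b_major"]).astype(float),
                   wsum(cols["b_minor"]).astype(float))
        wden = wsum(cden)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(wden != 0.0, wsum(cnum) / wden, np.nan)
            # difference of logs, so swapping the groups negates it exactly
            ln_ratio = np.log(np.maximum(hp_b, config.hp_floor)) - np.log(
                np.maximum(hp_a, config.hp_floor)
            )
        empty = n_sites == 0
        hp_a[empty] = np.nan
        hp_b[empty] = np.nan
        ln_ratio[empty] = np.nan
        fst = np.where(empty, np.nan, fst)
        out_parts.append(pd.DataFrame({
            "contig": contig, "start": starts, "end": ends,
            "n_sites": n_sites, "hp_a": hp_a, "hp_b": hp_b,
            "ln_hp_ratio": ln_ratio, "fst": fst,
        }))

    win = pd.concat(out_parts, ignore_index=True)
    win["discarded"] = win["n_sites"] < config.min_sites
    win["z_fst"] = np.nan
    win["z_hp_ratio"] = np.nan
    usable = (
        ~win["discarded"]
        & np.isfinite(win["fst"])
        & np.isfinite(win["ln_hp_ratio"])
    )
    if usable.sum() >= 2:
        if win.loc[usable, "fst"].std(ddof=1) > 0:
            win.loc[usable, "z_fst"] = z_transform(win.loc[usable, "fst"])
        if win.loc[usable, "ln_hp_ratio"].std(ddof=1) > 0:
            win.loc[usable, "z_hp_ratio"] = z_transform(
                win.loc[usable, "ln_hp_ratio"]
            )
    return win[WINDOW_COLUMNS]


def extract_outliers(windows: pd.DataFrame, z_cutoff: float = 5.0) -> pd.DataFrame:
    """Dual-outlier windows: z_fst > cutoff AND z_hp_ratio > cutoff (strict)."""
    mask = (
        ~windows["discarded"]
        & (windows["z_fst"] > z_cutoff)
        & (windows["z_hp_ratio"] > z_cutoff)
    )
    return windows[mask].reset_index(drop=True)
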