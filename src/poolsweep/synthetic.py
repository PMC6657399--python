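"""Synthetic pool-seq and qPCR data with planted ground truth.

The site simulator emulates two-group pooled sequencing of a diploid
population: SNP positions follow a Poisson process, background minor-allele
frequencies come from a symmetric Beta spectrum, the two groups' frequencies
are logit-jittered copies of the ancestral value (shared drift), and read
counts arise from a two-level binomial — first the finite pool of
chromosomes actually sequenced (40 x 10 diploids for the selected group,
20 x 10 for the control, by default), then Poisson read depth and binomial
allele sampling. The two-level scheme reproduces the extra count correlation
that finite pools impose on real pool-seq data.

Inside a planted sweep the selected group's frequency is pushed toward the
nearer boundary so its expected per-site heterozygosity is scaled by
``het_reduction``, and the control group's frequency is displaced by
``divergence_shift`` toward the opposite boundary, increasing between-group
differentiation without disturbing the calibrated heterozygosity loss.

Sites that come out monomorphic in the sampled reads, or with zero depth in
either group, are not emitted (a variant caller would not report them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ContigSpec, QpcrSample, SITE_COLUMNS, SweepTruth

_FREQ_EPS = 1e-3  # keep frequencies inside (0, 1) for the logit jitter


@dataclass(frozen=True)
class SimConfig:
    """Pool-seq simulation parameters (defaults mirror the study design:
    ~25x mean depth per group, 800 vs 400 pooled chromosomes)."""

    contigs: tuple[ContigSpec, ...] = (ContigSpec("chr1", 10_000_000),)
    snp_rate: float = 1.0 / 500.0
    depth_a: float = 25.0
    depth_b: float = 25.0
    haploids_a: int = 800
    haploids_b: int = 400
    sfs_shape: float = 0.2
    drift_sd: float = 0.2
    sweeps: tuple[SweepTruth, ...] = ()
    qual_mean: float = 40.0
    qual_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_a <= 0 or self.depth_b <= 0 or self.snp_rate <= 0:
            raise ValueError("depths and snp_rate must be positive")
        lengths = {c.contig: c.length for c in self.contigs}
        by_contig: dict[str, list[SweepTruth]] = {}
        for sw in self.sweeps:
            if sw.contig not in lengths:
                raise ValueError(f"sweep on unknown contig {sw.contig!r}")
            if not (1 <= sw.start and sw.end <= lengths[sw.contig]):
                raise ValueError(f"sweep {sw} outside contig bounds")
            by_contig.setdefault(sw.contig, []).append(sw)
        for sws in by_contig.values():
            sws = sorted(sws, key=lambda s: s.start)
            for prev, nxt in zip(sws, sws[1:]):
                if nxt.start <= prev.end:
                    raise ValueError("sweep intervals must not overlap")


def _scale_het(p: np.ndarray, factor: float) -> np.ndarray:
    """Push p toward its nearer boundary so p'(1-p') = factor * p(1-p)."""
    c = factor * p * (1.0 - p)
    disc = np.sqrt(np.maximum(0.0, 1.0 - 4.0 * c))
    low = (1.0 - disc) / 2.0
    high = (1.0 + disc) / 2.0
    return np.where(p <= 0.5, low, high)


def simulate_sites(config: SimConfig) -> tuple[pd.DataFrame, list[SweepTruth]]:
    """Simulate the two-group site table plus the ground-truth sweep list.

    Deterministic for a fixed config (per-contig substreams are spawned from
    the single seed, so adding a contig never perturbs earlier ones).
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.contigs))
    parts = []
    for (contig, length), ss in zip(config.contigs, streams):
        rng = np.random.default_rng(ss)
        n = rng.poisson(length * config.snp_rate)
        if n == 0:
            continue
        pos = np.unique(rng.integers(1, length + 1, size=n))
        m = len(pos)
        p_anc = np.clip(
            rng.beta(config.sfs_shape, config.sfs_shape, size=m),
            _FREQ_EPS, 1.0 - _FREQ_EPS,
        )
        logit = np.log(p_anc / (1.0 - p_anc))
        pa = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0.0, config.drift_sd, m))))
        pb = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0.0, config.drift_sd, m))))

        for sw in (s for s in config.sweeps if s.contig == contig):
            mask = (pos >= sw.start) & (pos <= sw.end)
            if not mask.any():
                continue
            target = _scale_het(pa[mask], sw.het_reduction)
            pa[mask] = target
            # control displaced toward the opposite boundary: the control
            # pool keeps the non-swept allele, raising differentiation
            away = np.where(pa[mask] <= 0.5, 1.0, -1.0)
            pb[mask] = np.clip(
                pb[mask] + away * sw.divergence_shift, _FREQ_EPS, 1.0 - _FREQ_EPS
            )

        rows = {}
        for tag, p, hap, depth in (
            ("a", pa, config.haploids_a, config.depth_a),
            ("b", pb, config.haploids_b, config.depth_b),
        ):
            pool_freq = rng.binomial(hap, p) / hap
            d = rng.poisson(depth, size=m)
            alt = rng.binomial(d, pool_freq)
            rows[f"{tag}_x"] = alt
            rows[f"{tag}_y"] = d - alt
        qual = np.maximum(0.0, rng.normal(config.qual_mean, config.qual_sd, m))

        # orient major/minor on pooled counts (tie -> the "reference" y allele)
        x_tot = rows["a_x"] + rows["b_x"]
        y_tot = rows["a_y"] + rows["b_y"]
        x_major = x_tot > y_tot
        part = pd.DataFrame({
            "contig": contig,
            "pos": pos.astype(np.int64),
            "qual": qual,
            "a_major": np.where(x_major, rows["a_x"], rows["a_y"]),
            "a_minor": np.where(x_major, rows["a_y"], rows["a_x"]),
            "b_major": np.where(x_major, rows["b_x"], rows["b_y"]),
            "b_minor": np.where(x_major, rows["b_y"], rows["b_x"]),
        })
        keep = (
            ((part["a_major"] + part["b_major"]) > 0)
            & ((part["a_minor"] + part["b_minor"]) > 0)
            & ((part["a_major"] + part["a_minor"]) > 0)
            & ((part["b_major"] + part["b_minor"]) > 0)
        )
        parts.append(part[keep])
    if parts:
        sites = pd.concat(parts, ignore_index=True)
    else:
        sites = pd.DataFrame(columns=SITE_COLUMNS)
    return sites, list(config.sweeps)


def write_truth_bed(sweeps, path) -> None:
    """Write planted sweep intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, sw in enumerate(sweeps, start=1):
            fh.write(f"{sw.contig}\t{sw.start - 1}\t{sw.end}\ttruth_{i:03d}\n")


def simulate_qpcr(
    n_stages: int = 5,
    stage_lengths_mm: list[float] | None = None,
    group_effect_dct: float = 1.5,
    stage_slope: float = 0.02,
    noise_sd: float = 0.15,
    seed: int = 0,
    *,
    n_samples_per_stage: int = 3,
    n_replicates: int = 3,
    sample_sd: float = 0.2,
    target_baseline: float = 24.0,
    reference_baseline: float = 18.0,
) -> list[QpcrSample]:
    """Simulate a two-group qPCR Ct table across fetal stages.

    Target Ct = target_baseline + stage_slope * stage_mm
    - group_effect_dct * [selected] + sample effect + replicate noise;
    the reference gene is flat at reference_baseline. A positive
    ``group_effect_dct`` therefore yields an expected selected/control fold
    ratio of 2**group_effect_dct, and a positive ``stage_slope`` (Ct rising,
    expression falling with fetal length) a negative fold-vs-stage rank
    correlation.
    """
    if n_stages < 2:
        raise ValueError("need at least two stages")
    if stage_lengths_mm is None:
        stage_lengths_mm = list(np.linspace(45.0, 210.0, n_stages))
    rng = np.random.default_rng(seed)
    samples = []
    for group in ("control", "selected"):
        effect = group_effect_dct if group == "selected" else 0.0
        for stage in stage_lengths_mm:
            for k in range(n_samples_per_stage):
                mu_t = (target_baseline + stage_slope * stage - effect
                        + rng.normal(0.0, sample_sd))
                mu_r = reference_baseline + rng.normal(0.0, sample_sd)
                samples.append(QpcrSample(
                    sample_id=f"{group[:3]}_{stage:g}mm_{k + 1}",
                    group=group,
                    stage_mm=float(stage),
                    target_cts=list(rng.normal(mu_t, noise_sd, n_replicates)),
                    reference_cts=list(rng.normal(mu_r, noise_sd, n_replicates)),
                ))
    return samples
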