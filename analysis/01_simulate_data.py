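#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/data/: a two-group pooled allele-count table (sync
format) for a 10-Mb genome carrying one 300-kb sweep in the selected group,
the matching null genome, the planted-truth BED, contig lengths, a synthetic
gene annotation (one gene deliberately inside the sweep), and a qPCR Ct
table with a log2 group effect of 1.5.
"""

from pathlib import Path

from poolsweep.expression import write_ct_csv
from poolsweep.synthetic import SimConfig, simulate_qpcr, simulate_sites, write_truth_bed
from poolsweep.types import ContigSpec, SweepTruth
from poolsweep.variant_io import write_sync_counts

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1

CONTIG = ContigSpec("chr1", 10_000_000)
SWEEP = SweepTruth("chr1", 5_000_001, 5_300_000,
                   het_reduction=0.1, divergence_shift=0.3)


def write_gene_bed(path: Path) -> None:
    """Synthetic gene annotation: 30-kb genes every 250 kb, plus one gene
    named SWEPT placed inside the planted sweep interval."""
    lines = []
    for i, start in enumerate(range(100_000, CONTIG.length - 30_000, 250_000), 1):
        name = f"gene_{i:03d}"
        if SWEEP.start <= start <= SWEEP.end - 30_000:
            name = f"SWEPT_{name}"
        lines.append(f"{CONTIG.contig}\t{start - 1}\t{start + 29_999}\t{name}\n")
    path.write_text("".join(lines))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    sweep_sites, truth = simulate_sites(
        SimConfig(contigs=(CONTIG,), sweeps=(SWEEP,), seed=SEED)
    )
    write_sync_counts(sweep_sites, OUT / "sweep_genome.sync")
    write_truth_bed(truth, OUT / "sweep_truth.bed")

    null_sites, _ = simulate_sites(SimConfig(contigs=(CONTIG,), seed=SEED))
    write_sync_counts(null_sites, OUT / "null_genome.sync")

    (OUT / "contigs.tsv").write_text(f"{CONTIG.contig}\t{CONTIG.length}\n")
    write_gene_bed(OUT / "genes.bed")

    qpcr = simulate_qpcr(group_effect_dct=1.5, seed=SEED)
    write_ct_csv(qpcr, OUT / "qpcr_ct.csv")

    print(f"sweep genome : {len(sweep_sites)} SNPs -> {OUT/'sweep_genome.sync'}")
    print(f"null genome  : {len(null_sites)} SNPs -> {OUT/'null_genome.sync'}")
    print(f"qPCR table   : {len(qpcr)} samples  -> {OUT/'qpcr_ct.csv'}")
    print(f"planted sweep: {SWEEP.contig}:{SWEEP.start}-{SWEEP.end} "
          f"(het_reduction={SWEEP.het_reduction}, shift={SWEEP.divergence_shift})")


if __name__ == "__main__":
    main()
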