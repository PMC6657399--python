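#!/usr/bin/env python
"""2^-ddCt analysis of the simulated qPCR table from 01_simulate_data.

Compares target-gene expression between the selected and control groups
across fetal stages, reports the per-stage fold ratios, the Welch test on
dCt, and the fold-vs-stage rank correlation. Writes results/expression/.
"""

import json
from pathlib import Path

from poolsweep.expression import group_comparison, read_ct_csv

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "expression"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    samples = read_ct_csv(ROOT / "data" / "qpcr_ct.csv")
    res = group_comparison(samples)

    res.per_sample.to_csv(OUT / "fold_per_sample.csv", index=False)
    res.per_stage.to_csv(OUT / "fold_per_stage.csv", index=False)
    summary = {
        "log2_fold_ratio": res.log2_fold_ratio,
        "log2_fold_ratio_se": res.log2_fold_ratio_se,
        "fold_ratio": 2.0 ** res.log2_fold_ratio,
        "p_value": res.p_value,
        "spearman_rho": res.spearman_rho,
        "spearman_p": res.spearman_p,
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(res.per_stage.to_string(index=False))
    print(f"\nselected/control fold ratio: {2 ** res.log2_fold_ratio:.2f} "
          f"(log2 = {res.log2_fold_ratio:.3f} +/- {res.log2_fold_ratio_se:.3f}), "
          f"Welch p = {res.p_value:.2e}")
    print(f"fold vs fetal length: Spearman rho = {res.spearman_rho:.2f} "
          f"(p = {res.spearman_p:.2e})")


if __name__ == "__main__":
    main()
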