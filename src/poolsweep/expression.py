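"""Relative qPCR expression via the 2^-ddCt method.

Each sample carries replicate Ct values for a target gene and a reference
(housekeeping) gene; dCt = mean target Ct - mean reference Ct, ddCt is taken
against a calibrator sample, and fold change = 2^-ddCt. Ratios of fold
changes between groups are calibrator-invariant, so the calibrator only
anchors the absolute scale; by default it is the control group at the
earliest fetal stage.

The between-group test is a two-sided Welch t-test on dCt values (the
approximately normal scale); the stage association is a Spearman rank
correlation of fold change against fetal length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import FoldChange, QpcrSample

SELECTED, CONTROL = "selected", "control"


def read_ct_csv(
    path, target_gene: str = "target", reference_gene: str = "reference"
) -> list[QpcrSample]:
    """Read a tidy Ct table (sample_id, group, stage_mm, gene, ct)."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "stage_mm", "gene", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    samples: dict[str, QpcrSample] = {}
    for row in df.itertuples(index=False):
        s = samples.setdefault(
            str(row.sample_id),
            QpcrSample(str(row.sample_id), str(row.group), float(row.stage_mm)),
        )
        if row.gene == target_gene:
            s.target_cts.append(float(row.ct))
        elif row.gene == reference_gene:
            s.reference_cts.append(float(row.ct))
    return list(samples.values())


def write_ct_csv(samples: Sequence[QpcrSample], path) -> None:
    rows = []
    for s in samples:
        for gene, cts in (("target", s.target_cts), ("reference", s.reference_cts)):
            rows.extend(
                (s.sample_id, s.group, s.stage_mm, gene, ct) for ct in cts
            )
    pd.DataFrame(
        rows, columns=["sample_id", "group", "stage_mm", "gene", "ct"]
    ).to_csv(path, index=False)


def delta_ct(sample: QpcrSample) -> float:
    """dCt = mean(target Ct) - mean(reference Ct)."""
    if not sample.target_cts or not sample.reference_cts:
        raise ValueError(f"sample {sample.sample_id}: missing Ct replicates")
    return fmean(sample.target_cts) - fmean(sample.reference_cts)


def fold_change(sample: QpcrSample, calibrator_delta_ct: float) -> FoldChange:
    """ddCt against the calibrator and fold = 2^-ddCt."""
    dct = delta_ct(sample)
    ddct = dct - calibrator_delta_ct
    return FoldChange(sample.sample_id, dct, ddct, 2.0 ** (-ddct))


def calibrator_delta_ct(samples: Sequence[QpcrSample]) -> float:
    """Mean dCt of the control-group samples at the earliest stage."""
    controls = [s for s in samples if s.group == CONTROL]
    if not controls:
        raise ValueError("no control-group samples to calibrate against")
    stage0 = min(s.stage_mm for s in controls)
    return fmean(delta_ct(s) for s in controls if s.stage_mm == stage0)


@dataclass
class GroupComparison:
    """Per-stage fold ratios plus the overall group test and stage trend."""

    per_stage: pd.DataFrame  # stage_mm, n_selected, n_control, fold_*, fold_ratio
    per_sample: pd.DataFrame  # sample_id, group, stage_mm, dct, ddct, fold
    calibrator_dct: float
    log2_fold_ratio: float  # control mean dCt - selected mean dCt
    log2_fold_ratio_se: float
    p_value: float  # two-sided Welch t-test on dCt
    spearman_rho: float  # fold vs stage, both groups pooled
    spearman_p: float


def group_comparison(samples: Sequence[QpcrSample]) -> GroupComparison:
    """Compare target expression between groups across matched stages.

    Stages present in only one group are excluded (with a warning) from the
    per-stage table and from the group test. The headline effect size is the
    log2 fold ratio selected/control, estimated as the difference of group
    mean dCt values (equivalently the log2 of the ratio of geometric-mean
    fold changes, calibrator-invariant).
    """
    groups = {s.group for s in samples}
    if not {SELECTED, CONTROL} <= groups:
        raise ValueError("need samples from both 'selected' and 'control' groups")
    cal = calibrator_delta_ct(samples)
    per_sample = pd.DataFrame(
        [
            (s.sample_id, s.group, s.stage_mm, *fold_change(s, cal)[1:])
            for s in samples
        ],
        columns=["sample_id", "group", "stage_mm", "dct", "ddct", "fold"],
    )
    stages_sel = set(per_sample.loc[per_sample["group"] == SELECTED, "stage_mm"])
    stages_ctl = set(per_sample.loc[per_sample["group"] == CONTROL, "stage_mm"])
    unmatched = stages_sel ^ stages_ctl
    if unmatched:
        warnings.warn(f"stages present in only one group excluded: {sorted(unmatched)}")
    matched = stages_sel & stages_ctl
    ps = per_sample[per_sample["stage_mm"].isin(matched)]

    rows = []
    for stage in sorted(matched):
        sel = ps[(ps["stage_mm"] == stage) & (ps["group"] == SELECTED)]
        ctl = ps[(ps["stage_mm"] == stage) & (ps["group"] == CONTROL)]
        # geometric-mean folds: 2^-mean(ddCt) per group
        fold_sel = 2.0 ** (-sel["ddct"].mean())
        fold_ctl = 2.0 ** (-ctl["ddct"].mean())
        rows.append(
            (stage, len(sel), len(ctl), fold_sel, fold_ctl, fold_sel / fold_ctl)
        )
    per_stage = pd.DataFrame(
        rows,
        columns=["stage_mm", "n_selected", "n_control",
                 "fold_selected", "fold_control", "fold_ratio"],
    )

    dct_sel = ps.loc[ps["group"] == SELECTED, "dct"].to_numpy()
    dct_ctl = ps.loc[ps["group"] == CONTROL, "dct"].to_numpy()
    log2_ratio = float(dct_ctl.mean() - dct_sel.mean())
    se = float(np.sqrt(
        dct_sel.var(ddof=1) / len(dct_sel) + dct_ctl.var(ddof=1) / len(dct_ctl)
    ))
    tt = stats.ttest_ind(dct_sel, dct_ctl, equal_var=False)
    rho, rho_p = stats.spearmanr(per_sample["fold"], per_sample["stage_mm"])
    return GroupComparison(
        per_stage=per_stage,
        per_sample=per_sample,
        calibrator_dct=cal,
        log2_fold_ratio=log2_ratio,
        log2_fold_ratio_se=se,
        p_value=float(tt.pvalue),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
    )
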