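"""Per-intron case/control comparison of splicing ratios: fold changes,
exact Mann-Whitney p-values, volcano classification, and dual-regulation
summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import CASE, CONTROL, mann_whitney_exact_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "differential_test",
    "classify",
    "volcano_table",
    "DualRegulationSummary",
    "dual_regulation_summary",
    "FOLD_CHANGE_THRESHOLD",
    "P_THRESHOLD",
]

# |log2 fold change| >= 1 and p <= 0.05 define the up/down classes.
FOLD_CHANGE_THRESHOLD = 2.0
P_THRESHOLD = 0.05


def classify(fold_change: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Volcano class per intron: 'up', 'down' or 'ns'.

    Pure function of (fold_change, p): up iff fc >= 2 and p <= 0.05,
    down iff fc <= 0.5 and p <= 0.05.
    """
    fold_change = np.asarray(fold_change, dtype=float)
    p = np.asarray(p, dtype=float)
    cls = np.full(fold_change.shape, "ns", dtype=object)
    sig = p <= P_THRESHOLD
    cls[sig & (fold_change >= FOLD_CHANGE_THRESHOLD)] = "up"
    cls[sig & (fold_change <= 1.0 / FOLD_CHANGE_THRESHOLD)] = "down"
    return cls


def differential_test(
    ratios: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Compare per-intron splicing ratios between case and control.

    ``ratios`` is a long table with columns sample_id, gene_id, ordinal,
    ratio. Introns lacking a defined ratio in any sample are excluded
    (logged), as are introns whose control mean is 0. Fold change is
    mean(case)/mean(control); p is the exact two-sided Mann-Whitney
    enumeration (normal approximation beyond the enumeration limit).
    """
    samples = sorted(set(ratios["sample_id"].astype(str)))
    case_samples = [s for s in samples if groups.get(s) == CASE]
    ctrl_samples = [s for s in samples if groups.get(s) == CONTROL]
    if not case_samples or not ctrl_samples:
        raise ValueError("both groups must contain at least one sample")

    wide = ratios.pivot_table(
        index=["gene_id", "ordinal"],
        columns="sample_id",
        values="ratio",
        aggfunc="first",
    )
    wide = wide.reindex(columns=case_samples + ctrl_samples)
    complete = wide.dropna()
    n_excluded = len(wide) - len(complete)
    if n_excluded:
        logger.info(
            "differential_test: excluded %d introns without ratios in all samples",
            n_excluded,
        )
    case_vals = complete[case_samples].to_numpy()
    ctrl_vals = complete[ctrl_samples].to_numpy()
    ctrl_mean = ctrl_vals.mean(axis=1)
    ok = ctrl_mean > 0
    n_zero_ctrl = int((~ok).sum())
    if n_zero_ctrl:
        logger.info(
            "differential_test: excluded %d introns with zero control mean",
            n_zero_ctrl,
        )
    complete = complete.loc[ok]
    case_vals = case_vals[ok]
    ctrl_vals = ctrl_vals[ok]
    ctrl_mean = ctrl_mean[ok]
    case_mean = case_vals.mean(axis=1)

    values = np.hstack([case_vals, ctrl_vals])
    mask = np.zeros(values.shape[1], dtype=bool)
    mask[: len(case_samples)] = True
    p = (
        mann_whitney_exact_matrix(values, mask)
        if len(values)
        else np.empty(0)
    )
    fc = case_mean / ctrl_mean
    out = pd.DataFrame(
        {
            "gene_id": complete.index.get_level_values("gene_id"),
            "ordinal": complete.index.get_level_values("ordinal"),
            "mean_case_ratio": case_mean,
            "mean_control_ratio": ctrl_mean,
            "fold_change": fc,
            "log2_fc": np.log2(fc, out=np.full_like(fc, -np.inf), where=fc > 0),
            "p": p,
        }
    ).reset_index(drop=True)
    out["class"] = classify(out["fold_change"].to_numpy(), out["p"].to_numpy())
    return out


def volcano_table(records: pd.DataFrame) -> dict:
    """Summary counts for the volcano screen."""
    up = records[records["class"] == "up"]
    down = records[records["class"] == "down"]
    return {
        "n_total": int(len(records)),
        "n_up": int(len(up)),
        "n_down": int(len(down)),
        "n_up_genes": int(up["gene_id"].nunique()),
        "n_down_genes": int(down["gene_id"].nunique()),
    }


@dataclass
class DualRegulationSummary:
    genes_with_up: frozenset
    genes_with_down: frozenset
    genes_with_both: frozenset
    first_intron_class: dict[str, str]
    first_intron_up_fraction: float | None
    first_intron_down_fraction: float | None


def dual_regulation_summary(records: pd.DataFrame) -> DualRegulationSummary:
    """Genes with up/down/both regulated introns and, among dual-
    regulated genes, the class of the first (ordinal 1) intron."""
    up_genes = frozenset(records.loc[records["class"] == "up", "gene_id"])
    down_genes = frozenset(records.loc[records["class"] == "down", "gene_id"])
    both = up_genes & down_genes

    first = records[records["ordinal"] == 1].set_index("gene_id")["class"]
    first_class = {g: first[g] for g in both if g in first.index}
    if first_class:
        n = len(first_class)
        up_frac = sum(c == "up" for c in first_class.values()) / n
        down_frac = sum(c == "down" for c in first_class.values()) / n
    else:
        up_frac = down_frac = None
    return DualRegulationSummary(
        up_genes, down_genes, both, first_class, up_frac, down_frac
    )
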