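"""Cohort-level descriptive statistics, clustering and group tests.

Works on a genes x samples value matrix (log2 IRI or expression RPKM)
with a case/control label per sample.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.special import comb

logger = logging.getLogger(__name__)

__all__ = [
    "CohortMatrix",
    "ZScoreMatrix",
    "zscore",
    "log2_iri_histogram",
    "pairwise_sample_correlation",
    "hierarchical_cluster",
    "linkage_to_newick",
    "mann_whitney_exact",
    "mann_whitney_exact_matrix",
    "group_mean_test",
    "fold_change_table",
    "fold_change_coupling",
    "CouplingResult",
]

CASE = "case"
CONTROL = "control"

# Above this many label assignments the exact null is abandoned for the
# tie-corrected normal approximation.
MAX_ENUMERATION = 500_000


@dataclass
class CohortMatrix:
    """Genes x samples value matrix with group labels.

    ``mode`` is ``"iri"`` (values are log2 IRI) or ``"expression"``
    (values are linear RPKM).
    """

    values: pd.DataFrame
    groups: dict[str, str]
    mode: str = "iri"
    detectable_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("iri", "expression"):
            raise ValueError(f"unknown mode {self.mode!r}")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        bad = {g for g in self.groups.values() if g not in (CASE, CONTROL)}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValueError("cohort matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.samples if self.groups[s] == CASE]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.samples if self.groups[s] == CONTROL]

    def linear_values(self) -> pd.DataFrame:
        """Values on the linear scale (2**V for iri mode)."""
        if self.mode == "iri":
            return np.exp2(self.values)
        return self.values


@dataclass
class ZScoreMatrix:
    """Row-standardized matrix; zero-variance rows are dropped and listed."""

    values: pd.DataFrame
    dropped: list[str]


def zscore(matrix: CohortMatrix) -> ZScoreMatrix:
    """Standardize each gene row: (V - mean) / sd, sd with ddof=1."""
    v = matrix.values
    mu = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = list(v.index[~keep])
    if dropped:
        logger.info("zscore: dropped %d zero-variance rows", len(dropped))
    z = v.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return ZScoreMatrix(z, dropped)


def log2_iri_histogram(
    matrix: CohortMatrix, bins: int | np.ndarray = 60
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Per-sample density histograms of log2 IRI plus mean/sd summary.

    Returns (densities, bin_edges, summary). Bin edges default to
    ``bins`` equal-width bins over the pooled value range; densities
    integrate to 1 per sample.
    """
    if matrix.mode != "iri":
        raise ValueError("histogram requires an iri-mode matrix")
    pooled = matrix.values.to_numpy().ravel()
    if np.unique(pooled).size < 2:
        raise ValueError("fewer than 2 distinct values; no histogram")
    if np.isscalar(bins):
        edges = np.linspace(pooled.min(), pooled.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    dens = {
        s: np.histogram(matrix.values[s], bins=edges, density=True)[0]
        for s in matrix.samples
    }
    densities = pd.DataFrame(dens)
    summary = pd.DataFrame(
        {
            "mean": matrix.values.mean(axis=0),
            "sd": matrix.values.std(axis=0, ddof=1),
            "group": pd.Series(matrix.groups),
        }
    ).loc[matrix.samples]
    return densities, edges, summary


def pairwise_sample_correlation(matrix: CohortMatrix) -> pd.DataFrame:
    """Pearson correlation between sample columns over the common genes.

    Constant columns get NaN rows/columns (diagonal kept at 1).
    """
    if matrix.n_genes < 3:
        raise ValueError("need at least 3 genes for sample correlation")
    v = matrix.values.to_numpy(dtype=float)
    sd = v.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(v, rowvar=False)
    const = sd == 0
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.samples, columns=matrix.samples)


def hierarchical_cluster(
    values: pd.DataFrame, axis: str = "samples"
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage agglomerative clustering on Euclidean distances.

    Returns (scipy linkage matrix, item labels). ``axis`` selects whether
    the columns ("samples") or rows ("genes") are clustered.
    """
    if axis == "samples":
        data = values.to_numpy(dtype=float).T
        labels = list(values.columns)
    elif axis == "genes":
        data = values.to_numpy(dtype=float)
        labels = list(values.index)
    else:
        raise ValueError(f"axis must be 'samples' or 'genes', got {axis!r}")
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    z = linkage(data, method="average", metric="euclidean")
    return z, labels


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    n = len(labels)
    nodes: dict[int, tuple[str, float]] = {
        i: (labels[i], 0.0) for i in range(n)
    }
    for k, (a, b, height, _cnt) in enumerate(z):
        sa, ha = nodes.pop(int(a))
        sb, hb = nodes.pop(int(b))
        branch_a = max(height - ha, 0.0)
        branch_b = max(height - hb, 0.0)
        nodes[n + k] = (
            f"({sa}:{branch_a:.6g},{sb}:{branch_b:.6g})",
            float(height),
        )
    (tree, _h), = nodes.values()
    return tree + ";"


# ---------------------------------------------------------------------------
# exact Mann-Whitney
# ---------------------------------------------------------------------------


def _rank_null(ranks: np.ndarray, n_pick: int) -> np.ndarray:
    """All rank-sum values for subsets of size ``n_pick`` (the exact/
    permutation null of the rank-sum statistic)."""
    idx = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(ranks.shape[0]), n_pick)
        ),
        dtype=np.intp,
    ).reshape(-1, n_pick)
    return ranks[idx].sum(axis=1)


def mann_whitney_exact(x, y) -> float:
    """Two-sided Mann-Whitney p-value via full enumeration of the
    rank-sum null over all group-label assignments.

    Mid-ranks are used for ties; two-sided p is twice the smaller tail
    probability, capped at 1. Falls back to the tie-corrected normal
    approximation when the assignment count exceeds ``MAX_ENUMERATION``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    n_small = min(x.size, y.size)
    if comb(pooled.size, n_small, exact=True) > MAX_ENUMERATION:
        return float(
            sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    ranks = sps.rankdata(pooled)
    small = ranks[: x.size] if x.size <= y.size else ranks[x.size:]
    t_obs = small.sum()
    null = _rank_null(ranks, n_small)
    eps = 1e-9
    p_lo = np.mean(null <= t_obs + eps)
    p_hi = np.mean(null >= t_obs - eps)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def mann_whitney_exact_matrix(
    values: np.ndarray, case_mask: np.ndarray
) -> np.ndarray:
    """Vectorized exact two-sided Mann-Whitney over many features.

    ``values`` is features x samples; ``case_mask`` flags the case
    columns. All features share the same label structure so the
    combination set is enumerated once.
    """
    values = np.asarray(values, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    n = values.shape[1]
    n_case = int(case_mask.sum())
    n_ctrl = n - n_case
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(values, axis=1)

    n_small = min(n_case, n_ctrl)
    if comb(n, n_small, exact=True) > MAX_ENUMERATION:
        res = sps.mannwhitneyu(
            values[:, case_mask],
            values[:, ~case_mask],
            alternative="two-sided",
            method="asymptotic",
            axis=1,
        )
        return np.asarray(res.pvalue, dtype=float)

    small_mask = case_mask if n_case <= n_ctrl else ~case_mask
    t_obs = ranks[:, small_mask].sum(axis=1)

    idx = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(n), n_small)
        ),
        dtype=np.intp,
    ).reshape(-1, n_small)
    onehot = np.zeros((idx.shape[0], n))
    onehot[np.arange(idx.shape[0])[:, None], idx] = 1.0
    null = onehot @ ranks.T  # n_comb x n_features

    eps = 1e-9
    p_lo = (null <= t_obs[None, :] + eps).mean(axis=0)
    p_hi = (null >= t_obs[None, :] - eps).mean(axis=0)
    p = 2.0 * np.minimum(p_lo, p_hi)
    p = np.minimum(p, 1.0)
    constant = np.ptp(values, axis=1) == 0
    p[constant] = 1.0
    return p


def group_mean_test(matrix: CohortMatrix) -> dict:
    """Exact two-sided Mann-Whitney on per-sample mean values,
    case vs control."""
    case = matrix.case_samples
    ctrl = matrix.control_samples
    if not case or not ctrl:
        raise ValueError("both groups must contain at least one sample")
    means = matrix.values.mean(axis=0)
    p = mann_whitney_exact(means[case].to_numpy(), means[ctrl].to_numpy())
    return {
        "p": p,
        "case_mean": float(means[case].mean()),
        "control_mean": float(means[ctrl].mean()),
        "n_case": len(case),
        "n_control": len(ctrl),
    }


# ---------------------------------------------------------------------------
# fold changes and their coupling
# ---------------------------------------------------------------------------


def fold_change_table(matrix: CohortMatrix) -> pd.DataFrame:
    """Per-gene fold change: mean(case linear values)/mean(control).

    Rows with non-positive control mean are dropped (logged).
    Returns columns ``fold_change`` and ``log2_fc``.
    """
    if not matrix.case_samples or not matrix.control_samples:
        raise ValueError("both groups required for fold changes")
    lin = matrix.linear_values()
    case_mean = lin[matrix.case_samples].mean(axis=1)
    ctrl_mean = lin[matrix.control_samples].mean(axis=1)
    ok = ctrl_mean > 0
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("fold_change_table: dropped %d genes with control mean <= 0", n_drop)
    fc = case_mean[ok] / ctrl_mean[ok]
    return pd.DataFrame({"fold_change": fc, "log2_fc": np.log2(fc)})


@dataclass
class CouplingResult:
    r: float
    p: float
    n: int
    bins: pd.DataFrame


def fold_change_coupling(
    iri_fc: pd.DataFrame, expr_fc: pd.DataFrame, n_bins: int = 10
) -> CouplingResult:
    """Pearson correlation of log2 fold changes (IRI vs expression) plus
    an equal-count bin summary along sorted IRI fold change.

    Bins are equal-count after sorting by IRI fold change; any remainder
    goes to the leftmost bins. Each bin reports the median/quartiles/
    whiskers of expression log2 FC and its mean IRI log2 FC.
    """
    joined = pd.DataFrame(
        {"iri": iri_fc["log2_fc"], "expr": expr_fc["log2_fc"]}
    ).dropna()
    n_dropped = max(len(iri_fc), len(expr_fc)) - len(joined)
    if n_dropped > 0:
        logger.info("fold_change_coupling: %d genes lacked both fold changes", n_dropped)
    if len(joined) < 3:
        raise ValueError("need >= 3 genes with both fold changes")
    r, p = sps.pearsonr(joined["iri"], joined["expr"])
    joined = joined.sort_values("iri", kind="mergesort")
    rows = []
    for b, pos in enumerate(np.array_split(np.arange(len(joined)), n_bins)):
        chunk = joined.iloc[pos]
        e = chunk["expr"].to_numpy()
        q1, med, q3 = np.percentile(e, [25, 50, 75])
        iqr = q3 - q1
        lo = e[e >= q1 - 1.5 * iqr].min()
        hi = e[e <= q3 + 1.5 * iqr].max()
        rows.append(
            {
                "bin": b + 1,
                "n": len(chunk),
                "mean_iri_log2_fc": chunk["iri"].mean(),
                "expr_median": med,
                "expr_q1": q1,
                "expr_q3": q3,
                "expr_whisker_lo": lo,
                "expr_whisker_hi": hi,
            }
        )
    return CouplingResult(float(r), float(p), len(joined), pd.DataFrame(rows))
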