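"""PCA over standardized cohort matrices, book-end gene selection on the
first component, and hypergeometric gene-set enrichment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "BookEndSelection",
    "pca",
    "orient_pc1",
    "select_book_ends",
    "hypergeom_enrichment",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class PCAResult:
    """Eigen-structure of the gene-gene covariance of a genes x samples
    matrix, obtained without materializing the N_g x N_g matrix.

    ``components`` holds orthonormal gene-coefficient vectors as columns
    (genes x k); ``projections`` are sample coordinates (samples x k);
    ``fractions`` are eigenvalue shares of the total variance.
    """

    eigenvalues: np.ndarray
    fractions: np.ndarray
    components: pd.DataFrame
    projections: pd.DataFrame
    pc1_flipped: bool = False


def pca(values: pd.DataFrame, center: bool = True) -> PCAResult:
    """Rank-limited eigendecomposition of the gene-gene covariance via
    SVD of the (row-centered) data matrix.

    Eigenvalues use the 1/(N_s - 1) normalization; fractions are computed
    over all nonzero eigenvalues. Raises on a zero-variance matrix.
    """
    x = values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples for PCA")
    xc = x - x.mean(axis=1, keepdims=True) if center else x
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n_samples - 1)
    total = eig.sum()
    if total <= 0:
        raise ValueError("zero-variance matrix")
    nonzero = eig > eig[0] * 1e-12
    k = int(nonzero.sum())
    eig = eig[:k]
    fractions = eig / eig.sum()
    comp_cols = [f"PC{i + 1}" for i in range(k)]
    components = pd.DataFrame(u[:, :k], index=values.index, columns=comp_cols)
    # sample coordinate on PC_k is P_k . x_s = s_k * v_ks
    projections = pd.DataFrame(
        (vt[:k].T * s[:k]), index=values.columns, columns=comp_cols
    )
    return PCAResult(eig, fractions, components, projections)


def orient_pc1(result: PCAResult) -> PCAResult:
    """Fix the PC1 sign convention so the majority of gene coefficients
    are positive. An exact 50/50 split keeps the sign (warned)."""
    c1 = result.components.iloc[:, 0].to_numpy()
    n_pos = int((c1 > 0).sum())
    n_neg = int((c1 < 0).sum())
    if n_pos == n_neg:
        logger.warning("orient_pc1: exact 50/50 sign split; keeping sign")
        return result
    if n_neg > n_pos:
        components = result.components.copy()
        projections = result.projections.copy()
        components.iloc[:, 0] *= -1
        projections.iloc[:, 0] *= -1
        return replace(
            result,
            components=components,
            projections=projections,
            pc1_flipped=True,
        )
    return result


@dataclass(frozen=True)
class BookEndSelection:
    negative_set: tuple[str, ...]
    positive_set: tuple[str, ...]
    n_neg: int
    n_pos: int


def select_book_ends(
    result: PCAResult, n_neg: int = 50, n_pos: int = 100
) -> BookEndSelection:
    """Genes with the most negative / most positive PC1 coefficients.

    Ties at either cutoff are broken by gene identifier order (logged).
    """
    c1 = result.components.iloc[:, 0]
    if len(c1) < n_neg + n_pos:
        raise ValueError(
            f"need >= {n_neg + n_pos} genes, have {len(c1)}"
        )
    genes = c1.index.to_numpy(dtype=object)
    coefs = c1.to_numpy()
    order = np.lexsort((genes, coefs))  # ascending coef, then gene id
    neg = tuple(genes[order[:n_neg]])
    pos = tuple(genes[order[len(genes) - n_pos:]][::-1])
    if n_neg and n_neg < len(genes):
        boundary = coefs[order[n_neg - 1]]
        if boundary == coefs[order[n_neg]]:
            logger.info("select_book_ends: tie at the negative cutoff; gene-id order used")
    if n_pos and n_pos < len(genes):
        boundary = coefs[order[len(genes) - n_pos]]
        if boundary == coefs[order[len(genes) - n_pos - 1]]:
            logger.info("select_book_ends: tie at the positive cutoff; gene-id order used")
    return BookEndSelection(neg, pos, n_neg, n_pos)


def hypergeom_enrichment(
    subset: set[str],
    population: set[str],
    collection: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``subset`` against each
    gene set, restricted to ``population``.

    p = P(X >= k) for k overlap genes out of a size-n subset drawn from a
    population of N containing K annotated genes. Returns a frame sorted
    by p with a Benjamini-Hochberg q column and a significance flag at
    raw p < ``alpha``.
    """
    if not population:
        raise ValueError("empty population")
    extra = subset - population
    if extra:
        raise ValueError(f"subset genes outside population: {sorted(extra)[:5]}")
    n_pop = len(population)
    n_sub = len(subset)
    rows = []
    for name, genes in collection.items():
        in_pop = genes & population
        k_set = len(in_pop)
        k_hit = len(in_pop & subset)
        p = float(hypergeom.sf(k_hit - 1, n_pop, k_set, n_sub))
        rows.append(
            {
                "set_name": name,
                "N": n_pop,
                "K": k_set,
                "n": n_sub,
                "k": k_hit,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_bh"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p"] < alpha
        df = df.sort_values(["p", "set_name"], kind="mergesort").reset_index(
            drop=True
        )
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            out[parts[0]] = {g for g in parts[2:] if g}
    return out


def write_gmt(path, collection: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, ""] + sorted(genes)) + "\n")
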