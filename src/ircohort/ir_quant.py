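"""RPKM, per-gene intron retention index (IRI) and per-intron splicing
ratios from region-level read counts.

Region classes in count tables:

* ``shared_exon`` / ``shared_intron`` — aggregate counts over a gene's
  constitutive exonic/intronic regions,
* ``intron#<k>`` — k-th reference intron (1-based, transcription order),
* ``exon_flank#<k>#up`` / ``...#down`` — the flanking exons of intron k.

A region's count is the number of reads overlapping it by >= 1 base; a
read overlapping exon and intron counts toward both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import CohortMatrix
from .gene_model import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "SHARED_EXON",
    "SHARED_INTRON",
    "intron_class",
    "flank_class",
    "RegionCountTable",
    "IRIRecord",
    "SplicingRatioRecord",
    "rpkm",
    "compute_iri",
    "iri_table",
    "compute_splicing_ratios",
    "splicing_ratio_table",
    "build_cohort_matrix",
    "read_region_counts",
    "read_library_sizes",
    "read_metadata",
]

SHARED_EXON = "shared_exon"
SHARED_INTRON = "shared_intron"

COUNT_COLUMNS = ["gene_id", "region_class", "chrom", "start", "end", "count"]


def intron_class(ordinal: int) -> str:
    return f"intron#{ordinal}"


def flank_class(ordinal: int, side: str) -> str:
    if side not in ("up", "down"):
        raise ValueError(f"side must be 'up' or 'down', got {side!r}")
    return f"exon_flank#{ordinal}#{side}"


@dataclass
class RegionCountTable:
    """Per-sample region counts plus the sample's total mapped reads."""

    sample_id: str
    library_size: int
    counts: pd.DataFrame  # columns = COUNT_COLUMNS

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        missing = set(COUNT_COLUMNS) - set(self.counts.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise ValueError("negative counts")

    def class_sums(self) -> pd.Series:
        """Total count per (gene_id, region_class)."""
        return self.counts.groupby(["gene_id", "region_class"], sort=False)[
            "count"
        ].sum()


@dataclass
class IRIRecord:
    gene_id: str
    exonic_density: float
    intronic_density: float
    iri: float | None
    log2_iri: float | None
    gene_rpkm: float
    detectable: bool


@dataclass
class SplicingRatioRecord:
    gene_id: str
    ordinal: int
    intron_rpkm: float
    flank_mean_rpkm: float
    ratio: float


def rpkm(count: float, length: int, library_size: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if length <= 0:
        raise ValueError("length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / (length / 1e3) / (library_size / 1e6)


def compute_iri(gene: GeneModel, table: RegionCountTable) -> IRIRecord:
    """IRI = read density over shared introns / density over shared exons.

    A gene is detectable iff its shared-exon RPKM > 1 and both densities
    are positive (so log2 IRI is finite). Genes with no shared introns or
    zero exonic density are undetectable with iri unset.
    """
    if gene.shared_exons is None or gene.shared_introns is None:
        raise ValueError(f"gene {gene.gene_id}: shared regions not derived")
    sub = table.counts[table.counts["gene_id"] == gene.gene_id]
    exon_count = sub.loc[sub["region_class"] == SHARED_EXON, "count"].sum()
    intron_count = sub.loc[sub["region_class"] == SHARED_INTRON, "count"].sum()
    return _iri_from_sums(gene, exon_count, intron_count, table.library_size)


def _iri_from_sums(
    gene: GeneModel, exon_count: float, intron_count: float, library_size: int
) -> IRIRecord:
    exon_len = sum(iv.length for iv in gene.shared_exons)
    intron_len = sum(iv.length for iv in gene.shared_introns)
    exonic_density = exon_count / exon_len if exon_len else 0.0
    intronic_density = intron_count / intron_len if intron_len else 0.0
    gene_rpkm = (
        rpkm(exon_count, exon_len, library_size) if exon_len else 0.0
    )
    if exonic_density > 0:
        iri = intronic_density / exonic_density
        log2_iri = math.log2(iri) if iri > 0 else None
    else:
        iri, log2_iri = None, None
    detectable = (
        gene_rpkm > 1 and exonic_density > 0 and intronic_density > 0
    )
    return IRIRecord(
        gene.gene_id,
        exonic_density,
        intronic_density,
        iri,
        log2_iri,
        gene_rpkm,
        detectable,
    )


def iri_table(genes: list[GeneModel], table: RegionCountTable) -> pd.DataFrame:
    """Vectorized IRI for many genes; one row per gene.

    Columns: exonic_density, intronic_density, iri, log2_iri, gene_rpkm,
    detectable. Ratios undefined at zero denominators are NaN.
    """
    sums = table.class_sums().unstack("region_class", fill_value=0)
    lens = pd.DataFrame(
        {
            "exon_len": {
                g.gene_id: sum(iv.length for iv in g.shared_exons)
                for g in genes
            },
            "intron_len": {
                g.gene_id: sum(iv.length for iv in g.shared_introns)
                for g in genes
            },
        }
    )
    df = lens.join(sums.reindex(columns=[SHARED_EXON, SHARED_INTRON], fill_value=0)).fillna(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        exd = np.where(df["exon_len"] > 0, df[SHARED_EXON] / df["exon_len"], 0.0)
        ind = np.where(
            df["intron_len"] > 0, df[SHARED_INTRON] / df["intron_len"], 0.0
        )
        iri = np.where(exd > 0, ind / np.where(exd > 0, exd, 1.0), np.nan)
        log2_iri = np.where(
            np.nan_to_num(iri) > 0, np.log2(np.where(iri > 0, iri, 1.0)), np.nan
        )
        gene_rpkm = np.where(
            df["exon_len"] > 0,
            df[SHARED_EXON]
            / (df["exon_len"] / 1e3)
            / (table.library_size / 1e6),
            0.0,
        )
    out = pd.DataFrame(
        {
            "exonic_density": exd,
            "intronic_density": ind,
            "iri": iri,
            "log2_iri": log2_iri,
            "gene_rpkm": gene_rpkm,
            "detectable": (gene_rpkm > 1) & (exd > 0) & (ind > 0),
        },
        index=df.index,
    )
    out.index.name = "gene_id"
    return out


def compute_splicing_ratios(
    gene: GeneModel, table: RegionCountTable
) -> list[SplicingRatioRecord]:
    """Per-intron RPKM over the mean RPKM of the two flanking exons.

    Records whose flank mean RPKM is 0 are omitted (count logged).
    """
    if gene.reference_introns is None:
        raise ValueError(
            f"gene {gene.gene_id}: reference introns not enumerated"
        )
    sub = table.counts[table.counts["gene_id"] == gene.gene_id]
    by_class = sub.set_index("region_class")["count"]
    out = []
    n_omitted = 0
    for ri in gene.reference_introns:
        k = ri.ordinal
        needed = [intron_class(k), flank_class(k, "up"), flank_class(k, "down")]
        if any(c not in by_class.index for c in needed):
            continue
        i_rpkm = rpkm(by_class[needed[0]], ri.intron.length, table.library_size)
        up_rpkm = rpkm(
            by_class[needed[1]], ri.upstream_exon.length, table.library_size
        )
        down_rpkm = rpkm(
            by_class[needed[2]], ri.downstream_exon.length, table.library_size
        )
        flank_mean = (up_rpkm + down_rpkm) / 2.0
        if flank_mean == 0:
            n_omitted += 1
            continue
        out.append(
            SplicingRatioRecord(gene.gene_id, k, i_rpkm, flank_mean, i_rpkm / flank_mean)
        )
    if n_omitted:
        logger.info(
            "gene %s: omitted %d introns with zero flank RPKM",
            gene.gene_id,
            n_omitted,
        )
    return out


def splicing_ratio_table(
    genes: list[GeneModel], table: RegionCountTable
) -> pd.DataFrame:
    """Vectorized splicing ratios for many genes.

    Returns a long table (gene_id, ordinal, intron_rpkm, flank_mean_rpkm,
    ratio); zero-flank introns are dropped.
    """
    lengths = []
    for g in genes:
        if g.reference_introns is None:
            raise ValueError(f"gene {g.gene_id}: reference introns not enumerated")
        for ri in g.reference_introns:
            lengths.append(
                (
                    g.gene_id,
                    ri.ordinal,
                    ri.intron.length,
                    ri.upstream_exon.length,
                    ri.downstream_exon.length,
                )
            )
    if not lengths:
        return pd.DataFrame(
            columns=["gene_id", "ordinal", "intron_rpkm", "flank_mean_rpkm", "ratio"]
        )
    ldf = pd.DataFrame(
        lengths,
        columns=["gene_id", "ordinal", "intron_len", "up_len", "down_len"],
    ).set_index(["gene_id", "ordinal"])

    sums = table.class_sums()
    cls = sums.index.get_level_values("region_class")
    ic = sums[cls.str.startswith("intron#")]
    uc = sums[cls.str.endswith("#up")]
    dc = sums[cls.str.endswith("#down")]

    def _by_ordinal(series: pd.Series) -> pd.Series:
        if series.empty:
            return pd.Series(dtype=float)
        idx = pd.MultiIndex.from_arrays(
            [
                series.index.get_level_values("gene_id"),
                series.index.get_level_values("region_class")
                .str.split("#")
                .str[1]
                .astype(int),
            ],
            names=["gene_id", "ordinal"],
        )
        return pd.Series(series.to_numpy(), index=idx)

    df = ldf.copy()
    df["intron_count"] = _by_ordinal(ic).reindex(df.index)
    df["up_count"] = _by_ordinal(uc).reindex(df.index)
    df["down_count"] = _by_ordinal(dc).reindex(df.index)
    df = df.dropna()
    lib = table.library_size
    intron_rpkm = df["intron_count"] / (df["intron_len"] / 1e3) / (lib / 1e6)
    up_rpkm = df["up_count"] / (df["up_len"] / 1e3) / (lib / 1e6)
    down_rpkm = df["down_count"] / (df["down_len"] / 1e3) / (lib / 1e6)
    flank_mean = (up_rpkm + down_rpkm) / 2.0
    ok = flank_mean > 0
    n_omitted = int((~ok).sum())
    if n_omitted:
        logger.info("splicing_ratio_table: omitted %d zero-flank introns", n_omitted)
    out = pd.DataFrame(
        {
            "intron_rpkm": intron_rpkm[ok],
            "flank_mean_rpkm": flank_mean[ok],
            "ratio": (intron_rpkm[ok] / flank_mean[ok]),
        }
    ).reset_index()
    return out


def build_cohort_matrix(
    per_sample: dict[str, pd.DataFrame],
    groups: dict[str, str],
    mode: str = "iri",
) -> CohortMatrix:
    """Assemble a genes x samples matrix over the genes detectable in
    every sample (intersection).

    ``per_sample`` maps sample id to an :func:`iri_table` result. Values
    are log2 IRI (``mode="iri"``) or shared-exon RPKM
    (``mode="expression"``).
    """
    if not per_sample:
        raise ValueError("no samples")
    detectable_counts: dict[str, int] = {}
    common: pd.Index | None = None
    for sample, df in per_sample.items():
        det = df.index[df["detectable"]]
        detectable_counts[sample] = len(det)
        if common is None:
            common = det
        else:
            new = common.intersection(det)
            if len(new) == 0 and len(common) > 0:
                raise ValueError(
                    f"detectable-gene intersection emptied by sample {sample}"
                )
            common = new
    assert common is not None
    if len(common) == 0:
        raise ValueError("empty detectable-gene intersection")
    col = "log2_iri" if mode == "iri" else "gene_rpkm"
    values = pd.DataFrame(
        {s: df.loc[common, col] for s, df in per_sample.items()}
    )
    values.index.name = "gene_id"
    logger.info(
        "cohort matrix: %d genes common to %d samples (per-sample detectable: %s)",
        len(common),
        len(per_sample),
        detectable_counts,
    )
    return CohortMatrix(values, groups, mode=mode, detectable_counts=detectable_counts)


# ---------------------------------------------------------------------------
# TSV readers
# ---------------------------------------------------------------------------


def read_library_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"], df["library_size"].astype(int)))


def read_region_counts(
    counts_path, library_sizes: dict[str, int]
) -> dict[str, RegionCountTable]:
    """Read a long counts TSV (sample_id + COUNT_COLUMNS) into per-sample
    tables."""
    df = pd.read_csv(counts_path, sep="\t")
    out = {}
    for sample, sub in df.groupby("sample_id", sort=False):
        if sample not in library_sizes:
            raise ValueError(f"no library size for sample {sample}")
        out[str(sample)] = RegionCountTable(
            str(sample),
            library_sizes[sample],
            sub[COUNT_COLUMNS].reset_index(drop=True),
        )
    return out


def read_metadata(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"].astype(str), df["group"]))
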