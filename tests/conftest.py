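import numpy as np
import pytest

from ircohort.gene_model import (
    GeneModel,
    GenomicInterval,
    Transcript,
    derive_shared_regions,
    enumerate_reference_introns,
)


def make_transcript(tx_id, gene_id, exon_pairs, chrom="chr1", strand="+"):
    exons = tuple(
        GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs
    )
    return Transcript(tx_id, gene_id, exons)


def make_gene(gene_id, *exon_pair_lists, chrom="chr1", strand="+"):
    txs = tuple(
        make_transcript(f"{gene_id}.t{i + 1}", gene_id, pairs, chrom, strand)
        for i, pairs in enumerate(exon_pair_lists)
    )
    return GeneModel(gene_id, txs)


def prepared_gene(gene_id, *exon_pair_lists, chrom="chr1", strand="+"):
    g = make_gene(gene_id, *exon_pair_lists, chrom=chrom, strand=strand)
    return enumerate_reference_introns(derive_shared_regions(g))


def random_gene_model(rng, gene_id="G1", strand=None, max_transcripts=5, max_exons=8):
    """Small random gene model for oracle-based property tests."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_tx = int(rng.integers(1, max_transcripts + 1))
    txs = []
    for t in range(n_tx):
        n_ex = int(rng.integers(1, max_exons + 1))
        pos = int(rng.integers(0, 20))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(1, 15))
            exons.append(GenomicInterval("chr1", pos, pos + length, strand))
            pos += length + int(rng.integers(1, 15))
        txs.append(Transcript(f"{gene_id}.t{t + 1}", gene_id, tuple(exons)))
    return GeneModel(gene_id, tuple(txs))


def brute_force_base_classes(gene):
    """Per-base oracle: classify every base of the union span."""
    span_start = min(t.span.start for t in gene.transcripts)
    span_end = max(t.span.end for t in gene.transcripts)
    shared_ex, shared_in, ambiguous, uncovered = set(), set(), set(), set()
    for pos in range(span_start, span_end):
        states = []
        for t in gene.transcripts:
            if any(e.start <= pos < e.end for e in t.exons):
                states.append("exon")
            elif t.span.start <= pos < t.span.end:
                states.append("intron")
            else:
                states.append("outside")
        if "outside" in states:
            uncovered.add(pos)
        elif all(s == "exon" for s in states):
            shared_ex.add(pos)
        elif all(s == "intron" for s in states):
            shared_in.add(pos)
        else:
            ambiguous.add(pos)
    return shared_ex, shared_in, ambiguous, uncovered


def interval_bases(intervals):
    return {p for iv in intervals for p in range(iv.start, iv.end)}


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
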