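import numpy as np
import pytest

from m6aging.annotation import GenomicInterval, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_random_model(rng, n_exons=5, chrom="chr1", strand=None, coding=True,
                      tid="tx"):
    """Random multi-exon transcript for projection/round-trip tests."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    pos = int(rng.integers(100, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(50, 500))
    if strand == "-":
        exons = exons[::-1]
    model = TranscriptModel(tid, tid, "protein_coding" if coding else "lncRNA", exons)
    if coding:
        L = model.length
        model.cds_start = int(rng.integers(1, L // 3))
        model.cds_end = int(rng.integers(2 * L // 3, L))
        model.__post_init__()
    return model


def project_base_oracle(iv, model):
    """Per-base enumeration oracle for genomic->transcript projection."""
    if iv.chrom != model.chrom or iv.strand != model.strand:
        return None
    # enumerate transcript positions base by base
    mapping = {}
    offset = 0
    for exon in model.exons:
        span = range(exon.start, exon.end)
        bases = span if model.strand == "+" else reversed(span)
        for t, g in enumerate(bases):
            mapping[g] = offset + t
        offset += len(exon)
    hits = [mapping[g] for g in range(iv.start, iv.end) if g in mapping]
    if not hits:
        return None
    return min(hits), max(hits) + 1
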