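"""Transcript annotation data model and I/O.

Coordinates are 0-based half-open everywhere internally (BED native; GTF is
converted on read). Transcript-space coordinates count nucleotides from the 5'
end of the mature (spliced) transcript, so minus-strand transcripts run
right-to-left along the genome.
"""

from __future__ import annotations

import gzip
import logging
import shutil
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other_noncoding")

#: annotation biotype -> collapsed four-class vocabulary
_BIOTYPE_COLLAPSE = {
    "protein_coding": "protein_coding",
    "mrna": "protein_coding",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "antisense": "lncRNA",
    "antisense_rna": "lncRNA",
    "processed_transcript": "lncRNA",
}


def collapse_biotype(raw: str) -> str:
    """Collapse an annotation biotype into the four-class vocabulary."""
    key = raw.strip().lower()
    if key in _BIOTYPE_COLLAPSE:
        return _BIOTYPE_COLLAPSE[key]
    if "pseudogene" in key:
        return "pseudogene"
    if key not in ("mirna", "snorna", "snrna", "rrna", "trna", "misc_rna",
                   "other_noncoding", "ncrna"):
        logger.warning("unrecognized biotype %r collapsed to other_noncoding", raw)
    return "other_noncoding"


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing gzip (sniffed by magic bytes)."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are stored 5'->3' in transcript orientation (for minus-strand
    transcripts the genomically rightmost exon comes first). ``cds_start`` /
    ``cds_end`` are transcript-space coordinates; both are ``None`` for
    noncoding transcripts.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"biotype must be one of {BIOTYPES}, got {self.biotype!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError("all exons must share one chrom and strand")
        # verify 5'->3' ordering and non-overlap in transcript orientation
        starts = [e.start for e in self.exons]
        if self.strand == "+":
            ok = all(self.exons[i].end <= self.exons[i + 1].start
                     for i in range(len(self.exons) - 1))
        else:
            ok = all(self.exons[i + 1].end <= self.exons[i].start
                     for i in range(len(self.exons) - 1))
        if not ok:
            raise ValueError(
                f"{self.transcript_id}: exons must be non-overlapping and sorted "
                f"5'->3' in transcript orientation (starts={starts}, strand={self.strand})"
            )
        if self.is_coding:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                    f"outside transcript of length {self.length}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    @property
    def genomic_span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )


def genomic_to_transcript(
    iv: GenomicInterval, model: TranscriptModel
) -> Optional[tuple[int, int]]:
    """Project a genomic interval into mature-transcript coordinates.

    Returns the half-open transcript-space interval covering the projection of
    ``iv`` intersected with the exons, or ``None`` if there is no exonic
    overlap (including chrom/strand mismatch). On the minus strand the
    orientation is reversed so that coordinates increase 5'->3'.
    """
    if iv.chrom != model.chrom or iv.strand != model.strand:
        return None
    lo, hi = None, None
    offset = 0
    for exon in model.exons:
        a = max(iv.start, exon.start)
        b = min(iv.end, exon.end)
        if a < b:
            if model.strand == "+":
                ta, tb = offset + (a - exon.start), offset + (b - exon.start)
            else:
                ta, tb = offset + (exon.end - b), offset + (exon.end - a)
            lo = ta if lo is None else min(lo, ta)
            hi = tb if hi is None else max(hi, tb)
        offset += len(exon)
    if lo is None:
        return None
    return lo, hi


def transcript_to_genomic_point(pos: int, model: TranscriptModel) -> int:
    """Map a transcript-space base position to its genomic coordinate."""
    if not 0 <= pos < model.length:
        raise ValueError(f"position {pos} outside transcript of length {model.length}")
    offset = 0
    for exon in model.exons:
        if pos < offset + len(exon):
            within = pos - offset
            if model.strand == "+":
                return exon.start + within
            return exon.end - 1 - within
        offset += len(exon)
    raise AssertionError("unreachable")


def transcript_span_to_genomic(
    tx_start: int, tx_end: int, model: TranscriptModel
) -> GenomicInterval:
    """Genomic span covering a transcript-space interval (introns included)."""
    g1 = transcript_to_genomic_point(tx_start, model)
    g2 = transcript_to_genomic_point(tx_end - 1, model)
    lo, hi = (g1, g2) if g1 <= g2 else (g2, g1)
    return GenomicInterval(model.chrom, lo, hi + 1, model.strand)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _model_from_bed12_fields(fields: Sequence[str], lineno: int) -> TranscriptModel:
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        thick_start, thick_end = int(fields[6]), int(fields[7])
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed BED12 at line {lineno}: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(f"malformed BED12 at line {lineno}: block count mismatch")
    exons = [
        GenomicInterval(chrom, chrom_start + s, chrom_start + s + w, strand)
        for s, w in zip(starts, sizes)
    ]
    if strand == "-":
        exons = exons[::-1]
    gene_id, biotype = name, "protein_coding"
    if "|" in name:  # extended name: transcript_id|gene_id|biotype
        parts = name.split("|")
        name = parts[0]
        gene_id = parts[1] if len(parts) > 1 and parts[1] else name
        biotype = parts[2] if len(parts) > 2 and parts[2] else "protein_coding"
    model = TranscriptModel(name, gene_id, collapse_biotype(biotype), exons)
    if thick_end > thick_start:
        cds = genomic_to_transcript(
            GenomicInterval(chrom, thick_start, thick_end, strand), model
        )
        if cds is None:
            raise ValueError(
                f"line {lineno}: CDS [{thick_start}, {thick_end}) outside exons"
            )
        model.cds_start, model.cds_end = cds
        model.__post_init__()  # re-validate with CDS set
    elif model.biotype == "protein_coding":
        model.biotype = "other_noncoding"
    return model


def _read_bed12(path: str | Path) -> list[TranscriptModel]:
    models = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            models.append(_model_from_bed12_fields(line.split("\t"), lineno))
    return models


def _read_gtf(path: str | Path) -> list[TranscriptModel]:
    import gffutils

    path = Path(path)
    tmp = None
    try:
        with open(path, "rb") as fh:
            gz = fh.read(2) == b"\x1f\x8b"
        if gz:
            tmp = tempfile.NamedTemporaryFile("wb", suffix=".gtf", delete=False)
            with gzip.open(path, "rb") as src:
                shutil.copyfileobj(src, tmp)
            tmp.close()
            path = Path(tmp.name)
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        models = []
        tx_ids = sorted(
            {f.attributes["transcript_id"][0]
             for f in db.all_features()
             if "transcript_id" in f.attributes and f.featuretype in ("exon", "CDS")}
        )
        exons_by_tx: dict[str, list] = {t: [] for t in tx_ids}
        cds_by_tx: dict[str, list] = {t: [] for t in tx_ids}
        meta: dict[str, dict] = {}
        for f in db.all_features():
            if "transcript_id" not in f.attributes:
                continue
            tid = f.attributes["transcript_id"][0]
            if f.featuretype == "exon":
                exons_by_tx[tid].append(f)
            elif f.featuretype == "CDS":
                cds_by_tx[tid].append(f)
            if tid not in meta:
                bt = None
                for key in ("transcript_biotype", "transcript_type",
                            "gene_biotype", "gene_type"):
                    if key in f.attributes:
                        bt = f.attributes[key][0]
                        break
                meta[tid] = {
                    "gene_id": f.attributes.get("gene_id", [tid])[0],
                    "biotype": bt,
                }
        for tid in tx_ids:
            feats = exons_by_tx[tid]
            if not feats:
                continue
            strand = feats[0].strand
            ivs = sorted(
                (GenomicInterval(f.seqid, f.start - 1, f.end, f.strand) for f in feats),
                key=lambda e: e.start,
                reverse=(strand == "-"),
            )
            cds_feats = cds_by_tx[tid]
            raw_bt = meta[tid]["biotype"]
            if raw_bt is None:
                raw_bt = "protein_coding" if cds_feats else "other_noncoding"
            model = TranscriptModel(
                tid, meta[tid]["gene_id"], collapse_biotype(raw_bt), ivs
            )
            if cds_feats:
                gmin = min(f.start - 1 for f in cds_feats)
                gmax = max(f.end for f in cds_feats)
                cds = genomic_to_transcript(
                    GenomicInterval(model.chrom, gmin, gmax, strand), model
                )
                if cds is None:
                    raise ValueError(f"{tid}: CDS outside exons")
                model.cds_start, model.cds_end = cds
                model.__post_init__()
            models.append(model)
        return models
    finally:
        if tmp is not None:
            Path(tmp.name).unlink(missing_ok=True)


def read_transcript_models(path: str | Path, format: str = "bed12") -> list[TranscriptModel]:
    """Read transcript models from a BED12 or GTF file (gzip accepted)."""
    if format == "bed12":
        return _read_bed12(path)
    if format == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown format {format!r} (expected 'gtf' or 'bed12')")


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models to BED12; name column is transcript|gene|biotype."""
    with open(path, "w") as fh:
        for m in models:
            exons = sorted(m.exons, key=lambda e: e.start)
            chrom_start = exons[0].start
            chrom_end = exons[-1].end
            if m.is_coding:
                span = transcript_span_to_genomic(m.cds_start, m.cds_end, m)
                thick_start, thick_end = span.start, span.end
            else:
                thick_start = thick_end = chrom_start
            sizes = ",".join(str(len(e)) for e in exons)
            starts = ",".join(str(e.start - chrom_start) for e in exons)
            name = f"{m.transcript_id}|{m.gene_id}|{m.biotype}"
            fh.write(
                f"{m.chrom}\t{chrom_start}\t{chrom_end}\t{name}\t0\t{m.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(exons)}\t{sizes},\t{starts},\n"
            )


def read_gene_set(path: str | Path) -> set[str]:
    """Read a gene set: one ID per line, ``#`` comments allowed, deduplicated."""
    out: set[str] = set()
    with open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    if not out:
        warnings.warn(f"gene set {path} is empty", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Cohort design and expression tables
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Subject-to-group mapping for a two-cohort (young/old) study."""

    subjects: pd.DataFrame  # columns: subject_id, group, age

    GROUPS = ("young", "old")

    def __post_init__(self) -> None:
        req = {"subject_id", "group"}
        if not req.issubset(self.subjects.columns):
            raise ValueError(f"design needs columns {req}")
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("subject_ids must be unique")
        bad = set(self.subjects["group"]) - set(self.GROUPS)
        if bad:
            raise ValueError(f"unknown groups {bad}; expected {self.GROUPS}")
        for g in self.GROUPS:
            if not (self.subjects["group"] == g).any():
                raise ValueError(f"group {g!r} is empty")

    def ids(self, group: str) -> list[str]:
        return self.subjects.loc[self.subjects["group"] == group, "subject_id"].tolist()

    @property
    def young(self) -> list[str]:
        return self.ids("young")

    @property
    def old(self) -> list[str]:
        return self.ids("old")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"subject_id": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.subjects.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionTable:
    """Gene/transcript x subject expression matrix (FPKM or raw counts)."""

    values: pd.DataFrame  # rows: feature IDs, columns: subject IDs
    is_fpkm: bool = True

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature IDs")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate subject IDs")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @classmethod
    def read_tsv(cls, path: str | Path, is_fpkm: bool = True) -> "ExpressionTable":
        with open_text(path) as fh:
            df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(df, is_fpkm=is_fpkm)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")
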