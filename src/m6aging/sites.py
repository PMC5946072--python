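"""m6A site calling, motif classification and quantification from MeRIP data.

Fragments from the immunoprecipitated (IP) library are compared against the
input (total RNA) library in sliding windows along each transcript. Windows
significantly enriched in IP fragments (one-sided Poisson test against the
library-size-scaled input expectation, BH-corrected) are merged into sites.
Each site is assigned one motif class from the nested hierarchy
GGACU > GACU > ACU > GAC by longest-match priority.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomicInterval, TranscriptModel

MOTIF_CLASSES = ("GGACU", "GACU", "ACU", "GAC")


@dataclass
class WindowCounts:
    """IP/input fragment counts in one sliding window.

    ``window`` is the genomic span of the window; ``tx_start``/``tx_end`` are
    the same window in mature-transcript coordinates when the window was tiled
    along a transcript.
    """

    window: GenomicInterval
    ip_count: int
    input_count: int
    transcript_id: Optional[str] = None
    tx_start: Optional[int] = None
    tx_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ip_count < 0 or self.input_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class M6ASite:
    """A called methylated fragment site."""

    interval: GenomicInterval
    transcript_id: str
    motif_class: str = "none"
    ip_fpkm: float = 0.0
    input_fpkm: float = 0.0
    enrichment: float = 1.0
    qvalue: float = 1.0
    fragment_count: int = 0  # IP fragments in the best window of the site
    tx_start: Optional[int] = None
    tx_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.enrichment <= 0:
            raise ValueError("enrichment must be > 0")
        if not 0 <= self.qvalue <= 1:
            raise ValueError("qvalue must be in [0, 1]")
        if self.motif_class not in MOTIF_CLASSES + ("none",):
            raise ValueError(f"unknown motif class {self.motif_class!r}")


@dataclass
class OverlapResult:
    """Venn decomposition of two site sets (e.g. young vs. old cohort).

    A site is *shared* iff it intersects >= 1 nt of any site in the other set
    on the same chrom and strand. ``shared_a``/``shared_b`` hold each side's
    overlapping sites; the two counts coincide when overlaps pair one-to-one
    (the usual case for merged, within-cohort non-overlapping site sets).
    """

    a_only: list[M6ASite]
    shared_a: list[M6ASite]
    shared_b: list[M6ASite]
    b_only: list[M6ASite]

    @property
    def shared(self) -> int:
        return len(self.shared_a)

    def counts(self) -> dict[str, int]:
        return {
            "a_only": len(self.a_only),
            "shared_a": len(self.shared_a),
            "shared_b": len(self.shared_b),
            "b_only": len(self.b_only),
        }


def classify_motif(site_sequence: str) -> str:
    """Classify a site sequence by longest-match motif priority.

    GGACU if present; else GACU; else ACU; else GAC; else "none". Case
    insensitive; DNA input (T) is mapped to RNA (U). The classes are nested
    substrings of the DRACH consensus, so priority makes them exclusive.
    """
    seq = site_sequence.upper().replace("T", "U")
    for motif in MOTIF_CLASSES:
        if motif in seq:
            return motif
    return "none"


def compute_fpkm(count: float, feature_length: int, libsize: int) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if feature_length <= 0:
        raise ValueError("feature_length must be > 0")
    if libsize <= 0:
        raise ValueError("libsize must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count * 1e9 / (feature_length * libsize)


def call_m6a_sites(
    windows: Sequence[WindowCounts],
    ip_libsize: int,
    input_libsize: int,
    q_threshold: float = 0.05,
    pseudocount: float = 0.5,
) -> list[M6ASite]:
    """Call m6A sites from windowed IP vs. input fragment counts.

    Per window: enrichment = ((ip+pc)/ip_libsize) / ((input+pc)/input_libsize);
    one-sided Poisson tail P(X >= ip) with expectation
    input * ip_libsize/input_libsize + pc; BH correction across all windows.
    Windows with q <= q_threshold and enrichment > 1 are kept and
    overlapping/adjacent significant windows on the same transcript are merged
    into one site carrying the counts of its maximal window.
    """
    if ip_libsize <= 0 or input_libsize <= 0:
        raise ValueError("library sizes must be > 0")
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must be in (0, 1)")
    if len(windows) == 0:
        return []
    # width is checked in transcript space when available: a spliced window's
    # genomic span includes introns
    widths = {
        (w.tx_end - w.tx_start) if w.tx_start is not None else len(w.window)
        for w in windows
    }
    if len(widths) > 1:
        raise ValueError(f"windows must share one width, got {sorted(widths)}")

    ip = np.array([w.ip_count for w in windows], dtype=float)
    inp = np.array([w.input_count for w in windows], dtype=float)
    ratio = ip_libsize / input_libsize
    enrichment = ((ip + pseudocount) / ip_libsize) / ((inp + pseudocount) / input_libsize)
    mu = inp * ratio + pseudocount
    pvals = stats.poisson.sf(ip - 1, mu)  # P(X >= ip)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    keep = (qvals <= q_threshold) & (enrichment > 1.0)
    if not keep.any():
        return []

    # merge overlapping/adjacent significant windows per transcript (or chrom)
    order = sorted(
        np.flatnonzero(keep),
        key=lambda i: (
            windows[i].transcript_id or "",
            windows[i].window.chrom,
            windows[i].window.strand,
            windows[i].tx_start if windows[i].tx_start is not None
            else windows[i].window.start,
        ),
    )
    sites: list[M6ASite] = []
    run: list[int] = []

    def _pos(i: int) -> tuple[int, int]:
        w = windows[i]
        if w.tx_start is not None:
            return w.tx_start, w.tx_end
        return w.window.start, w.window.end

    def _key(i: int) -> tuple:
        w = windows[i]
        return (w.transcript_id, w.window.chrom, w.window.strand)

    def _flush(run: list[int]) -> None:
        best = max(run, key=lambda i: (windows[i].ip_count, -_pos(i)[0]))
        w = windows[best]
        g_start = min(windows[i].window.start for i in run)
        g_end = max(windows[i].window.end for i in run)
        tx = [_pos(i) for i in run] if w.tx_start is not None else None
        length = (max(t[1] for t in tx) - min(t[0] for t in tx)) if tx else g_end - g_start
        sites.append(
            M6ASite(
                interval=GenomicInterval(w.window.chrom, g_start, g_end, w.window.strand),
                transcript_id=w.transcript_id or "",
                ip_fpkm=compute_fpkm(w.ip_count, length, ip_libsize),
                input_fpkm=compute_fpkm(w.input_count, length, input_libsize),
                enrichment=float(enrichment[best]),
                qvalue=float(min(qvals[i] for i in run)),
                fragment_count=int(w.ip_count),
                tx_start=min(t[0] for t in tx) if tx else None,
                tx_end=max(t[1] for t in tx) if tx else None,
            )
        )

    for i in order:
        if run and _key(i) == _key(run[-1]) and _pos(i)[0] <= _pos(run[-1])[1]:
            run.append(i)
        else:
            if run:
                _flush(run)
            run = [i]
    if run:
        _flush(run)
    return sites


def assign_motifs(
    sites: Iterable[M6ASite], sequences: Mapping[str, str]
) -> list[M6ASite]:
    """Assign motif classes to sites from their transcript sequences.

    Sites need ``tx_start``/``tx_end`` and a transcript present in
    ``sequences`` (id -> mature transcript sequence); others keep "none".
    """
    out = []
    for s in sites:
        cls = "none"
        seq = sequences.get(s.transcript_id)
        if seq is not None and s.tx_start is not None:
            cls = classify_motif(str(seq[s.tx_start:s.tx_end]))
        out.append(replace(s, motif_class=cls))
    return out


def overlap_sites(
    sites_a: Sequence[M6ASite], sites_b: Sequence[M6ASite]
) -> OverlapResult:
    """Classify two site sets into a-only / shared / b-only by >=1 nt overlap."""
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], IntervalTree] = {}
    for s in sites_b:
        key = (s.interval.chrom, s.interval.strand)
        trees.setdefault(key, IntervalTree()).addi(s.interval.start, s.interval.end)
    a_only, shared_a = [], []
    for s in sites_a:
        tree = trees.get((s.interval.chrom, s.interval.strand))
        if tree is not None and tree.overlap(s.interval.start, s.interval.end):
            shared_a.append(s)
        else:
            a_only.append(s)
    trees_a: dict[tuple[str, str], IntervalTree] = {}
    for s in sites_a:
        key = (s.interval.chrom, s.interval.strand)
        trees_a.setdefault(key, IntervalTree()).addi(s.interval.start, s.interval.end)
    b_only, shared_b = [], []
    for s in sites_b:
        tree = trees_a.get((s.interval.chrom, s.interval.strand))
        if tree is not None and tree.overlap(s.interval.start, s.interval.end):
            shared_b.append(s)
        else:
            b_only.append(s)
    return OverlapResult(a_only, shared_a, shared_b, b_only)


def tally_by_biotype(
    sites: Sequence[M6ASite], models: Mapping[str, TranscriptModel] | Sequence[TranscriptModel]
) -> dict[str, int]:
    """Count sites per collapsed transcript biotype; unknown IDs under 'unknown'."""
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    counts = {"protein_coding": 0, "lncRNA": 0, "pseudogene": 0,
              "other_noncoding": 0, "unknown": 0}
    for s in sites:
        m = models.get(s.transcript_id)
        counts[m.biotype if m is not None else "unknown"] += 1
    return counts


def tally_by_motif(
    sites: Sequence[M6ASite], per_transcript: bool = False
) -> pd.DataFrame:
    """Counts and proportions per motif class.

    Proportions are over the four motif classes; sites classified "none" are
    reported but excluded from the proportion denominator. With
    ``per_transcript`` each transcript contributes once per motif class.
    """
    if per_transcript:
        seen = {(s.transcript_id, s.motif_class) for s in sites}
        labels = [m for _, m in seen]
    else:
        labels = [s.motif_class for s in sites]
    counts = pd.Series(labels, dtype=object).value_counts()
    rows = []
    total = int(sum(counts.get(m, 0) for m in MOTIF_CLASSES))
    for m in MOTIF_CLASSES + ("none",):
        c = int(counts.get(m, 0))
        prop = c / total if (total > 0 and m != "none") else (0.0 if m != "none" else np.nan)
        rows.append({"motif_class": m, "count": c, "proportion": prop})
    return pd.DataFrame(rows)


def merip_qpcr_enrichment(
    ip_quantity: float,
    input_quantity: float,
    control_ip: float,
    control_input: float,
) -> float:
    """MeRIP-qPCR fold enrichment over a nonspecific-binding control.

    (target IP/input) / (control IP/input); e.g. 18S rRNA as the control.
    """
    for q in (ip_quantity, input_quantity, control_ip, control_input):
        if q <= 0:
            raise ValueError("quantities must be > 0")
    return (ip_quantity / input_quantity) / (control_ip / control_input)


def write_sites_bed(sites: Sequence[M6ASite], path) -> None:
    """Write sites as BED6+ (name=motif class, score=-10*log10(q))."""
    with open(path, "w") as fh:
        for s in sites:
            score = -10.0 * np.log10(max(s.qvalue, 1e-30))
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                f"{s.motif_class}\t{score:.1f}\t{s.interval.strand}\t"
                f"{s.transcript_id}\t{s.enrichment:.4g}\t{s.qvalue:.4g}\t"
                f"{s.ip_fpkm:.4g}\t{s.fragment_count}\n"
            )
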