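"""Synthetic-data generator for the whole pipeline.

Emulates the statistical structure of a two-cohort (young/old, n=11 per
group) MeRIP-seq aging study: a desk-scale transcriptome with planted
DRACH-class motifs at registered m6A sites, IP/input fragment libraries
(100-200 nt fragments, negative-binomial counts, 8x enrichment at sites,
fewer sites in the old cohort with a large shared fraction), cohort
expression tables with a planted shift for methylated genes, actinomycin-D
decay Ct series, and a miRNA intensity matrix with planted up/down sets.
Every generator is deterministic under a fixed seed and emits a
machine-readable truth registry for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    CohortDesign,
    ExpressionTable,
    GenomicInterval,
    TranscriptModel,
    transcript_span_to_genomic,
    write_bed12,
)
from .decay import DecaySeries
from .mirna import MirnaMatrix
from .sites import WindowCounts

_BASES = np.frombuffer(b"ACGU", dtype=np.uint8)

LET7_IDS = [
    "hsa-let-7a", "hsa-let-7b", "hsa-let-7c", "hsa-let-7d", "hsa-let-7e",
    "hsa-let-7f", "hsa-let-7g", "hsa-let-7i", "hsa-miR-98", "hsa-let-7a-2",
    "hsa-let-7f-2", "hsa-let-7b-2",
]


@dataclass
class SimulationConfig:
    """Default scenario of the emulated study.

    Defaults follow the study conditions: two cohorts of 11 subjects,
    ~1,000 methylated sites in the young cohort with ~75% shared with old,
    100-200 nt fragments, 8x IP enrichment, a focal AGO2-like transcript
    (methylated and stable in young, demethylated and destabilized in old),
    DROSHA-like (methylated in both, unchanged) and DICER1-like (unmethylated,
    reduced in old), decay half-lives 4.9/9.5/7.1 h, and an 887-miRNA array
    scenario with 550 up / 93 down (7 of 12 let-7 members down).
    """

    seed: int = 0
    # transcriptome
    n_transcripts: int = 1200
    fraction_coding: float = 0.8
    # cohorts
    n_subjects_per_group: int = 11
    # MeRIP sites
    n_sites_young: int = 1000
    cohort_effect: float = 0.25  # fraction of young sites lost in old
    old_only_fraction: float = 0.2  # old-only sites per dropped young site
    motif_mix: dict = field(
        default_factory=lambda: {"GGACU": 0.45, "GACU": 0.25, "ACU": 0.20, "GAC": 0.10}
    )
    fragment_length: tuple[int, int] = (100, 200)
    site_halfwidth: int = 50
    enrichment: float = 8.0
    ip_libsize: int = 300_000
    input_libsize: int = 300_000
    nb_dispersion: float = 0.1  # per-subject; pooled dispersion is this / n subjects
    # expression
    expr_log2_mean: float = 3.0
    expr_log2_sd: float = 1.5
    subject_log2_sd: float = 0.5
    meth_log2fc_shift: float = -0.5
    epsilon: float = 0.01
    # decay
    decay_conditions: dict = field(
        default_factory=lambda: {"empty_vector": 4.9, "METTL3_OE": 9.5, "METTL14_OE": 7.1}
    )
    decay_replicates: int = 3
    decay_timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    ct_noise_sd: float = 0.1
    # miRNA array
    n_mirna: int = 887
    n_mirna_up: int = 550
    n_mirna_down: int = 93
    mirna_effect: float = 1.0  # log10 intensity shift (~1 column-sd unit)
    mirna_subject_sd: float = 0.25
    mirna_base_mean: float = 2.5
    mirna_base_sd: float = 1.0
    mirna_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_transcripts < 10:
            raise ValueError("need >= 10 transcripts")
        for f in (self.fraction_coding, self.cohort_effect):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.n_mirna_up + self.n_mirna_down > self.n_mirna:
            raise ValueError("planted miRNA sets exceed the array size")


@dataclass
class PlantedSite:
    site_id: str
    transcript_id: str
    tx_start: int
    tx_end: int
    motif: str
    in_young: bool
    in_old: bool


@dataclass
class Transcriptome:
    """Models, sequences, per-transcript expression weights and site truth."""

    models: list[TranscriptModel]
    sequences: dict[str, str]
    base_log2_expr: dict[str, float]
    sites: list[PlantedSite]

    @property
    def model_map(self) -> dict[str, TranscriptModel]:
        return {m.transcript_id: m for m in self.models}

    def sites_for(self, cohort: str) -> list[PlantedSite]:
        key = "in_young" if cohort == "young" else "in_old"
        return [s for s in self.sites if getattr(s, key)]

    def methylated_genes(self, cohort: str) -> set[str]:
        return {s.transcript_id for s in self.sites_for(cohort)}


def _rng_for(cfg: SimulationConfig, stage: str) -> np.random.Generator:
    """One deterministic generator per stage, derived from the config seed."""
    stage_key = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little")
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stage_key]))


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.uint8)


def simulate_transcriptome(cfg: SimulationConfig) -> Transcriptome:
    """Random exon structures, transcript sequences and planted m6A sites.

    Coding transcripts get a UTR5/CDS/UTR3 split; site-bearing transcripts
    are drawn with probability proportional to expression (sites can only be
    detected on expressed transcripts) from those above the 25th expression
    percentile. Motifs are embedded at the planted site centers and every
    site is recorded in the truth registry.
    """
    rng = _rng_for(cfg, "transcriptome")
    n = cfg.n_transcripts
    n_coding = int(round(cfg.fraction_coding * n))
    cursors = {f"chr{i}": 1000 for i in range(1, 6)}
    models: list[TranscriptModel] = []
    seq_arrays: dict[str, np.ndarray] = {}
    focal = ["AGO2_like", "DROSHA_like", "DICER1_like"]

    for i in range(n):
        coding = i < n_coding
        tid = focal[i] if i < 3 else f"T{i:05d}"  # focal ids are coding (n_coding >= 3)
        length = int(rng.integers(600, 3001)) if coding else int(rng.integers(400, 2001))
        n_exons = int(rng.integers(1, 6))
        # partition length into exons of >= 50 nt where possible
        if n_exons * 50 > length:
            n_exons = max(1, length // 50)
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) \
            if n_exons > 1 else np.array([], dtype=int)
        exon_lens = np.diff(np.concatenate([[0], cuts, [length]])).astype(int)
        chrom = f"chr{rng.integers(1, 6)}"
        strand = "+" if rng.random() < 0.5 else "-"
        pos = cursors[chrom]
        g_exons = []
        for el in exon_lens:
            g_exons.append(GenomicInterval(chrom, pos, pos + int(el), strand))
            pos += int(el) + int(rng.integers(200, 2001))
        cursors[chrom] = pos + 500
        exons = g_exons[::-1] if strand == "-" else g_exons
        if coding:
            biotype = "protein_coding"
        else:
            biotype = str(rng.choice(["lncRNA", "pseudogene", "other_noncoding"],
                                     p=[0.5, 0.25, 0.25]))
        model = TranscriptModel(tid, tid, biotype, exons)
        if coding:
            utr5 = max(30, int(rng.uniform(0.05, 0.25) * length))
            utr3 = max(30, int(rng.uniform(0.15, 0.40) * length))
            model.cds_start, model.cds_end = utr5, length - utr3
            model.__post_init__()
        models.append(model)
        seq_arrays[tid] = _random_sequence(rng, length)

    base_log2 = {
        m.transcript_id: float(rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sd))
        for m in models
    }

    # --- plant sites, expression-weighted, above the 25th expression percentile
    ids = [m.transcript_id for m in models]
    expr = np.array([base_log2[t] for t in ids])
    floor = np.quantile(expr, 0.25)
    eligible = [
        j for j, m in enumerate(models)
        if expr[j] >= floor and m.length >= 4 * cfg.site_halfwidth
        and m.transcript_id != "DICER1_like"
    ]
    weights = np.exp2(expr[eligible])
    weights /= weights.sum()
    motifs = list(cfg.motif_mix)
    motif_p = np.array([cfg.motif_mix[m] for m in motifs], dtype=float)
    motif_p /= motif_p.sum()

    occupied: dict[str, list[tuple[int, int]]] = {t: [] for t in ids}
    sites: list[PlantedSite] = []

    def plant(tid: str, forced: bool = False) -> Optional[PlantedSite]:
        model = next(m for m in models if m.transcript_id == tid)
        hw = cfg.site_halfwidth
        for _ in range(30):
            c = int(rng.integers(hw, model.length - hw))
            a, b = c - hw, c + hw
            if any(a < e and s < b for s, e in occupied[tid]):
                continue
            motif = str(rng.choice(motifs, p=motif_p))
            arr = seq_arrays[tid]
            enc = np.frombuffer(motif.encode(), dtype=np.uint8)
            idx = np.array([int(np.where(_BASES == ch)[0][0]) for ch in enc])
            arr[c:c + len(motif)] = idx
            occupied[tid].append((a, b))
            return PlantedSite(f"S{len(sites):05d}", tid, a, b, motif, True, True)
        return None

    # focal sites first: AGO2-like loses methylation in old (it IS the cohort
    # effect, so a zero effect keeps it methylated in both); DROSHA-like in both
    for tid, in_old in (("AGO2_like", cfg.cohort_effect == 0), ("DROSHA_like", True)):
        s = plant(tid)
        assert s is not None
        s.in_old = in_old
        sites.append(s)

    while len(sites) < cfg.n_sites_young:
        j = eligible[int(rng.choice(len(eligible), p=weights))]
        s = plant(ids[j])
        if s is not None:
            sites.append(s)

    # cohort effect: old loses a fraction of the young sites...
    n_drop = int(round(cfg.cohort_effect * cfg.n_sites_young))
    droppable = [k for k, s in enumerate(sites) if s.transcript_id not in focal]
    for k in rng.choice(droppable, size=min(n_drop, len(droppable)), replace=False):
        sites[k].in_old = False
    # ...and gains a smaller old-only set
    n_old_only = int(round(cfg.old_only_fraction * n_drop))
    planted_old = 0
    while planted_old < n_old_only:
        j = eligible[int(rng.choice(len(eligible), p=weights))]
        s = plant(ids[j])
        if s is not None:
            s.in_young = False
            sites.append(s)
            planted_old += 1

    sequences = {t: _BASES[a].tobytes().decode() for t, a in seq_arrays.items()}
    return Transcriptome(models, sequences, base_log2, sites)


# ---------------------------------------------------------------------------
# MeRIP fragment libraries
# ---------------------------------------------------------------------------

def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture."""
    means = np.clip(means, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(means)
    lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
    return rng.poisson(lam)


def _tx_positions_to_genomic(model: TranscriptModel, positions: np.ndarray) -> np.ndarray:
    offsets = np.cumsum([0] + [len(e) for e in model.exons[:-1]])
    j = np.searchsorted(offsets, positions, side="right") - 1
    within = positions - offsets[j]
    starts = np.array([e.start for e in model.exons])
    ends = np.array([e.end for e in model.exons])
    if model.strand == "+":
        return starts[j] + within
    return ends[j] - 1 - within


def _sample_input_fragments(
    rng: np.random.Generator,
    tx: Transcriptome,
    libsize: int,
    dispersion: float,
    frag_len: tuple[int, int],
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Input (total RNA) fragments for one pooled library.

    Per-transcript fragment counts are negative binomial around
    libsize-proportional expectations (expression x length weights); fragment
    midpoints are uniform along the transcript. Returns the BED-like frame
    plus parallel arrays of transcript index and transcript-space midpoint.
    """
    models = tx.models
    lengths = np.array([m.length for m in models], dtype=float)
    expr = np.exp2(np.array([tx.base_log2_expr[m.transcript_id] for m in models]))
    w = expr * lengths
    means = libsize * w / w.sum()
    counts = _nb_counts(rng, means, dispersion)

    rows = {"chrom": [], "start": [], "end": [], "name": [], "score": [], "strand": []}
    tid_idx: list[np.ndarray] = []
    tx_mids: list[np.ndarray] = []
    for i, m in enumerate(models):
        c = int(counts[i])
        if c == 0:
            continue
        mids = rng.integers(0, m.length, size=c)
        flen = rng.integers(frag_len[0], frag_len[1] + 1, size=c)
        g_mid = _tx_positions_to_genomic(m, mids)
        rows["chrom"].extend([m.chrom] * c)
        rows["start"].extend(np.maximum(0, g_mid - flen // 2).tolist())
        rows["end"].extend((g_mid + (flen + 1) // 2).tolist())
        rows["name"].extend([m.transcript_id] * c)
        rows["score"].extend([0] * c)
        rows["strand"].extend([m.strand] * c)
        tid_idx.append(np.full(c, i))
        tx_mids.append(mids)
    return (
        pd.DataFrame(rows),
        np.concatenate(tid_idx) if tid_idx else np.array([], dtype=int),
        np.concatenate(tx_mids) if tx_mids else np.array([], dtype=int),
    )


def _sample_ip_fragments(
    rng: np.random.Generator,
    tx: Transcriptome,
    input_frags: pd.DataFrame,
    tid_idx: np.ndarray,
    tx_mids: np.ndarray,
    libsize: int,
    cohort_sites: dict[str, list[tuple[int, int]]],
    enrichment: float,
) -> pd.DataFrame:
    """IP fragments as a weighted resample of the input fragment pool.

    The immunoprecipitate draws from the same fragmented RNA pool as the
    input aliquot; fragments whose midpoint lies inside a methylated site of
    this cohort are drawn with ``enrichment``-fold weight. Coupling IP to the
    realized input pool makes the caller's Poisson test conditional on the
    input counts, so its FDR control is meaningful.
    """
    n = len(input_frags)
    weights = np.ones(n)
    ids = [m.transcript_id for m in tx.models]
    for i, tid in enumerate(ids):
        regions = cohort_sites.get(tid)
        if not regions:
            continue
        mask = tid_idx == i
        if not mask.any():
            continue
        mids = tx_mids[mask]
        in_site = np.zeros(mids.size, dtype=bool)
        for a, b in regions:
            in_site |= (mids >= a) & (mids < b)
        w = np.ones(mids.size)
        w[in_site] = enrichment
        weights[mask] = w
    idx = rng.choice(n, size=libsize, replace=True, p=weights / weights.sum())
    return input_frags.iloc[np.sort(idx)].reset_index(drop=True)


def transcript_windows(
    model: TranscriptModel, width: int = 50, step: int = 25
) -> list[tuple[int, int, GenomicInterval]]:
    """Sliding windows along the mature transcript, with genomic spans."""
    L = model.length
    if L < width:
        return [(0, L, transcript_span_to_genomic(0, L, model))]
    n_win = (L - width) // step + 1
    return [
        (j * step, j * step + width,
         transcript_span_to_genomic(j * step, j * step + width, model))
        for j in range(n_win)
    ]


def count_fragments_in_windows(
    ip_frags: pd.DataFrame,
    input_frags: pd.DataFrame,
    models: Sequence[TranscriptModel],
    width: int = 50,
    step: int = 25,
) -> list[WindowCounts]:
    """Count IP and input fragment midpoints in sliding transcript windows.

    Fragments are BED-like frames (chrom, start, end, strand); a fragment is
    assigned by its genomic midpoint to every window containing the midpoint's
    transcript-space projection.
    """
    def _index(frags: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
        mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
        out = {}
        for (chrom, strand), grp in frags.groupby(["chrom", "strand"], sort=False):
            out[(chrom, strand)] = np.sort(mids[grp.index.to_numpy()])
        return out

    ip_idx = _index(ip_frags.reset_index(drop=True))
    in_idx = _index(input_frags.reset_index(drop=True))
    windows: list[WindowCounts] = []
    for model in models:
        wins = transcript_windows(model, width, step)
        n_win = len(wins)
        counts = {}
        for label, idx in (("ip", ip_idx), ("input", in_idx)):
            acc = np.zeros(n_win, dtype=int)
            mids = idx.get((model.chrom, model.strand))
            if mids is not None:
                offset = 0
                for exon in model.exons:
                    lo = np.searchsorted(mids, exon.start, side="left")
                    hi = np.searchsorted(mids, exon.end, side="left")
                    g = mids[lo:hi]
                    if g.size:
                        if model.strand == "+":
                            pos = offset + (g - exon.start)
                        else:
                            pos = offset + (exon.end - 1 - g)
                        for d in range(-(-width // step)):  # windows per position
                            j = pos // step - d
                            valid = (j >= 0) & (j < n_win) & \
                                    (pos >= j * step) & (pos < j * step + width)
                            acc += np.bincount(j[valid], minlength=n_win)
                    offset += len(exon)
            counts[label] = acc
        for w_i, (ts, te, giv) in enumerate(wins):
            windows.append(
                WindowCounts(
                    window=giv,
                    ip_count=int(counts["ip"][w_i]),
                    input_count=int(counts["input"][w_i]),
                    transcript_id=model.transcript_id,
                    tx_start=ts,
                    tx_end=te,
                )
            )
    return windows


def simulate_merip_counts(
    cfg: SimulationConfig,
    tx: Transcriptome,
    window: int = 50,
    step: int = 25,
    return_fragments: bool = False,
):
    """Per-cohort window counts (and optionally fragment frames) + libsizes.

    Returns ``{cohort: (windows, ip_libsize, input_libsize)}``; with
    ``return_fragments`` each value also carries the IP and input fragment
    frames. Counts are pooled over the cohort's subjects, so the
    negative-binomial dispersion of the pooled library is the per-subject
    dispersion divided by the number of subjects.
    """
    rng = _rng_for(cfg, "merip")
    pooled_disp = cfg.nb_dispersion / cfg.n_subjects_per_group
    out = {}
    for cohort in ("young", "old"):
        cohort_sites: dict[str, list[tuple[int, int]]] = {}
        for s in tx.sites_for(cohort):
            cohort_sites.setdefault(s.transcript_id, []).append((s.tx_start, s.tx_end))
        inp, tid_idx, tx_mids = _sample_input_fragments(
            rng, tx, cfg.input_libsize, pooled_disp, cfg.fragment_length
        )
        ip = _sample_ip_fragments(
            rng, tx, inp, tid_idx, tx_mids, cfg.ip_libsize,
            cohort_sites, cfg.enrichment,
        )
        wc = count_fragments_in_windows(ip, inp, tx.models, window, step)
        if return_fragments:
            out[cohort] = (wc, len(ip), len(inp), ip, inp)
        else:
            out[cohort] = (wc, len(ip), len(inp))
    return out


def simulate_expression(
    cfg: SimulationConfig, tx: Transcriptome
) -> tuple[ExpressionTable, CohortDesign]:
    """Log-normal FPKM table with planted cohort shifts.

    Methylated genes (in either cohort) are shifted by ``meth_log2fc_shift``
    in the old group; the AGO2-like transcript is reduced further (-1 log2)
    and DICER1-like is reduced (-0.7) without methylation; DROSHA-like is
    unchanged.
    """
    rng = _rng_for(cfg, "expression")
    nsub = cfg.n_subjects_per_group
    young_ids = [f"Y{i + 1:02d}" for i in range(nsub)]
    old_ids = [f"O{i + 1:02d}" for i in range(nsub)]
    design = CohortDesign(
        pd.DataFrame(
            {
                "subject_id": young_ids + old_ids,
                "group": ["young"] * nsub + ["old"] * nsub,
                "age": np.concatenate(
                    [rng.integers(28, 33, nsub), rng.integers(62, 67, nsub)]
                ),
            }
        )
    )
    methylated = tx.methylated_genes("young") | tx.methylated_genes("old")
    genes = [m.transcript_id for m in tx.models]
    base = np.array([tx.base_log2_expr[g] for g in genes])
    old_shift = np.array(
        [
            -1.0 if g == "AGO2_like"
            else 0.0 if g == "DROSHA_like"
            else -0.7 if g == "DICER1_like"
            else (cfg.meth_log2fc_shift if g in methylated else 0.0)
            for g in genes
        ]
    )
    young = base[:, None] + rng.normal(0, cfg.subject_log2_sd, (len(genes), nsub))
    old = (base + old_shift)[:, None] + rng.normal(0, cfg.subject_log2_sd, (len(genes), nsub))
    values = pd.DataFrame(
        np.exp2(np.hstack([young, old])), index=genes, columns=young_ids + old_ids
    )
    return ExpressionTable(values, is_fpkm=True), design


def simulate_decay(cfg: SimulationConfig) -> list[DecaySeries]:
    """Ct series per condition/replicate under first-order decay.

    The target Ct rises by one cycle per half-life (2x loss of template);
    the reference (18S) Ct is constant; Gaussian Ct noise is added to every
    measurement.
    """
    rng = _rng_for(cfg, "decay")
    t = np.asarray(cfg.decay_timepoints, dtype=float)
    out = []
    for cond, t_half in cfg.decay_conditions.items():
        for rep in range(1, cfg.decay_replicates + 1):
            ct_ref = 12.0 + rng.normal(0, cfg.ct_noise_sd, t.size)
            ct_tgt = 22.0 + t / t_half + rng.normal(0, cfg.ct_noise_sd, t.size)
            out.append(DecaySeries(cond, f"rep{rep}", t, ct_tgt, ct_ref))
    return out


def simulate_mirna(cfg: SimulationConfig) -> tuple[MirnaMatrix, dict[str, str]]:
    """miRNA intensity matrix with planted up/down sets and truth labels.

    Intensities are log-normal (log10 base ~ N(mean, sd), per-subject noise);
    planted miRNAs get a +/- ``mirna_effect`` log10 shift in the old group.
    The let-7 subfamily contributes 12 detectable members of which 7 are in
    the planted down set.
    """
    rng = _rng_for(cfg, "mirna")
    n = cfg.n_mirna
    ids = LET7_IDS + [f"hsa-miR-{i:04d}" for i in range(n - len(LET7_IDS))]
    labels = {i: "null" for i in ids}
    non_let7 = ids[len(LET7_IDS):]
    down_let7 = LET7_IDS[:7]
    other_down = list(rng.choice(non_let7, size=cfg.n_mirna_down - 7, replace=False))
    remaining = [i for i in non_let7 if i not in set(other_down)]
    up = list(rng.choice(remaining, size=cfg.n_mirna_up, replace=False))
    for i in down_let7 + other_down:
        labels[i] = "down"
    for i in up:
        labels[i] = "up"

    nsub = cfg.n_subjects_per_group
    cols = [f"Y{i + 1:02d}" for i in range(nsub)] + [f"O{i + 1:02d}" for i in range(nsub)]
    base = rng.normal(cfg.mirna_base_mean, cfg.mirna_base_sd, n)
    shift = np.array(
        [cfg.mirna_effect if labels[i] == "up"
         else -cfg.mirna_effect if labels[i] == "down" else 0.0 for i in ids]
    )
    log_young = base[:, None] + rng.normal(0, cfg.mirna_subject_sd, (n, nsub))
    log_old = (base + shift)[:, None] + rng.normal(0, cfg.mirna_subject_sd, (n, nsub))
    values = pd.DataFrame(
        np.power(10.0, np.hstack([log_young, log_old])), index=ids, columns=cols
    )
    return MirnaMatrix(values), labels


# ---------------------------------------------------------------------------
# File emission (CLI / pipeline surface)
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def truth_registry(cfg: SimulationConfig, tx: Transcriptome,
                   mirna_labels: Optional[dict[str, str]] = None) -> dict:
    return {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "sites": [asdict(s) for s in tx.sites],
        "n_sites_young": len(tx.sites_for("young")),
        "n_sites_old": len(tx.sites_for("old")),
        "methylated_genes_young": sorted(tx.methylated_genes("young")),
        "methylated_genes_old": sorted(tx.methylated_genes("old")),
        "decay_t_half": dict(cfg.decay_conditions),
        "mirna_labels": mirna_labels or {},
    }


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Run every generator and write all pipeline inputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tx = simulate_transcriptome(cfg)
    write_fasta(tx.sequences, outdir / "transcripts.fa")
    write_bed12(tx.models, outdir / "transcripts.bed12")
    merip = simulate_merip_counts(cfg, tx, return_fragments=True)
    libsizes = {}
    for cohort, (_wc, n_ip, n_in, ip, inp) in merip.items():
        ip.to_csv(outdir / f"fragments_{cohort}_ip.bed", sep="\t",
                  header=False, index=False)
        inp.to_csv(outdir / f"fragments_{cohort}_input.bed", sep="\t",
                   header=False, index=False)
        libsizes[cohort] = {"ip": n_ip, "input": n_in}
    expr, design = simulate_expression(cfg, tx)
    expr.write_tsv(outdir / "expression_fpkm.tsv")
    design.write_tsv(outdir / "design.tsv")
    from .decay import write_decay_tsv

    write_decay_tsv(simulate_decay(cfg), outdir / "decay_ct.tsv")
    mirna, labels = simulate_mirna(cfg)
    mirna.write_tsv(outdir / "mirna_intensity.tsv")
    registry = truth_registry(cfg, tx, labels)
    registry["libsizes"] = libsizes
    with open(outdir / "truth.json", "w") as fh:
        json.dump(registry, fh, indent=1)
    return registry
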