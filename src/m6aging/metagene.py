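"""Metagene profiles: positional density of m6A sites along a normalized
transcript model and in fixed windows anchored at the start and stop codons."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel, genomic_to_transcript
from .sites import M6ASite

REGIONS = ("5'UTR", "CDS", "3'UTR")
DEFAULT_BINS = (20, 50, 30)


@dataclass
class MetageneProfile:
    """Pooled positional density of sites over coding transcripts.

    ``densities`` maps region name -> per-bin density; densities over all
    regions sum to 1 when at least one site maps. ``start_anchor`` and
    ``stop_anchor`` are per-nt site-midpoint counts in a +/- ``anchor_window``
    nt window centered on the start and stop codons (index 0 = -window nt).
    """

    densities: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    start_anchor: np.ndarray
    stop_anchor: np.ndarray
    anchor_window: int
    n_sites_used: int
    n_noncoding_skipped: int
    n_unmapped: int

    @property
    def is_empty(self) -> bool:
        return self.n_sites_used == 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in REGIONS:
            for i, (c, d) in enumerate(zip(self.counts[region], self.densities[region])):
                rows.append({"region": region, "bin": i, "count": int(c), "density": d})
        return pd.DataFrame(rows)


def _site_midpoint_tx(site: M6ASite, model: TranscriptModel) -> Optional[int]:
    """Transcript-space midpoint of a site, preferring stored tx coordinates."""
    if site.tx_start is not None and site.tx_end is not None:
        return (site.tx_start + site.tx_end) // 2
    proj = genomic_to_transcript(site.interval, model)
    if proj is None:
        return None
    return (proj[0] + proj[1]) // 2


def metagene_profile(
    sites: Sequence[M6ASite],
    models: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
    bins: tuple[int, int, int] = DEFAULT_BINS,
    anchor_window: int = 300,
) -> MetageneProfile:
    """Bin site midpoints into region-normalized 5'UTR/CDS/3'UTR densities.

    Each site's midpoint is projected to transcript space, assigned a region
    (the CDS is [cds_start, cds_end)), rescaled to its region's relative
    coordinate, and binned; densities are normalized to sum to 1 over all
    regions pooled. Sites on noncoding transcripts are skipped and counted.
    """
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    n5, nc, n3 = bins
    counts = {"5'UTR": np.zeros(n5), "CDS": np.zeros(nc), "3'UTR": np.zeros(n3)}
    start_anchor = np.zeros(2 * anchor_window)
    stop_anchor = np.zeros(2 * anchor_window)
    used = skipped = unmapped = 0

    for site in sites:
        model = models.get(site.transcript_id)
        if model is None:
            unmapped += 1
            continue
        if not model.is_coding:
            skipped += 1
            continue
        mid = _site_midpoint_tx(site, model)
        if mid is None or not 0 <= mid < model.length:
            unmapped += 1
            continue
        cs, ce, L = model.cds_start, model.cds_end, model.length
        if mid < cs:
            region, rel = "5'UTR", mid / cs
        elif mid < ce:
            region, rel = "CDS", (mid - cs) / (ce - cs)
        else:
            region, rel = "3'UTR", (mid - ce) / (L - ce)
        nb = len(counts[region])
        counts[region][min(int(rel * nb), nb - 1)] += 1
        used += 1
        for anchor, arr in ((cs, start_anchor), (ce, stop_anchor)):
            off = mid - anchor
            if -anchor_window <= off < anchor_window:
                arr[off + anchor_window] += 1

    total = sum(arr.sum() for arr in counts.values())
    densities = {
        r: (arr / total if total > 0 else arr.copy()) for r, arr in counts.items()
    }
    return MetageneProfile(
        densities=densities,
        counts=counts,
        start_anchor=start_anchor,
        stop_anchor=stop_anchor,
        anchor_window=anchor_window,
        n_sites_used=used,
        n_noncoding_skipped=skipped,
        n_unmapped=unmapped,
    )


def profile_uniformity_test(
    counts: np.ndarray, expected_weights: np.ndarray
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of bin counts against expected weights.

    ``expected_weights`` (e.g. nt width of each bin) are normalized to the
    observed total. Returns (chi2, p).
    """
    counts = np.asarray(counts, dtype=float)
    w = np.asarray(expected_weights, dtype=float)
    if counts.shape != w.shape:
        raise ValueError("counts and weights must align")
    expected = w / w.sum() * counts.sum()
    keep = expected > 0
    chi2, p = stats.chisquare(counts[keep], expected[keep])
    return float(chi2), float(p)


def region_bin_weights(
    models: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
    bins: tuple[int, int, int] = DEFAULT_BINS,
) -> dict[str, np.ndarray]:
    """Expected per-bin nt weights under uniform site placement.

    For pooled coding transcripts, a bin's weight is the summed nucleotide
    width it covers, so a uniform site distribution is uniform per nt, not
    per bin.
    """
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    n5, nc, n3 = bins
    weights = {"5'UTR": np.zeros(n5), "CDS": np.zeros(nc), "3'UTR": np.zeros(n3)}
    for m in models.values():
        if not m.is_coding:
            continue
        for region, nb, width in (
            ("5'UTR", n5, m.cds_start),
            ("CDS", nc, m.cds_end - m.cds_start),
            ("3'UTR", n3, m.length - m.cds_end),
        ):
            if width > 0:
                weights[region] += width / nb
    return weights
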