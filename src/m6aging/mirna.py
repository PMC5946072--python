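"""miRNA microarray differential expression with the Z-ratio statistic.

Raw fluorescence intensities are log10-transformed and z-scored within each
array (subject); each miRNA's group difference of mean z-scores is then
standardized by the SD of all per-miRNA differences (the NIA z-ratio
construction). A miRNA is called differentially expressed when it passes the
triple threshold: pairwise z-test p < .05, |Z ratio| > 1.5, and BH FDR < 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import CohortDesign

DEFAULT_THRESHOLDS = {"p": 0.05, "z_ratio": 1.5, "fdr": 0.3}


@dataclass
class MirnaMatrix:
    """miRNA x subject raw fluorescence intensities with a detectability mask."""

    intensities: pd.DataFrame
    detectable: Optional[pd.Series] = None  # per-miRNA boolean

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be >= 0")
        if self.detectable is None:
            self.detectable = pd.Series(True, index=self.intensities.index)

    @classmethod
    def read_tsv(cls, path) -> "MirnaMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.intensities.to_csv(path, sep="\t", index_label="mirna_id")


def detect_mirnas(
    m: MirnaMatrix, design: CohortDesign, floor: float = 1.0
) -> pd.Series:
    """Detectability call: intensity >= floor in >= half the subjects of
    either group."""
    x = m.intensities
    ok = pd.Series(False, index=x.index)
    for ids in (design.young, design.old):
        frac = (x[ids] >= floor).sum(axis=1) / len(ids)
        ok |= frac >= 0.5
    return ok


def zscore_normalize(m: MirnaMatrix) -> pd.DataFrame:
    """Per-array z-scores of log10(intensity + 1) over detectable miRNAs."""
    x = m.intensities.loc[m.detectable]
    if len(x) < 2:
        raise ValueError("need >= 2 detectable miRNAs per array")
    logged = np.log10(x + 1.0)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    if (sd <= 1e-12).any():  # exact zeros can round to ~1e-16
        raise ValueError("zero standard deviation in a column (constant array)")
    return (logged - mu) / sd


@dataclass
class ZRatioRecord:
    mirna_id: str
    mean_z_young: float
    mean_z_old: float
    z_ratio: float
    p: float
    fdr: float
    call: str  # up | down | unchanged


def z_ratio(
    z: pd.DataFrame,
    design: CohortDesign,
    p_threshold: float = DEFAULT_THRESHOLDS["p"],
    z_ratio_threshold: float = DEFAULT_THRESHOLDS["z_ratio"],
    fdr_threshold: float = DEFAULT_THRESHOLDS["fdr"],
) -> list[ZRatioRecord]:
    """Z-ratio differential expression, old vs. young.

    Per miRNA i: dz_i = mean_z(old) - mean_z(young);
    z_ratio_i = dz_i / sd({dz_j over all miRNAs}). The p-value is a two-sample
    z-test on the per-subject z-scores; BH FDR across miRNAs. A miRNA is
    called up iff p < p_threshold, z_ratio > z_ratio_threshold and
    fdr < fdr_threshold (down for z_ratio < -threshold), else unchanged.
    """
    young, old = design.young, design.old
    if len(young) < 2 or len(old) < 2:
        raise ValueError("both groups need >= 2 subjects")
    zy = z[young].to_numpy(dtype=float)
    zo = z[old].to_numpy(dtype=float)
    mean_y, mean_o = zy.mean(axis=1), zo.mean(axis=1)
    dz = mean_o - mean_y
    sd_dz = float(np.std(dz, ddof=1))
    if sd_dz == 0:
        zr = np.zeros_like(dz)
    else:
        zr = dz / sd_dz
    se = np.sqrt(zy.var(axis=1, ddof=1) / len(young) + zo.var(axis=1, ddof=1) / len(old))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_stat = np.where(se > 0, dz / se, np.where(dz == 0, 0.0, np.inf * np.sign(dz)))
    p = 2.0 * stats.norm.sf(np.abs(z_stat))
    _, fdr, _, _ = multipletests(p, method="fdr_bh")

    records = []
    for i, mid in enumerate(z.index):
        call = "unchanged"
        if p[i] < p_threshold and fdr[i] < fdr_threshold:
            if zr[i] > z_ratio_threshold:
                call = "up"
            elif zr[i] < -z_ratio_threshold:
                call = "down"
        records.append(
            ZRatioRecord(
                mirna_id=str(mid),
                mean_z_young=float(mean_y[i]),
                mean_z_old=float(mean_o[i]),
                z_ratio=float(zr[i]),
                p=float(p[i]),
                fdr=float(fdr[i]),
                call=call,
            )
        )
    return records


def records_frame(records: Sequence[ZRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def top_table(
    records: Sequence[ZRatioRecord], k: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k up- and down-called miRNAs ranked by |z_ratio| (ties by ID)."""
    if k < 1:
        raise ValueError("k must be >= 1")

    def pick(direction: str) -> pd.DataFrame:
        rows = [r for r in records if r.call == direction]
        rows.sort(key=lambda r: (-abs(r.z_ratio), r.mirna_id))
        return records_frame(rows[:k]) if rows else pd.DataFrame(
            columns=["mirna_id", "mean_z_young", "mean_z_old", "z_ratio",
                     "p", "fdr", "call"]
        )

    return pick("up"), pick("down")
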