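"""mRNA decay kinetics from actinomycin-D time courses.

Transcription is shut off with actinomycin D; remaining transcript abundance
is measured by RT-qPCR at timed intervals, normalized to a reference gene
(18S rRNA) and to the t=0 sample with the delta-delta-Ct method, and the
half-life t1/2 — the time for a transcript to reach 50% of its initial
abundance — is estimated from a first-order exponential decay model.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class DecaySeries:
    """One replicate's timed Ct measurements for a target and reference gene."""

    condition: str
    replicate: str
    timepoints: np.ndarray  # hours since actinomycin D; must include 0
    ct_target: np.ndarray
    ct_reference: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ct_target = np.asarray(self.ct_target, dtype=float)
        self.ct_reference = np.asarray(self.ct_reference, dtype=float)
        if not (self.timepoints.shape == self.ct_target.shape == self.ct_reference.shape):
            raise ValueError("timepoints/ct arrays must align")
        if self.timepoints[0] != 0:
            raise ValueError("timepoints must start at 0 (baseline sample)")
        if not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if not (np.isfinite(self.ct_target).all() and np.isfinite(self.ct_reference).all()):
            raise ValueError("Ct values must be finite")


@dataclass
class HalfLifeFit:
    """First-order decay fit. t_half = ln(2)/k when k > 0, else infinite."""

    t_half: float
    k: float
    r_squared: float
    n_points: int
    flag: str  # ok | no_decay | poor_fit

    POOR_FIT_R2 = 0.8


def relative_abundance(series: DecaySeries) -> np.ndarray:
    """Delta-delta-Ct relative abundance per timepoint; exactly 1 at t=0.

    dCt(t) = Ct_target(t) - Ct_reference(t); ddCt(t) = dCt(t) - dCt(0);
    abundance(t) = 2^(-ddCt(t)), assuming amplification efficiency 2.
    """
    dct = series.ct_target - series.ct_reference
    ddct = dct - dct[0]
    return np.power(2.0, -ddct)


def fit_half_life(
    timepoints: Sequence[float],
    abundance: Sequence[float],
    method: str = "loglinear",
) -> HalfLifeFit:
    """Estimate t1/2 from normalized abundance over time.

    ``loglinear`` (default): least-squares fit of ln(abundance) = -k*t with
    the intercept fixed at 0 (abundance(0) = 1 by construction of the
    delta-delta-Ct normalization); t_half = ln(2)/k. ``interpolate``: the
    literal first linear-interpolated crossing of abundance 0.5.
    """
    t = np.asarray(timepoints, dtype=float)
    a = np.asarray(abundance, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 timepoints")
    if np.any(a <= 0):
        raise ValueError("abundance must be > 0 (check upstream normalization)")

    log_a = np.log(a)
    denom = float(np.sum(t * t))
    k = float(-np.sum(t * log_a) / denom)
    resid = log_a - (-k * t)
    ss_tot = float(np.sum(log_a**2))  # uncentered: zero-intercept model
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    if method == "interpolate":
        t_half = _interpolated_crossing(t, a)
        if t_half is None:
            return HalfLifeFit(math.inf, k, r2, t.size, "no_decay")
        return HalfLifeFit(t_half, k, r2, t.size, "ok")
    if method != "loglinear":
        raise ValueError(f"unknown method {method!r}")

    if k <= 0:
        return HalfLifeFit(math.inf, k, r2, t.size, "no_decay")
    flag = "ok" if r2 >= HalfLifeFit.POOR_FIT_R2 else "poor_fit"
    return HalfLifeFit(math.log(2) / k, k, r2, t.size, flag)


def _interpolated_crossing(t: np.ndarray, a: np.ndarray) -> Optional[float]:
    for i in range(1, t.size):
        if a[i] <= 0.5 < a[i - 1]:
            # linear interpolation between the bracketing timepoints
            frac = (a[i - 1] - 0.5) / (a[i - 1] - a[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


def fit_series(series: DecaySeries, method: str = "loglinear") -> HalfLifeFit:
    """Convenience: delta-delta-Ct normalization then half-life fit."""
    return fit_half_life(series.timepoints, relative_abundance(series), method=method)


def compare_half_lives(
    fits: Sequence[tuple[str, str, HalfLifeFit]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize t1/2 per condition and Welch-test all condition pairs.

    ``fits`` holds (condition, replicate, fit) triples. Returns
    (summary, comparisons): per-condition mean/sd of replicate half-lives, and
    two-sided Welch t-test p-values for each condition pair (no multiplicity
    correction; each comparison is reported on its own). Conditions with a
    single replicate are summarized but excluded from testing.
    """
    by_cond: dict[str, list[float]] = {}
    for cond, _rep, fit in fits:
        by_cond.setdefault(cond, []).append(fit.t_half)
    summary = pd.DataFrame(
        [
            {
                "condition": c,
                "n_replicates": len(v),
                "mean_t_half": float(np.mean(v)),
                "sd_t_half": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
            }
            for c, v in by_cond.items()
        ]
    )
    rows = []
    for c1, c2 in itertools.combinations(sorted(by_cond), 2):
        v1, v2 = by_cond[c1], by_cond[c2]
        if len(v1) < 2 or len(v2) < 2:
            logger.warning("pair (%s, %s) skipped: need >= 2 replicates", c1, c2)
            continue
        if np.allclose(v1, np.mean(v1)) and np.allclose(v2, np.mean(v2)) \
                and np.isclose(np.mean(v1), np.mean(v2)):
            t_stat, p = 0.0, 1.0  # identical degenerate samples
        else:
            t_stat, p = stats.ttest_ind(v1, v2, equal_var=False)
        rows.append(
            {"condition_a": c1, "condition_b": c2,
             "t": float(t_stat), "p": float(p)}
        )
    return summary, pd.DataFrame(rows, columns=["condition_a", "condition_b", "t", "p"])


def read_decay_tsv(path) -> list[DecaySeries]:
    """Read a decay table (condition, replicate, time_h, ct_target, ct_reference)."""
    df = pd.read_csv(path, sep="\t", dtype={"condition": str, "replicate": str})
    out = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            DecaySeries(
                condition=cond,
                replicate=rep,
                timepoints=grp["time_h"].to_numpy(),
                ct_target=grp["ct_target"].to_numpy(),
                ct_reference=grp["ct_reference"].to_numpy(),
            )
        )
    return out


def write_decay_tsv(series: Sequence[DecaySeries], path) -> None:
    rows = []
    for s in series:
        for t, ct_t, ct_r in zip(s.timepoints, s.ct_target, s.ct_reference):
            rows.append(
                {"condition": s.condition, "replicate": s.replicate, "time_h": t,
                 "ct_target": ct_t, "ct_reference": ct_r}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
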