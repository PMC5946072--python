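"""Cohort expression comparison: log2 fold changes, ECDF curves, two-sample
Kolmogorov-Smirnov tests, and stratification by methylation status and
RNA-binding-protein (e.g. AUF1/HuR) target membership.

The central display is the empirical cumulative distribution function (ECDF)
of per-gene log2 fold changes (old over young), compared between strata with
the two-sample KS test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CohortDesign, ExpressionTable

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeRecord:
    """Per-gene cohort fold change with stratification flags."""

    gene_id: str
    mean_fpkm_young: float
    mean_fpkm_old: float
    log2fc: float
    methylated: bool = False
    target_sets: frozenset[str] = frozenset()


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison."""

    D: float
    p: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0 <= self.D <= 1:
            raise ValueError("D must be in [0, 1]")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


def log2_fold_changes(
    expr: ExpressionTable,
    design: CohortDesign,
    epsilon: float = 0.01,
    methylated: Optional[set[str]] = None,
    target_sets: Optional[Mapping[str, set[str]]] = None,
) -> list[FoldChangeRecord]:
    """Per-gene log2((mean_old + eps)/(mean_young + eps)) with strata flags.

    ``epsilon`` is a pseudo-FPKM keeping the ratio finite for unexpressed
    genes. ``methylated`` and ``target_sets`` (name -> gene set) fill the
    stratification flags.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    missing = (set(design.young) | set(design.old)) - set(expr.values.columns)
    if missing:
        raise ValueError(f"design subjects missing from expression table: {missing}")
    methylated = methylated or set()
    target_sets = target_sets or {}
    young = expr.values[design.young]
    old = expr.values[design.old]
    records = []
    for gene in expr.values.index:
        y, o = young.loc[gene], old.loc[gene]
        if y.isna().all() or o.isna().all():
            logger.info("gene %s has all-missing values in a group; excluded", gene)
            continue
        my, mo = float(y.mean()), float(o.mean())
        records.append(
            FoldChangeRecord(
                gene_id=str(gene),
                mean_fpkm_young=my,
                mean_fpkm_old=mo,
                log2fc=float(np.log2((mo + epsilon) / (my + epsilon))),
                methylated=gene in methylated,
                target_sets=frozenset(n for n, s in target_sets.items() if gene in s),
            )
        )
    return records


def ecdf_curve(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous ECDF step points (x, F(x)) at the sorted unique values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("ECDF needs at least one finite value")
    x = np.unique(arr)
    f = np.searchsorted(np.sort(arr), x, side="right") / arr.size
    return x, f


def ks_compare(a: Sequence[float], b: Sequence[float]) -> KSResult:
    """Two-sample KS test: exact sup-distance, asymptotic p-value.

    D is the exact supremum distance between the two ECDFs; the p-value comes
    from the asymptotic Kolmogorov distribution evaluated at
    sqrt(n1*n2/(n1+n2)) * D.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need >= 2 finite values")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / n1
    fb = np.searchsorted(b, grid, side="right") / n2
    d = float(np.max(np.abs(fa - fb)))
    en = n1 * n2 / (n1 + n2)
    p = float(np.clip(stats.kstwobign.sf(np.sqrt(en) * d), 0.0, 1.0))
    return KSResult(D=d, p=p, n1=n1, n2=n2)


@dataclass
class StratifiedCDFReport:
    """Per-stratum ECDFs plus pairwise KS comparisons of log2 fold changes."""

    ecdfs: dict[str, tuple[np.ndarray, np.ndarray]]
    sizes: dict[str, int]
    ks: dict[tuple[str, str], KSResult]
    skipped_pairs: list[tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum_a": a, "stratum_b": b, "n_a": self.sizes[a],
             "n_b": self.sizes[b], "D": r.D, "p": r.p}
            for (a, b), r in self.ks.items()
        ]
        return pd.DataFrame(rows)


def stratified_cdf_report(
    records: Sequence[FoldChangeRecord],
    strata: Mapping[str, Callable[[FoldChangeRecord], bool]],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> StratifiedCDFReport:
    """ECDF of log2fc per stratum and KS test for each requested pair.

    ``strata`` maps stratum name to a predicate over records; predicates may
    overlap. By default all unordered pairs of strata are compared. Strata
    with < 2 members cause their pairs to be skipped with a warning.
    """
    values = {
        name: np.array([r.log2fc for r in records if pred(r)])
        for name, pred in strata.items()
    }
    sizes = {name: int(v.size) for name, v in values.items()}
    ecdfs = {name: ecdf_curve(v) for name, v in values.items() if v.size > 0}
    if pairs is None:
        pairs = list(itertools.combinations(strata.keys(), 2))
    ks: dict[tuple[str, str], KSResult] = {}
    skipped = []
    for a, b in pairs:
        if sizes.get(a, 0) < 2 or sizes.get(b, 0) < 2:
            logger.warning("stratum pair (%s, %s) skipped: <2 members", a, b)
            skipped.append((a, b))
            continue
        ks[(a, b)] = ks_compare(values[a], values[b])
    return StratifiedCDFReport(ecdfs=ecdfs, sizes=sizes, ks=ks, skipped_pairs=skipped)


def methylation_expression_scatter(
    m6a_fpkm: Mapping[str, float], total_fpkm: Mapping[str, float]
) -> tuple[pd.DataFrame, float, float]:
    """Pair per-gene m6A FPKM with total-RNA FPKM; Spearman rank correlation.

    Returns (paired table, rho, p). With a constant margin rho is undefined
    and returned as NaN.
    """
    genes = sorted(set(m6a_fpkm) & set(total_fpkm))
    if len(genes) < 3:
        raise ValueError("need >= 3 shared genes")
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "m6a_fpkm": [m6a_fpkm[g] for g in genes],
            "total_fpkm": [total_fpkm[g] for g in genes],
        }
    )
    x, y = table["m6a_fpkm"].to_numpy(), table["total_fpkm"].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("degenerate (constant) input: Spearman rho undefined")
        return table, float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return table, float(rho), float(p)


def groupwise_t_tests(
    expr: ExpressionTable, design: CohortDesign
) -> pd.DataFrame:
    """Per-gene two-sided Welch t-test between the young and old cohorts."""
    young = expr.values[design.young].to_numpy(dtype=float)
    old = expr.values[design.old].to_numpy(dtype=float)
    t, p = stats.ttest_ind(old, young, axis=1, equal_var=False)
    return pd.DataFrame(
        {
            "gene_id": expr.values.index,
            "mean_young": young.mean(axis=1),
            "mean_old": old.mean(axis=1),
            "t": t,
            "p": p,
        }
    ).set_index("gene_id")
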