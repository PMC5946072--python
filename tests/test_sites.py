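import math
import re

import numpy as np
import pytest

from m6aging.annotation import GenomicInterval, TranscriptModel
from m6aging.sites import (
    M6ASite,
    WindowCounts,
    assign_motifs,
    call_m6a_sites,
    classify_motif,
    compute_fpkm,
    merip_qpcr_enrichment,
    overlap_sites,
    tally_by_biotype,
    tally_by_motif,
)


def motif_class_oracle(seq):
    """Independent regex-scan oracle: count occurrences of each motif, then
    pick the longest motif with any occurrence."""
    seq = seq.upper().replace("T", "U")
    hits = {m: len(re.findall(f"(?={m})", seq)) for m in ("GGACU", "GACU", "ACU", "GAC")}
    for m in sorted(hits, key=len, reverse=True):
        if hits[m] > 0:
            return m
    return "none"


class TestClassifyMotif:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAGGACUAA", "GGACU"),
            ("AAGACUAA", "GACU"),
            ("AAACUAA", "ACU"),
            ("AAGACAA", "GAC"),
            ("UUUUU", "none"),
            ("", "none"),
            ("aaggacuaa", "GGACU"),     # case-insensitive
            ("AAGGACTAA", "GGACU"),     # DNA input: T -> U
        ],
    )
    def test_examples(self, seq, expected):
        assert classify_motif(seq) == expected

    def test_hierarchy_nesting(self):
        # any GGACU-classified sequence also contains GACU and ACU
        seq = "CCGGACUCC"
        assert classify_motif(seq) == "GGACU"
        assert "GACU" in seq.replace("T", "U") and "ACU" in seq

    def test_agrees_with_regex_oracle(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(300):
            seq = "".join(rng.choice(bases, size=60))
            assert classify_motif(seq) == motif_class_oracle(seq)


def poisson_tail_oracle(k, mu):
    """P(X >= k) via direct log-pmf summation (independent of scipy)."""
    total = 0.0
    for i in range(int(k)):
        total += math.exp(-mu + i * math.log(mu) - math.lgamma(i + 1))
    return 1.0 - total


def _windows(pairs, chrom="chr1", width=50):
    return [
        WindowCounts(
            window=GenomicInterval(chrom, i * 25, i * 25 + width),
            ip_count=ip, input_count=inp, transcript_id="t1",
            tx_start=i * 25, tx_end=i * 25 + width,
        )
        for i, (ip, inp) in enumerate(pairs)
    ]


class TestCallSites:
    def test_strongly_enriched_window_called(self):
        wins = _windows([(100, 10)] + [(10, 10)] * 20)
        sites = call_m6a_sites(wins, 10_000, 10_000, q_threshold=0.05, pseudocount=0.5)
        assert len(sites) == 1
        site = sites[0]
        assert site.enrichment == pytest.approx(100.5 / 10.5)
        # one-sided Poisson tail against mu = 10 * 1 + 0.5, checked vs an
        # independent summation oracle
        assert poisson_tail_oracle(100, 10.5) < 1e-10
        assert site.qvalue < 1e-9

    def test_equal_counts_yield_no_sites(self):
        wins = _windows([(7, 7)] * 30)
        assert call_m6a_sites(wins, 1000, 1000) == []

    def test_all_zero_counts_yield_no_sites(self):
        wins = _windows([(0, 0)] * 30)
        assert call_m6a_sites(wins, 1000, 1000) == []

    def test_empty_input(self):
        assert call_m6a_sites([], 1000, 1000) == []

    def test_zero_libsize_rejected(self):
        with pytest.raises(ValueError):
            call_m6a_sites(_windows([(1, 1)]), 0, 1000)

    def test_monotone_in_q_threshold(self, rng):
        # one window per transcript: no merging, so the site count equals the
        # number of retained windows and is monotone in the threshold
        wins = [
            WindowCounts(
                window=GenomicInterval("chr1", i * 1000, i * 1000 + 50),
                ip_count=int(ip), input_count=int(inp),
                transcript_id=f"t{i}", tx_start=0, tx_end=50,
            )
            for i, (ip, inp) in enumerate(
                zip(rng.poisson(30, 200), rng.poisson(10, 200)))
        ]
        counts = [len(call_m6a_sites(wins, 5000, 5000, q_threshold=q))
                  for q in (1e-6, 0.01, 0.05, 0.5, 0.999)]
        assert counts == sorted(counts)

    def test_adjacent_significant_windows_merge(self):
        wins = _windows([(200, 5), (200, 5), (200, 5), (5, 5), (5, 5)])
        sites = call_m6a_sites(wins, 10_000, 10_000)
        assert len(sites) == 1
        assert (sites[0].tx_start, sites[0].tx_end) == (0, 100)
        assert sites[0].fragment_count == 200  # max-window counts

    def test_merged_sites_never_overlap(self, rng):
        pairs = [(int(x), 5) for x in rng.choice([5, 300], size=100, p=[0.7, 0.3])]
        sites = call_m6a_sites(_windows(pairs), 10_000, 10_000)
        sites = sorted(sites, key=lambda s: s.tx_start)
        for a, b in zip(sites, sites[1:]):
            assert a.tx_end <= b.tx_start

    def test_assign_motifs_from_sequence(self):
        wins = _windows([(200, 5), (5, 5)])
        sites = call_m6a_sites(wins, 10_000, 10_000)
        seq = "U" * 20 + "GGACU" + "U" * 100
        (site,) = assign_motifs(sites, {"t1": seq})
        assert site.motif_class == "GGACU"


class TestFpkm:
    def test_closed_form(self):
        assert compute_fpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_zero_count(self):
        assert compute_fpkm(0, 500, 10**6) == 0.0

    def test_scale_invariance(self):
        assert compute_fpkm(10, 1000, 10**6) == pytest.approx(
            compute_fpkm(20, 1000, 2 * 10**6))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_fpkm(1, 0, 100)
        with pytest.raises(ValueError):
            compute_fpkm(1, 100, 0)


def _site(chrom, start, end, strand="+", tid="t"):
    return M6ASite(interval=GenomicInterval(chrom, start, end, strand),
                   transcript_id=tid)


class TestOverlap:
    def test_one_nt_overlap_is_shared(self):
        res = overlap_sites([_site("chr1", 100, 150)], [_site("chr1", 149, 190)])
        assert res.counts() == {"a_only": 0, "shared_a": 1, "shared_b": 1, "b_only": 0}

    def test_half_open_abutting_not_shared(self):
        res = overlap_sites([_site("chr1", 100, 150)], [_site("chr1", 150, 200)])
        assert res.counts() == {"a_only": 1, "shared_a": 0, "shared_b": 0, "b_only": 1}

    def test_strand_and_chrom_must_match(self):
        res = overlap_sites([_site("chr1", 100, 150)],
                            [_site("chr1", 100, 150, strand="-"),
                             _site("chr2", 100, 150)])
        assert res.counts()["shared_a"] == 0

    def test_symmetry_and_invariants(self, rng):
        def random_sites(n):
            return [
                _site(f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(30, 120)),
                      "+" if rng.random() < 0.5 else "-")
                for s in rng.integers(0, 3000, size=n)
            ]

        a, b = random_sites(80), random_sites(80)
        res = overlap_sites(a, b)
        flipped = overlap_sites(b, a)
        assert len(res.a_only) + len(res.shared_a) == len(a)
        assert len(res.b_only) + len(res.shared_b) == len(b)
        assert res.counts()["shared_a"] == flipped.counts()["shared_b"]
        # O(n^2) oracle on the per-site overlap flags
        for s in a:
            expected = any(s.interval.overlaps(t.interval) for t in b)
            assert (s in res.shared_a) == expected


class TestTallies:
    def _models(self):
        def mk(tid, biotype):
            return TranscriptModel(tid, tid, biotype,
                                   [GenomicInterval("chr1", 0, 100)])
        return {
            "c1": mk("c1", "protein_coding"), "c2": mk("c2", "protein_coding"),
            "l1": mk("l1", "lncRNA"),
        }

    def test_biotype_counts(self):
        sites = [_site("chr1", 0, 10, tid=t) for t in ("c1", "c1", "c2", "l1", "zz")]
        counts = tally_by_biotype(sites, self._models())
        assert counts["protein_coding"] == 3
        assert counts["lncRNA"] == 1
        assert counts["unknown"] == 1

    def test_empty_sites(self):
        counts = tally_by_biotype([], self._models())
        assert sum(counts.values()) == 0

    def test_random_assignment_matches_groupby_oracle(self, rng):
        import pandas as pd

        models = self._models()
        tids = list(models) + ["??"]
        sites = [_site("chr1", 0, 10, tid=str(t))
                 for t in rng.choice(tids, size=500)]
        counts = tally_by_biotype(sites, models)
        oracle = pd.Series(
            [models[s.transcript_id].biotype if s.transcript_id in models
             else "unknown" for s in sites]).value_counts().to_dict()
        for k, v in oracle.items():
            assert counts[k] == v

    def test_motif_proportions(self):
        sites = [M6ASite(interval=GenomicInterval("chr1", 0, 10),
                         transcript_id="t", motif_class=m)
                 for m in ["GGACU", "GGACU", "GACU", "ACU"]]
        df = tally_by_motif(sites).set_index("motif_class")
        assert df.loc["GGACU", "proportion"] == pytest.approx(0.5)
        assert df.loc["GACU", "proportion"] == pytest.approx(0.25)
        assert df[df.index != "none"]["proportion"].sum() == pytest.approx(1.0)

    def test_single_class(self):
        sites = [M6ASite(interval=GenomicInterval("chr1", 0, 10),
                         transcript_id="t", motif_class="GAC")]
        df = tally_by_motif(sites).set_index("motif_class")
        assert df.loc["GAC", "proportion"] == pytest.approx(1.0)


class TestQpcrEnrichment:
    def test_fold_over_control(self):
        assert merip_qpcr_enrichment(8, 1, 1, 1) == pytest.approx(8.0)

    def test_no_enrichment(self):
        assert merip_qpcr_enrichment(3, 6, 1, 2) == pytest.approx(1.0)

    def test_composes_with_delta_ct_quantities(self):
        # quantities from 2^-Ct compose into plain exponent arithmetic
        ct = {"ip": 20.0, "inp": 23.0, "cip": 25.0, "cinp": 25.5}
        q = {k: 2.0 ** -v for k, v in ct.items()}
        expected = 2.0 ** (-(ct["ip"] - ct["inp"]) + (ct["cip"] - ct["cinp"]))
        assert merip_qpcr_enrichment(q["ip"], q["inp"], q["cip"], q["cinp"]) \
            == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            merip_qpcr_enrichment(0, 1, 1, 1)
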