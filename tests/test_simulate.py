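import numpy as np
import pytest

import m6aging as m
from m6aging.decay import fit_series
from m6aging.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_decay,
    simulate_expression,
    simulate_merip_counts,
    simulate_mirna,
    simulate_transcriptome,
)


def small_cfg(**overrides):
    """Reduced problem size for fast unit tests; structure unchanged."""
    defaults = dict(
        seed=11, n_transcripts=60, n_sites_young=30,
        ip_libsize=40_000, input_libsize=40_000,
        n_mirna=100, n_mirna_up=25, n_mirna_down=12,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestTranscriptome:
    def test_seed_determinism_byte_identical(self, tmp_path):
        from m6aging.simulate import write_fasta

        seqs = []
        for run in range(2):
            tx = simulate_transcriptome(small_cfg())
            p = tmp_path / f"run{run}.fa"
            write_fasta(tx.sequences, p)
            seqs.append(p.read_bytes())
        assert seqs[0] == seqs[1]

    def test_different_seeds_differ(self):
        t1 = simulate_transcriptome(small_cfg(seed=1))
        t2 = simulate_transcriptome(small_cfg(seed=2))
        assert t1.sequences != t2.sequences

    def test_planted_sites_contain_their_motif(self):
        tx = simulate_transcriptome(small_cfg())
        for s in tx.sites:
            seq = tx.sequences[s.transcript_id][s.tx_start:s.tx_end]
            assert s.motif in seq

    def test_all_coding_when_fraction_one(self):
        tx = simulate_transcriptome(small_cfg(fraction_coding=1.0))
        assert all(mdl.biotype == "protein_coding" for mdl in tx.models)

    def test_focal_transcript_contrasts(self):
        tx = simulate_transcriptome(small_cfg())
        young = tx.methylated_genes("young")
        old = tx.methylated_genes("old")
        assert "AGO2_like" in young and "AGO2_like" not in old
        assert "DROSHA_like" in young and "DROSHA_like" in old
        assert "DICER1_like" not in young and "DICER1_like" not in old

    def test_cohort_effect_zero_gives_identical_site_sets(self):
        tx = simulate_transcriptome(small_cfg(cohort_effect=0.0))
        ids_young = {s.site_id for s in tx.sites_for("young")}
        ids_old = {s.site_id for s in tx.sites_for("old")}
        assert ids_young == ids_old

    def test_young_has_more_sites_than_old_by_default(self):
        tx = simulate_transcriptome(small_cfg())
        assert len(tx.sites_for("young")) > len(tx.sites_for("old"))


class TestMeripCounts:
    def test_caller_recovers_planted_sites_at_reduced_scale(self):
        cfg = small_cfg()
        tx = simulate_transcriptome(cfg)
        (wc, n_ip, n_in) = simulate_merip_counts(cfg, tx)["young"]
        called = m.call_m6a_sites(wc, n_ip, n_in)
        by_tid = {}
        for s in called:
            by_tid.setdefault(s.transcript_id, []).append((s.tx_start, s.tx_end))
        truth = tx.sites_for("young")
        recovered = sum(
            any(a < s.tx_end and s.tx_start < b
                for a, b in by_tid.get(s.transcript_id, []))
            for s in truth
        )
        assert recovered / len(truth) >= 0.8

    def test_unit_enrichment_yields_no_calls(self):
        cfg = small_cfg(enrichment=1.0)
        tx = simulate_transcriptome(cfg)
        (wc, n_ip, n_in) = simulate_merip_counts(cfg, tx)["young"]
        called = m.call_m6a_sites(wc, n_ip, n_in)
        assert len(called) <= max(2, 0.001 * len(wc))

    def test_windows_share_width_and_counts_nonnegative(self):
        cfg = small_cfg()
        tx = simulate_transcriptome(cfg)
        (wc, _, _) = simulate_merip_counts(cfg, tx)["old"]
        widths = {w.tx_end - w.tx_start for w in wc}
        assert widths == {50}
        assert all(w.ip_count >= 0 and w.input_count >= 0 for w in wc)


class TestExpression:
    def test_table_matches_design_and_models(self):
        cfg = small_cfg()
        tx = simulate_transcriptome(cfg)
        expr, design = simulate_expression(cfg, tx)
        assert set(expr.values.columns) == set(design.young + design.old)
        assert len(design.young) == cfg.n_subjects_per_group
        assert set(expr.values.index) == {mdl.transcript_id for mdl in tx.models}

    def test_planted_shift_detected_by_ks(self):
        cfg = SimulationConfig(seed=5, n_transcripts=800, n_sites_young=250,
                               ip_libsize=1000, input_libsize=1000)
        tx = simulate_transcriptome(cfg)
        expr, design = simulate_expression(cfg, tx)
        meth = tx.methylated_genes("young") | tx.methylated_genes("old")
        recs = m.log2_fold_changes(expr, design, methylated=meth)
        rep = m.stratified_cdf_report(recs, {
            "methylated": lambda r: r.methylated,
            "rest": lambda r: not r.methylated})
        assert rep.ks[("methylated", "rest")].p < 0.05

    def test_no_shift_is_null(self):
        cfg = small_cfg(meth_log2fc_shift=0.0)
        tx = simulate_transcriptome(cfg)
        # focal transcripts keep their own planted shifts; exclude them
        expr, design = simulate_expression(cfg, tx)
        meth = (tx.methylated_genes("young") | tx.methylated_genes("old")) \
            - {"AGO2_like", "DROSHA_like", "DICER1_like"}
        recs = [r for r in m.log2_fold_changes(expr, design, methylated=meth)
                if r.gene_id not in ("AGO2_like", "DICER1_like")]
        rep = m.stratified_cdf_report(recs, {
            "methylated": lambda r: r.methylated,
            "rest": lambda r: not r.methylated})
        assert rep.ks[("methylated", "rest")].p > 0.05


class TestDecaySim:
    def test_noiseless_roundtrip_exact(self):
        cfg = small_cfg(ct_noise_sd=0.0)
        for s in simulate_decay(cfg):
            fit = fit_series(s)
            truth = cfg.decay_conditions[s.condition]
            assert fit.t_half == pytest.approx(truth, rel=1e-9)

    def test_condition_ordering_recovered(self):
        cfg = small_cfg()  # default Ct noise 0.1, triplicates
        fits = [(s.condition, s.replicate, fit_series(s))
                for s in simulate_decay(cfg)]
        summary, _ = m.compare_half_lives(fits)
        est = dict(zip(summary["condition"], summary["mean_t_half"]))
        assert est["empty_vector"] < est["METTL14_OE"] < est["METTL3_OE"]

    def test_timepoint_scaling_equivariance(self):
        cfg = small_cfg(ct_noise_sd=0.0)
        doubled = small_cfg(ct_noise_sd=0.0,
                            decay_timepoints=(0.0, 4.0, 8.0, 16.0))
        f1 = fit_series(simulate_decay(cfg)[0])
        s2 = simulate_decay(doubled)[0]
        # same scenario sampled on a 2x grid still recovers the true value
        assert fit_series(s2).t_half == pytest.approx(f1.t_half, rel=1e-9)


class TestMirnaSim:
    def test_zero_effect_all_null(self):
        _, labels = simulate_mirna(small_cfg(n_mirna_up=0, n_mirna_down=7))
        # only the forced let-7 subset remains planted when n_up=0
        assert all(v in ("null", "down") for v in labels.values())

    def test_label_counts_match_config(self):
        cfg = small_cfg()
        _, labels = simulate_mirna(cfg)
        vals = list(labels.values())
        assert vals.count("up") == cfg.n_mirna_up
        assert vals.count("down") == cfg.n_mirna_down

    def test_let7_subfamily_planted(self):
        _, labels = simulate_mirna(small_cfg())
        let7 = [k for k in labels if "let-7" in k or k == "hsa-miR-98"]
        assert len(let7) == 12
        assert sum(labels[k] == "down" for k in let7) == 7

    def test_seed_reproducibility(self):
        m1, _ = simulate_mirna(small_cfg())
        m2, _ = simulate_mirna(small_cfg())
        assert m1.intensities.equals(m2.intensities)


def test_simulate_all_outputs_feed_every_module(tmp_path):
    cfg = small_cfg()
    registry = simulate_all(cfg, tmp_path)
    # all declared inputs exist and parse with the package's own readers
    models = m.read_transcript_models(tmp_path / "transcripts.bed12", "bed12")
    assert len(models) == cfg.n_transcripts
    from m6aging.annotation import CohortDesign, ExpressionTable
    from m6aging.decay import read_decay_tsv
    from m6aging.mirna import MirnaMatrix
    from m6aging.pipeline import read_fragments_bed

    expr = ExpressionTable.read_tsv(tmp_path / "expression_fpkm.tsv")
    design = CohortDesign.read_tsv(tmp_path / "design.tsv")
    assert set(expr.values.columns) >= set(design.young)
    assert len(read_decay_tsv(tmp_path / "decay_ct.tsv")) == 9
    assert MirnaMatrix.read_tsv(tmp_path / "mirna_intensity.tsv") \
        .intensities.shape[0] == cfg.n_mirna
    frags = read_fragments_bed(tmp_path / "fragments_young_ip.bed")
    assert (frags["end"] > frags["start"]).all()
    assert registry["n_sites_young"] == cfg.n_sites_young
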