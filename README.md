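# m6aging

Analysis pipeline for N6-methyladenosine (m6A) epitranscriptomic profiling of
young versus old cohorts, as measured by MeRIP-seq (methylated-RNA
immunoprecipitation) together with total-RNA expression, RT-qPCR decay assays
and miRNA microarrays. It is aimed at researchers studying age-dependent mRNA
methylation and stability — e.g. how loss of m6A on an *AGO2*-like transcript
destabilizes it in older subjects and perturbs mature miRNA abundance.

Because studies of this design frequently deposit no raw data, the package
ships a first-class synthetic-data generator that emulates the study's inputs
(two cohorts of n = 11 subjects, ~1,000 methylated 100–200 nt fragments in the
young cohort with ~75% shared with old, planted focal transcripts), so every
stage is testable end to end against a machine-readable truth registry.

## What it computes

- **m6A site calling** — IP vs. input fragment counts in 50-nt sliding windows
  (step 25) along each transcript; per window the enrichment
  `((ip+c)/N_ip) / ((input+c)/N_input)` and a one-sided Poisson test of the IP
  count against the library-size-scaled input expectation; Benjamini–Hochberg
  FDR ≤ 0.05; significant windows merged into sites.
- **Motif classes** — each site is assigned one of the nested DRACH-derived
  classes by longest-match priority: GGACU ≻ GACU ≻ ACU ≻ GAC; tallies by
  class and by transcript biotype; young/old site overlap (≥ 1 nt,
  half-open intervals).
- **Metagene profiles** — site midpoints projected to transcript space and
  binned over 5'UTR/CDS/3'UTR (20/50/30 bins) plus ±300 nt windows anchored
  at the start and stop codons.
- **Expression CDFs** — per-gene log2((old+ε)/(young+ε)) fold changes,
  empirical CDFs per stratum (methylated vs. rest, RBP-target subsets), and
  two-sample Kolmogorov–Smirnov tests
  (exact D, asymptotic p at effective n = n₁n₂/(n₁+n₂)).
- **mRNA half-life** — ΔΔCt relative abundance `2^-(ΔCt(t)-ΔCt(0))` from
  actinomycin-D time courses, zero-intercept log-linear fit of
  ln A(t) = −kt, t½ = ln2/k, and Welch tests between conditions.
- **miRNA Z-ratios** — per-array z-scores of log10 intensity; per-miRNA
  Z ratio = Δz̄ / SD(all Δz̄); calls require pairwise z-test p < .05,
  |Z ratio| > 1.5 and FDR < 0.3.

## Worked example

```bash
m6a run --outdir demo --seed 1
cat demo/summary/summary.json
```

prints (abridged):

```json
{
 "n_sites_young": 879,
 "n_sites_old": 714,
 "fewer_sites_in_old": true,
 "overlap": {"a_only": 216, "shared_a": 663, "shared_b": 664, "b_only": 50},
 "ks_methylated_vs_rest": {"D": 0.719, "p": 5.06e-131},
 "t_half_by_condition": {"empty_vector": 5.29, "METTL3_OE": 11.85, "METTL14_OE": 9.52},
 "mirna_calls": {"down": 88, "unchanged": 795, "up": 3}
}
```

Reading: the caller recovered the planted site sets of both cohorts (879
called young sites for 1,000 planted — adjacent planted sites can merge into
one called site — and fewer sites in the old cohort, most shared); the
methylated genes' old/young fold-change distribution is strongly shifted
relative to unmethylated genes (KS); overexpressing the METTL3/METTL14
methyltransferases prolongs the *AGO2*-like transcript's half-life from ~5 h
to ~9–12 h (planted truth 4.9 → 9.5 / 7.1 h); and the miRNA stage calls the
planted down-set. Every stage is also available as its own subcommand
(`m6a simulate|call|overlap|tally|metagene|cdf|decay|mirna`) operating on
plain BED/FASTA/TSV files, and as library functions.

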