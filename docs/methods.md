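# Methods

## Scope and data model

The pipeline consumes aligned artifacts, not reads: transcript models (BED12
or GTF), transcript sequences (FASTA), fragment intervals per IP/input
library (BED), expression tables (TSV), qPCR Ct tables (TSV) and miRNA
intensity matrices (TSV). Coordinates are 0-based half-open throughout; GTF
is converted on read. Transcript-space coordinates count nucleotides from the
5' end of the mature transcript, so all strand logic is resolved once, at
projection time (`genomic_to_transcript`). Annotation biotypes are collapsed
to four classes (protein_coding, lncRNA, pseudogene, other_noncoding);
unrecognized labels fall into the last class with a logged warning. Analyses
run per transcript_id; in the synthetic data each gene has one isoform, and
for multi-isoform annotations the gene-level rollup takes the longest
isoform, the common metagene convention.

## m6A site calling

MeRIP enrichment is tested in 50-nt windows sliding by 25 nt along each
transcript. A fragment is assigned to every window containing the
transcript-space projection of its genomic midpoint; midpoint assignment
avoids length-weighting by the 100–200 nt fragment size. Per window with IP
count x and input count y,

- enrichment = ((x+c)/N_ip) / ((y+c)/N_input), pseudocount c = 0.5,
- p = P(Poisson(y·N_ip/N_input + c) ≥ x), one-sided,

with Benjamini–Hochberg correction across all windows of the run. Windows
with q ≤ 0.05 and enrichment > 1 are kept; overlapping or abutting
significant windows on one transcript merge into a site that carries its
best window's counts (so the per-site fragment count stays interpretable)
and the minimum q of its windows. The test conditions on the observed input
count; it is exact when the IP library is a (weighted) resample of the same
fragment pool as the input — which is how the generator produces IP
libraries, and approximately how immunoprecipitation works. No peak-calling
method is prescribed by the study design this emulates; this is the simplest
defensible IP-vs-input model and all knobs (window, step, q, pseudocount)
are configuration.

Motif classes GGACU/GACU/ACU/GAC are nested substrings, so naive counting
would double-count; longest-match priority makes the classes mutually
exclusive and deterministic (case-insensitive, T mapped to U). FPKM is
count·10⁹/(length·libsize); methylated-fragment FPKM uses the IP library
size as denominator, total-RNA FPKM the input/total library — the choice of
denominator is not dictated by the design, so both are reported per site.

Cohort overlap declares a site shared when it intersects ≥ 1 nt of any site
of the other cohort on the same chrom/strand (half-open). Because merged
sites within one cohort never overlap, sharing is one-to-one in practice;
both sides' shared lists are reported, and the Venn identities
(young_only + shared = total young, old_only + shared = total old) each hold
with their own side's shared count.

## Metagene profile

Site midpoints are binned into 20/50/30 bins over 5'UTR/[cds_start,
cds_end)/3'UTR after rescaling each region to unit length; densities are
pooled over transcripts and normalized to sum to 1 across all bins. Pooled
normalization (rather than per-transcript) is used since the anchored view
covers the alternative: raw per-nt midpoint counts in ±300 nt windows at the
start and stop codons. A chi-square utility compares bin counts against
nt-width expected weights, so a uniform-per-nt site distribution is the null
despite unequal region lengths.

## Cohort expression comparison

Per gene, log2((mean_old+ε)/(mean_young+ε)) with pseudo-FPKM ε = 0.01 keeps
zero-expression genes finite. Strata are predicates over fold-change
records — "methylated" means the gene owns ≥ 1 called site in either
cohort's set by default (a configuration choice; the gene-level mapping is
not otherwise determined) — and every stratum pair gets a two-sample KS
test: exact sup-distance between the ECDFs, asymptotic Kolmogorov p at
effective n = n₁n₂/(n₁+n₂). Asymptotic rather than exact small-sample
p-values: gene-level CDFs here have hundreds to thousands of points. The
null rejection rate at α = .05 measures 0.049 (1,000 simulations, n =
200/group) in the acceptance run. Per-gene between-cohort t-tests use
Welch's unequal-variance form. Spearman rank correlation pairs per-gene m6A
FPKM with total-RNA abundance; a constant margin is flagged (rho = NaN)
rather than raised.

## Decay kinetics

ΔCt(t) = Ct_target − Ct_reference, ΔΔCt(t) = ΔCt(t) − ΔCt(0), abundance
A(t) = 2^−ΔΔCt(t) with amplification efficiency fixed at 2 (classic ΔΔCt;
per-primer efficiencies out of scope). Since A(0) = 1 by construction, the
half-life fit is a zero-intercept least squares of ln A(t) = −kt; t½ = ln2/k;
R² is computed on the log scale with uncentered total SS (the model has no
intercept), flagging fits below 0.8 and non-decaying series (k ≤ 0, t½ = ∞).
The model-derived 50% crossing uses all timepoints and is noise-robust; a
literal linear-interpolation crossing of A = 0.5 is available as
`method="interpolate"` for comparison. Condition summaries use replicate
half-lives with pairwise two-sided Welch t-tests and no multiplicity
correction (three comparisons, reported individually). Error propagation
note: Ct noise σ maps to SE(t½) ≈ ln2·σ_ΔΔCt·t½²·√(Σt²+(Σt)²)/(ln2·Σt²), so
slow transcripts have much noisier half-lives; with σ = 0.1 and triplicates
the 4.9 vs 9.5 h Welch comparison has only moderate power, while the median
of repeated fits recovers t½ well within 10%.

## miRNA Z-ratio

Intensities are log10(x+1)-transformed (the offset avoids log 0) and
z-scored within each array over detectable miRNAs (sample SD, ddof = 1);
a miRNA is detectable when its intensity clears a floor in at least half the
subjects of either group. Per miRNA, Δz̄ = mean z(old) − mean z(young) and
Z ratio = Δz̄ / SD({Δz̄ over all miRNAs}) — the standard NIA microarray
construction. The p-value is a two-sample z-test on per-subject z-scores
("pairwise z-test" read as two-sample; a paired reading is not possible for
unpaired cohorts), BH-corrected; calls require p < .05, |Z ratio| > 1.5 and
FDR < 0.3. A structural property of the statistic: because it standardizes
by the spread of all per-miRNA differences, at most 1/1.5² ≈ 44% of features
can exceed the call threshold (Chebyshev), and a majority class of shifted
features recenters the per-array z-scores; when ~62% of miRNAs shift upward
the up class itself cannot clear |Z ratio| > 1.5 regardless of effect size
(bounded by 1/√0.62 ≈ 1.27). Minority-direction effects and null
specificity are recovered cleanly (down-sensitivity ≈ 0.91, null false-call
rate ≈ 0.015 in the acceptance run).

## Synthetic data

The generator's defaults are the emulated study's conditions: two cohorts of
11 subjects; 1,000 planted sites in the young cohort with a cohort effect of
0.25 (fraction of young sites demethylated in old, plus a 0.2-per-dropped
old-only fraction, giving 800 old sites, 750 shared — young > old with a
large shared fraction); 100–200 nt fragments; 8× IP enrichment at sites;
motif mix GGACU/GACU/ACU/GAC = 0.45/0.25/0.20/0.10; three focal transcripts
(AGO2-like: methylated in young only, expression −1 log2 in old; DROSHA-like:
methylated in both, unchanged; DICER1-like: unmethylated, −0.7 in old);
methylated genes shifted −0.5 log2 in old; decay conditions empty-vector/
METTL3-OE/METTL14-OE at t½ = 4.9/9.5/7.1 h, triplicates, timepoints 0/2/4/8 h,
Ct noise SD 0.1; 887 miRNAs with 550 up and 93 down planted at ~1 column-SD
(1.0 log10) including 7 of 12 let-7 members down.

The transcriptome is desk-scale: 1,200 transcripts (80% coding, 1–5 exons,
random UTR/CDS splits) on five chromosomes with random ACGU sequence and the
assigned motif embedded at each planted site. At this scale the planted site
count takes precedence over the study's "<1% of transcripts methylated"
sparsity, which would require >10⁵ transcripts. Site-bearing transcripts are
drawn expression-weighted from above the 25th expression percentile — sites
are only detectable on expressed transcripts. Input fragment counts per
transcript are negative binomial (per-subject dispersion 0.1, the field's
default for over-dispersed RNA counts; cohorts are pooled across 11 subjects
so the pooled dispersion is 0.1/11) with uniform midpoints; the IP library
resamples the realized input pool with `enrichment`-fold weight inside this
cohort's site intervals. Each generator stage derives its own RNG stream from
the single seed, so outputs are byte-identical per seed, and a truth registry
(sites, methylated gene sets, decay half-lives, miRNA labels) is emitted for
recovery tests.

What the generator does not emulate: real genome sequence and its motif
background statistics, per-subject MeRIP variation (cohorts are pooled, as
the per-cohort site sets are the analysis unit), batch and array-spatial
effects, isoform complexity, and amplification-efficiency variation in qPCR.
Passing recovery tests therefore demonstrates correctness of the statistical
machinery under the declared generative model, not performance on real
libraries.

## Problem sizes and determinism

Default analyses run in seconds to ~20 s on one CPU: ~78,000 windows per
cohort at 300k fragments per library; 1,000-simulation KS calibration; 200
noisy decay fits; 10–50 seeds of the 887-miRNA scenario. The pipeline
(`m6a run`) is deterministic given (config, seed): the manifest echoes the
config and sha256-hashes every output, completed stages are skipped on
rerun, and unknown configuration keys are rejected.

## Known limitations

- The Poisson window test conditions on input counts; with truly independent
  IP/input libraries (rather than a common fragment pool) input sampling
  noise would inflate the false-site rate beyond the nominal FDR.
- Site merging erases sub-site resolution; the paper-style "fragment" count
  is preserved as the best window's IP count, and both granularities are
  emitted.
- The asymptotic KS p-value is slightly conservative at small n (by design;
  see calibration above).
- Z-ratio up-calls are structurally bounded when a majority of features
  shift in one direction (see above); interpret majority-direction scans
  with a location-free statistic in mind.
- The Welch comparison of half-lives has low power at Ct noise ≥ 0.1 with
  triplicates; the half-life point estimates themselves are accurate.
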