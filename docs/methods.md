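# Methods

This note documents the statistical models behind `termscan`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Coordinates and windows

All coordinates are 0-based half-open (BED convention). The TSS and TES are
*points*: for a + strand gene `tss = start`, `tes = end`; mirrored on the −
strand. Windows are specified in transcript orientation — positive offsets
downstream of the anchor — and are half-open, so "TES to 50 bp upstream"
is `[TES−50, TES)` (exactly 50 bases) and "500 to 1000 bp downstream" is
`[TES+500, TES+1000)` (exactly 500 bases). On the − strand transcript
offset `o` maps to genomic base `anchor − 1 − o`, which makes every
statistic exactly strand-symmetric (tested by coordinate mirroring). The
boundary inclusivity of the source windows is not standardized anywhere;
half-open intervals were chosen because they keep window lengths
unambiguous and sums additive.

A gene whose window would cross a chromosome boundary is flagged invalid
rather than silently clipped: truncation would shrink numerator and
denominator asymmetrically and bias the ratio. Genes with a zero
denominator are likewise flagged, excluded from group statistics, and
counted in the output. No pseudocount alternative is applied by default
because it would make the ratio depend on sequencing depth.

## Read-through statistics

* Nascent (PRO-seq style): downstream 3′-end events over
  `[TES+500, TES+1000)` divided by events over `[TES−50, TES)`, on the
  gene's strand. The offset window skips the first 500 bases past the TES,
  where paused/terminating polymerase accumulates even in wild type.
* Occupancy (Pol II ChIP style): `[TES, TES+1000)` over `[TSS, TES+1000)`.
  The numerator window is contained in the denominator window, so valid
  ratios lie in [0, 1]. Occupancy queries default to strand-collapsed
  signal because polymerase ChIP is not strand-resolved; nascent 3′-end
  signal is strand-specific.

Both statistics are ratios of sums over one track, hence invariant under
global rescaling — spike-in normalization (implemented as scaling by the
ratio of spike-in totals, the minimal standard completion since no formula
is standard) provably cannot change any ratio, only absolute signal levels.

Group comparisons use linear-interpolation quartiles, whiskers at the most
extreme point within 1.5×IQR of the quartiles, and a two-sided two-sample
Student *t* test with pooled variance on the raw ratios. A switch applies
the test to `log2(ratio + ε)` (ε default 1e−3) for heavy-tailed data; box
summaries stay on the raw scale either way. When both groups are constant
and equal the test reports (t, p) = (0, 1) instead of NaN.

## Aberrant-polyadenylation calling

A transcript with records in both library types is called
`aberrant_polyA` iff it is up in the polyA-selected comparison
(log2 FC ≥ 1.5 and BH FDR ≤ 0.05) and not up in the ribo-depleted
comparison (log2 FC ≤ 0, no significance requirement — demanding
significance of a null effect would be incoherent); `concordant_up` iff up
in both; otherwise `not_called`. The calls partition all complete
transcripts; thresholds are configurable (the 1.5 cutoff is interpreted on
the log2 scale).

### Differential plumbing

`simple_differential` is declared plumbing for simulated counts, not a
negative-binomial framework: per-sample log2 CPM with pseudocount 0.5, a
pooled-variance t test per transcript, and Benjamini–Hochberg FDR across
transcripts. Library sizes are estimated by a **two-pass median-of-ratios**:
provisional per-sample medians of counts over the per-transcript geometric
mean, then a recomputation excluding transcripts whose provisional
between-group fold change exceeds 2-fold. The second pass matters: when a
minority of transcripts shifts strongly in one direction (exactly the
planted-aberrant design), those rows sit on opposite sides of the per-row
reference in the two groups and drag even a median or trimmed mean
off-center, biasing every fold change by ~0.1 on the log2 scale. Raw-total
CPM remains available (`norm="total"`), where the same effect is larger
(~0.4), which is why it is not the default.

## qPCR statistics

Per paired replicate *i*: unprocessed fraction `2^−(Ct_UT,i − Ct_CT,i)`;
percent input `100 · 2^((Ct_input,i − d) − Ct_IP,i)` with `d` = log2 of the
input dilution factor (default 0 = undiluted input). Amplification
efficiency is fixed at 2 — the formula presumes perfect doubling and no
standard-curve calibration is modelled. Ratios are computed per replicate
and then summarized (mean, sd with n−1), never from averaged Cts; replicate
pairing is by replicate index. Condition comparisons use the same pooled
Student *t* test as above.

## dNSAF

Unique spectral counts `uSpC_i` are summed from peptides mapping to a
single protein. Each shared peptide with count `c` and sharer set `M`
contributes `c · uSpC_i / Σ_{m∈M} uSpC_m` to each sharer, conserving total
counts. Then `dSAF_i = (uSpC_i + shared_i)/Length_i` and
`dNSAF_i = dSAF_i / Σ dSAF`, which sums to 1 by construction. Degenerate
shared peptides (all sharers with zero unique counts, where the
apportionment ratio is 0/0) are split equally among sharers and the
proteins flagged; a switch discards those counts instead (flags kept). With
no shared peptides the quantity reduces exactly to plain NSAF. Protein
length is taken as supplied, with no initiator-methionine or isoform
adjustment. Bait-vs-control labelling marks a protein bait-specific when it
is absent from the negative control or enriched at least `fold_min`
(default 3) by dNSAF ratio; the default rule is a plain fold cutoff because
no standard numeric rule exists for FLAG-control comparisons.

## Co-occupancy

Peaks are filtered at q < 1e−4; scores may be probability-scale q-values or
−log10(q) (declared, converted as `q = 10^−score`). A gene counts as
occupied when any retained peak intersects the closed window
[TSS − 1 kb, TSS + 1 kb]; distance is from the TSS point, strand-
independent, and a gene counts once regardless of peak multiplicity.
Inclusivity at exactly 1 kb is arbitrary and fixed as inclusive for
determinism. Co-occupied genes are those hit by every factor; the full
exclusive Venn partition is reported and always sums to the union size.

## Synthetic-data generative models

All generators are pure functions of `(config, seed)` (numpy `Generator`
seeded per stream; no global state) and write plain-text formats that parse
back bit-exactly.

* **Genome.** Genes are packed round-robin across 4 chromosomes with
  2 kb gene-free clearance on both sides — enough for every analysis
  window, so no gene is invalid by construction and no neighbor signal
  bleeds into downstream windows. Lengths: histone 0.4–1 kb, snRNA
  0.1–0.3 kb (uniform), protein-coding 2–50 kb (log-uniform).
* **Nascent track.** Per gene, `depth` single-base 3′-end events (the
  single-base convention matches how nascent-transcription reads are
  reduced to polymerase positions). With probability 1−f the event is
  uniform over the gene body; with probability f it falls G bases past the
  TES with G geometric (number-of-failures form, success probability
  1/(1+λ), mean exactly λ; default λ = 200). The closed form
  `P(a ≤ G < b) = (λ/(1+λ))^a − (λ/(1+λ))^b` is the oracle for expected
  window sums. Tail events beyond the 2 kb clearance are discarded, as
  unmappable reads would be; at the defaults the lost mass is ~5e−5.
  A memoryless tail is the simplest decaying shape with closed-form window
  probabilities; real termination profiles need not be memoryless.
* **Occupancy track.** Independent per-base Poisson: rate ρ = depth/L over
  the body, ρ·f·exp(−d/λ) at distance d into the first kb downstream;
  the expected occupancy ratio has a closed form from these rates.
* **Defaults for f.** 0.05 (WT) vs 0.3 (MUT) at histone and snRNA classes,
  0.05 in both conditions at protein-coding genes — the qualitative
  pattern of a class-specific termination defect. These are configuration,
  not claims about real effect sizes.
* **Dual-library counts.** Negative-binomial (var = μ + αμ², α = 0.05),
  4 replicates per group per library, 500 transcripts with 50 planted:
  4-fold up in the polyA-selected perturbation, 0.5-fold in ribo-depleted
  (aberrantly polyadenylated transcripts appear reduced in total-RNA
  libraries). Baselines are log-normal (ln-mean 6.0 ≈ 400 counts, ln-sd
  0.6): RDH transcripts are uniformly highly expressed, and this keeps
  counting noise below the dispersion floor. At these conditions the log2
  fold-change estimator has sd ≈ 0.23 (the α/n floor), so a planted
  transcript misses the 1.5 cutoff with probability ~1.5% — recall ~0.96 is
  the expected operating point, not a defect.
* **Spectral counts.** Lengths log-uniform 100–2000 residues, abundances
  log-normal; peptides per protein ∝ length (~20/kres, min 2); each peptide
  is shared with one other random protein with probability 0.2; counts are
  Poisson with rate ∝ summed abundance of the carrying proteins.
* **Ct tables.** `Ct_CT ~ baseline + N(0, σ)`,
  `Ct_UT = Ct_CT − log2(q) + N(0, σ)` with σ = 0.1 cycles and true
  unprocessed fractions q per (target, condition); noise-free tables invert
  exactly.

### What the generators do not emulate

Sequence content, mappability, GC or fragment-length bias, spike-in genome
mixing (spike-ins are scalar totals only), overlapping or nested genes,
transcript isoforms, batch effects, and peak-caller behaviour (the
co-occupancy stage consumes synthetic peak files directly). Passing tests
therefore demonstrate correctness of the statistics and recoverability
under the stated models, not robustness to every artefact of real
sequencing data.

## Problem sizes

Default simulations use 200 genes at 5000 events per gene, 500 transcripts
× 8 samples per library, 50 proteins at ~5000 total spectra, and 3 qPCR
replicates; multi-seed null checks use 20 seeds. These desk-scale sizes
give the statistics enough signal that every planted effect is recovered
with wide margins while a full test run stays fast.

## Known limitations

* The read-through ratio is undefined for genes with no signal in the
  50-bp upstream window; very high read-through (f → 1) starves the
  denominator and such genes drop out of group statistics — the exclusion
  counts are reported and should be inspected.
* `simple_differential` assumes log-scale normality and equal variances;
  it is a stand-in for count-model inference and is labelled as such.
* Percent-input assumes perfect primer efficiency in both IP and input.
* The dNSAF degenerate-case default (equal split) is conservative but
  arbitrary; audit `undistributed_flag` before interpreting flagged
  proteins.
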