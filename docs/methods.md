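# Methods

## Gene models and event consequences

A gene model is a genomic sequence with 1-based inclusive exon intervals
(transcript order), a strand, and the genomic positions of the translation
start and stop. Minus-strand genes are stored as given; every transcript
operation works on the reverse complement, so a single internal convention
covers both strands. Exported BED is 0-based half-open; GFF3 stays 1-based.

An AS event is a list of primitive edits applied 5′→3′: retain intron *k*
(the flanking exons and the intron merge into one genomic block; if a
flanking exon is itself skipped, as in the ScTOC1 intron-1-retention +
exon-2/3-skipping composite, the block simply ends at the intron boundary),
skip exon *k*, move a donor/acceptor by *n* nt (negative shortens the exon,
positive extends it into the intron), or include an alternative exon lying
strictly inside an intron. Edits that produce overlapping or inverted
segments are rejected; composite events must not touch the same boundary
twice.

Classification translates the edited CDS from the annotated start codon with
the standard genetic code. **PTC** means a stop codon at least one codon
upstream of the position homologous to the annotated stop — a purely
positional definition; no 50-nt rule or NMD-fate prediction is attempted,
because the classification target is the transcript annotation ("inserts a
PTC"), not degradation biology. `frame_preserved` requires both Δnt ≡ 0
(mod 3) and the absence of such a stop; `aa_delta` (amino acids lost) is
defined only then. If an edit removes the start codon the event is reported
as a classification error rather than silently classified.

### The clock-gene fixture

No public sequence accessions exist for the five sugarcane clock loci, so
the packaged fixture is **synthetic by construction**: exon/intron counts and
event geometry match the published gene structures, sequences are drawn by a
seeded generator (stop-free codons for the CDS; GT..AG introns whose
interiors carry stop codons in all three frames so any retention truncates
translation), and a small deterministic search over derived seeds guarantees
every event classifies exactly as published — e.g. the ScPRR73 combined
alt 5′ss E4 (−104 nt) / alt 3′ss E5 (−142 nt) event removes 246 nt and 82 aa
in frame (the event table's "245 nt" is inconsistent with its own 104 + 142
arithmetic, so 246 is used), and the ScPRR37 alt 3′ss in exon 4 removes
30 nt / 10 aa. The intron-retention list follows the fuller prose account
(ScPRR95 I3R + I7R; a standalone ScTOC1 I1R alongside the composite), so
every gene carries at least two retention events. Exon CDS lengths encode
the frame constraints directly: ScPRR37/ScTOC1 exon 3 is not a multiple of
3 (skipping frameshifts), and the 30-nt deletion is codon-aligned.

## Fragment quantification

Sizing maps migration (scan units) to bp through the ladder. The default is
piecewise-linear interpolation between flanking ladder points — transparent
and adequate at GeneScan-500-LIZ ladder density (≤ 60 bp spacing, < 1 bp
interpolation error under a mildly quadratic migration model). Local
Southern is available: the classic reciprocal law L = c + k/(m − m0) fitted
exactly through two overlapping ladder triplets bracketing the target, the
two estimates averaged, with a linear fallback when the three points are
collinear or the asymptote falls inside the migration range. Targets outside
the ladder span are sized by extrapolating the terminal segment and flagged
(assays with amplicons beyond the ladder's last fragment are real; the flag
makes the extrapolation auditable).

Assignment takes each sized peak to the nearest expected amplicon within
±2 bp (configurable); panels with two amplicons closer than twice the
tolerance are rejected at load time as ambiguous. Missing isoforms are
recorded as area 0 with a below-detection flag rather than dropped, so
downstream ratio handling sees them. Normalization divides each target area
by the **geometric mean** of that sample's reference-gene areas — the
standard multi-reference rule; the source assay names two reference genes
but not a combination rule. A sample whose references are all below
detection is excluded and listed. Normalization is exactly invariant to a
per-sample gain factor, which is what makes capillary areas comparable
across runs.

The raw-trace peak caller (synthetic path only) smooths with a moving
average, keeps local maxima above 5% of the trace maximum, and integrates
trapezoidally between flanking minima. Real inputs are expected as peak
tables; binary .fsa/ABIF parsing is out of scope.

## Zeitgeber-time normalization

The two-branch day/night mapping (README) is continuous at dusk (both
branches give ZT12), reduces to the identity under a 12 h/12 h photoperiod,
is strictly increasing within a cycle, and inverts exactly; tests hold these
to 1e-9. Courses longer than 24 h wrap into [0, 24) with the cycle kept in
`day_index`, so the two post-24 h points of a 26-h course land on their
early-morning ZT with their origin recoverable. Integer ZT labels round
half-up. Dawn/dusk are fixed per season; no within-course drift (single
published values per harvest) and no solar computation.

## Rhythm statistics

LOESS is local-linear with tricube weights (statsmodels `lowess`,
no robustifying iterations), span 0.5 by default, evaluated on a 0.1 h grid.
Replicates enter as individual points, never pre-averaged. The fit is
**circular in ZT** (period 24 h): the points are padded one period to each
side and the smoothing fraction rescaled so the bandwidth in hours is
unchanged. Without this, a peak near midnight is systematically dragged to
the window edge because the local fits at ZT≈0 see only one flank; with it,
phase recovery on noisy truncated-cosine series is within 2 h in > 95% of
seeded simulations at the default noise. The peak is the grid argmax of the
fitted curve on [ZT0, ZT22] (ties → earliest ZT), matching the windowed-
maximum rule used for these assays. Standard errors come from a seeded
bootstrap over replicate points (200 resamples by default); a constant
series fits as a constant with SE 0.

The expression call — an AS isoform is "expressed" iff its LOESS peak
reaches a floor and at least 5% of the paired FS isoform's peak — is **this
package's operational definition**; the assays this mirrors report
"not considered expressed" without a stated criterion, so the threshold is
explicit and configurable here.

Group comparisons: paired Student's t (FS vs AS within replicate-timepoint
by default), and one-way ANOVA with post-hoc Tukey HSD across organs; a
plain ANOVA design without the post-hoc is available for simulation work.
All-zero-variance inputs are flagged degenerate with p = 1 instead of
raising. No multiple-testing correction is applied by default (raw p < 0.05
is the convention being mirrored); Benjamini–Hochberg can be applied
downstream if desired.

## Splicing ratios and temperature

log(AS/FS) is computed per aligned replicate point; alignment uses the
sample id when available because (zt, replicate) keys collide once a 26-h
course wraps. Log base 10 by default and recorded in the outputs. Zeros are
handled by a symmetric pseudo-count, defaulting to half the smallest nonzero
normalized abundance in the dataset; points where both isoforms are below
detection are dropped and counted. Swapping AS and FS negates every ratio
exactly.

The **fold range** of a ratio rhythm is `base^(max − min)` — the max/min
ratio on the linear AS/FS scale — optionally over the LOESS-smoothed curve.
This reading is the only one invariant to the log base; the literal
quotient of log values is available behind a flag for comparison.

Temperature is matched to sampling instants by linear interpolation of the
weather series (stations log at fixed intervals). The regression is OLS of
log-ratio on °C pooled per (gene, event, organ, season), replicates pooled
rather than averaged; slope, R² (squared Pearson r of the matched pairs) and
the two-sided slope p are reported, with "significant negative" meaning
slope < 0 and p < α (default 0.05). Fewer than 3 matched points is an
error, not a silent NaN.

## Synthetic studies

Defaults mirror the field design: winter dawn 6:30/dusk 18:00 (11.5 h day),
summer 5:45/19:00 (13.25 h day); sampling every 2 h for 26 h starting 2 h
before dawn (14 points); 3 pooled biological replicates; leaf only in
winter, leaf + two internodes in summer. FS abundance is
`baseline + amplitude · max(0, cos(2π(zt − peak)/24))` — a truncated cosine,
because clock transcripts are sharply peaked and peak extraction is the
target statistic. The AS isoform is derived through its log-ratio:
`log10(AS/FS) = log10(rel_level) + ratio_amp·cos(2π(zt − ratio_peak)/24) +
temp_slope·(temp − season mean)`, with the LHY-like events peaking at dawn
with slope −0.05 /°C and the PRR-like events peaking mid-morning with no
temperature term. Replicate scatter is lognormal (σ = 0.15): areas are
positive and multiplicative error is what fluorescence shows. Temperature is
a seasonal mean (18 °C winter, 26 °C summer) plus a 5 °C diel cosine peaking
at 14:00 plus AR(1) noise (φ = 0.7, marginal sd 0.5 °C). Peak tables place
ladder fragments and one target peak per amplicon under a monotone
(mildly quadratic) migration model, areas scaled by a lognormal per-sample
gain (σ = 0.3); amplicon sizes sit inside the ladder span so the default
round trip involves no extrapolation. All randomness flows through one
seeded generator; identical seeds give byte-identical outputs.

What the generator does **not** emulate: stutter and pull-up artifacts, dye
spectral overlap, heteroscedastic baseline drift, partial splicing
intermediates, organ-specific waveform shapes, or weather beyond a cosine +
AR(1). Passing the recovery tests therefore demonstrates the pipeline's
correctness under its stated noise model, not robustness to every artifact
of real capillary data.

One deliberate realism: because the AS rhythm itself peaks in the cold part
of the night, the fitted temperature slope exceeds the configured coupling
(rhythm–temperature confounding). The slope-recovery acceptance simulation
therefore generates from the regression model directly, while the
end-to-end test asserts sign and significance, not the slope magnitude.

## Problem sizes

The test suite uses 500-replicate simulations for phase and slope recovery,
10,000 null replicates for the ANOVA type-I check, and full default studies
(168 samples, 1,176 abundance records) for the round-trip tests; the whole
suite runs in well under a minute on one core, a size chosen to keep the
Monte-Carlo standard errors a factor of a few below the asserted margins.

## Known limitations

- GFF3 I/O covers the gene/mRNA/exon/CDS/UTR feature set this pipeline
  writes; it is not a general-purpose GFF3 round-tripper.
- The Local Southern fallback to linear interpolation near degenerate
  triplets is heuristic.
- `expression_call` depends on a paired FS fit; orphan AS series fall back
  to a floor-only rule.
- Peak phases are grid argmaxes; no uncertainty is attached to the phase
  itself (the bootstrap bands cover the curve, not the argmax).
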