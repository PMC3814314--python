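# Methods

## Scope and model

`zicreg` implements the standard integrative recipe for a two-stage
ChIP-seq study of a developmental transcription factor: filter peak
calls, describe where binding sits relative to genes, quantify consensus
motif occurrence with a simulation-calibrated threshold, compare binding
across two developmental stages at the level of merged summit windows,
intersect binding with conserved non-coding elements (CNEs), and call
direct target genes by joining binding with differential expression.
All coordinates are 0-based half-open; 1-based dialects are converted on
ingest so every distance rule is applied in a single convention.

The pipeline operates on *summits*: every window rule (±2 kb stage
comparison, ±400 bp motif scan, ±500 bp CNE overlap, promoter and radius
association) is summit-centered.  Where a rule could plausibly use whole
peak intervals instead (the 100 kb target radius), both variants are
implemented and the summit form is the default.

## Key rules and their parameters

| rule | parameter | default | notes |
|---|---|---|---|
| repeat filter | max repeat fraction | 0.70, strict `>` | exactly 0.70 is retained |
| promoter | upstream window | 5 000 bp | upstream-only; symmetric ±5 kb available via `promoter_downstream` |
| GREAT domains | basal | −5 kb / +1 kb around TSS | strand-aware |
| | extension | 100 kb | truncated at the nearest other gene's basal boundary, clamped to chromosome ends |
| radius association | radius | 100 kb (alt 500 kb) | `\|summit − TSS\| ≤ r`, inclusive |
| motif scan | half window | 400 bp | window truncated at chromosome ends |
| calibration | cohort, target | n = 10 000, 85% | lower (type-1) empirical quantile |
| stage merge | flank | 2 000 bp | strictly overlapping windows merge |
| bound rescue | fold over background | 5× | alternative: 2-means on log densities |
| CNE rule | window, identity | 50 bp, 0.70 | *every* sliding window must pass |
| CNE overlap | summit flank | 500 bp | ≥1 bp overlap counts |
| DE presets | 8 hpf | FC > 1.2 (strict), p ≤ 0.05 | printed strictness kept per stage |
| | 24 hpf co-expressed | FC ≥ 1.5, p < 0.05 (strict) | |
| | 24 hpf depleted | FC ≥ 2, no p filter | |

P-values are consumed as provided; an optional Benjamini–Hochberg
adjustment (`adjust="bh"`, via `scipy.stats.false_discovery_control`) is
available but off by default, matching the raw-p filters above.

## Threshold calibration and score discreteness

The PWM match score is the log2 odds against a background distribution,
maximized over offsets and both strands; hard-masked (N) bases contribute
0, i.e. they score as background.  The detection threshold is the lower
empirical quantile of best-match scores over 10 000 sequences sampled
column-wise from the PWM itself, placed so that at least ⌈0.85·n⌉
calibration sequences score at or above it.

Because PWM sampling yields a *discrete* score law, the quantile can fall
inside a tie atom, in which case "score ≥ threshold" captures the whole
atom and out-of-sample detection exceeds the design rate by up to that
atom's mass.  The packaged Zic3 consensus PWM (12 positions, CAGCAG core,
per-position dominance 0.83–0.97 with deliberately unequal minor-base
probabilities) was designed so the score distribution is fine-grained
near the 15th percentile: its out-of-sample detection sits within ~1
point of 85%.  The property test for other calibration targets accounts
for the tie atom explicitly.  The same design keeps the chance-hit rate
of an 800 bp background window at a few percent, so that the fraction of
peaks with a motif is dominated by genuinely planted or bound motifs —
the regime the real scan operates in.  A fully degenerate PWM (a
probability-1 column at every position) makes all scores equal; the
calibrator then returns that unique score with detection rate 1.0 and a
warning.

## Stage comparison

Signal density for a region is `(Σ per-base signal / kb) × 10⁶ /
library size`.  The genome-wide background density is the 80% trimmed
mean over 200 random peak-free regions of matched length (seeded), which
is robust to residual signal contamination.  A region is *bound* in a
stage if it was peak-called there, or if its density reaches 5× the
background — the rescue that recovers true binding missed by peak
calling in one stage (including binding removed by the repeat filter,
whose signal remains in the track).  An alternative bound rule clusters
log1p densities per stage with 2-means and calls the upper cluster bound;
on well-separated bimodal data the two rules agree exactly, and the
fixed-fold rule is the default because it is deterministic and
parameter-transparent.

## CNE semantics

A CNE is a maximal interval in which every 50 bp sliding window has mean
identity ≥ 0.70; extraction is O(n) via prefix sums over the step-encoded
identity track.  Two consequences of this definition are worth noting.
First, a pure high-identity island flanked by zero-identity sequence is
called with a symmetric margin: boundary windows holding exactly
⌈50·(0.70−b)/(c−b)⌉ island bases (island identity `c`, background `b`)
still pass, so the called interval extends beyond the island by a
computable number of bases (15 bp for `c=1, b=0`).  The tests assert this
analytically rather than pretending the island is recovered verbatim.
Second, maximal intervals may overlap when two admissible runs are
separated by a single failing window start; both are reported, as both
are maximal under the rule.  Gaps without alignment carry identity 0.

## The synthetic data generator

The generator emulates the study design, not the organism: a 10 Mb
/ 5-chromosome i.i.d. genome with AT-dinucleotide repeat blocks; 200
spaced genes (TSS spacing ≥ 20 kb); 1000 peaks per stage of which 30%
are shared across stages (class I; the late-stage twin summit jittered
≤ 25 bp), the rest stage-exclusive (II/III); peak placement 10/30/60%
promoter/intragenic/intergenic, mirroring the distal bias of real
landscapes; an exact consensus motif written into the sequence within
±360 bp of 50% of summits; triangular signal bumps (half-width 300 bp,
peak height 100× the unit background, background noise per 100 bp bin)
in the stage(s) where a site is truly bound; 50 high-identity islands
(0.9 over a 0.3 background), half placed within 500 bp of summits; and
expression tables in which genes owning a planted, non-repeat site
within 100 kb of their TSS ("true targets") receive
|log2 FC| = log2(4) + N(0, 0.1) and Beta(0.005, 1) p-values, while nulls
get N(0, 0.1) log fold changes and uniform p-values.

Design notes:

- **Beta(0.005, 1) target p-values.**  With CDF `P(p ≤ α) = α^0.005`, the
  DE filter's operating point is available in closed form: 98.5% of true
  targets pass p ≤ 0.05, so the full pipeline can be required to recover
  ≥ 95% of true targets without the p-law itself being the binding
  constraint.  The p-values are drawn by inverse CDF (`U^(1/a)`), since
  numpy's beta sampler is inaccurate at very small shape parameters.
- **Summit spacing ≥ 900 bp** keeps one site's planted motif out of
  another site's ±400 bp scan window, so the expected motif-bearing
  fraction is exactly `plant rate + (1 − plant rate) × chance rate`.
- **Repeat sites** (5% of peaks) are planted inside 700 bp AT blocks and
  carry no owning gene: they model the artifact-prone calls the repeat
  filter removes.  Their signal bumps remain in the tracks, which is why
  region-level ground truth counts *all* true sites inside a region, not
  only the retained seeding peaks.
- **Determinism.**  All randomness flows from `numpy.random.SeedSequence`
  children of one seed; emitted files round floats to fixed precision,
  so identical seeds give byte-identical files.

What passing on synthetic data does *not* show: real ChIP-seq noise is
not uniform-per-bin, real repeats are not AT dinucleotide runs, real
motif instances are degenerate rather than exact consensus copies, real
fold changes are not a clean two-component mixture, and real gene/peak
densities differ (at the default density nearly every simulated gene is
a true target, so the false-discovery check is easier than on real
data).  The generator validates the *rules and their arithmetic*, not
biological effect sizes.

## Problem sizes and numerics

The standard study condition used by the test suite and the analysis
drivers is the generator default above (10 Mb, 200 genes, 1000
peaks/stage); the byte-identity determinism check runs a 1 Mb / 150
peaks-per-stage configuration, determinism being structural rather than
size-dependent.  Window-mean comparisons use a 1e-9 slack so identity
values written as decimals survive float round-trips; interval sets and
tracks use `searchsorted` on sorted arrays with precomputed prefix sums;
interval-tree association is verified against exhaustive double loops.

## Known limitations

- No replicate-aware differential binding; the two-stage comparison
  assumes one library per stage.
- The GREAT implementation covers domain construction and assignment
  only, not enrichment statistics.
- BigWig/BAM inputs are out of scope; tracks arrive as bedGraph/WIG and
  peaks as BED/narrowPeak.
- The "adjacent motif" distance in co-occurrence analysis defaults to
  250 bp within the shared scan window; the right value is
  context-dependent and configurable.
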