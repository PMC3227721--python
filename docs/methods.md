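# Methods

## Scope and model

`ciscompare` treats a transcription-factor binding site as a
mononucleotide position-frequency matrix (PFM): independent positions,
each a categorical distribution over A, C, G, T.  No dinucleotide or
higher-order dependencies are modelled, and no de novo motif discovery
is attempted — the matrices are inputs, supplied in TRANSFAC flat-file
format or generated synthetically.

Counts are smoothed with a pseudocount (default 0.01 per cell,
configurable per matrix) before conversion to frequencies.  The default
is small enough to leave well-populated matrices essentially unchanged
while keeping every frequency strictly positive, so that the
anti-consensus (worst-match) score is defined and the [0, 1]
normalisation below cannot divide by zero on matrices with zero counts.

### Matrix-similarity score

A window w of length L is scored

    I(i)   = Σ_b f(i,b) ln(4 f(i,b)),   0·ln 0 := 0
    S(w)   = Σ_i I(i) f(i, w_i)
    MSS(w) = (S(w) − S_min) / (S_max − S_min)

with S_min/S_max computed from the per-position minimum/maximum
frequency.  I(i) is per-position information content in nats (0 for a
uniform row, ln 4 ≈ 1.386 for a single-base row); weighting by I(i)
makes conserved core positions dominate the score.  The logarithm base
is irrelevant: it rescales I(i) by a constant that cancels in the
normalisation.  Two conventions are fixed deliberately:

* a matrix whose every position is uniform has S_max = S_min; every
  window then scores 1.0 (any window "matches" a model with no
  preferences);
* windows containing N are not scored — the scanner skips them and logs
  the count at debug level, since assembly gaps should neither match
  nor raise.

One global score per window is used; no separate core sub-score over a
5-position nucleus is computed.  Scanning both strands is the default:
a minus-strand site is found by scanning with the reverse-complemented
matrix and reported in plus-strand coordinates with strand "−".
Internally coordinates are 0-based half-open; exported hit tables are
1-based inclusive, and BED output is 0-based half-open, following each
format's convention.

Overlapping and repeated hits all count individually in the presence
matrix — no merging — because multiplicities (a class hit 8 times in
one fragment) are part of the signal the comparative layer consumes.
Whether counts should instead be collapsed per strand is not
determinable from the comparisons this design reproduces; both-strand
summing was chosen and is recorded in the run manifest.

### Cutoff calibration

Calibration takes explicit inputs — a non-empty set of true-site L-mers
and background sequences — rather than any particular database's
training sites, which decouples the statistic from proprietary data.
On a cutoff grid over [0, 1] (default step 0.005, finer than anything
desk-scale data can resolve):

* FN%(c) = percentage of true sites scoring < c (a site scoring exactly
  c counts as found, matching the scanner's ≥ c match rule);
* **minFN10** = the largest grid cutoff with FN% ≤ 10;
* the background match count at minFN10 (both strands) defines 100%
  false positives; FP%(c) scales other counts against it.  When that
  baseline is zero, FP% is identically 0 and a warning is logged;
* **minFP** = the smallest grid cutoff at which the background count
  reaches its minimum *over the segment [minFN10, 1]*.  Restricting the
  search to that segment (rather than the whole grid) keeps
  minFN10 ≤ minFP even when the background score maximum lies below
  minFN10, and matches the sweep's direction of travel;
* **minSum** = the cutoff in [minFN10, minFP] minimising FN% + FP%;
  ties resolve to the smallest (most sensitive) cutoff, making the
  result deterministic.

FN% is non-decreasing and FP% non-increasing by construction; the
profile constructor re-asserts both, plus the cutoff ordering, on every
calibration.

### Comparative layer

The presence matrix pools hits either per TF class (the `tf_class`
label carried by each matrix, summed over all matrices sharing the
class) or per individual matrix ("consensus" level).  "Present" means
count ≥ 1 and "absent" count = 0; both thresholds are arguments
(`min_count`, `absent_max`) for sensitivity analyses.  Group membership
is explicit user input: `sequences_with_territory` suggests a group
from the annotation table, but annotated activity can be ectopic, so
curated contrasts may exclude an annotated sequence and the tool never
auto-derives the groups.  Common/differential extraction is pure set
logic on the count table — no enrichment statistics (hypergeometric or
permutation p-values) are computed, because presence/absence across a
handful of sequences is the object of interest here; enrichment testing
would be a natural extension.

## Synthetic data and the benchmark regime

The generators emulate the three inputs the pipeline needs: background
DNA (i.i.d. with configurable composition, or first-order Markov with a
given transition matrix), frequency matrices of given length and mean
per-position information, and planted-motif datasets in which sampled
sites are written at uniformly drawn non-overlapping positions
(rejection sampling, 1000-retry cap) on either strand, with every
placement recorded as ground truth.  All generators are deterministic
under a fixed seed.

`generate_matrix` gives every position a randomly chosen consensus base
with probability p and splits the rest evenly, solving p so the
position's information meets the target.  By default every position
carries the target exactly: the resulting score distribution is a
ladder of discrete bands indexed by mismatch count (one mismatch costs
exactly 1/L of the score range), which makes calibrated-cutoff
behaviour stable — the 10%-FN quantile lands at a band edge, so the
operating false-negative rate sits well *below* 10% instead of exactly
at it.  An optional `jitter` parameter perturbs per-position targets
for rougher, more natural profiles; with jitter the bands smear and a
cutoff calibrated to 10% FN operates at essentially 10% FN, which is
the honest but knife-edge regime.

The packaged benchmark conditions (in `ciscompare.experiments`) are:
5 sequences × 5 kb of uniform background, 10 planted sites per
sequence, matrix length 14 at 1.29 nats/position mean information, 200
true sites and a 5 × 5 kb background for calibration.  This regime was
chosen so that (a) the expected number of background matches at the
minFN10 cutoff in ~50 k scanned windows is ≪ 1, which keeps minSum at
the sensitive end of the sweep, and (b) the operating FN rate at the
calibrated cutoff is ~2–4%, giving the recovery experiment
(sensitivity ≥ 0.9, false discovery proportion ≤ 0.2 under
50%-reciprocal-overlap, strand-matched truth matching) a comfortable
margin across seeds rather than a coin-flip at the 10% boundary.
A recovered-site criterion requiring strand match means a
near-palindromic consensus can register its own detections on the
opposite strand as false discoveries; with random 14-mers this is rare.

## What passing tests do and do not show

The synthetic experiments validate the machinery — scoring, cutoff
calibration, scanning, tallying and set logic — against ground truth.
They do not show that the pipeline recovers *biological* truth: real
enhancers have correlated, repeat-rich composition that i.i.d. or
first-order Markov background does not capture; real matrix libraries
contain redundant and overlapping models whose class assignments carry
curation choices; and real binding sites diverge from PFM assumptions.
The absolute per-class hit counts of the published comparison that the
packaged tables reproduce depend on a proprietary matrix library
(TRANSFAC 11.4) and on genomic fragment sequences that were never
deposited, so they cannot be recomputed from sequence here; the
packaged tables carry those counts as curated data, and the
reproducible surface is the comparative layer on top of them, which
this package recomputes exactly.

## Numerical and degenerate-input choices

* Pseudocount 0 plus an all-zero matrix position raises a
  degenerate-matrix error at construction.
* Cutoff grid: `linspace(0, 1, 1/step + 1)`, avoiding accumulated
  floating-point drift from repeated addition.
* Vectorised scanning accumulates per-position weights in the same
  order as the single-window scorer, so the two paths agree bit-exactly
  (tested against an independent brute-force oracle).
* Sequences shorter than the matrix yield empty hit lists, not errors;
  calibration against a background too short to scan raises.
* Non-overlap in planting is enforced per sequence; an infeasible
  request (n·L exceeding the sequence, or retry-cap exhaustion) raises
  a placement error.
* `restrict_rows` warns (not errors) on requested rows missing from a
  presence matrix, since row universes legitimately differ between
  matrix libraries.
* The non-redundant option keeps, per TF class, the matrix with the
  lexicographically smallest accession — deterministic, though
  arbitrary; it can only remove hits, never add them.
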