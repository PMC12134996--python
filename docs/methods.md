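# Methods

## Model and assumptions

A telomere is a tandem array of one primitive motif (period 4–30 bp for
telomerase-maintained telomeres; up to ~1 kb for transposon/ALT-style
ends) sitting at a natural DNA end. Long-read library preparation
preserves those ends, so on a read of length L a telomeric tract occupies
a suffix (G-rich strand, 3' end) or a prefix (C-rich strand, 5' end) —
never the interior. Everything downstream rests on this positional
assumption; circular genomes, chimeric reads, and adapter remnants
violate it and are out of scope.

Coordinates are 0-based half-open throughout the library; the on-disk
repeat-table dialect (tab-separated, eleven columns, 1-based inclusive
start/end) is converted at the file boundary.

## Motif classes

A detected consensus motif is reduced to its primitive root (a power of a
shorter motif collapses onto it), then mapped to the class of all cyclic
rotations of itself and of its reverse complement. The class identity is
the lexicographically smallest of those strings. The display orientation
is the strand with more G than C (the conventional telomere orientation),
rotated to its smallest phase; ties (G = C, palindromic classes) fall back
to the smaller minimal rotation, so the choice is always deterministic.
Note the canonical display rotation is not always the human-familiar
spelling (the TTAGGC class displays as AGGCTT); the single-motif path
always echoes the user's exact spelling instead. `class_distance` gives
the minimum Hamming distance over all rotation/strand alignments of two
equal-period classes — sequencing-error neighbours of a real TRM sit at
distance 1–2 and much lower abundance.

## Tandem repeat detection

For each candidate period p, positions i with s[i] = s[i+p] form a
self-match array (N never matches anything). Maximal runs of matches are
tandem segments; a run of length r spans r + p bases, i.e. (r+p)/p copies.

With mismatch tolerance f > 0, exact runs at least one period long act as
seeds and are greedily extended left and right across gaps, accepting a
gap only if it is (a) shorter than p and (b) at most f/(1−f) times the
adjacent exact run — every crossed segment then carries a mismatch
fraction ≤ f. The criterion is deliberately *local*: a long tract must
not bank a global mismatch budget that would let the call march into
unrelated flanking sequence (with a global budget, a 2.5-kb tract can
absorb ~500 mismatching bases and candidates found at period multiples
overshoot the tract boundary by hundreds of bases). With f = 0 the
detector reduces exactly to maximal-exact-run enumeration, which is how
it is verified against a brute-force oracle.

Each segment's motif is the column-majority consensus (ties A<C<G<T; N
never wins), reduced to its primitive root; segments whose primitive
period falls below k_min (e.g. homopolymers found at period 4) are
dropped. Overlapping calls of different periods are resolved by priority
— smaller period, then longer interval, then smaller canonical key — with
lower-priority calls *trimmed* to the bases not already claimed
(fragments are re-consensused and kept only if they still carry the
minimum copy number). Trimming rather than dropping matters: a chance
two-copy short-period blip straddling a telomere boundary must cost the
tract call a few bases, not the whole interval. Finally, same-class
intervals separated by at most `merge_gap` bases are fused into one
interval that remembers its covered sub-spans; gap bases never count as
occupancy.

Defaults: k_min 4, k_max 20 (the usual telomerase-motif range),
min_copies 2, max_mismatch_frac 0.2 (tolerates ~10% per-base error since
each substitution breaks two self-matches), merge_gap 50 bp.

## Occupancy analysis

**Ranking.** Reads with L ≥ 2t contribute their first and last t bp
(default t = 1000). Classes are ranked by total covered bases over both
windows and both orientations — occupied bases, not occurrence counts, so
periods compete fairly. Ties break by canonical key.

**Profiles.** For a class and reads with L ≥ 2n, four arrays of length n
count reads (not copies — each read contributes at most 1 per position)
covering each position: 5' arrays indexed from the read start, 3' arrays
from the read end (index 0 = last base = distance 1), separately for the
forward (display) and reverse orientations. Palindromic classes count in
both, so their forward and reverse arrays coincide. The middle region
[n, L−n) is variable per read; middle fractions are covered bp over total
middle bp across eligible reads. A read is *bipolar* if it carries a
forward interval in its 3' window and a reverse interval in its 5'
window.

**Strandedness.** score = (F3 + R5 − F5 − R3)/(F3 + R5 + F5 + R3) over
the four terminal totals (0 when empty). Verdicts are advisory
conventions with config-exposed thresholds: bipolar fraction > 0.05 →
`bipolar_suspect` (checked first — bipolar reads disqualify a motif
however stranded it looks); else score ≥ 0.8 and middle ≤ 0.05 →
`terminal_stranded`; score ≥ 0.8 with a busy middle →
`internal_stranded`; otherwise `unstranded`. The asymmetry ratio
max(3' fwd)/max(5' rev) (+inf when the 5' curve is empty) flags
transposase ultra-long libraries, which favour tracts at read 3' ends.

**Length estimate.** The occupancy at distance d from the read end is the
number of reads whose tract reaches depth d — the survival function of
tract lengths — so it falls to half its maximum at the median tract
length. The estimator takes whichever terminal curve (3' forward or 5'
reverse) has the larger maximum (3'-biased libraries have no 5' mirror,
so requiring both would fail on valid data), smooths it with a centred
moving average of the smallest odd width ≥ the motif period (odd so a
step crossing cannot shift; the width suppresses per-period phase ripple
at a cost of at most one period), and reports the largest d such that the
smoothed curve stays at or above half its maximum at every depth up to d.
An all-zero curve reports 0.

Because the chosen curve only sees the reads of one orientation, the
estimate converges to the median of the tract lengths *on that strand*;
in a mirrored library the two strand medians differ by ordinary sampling
noise (~25 bp at 250 reads per strand for a 2.5-kb lognormal), which is
what the tests compare against.

## Simulator

`simulate_library` draws read lengths (lognormal around a median),
assigns each read a telomere with probability `telomeric_read_fraction`,
draws the tract length (lognormal, or truncated normal), truncates it at
the read length — the spillover regime arises naturally — and places
exact motif repeats at the 3' end (forward) with probability
`three_prime_bias`, else at the 5' end (reverse complement). Optional
elements: a subtelomeric tandem tract at a fixed offset from the
telomeric end (mirrored per orientation), and an interstitial tract
centred mid-read on every read as a negative control. Errors are i.i.d.
per-base substitution/insertion/deletion applied after construction;
truth records pre-error lengths and coordinates, with spillover tracts
recorded as placed (what the read carries is the measurable quantity).
Per-read error seeds are drawn unconditionally so libraries differing
only in error rates share identical pre-error reads — paired comparisons
isolate the effect of noise.

The generator emulates positional structure, not platform realism: no
homopolymer-biased errors, quality values, chimeras, or adapters. Passing
tests therefore demonstrate the algorithmic properties (ranking,
strandedness, length recovery, bias directions) under controlled
conditions, not performance on any particular basecaller's output.

Defaults are the reference study condition used throughout the tests:
500 reads, 30-kb median length (σ_log 0.1), all telomeric, motif TTAGGC,
tract median 2500 bp (σ_log 0.2), zero error, unbiased orientation.

## Numerical choices and degenerate inputs

- Majority-consensus ties: fixed base order A<C<G<T; an all-N column
  yields A (and such intervals are dropped if the motif leaves ACGT).
- Detection candidates are deduplicated across periods after primitive
  reduction (a 6-periodic tract is found at periods 6, 12, 18 and must
  count once).
- Chance self-matches in random flanking sequence can extend or clip a
  tract call by a few bases at its inner boundary; truth-comparison
  tests allow a ≤3-read drift at ≤1% of depths, and exact-arithmetic
  fixtures plant a guard base at the tract boundary.
- Empty inputs: an empty read file yields nothing and reports zero
  records; ranking with no read ≥ 2t raises an explicit "no eligible
  reads" error naming the window; a class absent from the annotations
  warns and returns an all-zero profile; `asymmetry_ratio` returns +inf
  when the 5' reverse curve is empty.
- Rendering is SVG with a fixed hash salt and no timestamp, so identical
  profiles produce byte-identical files (golden-tested).

## Problem sizes

The test suite and `scripts/acceptance.py` run entirely on simulated
data sized for a single CPU: 500 mixed sequences (≤ 500 bp) for detector
/ oracle agreement, 1000 random motifs for canonicalization, a 500-read
20–30-kb library for parameter recovery, 200-read ladders for spillover,
300 reads for the 3'-bias regime, and 10 paired 150-read libraries for
the error-undercount direction. These sizes put order-statistic noise
well inside the asserted tolerances (one motif period for length
recovery).

## Limitations

- The detector is a deliberately simple self-match/seed-extend scheme; it
  does not reproduce any external tandem-repeat engine's scores, and very
  noisy tracts with no clean period-length window can be fragmented
  (fragments are rejoined by gap merging). An externally produced table
  can always be supplied for profiling instead.
- Variable-unit telomeres (e.g. (TG)₁₋₄G₂₋₃) surface as several
  concrete classes, as observed; `class_distance` supports post-hoc
  grouping but no automatic unification is attempted.
- Verdict thresholds encode by-eye judgement as conventions; they are
  exposed, not claimed optimal.
- The length estimate measures the double-stranded tract the reads carry:
  with real libraries it is expected to run short of hybridization-based
  estimates (blunting removes 3' overhangs, and sequencing errors break
  repeat copies — the undercount direction the tests verify).
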