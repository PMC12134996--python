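# telomotif

Telomeric repeat motif (TRM) discovery and telomere length estimation from
long sequencing reads.

## The problem

Telomeres are tandem arrays of a short motif — TTAGGC in *C. elegans*,
TTAGG in most insects, 25-mers in some yeasts — and the motif diverges
rapidly in several clades. Classical bioinformatic searches rank tandem
repeats by *frequency* in short-read libraries and fail whenever telomeres
are short, motifs are long, or the motif is not especially abundant.

Long reads (PacBio, ONT) preserve natural DNA ends. An intact telomere can
therefore only appear at a read end, and always in a fixed orientation: the
G-rich strand pointing toward the chromosome end shows up at read **3'**
ends, its reverse complement at read **5'** ends, and neither appears
mid-read. This *terminal stranded occupancy* pattern separates true TRMs
from interstitial repeats regardless of abundance, and the shape of the
occupancy curve carries the telomere length distribution.

## The method

For reads of length L ≥ 2t, every tandem repeat with period in [k, K] found
in the first and last *t* bp is assigned to its rotation/strand equivalence
class (all cyclic rotations of the motif and of its reverse complement are
one class), and classes are ranked by total occupied bases. For each
candidate class, a whole-read repeat annotation yields strand-resolved
positional occupancy over the first and last *n* bp of reads with L ≥ 2n,
plus a middle-occupancy fraction over the variable region [n, L−n).

Diagnostics on a profile with terminal totals F3 (3' forward), R5 (5'
reverse), F5, R3:

- strandedness score = (F3 + R5 − F5 − R3) / (F3 + R5 + F5 + R3);
  ≈ 1 for a telomere, ≈ 0 for unstranded repeats;
- bipolar read fraction: reads carrying the class at *both* ends — a high
  value disqualifies a motif however stranded it looks;
- asymmetry ratio max(3' fwd)/max(5' rev): ≫ 1 flags transposase
  ("ultra-long") libraries that lack the 5' mirror.

The occupancy at distance d from the read end counts reads whose tract
reaches at least d deep, i.e. the survival function of tract lengths. Its
half-maximum crossing — the largest d with smoothed occupancy ≥ y_max/2
everywhere up to d — estimates the **median telomere length**.

A simulator generates libraries with per-read ground truth (tract lengths,
orientation, coordinates) for the regimes that matter: ordinary mirrored
libraries, spillover (tracts ≥ read length), 3'-biased ultra-long
libraries, subtelomeric elements at a fixed offset, interstitial repeats,
and i.i.d. substitution/insertion/deletion errors.

## Worked example

`python examples/01_discover_motif.py` simulates 200 reads (~20 kb) whose
telomeres are TTAGGC tracts with a 2.5-kb median, then runs the full
discovery path:

```
149 motif classes in the terminal 1000 bp of 200 reads; top five:
  rank 1   AGGCTT       period 6   occupancy 200000 bp
  rank 2   CGTG         period 4   occupancy 218 bp
  ...
top class AGGCTT: strandedness score 1.000, middle fraction 0.0000, verdict terminal_stranded
median telomere length estimate: 2475 bp (from the five_prime_rev curve)
```

Rank 1 is the planted motif's class (AGGCTT is the canonical rotation of
TTAGGC's G-rich strand), three orders of magnitude above the background of
chance repeats; the verdict says it behaves like a telomere; the
half-maximum estimate recovers the simulated 2.5-kb median. The other
examples show the length estimator in isolation (`02`), the spillover /
3'-bias / bipolar failure modes (`03`), and external repeat tables plus
coverage subsampling (`04`).

## Command line

A thin CLI orchestrates ranking → profiling → plotting → summary:

```sh
telomotif -f reads.fasta -k 4 -K 20 -m 1 -M 100 -t 1000 -n 6000 --output-dir out
```

writes `out/summary.tsv` (rank, motif, period, occupancy, strandedness
score, middle fraction, bipolar fraction, verdict, median length) and one
occupancy panel per rank (`-e` arranges panels in a period × occupancy
grid instead). `-s TTAGGC` profiles a single motif and skips ranking;
`-T table.tsv` reuses a precomputed tandem-repeat table.

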