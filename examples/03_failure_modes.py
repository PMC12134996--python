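"""The three ways a real telomeric motif hides -- and one impostor.

1. Spillover: telomeres as long as the reads leak into the middle and the
   wrong end, flattening the strand bias.
2. 3'-biased (transposase, "ultra-long") libraries: no 5' mirror curve,
   but the 3' curve alone still carries the length signal.
3. Bipolar reads: a motif at *both* ends of the same reads is not a
   telomere, however stranded each end looks.
"""

import numpy as np

from telomotif import (
    DetectionParams,
    Read,
    SimParams,
    asymmetry_ratio,
    canonical_class,
    compute_profile,
    detect_whole_reads,
    estimate_median_length,
    score_terminal_strandedness,
    simulate_library,
)

det = DetectionParams()
cls = canonical_class("TTAGGC")

print("spillover: 10-kb reads, growing telomere tract medians")
for median in (1000, 5000, 10000, 50000):
    reads, _ = simulate_library(SimParams(
        n_reads=120, read_length=(10000, 0.05), motif="TTAGGC",
        telomere_length=(median, 0.2, "lognormal"), seed=3,
    ))
    prof = compute_profile(reads, cls, detect_whole_reads(reads, det), 2000)
    rep = score_terminal_strandedness(prof)
    print(f"  tract median {median:>6} bp -> score {rep.score:.3f}, "
          f"middle fraction {rep.middle_frac_max:.3f}, {rep.verdict.value}")

print("\n3'-biased library (every tract at the read 3' end)")
reads, truth = simulate_library(SimParams(
    n_reads=150, read_length=(25000, 0.1), motif="TTAGGC",
    telomere_length=(2500, 0.2, "lognormal"), three_prime_bias=1.0, seed=4,
))
prof = compute_profile(reads, cls, detect_whole_reads(reads, det), 8000)
est = estimate_median_length(prof)
print(f"  3'fwd peak / 5'rev peak = {asymmetry_ratio(prof):.1f}")
print(f"  estimate from the 3' curve alone: {est.median_length_bp} bp "
      f"(truth median {np.median([t.true_tract_length for t in truth]):.0f})")

print("\nbipolar impostor: TTGGGG at the 3' end AND CCCCAA at the 5' end")
rng = np.random.default_rng(5)
bases = np.frombuffer(b"ACGT", dtype=np.uint8)
reads = []
for i in range(40):
    seq = bytearray(bases[rng.integers(0, 4, 4000)].tobytes())
    seq[:300] = ("CCCCAA" * 50).encode()
    seq[-300:] = ("TTGGGG" * 50).encode()
    reads.append(Read(f"r{i}", seq.decode()))
prof = compute_profile(
    reads, canonical_class("TTGGGG"), detect_whole_reads(reads, det), 1000
)
rep = score_terminal_strandedness(prof)
print(f"  score {rep.score:.3f} looks telomeric, but "
      f"{rep.bipolar_read_fraction:.0%} of reads carry both ends "
      f"-> verdict {rep.verdict.value}")
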