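"""Ranking, profiles, length estimation, strandedness diagnostics."""

import math

import numpy as np
import pytest

from telomotif import (
    DetectionParams,
    Read,
    SimParams,
    Verdict,
    asymmetry_ratio,
    canonical_class,
    compute_profile,
    detect_whole_reads,
    estimate_median_length,
    rank_motifs,
    reverse_complement,
    score_terminal_strandedness,
    simulate_library,
)
from telomotif.errors import NoEligibleReadsError
from telomotif.occupancy import OccupancyProfile

from conftest import make_read
from oracles import naive_canonical_key, recount_terminal_occupancy

EXACT = DetectionParams(k_min=4, k_max=20, max_mismatch_frac=0.0, merge_gap=0)


def _guard_base(seq: bytearray, avoid: list[int]) -> int:
    forbidden = {seq[i] for i in avoid}
    for b in b"ACGT":
        if b not in forbidden:
            return b
    return ord("A")


def _tel_read(rng, rid, length, motif, tract, end="three"):
    """Random read with an exact telomeric tract at one end.

    The flank base adjacent to the tract is chosen so that chance
    self-matches cannot extend the tract call across the boundary (keeps
    the constructed-fixture arithmetic exact).
    """
    p = len(motif)
    if end == "three":
        read = make_read(rng, length, rid, tract=(motif, length - tract, length))
        seq = bytearray(read.sequence.encode())
        b = length - tract - 1
        seq[b] = _guard_base(seq, [b + p, b + 4, b + 5])
    else:
        read = make_read(
            rng, length, rid, tract=(reverse_complement(motif), 0, tract)
        )
        seq = bytearray(read.sequence.encode())
        b = tract
        seq[b] = _guard_base(seq, [b - p, b - 4, b - 5])
    from telomotif import Read

    return Read(rid, seq.decode())


class TestRankMotifs:
    def test_constructed_fixture_exact_occupancy(self, rng):
        reads = [
            _tel_read(rng, f"r{i}", 4000, "TTAGGC", 300) for i in range(10)
        ]
        table = rank_motifs(reads, EXACT, t=1000)
        top = table.get(1)
        assert top.motif_class.canonical_key == canonical_class("TTAGGC").canonical_key
        assert top.terminal_occupancy_bp == 3000
        assert table.n_reads_considered == 10

    def test_mid_read_repeats_outside_windows_are_absent(self, rng):
        reads = [
            _tel_read(rng, f"r{i}", 4000, "TTAGGC", 300) for i in range(10)
        ]
        reads += [
            make_read(rng, 4000, f"m{i}", tract=("CACTA", 1700, 2300))
            for i in range(10)
        ]
        table = rank_motifs(reads, EXACT, t=1000)
        keys = {e.motif_class.canonical_key for e in table}
        assert canonical_class("CACTA").canonical_key not in keys

    def test_ranking_matches_independent_recount(self, rng):
        reads = []
        for i in range(6):
            reads.append(_tel_read(rng, f"a{i}", 5000, "TTAGGC", 600))
        for i in range(6):
            reads.append(_tel_read(rng, f"b{i}", 5000, "TTAGG", 300))
        for i in range(6):
            reads.append(_tel_read(rng, f"c{i}", 5000, "TTGCGTCAGGG", 150))
        table = rank_motifs(reads, EXACT, t=1000)
        recount = recount_terminal_occupancy(reads, 4, 20, 1000)
        ours = {
            e.motif_class.canonical_key: e.terminal_occupancy_bp for e in table
        }
        assert ours == recount
        occ = [e.terminal_occupancy_bp for e in table]
        assert occ == sorted(occ, reverse=True)
        assert [e.rank for e in table] == list(range(1, len(table) + 1))

    def test_no_eligible_reads_is_explicit(self, rng):
        reads = [make_read(rng, 1500)]
        with pytest.raises(NoEligibleReadsError, match="2000"):
            rank_motifs(reads, EXACT, t=1000)


class TestComputeProfile:
    def test_single_read_terminal_tract(self, rng):
        n = 500
        read = _tel_read(rng, "r1", 2 * n, "TTAGGC", 300)
        intervals = detect_whole_reads([read], EXACT)
        prof = compute_profile([read], canonical_class("TTAGGC"), intervals, n)
        assert prof.three_prime_fwd[:300].tolist() == [1] * 300
        assert prof.three_prime_fwd[300:].sum() == 0
        assert prof.five_prime_fwd.sum() == 0
        assert prof.five_prime_rev.sum() == 0
        assert prof.three_prime_rev.sum() == 0
        assert prof.middle_fwd_frac == 0 and prof.middle_rev_frac == 0

    def test_reverse_complemented_read_mirrors(self, rng):
        n = 500
        read = _tel_read(rng, "r1", 2 * n, "TTAGGC", 300)
        flipped = Read("r1rc", reverse_complement(read.sequence))
        intervals = detect_whole_reads([flipped], EXACT)
        prof = compute_profile(
            [flipped], canonical_class("TTAGGC"), intervals, n
        )
        assert prof.five_prime_rev[:300].tolist() == [1] * 300
        assert prof.three_prime_fwd.sum() == 0

    def test_occupancy_counts_match_truth_survival(self, telomeric_library):
        """Zero-error simulation: the 3' forward occupancy at depth d is
        exactly the number of 3'-oriented reads whose tract reaches d."""
        reads, truth = telomeric_library
        intervals = detect_whole_reads(reads, EXACT)
        n = 6000
        prof = compute_profile(
            reads, canonical_class("TTAGGC"), intervals, n
        )
        eligible = {r.read_id for r in reads if r.length >= 2 * n}
        lengths = [
            t.true_tract_length
            for t in truth
            if t.read_id in eligible and t.orientation == "three_prime_fwd"
        ]
        expected = np.array(
            [sum(1 for L in lengths if L >= d) for d in range(1, n + 1)]
        )
        # chance self-matches in the random flank can extend or clip a
        # tract call by a few bases at its inner boundary, so the curves
        # agree exactly almost everywhere and never drift further than a
        # couple of reads
        diff = prof.three_prime_fwd - expected
        assert np.abs(diff).max() <= 3
        assert (diff == 0).mean() >= 0.99

    def test_short_reads_excluded_and_window_monotonicity(self, telomeric_library):
        reads, _ = telomeric_library
        intervals = detect_whole_reads(reads, EXACT)
        cls = canonical_class("TTAGGC")
        eligible = []
        for n in (2000, 6000, 9000, 11000):
            prof = compute_profile(reads, cls, intervals, n)
            eligible.append(prof.n_eligible_reads)
            assert prof.n_eligible_reads == sum(
                1 for r in reads if r.length >= 2 * n
            )
        assert eligible == sorted(eligible, reverse=True)

    def test_conservation_per_read(self, rng):
        n = 400
        read = _tel_read(rng, "r1", 3000, "TTAGG", 900)
        intervals = detect_whole_reads([read], EXACT)
        prof = compute_profile([read], canonical_class("TTAGG"), intervals, n)
        terminal = int(
            prof.five_prime_fwd.sum() + prof.three_prime_fwd.sum()
        )
        middle = prof.middle_fwd_frac * prof.middle_bp_total
        assert terminal + middle <= read.length

    def test_unknown_class_warns_and_is_empty(self, rng):
        read = make_read(rng, 2000)
        with pytest.warns(UserWarning, match="empty"):
            prof = compute_profile(
                [read], canonical_class("TTGCGTCAGGG"), {}, 500
            )
        assert prof.three_prime_fwd.sum() == 0


class TestEstimateMedianLength:
    def _profile(self, three, five_rev=None, period=6):
        n = len(three)
        z = np.zeros(n, dtype=np.int64)
        return OccupancyProfile(
            motif_class=canonical_class("TTAGGC"),
            n=n,
            five_prime_fwd=z.copy(),
            five_prime_rev=np.asarray(five_rev if five_rev is not None else z),
            three_prime_fwd=np.asarray(three),
            three_prime_rev=z.copy(),
            middle_fwd_frac=0.0,
            middle_rev_frac=0.0,
            n_eligible_reads=int(np.max(three)) if len(three) else 0,
        )

    def test_step_curve(self):
        three = np.where(np.arange(1, 4001) <= 2000, 10, 0)
        est = estimate_median_length(self._profile(three))
        assert est.median_length_bp == 2000
        assert est.curve_used == "three_prime_fwd"
        assert est.half_level == est.y_max / 2

    def test_all_zero_curve(self):
        est = estimate_median_length(self._profile(np.zeros(100, dtype=int)))
        assert est.median_length_bp == 0 and est.y_max == 0

    def test_picks_stronger_strand_curve(self):
        three = np.where(np.arange(1, 1001) <= 300, 5, 0)
        five = np.where(np.arange(1, 1001) <= 700, 50, 0)
        est = estimate_median_length(self._profile(three, five_rev=five))
        assert est.curve_used == "five_prime_rev"
        assert abs(est.median_length_bp - 700) <= 6

    def test_estimator_consistent_on_zero_error_simulation(self):
        """All tracts on the 3' curve; n >= 4x true median; the estimate
        lands within one period of the empirical truth median."""
        params = SimParams(
            n_reads=220, read_length=(24000, 0.05), motif="TTAGGC",
            telomere_length=(2500, 0.2, "lognormal"),
            three_prime_bias=1.0, seed=77,
        )
        reads, truth = simulate_library(params)
        intervals = detect_whole_reads(reads, EXACT)
        prof = compute_profile(
            reads, canonical_class("TTAGGC"), intervals, 10000
        )
        est = estimate_median_length(prof)
        true_median = np.median([t.true_tract_length for t in truth])
        assert abs(est.median_length_bp - true_median) <= 6


class TestStrandedness:
    def test_perfect_telomeric_fixture(self, rng):
        reads = [
            _tel_read(rng, f"r{i}", 4000, "TTAGGC", 400,
                      end="three" if i % 2 else "five")
            for i in range(10)
        ]
        intervals = detect_whole_reads(reads, EXACT)
        prof = compute_profile(reads, canonical_class("TTAGGC"), intervals, 1000)
        rep = score_terminal_strandedness(prof)
        assert rep.score == 1.0
        assert rep.verdict == Verdict.terminal_stranded

    def test_interstitial_only_fixture_unstranded(self, rng):
        reads = []
        for i in range(10):
            motif = "TTAGGC" if i % 2 else reverse_complement("TTAGGC")
            reads.append(
                make_read(rng, 4000, f"r{i}", tract=(motif, 1700, 2300))
            )
        intervals = detect_whole_reads(reads, EXACT)
        prof = compute_profile(reads, canonical_class("TTAGGC"), intervals, 1000)
        rep = score_terminal_strandedness(prof)
        assert rep.score == 0.0
        assert rep.verdict == Verdict.unstranded

    def test_bipolar_fixture_flagged(self, rng):
        # same class at both ends of every read: the disqualifying pattern
        reads = []
        for i in range(10):
            read = make_read(rng, 4000, f"r{i}", tract=("TTGGGG", 3700, 4000))
            seq = bytearray(read.sequence.encode())
            seq[0:300] = ("CCCCAA" * 50).encode()
            reads.append(Read(f"r{i}", seq.decode()))
        intervals = detect_whole_reads(reads, EXACT)
        prof = compute_profile(reads, canonical_class("TTGGGG"), intervals, 1000)
        rep = score_terminal_strandedness(prof)
        assert rep.bipolar_read_fraction == 1.0
        assert rep.verdict == Verdict.bipolar_suspect

    def test_asymmetry_mirrored_and_one_sided(self):
        n = 100
        up = np.where(np.arange(1, n + 1) <= 50, 10, 0)
        z = np.zeros(n, dtype=np.int64)
        mirrored = OccupancyProfile(
            motif_class=canonical_class("TTAGGC"), n=n,
            five_prime_fwd=z, five_prime_rev=up.copy(),
            three_prime_fwd=up.copy(), three_prime_rev=z,
            middle_fwd_frac=0, middle_rev_frac=0, n_eligible_reads=10,
        )
        assert asymmetry_ratio(mirrored) == 1.0
        one_sided = OccupancyProfile(
            motif_class=canonical_class("TTAGGC"), n=n,
            five_prime_fwd=z, five_prime_rev=z,
            three_prime_fwd=up.copy(), three_prime_rev=z,
            middle_fwd_frac=0, middle_rev_frac=0, n_eligible_reads=10,
        )
        assert asymmetry_ratio(one_sided) == math.inf

    def test_asymmetry_tracks_simulated_bias(self):
        params = SimParams(
            n_reads=300, read_length=(12000, 0.05), motif="TTAGGC",
            telomere_length=(1500, 0.1, "lognormal"),
            three_prime_bias=0.9, seed=31,
        )
        reads, _ = simulate_library(params)
        intervals = detect_whole_reads(reads, EXACT)
        prof = compute_profile(reads, canonical_class("TTAGGC"), intervals, 3000)
        ratio = asymmetry_ratio(prof)
        # 270:30 expectation; allow ~3 sigma of binomial noise on each count
        assert 5 <= ratio <= 20
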