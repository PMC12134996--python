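"""Tandem repeat detection on long reads.

The detector works per candidate period p: positions i where
``s[i] == s[i+p]`` form a self-match array, maximal runs of matches are
tandem segments, and the consensus motif is the column-majority base over
the copies.  With a nonzero mismatch tolerance, exact runs at least one
period long act as seeds and are greedily extended across short mismatch
gaps.  Consensus motifs that are an integer power of a shorter motif are
reduced to the primitive motif, so one telomere tract yields one period,
not every multiple of it.

With ``max_mismatch_frac=0`` the output is exactly the set of maximal
exact tandem runs (verifiable against brute-force enumeration); the
tolerant mode is a deliberately simple seed-and-extend scheme suited to
the ~1-10% error of long reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .motifs import canonical_class, primitive_root
from .seqio import Read, RepeatInterval

__all__ = ["DetectionParams", "find_tandem_repeats", "consensus_motif"]

_N = ord("N")
_BASES = "ACGT"


@dataclass(frozen=True)
class DetectionParams:
    """Tuning knobs of the detector.

    k_min, k_max
        Shortest and longest repeat period considered, in bp.
    min_copies
        Minimum (possibly fractional) number of tandem copies to report.
    max_mismatch_frac
        Tolerated fraction of self-match failures within a reported run;
        0 gives exact detection.
    merge_gap
        Same-class intervals separated by at most this many bases are
        fused into one interval (the gap bases are remembered and never
        counted as occupancy).
    """

    k_min: int = 4
    k_max: int = 20
    min_copies: float = 2.0
    max_mismatch_frac: float = 0.2
    merge_gap: int = 50

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError(f"k_min must be >= 1, got {self.k_min}")
        if self.k_min > self.k_max:
            raise ValueError(f"k_min {self.k_min} > k_max {self.k_max}")
        if self.min_copies < 2:
            raise ValueError(f"min_copies must be >= 2, got {self.min_copies}")
        if not (0 <= self.max_mismatch_frac <= 0.3):
            raise ValueError(
                f"max_mismatch_frac must be in [0, 0.3], got {self.max_mismatch_frac}"
            )
        if self.merge_gap < 0:
            raise ValueError(f"merge_gap must be >= 0, got {self.merge_gap}")


def consensus_motif(segment: str, period: int) -> str:
    """Column-majority consensus of a tandem segment.

    Position j of the result is the majority base among segment positions
    congruent to j modulo ``period``; ties go to the fixed order A<C<G<T,
    and N never wins a majority.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    if len(segment) < period:
        raise ValueError(
            f"segment of {len(segment)} bp shorter than period {period}"
        )
    arr = np.frombuffer(segment.encode(), dtype=np.uint8)
    ncopies = -(-arr.size // period)
    padded = np.zeros(ncopies * period, dtype=np.uint8)
    padded[: arr.size] = arr
    grid = padded.reshape(ncopies, period)
    counts = np.stack([(grid == ord(b)).sum(axis=0) for b in _BASES])
    # argmax tie-break picks the first (smallest) base index, i.e. A<C<G<T
    return "".join(_BASES[i] for i in counts.argmax(axis=0))


def _true_runs(match: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and (exclusive) ends of maximal True runs of a bool array."""
    if match.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    m = match.astype(np.int8)
    diff = np.diff(m)
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if match[0]:
        starts = np.concatenate(([0], starts))
    if match[-1]:
        ends = np.concatenate((ends, [match.size]))
    return starts, ends


def _tolerant_runs(
    starts: np.ndarray, ends: np.ndarray, p: int, frac: float
) -> list[tuple[int, int]]:
    """Greedy seed-and-extend merge of exact runs across mismatch gaps.

    Seeds are exact runs of length >= p (one clean period).  A seed is
    extended over a neighbouring run only if the gap is shorter than the
    period and small relative to that run (each crossed segment carries a
    mismatch fraction of at most ``frac``).  The criterion is local on
    purpose: a long tract must not bank a mismatch budget that lets the
    call march into unrelated flanking sequence.  Emitted spans never
    overlap; scanning is left to right, so the result is deterministic.
    """
    out: list[tuple[int, int]] = []
    n_runs = starts.size
    ratio = frac / (1 - frac)
    claimed = 0  # match-array coordinate below which everything is taken
    k = 0
    while k < n_runs:
        if ends[k] - starts[k] < p or starts[k] < claimed:
            k += 1
            continue
        lo, hi = int(starts[k]), int(ends[k])
        # extend right
        j = k + 1
        while j < n_runs:
            gap = int(starts[j]) - hi
            run = int(ends[j]) - int(starts[j])
            if gap >= p or gap > ratio * run:
                break
            hi = int(ends[j])
            j += 1
        # extend left
        i = k - 1
        while i >= 0:
            gap = lo - int(ends[i])
            run = int(ends[i]) - int(starts[i])
            if gap >= p or gap > ratio * run or int(starts[i]) < claimed:
                break
            lo = int(starts[i])
            i -= 1
        out.append((lo, hi))
        claimed = hi
        k = j
    return out


def _candidates_for_region(
    region: str, params: DetectionParams
) -> list[tuple[int, int, int, str]]:
    """All (start, end, period, motif) candidates before overlap resolution."""
    arr = np.frombuffer(region.encode(), dtype=np.uint8)
    n = arr.size
    seen: set[tuple[int, int, int, str]] = set()
    cands: list[tuple[int, int, int, str]] = []
    for p in range(params.k_min, min(params.k_max, n // 2) + 1):
        a, b = arr[:-p], arr[p:]
        match = (a == b) & (a != _N)
        starts, ends = _true_runs(match)
        if params.max_mismatch_frac == 0:
            spans = [(int(s), int(e)) for s, e in zip(starts, ends)]
        else:
            spans = _tolerant_runs(starts, ends, p, params.max_mismatch_frac)
        for lo, hi in spans:
            seg_len = hi - lo + p
            if seg_len / p < params.min_copies:
                continue
            motif = consensus_motif(region[lo : lo + seg_len], p)
            root = primitive_root(motif)
            period = len(root)
            if period < params.k_min:
                continue  # e.g. homopolymer found at a larger period
            if seg_len / period < params.min_copies:
                continue
            cand = (lo, lo + seg_len, period, root)
            if cand not in seen:
                seen.add(cand)
                cands.append(cand)
    return cands


def resolve_overlaps(
    cands: list[tuple[int, int, int, str]],
    region: str,
    min_copies: float,
) -> list[tuple[int, int, int, str]]:
    """Resolve overlapping calls of different periods into disjoint calls.

    Priority order: smaller period, then longer interval, then smaller
    canonical key.  A lower-priority call keeps only the parts of its span
    not already claimed; surviving fragments are re-consensused (their
    phase may have shifted) and kept only if they still carry
    ``min_copies`` copies.  Trimming rather than dropping matters: a
    two-copy blip of a short period straddling a telomere boundary must
    not erase a kilobases-long tract call.
    """
    if not cands:
        return []
    order = sorted(
        cands,
        key=lambda c: (
            c[2],
            -(c[1] - c[0]),
            canonical_class(c[3]).canonical_key,
            c[0],
            c[3],
        ),
    )
    claimed = np.zeros(len(region), dtype=bool)
    accepted: list[tuple[int, int, int, str]] = []
    for lo, hi, period, motif in order:
        if not claimed[lo:hi].any():
            accepted.append((lo, hi, period, motif))
            claimed[lo:hi] = True
            continue
        free = ~claimed[lo:hi]
        starts, ends = _true_runs(free)
        for s, e in zip(starts, ends):
            s, e = lo + int(s), lo + int(e)
            if (e - s) / period < min_copies or (e - s) < period:
                continue
            frag_motif = consensus_motif(region[s:e], period)
            # a fragment of a primitive-period region keeps its period; if
            # reduction says otherwise the fragment is degenerate -- drop it
            if len(primitive_root(frag_motif)) != period:
                continue
            accepted.append((s, e, period, frag_motif))
            claimed[s:e] = True
    accepted.sort()
    return accepted


def _merge_same_class(
    accepted: list[tuple[int, int, int, str]], merge_gap: int
) -> list[tuple[int, int, int, str, tuple[tuple[int, int], ...]]]:
    """Fuse same-class neighbours within merge_gap; keep covered sub-spans."""
    groups: dict[str, list[tuple[int, int, int, str]]] = {}
    for cand in accepted:
        groups.setdefault(canonical_class(cand[3]).canonical_key, []).append(cand)
    merged = []
    for key in sorted(groups):
        chain: list[tuple[int, int, int, str]] = []
        spans: list[tuple[int, int]] = []
        for cand in sorted(groups[key]):
            if chain and cand[0] - chain[-1][1] <= merge_gap:
                chain.append(cand)
                spans.append((cand[0], cand[1]))
            else:
                if chain:
                    merged.append(_finish_chain(chain, spans))
                chain = [cand]
                spans = [(cand[0], cand[1])]
        if chain:
            merged.append(_finish_chain(chain, spans))
    merged.sort()
    return merged


def _finish_chain(chain, spans):
    start, end = chain[0][0], chain[-1][1]
    period, motif = chain[0][2], chain[0][3]
    coalesced: list[tuple[int, int]] = []
    for s, e in spans:
        if coalesced and s <= coalesced[-1][1]:
            coalesced[-1] = (coalesced[-1][0], max(e, coalesced[-1][1]))
        else:
            coalesced.append((s, e))
    covered = tuple(coalesced) if len(coalesced) > 1 else None
    return (start, end, period, motif, covered)


def find_tandem_repeats(
    read: Read,
    params: DetectionParams,
    window: Optional[tuple[int, int]] = None,
) -> list[RepeatInterval]:
    """Detect tandem repeats on a read, optionally restricted to a window.

    Returns maximal intervals carrying at least ``min_copies`` tandem
    copies of a primitive motif with period in [k_min, k_max].  Overlapping
    calls of different periods are resolved (smaller period, then longer
    interval, then smaller canonical key) and same-class intervals within
    ``merge_gap`` are fused.  Coordinates are on the read, 0-based
    half-open, even when a window is given.
    """
    if window is None:
        a, b = 0, read.length
    else:
        a, b = window
        if not (0 <= a < b <= read.length):
            raise ValueError(
                f"window [{a},{b}) outside read {read.read_id} "
                f"of {read.length} bp"
            )
    region = read.sequence[a:b]
    cands = _candidates_for_region(region, params)
    accepted = resolve_overlaps(cands, region, params.min_copies)
    merged = _merge_same_class(accepted, params.merge_gap)
    intervals = []
    for start, end, period, motif, covered in merged:
        if covered is not None:
            covered = tuple((s + a, e + a) for s, e in covered)
            copies = sum(e - s for s, e in covered) / period
        else:
            copies = (end - start) / period
        intervals.append(
            RepeatInterval(
                read_id=read.read_id,
                start=start + a,
                end=end + a,
                period=period,
                motif=motif,
                copy_number=copies,
                read_length=read.length,
                covered=covered,
            )
        )
    intervals.sort(key=lambda iv: (iv.start, iv.period))
    return intervals
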