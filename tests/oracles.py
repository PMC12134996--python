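"""Independent brute-force oracles for the test suite.

Everything here is written against the *contract* of the operations it
checks, from scratch and in plain Python, so it shares no code path with
the package implementation.
"""

from __future__ import annotations

from collections import Counter

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def naive_rotations(s: str) -> list[str]:
    return [s[i:] + s[:i] for i in range(len(s))]


def naive_canonical_key(motif: str) -> str:
    """Smallest string over all rotations of motif and its revcomp."""
    # reduce to primitive root first
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif == motif[:d] * (n // d):
            motif = motif[:d]
            break
    return min(naive_rotations(motif) + naive_rotations(naive_revcomp(motif)))


def naive_consensus(segment: str, period: int) -> str:
    """Column majority with A<C<G<T tie-break; N never counted."""
    out = []
    for j in range(period):
        col = Counter(
            segment[i] for i in range(j, len(segment), period)
            if segment[i] != "N"
        )
        if not col:
            out.append("A")
            continue
        # highest count wins; ties go to A<C<G<T
        top = max(col.values())
        best = min(b for b in "ACGT" if col.get(b, 0) == top)
        out.append(best)
    return "".join(out)


def brute_force_tandem(
    seq: str,
    k_min: int,
    k_max: int,
    min_copies: float = 2.0,
    merge_gap: int = 0,
) -> set[tuple]:
    """Exact-mode reference detector: enumerate every (start, period) pair,
    keep maximal primitive runs with enough copies, resolve overlaps by
    (period, -length, canonical key, start), then fuse same-class
    neighbours within merge_gap.

    Returns a set of (start, end, period, motif, covered_bases) tuples.
    """
    n = len(seq)
    cands = set()
    for p in range(k_min, min(k_max, n // 2) + 1):
        j = 0
        while j < n - p:
            if seq[j] == seq[j + p] and seq[j] != "N":
                start = j
                while j < n - p and seq[j] == seq[j + p] and seq[j] != "N":
                    j += 1
                end = j + p
                if (end - start) / p >= min_copies:
                    unit = seq[start : start + p]
                    root = unit
                    for d in range(1, p):
                        if p % d == 0 and unit == unit[:d] * (p // d):
                            root = unit[:d]
                            break
                    if (
                        len(root) >= k_min
                        and (end - start) / len(root) >= min_copies
                    ):
                        cands.add((start, end, len(root), root))
            else:
                j += 1
    # overlap resolution: priority (smaller period, longer interval,
    # smaller key); lower-priority calls are trimmed to unclaimed bases,
    # fragments re-consensused and kept only with enough copies
    order = sorted(
        cands,
        key=lambda c: (
            c[2], -(c[1] - c[0]), naive_canonical_key(c[3]), c[0], c[3]
        ),
    )
    claimed = [False] * n
    accepted: list[tuple] = []
    for lo, hi, period, motif in order:
        if not any(claimed[lo:hi]):
            accepted.append((lo, hi, period, motif))
            for i in range(lo, hi):
                claimed[i] = True
            continue
        i = lo
        while i < hi:
            if claimed[i]:
                i += 1
                continue
            s = i
            while i < hi and not claimed[i]:
                i += 1
            e = i
            if (e - s) / period < min_copies:
                continue
            frag_motif = naive_consensus(seq[s:e], period)
            root = frag_motif
            for d in range(1, period):
                if period % d == 0 and frag_motif == frag_motif[:d] * (period // d):
                    root = frag_motif[:d]
                    break
            if len(root) != period:
                continue
            accepted.append((s, e, period, frag_motif))
            for j in range(s, e):
                claimed[j] = True
    accepted.sort()
    # same-class merging
    by_class: dict[str, list[tuple]] = {}
    for c in accepted:
        by_class.setdefault(naive_canonical_key(c[3]), []).append(c)
    out = set()
    for key in by_class:
        chain: list[tuple] = []
        for c in sorted(by_class[key]):
            if chain and c[0] - chain[-1][1] <= merge_gap:
                chain.append(c)
            else:
                if chain:
                    out.add(_chain_tuple(chain))
                chain = [c]
        if chain:
            out.add(_chain_tuple(chain))
    return out


def _chain_tuple(chain: list[tuple]) -> tuple:
    covered = sum(c[1] - c[0] for c in chain)
    return (chain[0][0], chain[-1][1], chain[0][2], chain[0][3], covered)


def intervals_as_tuples(intervals) -> set[tuple]:
    """Project package RepeatIntervals onto the oracle tuple space."""
    return {
        (iv.start, iv.end, iv.period, iv.motif, iv.covered_bases())
        for iv in intervals
    }


def recount_terminal_occupancy(reads, k_min, k_max, t) -> dict[str, int]:
    """Independent recount of clipped terminal occupancy per class."""
    totals: dict[str, int] = {}
    for read in reads:
        if read.length < 2 * t:
            continue
        for a, b in ((0, t), (read.length - t, read.length)):
            window_seq = read.sequence[a:b]
            for s, e, per, motif, covered in brute_force_tandem(
                window_seq, k_min, k_max
            ):
                key = naive_canonical_key(motif)
                totals[key] = totals.get(key, 0) + covered
    return totals
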