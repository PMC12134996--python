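"""Synthetic long-read libraries with ground-truth telomere annotations.

The generator emulates the regimes a telomere-motif search meets in real
libraries: ordinary telomeric reads (tract at one end, mirrored between
strands), spillover (tracts as long as or longer than the reads), 3'-biased
transposase libraries, a subtelomeric tandem element at a fixed offset from
the read end, and interstitial (mid-read) repeats as negative controls.
Sequencing error is i.i.d. per-base substitution/insertion/deletion --
deliberately platform-agnostic, since the consumer is the detection and
estimation code, not a basecaller.  Truth records the tract as placed
before errors are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import GeometryError
from .motifs import primitive_root, reverse_complement
from .seqio import Read

__all__ = ["SimParams", "SimTruth", "simulate_library", "apply_errors",
           "write_truth_table", "read_truth_table"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated library.

    read_length
        (median bp, lognormal sigma) of read lengths.
    telomere_length
        (median bp, dispersion, family); family "lognormal" treats the
        dispersion as the sigma of log length, "normal-truncated" as the
        coefficient of variation of a normal truncated at one period.
    three_prime_bias
        Probability a telomeric read carries its tract at the 3' end in
        forward orientation (vs 5' end as the reverse complement);
        0.5 is a normal library, 1.0 a transposase ultra-long library.
    subtelomere / interstitial
        Optional (motif, tract bp, offset bp from read end) element near
        the telomeric end, and optional (motif, tract bp) element placed
        mid-read on every read.
    """

    n_reads: int = 500
    read_length: tuple[float, float] = (30000, 0.1)
    telomeric_read_fraction: float = 1.0
    motif: str = "TTAGGC"
    telomere_length: tuple[float, float, str] = (2500, 0.2, "lognormal")
    error_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    three_prime_bias: float = 0.5
    subtelomere: Optional[tuple[str, int, int]] = None
    interstitial: Optional[tuple[str, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.telomeric_read_fraction <= 1):
            raise ValueError("telomeric_read_fraction must be in [0, 1]")
        if not (0 <= self.three_prime_bias <= 1):
            raise ValueError("three_prime_bias must be in [0, 1]")
        if any(not (0 <= r <= 0.15) for r in self.error_rates):
            raise ValueError("each error rate must be in [0, 0.15]")
        if primitive_root(self.motif) != self.motif:
            raise ValueError(
                f"motif {self.motif} is a power of a shorter motif"
            )
        if self.telomere_length[2] not in ("lognormal", "normal-truncated"):
            raise ValueError(
                f"unknown tract length family {self.telomere_length[2]!r}"
            )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated read (pre-error coordinates)."""

    read_id: str
    is_telomeric: bool
    true_tract_length: int
    orientation: Optional[str]  # "three_prime_fwd" | "five_prime_rev" | None
    tract_start: int
    tract_end: int


def _tile(motif: str, length: int) -> str:
    return (motif * (length // len(motif) + 1))[:length]


def _draw_tract(rng: np.random.Generator, spec: tuple[float, float, str],
                period: int) -> int:
    median, disp, family = spec
    if family == "lognormal":
        length = median * math.exp(disp * rng.standard_normal())
    else:  # normal-truncated
        length = rng.normal(median, disp * median)
    return max(period, int(round(length)))


def simulate_library(params: SimParams) -> tuple[list[Read], list[SimTruth]]:
    """Generate a read library and its per-read telomere ground truth.

    Deterministic for a given seed.  Telomeric tracts are exact motif
    repeats truncated at the read length (the spillover regime arises
    naturally once tracts reach read size); errors are applied afterwards,
    and truth keeps pre-error lengths and coordinates.
    """
    rng = np.random.default_rng(params.seed)
    med_L, sigma_L = params.read_length
    period = len(params.motif)
    reads: list[Read] = []
    truths: list[SimTruth] = []
    for i in range(params.n_reads):
        read_id = f"sim{i:05d}"
        L = max(2 * period, int(round(med_L * math.exp(sigma_L * rng.standard_normal()))))
        arr = _BASES[rng.integers(0, 4, size=L)]
        seq = bytearray(arr.tobytes())
        is_telomeric = rng.random() < params.telomeric_read_fraction
        three_prime = rng.random() < params.three_prime_bias
        tract_len = 0
        tract_start = tract_end = 0
        orientation = None
        if is_telomeric:
            tract_len = min(_draw_tract(rng, params.telomere_length, period), L)
            if three_prime:
                orientation = "three_prime_fwd"
                tract_start, tract_end = L - tract_len, L
                seq[tract_start:tract_end] = _tile(params.motif, tract_len).encode()
            else:
                orientation = "five_prime_rev"
                tract_start, tract_end = 0, tract_len
                seq[tract_start:tract_end] = _tile(
                    reverse_complement(params.motif), tract_len
                ).encode()
        if params.subtelomere is not None:
            sub_motif, sub_len, offset = params.subtelomere
            if offset + sub_len > L:
                raise GeometryError(
                    f"subtelomere offset {offset} + tract {sub_len} exceeds "
                    f"read length {L} ({read_id})"
                )
            if three_prime:
                s = L - offset - sub_len
                seq[s : s + sub_len] = _tile(sub_motif, sub_len).encode()
            else:
                seq[offset : offset + sub_len] = _tile(
                    reverse_complement(sub_motif), sub_len
                ).encode()
        if params.interstitial is not None:
            int_motif, int_len = params.interstitial
            if int_len > L:
                raise GeometryError(
                    f"interstitial tract {int_len} exceeds read length {L}"
                )
            s = (L - int_len) // 2
            unit = (
                int_motif if rng.random() < 0.5 else reverse_complement(int_motif)
            )
            seq[s : s + int_len] = _tile(unit, int_len).encode()
        final = seq.decode()
        # always drawn, so libraries differing only in error rates share
        # identical pre-error reads for a given seed (paired comparisons)
        err_seed = int(rng.integers(0, 2**31 - 1))
        if any(r > 0 for r in params.error_rates):
            final = apply_errors(final, params.error_rates, seed=err_seed)
        reads.append(Read(read_id=read_id, sequence=final))
        truths.append(
            SimTruth(
                read_id=read_id,
                is_telomeric=is_telomeric,
                true_tract_length=tract_len,
                orientation=orientation,
                tract_start=tract_start,
                tract_end=tract_end,
            )
        )
    return reads, truths


def apply_errors(
    seq: str, rates: tuple[float, float, float], seed: int
) -> str:
    """Apply i.i.d. per-base substitution/insertion/deletion errors.

    Each base is independently substituted (by a uniformly chosen
    different base) or deleted; independently, a random base is inserted
    after each position with the insertion probability.  Deterministic for
    a given seed; the expected length change is len * (ins - del).
    """
    p_sub, p_ins, p_del = rates
    if any(not (0 <= r <= 0.15) for r in rates):
        raise ValueError("each error rate must be in [0, 0.15]")
    if not seq or (p_sub == 0 and p_ins == 0 and p_del == 0):
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[arr]
    sub_mask = rng.random(n) < p_sub
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        idx[sub_mask] = (idx[sub_mask] + shift) % 4
        arr = _BASES[idx]
    keep = rng.random(n) >= p_del
    kept = arr[keep]
    ins_mask = rng.random(n) < p_ins
    if ins_mask.any():
        ins_pos = np.flatnonzero(ins_mask)
        # insert after original base i -> before kept-index cumsum(keep)[i]
        targets = np.cumsum(keep)[ins_pos]
        ins_bases = _BASES[rng.integers(0, 4, size=ins_pos.size)]
        kept = np.insert(kept, targets, ins_bases)
    return kept.tobytes().decode()


def write_truth_table(truths: list[SimTruth], path: str | Path) -> None:
    """Tab-separated ground-truth table (consumed by tests and examples)."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tis_telomeric\ttrue_tract_length\torientation"
            "\ttract_start\ttract_end\n"
        )
        for t in truths:
            fh.write(
                f"{t.read_id}\t{int(t.is_telomeric)}\t{t.true_tract_length}"
                f"\t{t.orientation or '.'}\t{t.tract_start}\t{t.tract_end}\n"
            )


def read_truth_table(path: str | Path) -> list[SimTruth]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, tel, length, orient, s, e = line.rstrip("\n").split("\t")
            out.append(
                SimTruth(
                    read_id=rid,
                    is_telomeric=bool(int(tel)),
                    true_tract_length=int(length),
                    orientation=None if orient == "." else orient,
                    tract_start=int(s),
                    tract_end=int(e),
                )
            )
    return out
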