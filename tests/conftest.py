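import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from telomotif import DetectionParams, Read, SimParams, simulate_library


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exact_params():
    """Exact detection: no mismatch tolerance, no gap merging."""
    return DetectionParams(k_min=4, k_max=20, max_mismatch_frac=0.0, merge_gap=0)


@pytest.fixture
def default_params():
    return DetectionParams()


def make_read(rng, length, read_id="read1", tract=None):
    """Random read, optionally with a repeat tract written over a span.

    tract: (motif, start, end) — motif tiled over [start, end).
    """
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytearray(bases[rng.integers(0, 4, size=length)].tobytes())
    if tract is not None:
        motif, start, end = tract
        tiled = (motif * ((end - start) // len(motif) + 1))[: end - start]
        seq[start:end] = tiled.encode()
    return Read(read_id=read_id, sequence=seq.decode())


@pytest.fixture
def telomeric_library():
    """Small zero-error telomeric library with truth (shared across tests)."""
    params = SimParams(
        n_reads=120,
        read_length=(20000, 0.1),
        motif="TTAGGC",
        telomere_length=(2500, 0.2, "lognormal"),
        seed=2024,
    )
    return simulate_library(params)
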