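"""Shared fixtures: the simulated panel and its precomputed aligner runs."""

from __future__ import annotations

import numpy as np
import pytest

from diagpart import Segment, simulate_panel
from diagpart.toy_aligner import find_seeds, gapped_extend, ungapped_extend

# fixed study seed for the suite; the acceptance script takes its own --seed
SUITE_SEED = 20240917


def make_random_segments(
    rng: np.random.Generator,
    n: int,
    with_reverse: bool = True,
    coord_span: int = 10_000,
) -> list[Segment]:
    """Random valid Segments for partitioning property tests."""
    out = []
    for _ in range(n):
        length = int(rng.integers(1, 200))
        ts = int(rng.integers(0, coord_span))
        qs = int(rng.integers(0, coord_span))
        strand = "-" if (with_reverse and rng.random() < 0.4) else "+"
        score = int(rng.integers(0, 10_000))
        out.append(
            Segment("t", ts, ts + length, "q", qs, qs + length, strand, score)
        )
    return out


@pytest.fixture(scope="session")
def panel_2kb():
    """The <=2 kb half of the benchmark panel (2 lengths x 41 divergences)."""
    return [p for p in simulate_panel(SUITE_SEED) if p.requested_length <= 2000]


@pytest.fixture(scope="session")
def panel_2kb_runs(panel_2kb):
    """Per-pair (pair, segments, unpartitioned reference alignments).

    Computed once per session; the reference run is the oracle that the
    partitioned runs in the acceptance tests are compared against.
    """
    runs = []
    for p in panel_2kb:
        seeds = find_seeds(p.seq_a, p.seq_b)
        segments = ungapped_extend(seeds, p.seq_a, p.seq_b)
        reference = gapped_extend(segments, p.seq_a, p.seq_b)
        runs.append((p, segments, reference))
    return runs
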