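"""Simulated homologous sequence pairs with controlled divergence.

The generator emulates the benchmark panel used to probe aligner
sensitivity: homologous cores of 1, 2, 5 and 10 kb diverged by 0-40%
substitutions in 1% steps, with short indels (1-5 nt, at 1% per position)
and random 1 kb flanks on both sides of both sequences.  The full panel is
the cross of 4 lengths x 41 divergence levels = 164 pairs.

The generator keeps an exact event log (which aligned core positions were
substituted, how many core positions are aligned at all), so the realized
divergence of a pair can be computed from bookkeeping alone, without
running any aligner.  All randomness comes from numpy's PCG64 generator
seeded from the caller's seed, so identical seeds give identical panels on
any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SequencePair",
    "simulate_pair",
    "simulate_panel",
    "realized_divergence",
    "PANEL_LENGTHS",
    "PANEL_DIVERGENCES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PANEL_LENGTHS = (1000, 2000, 5000, 10000)
PANEL_DIVERGENCES = tuple(range(0, 41))


@dataclass(frozen=True)
class SequencePair:
    """A simulated homologous pair with known core boundaries.

    ``core_a``/``core_b`` are the 0-based half-open intervals of the
    homologous cores (everything outside them is random flank).
    ``aligned_positions``/``substituted_positions`` are the generator's own
    event counts over aligned (non-indel) core positions.
    """

    seq_a: str
    seq_b: str
    core_a: tuple[int, int]
    core_b: tuple[int, int]
    requested_length: int
    divergence: float
    seed: int
    aligned_positions: int = field(default=0, repr=False)
    substituted_positions: int = field(default=0, repr=False)


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def simulate_pair(
    length: int,
    divergence: float,
    seed: int,
    indel_rate: float = 0.01,
    indel_sizes: tuple[int, int] = (1, 5),
    flank: int = 1000,
) -> SequencePair:
    """Generate one homologous pair.

    The ancestral core is uniform over ACGT.  The derived core applies
    substitutions at ``divergence`` percent per position (each substituted
    base replaced uniformly by one of the three alternatives), then indel
    events at ``indel_rate`` per ancestral position with sizes uniform on
    ``indel_sizes`` and insertion/deletion equally likely.  Substitutions
    are applied before indels, on the ancestral coordinate frame, which
    keeps the divergence accounting exact.  Finally ``flank`` random bases
    are prepended and appended to both sequences (four independent flanks).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= divergence <= 100):
        raise ValueError("divergence must be in [0, 100] percent")
    if indel_rate < 0 or indel_rate > 1:
        raise ValueError("indel_rate must be in [0, 1]")
    if flank < 0:
        raise ValueError("flank must be >= 0")

    rng = np.random.default_rng(seed)
    ancestral = _random_bases(rng, length)

    # per-position draws, fixed up front for determinism
    sub_mask = rng.random(length) < divergence / 100.0
    sub_shift = rng.integers(1, 4, size=length)
    indel_u = rng.random(length)
    indel_is_ins = rng.random(length) < 0.5
    lo, hi = indel_sizes
    indel_size = rng.integers(lo, hi + 1, size=length)

    derived = ancestral.copy()
    derived[sub_mask] = _BASES[
        (np.searchsorted(_BASES, ancestral[sub_mask]) + sub_shift[sub_mask]) % 4
    ]

    out: list[np.ndarray] = []
    aligned = 0
    substituted = 0
    i = 0
    while i < length:
        if indel_u[i] < indel_rate:
            size = int(indel_size[i])
            if indel_is_ins[i]:
                out.append(_random_bases(rng, size))
                # the current position itself is still aligned below
            else:
                i += size  # deleted ancestral positions are unaligned
                continue
        out.append(derived[i : i + 1])
        aligned += 1
        if sub_mask[i]:
            substituted += 1
        i += 1

    derived_core = np.concatenate(out) if out else np.empty(0, dtype=np.uint8)
    fa1, fa2 = _random_bases(rng, flank), _random_bases(rng, flank)
    fb1, fb2 = _random_bases(rng, flank), _random_bases(rng, flank)
    seq_a = np.concatenate([fa1, ancestral, fa2]).tobytes().decode("ascii")
    seq_b = np.concatenate([fb1, derived_core, fb2]).tobytes().decode("ascii")
    return SequencePair(
        seq_a=seq_a,
        seq_b=seq_b,
        core_a=(flank, flank + length),
        core_b=(flank, flank + len(derived_core)),
        requested_length=length,
        divergence=float(divergence),
        seed=int(seed),
        aligned_positions=aligned,
        substituted_positions=substituted,
    )


def simulate_panel(
    seed: int,
    lengths: Sequence[int] = PANEL_LENGTHS,
    divergences: Sequence[float] = PANEL_DIVERGENCES,
    indel_rate: float = 0.01,
) -> list[SequencePair]:
    """The full benchmark panel: one pair per (length, divergence) combination.

    With the defaults this is 4 lengths x 41 divergence levels = 164 pairs.
    Per-pair seeds are derived deterministically from the master seed, so
    two calls with the same master seed produce identical panels.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(lengths) * len(divergences))
    panel = []
    idx = 0
    for length in lengths:
        for d in divergences:
            child_seed = int(children[idx].generate_state(1, np.uint32)[0]) % (2**31)
            panel.append(
                simulate_pair(length, d, seed=child_seed, indel_rate=indel_rate)
            )
            idx += 1
    return panel


def realized_divergence(pair: SequencePair) -> float:
    """Substituted fraction (percent) among aligned core positions.

    Computed from the generator's own event log; no alignment is performed.
    """
    if pair.aligned_positions == 0:
        raise ValueError("pair carries no event log (no aligned positions)")
    return 100.0 * pair.substituted_positions / pair.aligned_positions
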