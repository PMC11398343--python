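"""Scoring schemes for the toy seed-filter-extend aligner.

The default substitution scores are the published HOXD70 matrix with the
classic affine gap penalties used alongside it (open 400, extend 30, a gap
of length g costing open + g*extend).  The remaining knobs are the
termination thresholds of the two extension stages: ``x_drop`` for the
ungapped diagonal extension, ``y_drop`` for the gapped extension, and the
minimum ungapped score ``hsp_threshold`` below which an HSP is discarded.

``x_drop`` and ``hsp_threshold`` follow the common defaults of the tool
family this package emulates; ``y_drop`` defaults to 3000 — large enough
to carry gapped extension across the short (1-5 nt) indels and local
mismatch runs of the simulated panel, while keeping the live DP band
(width ~ 2*y_drop/gap_extend) proportionate to the kilobase-scale
sequences this aligner is meant for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

__all__ = [
    "ScoringScheme",
    "hoxd70",
    "simple_scheme",
    "load_scheme",
    "encode",
    "revcomp",
    "ALPHABET",
]

ALPHABET = "ACGTN"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
# N never matches anything, including itself
_N_SCORE = -10_000

_HOXD70_ROWS = (
    (91, -114, -31, -123),
    (-114, 100, -125, -31),
    (-31, -125, 100, -114),
    (-123, -31, -114, 91),
)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap and termination parameters.

    ``matrix`` is a 5x5 int array over A,C,G,T,N.  Penalties are positive
    magnitudes; a length-g gap costs ``gap_open + g * gap_extend``.
    """

    matrix: np.ndarray
    gap_open: int = 400
    gap_extend: int = 30
    x_drop: int = 910
    y_drop: int = 3000
    hsp_threshold: int = 3000

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.shape != (5, 5):
            raise ValueError("matrix must be 5x5 over A,C,G,T,N")
        core = m[:4, :4]
        if not np.array_equal(core, core.T):
            raise ValueError("substitution matrix must be symmetric")
        if core.diagonal().min() < core[~np.eye(4, dtype=bool)].max():
            raise ValueError("match scores must dominate mismatch scores")
        for name in ("gap_open", "gap_extend", "x_drop", "y_drop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "matrix", m)

    def match_score(self, a: str, b: str) -> int:
        return int(self.matrix[_INDEX[a], _INDEX[b]])


def _full_matrix(core_rows) -> np.ndarray:
    m = np.full((5, 5), _N_SCORE, dtype=np.int64)
    m[:4, :4] = np.asarray(core_rows, dtype=np.int64)
    return m


def hoxd70(**overrides) -> ScoringScheme:
    """The default scheme: HOXD70 substitution scores, gaps 400+30/base."""
    return ScoringScheme(matrix=_full_matrix(_HOXD70_ROWS), **overrides)


def simple_scheme(match: int = 10, mismatch: int = -9, **overrides) -> ScoringScheme:
    """Uniform match/mismatch scheme, handy for hand-checkable tests."""
    core = np.full((4, 4), mismatch, dtype=np.int64)
    np.fill_diagonal(core, match)
    return ScoringScheme(matrix=_full_matrix(core), **overrides)


def load_scheme(source: IO[str] | Iterable[str]) -> ScoringScheme:
    """Parse a scheme from text.

    Format: optional ``key = value`` lines (gap_open, gap_extend, x_drop,
    y_drop, hsp_threshold), then a header line with the four bases and four
    matrix rows ``base s s s s``.  ``#`` comments and blank lines ignored.
    """
    params: dict[str, int] = {}
    order: list[str] = []
    rows: dict[str, list[int]] = {}
    for raw in source:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, val = (p.strip() for p in line.split("=", 1))
            params[key] = int(val)
            continue
        fields = line.split()
        if not order:
            if sorted(f.upper() for f in fields) != ["A", "C", "G", "T"]:
                raise ValueError("matrix header must list the four bases A C G T")
            order = [f.upper() for f in fields]
        else:
            base = fields[0].upper()
            rows[base] = [int(v) for v in fields[1:]]
            if len(rows[base]) != 4:
                raise ValueError(f"matrix row for {base} must have 4 scores")
    if len(rows) != 4:
        raise ValueError("matrix must have 4 rows")
    core = np.zeros((4, 4), dtype=np.int64)
    for r, base_r in enumerate("ACGT"):
        for c, base_c in enumerate("ACGT"):
            core[r, c] = rows[base_r][order.index(base_c)]
    return ScoringScheme(matrix=_full_matrix(core), **params)


_ENC = np.full(256, 4, dtype=np.uint8)
for _c, _i in _INDEX.items():
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 indices (unknown letters -> N)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
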