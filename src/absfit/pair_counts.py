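"""Pairwise character-state alignment counts, frequencies and the scoring matrix.

For an alignment with ``n`` sequences and ``k`` columns, every column and
every *ordered* pair of distinct sequences contributes one observation to the
unordered category of the two characters, so each unordered sequence pair
counts twice and the total is exactly ``s = k * n * (n - 1)``.  For DNA there
are ``d = 10`` categories: the 4 matches A-A, C-C, G-G, T-T and the 6
mismatches.  These counts are the raw material of both the substitution-fit
statistic and (via frequencies and the P-factor) of the tree-fit D values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np

from .io_core import ALPHABET, Msa

#: The 10 unordered DNA pair categories, in canonical order.
CATEGORIES: tuple[tuple[str, str], ...] = tuple(combinations_with_replacement(ALPHABET, 2))
#: Indices of the 4 match categories within :data:`CATEGORIES`.
MATCH_INDICES = tuple(i for i, (x, y) in enumerate(CATEGORIES) if x == y)

_PAIR_INDEX: dict[tuple[str, str], int] = {}
for _i, (_x, _y) in enumerate(CATEGORIES):
    _PAIR_INDEX[(_x, _y)] = _i
    _PAIR_INDEX[(_y, _x)] = _i


def category_index(x: str, y: str) -> int:
    """Index of the unordered pair category {x, y} in :data:`CATEGORIES`."""
    return _PAIR_INDEX[(x.upper(), y.upper())]


@dataclass(frozen=True)
class PairCounts:
    """Counts of pairwise aligned character states, one value per category."""

    counts: np.ndarray  # (10,) int64, canonical category order
    s: int
    d: int = 10
    source: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.d,):
            raise ValueError(f"expected {self.d} categories, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("negative pair counts")
        if counts.sum() != self.s:
            raise ValueError(f"counts sum to {counts.sum()}, declared s={self.s}")

    def __getitem__(self, pair: tuple[str, str]) -> int:
        return int(self.counts[category_index(*pair)])

    def as_dict(self) -> dict[str, int]:
        return {f"{x}-{y}": int(c) for (x, y), c in zip(CATEGORIES, self.counts)}


@dataclass(frozen=True)
class ScoringMatrix:
    """Per-alignment scoring values: match frequencies kept as-is, mismatch
    frequencies divided by the P-factor.

    A large P-factor shrinks mismatch scores, which amplifies the per-column
    D ratios at branch-supporting columns (where the across-branch mean is
    built from mismatches only) relative to non-supporting columns.
    """

    m4: np.ndarray  # (4, 4) symmetric, nucleotide order ACGT
    P: float
    source_msa: str = ""

    def __getitem__(self, pair: tuple[str, str]) -> float:
        x, y = pair
        return float(self.m4[ALPHABET.index(x.upper()), ALPHABET.index(y.upper())])


def count_pair_alignments(msa: Msa) -> PairCounts:
    """Count pairwise aligned character states over all columns and ordered
    sequence pairs of ``msa``."""
    # per-column base composition: comp[x, c] = #sequences with base x at column c
    comp = np.zeros((4, msa.k), dtype=np.int64)
    for x in range(4):
        comp[x] = (msa.codes == x).sum(axis=0)
    counts = np.empty(10, dtype=np.int64)
    for idx, (a, b) in enumerate(CATEGORIES):
        x, y = ALPHABET.index(a), ALPHABET.index(b)
        if x == y:
            counts[idx] = (comp[x] * (comp[x] - 1)).sum()
        else:
            counts[idx] = 2 * (comp[x] * comp[y]).sum()
    s = msa.k * msa.n * (msa.n - 1)
    return PairCounts(counts=counts, s=s, source=msa.label)


def frequencies(pc: PairCounts) -> np.ndarray:
    """Relative frequencies ``f_xy = C_xy / s`` in canonical category order."""
    if pc.s <= 0:
        raise ValueError("cannot normalise counts with s = 0")
    return pc.counts / pc.s


def scoring_matrix(freqs: np.ndarray, P: float = 10_000.0, source_msa: str = "") -> ScoringMatrix:
    """Build the scoring matrix from category frequencies and a P-factor.

    ``m_xy = f_xy`` for matches and ``f_xy / P`` for mismatches; P defaults
    to 10,000.
    """
    if P <= 0:
        raise ValueError(f"P-factor must be positive, got {P}")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (10,):
        raise ValueError(f"expected 10 category frequencies, got shape {freqs.shape}")
    m4 = np.zeros((4, 4))
    for idx, (a, b) in enumerate(CATEGORIES):
        x, y = ALPHABET.index(a), ALPHABET.index(b)
        val = freqs[idx] if x == y else freqs[idx] / P
        m4[x, y] = m4[y, x] = val
    return ScoringMatrix(m4=m4, P=float(P), source_msa=source_msa)


def dump_counts_tsv(pc: PairCounts, path: str | Path) -> None:
    """Audit dump: category, count, frequency — one row per category."""
    f = frequencies(pc)
    with Path(path).open("w") as fh:
        fh.write("category\tcount\tfrequency\n")
        for (x, y), c, fr in zip(CATEGORIES, pc.counts, f):
            fh.write(f"{x}-{y}\t{int(c)}\t{fr:.10g}\n")
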