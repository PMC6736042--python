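"""Tree-fit statistics: per-subset D values and the rank-correlation component B.

For each node-specific taxon subset the per-column ratio

    D_c = V1_c / V2_c

compares the mean scoring value among subset members (V1) with the mean
scoring value across the hypothesised branch (V2); the subset's D is the mean
of D_c over all columns.  At a column whose states are not shared across the
branch, V2 is built from mismatch scores only, which the P-factor has shrunk,
so such branch-supporting columns dominate D.  Splits present in the
generating tree therefore tend to carry larger D than the same splits under
data simulated without them.

Tree fit of a candidate model is then the rank agreement between the D
profile of the observed alignment and the D profiles of the model's
replicates: Spearman's r_s per replicate, Fisher-transformed, averaged, and
mapped back to B = 1 - tanh(z_mean).  Smaller B is better fit.

Each alignment is scored with its own scoring matrix (frequencies of its own
pair counts).  This makes V2 structurally positive: every character pair
co-occurring in a column of the alignment contributed at least one count to
that same alignment's frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import OrderMismatchError, SubsetSizeError
from .io_core import Msa, TaxonSubset
from .pair_counts import ScoringMatrix, count_pair_alignments, frequencies, scoring_matrix

logger = logging.getLogger(__name__)

#: Largest |r_s| admitted into the Fisher transformation.
RS_CLAMP = 0.999999999999999


@dataclass(frozen=True)
class SubsetDProfile:
    """Ordered vector of D values over a fixed set of node-specific subsets."""

    subset_order: tuple[str, ...]
    d_values: np.ndarray
    source_msa: str = ""
    P: float = 10_000.0

    def __post_init__(self):
        d = np.asarray(self.d_values, dtype=float)
        object.__setattr__(self, "d_values", d)
        if d.shape != (len(self.subset_order),):
            raise ValueError("d_values and subset_order lengths differ")


@dataclass(frozen=True)
class TreeFitResult:
    rs_per_replicate: np.ndarray
    z_per_replicate: np.ndarray
    z_mean: float
    B: float


def _col_comp(msa: Msa, rows: np.ndarray) -> np.ndarray:
    """(4, k) per-column base composition of the selected rows."""
    sub = msa.codes[rows]
    comp = np.zeros((4, msa.k), dtype=np.int64)
    for x in range(4):
        comp[x] = (sub == x).sum(axis=0)
    return comp


def column_v1(chars: Sequence[str] | np.ndarray, m: ScoringMatrix) -> float:
    """Mean scoring value over all unordered pairs of subset members at one column."""
    codes = _as_codes(chars)
    h = codes.size
    if h < 2:
        raise SubsetSizeError(f"subset must have >= 2 members, got {h}")
    u = np.bincount(codes, minlength=4).astype(float)
    total = (u @ m.m4 @ u - u @ np.diag(m.m4)) / 2.0
    return float(total / (h * (h - 1) / 2.0))


def column_v2(chars: Sequence[str] | np.ndarray, other: Sequence[str] | np.ndarray,
              m: ScoringMatrix) -> float:
    """Mean scoring value over all subset x complement character pairs at one column."""
    cu, cw = _as_codes(chars), _as_codes(other)
    h, b = cu.size, cw.size
    if h < 2 or b < 2:
        raise SubsetSizeError(f"need h >= 2 and b >= 2, got h={h}, b={b}")
    u = np.bincount(cu, minlength=4).astype(float)
    w = np.bincount(cw, minlength=4).astype(float)
    return float(u @ m.m4 @ w / (h * b))


def _as_codes(chars) -> np.ndarray:
    arr = np.asarray(chars)
    if arr.dtype.kind in "US":
        from .io_core import ALPHABET
        return np.array([ALPHABET.index(c.upper()) for c in arr], dtype=np.intp)
    return arr.astype(np.intp)


def d_value(msa: Msa, subset: TaxonSubset, m: ScoringMatrix) -> float:
    """Alignment-wide D for one subset: mean over columns of V1_c / V2_c."""
    rows = msa.row_indices(subset.members)
    comp_rows = np.setdiff1d(np.arange(msa.n), rows)
    h, b = rows.size, comp_rows.size
    if h < 2 or b < 2:
        raise SubsetSizeError(f"need h >= 2 and b >= 2, got h={h}, b={b}")
    U = _col_comp(msa, rows).astype(float)          # (4, k)
    W = _col_comp(msa, comp_rows).astype(float)     # (4, k)
    M = m.m4
    v1 = (np.einsum("xc,xy,yc->c", U, M, U) - np.diag(M) @ U) / 2.0
    v1 /= h * (h - 1) / 2.0
    v2 = np.einsum("xc,xy,yc->c", U, M, W) / (h * b)
    return float(np.mean(v1 / v2))


def profile(msa: Msa, subsets: Sequence[TaxonSubset], P: float = 10_000.0) -> SubsetDProfile:
    """D profile of one alignment over the fixed subset order, scored with the
    alignment's own scoring matrix."""
    if not subsets:
        raise ValueError("no subsets supplied")
    m = scoring_matrix(frequencies(count_pair_alignments(msa)), P, source_msa=msa.label)
    d = np.array([d_value(msa, sub, m) for sub in subsets])
    return SubsetDProfile(
        subset_order=tuple(sub.key for sub in subsets),
        d_values=d, source_msa=msa.label, P=float(P),
    )


def spearman_rs(obs: SubsetDProfile, rep: SubsetDProfile) -> float:
    """Tie-corrected Spearman correlation of two D profiles, clamped to
    +/- 0.999999999999999 so the Fisher transformation stays finite."""
    if obs.subset_order != rep.subset_order:
        raise OrderMismatchError("profiles were computed over different subset orders")
    if np.ptp(obs.d_values) == 0 or np.ptp(rep.d_values) == 0:
        logger.warning("constant D profile; r_s undefined, using 0")
        return 0.0
    rs = stats.spearmanr(obs.d_values, rep.d_values).statistic
    if np.isnan(rs):
        # a constant profile carries no rank information
        logger.warning("constant D profile; r_s undefined, using 0")
        return 0.0
    return float(np.clip(rs, -RS_CLAMP, RS_CLAMP))


def fit_B(obs: SubsetDProfile, reps: Sequence[SubsetDProfile]) -> TreeFitResult:
    """Tree-fit component B from observed-vs-replicate rank correlations."""
    if not reps:
        raise ValueError("need at least one replicate profile")
    rs = np.array([spearman_rs(obs, r) for r in reps])
    z = np.arctanh(rs)
    z_mean = float(z.mean())
    return TreeFitResult(rs_per_replicate=rs, z_per_replicate=z,
                         z_mean=z_mean, B=float(1.0 - np.tanh(z_mean)))


def dump_profile_tsv(p: SubsetDProfile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("subset\tD\n")
        for key, d in zip(p.subset_order, p.d_values):
            fh.write(f"{key}\t{d:.10g}\n")
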