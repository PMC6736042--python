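"""Gelfand-Ghosh fit statistics over pair-count distributions.

The criterion splits into a goodness-of-fit part (GGg) and a variance
penalty (GGp), both built from the negative-entropy function

    t(C, s) = -ln s + (1/s) * sum_{C_i > 0} C_i ln C_i ,

evaluated on observed counts, per-replicate counts, replicate means and the
observed/replicate-mean mixture.  GGg equals ``4 s`` times the
Jensen-Shannon divergence (natural log) between the observed and the
mean-replicate frequency vectors, so it is nonnegative and zero exactly at a
perfect fit; GGp is nonnegative by Jensen's inequality and zero when all
replicates agree.  The substitution-fit component A is the mean GGg across
the candidate models sharing one substitution scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ApplicabilityError
from .pair_counts import CATEGORIES, PairCounts


@dataclass(frozen=True)
class ReplicateSet:
    """Pair counts of q simulated replicates of one simulation model."""

    counts: np.ndarray  # (q, d) int64
    s: int
    sm_label: str = ""

    def __post_init__(self):
        counts = np.atleast_2d(np.asarray(self.counts, dtype=np.int64))
        object.__setattr__(self, "counts", counts)
        if counts.shape[0] < 1:
            raise ValueError("need at least one replicate")
        sums = counts.sum(axis=1)
        if not (sums == self.s).all():
            raise ValueError("all replicates must share the same total count s")

    @property
    def q(self) -> int:
        return self.counts.shape[0]

    @property
    def d(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_pair_counts(cls, pcs: Sequence[PairCounts], sm_label: str = "") -> "ReplicateSet":
        if not pcs:
            raise ValueError("need at least one replicate")
        s = pcs[0].s
        return cls(counts=np.vstack([pc.counts for pc in pcs]), s=s, sm_label=sm_label)

    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=0)


@dataclass(frozen=True)
class GGResult:
    ggg: float
    ggp: float
    gg: float
    t2: float
    t3: float
    t4: float
    per_replicate_t1: np.ndarray
    q: int
    s: int


def t_negentropy(counts: np.ndarray, s: float) -> float:
    """The t function: negative entropy of the count vector, 0*ln(0) := 0.

    Real-valued counts are accepted — replicate means need not be integers.
    """
    if s <= 0:
        raise ValueError(f"total count s must be positive, got {s}")
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    pos = c[c > 0]
    return float(-np.log(s) + (pos * np.log(pos)).sum() / s)


def _check_applicability(observed: PairCounts, reps: ReplicateSet) -> None:
    if observed.s != reps.s:
        raise ValueError(
            f"observed total s={observed.s} differs from replicate s={reps.s}; "
            "alignments must have identical dimensions"
        )
    missing_obs = [f"{x}-{y}" for (x, y), c in zip(CATEGORIES, observed.counts) if c == 0]
    if missing_obs:
        raise ApplicabilityError(
            "pair categories absent from the observed alignment: " + ", ".join(missing_obs)
        )
    totals = reps.counts.sum(axis=0)
    missing_rep = [f"{x}-{y}" for (x, y), c in zip(CATEGORIES, totals) if c == 0]
    if missing_rep:
        raise ApplicabilityError(
            "pair categories absent from the whole replicate distribution: "
            + ", ".join(missing_rep)
        )


def ggp(reps: ReplicateSet) -> float:
    """Variance penalty: ``2 s [mean_i t1(i) - t2]``; zero iff replicates agree."""
    t1 = np.array([t_negentropy(row, reps.s) for row in reps.counts])
    t2 = t_negentropy(reps.mean_counts(), reps.s)
    return float(2 * reps.s * (t1.mean() - t2))


def ggg(observed: PairCounts, reps: ReplicateSet, check_applicability: bool = True) -> float:
    """Goodness of fit: ``4 s [(t2 + t3)/2 - t4]``.

    Equals ``4 s`` times the Jensen-Shannon divergence between the observed
    and mean-replicate frequency vectors; zero iff they coincide.

    By default the test's applicability precondition is enforced: every pair
    category must occur in the observed alignment and at least once across
    the replicate distribution.  With ``check_applicability=False`` the
    statistic is still computed under the 0*ln(0) := 0 limit convention.
    """
    if check_applicability:
        _check_applicability(observed, reps)
    elif observed.s != reps.s:
        raise ValueError("observed and replicate totals s differ")
    s = reps.s
    t2 = t_negentropy(reps.mean_counts(), s)
    t3 = t_negentropy(observed.counts, s)
    t4 = t_negentropy((reps.mean_counts() + observed.counts) / 2.0, s)
    return float(4 * s * ((t2 + t3) / 2.0 - t4))


def gg_result(observed: PairCounts, reps: ReplicateSet) -> GGResult:
    """Full decomposition GG = GGg + GGp with all intermediate t values."""
    _check_applicability(observed, reps)
    s = reps.s
    t1 = np.array([t_negentropy(row, s) for row in reps.counts])
    t2 = t_negentropy(reps.mean_counts(), s)
    t3 = t_negentropy(observed.counts, s)
    t4 = t_negentropy((reps.mean_counts() + observed.counts) / 2.0, s)
    ggg_val = float(4 * s * ((t2 + t3) / 2.0 - t4))
    ggp_val = float(2 * s * (t1.mean() - t2))
    return GGResult(
        ggg=ggg_val, ggp=ggp_val, gg=ggg_val + ggp_val,
        t2=t2, t3=t3, t4=t4, per_replicate_t1=t1, q=reps.q, s=s,
    )


def substitution_fit_A(ggg_values: Sequence[float]) -> float:
    """Mean GGg over the w candidate models sharing one substitution scheme."""
    if len(ggg_values) == 0:
        raise ValueError("need at least one GGg value")
    return float(np.mean(ggg_values))
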