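"""Combine substitution fit (A) and tree fit (B) into T = A * B and rank models.

One comparison scores a single observed (EM) replicate against a candidate
simulation model (SM) represented by a distribution of q replicates:

* GGg between the observed pair counts and the SM replicate distribution;
* A = mean GGg over the SMs sharing the candidate's substitution scheme
  (the tree component perturbs GGg only slightly and randomly, so averaging
  over the candidate trees isolates the substitution signal);
* B from the rank correlation between the observed and replicate D profiles;
* T = A * B, smaller is better.

Model separation (MS) is the percentage of EM replicates for which a
preferred SM attains strictly lower T than a competitor; ties count against
the preferred model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gg_statistics import ReplicateSet, gg_result, ggg, substitution_fit_A
from .io_core import Msa, TaxonSubset
from .pair_counts import count_pair_alignments
from .tree_fit import SubsetDProfile, fit_B, profile


@dataclass(frozen=True)
class FitScore:
    A: float
    B: float
    T: float
    em_replicate_id: str
    sm_label: str
    ggg: float = float("nan")
    scheme: str = ""


@dataclass(frozen=True)
class SeparationResult:
    preferred_sm: str
    competitor_sm: str
    n_comparisons: int
    ms: float  # percentage in [0, 100]


@dataclass
class SimulationModelSet:
    """A candidate evolutionary model represented by its simulated replicates."""

    label: str
    scheme: str  # substitution-scheme identifier shared across candidate trees
    msas: Sequence[Msa]
    counts: ReplicateSet | None = None
    profiles: list[SubsetDProfile] | None = None

    def ensure_counts(self) -> ReplicateSet:
        if self.counts is None:
            self.counts = ReplicateSet.from_pair_counts(
                [count_pair_alignments(m) for m in self.msas], sm_label=self.label
            )
        return self.counts

    def ensure_profiles(self, subsets: Sequence[TaxonSubset], P: float) -> list[SubsetDProfile]:
        if self.profiles is None:
            self.profiles = [profile(m, subsets, P) for m in self.msas]
        return self.profiles


def t_statistic(A: float, B: float) -> float:
    """T = A * B; approximately zero at perfect fit."""
    if A < 0:
        raise ValueError("A must be nonnegative")
    return A * B


def score_models(
    em_replicates: Sequence[Msa],
    sms: Mapping[str, SimulationModelSet],
    subsets: Sequence[TaxonSubset],
    P: float = 10_000.0,
    stat: str = "ggg",
) -> list[FitScore]:
    """Score every EM replicate against every candidate SM.

    ``stat`` selects the substitution-fit ingredient: the default "ggg" or
    the full "gg" criterion.  A is averaged over the SMs sharing a scheme,
    then paired with each SM's own B.
    """
    if stat not in ("ggg", "gg"):
        raise ValueError(f"stat must be 'ggg' or 'gg', got {stat!r}")
    for sm in sms.values():
        sm.ensure_counts()
        sm.ensure_profiles(subsets, P)
    schemes: dict[str, list[str]] = {}
    for label, sm in sms.items():
        schemes.setdefault(sm.scheme, []).append(label)

    scores: list[FitScore] = []
    for ei, em in enumerate(em_replicates):
        em_id = em.label or f"em:{ei}"
        em_counts = count_pair_alignments(em)
        em_profile = profile(em, subsets, P)
        g_by_sm = {}
        for label, sm in sms.items():
            if stat == "ggg":
                g_by_sm[label] = ggg(em_counts, sm.counts)
            else:
                g_by_sm[label] = gg_result(em_counts, sm.counts).gg
        a_by_scheme = {
            scheme: substitution_fit_A([g_by_sm[l] for l in labels])
            for scheme, labels in schemes.items()
        }
        for label, sm in sms.items():
            B = fit_B(em_profile, sm.profiles).B
            A = a_by_scheme[sm.scheme]
            scores.append(FitScore(
                A=A, B=B, T=t_statistic(A, B), em_replicate_id=em_id,
                sm_label=label, ggg=g_by_sm[label], scheme=sm.scheme,
            ))
    return scores


def scores_table(scores: Sequence[FitScore]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in scores])


def ms_score(scores: Sequence[FitScore], preferred_sm: str, competitor_sm: str) -> SeparationResult:
    """Percentage of EM replicates where the preferred SM has strictly lower T."""
    pref = {s.em_replicate_id: s.T for s in scores if s.sm_label == preferred_sm}
    comp = {s.em_replicate_id: s.T for s in scores if s.sm_label == competitor_sm}
    shared = sorted(set(pref) & set(comp))
    if not shared:
        raise KeyError(
            f"no shared EM replicates scored for {preferred_sm!r} and {competitor_sm!r}"
        )
    wins = sum(1 for em in shared if pref[em] < comp[em])
    return SeparationResult(
        preferred_sm=preferred_sm, competitor_sm=competitor_sm,
        n_comparisons=len(shared), ms=100.0 * wins / len(shared),
    )


def mean_t(scores: Sequence[FitScore]) -> dict[str, float]:
    """Mean T per SM over all scored EM replicates."""
    acc: dict[str, list[float]] = {}
    for s in scores:
        acc.setdefault(s.sm_label, []).append(s.T)
    return {label: float(np.mean(v)) for label, v in acc.items()}


def rank_models(mean_t_by_sm: Mapping[str, float]) -> list[tuple[str, float]]:
    """Ascending mean T; ties broken by label order (stable, flagged upstream)."""
    return sorted(mean_t_by_sm.items(), key=lambda kv: (kv[1], kv[0]))


def random_pick_probability(n_models: int, n_trials: int) -> float:
    """Probability of picking one designated model out of ``n_models`` in every
    one of ``n_trials`` independent random draws."""
    if n_models < 1 or n_trials < 0:
        raise ValueError("need n_models >= 1 and n_trials >= 0")
    return float((1.0 / n_models) ** n_trials)
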