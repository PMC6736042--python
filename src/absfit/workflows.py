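"""Reproducible end-to-end study wiring used by the CLI, the test suite and
the acceptance script.

The reduced-scale power study mirrors the canonical two-tree design: a
six-taxon true tree (Tree I, A sister to B) against an alternative that
regrafts A next to C (Tree II), with data generated under a GTR+G model.
Candidate models are {Tree I, Tree II} x {GTR+G, K80}, i.e. the correct
model, a wrong-tree model, a wrong-substitution-scheme model and a
doubly-wrong model.  Observed-side replicates and the correct candidate's
replicate set are always simulated from disjoint random streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gc_test import gc_delta, gc_zscore
from .io_core import ModelTree, Msa, extract_subsets, tree_from_newick
from .model_ranking import (
    SimulationModelSet,
    mean_t,
    ms_score,
    rank_models,
    score_models,
)
from .simulator import SimulationSpec, SubstitutionModel, simulate_replicate_set

# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Six-taxon true tree: A sister to B. Branch lengths in expected subst./site.
TREE_I_NEWICK = "(((A:0.15,B:0.12):0.05,C:0.18):0.05,(D:0.14,E:0.11):0.06,F:0.20);"
#: Alternative tree: A regrafted as sister to C; otherwise identical.
TREE_II_NEWICK = "(((A:0.15,C:0.18):0.05,B:0.12):0.05,(D:0.14,E:0.11):0.06,F:0.20);"

#: AT-rich, transition-dominant GTR+G parameters typical of organellar DNA.
GTR_G_MODEL = SubstitutionModel(
    scheme="GTR",
    base_freqs=(0.31, 0.19, 0.21, 0.29),
    exchangeabilities=(1.4, 4.0, 1.2, 1.1, 5.0, 1.0),
    gamma_alpha=0.4,
    label="GTR+G",
)
K80_MODEL = SubstitutionModel(scheme="K80", kappa=2.5, label="K80")


@dataclass
class PowerStudyResult:
    mean_t_by_sm: dict[str, float]
    ranking: list[tuple[str, float]]
    ms_novel: dict[tuple[str, str], float]
    ms_gc: dict[tuple[str, str], float]
    n_em: int
    q: int
    k: int
    scores: list = field(default_factory=list)


def _default_candidates() -> dict[str, tuple[ModelTree, SubstitutionModel, str]]:
    tree1 = tree_from_newick(TREE_I_NEWICK, label="TreeI")
    tree2 = tree_from_newick(TREE_II_NEWICK, label="TreeII")
    return {
        "SM1": (tree1, GTR_G_MODEL, "GTR+G"),
        "SM2": (tree2, GTR_G_MODEL, "GTR+G"),
        "SM3": (tree1, K80_MODEL, "K80"),
        "SM4": (tree2, K80_MODEL, "K80"),
    }


def power_study(
    seed: int,
    n_em: int = 20,
    q: int = 100,
    k: int = 10_000,
    P: float = 10_000.0,
    stat: str = "ggg",
    with_gc: bool = True,
    candidates: Mapping[str, tuple[ModelTree, SubstitutionModel, str]] | None = None,
    em_candidate: str = "SM1",
) -> PowerStudyResult:
    """Run the two-tree power study at the given scale.

    The observed side is ``n_em`` replicates of the candidate named by
    ``em_candidate`` (by default the correct model SM1 = Tree I + GTR+G),
    drawn from a random stream disjoint from every candidate replicate set.
    Returns mean T and ranking per candidate, novel-test MS for every
    same-scheme preferred/competitor pair, and (optionally) the Goldman-Cox
    Z-score MS for the same pairs.
    """
    cands = dict(candidates) if candidates is not None else _default_candidates()
    seed_rng = np.random.default_rng(seed)
    seeds = {name: int(seed_rng.integers(2**31)) for name in cands}
    em_seed = int(seed_rng.integers(2**31))

    em_tree, em_model, _ = cands[em_candidate]
    em_msas, _ = simulate_replicate_set(
        SimulationSpec(tree=em_tree, model=em_model, k=k, q=n_em,
                       seed=em_seed, label="EM")
    )

    sm_msas: dict[str, list[Msa]] = {}
    sms: dict[str, SimulationModelSet] = {}
    for name, (tree, model, scheme) in cands.items():
        msas, counts = simulate_replicate_set(
            SimulationSpec(tree=tree, model=model, k=k, q=q,
                           seed=seeds[name], label=name)
        )
        sm_msas[name] = msas
        sms[name] = SimulationModelSet(label=name, scheme=scheme, msas=msas, counts=counts)

    subsets = extract_subsets([t for t, _, _ in cands.values()])
    scores = score_models(em_msas, sms, subsets, P=P, stat=stat)

    same_scheme_pairs = [
        (a, b)
        for a in cands for b in cands
        if a != b and cands[a][2] == cands[b][2]
    ]
    ms_novel = {
        (a, b): ms_score(scores, a, b).ms for (a, b) in same_scheme_pairs
    }

    ms_gc: dict[tuple[str, str], float] = {}
    if with_gc:
        # Goldman-Cox protocol: every replicate's delta is computed under the
        # model that generated it; an observed replicate's delta therefore
        # does not depend on the candidate it is compared against.
        em_deltas = np.array([gc_delta(m, em_tree, em_model).delta for m in em_msas])
        sm_deltas = {
            name: np.array([
                gc_delta(m, cands[name][0], cands[name][1]).delta
                for m in sm_msas[name]
            ])
            for name in cands
        }
        z = {
            name: np.array([gc_zscore(d, sm_deltas[name]) for d in em_deltas])
            for name in cands
        }
        for a, b in same_scheme_pairs:
            wins = int((z[a] < z[b]).sum())
            ms_gc[(a, b)] = 100.0 * wins / len(em_deltas)

    mt = mean_t(scores)
    return PowerStudyResult(
        mean_t_by_sm=mt,
        ranking=rank_models(mt),
        ms_novel=ms_novel,
        ms_gc=ms_gc,
        n_em=n_em, q=q, k=k,
        scores=scores,
    )
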