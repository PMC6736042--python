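"""Goldman-Cox comparator: multinomial and model log-likelihoods, delta, Z-scores.

The Goldman-Cox statistic is delta = ln L(multinomial) - ln L(model), where
the multinomial (unconstrained) likelihood is the product over columns of the
observed site-pattern frequencies — the maximum attainable likelihood for any
iid-site model — and the model likelihood is the phylogenetic likelihood of
the alignment under a fixed tree and substitution model, computed here by
Felsenstein pruning with the same among-site rate mixtures the simulator
offers.  Model parameters are *fixed* (no optimisation); externally computed
log-likelihoods can be supplied instead via TSV to mirror protocols that
re-optimise per replicate.

A replicate's delta is compared with a candidate model's delta distribution
through the absolute Z-score |delta - mean| / sd (sample sd, n-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import ZeroVarianceError
from .io_core import ModelTree, Msa
from .simulator import SubstitutionModel


@dataclass(frozen=True)
class GCResult:
    delta: float
    model_loglik: float
    multinomial_loglik: float
    loglik_source: str = "internal_pruning"


def multinomial_loglik(msa: Msa) -> float:
    """Unconstrained log-likelihood: sum over distinct site patterns p of
    N_p * ln(N_p / k)."""
    _, counts = np.unique(msa.codes.T, axis=0, return_counts=True)
    return float((counts * np.log(counts / msa.k)).sum())


def pruning_loglik(msa: Msa, tree: ModelTree, model: SubstitutionModel) -> float:
    """Felsenstein-pruning log-likelihood of ``msa`` under fixed tree and model.

    Site patterns are compressed; underflow is guarded by per-node scaling
    with the scale factors accumulated in log space per rate class.
    """
    patterns, counts = np.unique(msa.codes.T, axis=0, return_counts=True)
    npat = patterns.shape[0]
    leaf_row = {t: i for i, t in enumerate(msa.taxa)}
    missing = tree.taxon_set.symmetric_difference(msa.taxa)
    if missing:
        raise ValueError(f"tree/alignment taxon mismatch: {sorted(missing)}")

    pi = np.asarray(model.base_freqs)
    w, U, Uinv = model.eigen()
    rates, wts = model.site_rate_classes()

    log_site = np.empty((rates.size, npat))
    for ci, r in enumerate(rates):
        log_scale = np.zeros(npat)
        partials: dict[int, np.ndarray] = {}
        for node in tree.tree.postorder_node_iter():
            if node.is_leaf():
                part = np.zeros((npat, 4))
                part[np.arange(npat), patterns[:, leaf_row[node.taxon.label]]] = 1.0
            else:
                part = np.ones((npat, 4))
                for child in node.child_nodes():
                    t = child.edge.length or 0.0
                    P = (U * np.exp(w * t * r)) @ Uinv
                    P = np.clip(P, 0.0, None)
                    part *= partials.pop(id(child)) @ P.T
                mx = part.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                part /= mx[:, None]
                log_scale += np.log(mx)
            partials[id(node)] = part
        root_part = partials[id(tree.tree.seed_node)]
        lik = root_part @ pi
        log_site[ci] = np.where(lik > 0, np.log(np.maximum(lik, 1e-300)), -np.inf) + log_scale
    with np.errstate(divide="ignore"):
        per_pattern = logsumexp(log_site, axis=0, b=wts[:, None])
    return float((counts * per_pattern).sum())


def gc_delta(msa: Msa, tree: ModelTree, model: SubstitutionModel) -> GCResult:
    """delta = multinomial log-likelihood minus fixed-parameter model log-likelihood."""
    mult = multinomial_loglik(msa)
    mod = pruning_loglik(msa, tree, model)
    return GCResult(delta=mult - mod, model_loglik=mod, multinomial_loglik=mult)


def gc_zscore(em_delta: float, sm_deltas: Sequence[float]) -> float:
    """|em_delta - mean(sm_deltas)| / sd(sm_deltas) with sample (n-1) sd."""
    sm = np.asarray(sm_deltas, dtype=float)
    if sm.size < 2:
        raise ValueError("need at least 2 replicate delta values")
    sd = sm.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("replicate delta distribution has zero spread")
    return float(abs(em_delta - sm.mean()) / sd)


def read_loglik_tsv(path: str | Path) -> dict[str, float]:
    """Read externally computed log-likelihoods: lines of 'replicate_id<TAB>loglik'."""
    out: dict[str, float] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.lower().startswith("replicate"):
            continue
        rep_id, val = ln.split("\t")[:2]
        out[rep_id] = float(val)
    return out
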