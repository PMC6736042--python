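"""Sequence simulation along a fixed tree under reversible DNA substitution models.

Supports JC, K80, HKY and GTR rate matrices with optional discrete-gamma
rate heterogeneity (equal-probability categories represented by their means),
a proportion of invariant sites, and explicit free-rate categories.  The rate
matrix is always normalised to one expected substitution per site at
stationarity, so branch lengths are in expected substitutions per site.

Random number usage order is fixed and documented so runs are reproducible
from the seed alone: (1) root states, (2) per-site rate classes, (3) branch
transitions in preorder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaincinv, gammainc

from .io_core import ModelTree, Msa
from .pair_counts import count_pair_alignments
from .gg_statistics import ReplicateSet

_SCHEMES = ("JC", "K80", "HKY", "GTR")
# exchangeability order matches the unordered mismatch categories AC, AG, AT, CG, CT, GT
_EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible DNA substitution model with fixed numerical parameters.

    ``kappa`` is the transition/transversion rate ratio used by K80 and HKY;
    ``exchangeabilities`` are the six GTR rates in the order
    AC, AG, AT, CG, CT, GT.  ``free_rates`` is a list of (rate, weight)
    pairs with weights summing to 1 and mean rate 1; it is mutually exclusive
    with the gamma/invariant options.
    """

    scheme: str
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 2.0
    exchangeabilities: tuple[float, ...] | None = None
    gamma_alpha: float | None = None
    gamma_categories: int = 4
    p_invariant: float | None = None
    free_rates: tuple[tuple[float, float], ...] | None = None
    label: str = ""

    def __post_init__(self):
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {_SCHEMES}")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if self.scheme in ("JC", "K80"):
            freqs = np.full(4, 0.25)
        if freqs.shape != (4,) or (freqs <= 0).any() or abs(freqs.sum() - 1) > 1e-8:
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        object.__setattr__(self, "base_freqs", tuple(freqs / freqs.sum()))
        if self.scheme == "GTR":
            if self.exchangeabilities is None or len(self.exchangeabilities) != 6:
                raise ValueError("GTR requires 6 exchangeabilities (AC, AG, AT, CG, CT, GT)")
            if any(r < 0 for r in self.exchangeabilities):
                raise ValueError("exchangeabilities must be nonnegative")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be positive")
        if self.p_invariant is not None and not (0 <= self.p_invariant < 1):
            raise ValueError("p_invariant must lie in [0, 1)")
        if self.free_rates is not None:
            if self.gamma_alpha is not None or self.p_invariant is not None:
                raise ValueError("free_rates is exclusive with gamma/invariant options")
            rates = np.array([r for r, _ in self.free_rates])
            wts = np.array([w for _, w in self.free_rates])
            if (rates < 0).any() or (wts <= 0).any():
                raise ValueError("free rates must be nonnegative with positive weights")
            if abs(wts.sum() - 1) > 1e-8 or abs(rates @ wts - 1) > 1e-6:
                raise ValueError("free-rate weights must sum to 1 with mean rate 1")

    # -- rate matrix ------------------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        """Normalised generator Q (mean rate 1 at stationarity)."""
        pi = np.asarray(self.base_freqs)
        if self.scheme == "JC":
            ex = np.ones(6)
        elif self.scheme in ("K80", "HKY"):
            # transitions: A<->G and C<->T
            ex = np.ones(6)
            ex[1] = self.kappa  # AG
            ex[4] = self.kappa  # CT
        else:
            ex = np.asarray(self.exchangeabilities, dtype=float)
        Q = np.zeros((4, 4))
        for (i, j), r in zip(_EXCH_PAIRS, ex):
            Q[i, j] = r * pi[j]
            Q[j, i] = r * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via its symmetrised form (stable for
        reversible models): returns (eigenvalues, right vectors U, U^-1)
        with Q = U diag(w) U^-1."""
        pi = np.asarray(self.base_freqs)
        Q = self.rate_matrix()
        sp = np.sqrt(pi)
        S = (sp[:, None] * Q) / sp[None, :]
        w, V = np.linalg.eigh((S + S.T) / 2.0)
        U = V / sp[:, None]
        Uinv = V.T * sp[None, :]
        return w, U, Uinv

    # -- among-site rates -------------------------------------------------

    def site_rate_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the among-site rate mixture; mean rate 1."""
        if self.free_rates is not None:
            rates = np.array([r for r, _ in self.free_rates])
            wts = np.array([w for _, w in self.free_rates])
            return rates, wts
        p_inv = self.p_invariant or 0.0
        if self.gamma_alpha is not None:
            g = discrete_gamma_rates(self.gamma_alpha, self.gamma_categories)
            rates = g / (1.0 - p_inv)
            wts = np.full(self.gamma_categories, (1.0 - p_inv) / self.gamma_categories)
        else:
            rates = np.array([1.0 / (1.0 - p_inv)])
            wts = np.array([1.0 - p_inv])
        if p_inv > 0:
            rates = np.concatenate([[0.0], rates])
            wts = np.concatenate([[p_inv], wts])
        return rates, wts


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (category means),
    mean-1 gamma with shape ``alpha``."""
    if alpha <= 0 or n_categories < 1:
        raise ValueError("alpha must be positive and n_categories >= 1")
    k = n_categories
    # quantile boundaries of Gamma(alpha, rate=alpha)
    edges = gammaincinv(alpha, np.linspace(0, 1, k + 1)) / alpha
    edges[-1] = np.inf
    # E[X | a < X < b] * P(a < X < b) = gammainc(alpha+1, beta*b) - gammainc(alpha+1, beta*a)
    upper = gammainc(alpha + 1, np.where(np.isinf(edges), np.inf, alpha * edges))
    rates = k * np.diff(upper)
    return rates / (rates.mean())  # guard tiny numerical drift; mean is 1 by construction


def transition_matrix(model: SubstitutionModel, branch_length: float,
                      rate_multiplier: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q * t * r): row-stochastic transition probabilities."""
    if branch_length < 0:
        raise ValueError("branch length must be nonnegative")
    w, U, Uinv = model.eigen()
    P = (U * np.exp(w * branch_length * rate_multiplier)) @ Uinv
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class SimulationSpec:
    tree: ModelTree
    model: SubstitutionModel
    k: int
    q: int = 1
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.k < 1 or self.q < 1:
            raise ValueError("need k >= 1 and q >= 1")


def simulate_alignment(spec: SimulationSpec, rng: np.random.Generator | None = None,
                       label: str | None = None) -> Msa:
    """Simulate one gap-free alignment along ``spec.tree`` under ``spec.model``.

    Deterministic given the seed.  Draw order: root states, then per-site
    rate classes, then child states branch by branch in preorder.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    model, k = spec.model, spec.k
    pi = np.asarray(model.base_freqs)
    w, U, Uinv = model.eigen()
    rates, wts = model.site_rate_classes()

    root = spec.tree.tree.seed_node
    root_states = rng.choice(4, size=k, p=pi)
    classes = rng.choice(rates.size, size=k, p=wts / wts.sum())

    states = {id(root): root_states}
    for node in spec.tree.tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_states = states[id(node.parent_node)]
        child = np.empty(k, dtype=np.int64)
        for ci, r in enumerate(rates):
            sel = classes == ci
            if not sel.any():
                continue
            if t * r == 0.0:
                child[sel] = parent_states[sel]
                continue
            P = (U * np.exp(w * t * r)) @ Uinv
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            cum = P.cumsum(axis=1)
            u = rng.random(int(sel.sum()))
            child[sel] = (u[:, None] >= cum[parent_states[sel]]).sum(axis=1)
        states[id(node)] = child

    taxa, rows = [], []
    for leaf in spec.tree.tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append(states[id(leaf)])
    order = np.argsort(taxa, kind="stable")
    return Msa(
        taxa=tuple(taxa[i] for i in order),
        codes=np.vstack([rows[i] for i in order]).astype(np.uint8),
        label=label if label is not None else spec.label,
    )


def simulate_replicate_set(spec: SimulationSpec) -> tuple[list[Msa], ReplicateSet]:
    """Simulate ``spec.q`` independent alignments and their pair counts.

    One generator seeded with ``spec.seed`` drives all replicates in order.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.label or "rep"
    msas = [
        simulate_alignment(spec, rng=rng, label=f"{base}:{i}")
        for i in range(spec.q)
    ]
    reps = ReplicateSet.from_pair_counts(
        [count_pair_alignments(m) for m in msas], sm_label=spec.label
    )
    return msas, reps
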