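"""Alignment and tree I/O, validation, and node-specific taxon subset enumeration.

Alignments are strict, gap-free DNA matrices over {A, C, G, T}: the pairwise
count statistics downstream are undefined for gaps and ambiguity codes, so
anything else is rejected at parse time.  Candidate trees are treated as
unrooted; the splits (internal branches) of the candidate trees define the
node-specific taxon subsets over which tree fit is measured.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

from .errors import (
    AlphabetError,
    DimensionError,
    DuplicateTaxonError,
    SubsetSizeError,
    TaxonMismatchError,
    UnresolvedTreeError,
)

logger = logging.getLogger(__name__)

#: Nucleotide order used for all integer encodings in the package.
ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}

#: Separator reserved for canonical subset keys; taxon labels may not contain it.
SUBSET_KEY_SEP = "|"


# ---------------------------------------------------------------------------
# Msa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Msa:
    """A gap-free aligned DNA character matrix.

    Parameters
    ----------
    taxa
        Ordered, unique taxon labels (length ``n``).
    codes
        ``(n, k)`` uint8 matrix with A=0, C=1, G=2, T=3.
    label
        Optional provenance identifier (file name, replicate id, ...).
    """

    taxa: tuple[str, ...]
    codes: np.ndarray
    label: str = ""

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=np.uint8)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 2 or codes.shape[1] < 1:
            raise DimensionError(f"alignment matrix must be 2-D with k >= 1, got shape {codes.shape}")
        if codes.shape[0] != len(self.taxa):
            raise DimensionError(
                f"{len(self.taxa)} taxon labels but {codes.shape[0]} matrix rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateTaxonError("duplicate taxon labels in alignment")
        if codes.max(initial=0) > 3:
            raise AlphabetError("?", int(np.argwhere(codes > 3)[0][1]) + 1, "?")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def k(self) -> int:
        return self.codes.shape[1]

    def sequence(self, taxon: str) -> str:
        row = self.codes[self.taxa.index(taxon)]
        return "".join(ALPHABET[c] for c in row)

    def sequences(self) -> dict[str, str]:
        return {t: self.sequence(t) for t in self.taxa}

    def row_indices(self, members: Iterable[str]) -> np.ndarray:
        idx = {t: i for i, t in enumerate(self.taxa)}
        return np.fromiter((idx[m] for m in sorted(members)), dtype=np.intp)


def msa_from_sequences(pairs: Sequence[tuple[str, str]], label: str = "") -> Msa:
    """Build an :class:`Msa` from ``(taxon, sequence)`` pairs, validating strictly.

    Input is case-insensitive; ``U`` is accepted as ``T`` with a warning.
    """
    if not pairs:
        raise DimensionError("empty alignment")
    taxa = [t for t, _ in pairs]
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise DuplicateTaxonError(f"duplicate taxon label(s): {', '.join(dup)}")
    k = len(pairs[0][1])
    if k == 0:
        raise DimensionError(f"sequence for {taxa[0]!r} is empty")
    rows = []
    saw_u = False
    for taxon, seq in pairs:
        seq = seq.upper()
        if "U" in seq:
            saw_u = True
            seq = seq.replace("U", "T")
        if len(seq) != k:
            raise DimensionError(
                f"ragged alignment: {taxon!r} has length {len(seq)}, expected {k}"
            )
        row = np.empty(k, dtype=np.uint8)
        for j, ch in enumerate(seq):
            code = _CODE.get(ch)
            if code is None:
                raise AlphabetError(taxon, j + 1, ch)
            row[j] = code
        rows.append(row)
    if saw_u:
        logger.warning("RNA-style 'U' characters were mapped to 'T'")
    return Msa(taxa=tuple(taxa), codes=np.vstack(rows), label=label)


def read_msa(path: str | Path, format: str = "fasta") -> Msa:
    """Read a gap-free DNA alignment from FASTA or relaxed sequential PHYLIP.

    Raises :class:`AlphabetError` for any character outside {A, C, G, T}
    (reporting taxon and column), :class:`DimensionError` for ragged rows and
    :class:`DuplicateTaxonError` for repeated labels.
    """
    path = Path(path)
    if format == "fasta":
        with path.open() as fh:
            pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
        if not pairs:
            raise DimensionError(f"no FASTA records in {path}")
    elif format == "phylip":
        pairs = _read_relaxed_phylip(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return msa_from_sequences(pairs, label=path.name)


def _read_relaxed_phylip(path: Path) -> list[tuple[str, str]]:
    # Relaxed sequential PHYLIP: "n k" header, then one "name sequence"
    # record per line (sequence may continue on following unlabeled lines).
    # Biopython's phylip readers are interleaved or strict-name, hence this
    # small reader.
    lines = [ln.rstrip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise DimensionError(f"empty PHYLIP file {path}")
    try:
        n, k = (int(tok) for tok in lines[0].split()[:2])
    except (ValueError, IndexError):
        raise DimensionError(f"malformed PHYLIP header in {path}: {lines[0]!r}")
    pairs: list[tuple[str, str]] = []
    for ln in lines[1:]:
        parts = ln.split(None, 1)
        if pairs and len(pairs[-1][1]) < k:
            # continuation of the previous sequence
            pairs[-1] = (pairs[-1][0], pairs[-1][1] + "".join(ln.split()))
        elif len(parts) == 2:
            pairs.append((parts[0], "".join(parts[1].split())))
        else:
            raise DimensionError(f"unexpected PHYLIP line: {ln!r}")
    if len(pairs) != n:
        raise DimensionError(f"PHYLIP header declares {n} sequences, found {len(pairs)}")
    return pairs


def write_msa(msa: Msa, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment as FASTA or relaxed sequential PHYLIP."""
    path = Path(path)
    seqs = msa.sequences()
    with path.open("w") as fh:
        if format == "fasta":
            for taxon in msa.taxa:
                fh.write(f">{taxon}\n{seqs[taxon]}\n")
        elif format == "phylip":
            fh.write(f"{msa.n} {msa.k}\n")
            for taxon in msa.taxa:
                fh.write(f"{taxon}  {seqs[taxon]}\n")
        else:
            raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# ModelTree
# ---------------------------------------------------------------------------

@dataclass
class ModelTree:
    """A candidate (model) tree: an unrooted topology with optional branch lengths.

    Rooted Newick inputs are unrooted by suppressing the degree-2 root node —
    splits, not rootings, define the node-specific taxon subsets.
    """

    tree: dendropy.Tree
    label: str = ""

    def __post_init__(self):
        self.tree.is_rooted = False
        # collapse a degree-2 root left over from rooted Newick input
        self.tree.deroot()
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise DuplicateTaxonError("duplicate leaf labels in tree")
        for edge in self.tree.edges():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length} in tree {self.label!r}")

    @property
    def taxon_set(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def require_resolved(self) -> None:
        """Raise :class:`UnresolvedTreeError` unless every internal node has degree 3."""
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            degree = len(node.child_nodes()) + (0 if node.parent_node is None else 1)
            expected = 3
            if node.parent_node is None and self.n_leaves == 2:
                expected = 2
            if degree != expected:
                raise UnresolvedTreeError(
                    f"tree {self.label!r} has a node of degree {degree}; "
                    "candidate trees must be fully resolved"
                )

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_trees(path: str | Path, labels: Sequence[str] | None = None) -> list[ModelTree]:
    """Read one or more Newick trees from a file."""
    tree_list = dendropy.TreeList.get(path=str(path), schema="newick",
                                      preserve_underscores=True)
    trees = []
    for i, t in enumerate(tree_list):
        lbl = labels[i] if labels else (t.label or f"tree{i + 1}")
        trees.append(ModelTree(tree=t, label=lbl))
    return trees


def tree_from_newick(newick: str, label: str = "") -> ModelTree:
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return ModelTree(tree=t, label=label)


# ---------------------------------------------------------------------------
# TaxonSubset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonSubset:
    """The taxa on one side of an internal branch of a candidate tree.

    Identity is by member set only; the two sides of one branch are two
    distinct subsets, each carrying its own D value downstream.
    """

    members: frozenset[str]
    complement_size: int

    def __post_init__(self):
        if len(self.members) < 2 or self.complement_size < 2:
            raise SubsetSizeError(
                f"subset of size {len(self.members)} with complement {self.complement_size}; "
                "both sides of an internal branch must have >= 2 taxa"
            )

    @property
    def key(self) -> str:
        return SUBSET_KEY_SEP.join(sorted(self.members))

    @property
    def h(self) -> int:
        return len(self.members)


def extract_subsets(trees: Sequence[ModelTree]) -> list[TaxonSubset]:
    """Enumerate node-specific taxon subsets from candidate trees.

    For every internal branch of every tree, both side-subsets are emitted;
    duplicates across branches and trees are removed; the output is sorted by
    canonical key so D-vectors align across alignments in one test run.
    """
    if not trees:
        raise ValueError("no candidate trees supplied")
    taxa = trees[0].taxon_set
    for t in trees[1:]:
        if t.taxon_set != taxa:
            raise TaxonMismatchError(
                f"tree {t.label!r} has leaf set differing from tree {trees[0].label!r}"
            )
    n = len(taxa)
    seen: dict[frozenset[str], TaxonSubset] = {}
    for mt in trees:
        mt.require_resolved()
        for node in mt.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(below) < 2 or n - len(below) < 2:
                continue  # pendant edge
            for side in (below, taxa - below):
                if side not in seen:
                    seen[side] = TaxonSubset(members=side, complement_size=n - len(side))
    return sorted(seen.values(), key=lambda s: s.key)
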