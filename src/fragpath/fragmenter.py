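"""Fragment enumeration and binary fingerprint matrices.

Two fragment families describe a molecule:

* **linear** fragments — simple paths (no repeated atom) of 2–7 atoms by
  default, labelled by the alternating sequence of atom labels and bond marks
  (``C-C-O``, ``C:C:C``); a path and its reverse are the same fragment.
* **atom-centered** fragments — an atom together with a subset of its direct
  neighbours, 2–4 atoms total by default, labelled as the centre followed by
  the sorted multiset of ``(bond mark, neighbour)`` pairs (``C(-C)(-O)``).

The label grammar is this package's own; only set semantics matter downstream.
Formal charges are folded into atom labels (``O-``), aromatic bonds use ``:``.
Presence/absence of each vocabulary fragment makes a compound's binary
fingerprint; occurrence counts are deliberately not used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_io import Molecule, PathwayMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragment:
    label: str
    kind: str  # "linear" | "atom_centered"
    n_atoms: int


@dataclass(frozen=True)
class FragmentConfig:
    """Fragment-size bounds; defaults follow the linear 2–7 / centered 2–4 scheme."""

    linear_min: int = 2
    linear_max: int = 7
    centered_min: int = 2
    centered_max: int = 4

    def __post_init__(self) -> None:
        if not (1 <= self.linear_min <= self.linear_max):
            raise ValueError("require 1 <= linear_min <= linear_max")
        if not (2 <= self.centered_min <= self.centered_max):
            raise ValueError("require 2 <= centered_min <= centered_max")


def _iter_linear(mol: Molecule, min_atoms: int, max_atoms: int):
    """List of (canonical label, atom index tuple) over every simple path."""
    labels = mol.atom_labels()
    adj = mol.adjacency()
    results: list[tuple[str, tuple[int, ...]]] = []

    if min_atoms <= 1:
        for i, lab in enumerate(labels):
            results.append((lab, (i,)))

    path: list[int] = []
    parts: list[str] = []
    visited = [False] * mol.n_atoms

    def dfs(i: int) -> None:
        path.append(i)
        visited[i] = True
        parts.append(labels[i])
        if len(path) >= max(min_atoms, 2):
            fwd = "".join(parts)
            rev = "".join(reversed(parts))
            # canonical orientation: lexicographically smaller string
            results.append((min(fwd, rev), tuple(path)))
        if len(path) < max_atoms:
            for j, mark in adj[i]:
                if not visited[j]:
                    parts.append(mark)
                    dfs(j)
                    parts.pop()
        visited[i] = False
        path.pop()
        parts.pop()

    for start in range(mol.n_atoms):
        dfs(start)
    return results


def enumerate_linear_fragments(
    mol: Molecule, min_atoms: int = 2, max_atoms: int = 7
) -> set[Fragment]:
    """All simple atom/bond paths of ``min_atoms..max_atoms`` atoms, as canonical labels."""
    if not (1 <= min_atoms <= max_atoms):
        raise ValueError("require 1 <= min_atoms <= max_atoms")
    out: dict[str, int] = {}
    for label, atoms in _iter_linear(mol, min_atoms, max_atoms):
        out.setdefault(label, len(atoms))
    return {Fragment(lbl, "linear", n) for lbl, n in out.items()}


def _centered_label(center: str, nbrs: list[tuple[str, str]]) -> str:
    """Canonical atom-centered label: centre + sorted (mark, neighbour) multiset."""
    return center + "".join(f"({m}{lab})" for m, lab in sorted(nbrs))


def _iter_centered(mol: Molecule, min_atoms: int, max_atoms: int):
    from itertools import combinations

    labels = mol.atom_labels()
    adj = mol.adjacency()
    for i in range(mol.n_atoms):
        nbrs = adj[i]
        lo = max(min_atoms - 1, 1)
        hi = min(len(nbrs), max_atoms - 1)
        for size in range(lo, hi + 1):
            for combo in combinations(range(len(nbrs)), size):
                chosen = [(nbrs[c][1], labels[nbrs[c][0]]) for c in combo]
                atoms = (i,) + tuple(nbrs[c][0] for c in combo)
                yield _centered_label(labels[i], chosen), atoms


def enumerate_atom_centered_fragments(
    mol: Molecule, min_atoms: int = 2, max_atoms: int = 4
) -> set[Fragment]:
    """Every atom with every neighbour subset keeping total size within bounds."""
    if not (2 <= min_atoms <= max_atoms):
        raise ValueError("require 2 <= min_atoms <= max_atoms")
    out: dict[str, int] = {}
    for label, atoms in _iter_centered(mol, min_atoms, max_atoms):
        out.setdefault(label, len(atoms))
    return {Fragment(lbl, "atom_centered", n) for lbl, n in out.items()}


def fragment_set(mol: Molecule, config: FragmentConfig = FragmentConfig()) -> set[Fragment]:
    """Union of linear and atom-centered fragments under ``config``."""
    return enumerate_linear_fragments(
        mol, config.linear_min, config.linear_max
    ) | enumerate_atom_centered_fragments(mol, config.centered_min, config.centered_max)


def fragment_labels(mol: Molecule, config: FragmentConfig = FragmentConfig()) -> set[str]:
    return {f.label for f in fragment_set(mol, config)}


def fragment_atom_hits(
    mol: Molecule, labels: set[str], config: FragmentConfig = FragmentConfig()
) -> dict[str, list[tuple[int, ...]]]:
    """Atom-index tuples of every occurrence of the requested fragment labels.

    Used to highlight enriched fragments on a query structure.  Linear hits
    report the path atoms in path order (one orientation per occurrence);
    centered hits report centre first.
    """
    hits: dict[str, set[tuple[int, ...]]] = {}
    for label, atoms in _iter_linear(mol, config.linear_min, config.linear_max):
        if label in labels:
            canon = atoms if atoms <= atoms[::-1] else atoms[::-1]
            hits.setdefault(label, set()).add(canon)
    for label, atoms in _iter_centered(mol, config.centered_min, config.centered_max):
        if label in labels:
            hits.setdefault(label, set()).add((atoms[0],) + tuple(sorted(atoms[1:])))
    return {lbl: sorted(occ) for lbl, occ in hits.items()}


# ---------------------------------------------------------------------------
# Fingerprint matrix


@dataclass
class FingerprintMatrix:
    """Compounds × fragment-vocabulary binary presence matrix.

    ``values`` is uint8 in {0,1}; row order matches ``compound_ids``; the
    vocabulary is lexicographically sorted when built from a corpus, which
    makes column order stable across input permutations.
    """

    compound_ids: list[str]
    vocabulary: list[str]
    values: np.ndarray
    _row_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.compound_ids), len(self.vocabulary)):
            raise ValueError("matrix shape does not match ids/vocabulary")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("fingerprint values must be binary")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids")
        self._row_index = {c: i for i, c in enumerate(self.compound_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, compound_id: str) -> np.ndarray:
        return self.values[self._row_index[compound_id]]

    def row_indices(self, compound_ids) -> np.ndarray:
        return np.array([self._row_index[c] for c in compound_ids], dtype=np.intp)

    def subset_rows(self, indices) -> "FingerprintMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return FingerprintMatrix(
            [self.compound_ids[i] for i in idx], self.vocabulary, self.values[idx]
        )

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("compound_id\t" + "\t".join(self.vocabulary) + "\n")
            for cid, row in zip(self.compound_ids, self.values):
                fh.write(cid + "\t" + "\t".join(map(str, row)) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "FingerprintMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            vocab = header[1:]
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([int(v) for v in parts[1:]])
        return cls(ids, vocab, np.array(rows, dtype=np.uint8))

    def to_sparse(self, path) -> None:
        """Compact form: ``compound_id <tab> space-separated column indices``."""
        with open(path, "w") as fh:
            for cid, row in zip(self.compound_ids, self.values):
                cols = np.flatnonzero(row)
                fh.write(cid + "\t" + " ".join(map(str, cols)) + "\n")


def fingerprint(
    mol: Molecule, vocabulary: list[str], config: FragmentConfig = FragmentConfig()
) -> np.ndarray:
    """Binary vector of ``mol`` aligned to ``vocabulary``; out-of-vocabulary fragments ignored."""
    if not vocabulary:
        raise ValueError("vocabulary is empty")
    frags = fragment_labels(mol, config)
    unknown = frags - set(vocabulary)
    if unknown:
        logger.debug("%s: %d fragments outside vocabulary ignored", mol.id, len(unknown))
    return np.fromiter((1 if v in frags else 0 for v in vocabulary), dtype=np.uint8)


def build_matrix(
    mols: list[Molecule], config: FragmentConfig = FragmentConfig()
) -> FingerprintMatrix:
    """Fingerprint a corpus; vocabulary = sorted union of all observed fragments."""
    if not mols:
        raise ValueError("no molecules")
    per_mol = [fragment_labels(m, config) for m in mols]
    vocab = sorted(set().union(*per_mol))
    if not vocab:
        raise ValueError("no fragments: corpus yields an empty vocabulary")
    col = {lbl: j for j, lbl in enumerate(vocab)}
    values = np.zeros((len(mols), len(vocab)), dtype=np.uint8)
    for i, frags in enumerate(per_mol):
        for lbl in frags:
            values[i, col[lbl]] = 1
    return FingerprintMatrix([m.id for m in mols], vocab, values)


def merge_redundant(
    matrix: FingerprintMatrix, pmap: PathwayMap
) -> tuple[FingerprintMatrix, PathwayMap, dict[str, list[str]]]:
    """Collapse compounds with identical fingerprints into one representative.

    Structurally indistinguishable compounds (e.g. stereoisomers at the
    heavy-atom-graph level) would otherwise leak between training and test
    sets.  The representative is the first-seen compound; its pathway set is
    the union over the merged group.  Returns the merge log
    ``representative -> all ids in the group`` for groups of size > 1.
    """
    groups: dict[bytes, list[int]] = {}
    for i in range(matrix.shape[0]):
        groups.setdefault(matrix.values[i].tobytes(), []).append(i)
    keep = sorted(idx[0] for idx in groups.values())
    rename: dict[str, str] = {}
    log: dict[str, list[str]] = {}
    for idx in groups.values():
        rep = matrix.compound_ids[idx[0]]
        members = [matrix.compound_ids[i] for i in idx]
        if len(idx) > 1:
            log[rep] = members
            for m in members[1:]:
                rename[m] = rep
    merged = matrix.subset_rows(keep)
    return merged, pmap.rename_compounds(rename), log
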