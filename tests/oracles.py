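"""Independent brute-force oracles used by the tests.

These deliberately share no code path with the package: fragments are found
by trying every atom permutation / neighbour subset, and the hypergeometric
upper tail by enumerating every possible draw.
"""

from itertools import combinations, permutations

from fragpath.chem_io import Molecule


def brute_force_linear(mol: Molecule, min_atoms: int, max_atoms: int) -> set[str]:
    """Every simple path found by testing all atom-index permutations."""
    n = mol.n_atoms
    labels = mol.atom_labels()
    bond = {}
    for i, j, mark in mol.bonds:
        bond[(i, j)] = mark
        bond[(j, i)] = mark
    out: set[str] = set()
    if min_atoms <= 1:
        out.update(labels)
    for k in range(max(min_atoms, 2), min(max_atoms, n) + 1):
        for perm in permutations(range(n), k):
            marks = [bond.get((perm[t], perm[t + 1])) for t in range(k - 1)]
            if any(m is None for m in marks):
                continue
            parts = [labels[perm[0]]]
            for t in range(k - 1):
                parts += [marks[t], labels[perm[t + 1]]]
            fwd = "".join(parts)
            rev = "".join(reversed(parts))
            out.add(min(fwd, rev))
    return out


def brute_force_centered(mol: Molecule, min_atoms: int, max_atoms: int) -> set[str]:
    """Every atom-centered fragment by explicit neighbour-subset enumeration."""
    labels = mol.atom_labels()
    nbrs: dict[int, list[tuple[str, str]]] = {i: [] for i in range(mol.n_atoms)}
    for i, j, mark in mol.bonds:
        nbrs[i].append((mark, labels[j]))
        nbrs[j].append((mark, labels[i]))
    out: set[str] = set()
    for center in range(mol.n_atoms):
        for size in range(1, len(nbrs[center]) + 1):
            if not (min_atoms <= size + 1 <= max_atoms):
                continue
            for subset in combinations(range(len(nbrs[center])), size):
                chosen = sorted(nbrs[center][s] for s in subset)
                out.add(labels[center] + "".join(f"({m}{l})" for m, l in chosen))
    return out


def hypergeom_tail_by_enumeration(M: int, K: int, N: int, x: int) -> float:
    """P(X >= x) by enumerating all C(M, N) draws from a pool whose first K
    items are marked."""
    total = 0
    hits = 0
    for draw in combinations(range(M), N):
        total += 1
        if sum(1 for el in draw if el < K) >= x:
            hits += 1
    return hits / total if total else 1.0
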