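"""Reading and validation of compound structures and pathway membership tables.

Compounds enter as MDL V2000 SDF records or SMILES strings and are reduced to
heavy-atom graphs: explicit hydrogens are stripped, aromaticity is perceived
with RDKit's standard model, and aromatic bonds are labelled distinctly from
alternating single/double bonds so that kekulized and aromatic inputs of the
same ring yield identical fragment sets.  Stereochemistry, isotopes and salt
standardization are deliberately ignored.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit's C++ logging is noisy on deliberately dirty records; parse failures
# are reported through this module's logger and returned skip counts instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

#: bond-order → label used in fragment strings (aromatic kept distinct)
BOND_MARKS = {1.0: "-", 2.0: "=", 3.0: "#"}
AROMATIC_MARK = ":"


def atom_label(element: str, charge: int) -> str:
    """Element symbol with the formal charge appended when nonzero (``O-``, ``N+``, ``Fe+2``)."""
    if charge == 0:
        return element
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return f"{element}{sign}" if mag == 1 else f"{element}{sign}{mag}"


@dataclass(frozen=True)
class Molecule:
    """Heavy-atom molecular graph.

    atoms: tuple of ``(element symbol, formal charge, aromatic flag)``.
    bonds: tuple of ``(i, j, mark)`` with ``i < j`` and mark in ``- = # :``.
    Hydrogens are implicit; there is at most one bond per atom pair.
    """

    id: str
    atoms: tuple[tuple[str, int, bool], ...]
    bonds: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        seen: set[tuple[int, int]] = set()
        for i, j, mark in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id!r}: invalid bond ({i},{j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"molecule {self.id!r}: duplicate bond {key}")
            seen.add(key)
            if mark not in "-=#:":
                raise ValueError(f"molecule {self.id!r}: unknown bond mark {mark!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_labels(self) -> list[str]:
        return [atom_label(sym, chg) for sym, chg, _ in self.atoms]

    def adjacency(self) -> list[list[tuple[int, str]]]:
        adj: list[list[tuple[int, str]]] = [[] for _ in self.atoms]
        for i, j, mark in self.bonds:
            adj[i].append((j, mark))
            adj[j].append((i, mark))
        return adj


def _from_rdkit(mol: Chem.Mol, mol_id: str) -> Molecule:
    mol = Chem.RemoveHs(mol)
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic()) for a in mol.GetAtoms()
    )
    bonds = []
    for b in mol.GetBonds():
        if b.GetIsAromatic():
            mark = AROMATIC_MARK
        else:
            mark = BOND_MARKS.get(b.GetBondTypeAsDouble())
            if mark is None:
                raise ValueError(
                    f"molecule {mol_id!r}: unsupported bond order {b.GetBondTypeAsDouble()}"
                )
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j), mark))
    return Molecule(id=mol_id, atoms=atoms, bonds=tuple(sorted(bonds)))


def parse_smiles(smiles: str, mol_id: str) -> Molecule:
    """Parse one SMILES string into a heavy-atom :class:`Molecule`."""
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"invalid SMILES {smiles!r} (id={mol_id!r})")
    return _from_rdkit(rd, mol_id)


def read_sdf(path) -> tuple[list[Molecule], int]:
    """Read a multi-record MDL V2000 SDF file.

    Returns ``(molecules, n_skipped)``: unparseable records are skipped with a
    logged warning rather than aborting the run (real compound databases are
    dirty).  The record name (or, failing that, the first data field) becomes
    the molecule id.  An id collision between two different structures is an
    error; an exact duplicate record under the same id keeps the first copy.
    """
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    except OSError as exc:
        raise ValueError(f"unreadable or empty SDF file: {path}") from exc
    mols: list[Molecule] = []
    seen: dict[str, str] = {}  # id -> canonical SMILES
    skipped = 0
    for idx, rd in enumerate(supplier):
        if rd is None:
            skipped += 1
            logger.warning("skipping unparseable SDF record %d in %s", idx, path)
            continue
        mol_id = rd.GetProp("_Name").strip() if rd.HasProp("_Name") else ""
        if not mol_id:
            props = rd.GetPropNames()
            mol_id = rd.GetProp(props[0]).strip() if props else f"mol{idx}"
        canon = Chem.MolToSmiles(rd)
        if mol_id in seen:
            if seen[mol_id] != canon:
                raise ValueError(
                    f"id collision: {mol_id!r} appears with two different structures"
                )
            logger.warning("duplicate record for id %r; keeping first", mol_id)
            continue
        seen[mol_id] = canon
        mols.append(_from_rdkit(rd, mol_id))
    if not mols and skipped == 0:
        raise ValueError(f"empty SDF file: {path}")
    if not mols:
        raise ValueError(f"no parseable records in SDF file: {path}")
    return mols, skipped


def read_smiles_file(path) -> list[Molecule]:
    """Read a SMILES file: one molecule per line, optional tab-separated id."""
    mols = []
    with open(path) as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"mol{idx}"
            mols.append(parse_smiles(smiles, mol_id))
    if not mols:
        raise ValueError(f"empty SMILES file: {path}")
    return mols


class PathwayMap:
    """Pathway → compound membership with the derived reverse map.

    Multi-label by design: a compound may belong to several pathways.  Every
    compound in the map belongs to at least one pathway (compounds orphaned by
    filtering are dropped from the reverse map).
    """

    def __init__(self, pathways: dict[str, set[str]]):
        self._fwd = {p: frozenset(cs) for p, cs in pathways.items() if cs}
        rev: dict[str, set[str]] = {}
        for p, cs in self._fwd.items():
            for c in cs:
                rev.setdefault(c, set()).add(p)
        self._rev = {c: frozenset(ps) for c, ps in rev.items()}

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self._fwd)

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self._rev)

    def compounds_of(self, pathway_id: str) -> frozenset[str]:
        return self._fwd[pathway_id]

    def pathways_of(self, compound_id: str) -> frozenset[str]:
        return self._rev.get(compound_id, frozenset())

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._fwd

    def __len__(self) -> int:
        return len(self._fwd)

    def __eq__(self, other) -> bool:
        return isinstance(other, PathwayMap) and self._fwd == other._fwd

    def items(self):
        return self._fwd.items()

    def rename_compounds(self, mapping: dict[str, str]) -> "PathwayMap":
        """Return a map with compound ids replaced per ``mapping`` (used by merging)."""
        return PathwayMap(
            {p: {mapping.get(c, c) for c in cs} for p, cs in self._fwd.items()}
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pathway_id\tcompound_id\n")
            for p in sorted(self._fwd):
                for c in sorted(self._fwd[p]):
                    fh.write(f"{p}\t{c}\n")


_HEADER_TOKENS = {"pathway", "pathway_id", "pathwayid"}


def read_pathway_map(path) -> PathwayMap:
    """Read a two-column TSV ``pathway_id <tab> compound_id`` (header optional)."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for idx, row in enumerate(reader):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {idx + 1} has fewer than 2 columns")
            p, c = row[0].strip(), row[1].strip()
            if idx == 0 and p.lower() in _HEADER_TOKENS:
                continue
            pathways.setdefault(p, set()).add(c)
    if not pathways:
        raise ValueError(f"empty pathway map: {path}")
    return PathwayMap(pathways)


def filter_pathways(pmap: PathwayMap, min_compounds: int = 10) -> PathwayMap:
    """Keep pathways with at least ``min_compounds`` distinct compounds.

    Compounds left without any pathway disappear from the reverse map.
    Idempotent.  The default threshold of 10 matches the curation rule used
    for real pathway databases.
    """
    if min_compounds < 1:
        raise ValueError("min_compounds must be >= 1")
    return PathwayMap(
        {p: set(cs) for p, cs in pmap.items() if len(cs) >= min_compounds}
    )


def missing_structures(pmap: PathwayMap, structure_ids) -> set[str]:
    """Compound ids referenced by the map but absent from the structure set."""
    return set(pmap.compound_ids) - set(structure_ids)
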