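"""Synthetic inputs with known ground truth.

Two fixture levels, so the statistical machinery and the chemistry machinery
can be exercised independently:

* :func:`generate_planted_matrix` — an abstract fingerprint matrix with
  planted fragment enrichment: each pathway owns a few dedicated fragment
  columns whose presence probability is ``p_in`` for members and ``p_bg``
  for everyone else; all remaining cells are background ``Bernoulli(p_bg)``.
  Setting ``p_in == p_bg`` yields a pure null design (no recoverable signal).
  ``n_subfamilies > 1`` splits each pathway's members and enriched columns
  into disjoint structural sub-families, producing pathways that are
  statistically coherent but pairwise heterogeneous — the regime where
  profile pooling beats nearest-neighbour similarity.

* :func:`generate_toy_smiles_library` — a small real-chemistry library of
  three scaffold families (fatty alcohols/acids, substituted benzenes,
  organophosphates), family = pathway, including one molecule annotated to
  two families and one duplicate structure under two ids (to exercise
  fingerprint-level merging).

Both generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import PathwayMap
from .fragmenter import FingerprintMatrix


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted-enrichment simulation.

    Defaults describe a strong-signal desk-scale study: 20 pathways of 30
    compounds, 400 fragments of which 5 per pathway are enriched, in-pathway
    presence probability 0.9 against a 0.05 background, and 10% of compounds
    annotated to a second pathway.
    """

    n_pathways: int = 20
    compounds_per_pathway: int = 30
    vocab_size: int = 400
    n_enriched_per_pathway: int = 5
    p_in: float = 0.9
    p_bg: float = 0.05
    frac_multi: float = 0.1
    n_subfamilies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_bg <= self.p_in <= 1):
            raise ValueError("require 0 <= p_bg <= p_in <= 1")
        if not (0 <= self.frac_multi < 1):
            raise ValueError("frac_multi must be in [0, 1)")
        if min(self.n_pathways, self.compounds_per_pathway, self.vocab_size,
               self.n_enriched_per_pathway, self.n_subfamilies) < 1:
            raise ValueError("all counts must be positive")
        if self.vocab_size < self.n_pathways * self.n_enriched_per_pathway:
            raise ValueError("vocab_size too small for the enriched blocks")
        if self.n_subfamilies > self.n_enriched_per_pathway:
            raise ValueError("need at least one enriched fragment per sub-family")


def generate_planted_matrix(
    design: PlantedDesign,
) -> tuple[FingerprintMatrix, PathwayMap, dict[str, list[str]]]:
    """Planted-enrichment fingerprint matrix, its pathway map, and the truth
    map pathway → enriched fragment labels.

    All-zero fragment columns (possible by chance at low ``p_bg``) are dropped
    so the matrix honours the corpus-built-vocabulary invariant; the truth map
    refers to the surviving labels.
    """
    d = design
    rng = np.random.default_rng(d.seed)
    n_comp = d.n_pathways * d.compounds_per_pathway
    comp_ids = [f"c{i:04d}" for i in range(n_comp)]
    path_ids = [f"P{p:02d}" for p in range(d.n_pathways)]
    frag_ids = [f"f{j:04d}" for j in range(d.vocab_size)]

    primary = np.repeat(np.arange(d.n_pathways), d.compounds_per_pathway)
    membership: dict[str, set[str]] = {p: set() for p in path_ids}
    second = np.full(n_comp, -1)
    n_multi = int(d.frac_multi * n_comp)
    if n_multi and d.n_pathways > 1:
        multi_rows = rng.choice(n_comp, size=n_multi, replace=False)
        for i in multi_rows:
            other = int(rng.integers(d.n_pathways - 1))
            if other >= primary[i]:
                other += 1
            second[i] = other
    for i in range(n_comp):
        membership[path_ids[primary[i]]].add(comp_ids[i])
        if second[i] >= 0:
            membership[path_ids[second[i]]].add(comp_ids[i])

    values = (rng.random((n_comp, d.vocab_size)) < d.p_bg).astype(np.uint8)
    e = d.n_enriched_per_pathway
    # sub-family assignment of each compound within its primary pathway
    subfam = rng.integers(d.n_subfamilies, size=n_comp)
    # multi-pathway compounds sample enriched columns from both their pathways:
    # each pathway's block is drawn at p_in diluted by the membership count
    # (never below background), so their per-pathway signal is mixed/weaker
    n_member = 1 + (second >= 0)
    truth: dict[str, list[str]] = {}
    for p in range(d.n_pathways):
        cols = np.arange(p * e, (p + 1) * e)
        truth[path_ids[p]] = [frag_ids[c] for c in cols]
        col_fam = np.arange(e) % d.n_subfamilies  # enriched columns split round-robin
        members = [i for i in range(n_comp) if primary[i] == p or second[i] == p]
        for i in members:
            mine = cols[col_fam == subfam[i]] if d.n_subfamilies > 1 else cols
            p_eff = max(d.p_bg, d.p_in / n_member[i])
            values[i, mine] = rng.random(len(mine)) < p_eff

    nonzero = values.any(axis=0)
    kept = np.flatnonzero(nonzero)
    values = values[:, kept]
    kept_labels = [frag_ids[j] for j in kept]
    kept_set = set(kept_labels)
    truth = {p: [f for f in fr if f in kept_set] for p, fr in truth.items()}

    matrix = FingerprintMatrix(comp_ids, kept_labels, values)
    return matrix, PathwayMap(membership), truth


# ---------------------------------------------------------------------------
# Toy SMILES library


def _toy_families(rng: np.random.Generator) -> dict[str, list[str]]:
    chains = [("C" * k) for k in range(1, 8)]
    alcohols = [c + "O" for c in chains]
    acids = [c + "C(=O)O" for c in chains]
    benz_subs = ["O", "N", "Cl", "Br", "C", "OC", "C=C", "C#N", "F", "CC", "I", "CO"]
    benzenes = ["c1ccccc1" + s for s in benz_subs] + ["c1ccccc1", "Cc1ccc(C)cc1"]
    phos = [c + "OP(=O)(O)O" for c in chains]
    phos += ["OCC(O)COP(=O)(O)O", "OC(CO)COP(=O)(O)OP(=O)(O)O", "OCC(O)C(O)COP(=O)(O)O",
             "NCCOP(=O)(O)O", "OC(C(=O)O)COP(=O)(O)O", "C(COP(=O)(O)O)N", "OCC(N)COP(=O)(O)O"]
    fams = {
        "alcohol_acid": alcohols + acids,
        "benzenoid": benzenes,
        "organophosphate": phos,
    }
    for f in fams.values():
        rng.shuffle(f)
    return fams


def generate_toy_smiles_library(seed: int = 0) -> tuple[list[tuple[str, str]], PathwayMap]:
    """A three-family SMILES library with one shared and one duplicated compound.

    Families (= pathways): linear alcohols/acids, substituted benzenes and
    organophosphates, each >= 12 molecules.  ``shared_benzoate`` (benzoic
    acid) is annotated to both the benzenoid and the alcohol/acid family;
    ``dup_a``/``dup_b`` are the same structure (butan-1-ol, itself also a
    family member) under two ids, for exercising identical-fingerprint merging.
    """
    rng = np.random.default_rng(seed)
    fams = _toy_families(rng)
    records: list[tuple[str, str]] = []
    membership: dict[str, set[str]] = {f: set() for f in fams}
    for fam, smis in fams.items():
        for i, smi in enumerate(smis):
            cid = f"{fam}_{i:02d}"
            records.append((cid, smi))
            membership[fam].add(cid)
    records.append(("shared_benzoate", "OC(=O)c1ccccc1"))
    membership["benzenoid"].add("shared_benzoate")
    membership["alcohol_acid"].add("shared_benzoate")
    records.append(("dup_a", "CCCCO"))
    membership["alcohol_acid"].add("dup_a")
    records.append(("dup_b", "OCCCC"))
    membership["organophosphate"].add("dup_b")
    return records, PathwayMap(membership)


def write_smiles(records: list[tuple[str, str]], path) -> None:
    """One ``SMILES <tab> id`` line per record (the format chem_io reads)."""
    with open(path, "w") as fh:
        for cid, smi in records:
            fh.write(f"{smi}\t{cid}\n")


def write_sdf(records: list[tuple[str, str]], path) -> None:
    """MDL V2000 multi-record SDF of the library (via RDKit)."""
    from rdkit import Chem

    with Chem.SDWriter(str(path)) as w:
        for cid, smi in records:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"bad SMILES in library: {smi!r}")
            mol.SetProp("_Name", cid)
            w.write(mol)
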