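import logging

import numpy as np
import pytest

import fragpath as fp

# low-n_random warnings are expected all over the suite; keep output readable
logging.getLogger("fragpath").setLevel(logging.ERROR)
for name in ("fragpath.null_model", "fragpath.predict_eval", "fragpath.profiles"):
    logging.getLogger(name).setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_library():
    """(records, pathway map) of the three-family SMILES library."""
    return fp.generate_toy_smiles_library(seed=0)


@pytest.fixture(scope="session")
def toy_matrix(toy_library):
    """Fingerprint matrix of the toy library plus merged matrix/map/log."""
    records, pmap = toy_library
    mols = [fp.parse_smiles(smi, cid) for cid, smi in records]
    matrix = fp.build_matrix(mols)
    merged, merged_map, log = fp.merge_redundant(matrix, pmap)
    return {"mols": mols, "matrix": matrix, "pmap": pmap,
            "merged": merged, "merged_map": merged_map, "log": log}


@pytest.fixture(scope="session")
def small_planted():
    """A small strong-signal planted design with fitted models (shared, read-only)."""
    design = fp.PlantedDesign(
        n_pathways=5, compounds_per_pathway=12, vocab_size=80,
        n_enriched_per_pathway=4, seed=1,
    )
    matrix, pmap, truth = fp.generate_planted_matrix(design)
    ids = set(matrix.compound_ids)
    profiles = [
        fp.build_profile(matrix, pmap.compounds_of(p) & ids, p)
        for p in pmap.pathway_ids
    ]
    nulls = fp.build_nulls(matrix, profiles, n_random=300, seed=2)
    return {"design": design, "matrix": matrix, "pmap": pmap, "truth": truth,
            "profiles": profiles, "nulls": nulls}
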