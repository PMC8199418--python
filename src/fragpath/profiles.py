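"""Pathway enrichment profiles (Pv) and the compound-matching score (Sc).

A pathway's profile assigns each vocabulary fragment the upper-tail
cumulative hypergeometric probability of seeing the fragment's in-pathway
count by chance, given its frequency in the whole compound database:

    Pv_i = P(X >= x_i),  X ~ Hypergeometric(M, K_i, N)

with M the number of compounds in the database, K_i the number carrying
fragment i, N the pathway size and x_i the in-pathway carriers.  Zero
p-values (possible only through floating-point underflow) are floored at the
profile's smallest nonzero Pv divided by 50 so logarithms stay finite.

A compound X is matched against a profile by the mean negative log
probability over the fragments it contains:

    Sc = - sum_i log(Pv_i) X_i / sum_i X_i      (natural log)

Only fragments present in the compound contribute; a compound with no
vocabulary fragment is unscorable and scores 0 by convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .fragmenter import FingerprintMatrix

logger = logging.getLogger(__name__)

#: zero Pv entries are replaced by (smallest nonzero Pv in the profile) / this
P_FLOOR_DIVISOR = 50.0


def hypergeom_upper_tail(M: int, K: int, N: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(M, K, N): draws of size N from a pool
    of M containing K marked items; upper tail of the number of marked draws."""
    if not (0 <= x <= N <= M and 0 <= K <= M):
        raise ValueError(f"invalid hypergeometric arguments M={M} K={K} N={N} x={x}")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, M, K, N))


@dataclass
class PathwayProfile:
    """Per-fragment enrichment p-values for one pathway.

    ``pv`` is aligned to ``vocabulary``; ``K`` and ``x`` are the database and
    in-pathway carrier counts per fragment; ``M``/``N`` the database and
    pathway sizes.  ``weights`` caches ``-log(pv)`` for scoring.
    """

    pathway_id: str
    vocabulary: list[str]
    pv: np.ndarray
    K: np.ndarray
    x: np.ndarray
    M: int
    N: int
    p_floor: float

    def __post_init__(self) -> None:
        self.pv = np.asarray(self.pv, dtype=np.float64)
        if not ((self.pv > 0) & (self.pv <= 1)).all():
            raise ValueError("pv must lie in (0, 1] after flooring")
        if len(self.pv) != len(self.vocabulary):
            raise ValueError("pv length must equal vocabulary size")
        if (self.x > np.minimum(self.K, self.N)).any():
            raise ValueError("x cannot exceed min(K, N)")
        self.weights = -np.log(self.pv)

    def to_files(self, tsv_path, json_path) -> None:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "pathway_id": self.pathway_id,
                    "M": self.M,
                    "N": self.N,
                    "p_floor": self.p_floor,
                },
                fh,
                indent=1,
            )
        with open(tsv_path, "w") as fh:
            fh.write("fragment\tK\tx\tpv\n")
            for lbl, K, x, pv in zip(self.vocabulary, self.K, self.x, self.pv):
                fh.write(f"{lbl}\t{K}\t{x}\t{pv:.17g}\n")

    @classmethod
    def from_files(cls, tsv_path, json_path) -> "PathwayProfile":
        with open(json_path) as fh:
            head = json.load(fh)
        vocab, Ks, xs, pvs = [], [], [], []
        with open(tsv_path) as fh:
            fh.readline()
            for line in fh:
                lbl, K, x, pv = line.rstrip("\n").split("\t")
                vocab.append(lbl)
                Ks.append(int(K))
                xs.append(int(x))
                pvs.append(float(pv))
        return cls(
            head["pathway_id"],
            vocab,
            np.array(pvs),
            np.array(Ks, dtype=np.int64),
            np.array(xs, dtype=np.int64),
            head["M"],
            head["N"],
            head["p_floor"],
        )


def build_profile(
    matrix: FingerprintMatrix,
    pathway_compound_ids,
    pathway_id: str = "",
    exclude=(),
) -> PathwayProfile:
    """Enrichment profile of one pathway against the whole-matrix background.

    ``exclude`` removes compounds (typically the query, for leave-one-out
    scoring) from both the pathway and the background before counting.
    """
    exclude = set(exclude)
    members = set(pathway_compound_ids) - exclude
    if len(members) < 2:
        raise ValueError(f"pathway {pathway_id!r} needs >= 2 compounds, got {len(members)}")
    missing = members - set(matrix.compound_ids)
    if missing:
        raise ValueError(f"pathway {pathway_id!r}: compounds missing from matrix: {sorted(missing)[:5]}")
    if exclude:
        keep = [i for i, c in enumerate(matrix.compound_ids) if c not in exclude]
        matrix = matrix.subset_rows(keep)
    values = matrix.values
    M = values.shape[0]
    rows = matrix.row_indices(sorted(members))
    N = len(rows)
    K = values.sum(axis=0, dtype=np.int64)
    x = values[rows].sum(axis=0, dtype=np.int64)
    # upper tail P(X >= x); sf(x-1) so x == 0 gives exactly 1
    pv = hypergeom.sf(x - 1, M, K, N)
    nonzero = pv[pv > 0]
    if nonzero.size == 0:
        raise ValueError(f"pathway {pathway_id!r}: all p-values underflowed to zero")
    p_floor = float(nonzero.min() / P_FLOOR_DIVISOR)
    if (pv == 0).any():
        logger.debug("pathway %s: flooring %d zero p-values at %.3g", pathway_id, int((pv == 0).sum()), p_floor)
        pv = np.where(pv == 0, p_floor, pv)
    return PathwayProfile(
        pathway_id=pathway_id,
        vocabulary=list(matrix.vocabulary),
        pv=pv,
        K=K,
        x=x,
        M=M,
        N=N,
        p_floor=p_floor,
    )


def score(x_vec: np.ndarray, profile: PathwayProfile) -> float:
    """Matching score Sc of one fingerprint against a profile.

    Mean of -log(Pv) over the fragments present in the compound; 0 (with a
    warning) for a compound carrying no vocabulary fragment, so that batch
    prediction never aborts — such compounds are flagged unscorable upstream.
    """
    x_vec = np.asarray(x_vec)
    if x_vec.shape != (len(profile.vocabulary),):
        raise ValueError("fingerprint is not aligned to the profile vocabulary")
    n = int(x_vec.sum())
    if n == 0:
        logger.warning("zero-fragment compound: Sc defined as 0")
        return 0.0
    return float(profile.weights @ (x_vec != 0)) / n


def score_many(values: np.ndarray, profile: PathwayProfile) -> np.ndarray:
    """Vectorized :func:`score` over the rows of a binary matrix (0 for empty rows)."""
    values = np.asarray(values)
    num = values @ profile.weights
    den = values.sum(axis=1)
    return np.divide(num, den, out=np.zeros(len(values)), where=den > 0)
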