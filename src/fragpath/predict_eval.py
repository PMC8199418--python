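"""Pathway ranking, enriched-fragment reports, the k-NN baseline and ROC/AUC.

A query compound is scored against every pathway profile, calibrated through
that pathway's null model, and the pathways are ranked by increasing p-value
(ties: decreasing z-score, then pathway id).  Taking the top-n ranked
pathways as predictions for n = 1..P defines a family of predictors of
increasing sensitivity; sweeping n and pooling (compound, pathway) pairs
yields the ROC curve, whose area quantifies overall ranking quality
(AUC = 0.5 is random, 1.0 perfect).

The pairwise baseline ranks pathways by the best Tanimoto similarity of any
of the query's k nearest database neighbours annotated to the pathway.

Evaluation is a tenfold cross-validation with a seeded, recorded partition so
the profile method and the baseline can share exactly the same folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_io import Molecule, PathwayMap
from .fragmenter import FingerprintMatrix, FragmentConfig, fragment_atom_hits
from .null_model import NullModel, build_nulls, p_from_z
from .profiles import PathwayProfile, build_profile, score_many

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayScore:
    pathway_id: str
    sc: float
    z: float
    p: float
    rank: int


@dataclass
class PredictionResult:
    """Full pathway ranking for one compound (empty and flagged if unscorable)."""

    compound_id: str
    entries: list[PathwayScore]
    unscorable: bool = False

    def ranking(self) -> list[str]:
        return [e.pathway_id for e in self.entries]

    def rank_of(self, pathway_id: str) -> int:
        for e in self.entries:
            if e.pathway_id == pathway_id:
                return e.rank
        raise KeyError(pathway_id)


def _rank_entries(pids, sc, z, p) -> list[PathwayScore]:
    # increasing p, ties by decreasing z then pathway id
    order = sorted(range(len(pids)), key=lambda j: (p[j], -z[j], pids[j]))
    return [
        PathwayScore(pids[j], float(sc[j]), float(z[j]), float(p[j]), r + 1)
        for r, j in enumerate(order)
    ]


def predict(
    x_vec: np.ndarray,
    profiles: list[PathwayProfile],
    nulls: list[NullModel],
    compound_id: str = "",
) -> PredictionResult:
    """Rank all pathways for one fingerprint by calibrated p-value."""
    return predict_all(np.asarray(x_vec)[None, :], [compound_id], profiles, nulls)[0]


def predict_all(
    values: np.ndarray,
    compound_ids: list[str],
    profiles: list[PathwayProfile],
    nulls: list[NullModel],
) -> list[PredictionResult]:
    """Vectorized :func:`predict` over the rows of a fingerprint matrix."""
    if [p.pathway_id for p in profiles] != [n.pathway_id for n in nulls]:
        raise ValueError("profiles and null models are not aligned by pathway_id")
    values = np.asarray(values)
    pids = [p.pathway_id for p in profiles]
    S = np.column_stack([score_many(values, p) for p in profiles])
    Z = np.column_stack([(S[:, j] - n.mean_sr) / n.sd_sr for j, n in enumerate(nulls)])
    P = np.column_stack([p_from_z(Z[:, j], n) for j, n in enumerate(nulls)])
    scorable = values.sum(axis=1) > 0
    out = []
    for i, cid in enumerate(compound_ids):
        if not scorable[i]:
            out.append(PredictionResult(cid, [], unscorable=True))
        else:
            out.append(PredictionResult(cid, _rank_entries(pids, S[i], Z[i], P[i])))
    return out


def top_n(result: PredictionResult, n: int) -> set[str]:
    """The first n ranked pathways (the top-n predictor family member)."""
    if result.unscorable:
        return set()
    if not (1 <= n <= len(result.entries)):
        raise ValueError(f"n must be in 1..{len(result.entries)}")
    return {e.pathway_id for e in result.entries[:n]}


def filter_predictions(results, n: int = 1, p_max: float | None = None):
    """Generic (rank <= n, p < p_max) filter over prediction entries."""
    kept = []
    for r in results:
        for e in r.entries[:n]:
            if p_max is None or e.p < p_max:
                kept.append((r.compound_id, e))
    return kept


# ---------------------------------------------------------------------------
# Enriched fragments


def enriched_fragments(
    profile: PathwayProfile, k: int | None = None, p_threshold: float | None = None
) -> list[tuple[str, float, int, int]]:
    """Fragments of a profile sorted by ascending Pv (ties by label).

    With ``k``, exactly the k most enriched are returned; with
    ``p_threshold``, those with Pv <= threshold.  These are the substructures
    characteristic of the pathway.
    """
    order = sorted(range(len(profile.vocabulary)), key=lambda j: (profile.pv[j], profile.vocabulary[j]))
    rows = [
        (profile.vocabulary[j], float(profile.pv[j]), int(profile.K[j]), int(profile.x[j]))
        for j in order
    ]
    if p_threshold is not None:
        rows = [r for r in rows if r[1] <= p_threshold]
    if k is not None:
        rows = rows[:k]
    return rows


def enriched_fragments_in_compound(
    profile: PathwayProfile,
    mol: Molecule,
    config: FragmentConfig = FragmentConfig(),
    k: int | None = None,
):
    """Enriched fragments restricted to those a query compound contains,
    each with the atom-index tuples of its occurrences in the query."""
    hits = fragment_atom_hits(mol, set(profile.vocabulary), config)
    rows = [r for r in enriched_fragments(profile) if r[0] in hits]
    if k is not None:
        rows = rows[:k]
    return [(lbl, pv, K, x, hits[lbl]) for lbl, pv, K, x in rows]


# ---------------------------------------------------------------------------
# Tanimoto k-NN baseline


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| for binary vectors; 0 when both are all-zero."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    union = int((a | b).sum())
    return (int((a & b).sum()) / union) if union else 0.0


def _tanimoto_to_rows(x_vec: np.ndarray, values: np.ndarray) -> np.ndarray:
    x = np.asarray(x_vec, dtype=np.float64)
    inter = values @ x
    union = values.sum(axis=1) + x.sum() - inter
    return np.divide(inter, union, out=np.zeros(len(values)), where=union > 0)


def knn_predict(
    x_vec: np.ndarray,
    matrix: FingerprintMatrix,
    pmap: PathwayMap,
    k: int = 3,
    compound_id: str = "",
    pathway_ids: list[str] | None = None,
) -> PredictionResult:
    """Rank pathways by the best Tanimoto similarity among the query's top-k
    neighbours annotated to each pathway.

    The query must not be a row of ``matrix`` (cross-validation contract).
    Pathways not represented in the top-k are appended after all covered
    ones, ordered by their best similarity over the full database, so the
    top-n sweep is defined for every pathway.  ``sc`` holds the similarity;
    z and p are not defined for this baseline (NaN).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pids = pathway_ids if pathway_ids is not None else pmap.pathway_ids
    sims = _tanimoto_to_rows(x_vec, matrix.values)
    # deterministic neighbour order: similarity desc, compound id asc
    order = sorted(range(len(sims)), key=lambda i: (-sims[i], matrix.compound_ids[i]))
    topk = order[: min(k, len(order))]
    row_of = {c: i for i, c in enumerate(matrix.compound_ids)}
    best_topk: dict[str, float] = {}
    for i in topk:
        for p in pmap.pathways_of(matrix.compound_ids[i]):
            if p in pids and sims[i] > best_topk.get(p, -1.0):
                best_topk[p] = float(sims[i])
    best_all: dict[str, float] = {}
    for p in pids:
        members = [row_of[c] for c in pmap.compounds_of(p) if c in row_of] if p in pmap else []
        best_all[p] = float(sims[members].max()) if members else 0.0
    covered = sorted(best_topk, key=lambda p: (-best_topk[p], p))
    uncovered = sorted((p for p in pids if p not in best_topk), key=lambda p: (-best_all[p], p))
    entries = [
        PathwayScore(p, best_topk.get(p, best_all[p]), float("nan"), float("nan"), r + 1)
        for r, p in enumerate(covered + uncovered)
    ]
    return PredictionResult(compound_id, entries)


# ---------------------------------------------------------------------------
# ROC / AUC over the top-n sweep


def _pair_arrays(results, pmap: PathwayMap):
    """(ranks, truths) over all (compound, pathway) pairs; compounds without a
    true pathway among their ranked set are skipped with a warning."""
    ranks, truths = [], []
    skipped = 0
    for r in results:
        if r.unscorable or not r.entries:
            skipped += 1
            continue
        true_set = pmap.pathways_of(r.compound_id)
        if not any(e.pathway_id in true_set for e in r.entries):
            skipped += 1
            continue
        for e in r.entries:
            ranks.append(e.rank)
            truths.append(e.pathway_id in true_set)
    if skipped:
        logger.warning("roc_auc: skipped %d compounds with no evaluable true pathway", skipped)
    return np.array(ranks, dtype=np.int64), np.array(truths, dtype=bool)


def auc_from_ranks(ranks: np.ndarray, truths: np.ndarray) -> float:
    """AUC of the pooled top-n sweep by trapezoidal integration.

    At each cutoff n, pairs with rank <= n are predicted positive; TPR/FPR
    are pooled over all pairs.  Equivalent to a rank-score ROC with ties
    handled by the trapezoid rule.
    """
    if truths.sum() == 0:
        raise ValueError("no true (compound, pathway) pairs to evaluate")
    n_pos = int(truths.sum())
    n_neg = int(len(truths) - n_pos)
    max_rank = int(ranks.max())
    tp = np.bincount(ranks[truths], minlength=max_rank + 1)[1:].cumsum()
    fp = np.bincount(ranks[~truths], minlength=max_rank + 1)[1:].cumsum()
    tpr = np.concatenate([[0.0], tp / n_pos])
    if n_neg == 0:
        return 1.0  # every pathway true for every compound: sweep is degenerate
    fpr = np.concatenate([[0.0], fp / n_neg])
    return float(np.trapezoid(tpr, fpr))


def roc_auc(results, pmap: PathwayMap) -> float:
    """Pooled pair-level AUC of a set of prediction results."""
    ranks, truths = _pair_arrays(results, pmap)
    return auc_from_ranks(ranks, truths)


def per_pathway_auc(results, pmap: PathwayMap) -> dict[str, float]:
    """AUC restricted to one pathway's (compound, pathway) column at a time."""
    out: dict[str, float] = {}
    by_pid: dict[str, list[tuple[int, bool]]] = {}
    for r in results:
        if r.unscorable or not r.entries:
            continue
        true_set = pmap.pathways_of(r.compound_id)
        for e in r.entries:
            by_pid.setdefault(e.pathway_id, []).append((e.rank, e.pathway_id in true_set))
    for pid, pairs in sorted(by_pid.items()):
        ranks = np.array([p[0] for p in pairs])
        truths = np.array([p[1] for p in pairs])
        if truths.any():
            out[pid] = auc_from_ranks(ranks, truths)
    return out


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class EvaluationReport:
    """Aggregate cross-validated performance of one method."""

    method: str
    seed: int
    n_folds: int
    global_auc: float
    per_pathway_auc: dict[str, float]
    per_size_bin_auc: list[dict]
    single_pathway_auc: float | None
    multi_pathway_auc: float | None
    per_group_auc: dict[str, float] = field(default_factory=dict)
    fold_assignment: dict[str, int] = field(default_factory=dict)
    n_unscorable: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "method": self.method,
                    "seed": self.seed,
                    "n_folds": self.n_folds,
                    "global_auc": self.global_auc,
                    "per_pathway_auc": self.per_pathway_auc,
                    "per_size_bin_auc": self.per_size_bin_auc,
                    "single_pathway_auc": self.single_pathway_auc,
                    "multi_pathway_auc": self.multi_pathway_auc,
                    "per_group_auc": self.per_group_auc,
                    "n_unscorable": self.n_unscorable,
                    "fold_assignment": self.fold_assignment,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def assign_folds(compound_ids: list[str], seed: int, n_folds: int = 10) -> dict[str, int]:
    """Seeded uniform partition of compounds into folds (recorded, reusable)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(compound_ids))
    folds: dict[str, int] = {}
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        for i in chunk:
            folds[compound_ids[i]] = f
    return folds


def _subset_auc(results_by_cid, cids, pmap) -> float | None:
    subset = [results_by_cid[c] for c in cids if c in results_by_cid]
    try:
        return roc_auc(subset, pmap) if subset else None
    except ValueError:
        return None


def tenfold_cv(
    matrix: FingerprintMatrix,
    pmap: PathwayMap,
    seed: int = 0,
    method: str = "profile",
    n_folds: int = 10,
    n_random: int = 1000,
    k: int = 3,
    n_size_bins: int = 8,
    groups: dict[str, str] | None = None,
    fold_assignment: dict[str, int] | None = None,
) -> EvaluationReport:
    """Cross-validated evaluation of the profile method or the k-NN baseline.

    The matrix is expected deduplicated (merge_redundant) and the map
    filtered; per fold, profiles and null models (or the neighbour set) are
    rebuilt from the other folds only.  Passing the same seed — or an explicit
    ``fold_assignment`` — to both methods evaluates them on exactly the same
    partition.  Pathways with fewer than 2 training compounds in a fold are
    skipped for that fold with a warning.
    """
    if method not in ("profile", "knn"):
        raise ValueError(f"unknown method {method!r}")
    eval_ids = [c for c in matrix.compound_ids if pmap.pathways_of(c)]
    if not eval_ids:
        raise ValueError("no compound in the matrix has a pathway annotation")
    folds = fold_assignment or assign_folds(list(matrix.compound_ids), seed, n_folds)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_folds)]

    results: list[PredictionResult] = []
    for f in range(n_folds):
        test_idx = [i for i, c in enumerate(matrix.compound_ids) if folds[c] == f]
        train_idx = [i for i, c in enumerate(matrix.compound_ids) if folds[c] != f]
        if not test_idx:
            continue
        train = matrix.subset_rows(train_idx)
        train_ids = set(train.compound_ids)
        pids = []
        for pid in pmap.pathway_ids:
            n_train = len(pmap.compounds_of(pid) & train_ids)
            if n_train >= 2:
                pids.append(pid)
            else:
                logger.warning("fold %d: pathway %s has %d training compounds; skipped", f, pid, n_train)
        if not pids:
            raise ValueError(f"fold {f}: no pathway has enough training compounds")
        test_ids = [matrix.compound_ids[i] for i in test_idx]
        test_values = matrix.values[test_idx]
        if method == "profile":
            profs = [
                build_profile(train, pmap.compounds_of(pid) & train_ids, pid)
                for pid in pids
            ]
            nulls = build_nulls(train, profs, n_random=n_random, seed=fold_seeds[f])
            results.extend(predict_all(test_values, test_ids, profs, nulls))
        else:
            for cid, row in zip(test_ids, test_values):
                if row.sum() == 0:
                    results.append(PredictionResult(cid, [], unscorable=True))
                else:
                    results.append(knn_predict(row, train, pmap, k=k, compound_id=cid, pathway_ids=pids))

    by_cid = {r.compound_id: r for r in results}
    n_unscorable = sum(r.unscorable for r in results)
    global_auc = roc_auc(results, pmap)
    per_pw = per_pathway_auc(results, pmap)

    # equal-frequency bins over compound size (number of fragments present)
    sizes = {c: int(matrix.row(c).sum()) for c in by_cid}
    evaluable = [c for c in by_cid if not by_cid[c].unscorable]
    size_bins: list[dict] = []
    if evaluable:
        vals = np.array([sizes[c] for c in evaluable])
        nb = min(n_size_bins, len(np.unique(vals)))
        edges = np.unique(np.quantile(vals, np.linspace(0, 1, nb + 1)))
        for lo, hi in zip(edges[:-1], edges[1:]):
            cids = [c for c in evaluable if lo <= sizes[c] <= hi]
            auc = _subset_auc(by_cid, cids, pmap)
            size_bins.append({"min_size": float(lo), "max_size": float(hi), "n": len(cids), "auc": auc})

    single = [c for c in evaluable if len(pmap.pathways_of(c)) == 1]
    multi = [c for c in evaluable if len(pmap.pathways_of(c)) > 1]
    per_group: dict[str, float] = {}
    if groups:
        for g in sorted(set(groups.values())):
            gp = {p for p, gg in groups.items() if gg == g}
            sub = []
            for r in results:
                if r.unscorable:
                    continue
                entries = [e for e in r.entries if e.pathway_id in gp]
                if entries:
                    sub.append(PredictionResult(r.compound_id, entries))
            try:
                per_group[g] = roc_auc(sub, pmap)
            except ValueError:
                pass

    return EvaluationReport(
        method=method,
        seed=seed,
        n_folds=n_folds,
        global_auc=global_auc,
        per_pathway_auc=per_pw,
        per_size_bin_auc=size_bins,
        single_pathway_auc=_subset_auc(by_cid, single, pmap),
        multi_pathway_auc=_subset_auc(by_cid, multi, pmap),
        per_group_auc=per_group,
        fold_assignment=folds,
        n_unscorable=n_unscorable,
    )
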