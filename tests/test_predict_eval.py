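import json

import numpy as np
import pytest

import fragpath as fp
from fragpath.predict_eval import (
    PathwayScore,
    PredictionResult,
    assign_folds,
    auc_from_ranks,
    filter_predictions,
)


def make_result(cid, ordered_pids, ps=None):
    ps = ps or [(r + 1) / len(ordered_pids) for r in range(len(ordered_pids))]
    entries = [PathwayScore(p, 0.0, 0.0, ps[r], r + 1) for r, p in enumerate(ordered_pids)]
    return PredictionResult(cid, entries)


class TestPredict:
    def test_planted_member_ranks_its_pathway_first(self, small_planted):
        sp = small_planted
        hits = 0
        for cid in sp["matrix"].compound_ids:
            r = fp.predict(sp["matrix"].row(cid), sp["profiles"], sp["nulls"], cid)
            if r.entries[0].pathway_id in sp["pmap"].pathways_of(cid):
                hits += 1
        assert hits >= 0.9 * len(sp["matrix"].compound_ids)

    def test_identical_profiles_tie_broken_by_pathway_id(self):
        values = np.zeros((12, 3), dtype=np.uint8)
        values[:4, 0] = 1
        values[:, 1] = 1
        values[::3, 2] = 1
        mat = fp.FingerprintMatrix([f"c{i}" for i in range(12)], ["f0", "f1", "f2"], values)
        members = {"c0", "c1", "c2", "c3"}
        pa = fp.build_profile(mat, members, "A")
        pb = fp.build_profile(mat, members, "B")
        nulls = fp.build_nulls(mat, [pa, pb], n_random=50, seed=1)
        r = fp.predict(values[0], [pa, pb], nulls, "c0")
        assert r.entries[0].p == r.entries[1].p
        assert [e.pathway_id for e in r.entries] == ["A", "B"]
        assert [e.rank for e in r.entries] == [1, 2]

    def test_zero_fragment_compound_flagged_unscorable(self, small_planted):
        sp = small_planted
        r = fp.predict(np.zeros(sp["matrix"].shape[1], dtype=np.uint8),
                       sp["profiles"], sp["nulls"], "empty")
        assert r.unscorable and r.entries == []

    def test_p_values_nondecreasing_with_rank(self, small_planted):
        sp = small_planted
        r = fp.predict(sp["matrix"].values[0], sp["profiles"], sp["nulls"], "c")
        ps = [e.p for e in r.entries]
        assert ps == sorted(ps)
        assert [e.rank for e in r.entries] == list(range(1, len(ps) + 1))

    def test_misaligned_models_rejected(self, small_planted):
        sp = small_planted
        with pytest.raises(ValueError):
            fp.predict(sp["matrix"].values[0], sp["profiles"], sp["nulls"][::-1], "c")


class TestTopN:
    def test_nesting_and_bounds(self):
        r = make_result("c", ["A", "B", "C"])
        assert fp.top_n(r, 1) == {"A"}
        assert fp.top_n(r, 1) <= fp.top_n(r, 2) <= fp.top_n(r, 3)
        assert fp.top_n(r, 3) == {"A", "B", "C"}
        with pytest.raises(ValueError):
            fp.top_n(r, 4)

    def test_p_threshold_filter(self):
        r = make_result("c", ["A", "B", "C"], ps=[0.01, 0.2, 0.9])
        kept = filter_predictions([r], n=2, p_max=0.05)
        assert [(cid, e.pathway_id) for cid, e in kept] == [("c", "A")]


class TestEnrichedFragments:
    def test_planted_truth_fragments_have_lowest_pv(self, small_planted):
        sp = small_planted
        for pid in sp["pmap"].pathway_ids:
            prof = next(p for p in sp["profiles"] if p.pathway_id == pid)
            k = len(sp["truth"][pid])
            top = {lbl for lbl, _, _, _ in fp.enriched_fragments(prof, k=k)}
            assert top == set(sp["truth"][pid])

    def test_threshold_one_returns_sorted_vocabulary(self, small_planted):
        prof = small_planted["profiles"][0]
        rows = fp.enriched_fragments(prof, p_threshold=1.0)
        assert len(rows) == len(prof.vocabulary)
        pvs = [r[1] for r in rows]
        assert pvs == sorted(pvs)

    def test_absent_fragment_ranks_last(self):
        values = np.zeros((10, 2), dtype=np.uint8)
        values[5:, 0] = 1
        values[:4, 1] = 1
        mat = fp.FingerprintMatrix([f"c{i}" for i in range(10)], ["absent", "present"], values)
        prof = fp.build_profile(mat, {"c0", "c1", "c2"}, "P")
        rows = fp.enriched_fragments(prof)
        assert rows[-1][0] == "absent" and rows[-1][1] == 1.0

    def test_compound_restricted_report_carries_atom_hits(self, toy_matrix):
        merged, pmap = toy_matrix["merged"], toy_matrix["merged_map"]
        ids = set(merged.compound_ids)
        prof = fp.build_profile(merged, pmap.compounds_of("benzenoid") & ids, "benzenoid")
        mol = fp.parse_smiles("c1ccccc1O", "phenol")
        rows = fp.enriched_fragments_in_compound(prof, mol, k=3)
        assert rows
        for lbl, pv, K, x, hits in rows:
            assert lbl in set(prof.vocabulary) and hits
            for occ in hits:
                assert all(0 <= a < mol.n_atoms for a in occ)


class TestTanimoto:
    def test_examples(self):
        assert fp.tanimoto(np.array([1, 1, 0]), np.array([1, 1, 0])) == 1.0
        assert fp.tanimoto(np.array([1, 0, 0]), np.array([0, 1, 1])) == 0.0
        assert fp.tanimoto(np.array([1, 1, 0]), np.array([0, 1, 1])) == pytest.approx(1 / 3)
        assert fp.tanimoto(np.zeros(3), np.zeros(3)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fp.tanimoto(np.ones(2), np.ones(3))


class TestKnnPredict:
    def test_duplicate_query_with_k1_reproduces_labels(self, small_planted):
        sp = small_planted
        mat, pmap = sp["matrix"], sp["pmap"]
        query_id = mat.compound_ids[0]
        rest = mat.subset_rows(range(1, mat.shape[0]))
        # plant an exact duplicate of the query inside the database
        dup = fp.FingerprintMatrix(
            ["dup"] + rest.compound_ids, mat.vocabulary,
            np.vstack([mat.values[0], rest.values]))
        pm = fp.PathwayMap(dict({p: set(pmap.compounds_of(p)) - {query_id} | (
            {"dup"} if query_id in pmap.compounds_of(p) else set())
            for p in pmap.pathway_ids}))
        r = fp.knn_predict(mat.values[0], dup, pm, k=1, compound_id=query_id)
        assert r.entries[0].pathway_id in pm.pathways_of("dup")
        assert r.entries[0].sc == 1.0

    def test_k_equals_database_uses_best_similarity_per_pathway(self, small_planted):
        sp = small_planted
        mat, pmap = sp["matrix"], sp["pmap"]
        query = mat.values[0]
        db = mat.subset_rows(range(1, mat.shape[0]))
        r = fp.knn_predict(query, db, pmap, k=db.shape[0], compound_id="q")
        best = {}
        for cid in db.compound_ids:
            s = fp.tanimoto(query, db.row(cid))
            for p in pmap.pathways_of(cid):
                best[p] = max(best.get(p, 0.0), s)
        expected = sorted(best, key=lambda p: (-best[p], p))
        assert r.ranking() == expected

    def test_ranks_cover_all_pathways(self, small_planted):
        sp = small_planted
        mat, pmap = sp["matrix"], sp["pmap"]
        r = fp.knn_predict(mat.values[3], mat.subset_rows(range(4, 40)), pmap, k=3)
        assert sorted(r.ranking()) == pmap.pathway_ids
        assert [e.rank for e in r.entries] == list(range(1, len(pmap) + 1))


class TestRocAuc:
    def test_perfect_ranking_gives_one(self):
        pmap = fp.PathwayMap({"A": {"c0"}, "B": {"c1"}, "C": {"c0", "c1"}})
        results = [make_result("c0", ["A", "C", "B"]), make_result("c1", ["B", "C", "A"])]
        assert fp.roc_auc(results, pmap) == 1.0

    def test_reversed_ranking_gives_zero(self):
        pmap = fp.PathwayMap({"A": {"c0"}, "B": {"c1"}})
        results = [make_result("c0", ["B", "A"]), make_result("c1", ["A", "B"])]
        assert fp.roc_auc(results, pmap) == 0.0

    def test_random_ranking_near_half(self):
        rng = np.random.default_rng(0)
        pids = [f"P{i:02d}" for i in range(20)]
        pmap = fp.PathwayMap(
            {p: {f"c{j}" for j in range(300) if rng.random() < 0.08} for p in pids})
        results = [make_result(f"c{j}", list(rng.permutation(pids))) for j in range(300)]
        assert fp.roc_auc(results, pmap) == pytest.approx(0.5, abs=0.03)

    def test_matches_sklearn_rank_roc(self):
        """Independent cross-check: the top-n sweep equals a rank-score ROC."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(5):
            n_pairs = 500
            ranks = rng.integers(1, 21, size=n_pairs)
            truths = rng.random(n_pairs) < 0.2
            if not truths.any() or truths.all():
                continue
            ours = auc_from_ranks(ranks, truths)
            theirs = roc_auc_score(truths, -ranks.astype(float))
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_true_pairs_is_an_error(self):
        pmap = fp.PathwayMap({"A": {"other"}})
        with pytest.raises(ValueError):
            fp.roc_auc([make_result("c0", ["A"])], pmap)


class TestCrossValidation:
    def test_folds_partition_compounds(self):
        ids = [f"c{i}" for i in range(37)]
        folds = assign_folds(ids, seed=3, n_folds=10)
        assert set(folds) == set(ids)
        assert set(folds.values()) == set(range(10))

    def test_same_seed_reproduces_report(self, small_planted):
        sp = small_planted
        a = fp.tenfold_cv(sp["matrix"], sp["pmap"], seed=5, n_random=100)
        b = fp.tenfold_cv(sp["matrix"], sp["pmap"], seed=5, n_random=100)
        assert json.dumps(a.__dict__, default=str, sort_keys=True) == json.dumps(
            b.__dict__, default=str, sort_keys=True)

    def test_methods_share_fold_assignment(self, small_planted):
        sp = small_planted
        a = fp.tenfold_cv(sp["matrix"], sp["pmap"], seed=5, method="profile", n_random=100)
        b = fp.tenfold_cv(sp["matrix"], sp["pmap"], seed=5, method="knn")
        assert a.fold_assignment == b.fold_assignment

    def test_strong_signal_recovers_high_auc(self, small_planted):
        sp = small_planted
        rep = fp.tenfold_cv(sp["matrix"], sp["pmap"], seed=7, n_random=200)
        assert rep.global_auc > 0.9
        # pooled AUC lies within the per-pathway range on this balanced design
        aucs = list(rep.per_pathway_auc.values())
        assert min(aucs) - 1e-9 <= rep.global_auc <= max(aucs) + 1e-9

    def test_profile_beats_label_shuffled_control(self):
        wins = 0
        for s in range(10):
            d = fp.PlantedDesign(n_pathways=6, compounds_per_pathway=12, vocab_size=120,
                                 p_in=0.7, p_bg=0.08, frac_multi=0.0, seed=s)
            mat, pmap, _ = fp.generate_planted_matrix(d)
            rng = np.random.default_rng(1000 + s)
            remap = dict(zip(mat.compound_ids, list(rng.permutation(mat.compound_ids))))
            shuffled = fp.PathwayMap(
                {p: {remap[c] for c in pmap.compounds_of(p)} for p in pmap.pathway_ids})
            true_auc = fp.tenfold_cv(mat, pmap, seed=s, n_random=100).global_auc
            null_auc = fp.tenfold_cv(mat, shuffled, seed=s, n_random=100).global_auc
            wins += true_auc > null_auc
        assert wins >= 9

    def test_multi_pathway_compounds_score_worse_than_single(self):
        """Mixed fragment signals dilute multi-pathway compounds' rankings."""
        d = fp.PlantedDesign(n_pathways=10, compounds_per_pathway=20, vocab_size=200,
                             p_in=0.6, p_bg=0.05, frac_multi=0.3, seed=3)
        mat, pmap, _ = fp.generate_planted_matrix(d)
        rep = fp.tenfold_cv(mat, pmap, seed=3, n_random=200)
        assert rep.multi_pathway_auc < rep.single_pathway_auc

    def test_shared_backbone_compound_ranks_both_families_high(self, toy_matrix):
        """A compound bridging two families puts both near the top of its ranking."""
        merged, pmap = toy_matrix["merged"], toy_matrix["merged_map"]
        ids = set(merged.compound_ids)
        profs = [fp.build_profile(merged, pmap.compounds_of(p) & ids, p)
                 for p in pmap.pathway_ids]
        nulls = fp.build_nulls(merged, profs, n_random=300, seed=1)
        r = fp.predict(merged.row("shared_benzoate"), profs, nulls, "shared_benzoate")
        assert set(r.ranking()[:2]) == {"benzenoid", "alcohol_acid"}
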