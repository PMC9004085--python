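import numpy as np
import pytest

from hgdti import aupr, auroc, run_experiment, stratified_kfold
from hgdti.evaluation import filter_jaccard, filter_similar_dtis, unique_split


def auroc_reference(scores, labels):
    """O(n^2) pair counting: wins + half-ties over positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_reference(scores, labels):
    """Stepwise precision-recall integration at each distinct threshold."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    s = np.asarray(scores)[order]
    y = np.asarray(labels)[order]
    P = y.sum()
    area, prev_recall, tp, n_seen = 0.0, 0.0, 0, 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:  # consume a tie block at once
            j += 1
        tp += y[i:j].sum()
        n_seen = j
        recall = tp / P
        precision = tp / n_seen
        area += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    return area


class TestMetrics:
    def test_perfect_and_inverted_scorers(self):
        y = [0, 0, 1, 1]
        assert auroc([0.1, 0.2, 0.8, 0.9], y) == 1.0
        assert aupr([0.1, 0.2, 0.8, 0.9], y) == 1.0
        assert auroc([0.9, 0.8, 0.2, 0.1], y) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_agreement_with_quadratic_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # force ties
        assert np.isclose(auroc(scores, y), auroc_reference(scores, y), atol=1e-12)
        assert np.isclose(aupr(scores, y), aupr_reference(scores, y), atol=1e-12)

    def test_random_scorer_calibration(self):
        rng = np.random.default_rng(0)
        n, ratio = 2200, 10
        y = np.r_[np.ones(n // (ratio + 1)), np.zeros(n - n // (ratio + 1))]
        rocs = [auroc(rng.random(n), y) for _ in range(10)]
        prs = [aupr(rng.random(n), y) for _ in range(10)]
        assert abs(np.mean(rocs) - 0.5) < 0.05
        assert abs(np.mean(prs) - 1 / 11) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError, match="single class"):
            aupr([0.1, 0.2], [0, 0])


class TestStratifiedKFold:
    def test_fold_class_counts(self):
        y = np.r_[np.ones(20, int), np.zeros(200, int)]
        split = stratified_kfold(y, k=10, seed=0)
        for fold in split.folds:
            assert y[fold].sum() == 2 and len(fold) == 22

    def test_union_and_disjointness(self):
        y = np.r_[np.ones(20, int), np.zeros(200, int)]
        split = stratified_kfold(y, k=10, seed=1)
        flat = np.concatenate(split.folds)
        assert len(flat) == 220 and len(set(flat)) == 220

    def test_seed_changes_assignment_not_counts(self):
        y = np.r_[np.ones(20, int), np.zeros(200, int)]
        a = stratified_kfold(y, k=10, seed=1)
        b = stratified_kfold(y, k=10, seed=2)
        assert any(not np.array_equal(x, z) for x, z in zip(a.folds, b.folds))
        assert all(y[x].sum() == y[z].sum() for x, z in zip(a.folds, b.folds))

    def test_too_few_members_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            stratified_kfold(np.r_[np.ones(5, int), np.zeros(50, int)], k=10)


def greedy_reference(positives, should_remove):
    kept = []
    for p in sorted(positives):
        if any(should_remove(p, q) for q in kept):
            continue
        kept.append(p)
    return kept


class TestSimilarityFilter:
    def test_no_similarity_no_removal(self):
        pos = [(0, 0), (1, 1), (2, 0)]
        kept, removed = filter_similar_dtis(pos, np.zeros((3, 3)), np.zeros((2, 2)))
        assert kept == sorted(pos) and removed == {}

    def test_shared_drug_removed_via_unit_self_similarity(self):
        drug_sim = np.eye(2)
        prot_sim = np.zeros((2, 2))
        kept, removed = filter_similar_dtis([(0, 0), (0, 1)], drug_sim, prot_sim)
        assert kept == [(0, 0)]
        assert removed == {(0, 1): (0, 0)}

    def test_matches_greedy_reference_scan(self):
        rng = np.random.default_rng(3)
        n_d, n_t = 6, 7
        ds = rng.random((n_d, n_d))
        ds = (ds + ds.T) / 2
        ps = rng.random((n_t, n_t))
        ps = (ps + ps.T) / 2
        pos = [(int(rng.integers(n_d)), int(rng.integers(n_t))) for _ in range(12)]
        pos = sorted(set(pos))
        kept, _ = filter_similar_dtis(pos, ds, ps, t_drug=0.6, t_prot=0.4)
        ref = greedy_reference(
            pos, lambda p, q: ds[p[0], q[0]] > 0.6 or ps[p[1], q[1]] > 0.4)
        assert kept == ref

    def test_idempotent_and_shrinking(self):
        rng = np.random.default_rng(5)
        ds = rng.random((5, 5))
        ds = (ds + ds.T) / 2
        ps = np.zeros((5, 5))
        pos = [(i, j) for i in range(5) for j in range(3)]
        kept, _ = filter_similar_dtis(pos, ds, ps)
        again, removed = filter_similar_dtis(kept, ds, ps)
        assert again == kept and removed == {}
        assert set(kept) <= set(pos)


class TestJaccardFilter:
    def test_identical_profiles_trigger_removal(self):
        M = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]], dtype=float)
        kept, removed = filter_jaccard([(0, 0), (1, 1), (2, 0)], drug_assoc=M)
        assert (1, 1) in removed and kept == [(0, 0), (2, 0)]

    def test_disjoint_profiles_retained(self):
        M = np.array([[1, 0], [0, 1]], dtype=float)
        kept, _ = filter_jaccard([(0, 0), (1, 1)], drug_assoc=M)
        assert kept == [(0, 0), (1, 1)]

    def test_jaccard_values_match_set_oracle(self):
        rng = np.random.default_rng(1)
        M = (rng.random((6, 8)) < 0.4).astype(float)
        from hgdti.evaluation import _jaccard_rows

        J = _jaccard_rows(M)
        for a in range(6):
            for b in range(6):
                sa = {k for k in range(8) if M[a, k]}
                sb = {k for k in range(8) if M[b, k]}
                ref = len(sa & sb) / len(sa | sb) if sa | sb else 0.0
                assert np.isclose(J[a, b], ref, atol=1e-12)

    def test_disease_mode_checks_protein_profiles_too(self):
        drug = np.zeros((2, 3))
        prot = np.array([[1, 1, 0], [1, 1, 0]], dtype=float)
        kept, removed = filter_jaccard([(0, 0), (1, 1)], drug_assoc=drug,
                                       prot_assoc=prot)
        assert kept == [(0, 0)] and (1, 1) in removed

    def test_non_binary_matrix_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            filter_jaccard([(0, 0)], drug_assoc=np.array([[0.5]]))


class TestUniqueSplit:
    def test_star_graph_is_non_unique(self):
        non_unique, unique = unique_split([(0, 0), (0, 1), (0, 2)])
        assert unique == [] and len(non_unique) == 3

    def test_perfect_matching_is_unique(self):
        pairs = [(i, i) for i in range(4)]
        non_unique, unique = unique_split(pairs)
        assert non_unique == [] and unique == pairs

    def test_partition_matches_degree_oracle(self):
        rng = np.random.default_rng(2)
        pairs = sorted({(int(rng.integers(6)), int(rng.integers(6))) for _ in range(12)})
        non_unique, unique = unique_split(pairs)
        assert sorted(non_unique + unique) == pairs
        from collections import Counter

        dd = Counter(d for d, _ in pairs)
        td = Counter(t for _, t in pairs)
        for d, t in unique:
            assert dd[d] == 1 and td[t] == 1
        for d, t in non_unique:
            assert dd[d] > 1 or td[t] > 1


FAST = dict(dim=16, max_epochs=3, batch_size=None)


class TestRunExperiment:
    def test_cv_report_shape(self, tiny_graph):
        rep = run_experiment(tiny_graph, "cv", n_trials=2, k=3, ratio=2,
                             base_seed=1, model_params=FAST)
        assert len(rep.records) == 2 * 3
        assert set(rep.records.columns) == {"trial", "fold", "auroc", "aupr"}
        assert ((rep.records[["auroc", "aupr"]] >= 0).all().all()
                and (rep.records[["auroc", "aupr"]] <= 1).all().all())
        assert rep.auroc_sd >= 0 and len(rep.trial_seeds) == 2

    def test_ablation_differs_from_baseline(self, tiny_graph):
        base = run_experiment(tiny_graph, "cv", n_trials=1, k=2, ratio=2,
                              base_seed=2, model_params=FAST)
        abl = run_experiment(tiny_graph, "ablation", drop={"disease"},
                             n_trials=1, k=2, ratio=2, base_seed=2,
                             model_params=FAST)
        assert abl.auroc_mean != base.auroc_mean

    def test_unique_scenario_trains_on_non_unique_only(self, tiny_graph):
        pos = tiny_graph.positive_pairs()
        non_unique, unique = unique_split(pos)
        if not unique:
            pytest.skip("fixture has no unique positives at this seed")
        rep = run_experiment(tiny_graph, "unique", n_trials=1, ratio=2,
                             base_seed=3, model_params=FAST)
        assert len(rep.records) == 1

    def test_filtered_scenario_runs(self, tiny_graph):
        rep = run_experiment(tiny_graph, "filtered-similarity", n_trials=1, k=2,
                             ratio=2, base_seed=4, model_params=FAST)
        assert len(rep.records) == 2
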