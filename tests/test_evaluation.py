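"""AUPR, ranking, hold-out CV, LOOCV degree bias, and the NS/LP baselines."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcmds.evaluation import (
    HoldoutPlan,
    ablation_run,
    aupr,
    average_rank_of_positives,
    holdout_cv,
    holdout_cv_many,
    loocv_degree_bias,
    lp_baseline_scores,
    ns_baseline_scores,
)
from lcmds.io import DrugCatalog, InteractionMatrix, SimilarityMatrix

from conftest import two_block_network


def aupr_oracle(scores, labels):
    """Brute-force step-wise average precision with tie groups."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        group = scores == thr
        tp += labels[group].sum()
        fp += (group.sum() - labels[group].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAUPR:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], 1.0),
            ([0.9, 0.8, 0.3, 0.2], [0, 1, 0, 1], 0.5),
            ([0.9, 0.8, 0.3, 0.2], [0, 0, 1, 1], 5 / 12),
        ],
    )
    def test_hand_values(self, scores, labels, expected):
        assert aupr(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            aupr([0.4, 0.6], [1, 1])

    def test_matches_enumeration_oracle_exhaustively(self):
        """All label configurations on small tie-rich score vectors."""
        score_sets = [
            np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4]),
            np.array([0.5, 0.5, 0.4, 0.4, 0.3, 0.2]),
            np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.1]),
        ]
        for scores in score_sets:
            n = len(scores)
            for labels in itertools.product([0, 1], repeat=n):
                y = np.array(labels)
                if y.min() == y.max():
                    continue
                assert aupr(scores, y) == pytest.approx(
                    aupr_oracle(scores, y), abs=1e-12), (scores, labels)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert aupr(scores, labels) == pytest.approx(
            aupr_oracle(scores, labels), abs=1e-12)


class TestAverageRank:
    def test_hand_value(self):
        assert average_rank_of_positives([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0]) == 1.5

    def test_all_positive_forces_mid_rank(self):
        assert average_rank_of_positives([0.5, 0.9, 0.2], [1, 1, 1]) == pytest.approx(2.0)

    def test_all_tied_scores_mid_rank(self):
        assert average_rank_of_positives([0.4] * 5, [0, 0, 1, 0, 0]) == pytest.approx(3.0)

    def test_perfect_predictor_rank(self):
        labels = np.array([1, 1, 1, 0, 0, 0, 0])
        scores = labels.astype(float)
        assert average_rank_of_positives(scores, labels) == pytest.approx(2.0)


class TestBaselines:
    def test_ns_is_similarity_sum_over_partners(self):
        A, S, cluster = two_block_network(4)
        q = np.linspace(0.1, 0.9, 8)
        scores = ns_baseline_scores(A, q)
        expected = np.array([q[A.values[:, j] == 1].sum() for j in range(8)])
        np.testing.assert_allclose(scores, expected)

    def test_ns_zero_query_gives_zero(self):
        A, _, _ = two_block_network(4)
        np.testing.assert_allclose(ns_baseline_scores(A, np.zeros(8)), 0.0)

    def test_ns_degree_doubling_doubles_score(self):
        """Duplicating an interacting partner (at equal similarity)
        doubles the NS score -- the degree bias made explicit."""
        cat3 = DrugCatalog.from_ids(["t", "p", "x"])
        A3 = InteractionMatrix(cat3, np.array(
            [[0, 1, 0], [1, 0, 0], [0, 0, 0]])).values  # t has 1 partner
        cat4 = DrugCatalog.from_ids(["t", "p", "p2", "x"])
        A4 = np.zeros((4, 4), dtype=int)
        A4[0, 1] = A4[1, 0] = A4[0, 2] = A4[2, 0] = 1  # t has 2 partners
        s1 = ns_baseline_scores(InteractionMatrix(cat3, A3), np.array([0.0, 0.6, 0.2]))
        s2 = ns_baseline_scores(InteractionMatrix(cat4, A4),
                                np.array([0.0, 0.6, 0.6, 0.2]))
        assert s2[0] == pytest.approx(2 * s1[0])

    def test_lp_small_beta_approaches_one_step_scores(self):
        A, S, _ = two_block_network(4)
        rng = np.random.default_rng(0)
        q = rng.uniform(0.1, 0.9, 8)
        lp = lp_baseline_scores(A, S, q, beta=1e-6)
        # one diffusion step from the query row of the normalized graph
        W_row = np.concatenate([q, [1.0]])
        W_row = W_row / W_row.sum()
        one_step = W_row[:8] @ A.values
        np.testing.assert_allclose(lp / np.max(lp), one_step / np.max(one_step),
                                   atol=1e-4)

    def test_lp_two_node_closed_form(self):
        """Symmetric two-drug network: geometric-series value by hand."""
        cat = DrugCatalog.from_ids(["a", "b"])
        A = InteractionMatrix(cat, np.array([[0, 1], [1, 0]]))
        S = SimilarityMatrix(cat, np.array([[1.0, 0.5], [0.5, 1.0]]))
        beta = 0.4
        q = np.array([0.5, 0.5])
        W = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])
        W = W / W.sum(axis=1, keepdims=True)
        Y = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
        F = np.linalg.solve(np.eye(3) - beta * W, (1 - beta) * Y)
        np.testing.assert_allclose(lp_baseline_scores(A, S, q, beta), F[2])

    def test_lp_nonnegative_finite(self):
        A, S, _ = two_block_network(4)
        for beta in (0.1, 0.5, 0.9):
            lp = lp_baseline_scores(A, S, np.full(8, 0.3), beta)
            assert np.all(np.isfinite(lp))
            assert np.all(lp >= 0)


class TestHoldoutCV:
    def test_identical_seeds_identical_auprs(self, tiny_dataset):
        ds = tiny_dataset
        plan = HoldoutPlan(ratio=0.25, repetitions=2, seeds=(5, 5))
        rep = holdout_cv(ds.interactions, ds.similarity, plan, "rls")
        assert rep.auprs[0] == rep.auprs[1]

    def test_full_report_reproducible(self, tiny_dataset):
        ds = tiny_dataset
        plan = HoldoutPlan(ratio=0.25, repetitions=3)
        r1 = holdout_cv(ds.interactions, ds.similarity, plan, "ds")
        r2 = holdout_cv(ds.interactions, ds.similarity, plan, "ds")
        assert r1.auprs == r2.auprs

    def test_no_test_drug_information_in_training(self, tiny_dataset, monkeypatch):
        """Leakage check: the training matrices passed to the engine
        never contain a row/column of any withheld drug."""
        import lcmds.evaluation as ev

        ds = tiny_dataset
        seen = []
        orig = ev.lcm_predict_all

        def spy(A_tr, S_tr, queries, methods, config):
            seen.append(tuple(A_tr.drugs.ids))
            return orig(A_tr, S_tr, queries, methods, config)

        monkeypatch.setattr(ev, "lcm_predict_all", spy)
        plan = HoldoutPlan(ratio=0.25, repetitions=2)
        holdout_cv(ds.interactions, ds.similarity, plan, "rls")
        all_ids = set(ds.interactions.drugs.ids)
        for train_ids in seen:
            withheld = all_ids - set(train_ids)
            assert len(withheld) == max(1, round(0.25 * 16))
            assert not withheld & set(train_ids)

    def test_perfect_and_random_predictors(self, tiny_dataset):
        """A predictor that outputs the withheld truth has AUPR 1; a
        random one sits near the pair prevalence."""
        ds = tiny_dataset
        m = len(ds.interactions.drugs)
        rng = np.random.default_rng(0)
        aupr_perfect = []
        aupr_random = []
        prevalence = []
        from lcmds.evaluation import _split

        for seed in range(30):
            train, test = _split(m, 0.25, seed)
            truth = ds.interactions.values[np.ix_(test, train)].ravel()
            if truth.min() == truth.max():
                continue
            aupr_perfect.append(aupr(truth.astype(float), truth))
            aupr_random.append(aupr(rng.random(truth.size), truth))
            prevalence.append(truth.mean())
        assert np.allclose(aupr_perfect, 1.0)
        se = np.std(aupr_random) / np.sqrt(len(aupr_random))
        assert abs(np.mean(aupr_random) - np.mean(prevalence)) < 3 * se + 0.05

    def test_shared_pass_matches_individual_runs(self, tiny_dataset):
        ds = tiny_dataset
        plan = HoldoutPlan(ratio=0.25, repetitions=2)
        many = holdout_cv_many(ds.interactions, ds.similarity, plan,
                               ["mlknn", "ns"])
        single = holdout_cv(ds.interactions, ds.similarity, plan, "mlknn")
        assert many["mlknn"].auprs == single.auprs


class TestAblationRun:
    def test_regular_variant_equals_plain_ds(self, tiny_dataset):
        ds = tiny_dataset
        plan = HoldoutPlan(ratio=0.25, repetitions=2)
        reg = ablation_run(ds.interactions, ds.similarity, plan, "regular")
        plain = holdout_cv(ds.interactions, ds.similarity, plan, "ds")
        assert reg.auprs == plain.auprs

    def test_unknown_variant_rejected(self, tiny_dataset):
        ds = tiny_dataset
        with pytest.raises(ValueError, match="variant"):
            ablation_run(ds.interactions, ds.similarity,
                         HoldoutPlan(repetitions=1), "no_kernel")


class TestLOOCVDegreeBias:
    def test_scores_proportional_to_degree_give_correlation_one(self):
        """NS on a flat-similarity network scores each target by its
        degree exactly, so the per-round correlation is 1."""
        rng = np.random.default_rng(3)
        m = 12
        upper = np.triu(rng.integers(0, 2, (m, m)), k=1)
        A = upper + upper.T
        for i in range(m):  # ensure degree >= 1 and some spread
            if A[i].sum() == 0:
                A[i, (i + 1) % m] = A[(i + 1) % m, i] = 1
        cat = DrugCatalog.from_ids(f"d{i}" for i in range(m))
        Am = InteractionMatrix(cat, A)
        S = SimilarityMatrix(cat, np.full((m, m), 1.0))
        summary = loocv_degree_bias(Am, S, "ns")
        finite = [v for v in summary.spearman_by_round if np.isfinite(v)]
        assert np.allclose(finite, 1.0)

    def test_random_scores_uncorrelated(self, monkeypatch, tiny_dataset):
        import lcmds.evaluation as ev

        ds = tiny_dataset
        rng = np.random.default_rng(12)

        def random_predictor(A_tr, S_tr, queries, methods, config, beta=None):
            q = np.atleast_2d(queries)
            return {m: rng.random((q.shape[0], len(A_tr.drugs))) for m in methods}

        monkeypatch.setattr(ev, "_predict_methods",
                            lambda *a, **k: random_predictor(*a, **k))
        summary = ev.loocv_degree_bias(ds.interactions, ds.similarity, "rls")
        assert abs(summary.spearman_mean) < 0.25

    def test_average_ranks_recorded_per_drug(self, tiny_dataset):
        ds = tiny_dataset
        summary = loocv_degree_bias(ds.interactions, ds.similarity, "ns")
        assert len(summary.average_ranks) == 16
        assert all(r >= 1 for r in summary.average_ranks)
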