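import numpy as np
import pytest

from hetmda.model import (
    AttentionState,
    DecoderState,
    Embedding,
    ModelConfig,
    attention_coefficients,
    cross_entropy_loss,
    decode,
    gcn_layer,
    neighborhoods_from_adjacency,
    predict,
    reinforce,
    reinforcement_loss,
    train,
)
from hetmda.synthetic import SyntheticSpec, generate


def full_mask(k):
    m = np.ones((k, k), dtype=bool)
    np.fill_diagonal(m, False)
    return m


class TestGcnLayer:
    def test_identity_propagation_is_inert_on_nonnegative_features(self, rng):
        x = rng.random((4, 4))
        got = gcn_layer(x, np.eye(4), np.eye(4)).values
        np.testing.assert_allclose(got, x)

    def test_zero_weights_give_zero_embedding(self, rng):
        got = gcn_layer(rng.random((4, 4)), rng.random((4, 4)), np.zeros((4, 2))).values
        assert np.all(got == 0)

    def test_matches_straight_line_product_oracle(self, rng):
        a, x, w = rng.standard_normal((3, 3)), rng.standard_normal((3, 3)), rng.standard_normal((3, 2))
        got = gcn_layer(x, a, w).values
        expect = np.maximum(a @ x @ w, 0.0)  # independent straight-line evaluation
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="non-conformable"):
            gcn_layer(rng.random((3, 3)), rng.random((4, 4)), rng.random((3, 2)))


class TestAttention:
    def test_singleton_neighborhood_gets_full_weight(self, rng):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 1] = True
        att = attention_coefficients(rng.random((3, 2)), AttentionState(np.eye(2), mask))
        assert att.coefficients[0, 1] == pytest.approx(1.0)

    def test_equal_scores_split_evenly(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, [1, 2]] = True
        emb = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])  # equal scores for both neighbors
        att = attention_coefficients(emb, AttentionState(np.eye(2), mask))
        np.testing.assert_allclose(att.coefficients[0, 1:], [0.5, 0.5])

    def test_log_two_score_gap_gives_two_to_one_odds(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, [1, 2]] = True
        emb = np.array([[1.0, 0.0], [np.log(2.0), 1.0], [0.0, 1.0]])
        att = attention_coefficients(emb, AttentionState(np.eye(2), mask))
        np.testing.assert_allclose(att.coefficients[0, 1:], [2 / 3, 1 / 3], atol=1e-12)

    def test_rows_with_neighbors_sum_to_one(self, rng):
        mask = rng.random((6, 6)) < 0.5
        np.fill_diagonal(mask, False)
        att = attention_coefficients(rng.random((6, 3)), AttentionState(rng.random((3, 3)), mask))
        has = mask.any(axis=1)
        np.testing.assert_allclose(att.coefficients[has].sum(axis=1), 1.0, atol=1e-9)
        assert att.coefficients.min() >= 0

    def test_empty_neighborhood_falls_back_to_pass_through(self, rng):
        mask = np.zeros((2, 2), dtype=bool)
        emb = rng.random((2, 3))
        att = attention_coefficients(emb, AttentionState(rng.random((3, 3)), mask))
        h = reinforce(emb, att).values
        np.testing.assert_array_equal(h, emb)


class TestReinforce:
    def test_single_neighbor_copies_its_embedding(self, rng):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 1] = True
        emb = rng.random((2, 3))
        att = attention_coefficients(emb, AttentionState(np.eye(3), mask))
        h = reinforce(emb, att).values
        np.testing.assert_allclose(h[0], emb[1])

    def test_even_weights_give_midpoint(self):
        att = AttentionState(np.eye(1), full_mask(3))
        att.agg = np.array([[0.0, 0.5, 0.5], [0, 1, 0], [0, 0, 1]])
        att.coefficients = att.agg
        h = reinforce(np.array([[5.0], [0.0], [2.0]]), att).values
        assert h[0, 0] == pytest.approx(1.0)

    def test_aggregate_stays_in_neighbor_convex_hull(self, rng):
        emb = rng.standard_normal((6, 4))
        mask = rng.random((6, 6)) < 0.6
        np.fill_diagonal(mask, False)
        att = attention_coefficients(emb, AttentionState(rng.standard_normal((4, 4)), mask))
        h = reinforce(emb, att).values
        for i in range(6):
            nb = np.flatnonzero(mask[i])
            if nb.size:  # per-coordinate bounds of the hull
                assert np.all(h[i] >= emb[nb].min(axis=0) - 1e-12)
                assert np.all(h[i] <= emb[nb].max(axis=0) + 1e-12)


class TestReinforcementLoss:
    def test_identical_embeddings_cost_nothing(self):
        att = attention_coefficients(np.ones((3, 2)), AttentionState(np.eye(2), full_mask(3)))
        assert reinforcement_loss(np.ones((3, 2)), att) == pytest.approx(0.0)

    def test_two_node_direct_evaluation(self):
        att = AttentionState(np.eye(1), full_mask(2))
        att.coefficients = np.array([[0.0, 1.0], [1.0, 0.0]])
        att.agg = att.coefficients
        # scalar embeddings 0 and 2, full attention both directions: 4 + 4
        assert reinforcement_loss(np.array([[0.0], [2.0]]), att) == pytest.approx(8.0)

    def test_quadratic_scaling(self, rng):
        emb = rng.standard_normal((5, 3))
        att = attention_coefficients(emb, AttentionState(np.eye(3), full_mask(5)))
        base = reinforcement_loss(emb, att)
        scaled = reinforcement_loss(3.0 * emb, att)
        assert scaled == pytest.approx(9.0 * base, rel=1e-6)


class TestDecode:
    def test_zero_decoder_gives_maximal_uncertainty(self, rng):
        y = decode(rng.random((5, 3)), DecoderState(np.zeros((3, 3))), m=3)
        np.testing.assert_allclose(y, 0.5)

    def test_scalar_closed_form(self):
        y = decode(np.array([[1.0], [1.0]]), DecoderState(np.array([[1.0]])), m=1)
        assert y[0, 0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)

    def test_matches_elementwise_bilinear_oracle(self, rng):
        h = rng.standard_normal((5, 4))
        w = rng.standard_normal((4, 4))
        y = decode(h, DecoderState(w), m=3)
        hr, hd = h[:3], h[3:]
        for i in range(3):
            for j in range(2):
                logit = sum(hr[i, p] * w[p, q] * hd[j, q] for p in range(4) for q in range(4))
                assert y[i, j] == pytest.approx(1 / (1 + np.exp(-logit)), abs=1e-12)

    def test_monotone_in_logit(self, rng):
        h = rng.standard_normal((4, 3))
        w = rng.standard_normal((3, 3))
        y0 = decode(h, DecoderState(w), m=2)
        # raise exactly the (0, 0) logit: add a positive multiple of its rank-1 direction
        w2 = w + 1e-3 * np.outer(h[0], h[2])
        y1 = decode(h, DecoderState(w2), m=2)
        assert y1[0, 0] > y0[0, 0]


class TestCrossEntropy:
    def test_uniform_uncertainty(self):
        scores = np.full((2, 2), 0.5)
        truth = np.array([[1, 0], [0, 1]])
        assert cross_entropy_loss(scores, truth) == pytest.approx(4 * np.log(2), abs=1e-9)

    def test_perfect_fit_is_free(self):
        truth = np.array([[1, 0]])
        assert cross_entropy_loss(truth.astype(float), truth) == pytest.approx(0.0, abs=1e-9)

    def test_direct_evaluation(self):
        scores = np.array([[0.9, 0.2]])
        truth = np.array([[1, 0]])
        assert cross_entropy_loss(scores, truth) == pytest.approx(
            -(np.log(0.9) + np.log(0.8)), abs=1e-9
        )

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cross_entropy_loss(np.array([[0.5]]), np.array([[1]]), np.zeros((1, 1), bool))


class TestTrain:
    def test_zero_lambda_reduces_total_to_cross_entropy(self, tiny_dataset):
        cfg = ModelConfig(h=4, epochs=5, seed=0, lambda_reinforce=0.0)
        st = train(tiny_dataset.sm, tiny_dataset.sd, tiny_dataset.assoc, cfg)
        np.testing.assert_array_equal(st.loss_report.total, st.loss_report.cross_entropy)

    def test_loss_decreases_on_planted_data(self):
        ds = generate(SyntheticSpec(m=30, n=20, seed=4))
        cfg = ModelConfig(h=16, epochs=100, seed=4)
        st = train(ds.sm, ds.sd, ds.assoc, cfg)
        assert st.loss_report.total[-1] < st.loss_report.total[0]

    def test_identical_seeds_reproduce_identical_histories(self, tiny_dataset):
        cfg = ModelConfig(h=4, epochs=10, seed=7)
        a = train(tiny_dataset.sm, tiny_dataset.sd, tiny_dataset.assoc, cfg)
        b = train(tiny_dataset.sm, tiny_dataset.sd, tiny_dataset.assoc, cfg)
        assert a.loss_report.total == b.loss_report.total
        np.testing.assert_array_equal(a.w0, b.w0)

    def test_divergence_reports_epoch(self, tiny_dataset):
        cfg = ModelConfig(h=4, epochs=200, seed=0, learning_rate=1e100)
        with pytest.raises(FloatingPointError, match="epoch"), np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                train(tiny_dataset.sm, tiny_dataset.sd, tiny_dataset.assoc, cfg)

    def test_large_reinforcement_weight_contracts_within_group_embeddings(self):
        ds = generate(SyntheticSpec(m=20, n=14, seed=5))
        emb = {}
        for lam in (0.0, 1000.0):
            cfg = ModelConfig(h=8, epochs=100, seed=5, lambda_reinforce=lam)
            emb[lam] = train(ds.sm, ds.sd, ds.assoc, cfg).embedding
        def within_group_var(h):
            groups = np.concatenate([ds.mirna_groups, 2 + ds.disease_groups])
            return np.mean([h[groups == g].var(axis=0).mean() for g in np.unique(groups)])
        assert within_group_var(emb[1000.0]) < within_group_var(emb[0.0])

    def test_negative_sampling_trains_on_subset(self, tiny_dataset):
        cfg = ModelConfig(h=4, epochs=5, seed=0, neg_ratio=1)
        st = train(tiny_dataset.sm, tiny_dataset.sd, tiny_dataset.assoc, cfg)
        assert np.isfinite(st.loss_report.total).all()


class TestPredict:
    @pytest.fixture
    def model(self, tiny_dataset):
        cfg = ModelConfig(h=4, epochs=5, seed=1)
        return train(tiny_dataset.sm, tiny_dataset.sd, tiny_dataset.assoc, cfg)

    def test_pair_scores_are_matrix_entries(self, model):
        (r, d, s), = predict(model, [("mir-001", "dis-002")])
        assert s == model.scores[1, 2]

    def test_empty_request_gives_empty_result(self, model):
        assert predict(model, []) == []

    def test_all_pairs_flatten_the_score_matrix(self, model):
        rows = predict(model)
        got = np.array([s for _, _, s in rows]).reshape(model.scores.shape)
        np.testing.assert_array_equal(got, model.scores)

    def test_unknown_name_raises_lookup_error(self, model):
        with pytest.raises(KeyError, match="unknown miRNA"):
            predict(model, [("nope", "dis-000")])


class TestNeighborhoods:
    def test_nonzero_rule_excludes_diagonal(self):
        a = np.array([[1.0, 0.2], [0.2, 1.0]])
        mask = neighborhoods_from_adjacency(a)
        assert not mask[0, 0] and mask[0, 1]

    def test_top_k_keeps_strongest(self):
        a = np.array([[0, 0.9, 0.1, 0.5], [0.9, 0, 0, 0], [0.1, 0, 0, 0], [0.5, 0, 0, 0]])
        mask = neighborhoods_from_adjacency(a, rule="top_k", top_k=2)
        assert mask[0].tolist() == [False, True, False, True]
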