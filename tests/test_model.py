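"""Model mathematics: single-case reference ops against hand oracles, and
the batched multi-layer forward against a straight-line per-node
implementation of the same mathematics."""

import numpy as np
import pytest

from metapathlink.config import ModelConfig
from metapathlink.metapath import parse_catalog, sample_instances
from metapathlink.model import (MetapathAttentionModel, bce_loss,
                                encode_instance_mean, encode_instance_rotate,
                                init_params, inter_aggregate, intra_aggregate,
                                metapath_summary, predict_score, score_matrix)
from metapathlink.synthetic import SyntheticSpec, fixture_small, generate_synthetic

RNG = np.random.default_rng(99)


# ---------------------------------------------------------------------
# instance encoders


class TestRotateEncoder:
    def test_single_node_unchanged(self):
        v = RNG.normal(size=8)
        np.testing.assert_allclose(encode_instance_rotate([v], []), v)

    def test_identity_relations_equal_mean(self):
        for _ in range(20):
            n = RNG.integers(1, 5)
            vecs = [RNG.normal(size=6) for _ in range(n)]
            rels = [np.ones(3, dtype=complex) for _ in range(n - 1)]
            np.testing.assert_allclose(
                encode_instance_rotate(vecs, rels),
                encode_instance_mean(vecs), atol=1e-12)

    def test_three_node_complex_oracle(self):
        # hand evaluation in complex arithmetic: o3 = h3 + (h2 + h1 r1) r2
        h1, h2, h3 = (np.array([1.0, 2.0]), np.array([0.5, -1.0]),
                      np.array([-2.0, 0.25]))
        r1 = np.array([np.exp(1j * 0.3)])
        r2 = np.array([np.exp(-1j * 1.1)])
        z1, z2, z3 = 1 + 2j, 0.5 - 1j, -2 + 0.25j
        expected = (z3 + (z2 + z1 * r1[0]) * r2[0]) / 3
        got = encode_instance_rotate([h1, h2, h3], [r1, r2])
        np.testing.assert_allclose(got, [expected.real, expected.imag],
                                   atol=1e-12)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            encode_instance_rotate([np.ones(3)], [])

    def test_non_unit_relation_rejected(self):
        with pytest.raises(ValueError, match="modulus"):
            encode_instance_rotate([np.ones(4), np.ones(4)],
                                   [np.array([0.5 + 0j, 1 + 0j])])

    def test_relation_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode_instance_rotate([np.ones(4), np.ones(4)], [])


class TestMeanEncoder:
    def test_single_vector(self):
        v = RNG.normal(size=4)
        np.testing.assert_allclose(encode_instance_mean([v]), v)

    def test_opposite_vectors_cancel(self):
        v = RNG.normal(size=4)
        np.testing.assert_allclose(encode_instance_mean([v, -v]), 0.0,
                                   atol=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            encode_instance_mean([])


# ---------------------------------------------------------------------
# attention stages


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


class TestIntraAggregate:
    def test_single_instance_softmax_is_one(self):
        target = RNG.normal(size=4)
        enc = RNG.normal(size=4)
        deltas = RNG.normal(size=(3, 8))
        out, alphas = intra_aggregate(target, [enc], deltas)
        np.testing.assert_allclose(alphas, 1.0)
        np.testing.assert_allclose(out, np.tile(_elu(enc), 3), atol=1e-12)

    def test_identical_encodings_share_weight(self):
        target = RNG.normal(size=4)
        enc = RNG.normal(size=4)
        out, alphas = intra_aggregate(target, [enc, enc], RNG.normal(size=(2, 8)))
        np.testing.assert_allclose(alphas, 0.5)

    def test_alphas_sum_to_one(self):
        target = RNG.normal(size=6)
        encs = [RNG.normal(size=6) for _ in range(7)]
        _, alphas = intra_aggregate(target, encs, RNG.normal(size=(4, 12)))
        np.testing.assert_allclose(alphas.sum(axis=1), 1.0, atol=1e-6)

    def test_five_instance_scalar_oracle(self):
        """Direct per-scalar evaluation of score -> softmax -> weighted sum."""
        d, K = 3, 2
        target = RNG.normal(size=2 * d)
        encs = [RNG.normal(size=2 * d) for _ in range(5)]
        deltas = RNG.normal(size=(K, 4 * d))
        out, alphas = intra_aggregate(target, encs, deltas, leaky_slope=0.01)
        expected_heads = []
        for k in range(K):
            scores = []
            for e in encs:
                s = sum(deltas[k][j] * np.concatenate([target, e])[j]
                        for j in range(4 * d))
                scores.append(s if s > 0 else 0.01 * s)
            w = np.exp(scores) / np.sum(np.exp(scores))
            agg = sum(wi * np.asarray(e) for wi, e in zip(w, encs))
            expected_heads.append(_elu(agg))
            np.testing.assert_allclose(alphas[k], w, atol=1e-10)
        np.testing.assert_allclose(out, np.concatenate(expected_heads),
                                   atol=1e-10)

    def test_empty_instances_rejected(self):
        with pytest.raises(ValueError):
            intra_aggregate(np.ones(4), [], RNG.normal(size=(1, 8)))


class TestMetapathSummary:
    def test_zero_input_gives_zero(self):
        W = RNG.normal(size=(3, 4))
        s = metapath_summary(np.zeros((5, 4)), W, np.zeros(3))
        np.testing.assert_allclose(s, 0.0)

    def test_identical_nodes_collapse_to_one_vector(self):
        h = RNG.normal(size=4)
        W, b = RNG.normal(size=(3, 4)), RNG.normal(size=3)
        s = metapath_summary(np.tile(h, (6, 1)), W, b)
        np.testing.assert_allclose(s, np.tanh(W @ h + b), atol=1e-12)

    def test_random_elementwise_oracle(self):
        H = RNG.normal(size=(5, 4))
        W, b = RNG.normal(size=(3, 4)), RNG.normal(size=3)
        expected = np.mean([np.tanh(W @ h + b) for h in H], axis=0)
        np.testing.assert_allclose(metapath_summary(H, W, b), expected,
                                   atol=1e-12)
        assert np.all(np.abs(metapath_summary(H, W, b)) < 1.0)

    def test_empty_type_rejected(self):
        with pytest.raises(ValueError):
            metapath_summary(np.zeros((0, 4)), np.eye(4), np.zeros(4))


class TestInterAggregate:
    def test_single_metapath_passthrough(self):
        H = RNG.normal(size=(5, 6))
        fused, beta = inter_aggregate([H], [RNG.normal(size=3)],
                                      RNG.normal(size=3))
        np.testing.assert_allclose(beta, [1.0])
        np.testing.assert_allclose(fused, H)

    def test_equal_summaries_average(self):
        H1, H2 = RNG.normal(size=(4, 6)), RNG.normal(size=(4, 6))
        s = RNG.normal(size=3)
        fused, beta = inter_aggregate([H1, H2], [s, s], RNG.normal(size=3))
        np.testing.assert_allclose(beta, [0.5, 0.5])
        np.testing.assert_allclose(fused, 0.5 * H1 + 0.5 * H2, atol=1e-12)

    def test_three_metapath_straightline_oracle(self):
        Hs = [RNG.normal(size=(4, 6)) for _ in range(3)]
        ss = [RNG.normal(size=5) for _ in range(3)]
        c = RNG.normal(size=5)
        e = np.array([c @ s for s in ss])
        w = np.exp(e - e.max())
        w = w / w.sum()
        expected = sum(wi * H for wi, H in zip(w, Hs))
        fused, beta = inter_aggregate(Hs, ss, c)
        np.testing.assert_allclose(beta, w, atol=1e-12)
        np.testing.assert_allclose(fused, expected, atol=1e-12)
        np.testing.assert_allclose(beta.sum(), 1.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            inter_aggregate([np.zeros((3, 4)), np.zeros((3, 5))],
                            [np.zeros(2), np.zeros(2)], np.zeros(2))


# ---------------------------------------------------------------------
# scoring and loss


class TestPredictScore:
    def test_orthogonal_is_half(self):
        assert predict_score([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.5)

    def test_worked_inner_product(self):
        assert predict_score([1.0, 2.0], [3.0, -1.0]) == \
            pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)

    def test_symmetry_exact(self):
        a, b = RNG.normal(size=8), RNG.normal(size=8)
        assert predict_score(a, b) == predict_score(b, a)

    def test_monotone_in_inner_product(self):
        h = RNG.normal(size=8)
        scales = np.linspace(-2, 2, 9)
        scores = [predict_score(h, s * h) for s in scales]
        assert np.all(np.diff(scores) > 0)

    def test_aligned_large_norm_saturates(self):
        h = np.ones(4) * 100.0
        assert predict_score(h, h) == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_score(np.ones(3), np.ones(4))


class TestBceLoss:
    def test_confident_correct_is_near_zero(self):
        assert bce_loss([1 - 1e-9], [1e-9], reduction="sum") < 1e-6

    def test_uninformative_closed_form(self):
        n = 7
        loss = bce_loss([0.5] * n, [0.5] * n, reduction="sum")
        assert loss == pytest.approx(2 * n * np.log(2), abs=1e-10)

    def test_single_positive_closed_form(self):
        assert bce_loss([0.8], [], reduction="sum") == \
            pytest.approx(-np.log(0.8), abs=1e-10)

    def test_mean_reduction_divides_by_total(self):
        s = bce_loss([0.7, 0.6], [0.4], reduction="sum")
        m = bce_loss([0.7, 0.6], [0.4], reduction="mean")
        assert m == pytest.approx(s / 3)

    def test_boundary_scores_clamped(self):
        assert np.isfinite(bce_loss([1.0], [0.0], reduction="sum"))


# ---------------------------------------------------------------------
# batched model vs straight-line oracle

from oracles import straightline_forward  # noqa: E402


def _nets_for_oracle():
    yield fixture_small()
    net, _ = generate_synthetic(SyntheticSpec(
        n_m=4, n_c=3, n_d=3, n_blocks=2, p_in=0.6, p_out=0.2, seed=11))
    yield net


class TestBatchedForwardMatchesOracle:
    @pytest.mark.parametrize("layers", [1, 2])
    @pytest.mark.parametrize("variant", ["full", "nb", "avg"])
    def test_forward_equivalence(self, layers, variant):
        cfg = ModelConfig(hidden_dim=6, heads=2, attention_dim=5,
                          neighbors=10**6, layers=layers, dropout=0.0)
        for net in _nets_for_oracle():
            for draw in range(3):
                model = MetapathAttentionModel(net, cfg, variant)
                params = init_params(net, cfg, seed=100 + draw)
                sampled = model.sample_epoch(np.random.default_rng(0))
                got = model.forward(params, sampled, train=False)
                want = straightline_forward(net, cfg, params.state_dict(),
                                            variant)
                for a in ("microbe", "disease", "drug"):
                    np.testing.assert_allclose(
                        got[a].data, want[a], atol=1e-5,
                        err_msg=f"{a} embeddings diverge ({variant}, L={layers})")

    def test_catalog_order_invariance(self):
        """Shuffling edge-list input order leaves embeddings unchanged:
        the lexicographic catalog pins every index."""
        net = fixture_small()
        shuffled = type(net)(
            catalog=net.catalog,
            md_edges=frozenset(sorted(net.md_edges, reverse=True)),
            mc_edges=frozenset(sorted(net.mc_edges, reverse=True)),
            dc_edges=frozenset(sorted(net.dc_edges, reverse=True)))
        cfg = ModelConfig(hidden_dim=4, heads=2, attention_dim=4,
                          neighbors=10**6, layers=1, dropout=0.0)
        p1 = init_params(net, cfg, seed=5)
        p2 = init_params(shuffled, cfg, seed=5)
        m1 = MetapathAttentionModel(net, cfg)
        m2 = MetapathAttentionModel(shuffled, cfg)
        h1 = m1.forward(p1, m1.sample_epoch(np.random.default_rng(0)))
        h2 = m2.forward(p2, m2.sample_epoch(np.random.default_rng(0)))
        for a in h1:
            np.testing.assert_allclose(h1[a].data, h2[a].data, atol=1e-12)


class TestModelMechanics:
    def test_state_dict_roundtrip(self, small_net):
        cfg = ModelConfig(hidden_dim=4, heads=2, attention_dim=4, layers=1)
        p = init_params(small_net, cfg, seed=1)
        state = p.state_dict()
        for t in p.all_tensors():
            t.data = t.data + 1.0
        p.load_state_dict(state)
        for name, arr in p.state_dict().items():
            np.testing.assert_array_equal(arr, state[name])
        assert p.check_finite()

    def test_init_is_seed_deterministic(self, small_net):
        cfg = ModelConfig(hidden_dim=4, heads=2, attention_dim=4, layers=1)
        s1 = init_params(small_net, cfg, seed=9).state_dict()
        s2 = init_params(small_net, cfg, seed=9).state_dict()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_dropout_changes_training_output(self, small_net):
        cfg = ModelConfig(hidden_dim=4, heads=2, attention_dim=4, layers=1,
                          dropout=0.5)
        model = MetapathAttentionModel(small_net, cfg)
        p = init_params(small_net, cfg, seed=2)
        sampled = model.sample_epoch(np.random.default_rng(0))
        h_eval = model.forward(p, sampled, train=False)
        h_train = model.forward(p, sampled, train=True,
                                dropout_rng=np.random.default_rng(1))
        assert not np.allclose(h_eval["microbe"].data, h_train["microbe"].data)

    def test_score_matrix_matches_pairwise(self):
        hm = RNG.normal(size=(4, 6))
        hd = RNG.normal(size=(3, 6))
        S = score_matrix(hm, hd)
        assert S.shape == (4, 3)
        assert S[1, 2] == pytest.approx(predict_score(hm[1], hd[2]))

    def test_unknown_variant_rejected(self, small_net):
        with pytest.raises(ValueError, match="variant"):
            MetapathAttentionModel(small_net, ModelConfig(), "bogus")

    def test_odd_hidden_dim_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ModelConfig(hidden_dim=7)
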