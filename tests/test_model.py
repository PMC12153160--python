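"""Network components against explicit-loop oracles and exact identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scatddi import ScatConfig, ScatModel, global_max_pool, link_embed, residual_combine
from scatddi.autodiff import Tensor
from scatddi.training import _nll_from_logits


# ---------------------------------------------------------------------------
# explicit-loop oracles
# ---------------------------------------------------------------------------

def softmax_rows_loop(S):
    out = np.zeros_like(S)
    for i in range(S.shape[0]):
        e = [math.exp(v - max(S[i])) for v in S[i]]
        out[i] = np.array(e) / sum(e)
    return out


def cross_attention_oracle(model, U1, U2):
    """Triple-loop evaluation of shared-weight multi-head cross-attention."""
    cfg = model.config
    hd, nh = cfg.head_dim, cfg.n_heads
    Wq, Wk, Wv = (model.params[n].data for n in ("Wq", "Wk", "Wv"))
    Wz = model.params["Wz"].data

    def one_direction(Uq, Ukv):
        heads, A_all = [], []
        for j in range(nh):
            Q = Uq @ Wq[:, j * hd:(j + 1) * hd]
            K = Ukv @ Wk[:, j * hd:(j + 1) * hd]
            V = Ukv @ Wv[:, j * hd:(j + 1) * hd]
            S = np.zeros((Uq.shape[0], Ukv.shape[0]))
            for qi in range(Uq.shape[0]):
                for ki in range(Ukv.shape[0]):
                    S[qi, ki] = float(np.dot(Q[qi], K[ki])) / math.sqrt(hd)
            A = softmax_rows_loop(S)
            heads.append(A @ V)
            A_all.append(A)
        return np.concatenate(heads, axis=1) @ Wz, np.stack(A_all)

    return one_direction(U1, U2), one_direction(U2, U1)


def link_attention_oracle(model, F1, F2):
    W12 = model.params["W12"].data
    b = model.params["b12"].data
    W = model.params["W_link"].data
    cat = np.concatenate([F1, F2])
    D = len(F1)
    a_hat = np.zeros(D)
    for d in range(D):
        pre = sum(cat[j] * W12[j, d] for j in range(2 * D)) + b[d]
        a_hat[d] = W[d] * max(pre, 0.0)
    e = np.exp(a_hat - a_hat.max())
    return e / e.sum()


@pytest.fixture
def tiny_model(tiny_config):
    return ScatModel(tiny_config)


# ---------------------------------------------------------------------------
# BiGRU
# ---------------------------------------------------------------------------

class TestBiGRU:
    def test_zero_input_zero_weights_fixed_point(self, tiny_config):
        model = ScatModel(tiny_config)
        for name, p in model.params.items():
            if name.startswith("gru"):
                p.data[:] = 0.0
        out = model.bigru_encode(np.zeros((1, tiny_config.d_fused)))
        np.testing.assert_allclose(out, 0.0)

    def test_output_shape(self, tiny_model, tiny_config, rng):
        E = rng.standard_normal((7, tiny_config.d_fused))
        assert tiny_model.bigru_encode(E).shape == (7, tiny_config.gd)

    def test_backward_direction_equals_forward_on_reversed_input(
            self, tiny_config, rng):
        """Oracle: with shared direction weights, the backward half of the
        encoding equals the forward GRU run on the reversed sequence,
        reversed back."""
        model = ScatModel(tiny_config)
        for layer in range(tiny_config.gru_layers):
            for suffix in ("W", "U", "b"):
                model.params[f"gru_l{layer}b_{suffix}"].data[:] = \
                    model.params[f"gru_l{layer}f_{suffix}"].data
        E = rng.standard_normal((5, tiny_config.d_fused))
        H = tiny_config.gru_hidden
        out = model.bigru_encode(E)
        out_rev = model.bigru_encode(E[::-1])
        np.testing.assert_allclose(out[:, H:], out_rev[::-1, :H], atol=1e-12)


# ---------------------------------------------------------------------------
# cross-attention
# ---------------------------------------------------------------------------

class TestCrossAttention:
    def test_matches_loop_oracle(self, tiny_model, tiny_config, rng):
        for _ in range(10):
            U1 = rng.standard_normal((3, tiny_config.gd))
            U2 = rng.standard_normal((4, tiny_config.gd))
            (Z1, A1), (Z2, A2) = tiny_model.cross_attention(U1, U2)
            (Z1o, A1o), (Z2o, A2o) = cross_attention_oracle(tiny_model, U1, U2)
            for got, want in ((Z1, Z1o), (A1, A1o), (Z2, Z2o), (A2, A2o)):
                assert np.abs(got - want).max() < 1e-6

    def test_single_key_softmax_is_one(self, tiny_model, tiny_config, rng):
        U1 = rng.standard_normal((1, tiny_config.gd))
        U2 = rng.standard_normal((1, tiny_config.gd))
        (Z1, A1), _ = tiny_model.cross_attention(U1, U2)
        np.testing.assert_allclose(A1, 1.0)
        hd, nh = tiny_config.head_dim, tiny_config.n_heads
        V = U2 @ tiny_model.params["Wv"].data
        np.testing.assert_allclose(Z1, V @ tiny_model.params["Wz"].data)

    def test_swap_symmetry_is_exact(self, tiny_model, tiny_config, rng):
        U1 = rng.standard_normal((3, tiny_config.gd))
        U2 = rng.standard_normal((5, tiny_config.gd))
        (Z1, A1), (Z2, A2) = tiny_model.cross_attention(U1, U2)
        (Z2s, A2s), (Z1s, A1s) = tiny_model.cross_attention(U2, U1)
        np.testing.assert_array_equal(Z1, Z1s)
        np.testing.assert_array_equal(Z2, Z2s)
        np.testing.assert_array_equal(A1, A1s)
        np.testing.assert_array_equal(A2, A2s)

    @given(t1=st.integers(1, 6), t2=st.integers(1, 6),
           scale=st.floats(0.1, 30.0))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_attention_rows_sum_to_one(self, t1, t2, scale):
        cfg = ScatConfig(d_w=6, d_d=4, d_g=2, gru_hidden=4, gru_layers=1,
                         head_dim=4, n_heads=2, dropout=0.0, seed=3)
        model = ScatModel(cfg)
        r = np.random.Generator(np.random.PCG64(42))
        U1 = r.standard_normal((t1, cfg.gd)) * scale
        U2 = r.standard_normal((t2, cfg.gd)) * scale
        (_, A1), (_, A2) = model.cross_attention(U1, U2)
        np.testing.assert_allclose(A1.sum(axis=-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(A2.sum(axis=-1), 1.0, atol=1e-6)
        assert (A1 >= 0).all() and (A1 <= 1).all()

    def test_feature_dim_mismatch_rejected(self, tiny_model, tiny_config, rng):
        with pytest.raises(ValueError):
            tiny_model.cross_attention_batch(
                Tensor(rng.standard_normal((1, 3, tiny_config.gd))),
                Tensor(rng.standard_normal((1, 3, tiny_config.gd + 1))))


# ---------------------------------------------------------------------------
# small exact pieces
# ---------------------------------------------------------------------------

class TestResidualPoolLink:
    def test_residual_identity_and_half(self, rng):
        U = rng.standard_normal((4, 6))
        np.testing.assert_array_equal(residual_combine(U, U), U)
        np.testing.assert_allclose(residual_combine(np.zeros_like(U), U), U / 2)
        Z = rng.standard_normal((4, 6))
        np.testing.assert_allclose(residual_combine(Z, U), (Z + U) / 2)

    def test_residual_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            residual_combine(rng.standard_normal((2, 3)),
                             rng.standard_normal((3, 2)))

    def test_max_pool_matches_columnwise_loop(self, rng):
        F = rng.standard_normal((5, 8))
        want = np.array([max(F[t, d] for t in range(5)) for d in range(8)])
        np.testing.assert_array_equal(global_max_pool(F), want)

    def test_max_pool_permutation_invariant_and_t1(self, rng):
        F = rng.standard_normal((6, 4))
        perm = rng.permutation(6)
        np.testing.assert_array_equal(global_max_pool(F), global_max_pool(F[perm]))
        row = rng.standard_normal((1, 4))
        np.testing.assert_array_equal(global_max_pool(row), row[0])

    def test_link_attention_matches_loop_oracle(self, tiny_model, tiny_config, rng):
        for _ in range(10):
            F1 = rng.standard_normal(tiny_config.gd)
            F2 = rng.standard_normal(tiny_config.gd)
            got = tiny_model.link_attention(F1, F2)
            want = link_attention_oracle(tiny_model, F1, F2)
            assert np.abs(got - want).max() < 1e-6
            assert abs(got.sum() - 1.0) < 1e-9

    def test_link_attention_uniform_when_preactivation_constant(self, tiny_model, tiny_config):
        D = tiny_config.gd
        tiny_model.params["W_link"].data[:] = 0.0  # a_hat identically zero
        a = tiny_model.link_attention(np.ones(D), np.ones(D))
        np.testing.assert_allclose(a, 1.0 / D)

    def test_link_embed_properties(self, rng):
        F1, F2, a = (rng.standard_normal(6) for _ in range(3))
        np.testing.assert_allclose(link_embed(np.ones(6), F2, a), a * F2)
        F1z = F1.copy()
        F1z[2] = 0.0
        assert link_embed(F1z, F2, a)[2] == 0.0
        np.testing.assert_array_equal(link_embed(F1, F2, a),
                                      link_embed(F2, F1, a))


class TestClassifier:
    def test_zero_weights_give_uniform(self, tiny_model, tiny_config):
        tiny_model.params["Wc"].data[:] = 0.0
        tiny_model.params["bc"].data[:] = 0.0
        p = tiny_model.classify(np.ones(tiny_config.gd))
        np.testing.assert_allclose(p, 0.2)

    def test_single_logit_softmax_closed_form(self, tiny_model, tiny_config):
        tiny_model.params["Wc"].data[:] = 0.0
        tiny_model.params["bc"].data[:] = np.array([1.0, 0, 0, 0, 0])
        p = tiny_model.classify(np.zeros(tiny_config.gd))
        assert abs(p[0] - math.e / (math.e + 4)) < 1e-12

    def test_probabilities_sum_to_one(self, tiny_model, tiny_config, rng):
        p = tiny_model.classify(rng.standard_normal(tiny_config.gd) * 10)
        assert abs(p.sum() - 1.0) < 1e-9 and (p >= 0).all()


# ---------------------------------------------------------------------------
# full forward
# ---------------------------------------------------------------------------

class TestForward:
    def test_eval_mode_is_deterministic(self, tiny_model, tiny_config, rng):
        E1 = rng.standard_normal((4, tiny_config.d_fused))
        E2 = rng.standard_normal((3, tiny_config.d_fused))
        np.testing.assert_array_equal(tiny_model.forward(E1, E2),
                                      tiny_model.forward(E1, E2))

    @pytest.mark.parametrize("t1,t2", [(1, 1), (2, 7), (5, 3)])
    def test_output_shape_for_any_lengths(self, tiny_model, tiny_config, rng, t1, t2):
        p = tiny_model.forward(rng.standard_normal((t1, tiny_config.d_fused)),
                               rng.standard_normal((t2, tiny_config.d_fused)))
        assert p.shape == (tiny_config.n_classes,)
        assert abs(p.sum() - 1.0) < 1e-6

    def test_padding_does_not_change_results(self, tiny_model, tiny_config, rng):
        """A short pair evaluated alone equals the same pair inside a batch
        with longer sequences (masking correctness)."""
        E1 = rng.standard_normal((2, tiny_config.d_fused))
        E2 = rng.standard_normal((3, tiny_config.d_fused))
        L1 = rng.standard_normal((6, tiny_config.d_fused))
        L2 = rng.standard_normal((5, tiny_config.d_fused))
        alone = tiny_model.forward_batch([E1], [E2])["probs"][0]
        batched = tiny_model.forward_batch([E1, L1], [E2, L2])["probs"][0]
        np.testing.assert_allclose(batched, alone, atol=1e-10)

    def test_gradients_match_finite_differences(self, tiny_config, rng):
        model = ScatModel(tiny_config)
        E1 = [rng.standard_normal((3, tiny_config.d_fused)) for _ in range(2)]
        E2 = [rng.standard_normal((3, tiny_config.d_fused)) for _ in range(2)]
        labels = np.array([1, 3])

        def loss_value():
            out = model.forward_batch(E1, E2, train=True)
            return float(_nll_from_logits(out["logits"], labels, None).data)

        out = model.forward_batch(E1, E2, train=True)
        loss = _nll_from_logits(out["logits"], labels, None)
        model.zero_grad()
        loss.backward()
        eps = 1e-5
        check_rng = np.random.Generator(np.random.PCG64(0))
        for name, p in model.params.items():
            flat = p.data.reshape(-1)
            grad = (p.grad if p.grad is not None else np.zeros_like(p.data)).reshape(-1)
            n_entries = flat.size
            picks = (range(n_entries) if n_entries <= 12 else
                     check_rng.choice(n_entries, size=10, replace=False))
            for idx in picks:
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = loss_value()
                flat[idx] = orig - eps
                lo = loss_value()
                flat[idx] = orig
                fd = (hi - lo) / (2 * eps)
                assert abs(grad[idx] - fd) <= 1e-6 + 1e-4 * max(abs(fd), abs(grad[idx])), \
                    f"{name}[{idx}]: analytic {grad[idx]} vs numeric {fd}"


def test_checkpoint_round_trip(tmp_path, tiny_config, rng):
    model = ScatModel(tiny_config)
    E1 = rng.standard_normal((3, tiny_config.d_fused))
    E2 = rng.standard_normal((2, tiny_config.d_fused))
    before = model.forward(E1, E2)
    path = tmp_path / "model.npz"
    model.save(path)
    restored = ScatModel.load(path)
    np.testing.assert_array_equal(restored.forward(E1, E2), before)
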