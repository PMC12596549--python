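"""Architecture primitives: recurrent encoding, residual feature update,
attention mask, output head, checkpointing and transfer initialization."""

import numpy as np
import pytest

from cardiofair._autodiff import Tensor
from cardiofair.network import (ModelState, attention_mask, attention_update,
                                bilstm_forward, forward, init_state,
                                load_checkpoint, make_checkpoint, predict_head,
                                predict_proba, residual_update, restore_state,
                                save_checkpoint, tabular_to_sequence,
                                transfer_init, TransferError)


def _sigma(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestSequenceView:
    def test_shape_contract(self, small_matrix):
        seq = tabular_to_sequence(small_matrix.values)
        assert len(seq) == 25
        assert all(tok.shape == (small_matrix.n, 1) for tok in seq)

    def test_determinism_on_identical_rows(self):
        X = np.tile(np.arange(5.0), (2, 1))
        seq = tabular_to_sequence(X)
        for tok in seq:
            assert tok[0, 0] == tok[1, 0]

    def test_column_permutation_permutes_tokens(self, rng):
        X = rng.random((3, 6))
        perm = rng.permutation(6)
        seq = tabular_to_sequence(X)
        seq_p = tabular_to_sequence(X[:, perm])
        for t, source in enumerate(perm):
            np.testing.assert_array_equal(seq_p[t], seq[source])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            tabular_to_sequence(np.array([[1.0, np.nan]]))


class TestBiLSTM:
    def test_hidden_width_is_twice_hidden_size(self, rng):
        state = init_state([f"x{i}" for i in range(4)], hidden_size=128, seed=0)
        seq = tabular_to_sequence(rng.random((2, 4)))
        hs = bilstm_forward(seq, state.numpy_params(), 128)
        assert all(h.shape == (2, 256) for h in hs)

    def test_zero_weights_give_zero_hidden_states(self, rng):
        state = init_state(["a", "b", "c"], hidden_size=4, seed=0)
        params = {k: np.zeros_like(v.data) for k, v in state.params.items()}
        seq = tabular_to_sequence(rng.random((3, 3)))
        hs = bilstm_forward(seq, params, 4)
        for h in hs:
            np.testing.assert_array_equal(h, np.zeros((3, 8)))

    def test_palindrome_symmetry_via_cell_unrolling(self, rng):
        """With identical forward/backward cells and a palindromic input,
        the backward hidden at T+1-t equals the forward hidden at t."""
        state = init_state(["a", "b", "c"], hidden_size=5, seed=3)
        params = state.numpy_params()
        for side in ("Wx", "Wh", "b"):
            params[f"lstm_bw_{side}"] = params[f"lstm_fw_{side}"]
        x = rng.random((2, 1))
        seq = [x, rng.random((2, 1)), x][:3]
        seq[2] = seq[0]  # palindrome of length 3
        hs = bilstm_forward(seq, params, 5)
        T = 3
        for t in range(T):
            hf_t = hs[t][:, :5]
            hb_mirror = hs[T - 1 - t][:, 5:]
            np.testing.assert_allclose(hf_t, hb_mirror, atol=1e-12)


class TestResidualUpdate:
    def test_full_residual_limit_is_identity(self, rng):
        xf = rng.random((2, 4))
        out = residual_update(rng.random((2, 1)), xf, rng.random((1, 4)),
                              rng.random((4, 4)), lam=1.0)
        np.testing.assert_allclose(out, xf, atol=1e-12)

    def test_no_residual_limit_is_plain_activation(self, rng):
        x, xf = rng.random((2, 1)), rng.random((2, 4))
        Wi, Wr = rng.random((1, 4)), rng.random((4, 4))
        out = residual_update(x, xf, Wi, Wr, lam=0.0)
        np.testing.assert_allclose(out, _sigma(x @ Wi + xf @ Wr), atol=1e-12)

    def test_scalar_substitution_oracle(self):
        # Wi=1, Wr=0, X=0, XF=0, lam=0.5: (1-0.5)*sigma(0) + 0.5*0 = 0.25
        out = residual_update(np.zeros((1, 1)), np.zeros((1, 1)),
                              np.ones((1, 1)), np.zeros((1, 1)), lam=0.5)
        assert out[0, 0] == pytest.approx(0.25)

    def test_rewrite_equivalence_with_update_plus_scaled_difference(self, rng):
        """(1-lam)*a + lam*XF equals a + lam*(XF - a) to 1e-12."""
        for _ in range(20):
            x, xf = rng.normal(size=(3, 1)), rng.normal(size=(3, 6))
            Wi, Wr = rng.normal(size=(1, 6)), rng.normal(size=(6, 6))
            lam = rng.random()
            a = _sigma(x @ Wi + xf @ Wr)
            ours = residual_update(x, xf, Wi, Wr, lam)
            published_form = a + lam * (xf - a)
            np.testing.assert_allclose(ours, published_form, atol=1e-12)


class TestAttention:
    def test_zero_parameters_give_half_mask(self):
        m = attention_mask(np.zeros((2, 3)), np.zeros((3, 3)), np.zeros((1, 3)))
        np.testing.assert_array_equal(m, np.full((2, 3), 0.5))

    def test_large_bias_saturates_toward_one(self):
        m = attention_mask(np.zeros((1, 2)), np.zeros((2, 2)),
                           np.full((1, 2), 50.0))
        assert np.all(m > 1 - 1e-12)

    def test_mask_matches_scalar_sigmoid_oracle(self):
        h = np.array([[0.5, -1.0]])
        Wm = np.array([[1.0, 0.0], [0.0, 2.0]])
        bm = np.array([[0.1, -0.2]])
        np.testing.assert_allclose(attention_mask(h, Wm, bm),
                                   _sigma(h @ Wm + bm), atol=1e-15)

    def test_identity_limit_and_skip_connection(self):
        xf = np.array([[1.0, 2.0]])
        assert np.array_equal(attention_update(xf, np.zeros((1, 2)),
                                               np.zeros((1, 2))), xf)
        res = np.array([[0.5, 0.5]])
        np.testing.assert_array_equal(attention_update(xf, np.zeros((1, 2)), res),
                                      xf + res)

    def test_elementwise_oracle(self):
        out = attention_update(np.array([[1.0, 2.0]]),
                               np.array([[0.5, 0.5]]), np.zeros((1, 2)))
        np.testing.assert_array_equal(out, np.array([[1.5, 3.0]]))


class TestHead:
    def test_zero_parameters_give_half(self):
        assert predict_head(np.zeros((1, 4)), np.zeros((4, 1)),
                            np.zeros((1, 1)))[0] == 0.5

    def test_large_bias_saturates(self):
        out = predict_head(np.zeros((1, 4)), np.zeros((4, 1)),
                           np.full((1, 1), 20.0))
        assert out[0] > 0.999

    def test_monotone_in_logit(self, rng):
        Wo = rng.normal(size=(3, 1))
        h = rng.normal(size=(5, 3))
        logits = (h @ Wo).reshape(-1)
        order = np.argsort(logits)
        out = predict_head(h, Wo, np.zeros((1, 1)))
        assert np.all(np.diff(out[order]) > 0)


class TestFullForward:
    def test_output_is_probability_for_any_finite_input(self, rng):
        state = init_state([f"x{i}" for i in range(6)], hidden_size=5, seed=2)
        X = rng.normal(scale=10.0, size=(8, 6))
        p = predict_proba(state, X)
        assert np.all((p >= 0) & (p <= 1))

    def test_forward_is_deterministic(self, rng, small_matrix):
        state = init_state(small_matrix.feature_names, hidden_size=4, seed=9)
        X = small_matrix.values[:10]
        np.testing.assert_array_equal(predict_proba(state, X),
                                      predict_proba(state, X))

    def test_without_ra_equals_plain_bilstm_head(self, rng):
        """The no-residual-attention arm reduces exactly to BiLSTM + head."""
        names = [f"x{i}" for i in range(5)]
        state = init_state(names, hidden_size=4, seed=7,
                           use_residual_attention=False)
        X = rng.random((6, 5))
        got = predict_proba(state, X)
        params = state.numpy_params()
        hs = bilstm_forward(tabular_to_sequence(X), params, 4)
        want = predict_head(hs[-1], params["head_Wo"], params["head_bo"])
        np.testing.assert_array_equal(got, want)

    def test_mean_pooling_switch_changes_summary_not_contract(self, rng):
        names = [f"x{i}" for i in range(5)]
        X = rng.random((4, 5))
        last = init_state(names, hidden_size=4, seed=7, pool="last")
        mean = init_state(names, hidden_size=4, seed=7, pool="mean")
        p_last, p_mean = predict_proba(last, X), predict_proba(mean, X)
        assert np.all((p_mean >= 0) & (p_mean <= 1))
        assert not np.array_equal(p_last, p_mean)


class TestCheckpoints:
    def test_save_load_round_trip_is_bit_identical(self, tmp_path, rng):
        state = init_state([f"x{i}" for i in range(5)], hidden_size=3, seed=4)
        X = rng.random((4, 5))
        before = predict_proba(state, X)
        path = tmp_path / "model.npz"
        save_checkpoint(state, path, provenance="test")
        restored = restore_state(load_checkpoint(path))
        np.testing.assert_array_equal(predict_proba(restored, X), before)

    def test_strict_mismatch_names_offender(self, tmp_path):
        src = init_state([f"x{i}" for i in range(5)], hidden_size=3, seed=4)
        dst = init_state([f"x{i}" for i in range(5)], hidden_size=8, seed=4)
        with pytest.raises(TransferError, match="H_dim"):
            transfer_init(dst, make_checkpoint(src), strict=True)

    def test_transfer_copies_recurrent_but_refreshes_head(self):
        src = init_state([f"x{i}" for i in range(5)], hidden_size=3, seed=4)
        dst = init_state([f"x{i}" for i in range(5)], hidden_size=3, seed=99)
        out = transfer_init(dst, make_checkpoint(src), strict=True, head_seed=1)
        np.testing.assert_array_equal(out.params["lstm_fw_Wx"].data,
                                      src.params["lstm_fw_Wx"].data)
        assert not np.array_equal(out.params["head_Wo"].data,
                                  src.params["head_Wo"].data)

    def test_non_strict_with_empty_checkpoint_is_fresh_seeded_init(self):
        from cardiofair.network import Checkpoint
        dst = init_state([f"x{i}" for i in range(5)], hidden_size=3, seed=12)
        empty = Checkpoint(arrays={}, fingerprint={})
        out = transfer_init(dst, empty, strict=False, head_seed=2)
        for name in ("lstm_fw_Wx", "res_Wi", "attn_Wm"):
            np.testing.assert_array_equal(out.params[name].data,
                                          dst.params[name].data)

    def test_transfer_without_checkpoint_keeps_fresh_init(self):
        dst = init_state([f"x{i}" for i in range(5)], hidden_size=3, seed=12)
        out = transfer_init(dst, None)
        for name, p in dst.params.items():
            np.testing.assert_array_equal(out.params[name].data, p.data)
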