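"""The residual-attention bidirectional LSTM classifier.

Architecture, reading one encoded record as a length-T sequence of scalar
tokens (T = number of encoded columns, fixed column order):

1. a bidirectional LSTM encodes the sequence; per step the forward and
   backward hidden states are concatenated, ``h_t = [hf_t ; hb_t]``;
2. a residual feature track updates
   ``XF_{t+1} = (1-lambda) * fa(Wi x_t + Wr XF_t) + lambda * XF_t``
   (algebraically the same as ``fa(.) + lambda*(XF_t - fa(.))``), where
   ``lambda`` in [0, 1] is a fixed residual-influence coefficient;
3. a learned sigmoid attention mask ``M_t = sigmoid(Wm H_t + bm)`` soft-
   amplifies the feature track, ``H_{t+1} = (1 + M_t) ⊙ XF_t + h_t``, with
   the BiLSTM output ``h_t`` as the skip (residual) branch;
4. a sigmoid head maps the final state to a disease probability
   ``yhat = sigmoid(Wo H_T + bo)``; the decision threshold is 0.5.

Disabling residual attention (the "without RA" ablation arm) removes the
feature track and mask entirely, leaving a plain BiLSTM + head.

The same forward code runs on autodiff tensors (training) and raw ndarrays
(inference / attribution); both paths produce identical numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, sigmoid, tanh

__all__ = ["ModelState", "Checkpoint", "init_state", "forward", "predict_proba",
           "bilstm_forward", "residual_update", "attention_mask",
           "attention_update", "predict_head", "transfer_init",
           "save_checkpoint", "load_checkpoint", "TransferError",
           "RECURRENT_PARAMS", "HEAD_PARAMS"]

CHECKPOINT_FORMAT = "cardiofair-checkpoint-v1"

#: parameter groups: transfer init copies the first set, re-initializes the second
RECURRENT_PARAMS = ("lstm_fw_Wx", "lstm_fw_Wh", "lstm_fw_b",
                    "lstm_bw_Wx", "lstm_bw_Wh", "lstm_bw_b",
                    "res_Wi", "res_Wr", "attn_Wm", "attn_bm")
HEAD_PARAMS = ("head_Wo", "head_bo")


class TransferError(ValueError):
    """Checkpoint incompatible with the model under strict transfer."""


@dataclass
class ModelState:
    """All trainable parameters plus the architectural configuration."""

    params: dict[str, Tensor]
    feature_names: list[str]
    hidden_size: int
    lam: float = 0.5
    pool: str = "last"                      # "last" or "mean"
    use_residual_attention: bool = True
    token_dim: int = 1

    @property
    def seq_len(self) -> int:
        return len(self.feature_names)

    def fingerprint(self) -> dict:
        return {"feature_names": list(self.feature_names),
                "d": len(self.feature_names), "T": self.seq_len,
                "H_dim": self.hidden_size}

    def numpy_params(self) -> dict[str, np.ndarray]:
        return {k: v.data for k, v in self.params.items()}

    def copy(self) -> "ModelState":
        return replace(self, params={k: Tensor(v.data.copy(), requires_grad=True)
                                     for k, v in self.params.items()})


@dataclass
class Checkpoint:
    """Serializable parameter snapshot with a schema fingerprint."""

    arrays: dict[str, np.ndarray]
    fingerprint: dict
    provenance: str = ""
    format: str = CHECKPOINT_FORMAT


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int | None = None) -> np.ndarray:
    """U(-k, k) with k = 1/sqrt(fan_in); recurrent tensors pass the hidden
    width as fan-in (the standard recurrent convention) so scalar-token
    input weights do not start an order of magnitude larger than the rest."""
    bound = 1.0 / np.sqrt(fan_in if fan_in is not None else shape[0])
    return rng.uniform(-bound, bound, size=shape)


def _param_shapes(f: int, H: int) -> dict[str, tuple[int, int]]:
    return {
        "lstm_fw_Wx": (f, 4 * H), "lstm_fw_Wh": (H, 4 * H), "lstm_fw_b": (1, 4 * H),
        "lstm_bw_Wx": (f, 4 * H), "lstm_bw_Wh": (H, 4 * H), "lstm_bw_b": (1, 4 * H),
        "res_Wi": (f, 2 * H), "res_Wr": (2 * H, 2 * H),
        "attn_Wm": (2 * H, 2 * H), "attn_bm": (1, 2 * H),
        "head_Wo": (2 * H, 1), "head_bo": (1, 1),
    }


def init_state(feature_names: list[str], hidden_size: int = 128, lam: float = 0.5,
               seed: int = 0, pool: str = "last",
               use_residual_attention: bool = True) -> ModelState:
    """Seeded fan-in uniform initialization of every parameter tensor."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0,1], got {lam}")
    if pool not in ("last", "mean"):
        raise ValueError(f"pool must be 'last' or 'mean', got {pool!r}")
    rng = np.random.default_rng(seed)
    params = {}
    for name, shape in _param_shapes(1, hidden_size).items():
        fan = hidden_size if name.startswith("lstm") else 2 * hidden_size
        params[name] = Tensor(_uniform_fan_in(rng, shape, fan_in=fan),
                              requires_grad=True)
    return ModelState(params=params, feature_names=list(feature_names),
                      hidden_size=hidden_size, lam=lam, pool=pool,
                      use_residual_attention=use_residual_attention)


# --------------------------------------------------------------- primitives

def _lstm_cell(x_t, h, c, Wx, Wh, b, H: int):
    z = x_t @ Wx + h @ Wh + b
    i = sigmoid(z[:, 0 * H:1 * H])
    f = sigmoid(z[:, 1 * H:2 * H])
    g = tanh(z[:, 2 * H:3 * H])
    o = sigmoid(z[:, 3 * H:4 * H])
    c_new = f * c + i * g
    return o * tanh(c_new), c_new


def bilstm_forward(seq, params, hidden_size: int):
    """Hidden sequence of a bidirectional LSTM.

    `seq` is a list of T (n, f) tokens.  Returns the list
    ``[h_1, ..., h_T]`` with ``h_t = [hf_t ; hb_t]`` of width 2*hidden_size,
    where the forward pass reads t = 1..T and the backward pass t = T..1.
    """
    H = hidden_size
    n = seq[0].shape[0]
    zeros = np.zeros((n, H))
    hf, cf = zeros, zeros
    fw = []
    for x_t in seq:
        hf, cf = _lstm_cell(x_t, hf, cf, params["lstm_fw_Wx"],
                            params["lstm_fw_Wh"], params["lstm_fw_b"], H)
        fw.append(hf)
    hb, cb = zeros, zeros
    bw = [None] * len(seq)
    for t in range(len(seq) - 1, -1, -1):
        hb, cb = _lstm_cell(seq[t], hb, cb, params["lstm_bw_Wx"],
                            params["lstm_bw_Wh"], params["lstm_bw_b"], H)
        bw[t] = hb
    return [concat([f, b], axis=1) for f, b in zip(fw, bw)]


def residual_update(x_t, xf_t, Wi, Wr, lam: float, fa=sigmoid):
    """``XF_{t+1} = (1-lam)*fa(Wi x + Wr XF) + lam*XF``."""
    a = fa(x_t @ Wi + xf_t @ Wr)
    return (1.0 - lam) * a + lam * xf_t


def attention_mask(h_state, Wm, bm):
    """Learned sigmoid gate ``M = sigmoid(Wm H + bm)``; entries in (0, 1)."""
    return sigmoid(h_state @ Wm + bm)


def attention_update(xf_t, mask, residual):
    """``H_{t+1} = (1 + M) ⊙ XF + residual`` (skip from the encoder)."""
    return (1.0 + mask) * xf_t + residual


def predict_head(h_final, Wo, bo):
    """Disease probability ``sigmoid(Wo H + bo)`` as a length-n vector."""
    out = sigmoid(h_final @ Wo + bo)
    return out.reshape(-1) if isinstance(out, Tensor) else np.asarray(out).reshape(-1)


def tabular_to_sequence(X: np.ndarray) -> list[np.ndarray]:
    """View each encoded row as a length-d sequence of scalar tokens."""
    X = np.asarray(X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in the design matrix")
    return [X[:, t:t + 1] for t in range(X.shape[1])]


# ------------------------------------------------------------- full forward

def forward(state: ModelState, X: np.ndarray, train: bool = False):
    """Full forward pass; probability per row.

    With ``train=True`` the graph is built on the state's parameter tensors
    (so ``loss.backward()`` reaches them); otherwise raw ndarrays are used.
    """
    params = state.params if train else state.numpy_params()
    seq = tabular_to_sequence(X)
    hs = bilstm_forward(seq, params, state.hidden_size)
    n = X.shape[0]
    if state.use_residual_attention:
        xf = np.zeros((n, 2 * state.hidden_size))
        h_state = np.zeros((n, 2 * state.hidden_size))
        collected = []
        for x_t, h_t in zip(seq, hs):
            m = attention_mask(h_state, params["attn_Wm"], params["attn_bm"])
            h_state = attention_update(xf, m, h_t)
            xf = residual_update(x_t, xf, params["res_Wi"], params["res_Wr"], state.lam)
            collected.append(h_state)
        final = h_state if state.pool == "last" else _mean_states(collected)
    else:
        final = hs[-1] if state.pool == "last" else _mean_states(hs)
    return predict_head(final, params["head_Wo"], params["head_bo"])


def _mean_states(states):
    acc = states[0]
    for s in states[1:]:
        acc = acc + s
    return acc / len(states)


def predict_proba(state: ModelState, X: np.ndarray) -> np.ndarray:
    """Gradient-free probabilities (identical numbers to the training path)."""
    return np.asarray(forward(state, X, train=False))


def predict_label(state: ModelState, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return (predict_proba(state, X) >= threshold).astype(int)


# --------------------------------------------------------------- checkpoints

def make_checkpoint(state: ModelState, provenance: str = "") -> Checkpoint:
    return Checkpoint(arrays={k: v.data.copy() for k, v in state.params.items()},
                      fingerprint=state.fingerprint(), provenance=provenance)


def save_checkpoint(state_or_ckpt, path: str | Path, provenance: str = "") -> None:
    """Single-archive format: named float64 arrays + JSON metadata."""
    ckpt = (state_or_ckpt if isinstance(state_or_ckpt, Checkpoint)
            else make_checkpoint(state_or_ckpt, provenance))
    meta = json.dumps({"format": ckpt.format, "fingerprint": ckpt.fingerprint,
                       "provenance": ckpt.provenance})
    np.savez(Path(path), __meta__=np.array(meta), **ckpt.arrays)


def load_checkpoint(path: str | Path) -> Checkpoint:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        arrays = {k: z[k].copy() for k in z.files if k != "__meta__"}
    if meta.get("format") != CHECKPOINT_FORMAT:
        raise TransferError(f"unrecognized checkpoint format {meta.get('format')!r}")
    return Checkpoint(arrays=arrays, fingerprint=meta["fingerprint"],
                      provenance=meta.get("provenance", ""))


def restore_state(ckpt: Checkpoint, lam: float = 0.5, pool: str = "last",
                  use_residual_attention: bool = True) -> ModelState:
    """Rebuild a full ModelState from a checkpoint (bit-identical parameters)."""
    params = {k: Tensor(v.copy(), requires_grad=True) for k, v in ckpt.arrays.items()}
    return ModelState(params=params, feature_names=ckpt.fingerprint["feature_names"],
                      hidden_size=ckpt.fingerprint["H_dim"], lam=lam, pool=pool,
                      use_residual_attention=use_residual_attention)


def transfer_init(state: ModelState, checkpoint: Checkpoint | None,
                  strict: bool = True, head_seed: int = 0) -> ModelState:
    """Initialize from a pretrained checkpoint.

    Recurrent and residual-attention parameters are copied; the output head
    is re-initialized fresh (seeded).  With ``strict`` the checkpoint's
    schema fingerprint must match the model's; with ``strict=False`` only
    shape-matching tensors are copied and the rest keep their fresh
    initialization.  ``checkpoint=None`` (the "without transfer" arm) leaves
    the fresh initialization untouched.
    """
    out = state.copy()
    if checkpoint is None:
        return out
    if strict:
        fp, want = checkpoint.fingerprint, state.fingerprint()
        mismatched = [k for k in want if fp.get(k) != want[k]]
        if mismatched:
            raise TransferError(
                f"checkpoint fingerprint mismatch on {mismatched}: "
                f"{ {k: (fp.get(k), want[k]) for k in mismatched if k != 'feature_names'} }")
    rng = np.random.default_rng(head_seed)
    for name in RECURRENT_PARAMS:
        src = checkpoint.arrays.get(name)
        if src is None:
            continue
        if src.shape == out.params[name].data.shape:
            out.params[name] = Tensor(src.copy(), requires_grad=True)
        elif strict:
            raise TransferError(f"shape mismatch for tensor {name!r}: "
                                f"{src.shape} vs {out.params[name].data.shape}")
    fan = out.params["head_Wo"].data.shape[0]
    for name in HEAD_PARAMS:
        shape = out.params[name].data.shape
        out.params[name] = Tensor(_uniform_fan_in(rng, shape, fan_in=fan),
                                  requires_grad=True)
    return out
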