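"""The scTransformer decoder: scm-attention, multi-head aggregation,
feed-forward, average pooling and linear reconstruction heads.

scm-attention replaces softmax attention entirely with ReLU:
    Q, K, V = ReLU(split(X W + b))
    scores  = Q K^T / sqrt(s)
    out     = ReLU(mask(scores)) V
The causal mask hides future sub-vectors; with ReLU in place of softmax,
"masked to infinity" is realised as -inf before the ReLU, i.e. masked
score entries are exactly zero afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, concatenate
from .data_model import LatentRepresentation, ScmModelConfig


# ---------------------------------------------------------------------------
# weight containers (functional API)
# ---------------------------------------------------------------------------

@dataclass
class ScmAttentionWeights:
    """Joint QKV projection (s x 3s), bias (3s,), H heads, merge (s x s)."""

    W_qkv: np.ndarray
    b: np.ndarray
    H: int = 1
    W_out: np.ndarray | None = None

    def __post_init__(self):
        self.W_qkv = np.asarray(self.W_qkv, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        s = self.W_qkv.shape[0]
        if self.W_qkv.shape != (s, 3 * s):
            raise ValueError(f"W_qkv must be (s, 3s), got {self.W_qkv.shape}")
        if self.b.shape != (3 * s,):
            raise ValueError(f"b must be (3s,), got {self.b.shape}")
        if s % self.H != 0:
            raise ValueError(f"H ({self.H}) must divide s ({s})")
        if self.W_out is None:
            self.W_out = np.eye(s)
        self.W_out = np.asarray(self.W_out, dtype=np.float64)
        if self.W_out.shape != (s, s):
            raise ValueError("W_out must be (s, s)")

    @property
    def s(self) -> int:
        return self.W_qkv.shape[0]


@dataclass
class DecoderLayerWeights:
    attention: ScmAttentionWeights
    gamma1: np.ndarray
    beta1: np.ndarray
    gamma2: np.ndarray
    beta2: np.ndarray
    W1: np.ndarray  # (s, 2s)
    b1: np.ndarray  # (2s,)
    W2: np.ndarray  # (2s, s)
    b2: np.ndarray  # (s,)

    def __post_init__(self):
        s = self.attention.s
        for name in ("gamma1", "beta1", "gamma2", "beta2", "W1", "b1", "W2", "b2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.W1.shape != (s, 2 * s) or self.b1.shape != (2 * s,):
            raise ValueError("feed-forward W1/b1 must be (s, 2s)/(2s,)")
        if self.W2.shape != (2 * s, s) or self.b2.shape != (s,):
            raise ValueError("feed-forward W2/b2 must be (2s, s)/(s,)")


@dataclass
class ReconstructionHead:
    """Affine map (s -> v_out), no activation."""

    W1: np.ndarray
    b1: np.ndarray

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.b1 = np.asarray(self.b1, dtype=np.float64)
        if self.W1.ndim != 2 or self.b1.shape != (self.W1.shape[1],):
            raise ValueError("head shapes inconsistent")

    @property
    def v_out(self) -> int:
        return self.W1.shape[1]


def causal_mask(n_sub: int) -> np.ndarray:
    """Boolean (n_sub x n_sub); entry [i, j] True iff j <= i."""
    return np.tril(np.ones((n_sub, n_sub), dtype=bool))


# ---------------------------------------------------------------------------
# differentiable building blocks (Tensor in, Tensor out)
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


def _layernorm_t(X: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    mu = X.mean(axis=-1, keepdims=True)
    xc = X - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + _LN_EPS) ** -0.5 * gamma + beta


def _attention_t(X: Tensor, W_qkv: Tensor, b: Tensor, W_out: Tensor,
                 H: int, mask: np.ndarray, s: int) -> Tensor:
    qkv = (X @ W_qkv + b).relu()
    Q = qkv[:, :, 0 * s:1 * s]
    K = qkv[:, :, 1 * s:2 * s]
    V = qkv[:, :, 2 * s:3 * s]
    dh = s // H
    mask_f = mask.astype(np.float64)
    heads = []
    for h in range(H):
        sl = (slice(None), slice(None), slice(h * dh, (h + 1) * dh))
        Qh, Kh, Vh = Q[sl], K[sl], V[sl]
        scores = (Qh @ Kh.transpose_last()) * (1.0 / np.sqrt(s))
        attn = scores.relu() * mask_f  # -inf pre-ReLU == zero post-ReLU
        heads.append(attn @ Vh)
    merged = heads[0] if H == 1 else concatenate(heads, axis=-1)
    return merged @ W_out


def _decoder_layer_t(X: Tensor, p: dict[str, Tensor], H: int, s: int,
                     mask: np.ndarray, drop_rate: float = 0.0,
                     rng: np.random.Generator | None = None) -> Tensor:
    attn = _attention_t(_layernorm_t(X, p["ln1_gamma"], p["ln1_beta"]),
                        p["attn_W_qkv"], p["attn_b"], p["attn_W_out"], H, mask, s)
    if drop_rate > 0 and rng is not None:
        keep = (rng.random(attn.shape) >= drop_rate) / (1.0 - drop_rate)
        attn = attn * keep
    X1 = X + attn
    hidden = (_layernorm_t(X1, p["ln2_gamma"], p["ln2_beta"]) @ p["ffn_W1"]
              + p["ffn_b1"]).relu()
    if drop_rate > 0 and rng is not None:
        keep = (rng.random(hidden.shape) >= drop_rate) / (1.0 - drop_rate)
        hidden = hidden * keep
    return X1 + hidden @ p["ffn_W2"] + p["ffn_b2"]


# ---------------------------------------------------------------------------
# functional operations (ndarray in, ndarray out)
# ---------------------------------------------------------------------------

def scm_attention(X: np.ndarray, weights: ScmAttentionWeights,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Multi-head scm-attention on (n_cells x n_sub x s)."""
    X = np.asarray(X, dtype=np.float64)
    if not all(np.all(np.isfinite(a)) for a in (weights.W_qkv, weights.b, weights.W_out)):
        raise ValueError("non-finite attention weights")
    n_sub = X.shape[1]
    if mask is None:
        mask = causal_mask(n_sub)
    out = _attention_t(Tensor(X), Tensor(weights.W_qkv), Tensor(weights.b),
                       Tensor(weights.W_out), weights.H, mask, weights.s)
    return out.data


def decoder_layer(X: np.ndarray, weights: DecoderLayerWeights,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """One pre-norm decoder layer (no dropout in the functional path)."""
    X = np.asarray(X, dtype=np.float64)
    s = weights.attention.s
    if mask is None:
        mask = causal_mask(X.shape[1])
    p = {
        "ln1_gamma": Tensor(weights.gamma1), "ln1_beta": Tensor(weights.beta1),
        "ln2_gamma": Tensor(weights.gamma2), "ln2_beta": Tensor(weights.beta2),
        "attn_W_qkv": Tensor(weights.attention.W_qkv),
        "attn_b": Tensor(weights.attention.b),
        "attn_W_out": Tensor(weights.attention.W_out),
        "ffn_W1": Tensor(weights.W1), "ffn_b1": Tensor(weights.b1),
        "ffn_W2": Tensor(weights.W2), "ffn_b2": Tensor(weights.b2),
    }
    return _decoder_layer_t(Tensor(X), p, weights.attention.H, s, mask).data


def pool_latent(X_decoder: np.ndarray,
                modality_slices: dict[str, slice]) -> dict[str, LatentRepresentation]:
    """Average-pool decoder output over each modality's positions."""
    X_decoder = np.asarray(X_decoder, dtype=np.float64)
    n_sub = X_decoder.shape[1]
    covered = []
    out = {}
    for name, sl in modality_slices.items():
        idx = range(*sl.indices(n_sub))
        if len(idx) == 0:
            raise ValueError(f"empty slice for modality {name}")
        covered.extend(idx)
        out[name] = LatentRepresentation(
            values=X_decoder[:, sl, :].mean(axis=1), modality=name
        )
    if sorted(covered) != list(range(n_sub)):
        raise ValueError("modality slices must partition the sub-vector positions")
    return out


def reconstruct(latent: np.ndarray, head: ReconstructionHead) -> np.ndarray:
    """Affine reconstruction: latent W1 + b1."""
    latent = np.asarray(latent, dtype=np.float64)
    if latent.shape[1] != head.W1.shape[0]:
        raise ValueError(
            f"latent width {latent.shape[1]} != head input {head.W1.shape[0]}"
        )
    return latent @ head.W1 + head.b1


# ---------------------------------------------------------------------------
# trainable model
# ---------------------------------------------------------------------------

class ScmFormerModel:
    """Decoder stack plus per-modality reconstruction heads.

    `modality_names` fixes the order in which modalities are concatenated
    along the sub-vector axis; `n_sub_per_mod` gives each modality's
    sub-vector count; `head_dims` maps head name -> output feature count.
    """

    def __init__(self, config: ScmModelConfig, modality_names: list[str],
                 n_sub_per_mod: list[int], head_dims: dict[str, int]):
        self.config = config
        self.modality_names = list(modality_names)
        self.n_sub_per_mod = [int(n) for n in n_sub_per_mod]
        self.head_dims = {k: int(v) for k, v in head_dims.items()}
        self.n_sub_total = sum(self.n_sub_per_mod)
        self._mask = causal_mask(self.n_sub_total)

        s = config.s
        rng = np.random.default_rng(config.seed)

        def normal(shape, scale):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        self.params: dict[str, Tensor] = {}
        self.params["pos_table"] = normal((self.n_sub_total, s), 0.02)
        self.params["mod_table"] = normal((len(modality_names), s), 0.02)
        for l in range(config.n_layers):
            pre = f"layer{l}_"
            self.params[pre + "attn_W_qkv"] = normal((s, 3 * s), 1.0 / np.sqrt(s))
            self.params[pre + "attn_b"] = Tensor(
                np.full(3 * s, 0.1), requires_grad=True
            )
            self.params[pre + "attn_W_out"] = normal((s, s), 1.0 / np.sqrt(s))
            for ln in ("ln1", "ln2"):
                self.params[pre + ln + "_gamma"] = Tensor(np.ones(s), requires_grad=True)
                self.params[pre + ln + "_beta"] = Tensor(np.zeros(s), requires_grad=True)
            self.params[pre + "ffn_W1"] = normal((s, 2 * s), 1.0 / np.sqrt(s))
            self.params[pre + "ffn_b1"] = Tensor(np.zeros(2 * s), requires_grad=True)
            self.params[pre + "ffn_W2"] = normal((2 * s, s), 1.0 / np.sqrt(2 * s))
            self.params[pre + "ffn_b2"] = Tensor(np.zeros(s), requires_grad=True)
        for name, v_out in self.head_dims.items():
            self.params[f"head_{name}_W"] = normal((s, v_out), 1.0 / np.sqrt(s))
            self.params[f"head_{name}_b"] = Tensor(np.zeros(v_out), requires_grad=True)

    # -- persistence ----------------------------------------------------------

    @property
    def meta(self) -> dict:
        return {
            "modality_names": self.modality_names,
            "n_sub_per_mod": self.n_sub_per_mod,
            "head_dims": self.head_dims,
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("parameter name mismatch on load")
        for k, v in state.items():
            if v.shape != self.params[k].data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: saved {v.shape}, "
                    f"expected {self.params[k].data.shape}"
                )
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    # -- forward --------------------------------------------------------------

    def modality_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, n in zip(self.modality_names, self.n_sub_per_mod):
            out[name] = slice(start, start + n)
            start += n
        return out

    def _layer_params(self, l: int) -> dict[str, Tensor]:
        pre = f"layer{l}_"
        return {k[len(pre):]: v for k, v in self.params.items() if k.startswith(pre)}

    def forward(self, sub_vectors: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[dict[str, Tensor], dict[str, Tensor]]:
        """Run the decoder on concatenated sub-vectors (n x n_sub_total x s).

        Returns (latents, reconstructions) as Tensors keyed by modality /
        head name, so losses stay differentiable.
        """
        sub_vectors = np.asarray(sub_vectors, dtype=np.float64)
        if sub_vectors.shape[1] != self.n_sub_total:
            raise ValueError(
                f"expected {self.n_sub_total} sub-vectors, got {sub_vectors.shape[1]}"
            )
        codes = np.concatenate([
            np.full(n, i) for i, n in enumerate(self.n_sub_per_mod)
        ])
        X = (Tensor(sub_vectors) + self.params["pos_table"]
             + self.params["mod_table"][codes])
        drop = self.config.drop_rate if training else 0.0
        for l in range(self.config.n_layers):
            X = _decoder_layer_t(X, self._layer_params(l), self.config.H,
                                 self.config.s, self._mask, drop, rng)
        latents = {}
        for name, sl in self.modality_slices().items():
            latents[name] = X[:, sl, :].mean(axis=1)
        recons = {}
        for name in self.head_dims:
            pooled = latents.get(name)
            if pooled is None:  # generation head fed from the full pooled latent
                pooled = X.mean(axis=1)
            recons[name] = pooled @ self.params[f"head_{name}_W"] \
                + self.params[f"head_{name}_b"]
        return latents, recons

    def forward_arrays(self, sub_vectors: np.ndarray
                       ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        """Inference-mode forward returning plain arrays (no dropout)."""
        latents, recons = self.forward(sub_vectors, training=False)
        return ({k: v.data for k, v in latents.items()},
                {k: v.data for k, v in recons.items()})
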