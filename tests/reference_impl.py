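"""Straight-line reference implementation of the decoder arithmetic.

Everything here is explicit Python loops over scalars — deliberately
independent of the package's vectorized/autodiff path so it can serve
as an oracle.
"""

import numpy as np

LN_EPS = 1e-5


def _relu(x: float) -> float:
    return x if x > 0.0 else 0.0


def ref_qkv(X, W, b):
    n, P, s = X.shape
    out = np.zeros((n, P, 3 * s))
    for i in range(n):
        for p in range(P):
            for o in range(3 * s):
                acc = b[o]
                for a in range(s):
                    acc += X[i, p, a] * W[a, o]
                out[i, p, o] = _relu(acc)
    return out


def ref_scm_attention(X, W, b, W_out, H, mask):
    n, P, s = X.shape
    qkv = ref_qkv(X, W, b)
    Q, K, V = qkv[:, :, :s], qkv[:, :, s:2 * s], qkv[:, :, 2 * s:]
    dh = s // H
    concat = np.zeros((n, P, s))
    for h in range(H):
        lo, hi = h * dh, (h + 1) * dh
        for i in range(n):
            for p in range(P):
                att = np.zeros(P)
                for q in range(P):
                    if not mask[p, q]:
                        att[q] = 0.0  # masked to -inf pre-ReLU
                        continue
                    score = 0.0
                    for d in range(lo, hi):
                        score += Q[i, p, d] * K[i, q, d]
                    att[q] = _relu(score / np.sqrt(s))
                for d in range(lo, hi):
                    acc = 0.0
                    for q in range(P):
                        acc += att[q] * V[i, q, d]
                    concat[i, p, d] = acc
    out = np.zeros((n, P, s))
    for i in range(n):
        for p in range(P):
            for o in range(s):
                acc = 0.0
                for d in range(s):
                    acc += concat[i, p, d] * W_out[d, o]
                out[i, p, o] = acc
    return out


def ref_layernorm(X, gamma, beta):
    n, P, s = X.shape
    out = np.zeros_like(X)
    for i in range(n):
        for p in range(P):
            z = X[i, p]
            mu = sum(z) / s
            var = sum((zi - mu) ** 2 for zi in z) / s
            sd = np.sqrt(var + LN_EPS)
            for j in range(s):
                out[i, p, j] = (z[j] - mu) / sd * gamma[j] + beta[j]
    return out


def ref_decoder_layer(X, w, mask):
    """w: DecoderLayerWeights-compatible object."""
    a = w.attention
    attn = ref_scm_attention(ref_layernorm(X, w.gamma1, w.beta1),
                             a.W_qkv, a.b, a.W_out, a.H, mask)
    X1 = X + attn
    n, P, s = X.shape
    out = X1.copy()
    ln = ref_layernorm(X1, w.gamma2, w.beta2)
    for i in range(n):
        for p in range(P):
            hidden = np.zeros(2 * s)
            for o in range(2 * s):
                acc = w.b1[o]
                for j in range(s):
                    acc += ln[i, p, j] * w.W1[j, o]
                hidden[o] = _relu(acc)
            for o in range(s):
                acc = w.b2[o]
                for j in range(2 * s):
                    acc += hidden[j] * w.W2[j, o]
                out[i, p, o] += acc
    return out


def ref_pool(X, sl):
    n, P, s = X.shape
    idx = list(range(P))[sl]
    out = np.zeros((n, s))
    for i in range(n):
        for j in range(s):
            acc = 0.0
            for p in idx:
                acc += X[i, p, j]
            out[i, j] = acc / len(idx)
    return out


def ref_reconstruct(latent, W, b):
    n, s = latent.shape
    v = W.shape[1]
    out = np.zeros((n, v))
    for i in range(n):
        for o in range(v):
            acc = b[o]
            for j in range(s):
                acc += latent[i, j] * W[j, o]
            out[i, o] = acc
    return out


def random_layer_weights(rng, s, H):
    """Random DecoderLayerWeights for oracle fixtures."""
    from scmformer.scm_model import DecoderLayerWeights, ScmAttentionWeights
    attn = ScmAttentionWeights(
        W_qkv=rng.normal(size=(s, 3 * s)),
        b=rng.normal(size=3 * s),
        H=H,
        W_out=rng.normal(size=(s, s)),
    )
    return DecoderLayerWeights(
        attention=attn,
        gamma1=rng.normal(1.0, 0.2, size=s), beta1=rng.normal(size=s),
        gamma2=rng.normal(1.0, 0.2, size=s), beta2=rng.normal(size=s),
        W1=rng.normal(size=(s, 2 * s)), b1=rng.normal(size=2 * s),
        W2=rng.normal(size=(2 * s, s)), b2=rng.normal(size=s),
    )
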