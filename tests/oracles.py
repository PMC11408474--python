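"""Independent scalar-loop reference implementations used to cross-check
the vectorized attention code.  Deliberately written with explicit Python
loops and no shared code with gaitphase.transformer."""

import math

import numpy as np


def softmax_row(row):
    m = max(row)
    e = [math.exp(v - m) for v in row]
    s = sum(e)
    return [v / s for v in e]


def multi_head_attention_loops(q_in, kv_in, W_Q, W_K, W_V, W_O, b_O,
                               n_heads, scale):
    """Nested-loop multi-head dot-product attention.

    q_in: (Sq, d), kv_in: (Sk, d); returns (out (Sq, d), attn (h, Sq, Sk)).
    """
    Sq, d = q_in.shape
    Sk = kv_in.shape[0]
    dh = d // n_heads

    def project(x, W):
        S = len(x)
        out = [[0.0] * d for _ in range(S)]
        for s in range(S):
            for j in range(d):
                acc = 0.0
                for k in range(d):
                    acc += x[s][k] * W[k][j]
                out[s][j] = acc
        return out

    Q = project(q_in.tolist(), W_Q.tolist())
    K = project(kv_in.tolist(), W_K.tolist())
    V = project(kv_in.tolist(), W_V.tolist())

    attn = np.zeros((n_heads, Sq, Sk))
    concat_heads = [[0.0] * d for _ in range(Sq)]
    for h in range(n_heads):
        lo = h * dh
        for s in range(Sq):
            scores = []
            for t in range(Sk):
                acc = 0.0
                for j in range(lo, lo + dh):
                    acc += Q[s][j] * K[t][j]
                scores.append(acc / scale)
            weights = softmax_row(scores)
            for t in range(Sk):
                attn[h, s, t] = weights[t]
            for j in range(lo, lo + dh):
                acc = 0.0
                for t in range(Sk):
                    acc += weights[t] * V[t][j]
                concat_heads[s][j] = acc

    out = np.zeros((Sq, d))
    for s in range(Sq):
        for j in range(d):
            acc = b_O[j]
            for k in range(d):
                acc += concat_heads[s][k] * W_O[k][j]
            out[s, j] = acc
    return out, attn
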