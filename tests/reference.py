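"""Scalar nested-loop reference implementation of the model's forward pass.

Deliberately independent of the package's vectorized/autograd path: every
matrix product, GRU update, softmax and aggregation is written as explicit
Python loops over floats. Used as the oracle for equivalence tests.
"""

from __future__ import annotations

import math


def _matvec(W, x):
    # W: list of rows [in][out] -> returns length-out list for input x
    n_in, n_out = len(W), len(W[0])
    return [sum(W[i][j] * x[i] for i in range(n_in)) for j in range(n_out)]


def _vadd(*vs):
    return [sum(parts) for parts in zip(*vs)]


def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def _softmax(scores):
    m = max(scores)
    es = [math.exp(s - m) for s in scores]
    z = sum(es)
    return [e / z for e in es]


def gru_step(p, prefix, h_prev, x):
    """One GRU update with separate z/r/n gates, scalar arithmetic."""
    W = lambda g: p[f"{prefix}_W{g}"].tolist()
    U = lambda g: p[f"{prefix}_U{g}"].tolist()
    b = lambda g: p[f"{prefix}_b{g}"].tolist()
    z = [_sigmoid(v) for v in _vadd(_matvec(W("z"), x), _matvec(U("z"), h_prev), b("z"))]
    r = [_sigmoid(v) for v in _vadd(_matvec(W("r"), x), _matvec(U("r"), h_prev), b("r"))]
    rh = [r[k] * h_prev[k] for k in range(len(h_prev))]
    n = [math.tanh(v) for v in _vadd(_matvec(W("n"), x), _matvec(U("n"), rh), b("n"))]
    return [(1.0 - z[k]) * n[k] + z[k] * h_prev[k] for k in range(len(n))]


def encode_site(p, side, ids, h_size):
    """One site's window -> (embedding w [2h], alpha [L])."""
    E = p["E"].tolist()
    xs = [E[int(i)] for i in ids]
    L = len(xs)
    hf, h = [], [0.0] * h_size
    for x in xs:
        h = gru_step(p, f"gru_{side}_fwd", h, x)
        hf.append(h)
    hb, h = [None] * L, [0.0] * h_size
    for j in range(L - 1, -1, -1):
        h = gru_step(p, f"gru_{side}_bwd", h, xs[j])
        hb[j] = h
    H = [hf[j] + hb[j] for j in range(L)]  # concat -> 2h
    Wt, bt = p[f"Ft_{side}_W"].tolist(), p[f"Ft_{side}_b"].tolist()
    ts = p[f"ts_{side}"].tolist()
    scores = []
    for j in range(L):
        t = [math.tanh(v) for v in _vadd(_matvec(Wt, H[j]), bt)]
        scores.append(sum(t[k] * ts[k] for k in range(len(ts))))
    alpha = _softmax(scores)
    w = [sum(alpha[j] * H[j][k] for j in range(L)) for k in range(len(H[0]))]
    return w, alpha


def cross_attention(W_a, W_d):
    """Lists of site embeddings -> (V_a, V_d, beta_a, beta_d)."""
    dot = lambda u, v: sum(ui * vi for ui, vi in zip(u, v))
    beta_a = [_softmax([dot(wa, wd) for wd in W_d]) for wa in W_a]
    beta_d = [_softmax([dot(wd, wa) for wa in W_a]) for wd in W_d]
    V_a = [
        [sum(row[j] * W_d[j][k] for j in range(len(W_d))) for k in range(len(W_d[0]))]
        for row in beta_a
    ]
    V_d = [
        [sum(row[i] * W_a[i][k] for i in range(len(W_a))) for k in range(len(W_a[0]))]
        for row in beta_d
    ]
    return V_a, V_d, beta_a, beta_d


def site_attention(p, side, V):
    Wc, bc = p[f"Fc_{side}_W"].tolist(), p[f"Fc_{side}_b"].tolist()
    cs = p[f"cs_{side}"].tolist()
    scores = []
    for v in V:
        c = [math.tanh(u) for u in _vadd(_matvec(Wc, v), bc)]
        scores.append(sum(c[k] * cs[k] for k in range(len(cs))))
    gamma = _softmax(scores)
    r = [sum(gamma[i] * V[i][k] for i in range(len(V))) for k in range(len(V[0]))]
    return r, gamma


def forward_record(params, h_size, acceptor_ids, donor_ids):
    """Full forward pass for one record; ids are [m][L] / [n][L] int lists."""
    p = params.arrays
    W_a, alpha_a = zip(*[encode_site(p, "a", ids, h_size) for ids in acceptor_ids])
    W_d, alpha_d = zip(*[encode_site(p, "d", ids, h_size) for ids in donor_ids])
    V_a, V_d, beta_a, beta_d = cross_attention(list(W_a), list(W_d))
    r_a, gamma_a = site_attention(p, "a", V_a)
    r_d, gamma_d = site_attention(p, "d", V_d)
    r = r_a + r_d
    hidden = [max(0.0, v) for v in _vadd(_matvec(p["Fr_W"].tolist(), r), p["Fr_b"].tolist())]
    logit = _vadd(_matvec(p["Fp_W"].tolist(), hidden), p["Fp_b"].tolist())[0]
    y_hat = _sigmoid(logit)
    return {
        "y_hat": y_hat,
        "alpha_a": list(alpha_a), "alpha_d": list(alpha_d),
        "beta_a": beta_a, "beta_d": beta_d,
        "gamma_a": gamma_a, "gamma_d": gamma_d,
    }


def bce_loss(y_hats, ys, params=None, lambda_l2=0.0):
    total = 0.0
    for yh, y in zip(y_hats, ys):
        yh = min(max(yh, 1e-7), 1.0 - 1e-7)
        total += -(y * math.log(yh) + (1.0 - y) * math.log(1.0 - yh))
    out = total / len(ys)
    if params is not None and lambda_l2 > 0:
        reg = 0.0
        for arr in params.arrays.values():
            reg += float(sum(x * x for x in arr.reshape(-1)))
        out += lambda_l2 * reg
    return out
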