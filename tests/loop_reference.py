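"""Independent scalar-loop reference for the encoder forward pass.

Implements the gate / attention / fusion / convolution chain with explicit
python loops and per-row softmaxes — no shared code with the package's
vectorized implementation.  Slow by design; use only on b <= ~8.
"""

import math

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x)) if x >= 0 else \
        math.exp(x) / (1.0 + math.exp(x))


def gate(X, P, B):
    n, c = X.shape
    out = np.zeros((n, c))
    for i in range(n):
        for j in range(c):
            s = B[j]
            for k in range(c):
                s += X[i, k] * P[k, j]
            out[i, j] = X[i, j] * _sigmoid(s)
    return out


def _softmax(row):
    m = max(row)
    e = [math.exp(v - m) for v in row]
    s = sum(e)
    return [v / s for v in e]


def attention_layer(I, deg, D, P, B, conv=False):
    b, c = D.shape
    Dp = np.zeros((b, c))
    if conv:
        for i in range(b):
            for j in range(c):
                Dp[i, j] = sum(I[i, m] * D[m, j] for m in range(b))
    else:
        S = np.zeros((b, b))
        for i in range(b):
            for j in range(b):
                S[i, j] = sum(I[i, m] * D[m, k] * D[j, k]
                              for m in range(b) for k in range(c))
        for i in range(b):
            w = _softmax(list(S[i]))
            for j in range(c):
                Dp[i, j] = sum(w[m] * D[m, j] for m in range(b))
    out = np.zeros((b, c))
    for i in range(b):
        for j in range(c):
            pre = B[j] + sum(Dp[i, k] * P[k, j] for k in range(c))
            val = pre if pre > 0 else 0.0
            out[i, j] = val / deg[i] if deg[i] > 0 else 0.0
    return out


def branch(I, deg, D0, Pg, Bg, Pm, Bm, L, conv=False):
    layers = [gate(D0, Pg, Bg)]
    for _ in range(L):
        layers.append(attention_layer(I, deg, layers[-1], Pm, Bm, conv=conv))
    mean = sum(layers) / (L + 1)
    return mean, layers


def forward(values, incidences_I, incidences_deg, R, L, enabled,
            conv=False):
    """Full reference pass; `values` is the name -> ndarray parameter dict."""
    D0, M0 = values["D0"], values["M0"]
    b, c = D0.shape
    means, layer_lists = {}, {}
    for x in enabled:
        means[x], layer_lists[x] = branch(
            incidences_I[x], incidences_deg[x], D0,
            values[f"P_g_{x}"], values[f"B_g_{x}"],
            values[f"P_m_{x}"], values[f"B_m_{x}"], L, conv=conv)
    omega = np.zeros((b, len(enabled)))
    if enabled:
        scores = np.zeros((b, len(enabled)))
        a, Pa = values["a"], values["P_a"]
        for col, x in enumerate(enabled):
            for i in range(b):
                scores[i, col] = sum(means[x][i, k] * Pa[k, l] * a[l]
                                     for k in range(c) for l in range(c))
        for i in range(b):
            omega[i] = _softmax(list(scores[i]))
    Ds = np.zeros((b, c))
    for col, x in enumerate(enabled):
        for i in range(b):
            for j in range(c):
                Ds[i, j] += omega[i, col] * means[x][i, j]

    t = M0.shape[0]
    deg_row = [sum(R[i]) for i in range(b)]
    deg_col = [sum(R[:, j]) for j in range(t)]
    Dc = [gate(D0, values["P_g_c"], values["b_g_c"])]
    M = [M0.copy()]
    Dm = []
    for l in range(L + 1):
        cur = np.zeros((b, c))
        for col, x in enumerate(enabled):
            for i in range(b):
                for j in range(c):
                    cur[i, j] += omega[i, col] * layer_lists[x][l][i, j]
        cur += 0.5 * Dc[l]
        Dm.append(cur)
        if l < L:
            nxt = np.zeros((b, c))
            for i in range(b):
                for j in range(c):
                    pre = values["b_m_c"][j] + sum(
                        R[i, e] * M[l][e, k] * values["P_m_c"][k, j]
                        for e in range(t) for k in range(c))
                    val = pre if pre > 0 else 0.0
                    nxt[i, j] = val / deg_row[i] if deg_row[i] > 0 else 0.0
            Dc.append(nxt)
            nxtM = np.zeros((t, c))
            for e in range(t):
                for j in range(c):
                    pre = values["b_t_c"][j] + sum(
                        R[i, e] * Dm[l][i, k] * values["P_t_c"][k, j]
                        for i in range(b) for k in range(c))
                    val = pre if pre > 0 else 0.0
                    nxtM[e, j] = val / deg_col[e] if deg_col[e] > 0 else 0.0
            M.append(nxtM)
    D = Ds + sum(Dm) / (L + 1)
    Mfin = sum(M) / (L + 1)
    return {"D": D, "M": Mfin, "omega": omega, "Ds": Ds, "means": means}


def bpr_reference(triples, D, M, theta=None, delta=0.0):
    total = 0.0
    for d, i, j in triples:
        sp = sum(D[d, k] * M[i, k] for k in range(D.shape[1]))
        sn = sum(D[d, k] * M[j, k] for k in range(D.shape[1]))
        total += -math.log(_sigmoid(sp - sn))
    if theta is not None and delta:
        total += delta * sum(float((p ** 2).sum()) for p in theta)
    return total


def ssl_reference(D, values, incidences_I, enabled, perms):
    total = 0.0
    for x in enabled:
        I = incidences_I[x]
        b, c = D.shape
        Dx = gate(D, values[f"P_sg_{x}"], values[f"b_sg_{x}"])
        S = np.zeros((b, c))
        valid = []
        for d in range(b):
            nnz = [v for v in range(b) if I[d, v] > 0]
            if nnz:
                valid.append(d)
                for j in range(c):
                    S[d, j] = sum(I[d, v] * Dx[v, j] for v in range(b)) / len(nnz)
        if not valid:
            continue
        g = S[valid].sum(axis=0) / len(valid)
        rp, cp = perms[x]
        Sneg = S[rp][:, cp]
        for d in valid:
            f1 = float(Dx[d] @ S[d]) - float(Dx[d] @ Sneg[d])
            f2 = float(S[d] @ g) - float(Sneg[d] @ g)
            total += -math.log(_sigmoid(f1)) - math.log(_sigmoid(f2))
    return total
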