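"""Independent naive-loop oracles for every pipeline equation.

Each function is a direct transcription of the defining formulas using
explicit Python loops (including hand-rolled matrix products), kept free of
any code from the package so it can serve as an independent reference on
small instances.
"""

from __future__ import annotations

import numpy as np


def hamming_oracle(MD, side):
    MD = np.asarray(MD, dtype=float)
    if side == "mirna":
        MD = MD.T
    n_comp, n_ent = MD.shape
    S = np.zeros((n_ent, n_ent))
    for i in range(n_ent):
        for j in range(n_ent):
            mismatches = 0
            for k in range(n_comp):
                if MD[k, i] != MD[k, j]:
                    mismatches += 1
            S[i, j] = 1 - mismatches / n_comp
    return S


def top_k_oracle(S, i, k):
    n = S.shape[0]
    order = sorted(range(n), key=lambda j: (-S[i, j], j))
    top = order[:k]
    if i not in top:
        top = order[: k - 1] + [i]
    return top


def sparse_kernel_oracle(S, k):
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    P = np.zeros((n, n))
    for i in range(n):
        nbrs = top_k_oracle(S, i, k)
        denom = sum(S[i, j] for j in nbrs)
        if denom > 0:
            for j in nbrs:
                P[i, j] = S[i, j] / denom
        else:
            P[i, i] = 1.0
    return P


def initial_status_oracle(A, B, C):
    mats = [np.asarray(m, dtype=float) for m in (A, B, C)]
    n = mats[0].shape[0]
    out = [np.zeros_like(m) for m in mats]
    for i in range(n):
        for j in range(n):
            tot = mats[0][i, j] + mats[1][i, j] + mats[2][i, j]
            if tot > 0:
                for x in range(3):
                    out[x][i, j] = mats[x][i, j] / tot
    return out


def _matmul_oracle(A, B):
    n, m = A.shape
    m2, p = B.shape
    assert m == m2
    C = np.zeros((n, p))
    for i in range(n):
        for j in range(p):
            acc = 0.0
            for k in range(m):
                acc += A[i, k] * B[k, j]
            C[i, j] = acc
    return C


def cross_diffusion_oracle(norm, P, iterations, delta):
    init = [np.asarray(m, dtype=float).copy() for m in norm]
    cur = [m.copy() for m in init]
    for _ in range(iterations):
        nxt = []
        for x in range(3):
            y, z = (x + 1) % 3, (x + 2) % 3
            avg_cur = (cur[y] + cur[z]) / 2
            diff = _matmul_oracle(_matmul_oracle(P[x], avg_cur), P[x].T)
            nxt.append(delta * diff + (1 - delta) * (init[y] + init[z]) / 2)
        cur = nxt
    return cur


def weight_matrix_oracle(S_temp, k):
    S_temp = np.asarray(S_temp, dtype=float)
    n = S_temp.shape[0]
    sets = [set(top_k_oracle(S_temp, i, k)) for i in range(n)]
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            in_ij = j in sets[i]
            in_ji = i in sets[j]
            if in_ij and in_ji:
                W[i, j] = 1.0
            elif not in_ij and not in_ji:
                W[i, j] = 0.0
            else:
                W[i, j] = 0.5
    return W


def fuse_oracle(S_a, S_b, S_c, k, iterations, delta):
    P = [sparse_kernel_oracle(S, k) for S in (S_a, S_b, S_c)]
    norm = initial_status_oracle(S_a, S_b, S_c)
    diffused = cross_diffusion_oracle(norm, P, iterations, delta)
    S_temp = (diffused[0] + diffused[1] + diffused[2]) / 3
    W = weight_matrix_oracle(S_temp, k)
    return S_temp * W, S_temp, W


def mirna_network_oracle(MD, MM_star, alpha):
    MD = np.asarray(MD, dtype=float)
    n_m, n_d = MD.shape
    MDm = np.zeros_like(MD)
    for i in range(n_m):
        for j in range(n_d):
            contrib = 0.0
            for k in range(n_m):
                if k != i:
                    contrib += MM_star[i, k] * MD[k, j]
            MDm[i, j] = MD[i, j] + alpha * contrib
    return MDm


def disease_network_oracle(MD, DD_star, beta):
    MD = np.asarray(MD, dtype=float)
    n_m, n_d = MD.shape
    MDd = np.zeros_like(MD)
    for i in range(n_m):
        for j in range(n_d):
            contrib = 0.0
            for k in range(n_d):
                if k != j:
                    contrib += MD[i, k] * DD_star[k, j]
            MDd[i, j] = MD[i, j] + beta * contrib
    return MDd


def projection_oracle(MDd, MDm, MM_star, DD_star, gamma):
    n_m, n_d = MDd.shape
    Fpm = np.zeros((n_d, n_m))
    for i in range(n_d):
        for j in range(n_m):
            dot = 0.0
            norm_sq = 0.0
            for k in range(n_m):
                dot += MDd.T[i, k] * MM_star[k, j]
                norm_sq += MM_star[k, j] ** 2
            Fpm[i, j] = dot / np.sqrt(norm_sq) if norm_sq > 0 else 0.0
    Fpd = np.zeros((n_m, n_d))
    for i in range(n_m):
        for j in range(n_d):
            dot = 0.0
            norm_sq = 0.0
            for k in range(n_d):
                dot += MDm[i, k] * DD_star[k, j]
                norm_sq += DD_star[k, j] ** 2
            Fpd[i, j] = dot / np.sqrt(norm_sq) if norm_sq > 0 else 0.0
    Fpf = (1 - gamma) * Fpm.T + gamma * Fpd
    return Fpm, Fpd, Fpf


def auc_rank_oracle(positives, negatives):
    """Tie-aware Mann-Whitney AUC by brute-force pairwise comparison."""
    wins = 0.0
    for p in positives:
        for q in negatives:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(positives) * len(negatives))


def random_kernel(rng, n):
    """Random symmetric similarity matrix with unit diagonal, entries in [0,1]."""
    A = rng.random((n, n))
    S = (A + A.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


def random_instance(rng, n_m, n_d, density=0.3):
    """Random association matrix plus four random kernels."""
    MD = (rng.random((n_m, n_d)) < density).astype(float)
    # guarantee at least one association so evaluation protocols are runnable
    if MD.sum() == 0:
        MD[rng.integers(n_m), rng.integers(n_d)] = 1.0
    return (
        MD,
        random_kernel(rng, n_m),
        random_kernel(rng, n_m),
        random_kernel(rng, n_d),
        random_kernel(rng, n_d),
    )
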