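"""Multi-kernel similarity fusion by sparse-kernel cross-diffusion.

Three similarity kernels per entity type (for miRNAs: functional, sequence,
Hamming; for diseases: semantic, functional, Hamming) are blended into one
integrated kernel in four steps:

1. each kernel is restricted to every entity's k nearest neighbors and
   row-normalized over that support (sparse kernel);
2. each kernel is ratio-normalized entrywise against the sum of all three
   (initial status);
3. the three kernels cross-diffuse for a fixed number of rounds: each next
   state is ``delta * P_x (avg of the other two current states) P_x^T +
   (1 - delta) * (avg of the other two initial states)``, with all three
   next states computed from the same previous states so the result does
   not depend on update order;
4. the three diffused kernels are averaged and multiplied elementwise by a
   neighbor-agreement weight matrix (1 for mutual top-k neighbors, 0 for
   mutual strangers, 0.5 otherwise) to suppress noise.
"""

from __future__ import annotations

import numpy as np

from .types import (
    FusedSimilarity,
    FusionConfig,
    KernelMatrix,
    SparseKernel,
    ValidationError,
)

__all__ = [
    "sparse_kernel",
    "initial_status",
    "cross_diffusion",
    "neighbor_weight_matrix",
    "fuse",
]


def _top_k_neighbors(S: np.ndarray, k: int) -> list[list[int]]:
    """Per-row k-nearest-neighbor index lists, self always included.

    Rows are ranked by similarity descending with ties broken by ascending
    entity index, which keeps the selection deterministic across platforms.
    """
    n = S.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"neighbor count k={k} must lie in [1, {n}]")
    sets: list[list[int]] = []
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, -S[i]))  # similarity desc, index asc
        top = list(order[:k])
        if i not in top:
            top = list(order[: k - 1]) + [i]
        sets.append(top)
    return sets


def sparse_kernel(kernel: KernelMatrix | np.ndarray, k: int) -> SparseKernel:
    """Restrict a kernel to k-nearest-neighbor support and row-normalize.

    P(i, j) = S(i, j) / sum_{l in N_i} S(i, l) for j in N_i, else 0. A row
    whose neighbor mass is zero falls back to the self-only row P(i, i) = 1.
    """
    S = kernel.S if isinstance(kernel, KernelMatrix) else np.asarray(kernel, dtype=float)
    sets = _top_k_neighbors(S, k)
    n = S.shape[0]
    P = np.zeros_like(S)
    for i, nbrs in enumerate(sets):
        mass = S[i, nbrs].sum()
        if mass > 0:
            P[i, nbrs] = S[i, nbrs] / mass
        else:
            P[i, i] = 1.0
    return SparseKernel(P, sets)


def initial_status(
    S_a: KernelMatrix | np.ndarray,
    S_b: KernelMatrix | np.ndarray,
    S_c: KernelMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ratio-normalize three kernels entrywise against their sum.

    Where the three-way sum is zero all three outputs are set to 0 (no
    similarity is invented); elsewhere the outputs sum to exactly 1.
    """
    mats = [m.S if isinstance(m, KernelMatrix) else np.asarray(m, dtype=float) for m in (S_a, S_b, S_c)]
    if not (mats[0].shape == mats[1].shape == mats[2].shape):
        raise ValidationError("kernels must share a common shape")
    total = mats[0] + mats[1] + mats[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = tuple(np.where(total > 0, m / np.where(total > 0, total, 1.0), 0.0) for m in mats)
    return out


def cross_diffusion(
    normalized: tuple[np.ndarray, np.ndarray, np.ndarray],
    sparse: tuple[SparseKernel, SparseKernel, SparseKernel],
    cfg: FusionConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the three-way cross-diffusion for ``cfg.iterations`` rounds.

    Within a round every kernel is updated from the previous round's states
    (Jacobi style). With delta=0 the diffusion term vanishes and every
    kernel is the constant average of the other two initial states.
    """
    init = [np.asarray(m, dtype=float) for m in normalized]
    P = [sk.P for sk in sparse]
    if any(p.shape != init[0].shape for p in P + init):
        raise ValidationError("normalized matrices and sparse kernels must share one shape")
    cur = [m.copy() for m in init]
    d = cfg.delta
    for _ in range(cfg.iterations):
        nxt = []
        for x in range(3):
            y, z = (x + 1) % 3, (x + 2) % 3
            diff = P[x] @ ((cur[y] + cur[z]) / 2) @ P[x].T
            nxt.append(d * diff + (1 - d) * (init[y] + init[z]) / 2)
        cur = nxt
    return tuple(cur)


def neighbor_weight_matrix(S_temp: np.ndarray, k: int) -> np.ndarray:
    """Agreement weights from mutual k-nearest-neighborhood in ``S_temp``.

    W(i, j) = 1 if i and j are in each other's neighbor sets, 0 if in
    neither, 0.5 otherwise; the diagonal is 1 since every entity is its own
    neighbor.
    """
    S_temp = np.asarray(S_temp, dtype=float)
    sets = _top_k_neighbors(S_temp, k)
    n = S_temp.shape[0]
    member = np.zeros((n, n), dtype=bool)
    for i, nbrs in enumerate(sets):
        member[i, nbrs] = True
    W = np.where(member & member.T, 1.0, np.where(member | member.T, 0.5, 0.0))
    return W


def fuse(
    kernel_a: KernelMatrix,
    kernel_b: KernelMatrix,
    kernel_c: KernelMatrix,
    cfg: FusionConfig,
) -> FusedSimilarity:
    """Full fusion pipeline for one entity side.

    The three kernels play symmetric roles; the output is invariant to the
    order they are passed in.
    """
    if not (kernel_a.entity_names == kernel_b.entity_names == kernel_c.entity_names):
        raise ValidationError("kernels must be aligned on the same entity names")
    kernels = (kernel_a, kernel_b, kernel_c)
    sparse = tuple(sparse_kernel(k, cfg.k_neighbors) for k in kernels)
    norm = initial_status(*kernels)
    diffused = cross_diffusion(norm, sparse, cfg)
    S_temp = (diffused[0] + diffused[1] + diffused[2]) / 3
    S_temp = (S_temp + S_temp.T) / 2  # symmetric inputs give symmetric output; kill float drift
    W = neighbor_weight_matrix(S_temp, cfg.k_neighbors)
    S_star = S_temp * W
    return FusedSimilarity(S_star, S_temp, W)
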