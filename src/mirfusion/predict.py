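"""Weighted bipartite networks and space-projection scores.

The Boolean association matrix is enriched with similarity-propagated
contributions (alpha on the miRNA side, beta on the disease side) and each
enriched network is projected onto the opposite similarity space: a pair's
score is the inner product of the entity's weighted association profile with
the partner's similarity column, normalized by that column's Euclidean norm
(a cosine-like projection). The final score blends the miRNA-space and
disease-space projections with weight gamma.
"""

from __future__ import annotations

import numpy as np

from .fusion import fuse
from .similarity import hamming_similarity
from .types import (
    AssociationData,
    FusedSimilarity,
    KernelMatrix,
    ModelConfig,
    ScoreMatrix,
    ValidationError,
    WeightedNetwork,
)

__all__ = [
    "mirna_weighted_network",
    "disease_weighted_network",
    "space_projection",
    "fuse_both_sides",
    "predict_full",
]


def _star(S: FusedSimilarity | np.ndarray) -> np.ndarray:
    return S.S_star if isinstance(S, FusedSimilarity) else np.asarray(S, dtype=float)


def mirna_weighted_network(
    assoc: AssociationData, MMis_star: FusedSimilarity | np.ndarray, alpha: float
) -> np.ndarray:
    """MDm(i,j) = MD(i,j) + alpha * sum_{k != i} MMis*(i,k) MD(k,j)."""
    S = _star(MMis_star)
    if S.shape[0] != assoc.n_mirna:
        raise ValidationError("miRNA kernel dimension does not match association matrix")
    S0 = S.copy()
    np.fill_diagonal(S0, 0.0)  # self term excluded
    return assoc.MD + alpha * (S0 @ assoc.MD)


def disease_weighted_network(
    assoc: AssociationData, DDis_star: FusedSimilarity | np.ndarray, beta: float
) -> np.ndarray:
    """MDd(i,j) = MD(i,j) + beta * sum_{k != j} MD(i,k) DDis*(k,j)."""
    S = _star(DDis_star)
    if S.shape[0] != assoc.n_disease:
        raise ValidationError("disease kernel dimension does not match association matrix")
    S0 = S.copy()
    np.fill_diagonal(S0, 0.0)
    return assoc.MD + beta * (assoc.MD @ S0)


def _project(profiles: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Project rows of ``profiles`` onto the columns of ``S``, norm-scaled.

    Columns of S with zero norm yield score 0 for every row.
    """
    norms = np.linalg.norm(S, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    out = (profiles @ S) / safe
    out[:, norms == 0] = 0.0
    return out


def space_projection(
    MDd: np.ndarray,
    MDm: np.ndarray,
    MMis_star: FusedSimilarity | np.ndarray,
    DDis_star: FusedSimilarity | np.ndarray,
    gamma: float,
    assoc: AssociationData,
) -> ScoreMatrix:
    """Combine miRNA-space and disease-space projections into final scores.

    Fpm(i,j) = <MDd^T(i,:), MMis*(:,j)> / ||MMis*(:,j)||  (disease-by-miRNA)
    Fpd(i,j) = <MDm(i,:),  DDis*(:,j)> / ||DDis*(:,j)||   (miRNA-by-disease)
    Fpf      = (1 - gamma) * Fpm^T + gamma * Fpd
    """
    Sm = _star(MMis_star)
    Sd = _star(DDis_star)
    Fpm = _project(MDd.T, Sm)
    Fpd = _project(MDm, Sd)
    Fpf = (1 - gamma) * Fpm.T + gamma * Fpd
    return ScoreMatrix(
        list(assoc.mirna_names),
        list(assoc.disease_names),
        Fpm,
        Fpd,
        Fpf,
        assoc.MD.copy(),
    )


def fuse_both_sides(
    assoc: AssociationData, kernels: dict[str, KernelMatrix], cfg: ModelConfig
) -> tuple[FusedSimilarity, FusedSimilarity]:
    """Hamming kernels from the (possibly masked) associations, then fusion.

    ``kernels`` maps the four externally supplied kernels:
    ``mirna_functional``, ``mirna_sequence``, ``disease_semantic``,
    ``disease_functional``.
    """
    mm_h = hamming_similarity(assoc, "mirna")
    dd_h = hamming_similarity(assoc, "disease")
    for key, names in (
        ("mirna_functional", assoc.mirna_names),
        ("mirna_sequence", assoc.mirna_names),
        ("disease_semantic", assoc.disease_names),
        ("disease_functional", assoc.disease_names),
    ):
        if key not in kernels:
            raise ValidationError(f"missing kernel {key!r}")
        if kernels[key].entity_names != list(names):
            raise ValidationError(f"kernel {key!r} is not aligned with the association names")
    k_m = min(cfg.fusion.k_neighbors, assoc.n_mirna)
    k_d = min(cfg.fusion.k_neighbors, assoc.n_disease)
    cfg_m = type(cfg.fusion)(k_neighbors=k_m, iterations=cfg.fusion.iterations, delta=cfg.fusion.delta)
    cfg_d = type(cfg.fusion)(k_neighbors=k_d, iterations=cfg.fusion.iterations, delta=cfg.fusion.delta)
    mm = fuse(kernels["mirna_functional"], kernels["mirna_sequence"], mm_h, cfg_m)
    dd = fuse(kernels["disease_semantic"], kernels["disease_functional"], dd_h, cfg_d)
    return mm, dd


def predict_full(
    assoc: AssociationData,
    kernels: dict[str, KernelMatrix],
    cfg: ModelConfig | None = None,
    fused: tuple[FusedSimilarity, FusedSimilarity] | None = None,
) -> ScoreMatrix:
    """Run the whole pipeline: Hamming kernels, fusion, weighting, projection.

    Deterministic given inputs and configuration. ``fused`` lets callers
    reuse precomputed fused similarities (the non-reference fast
    cross-validation mode); by default both sides are fused from scratch.
    """
    cfg = cfg or ModelConfig()
    if fused is None:
        fused = fuse_both_sides(assoc, kernels, cfg)
    mm, dd = fused
    MDm = mirna_weighted_network(assoc, mm, cfg.alpha)
    MDd = disease_weighted_network(assoc, dd, cfg.beta)
    return space_projection(MDd, MDm, mm, dd, cfg.gamma, assoc)
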