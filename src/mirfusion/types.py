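"""Core data containers for the fusion/projection pipeline.

All matrices are plain ``numpy.ndarray`` objects carried alongside ordered
identifier lists; the canonical entity order everywhere in the package is
lexicographic over identifiers, fixed once at load/generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "AssociationData",
    "KernelMatrix",
    "FusionConfig",
    "ModelConfig",
    "SparseKernel",
    "FusedSimilarity",
    "WeightedNetwork",
    "ScoreMatrix",
    "EvalReport",
    "KERNEL_LABELS",
]

KERNEL_LABELS = ("functional", "sequence", "semantic", "hamming")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class AssociationData:
    """Boolean bipartite miRNA-disease association matrix with entity names.

    ``MD[i, j] == 1`` records an experimentally verified association between
    miRNA ``mirna_names[i]`` and disease ``disease_names[j]``; unlisted pairs
    are 0 (unverified, not necessarily absent).
    """

    mirna_names: list[str]
    disease_names: list[str]
    MD: np.ndarray

    def __post_init__(self) -> None:
        self.MD = np.asarray(self.MD, dtype=float)
        if len(set(self.mirna_names)) != len(self.mirna_names):
            raise ValidationError("duplicate miRNA identifiers")
        if len(set(self.disease_names)) != len(self.disease_names):
            raise ValidationError("duplicate disease identifiers")
        if len(self.mirna_names) < 2 or len(self.disease_names) < 2:
            raise ValidationError("need at least 2 miRNAs and 2 diseases")
        if self.MD.shape != (len(self.mirna_names), len(self.disease_names)):
            raise ValidationError(
                f"association matrix shape {self.MD.shape} does not match "
                f"{len(self.mirna_names)} miRNAs x {len(self.disease_names)} diseases"
            )
        if not np.isin(self.MD, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(self.MD, (0.0, 1.0)))[0]
            raise ValidationError(
                f"association entries must be 0 or 1; found "
                f"{self.MD[tuple(bad)]!r} at ({self.mirna_names[bad[0]]}, "
                f"{self.disease_names[bad[1]]})"
            )

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_names)

    @property
    def n_disease(self) -> int:
        return len(self.disease_names)

    @property
    def n_associations(self) -> int:
        return int(self.MD.sum())

    def copy(self) -> "AssociationData":
        return AssociationData(list(self.mirna_names), list(self.disease_names), self.MD.copy())


@dataclass
class KernelMatrix:
    """One named square similarity kernel, symmetric with unit diagonal."""

    entity_names: list[str]
    S: np.ndarray
    label: str

    _SYM_TOL = 1e-8

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.entity_names)
        if self.S.shape != (n, n):
            raise ValidationError(f"kernel shape {self.S.shape} does not match {n} names")
        if self.label not in KERNEL_LABELS:
            raise ValidationError(f"unknown kernel label {self.label!r}; expected one of {KERNEL_LABELS}")
        asym = np.abs(self.S - self.S.T)
        if asym.size and asym.max() > self._SYM_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"kernel asymmetric: S({self.entity_names[i]},{self.entity_names[j]})="
                f"{self.S[i, j]:.6g} vs {self.S[j, i]:.6g}"
            )
        diag = np.diag(self.S)
        if n and np.abs(diag - 1.0).max() > self._SYM_TOL:
            i = int(np.argmax(np.abs(diag - 1.0)))
            raise ValidationError(
                f"kernel diagonal must be 1; S({self.entity_names[i]},"
                f"{self.entity_names[i]})={diag[i]:.6g}"
            )
        np.fill_diagonal(self.S, 1.0)
        if self.S.size and (self.S.min() < -self._SYM_TOL or self.S.max() > 1 + self._SYM_TOL):
            raise ValidationError("kernel entries must lie in [0, 1]")
        np.clip(self.S, 0.0, 1.0, out=self.S)

    @property
    def n(self) -> int:
        return len(self.entity_names)


@dataclass
class FusionConfig:
    """Knobs of the sparse-kernel cross-diffusion step.

    ``k_neighbors`` is the per-entity neighbor-set size (self included) used
    both for the sparse kernels and the agreement weight matrix; ``iterations``
    the number of diffusion rounds; ``delta`` the diffusion-vs-initial weight.
    """

    k_neighbors: int = 36
    iterations: int = 10
    delta: float = 0.1

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValidationError("delta must lie in [0, 1]")


@dataclass
class ModelConfig:
    """Full model configuration: projection weights plus fusion settings.

    alpha/beta weight the similarity-propagated contributions in the
    miRNA/disease weighted networks; gamma blends miRNA-space and
    disease-space projection scores (gamma=0 -> miRNA space only).
    Defaults are the reference operating point of the method.
    """

    alpha: float = 0.02
    beta: float = 0.02
    gamma: float = 0.27
    fusion: FusionConfig = field(default_factory=FusionConfig)
    fast_loocv: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SparseKernel:
    """Row-normalized kernel restricted to each row's k nearest neighbors."""

    P: np.ndarray
    neighbor_sets: list[list[int]]


@dataclass
class FusedSimilarity:
    """Integrated similarity after cross-diffusion and neighbor weighting.

    ``S_star = S_temp * W`` elementwise, where S_temp averages the three
    diffused kernels and W scores neighbor agreement in {0, 0.5, 1}.
    """

    S_star: np.ndarray
    S_temp: np.ndarray
    W: np.ndarray


@dataclass
class WeightedNetwork:
    """Similarity-reweighted association matrices (miRNA side / disease side)."""

    MDm: np.ndarray
    MDd: np.ndarray


@dataclass
class ScoreMatrix:
    """Projection scores for every miRNA-disease pair.

    Fpm is disease-by-miRNA (miRNA-space projection), Fpd miRNA-by-disease
    (disease-space projection), and Fpf the gamma-blended final score,
    miRNA-by-disease. ``known_mask`` copies the association matrix the scores
    were computed from so ranking/evaluation can exclude verified pairs;
    scores themselves are never zeroed at known positions.
    """

    mirna_names: list[str]
    disease_names: list[str]
    Fpm: np.ndarray | None
    Fpd: np.ndarray | None
    Fpf: np.ndarray
    known_mask: np.ndarray


@dataclass
class EvalReport:
    """Outcome of one cross-validation protocol run.

    ``roc_points`` is an (n, 2) array of (FPR, TPR) pairs from the pooled
    threshold sweep; ``fold_records`` a DataFrame with one row per fold.
    """

    auc: float
    roc_points: np.ndarray
    fold_records: "object"  # pandas.DataFrame
    protocol: str
    config_used: ModelConfig
    positive_scores: np.ndarray | None = None
    negative_scores: np.ndarray | None = None
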