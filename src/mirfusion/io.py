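"""Readers and writers for the package's TSV formats.

Associations travel either as a tab-separated edge list ``mirna_id
disease_id [0/1]`` (no header; unlisted pairs are 0) or as a named 0/1
matrix with a header row and first-column row names. Kernels and scores are
named TSV matrices / long tables. Entity order is canonicalized to
lexicographic everywhere so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    AssociationData,
    FusionConfig,
    KernelMatrix,
    ModelConfig,
    ScoreMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_association_table",
    "write_association_matrix",
    "read_kernel_matrix",
    "write_kernel_matrix",
    "write_scores",
    "read_scores",
    "read_config",
    "write_config",
]


def read_association_table(path: str | Path, format: str = "edge_list") -> AssociationData:
    """Load an association table from an edge list or a named 0/1 matrix.

    Edge-list rows are ``(mirna_id, disease_id)`` or
    ``(mirna_id, disease_id, flag)`` with flag in {0, 1}; a pair listed with
    flag 0 contributes its entities but no association. Names are sorted
    lexicographically in the returned object.
    """
    path = Path(path)
    if format == "edge_list":
        return _read_edge_list(path)
    if format == "matrix":
        return _read_association_matrix(path)
    raise ValidationError(f"unknown association format {format!r}")


def _read_edge_list(path: Path) -> AssociationData:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"no associations in {path}") from None
    if df.shape[1] == 2:
        df[2] = "1"
    elif df.shape[1] != 3:
        raise ValidationError(
            f"{path}: edge list must have 2 or 3 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = ["mirna", "disease", "flag"]
    flags = {}
    for row_no, (m, d, f) in enumerate(df.itertuples(index=False), start=1):
        if f not in ("0", "1"):
            raise ValidationError(f"{path}: row {row_no} has non-0/1 value {f!r}")
        v = int(f)
        key = (m, d)
        if key in flags and flags[key] != v:
            raise ValidationError(f"{path}: conflicting entries for pair ({m}, {d})")
        flags[key] = v
    if not flags:
        raise ValidationError(f"no associations in {path}")
    mirnas = sorted({m for m, _ in flags})
    diseases = sorted({d for _, d in flags})
    mi = {m: i for i, m in enumerate(mirnas)}
    di = {d: j for j, d in enumerate(diseases)}
    MD = np.zeros((len(mirnas), len(diseases)))
    for (m, d), v in flags.items():
        MD[mi[m], di[d]] = v
    return AssociationData(mirnas, diseases, MD)


def _read_association_matrix(path: Path) -> AssociationData:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"no associations in {path}") from None
    if df.empty:
        raise ValidationError(f"no associations in {path}")
    vals = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isin(vals, (0.0, 1.0)))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{path}: cell ({df.index[i]}, {df.columns[j]}) holds {vals[i, j]!r}, expected 0 or 1"
        )
    df = df.sort_index(axis=0).sort_index(axis=1)
    return AssociationData(
        [str(x) for x in df.index], [str(x) for x in df.columns], df.to_numpy(dtype=float)
    )


def write_association_matrix(assoc: AssociationData, path: str | Path) -> None:
    df = pd.DataFrame(assoc.MD.astype(int), index=assoc.mirna_names, columns=assoc.disease_names)
    df.to_csv(path, sep="\t")


def read_kernel_matrix(
    path: str | Path, expected_names: list[str], label: str = "functional"
) -> KernelMatrix:
    """Load a named square similarity matrix, reordered to ``expected_names``.

    Header names must cover ``expected_names``; asymmetry beyond 1e-8 is an
    error (never silently averaged), and a diagonal off by more than 1e-8
    is an error (small drift is snapped to 1 with a logged note).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = [n for n in expected_names if n not in df.index or n not in df.columns]
    if missing:
        raise ValidationError(f"{path}: kernel is missing entities {missing}")
    df = df.loc[expected_names, expected_names]
    S = df.to_numpy(dtype=float)
    diag = np.diag(S)
    drift = np.abs(diag - 1.0)
    if drift.size and drift.max() > 0 and drift.max() <= 1e-8:
        logger.info("%s: snapping %d near-unit diagonal entries to 1", path, int((drift > 0).sum()))
    return KernelMatrix(list(expected_names), S, label)


def write_kernel_matrix(kernel: KernelMatrix, path: str | Path) -> None:
    df = pd.DataFrame(kernel.S, index=kernel.entity_names, columns=kernel.entity_names)
    df.to_csv(path, sep="\t")


def _score_sort(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["score", "mirna_id", "disease_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    """Write final scores as a long table sorted by score descending.

    Columns: mirna_id, disease_id, score, known_flag. Ties are broken by
    (mirna_id, disease_id) ascending. Floats are written at full precision
    so the table round-trips bit-exactly through :func:`read_scores`.
    """
    n_m, n_d = scores.Fpf.shape
    mi, dj = np.meshgrid(np.arange(n_m), np.arange(n_d), indexing="ij")
    df = pd.DataFrame(
        {
            "mirna_id": np.asarray(scores.mirna_names, dtype=object)[mi.ravel()]
            if n_m
            else np.array([], dtype=object),
            "disease_id": np.asarray(scores.disease_names, dtype=object)[dj.ravel()]
            if n_d
            else np.array([], dtype=object),
            "score": scores.Fpf.ravel(),
            "known_flag": scores.known_mask.astype(int).ravel(),
        }
    )
    df = _score_sort(df)
    # shortest round-trip repr keeps the table bit-exact through read_scores
    df["score"] = [repr(float(v)) for v in df["score"]]
    df.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> ScoreMatrix:
    """Rebuild a ScoreMatrix (Fpf and known_mask only) from a score table."""
    df = pd.read_csv(
        path, sep="\t", dtype={"mirna_id": str, "disease_id": str}, float_precision="round_trip"
    )
    mirnas = sorted(df["mirna_id"].unique())
    diseases = sorted(df["disease_id"].unique())
    mi = {m: i for i, m in enumerate(mirnas)}
    di = {d: j for j, d in enumerate(diseases)}
    Fpf = np.zeros((len(mirnas), len(diseases)))
    mask = np.zeros_like(Fpf)
    for m, d, s, k in df.itertuples(index=False):
        Fpf[mi[m], di[d]] = s
        mask[mi[m], di[d]] = k
    return ScoreMatrix(mirnas, diseases, None, None, Fpf, mask)


_CONFIG_KEYS = {"alpha", "beta", "gamma", "k_neighbors", "iterations", "delta", "seed", "fast_loocv"}


def read_config(path: str | Path) -> dict:
    """Read a flat key-value configuration file (YAML syntax, flat keys)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: configuration must be flat key-value pairs")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return data


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_from_dict(data: dict) -> ModelConfig:
    """Build a ModelConfig from flat key-value pairs, applying defaults."""
    fusion = FusionConfig(
        k_neighbors=int(data.get("k_neighbors", 36)),
        iterations=int(data.get("iterations", 10)),
        delta=float(data.get("delta", 0.1)),
    )
    return ModelConfig(
        alpha=float(data.get("alpha", 0.02)),
        beta=float(data.get("beta", 0.02)),
        gamma=float(data.get("gamma", 0.27)),
        fusion=fusion,
        fast_loocv=bool(data.get("fast_loocv", False)),
    )
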