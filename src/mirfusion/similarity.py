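"""Hamming similarity kernels derived from the Boolean association matrix.

Two entities are similar when their association profiles (columns of MD for
diseases, rows for miRNAs) agree in many positions: similarity is one minus
the fraction of mismatching components. Because the profiles change whenever
associations are masked, these kernels are recomputed inside every
cross-validation fold.
"""

from __future__ import annotations

import numpy as np

from .types import AssociationData, KernelMatrix, ValidationError

__all__ = ["hamming_similarity"]


def hamming_similarity(assoc: AssociationData, side: str) -> KernelMatrix:
    """Compute the Hamming similarity kernel for one side of the network.

    ``side="disease"`` compares columns of MD (profiles of length n_mirna);
    ``side="mirna"`` compares rows (profiles of length n_disease). Two
    identical profiles - including two all-zero profiles, which arise under
    masking - get similarity 1.
    """
    if side == "disease":
        profiles = assoc.MD  # columns are disease profiles
        names = assoc.disease_names
    elif side == "mirna":
        profiles = assoc.MD.T
        names = assoc.mirna_names
    else:
        raise ValidationError(f"side must be 'disease' or 'mirna', got {side!r}")
    length = profiles.shape[0]
    # integer mismatch counts keep S = 1 - k/n exact (and exactly symmetric)
    P = profiles.astype(np.int64)
    mismatches = P.T @ (1 - P) + (1 - P).T @ P
    S = 1.0 - mismatches / length
    np.fill_diagonal(S, 1.0)
    return KernelMatrix(list(names), S, "hamming")
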