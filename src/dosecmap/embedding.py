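"""Jaccard distances between drugs' target-gene sets and a deterministic
2-D map (classical metric MDS) analogous to the published target-similarity
plots, where the low- and high-dose target sets of a dose-bipartite drug
separate visibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .targets import TargetGeneSet

logger = logging.getLogger(__name__)

__all__ = ["SimilarityMatrix", "target_distance_matrix", "embed_2d"]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric Jaccard distance matrix over labelled target sets."""

    labels: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.labels),) * 2:
            raise ParameterError("distance matrix shape does not match labels")
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
            raise ParameterError("distance matrix must be symmetric with zero "
                                 "diagonal")
        object.__setattr__(self, "D", D)


def _signed_elements(s: TargetGeneSet) -> frozenset[tuple[str, int]]:
    return (frozenset((g, +1) for g in s.up_targets)
            | frozenset((g, -1) for g in s.down_targets))


def target_distance_matrix(sets: list[TargetGeneSet],
                           signed: bool = True) -> SimilarityMatrix:
    """Pairwise Jaccard distances ``1 - |Ti ∩ Tj| / |Ti ∪ Tj|``.

    With ``signed=True`` (default) set elements are (gene, direction)
    pairs, so two conditions that move the same genes in opposite
    directions are maximally distant — the property that separates the low
    and high dose bands of a dose-flip compound.  With ``signed=False`` the
    plain union of up and down targets is compared.  Two empty sets are at
    maximal distance 1 (logged); the diagonal is always 0.
    """
    if len(sets) < 2:
        raise ParameterError("need at least two target sets")
    if signed:
        elems = [_signed_elements(s) for s in sets]
    else:
        elems = [frozenset(s.all_targets) for s in sets]
    labels = tuple(f"{s.drug_id}:{s.dose_band}" for s in sets)
    n = len(sets)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(elems[i] | elems[j])
            if union == 0:
                logger.warning("both %s and %s have empty target sets; "
                               "distance set to 1", labels[i], labels[j])
                d = 1.0
            else:
                d = 1.0 - len(elems[i] & elems[j]) / union
            D[i, j] = D[j, i] = d
    return SimilarityMatrix(labels=labels, D=D)


def embed_2d(M: SimilarityMatrix, method: str = "cmds") -> np.ndarray:
    """Deterministic 2-D coordinates by classical (Torgerson) metric MDS.

    Double-centres ``-D**2 / 2`` and projects on the top two eigenpairs.
    Axis signs are fixed by making the first non-zero loading positive, so
    repeated runs give identical output.  If fewer than two positive
    eigenvalues exist the missing axes are zero-padded with a warning.
    """
    if method != "cmds":
        raise ParameterError(f"unknown embedding method {method!r}")
    n = len(M.labels)
    if n < 3:
        raise ParameterError("need at least three points to embed")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M.D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, 2))
    pos = 0
    for ax in range(2):
        if ax < evals.size and evals[ax] > 1e-12:
            coords[:, ax] = evecs[:, ax] * np.sqrt(evals[ax])
            pos += 1
    if pos < 2:
        logger.warning("only %d positive eigenvalue(s); remaining axes zero-padded",
                       pos)
    for ax in range(2):
        nz = np.flatnonzero(np.abs(coords[:, ax]) > 1e-12)
        if nz.size and coords[nz[0], ax] < 0:
            coords[:, ax] = -coords[:, ax]
    return coords
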