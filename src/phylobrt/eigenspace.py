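"""Principal coordinate analysis (PCoA) of a patristic distance matrix.

Phylogenetic eigenvector regression represents relatedness among species as
coordinates on the principal axes of the tip-to-tip distance matrix: the
double-centered matrix B = -1/2 * J D^2 J (Gower centering) is
eigendecomposed, and each positive-eigenvalue axis is scaled by the square
root of its eigenvalue so Euclidean distances in the coordinate space
approximate the input distances. The leading axes, ranked by eigenvalue,
are then carried into the regression as "phylogenetic eigenvectors".

Patristic distances need not be Euclidean-embeddable, so negative
eigenvalues can occur; they are recorded but excluded from coordinates and
from the explained-variation fractions (no Lingoes/Cailliez correction is
applied).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .phylo_trees import DistanceMatrix

__all__ = ["EigenBasis", "PhyloCoordinates", "pcoa", "select_eigenvectors"]

_EIGENVECTOR_PREFIX = "eigenvector_"


@dataclass
class EigenBasis:
    """Full principal-coordinate decomposition of a distance matrix.

    Attributes
    ----------
    eigenvalues :
        All eigenvalues of the double-centered matrix, sorted descending
        (negative ones included for the record).
    coordinates :
        Species x n_positive matrix; axis k is the unit eigenvector of the
        k-th largest positive eigenvalue scaled by sqrt(eigenvalue).
    explained_fraction :
        Per positive axis, eigenvalue / sum of positive eigenvalues.
    labels :
        Species labels, matching the coordinate rows.
    """

    eigenvalues: np.ndarray
    coordinates: np.ndarray
    explained_fraction: np.ndarray
    labels: list

    @property
    def n_positive(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class PhyloCoordinates:
    """The selected leading eigenvector scores, ready for model assembly."""

    labels: list
    scores: np.ndarray  # species x k
    k: int
    cum_fraction: float
    column_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.column_names:
            self.column_names = [
                f"{_EIGENVECTOR_PREFIX}{i + 1}" for i in range(self.k)
            ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.labels, columns=self.column_names
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")


def pcoa(D: DistanceMatrix) -> EigenBasis:
    """Principal coordinate analysis by Gower double-centering.

    Computes B = -1/2 * (I - 11'/n) D^2 (I - 11'/n) and its symmetric
    eigendecomposition. Coordinates are built from the positive eigenvalues
    only. Eigenvector signs are fixed by forcing the largest-magnitude
    loading on each axis to be positive, so outputs are reproducible across
    LAPACK builds.
    """
    M = np.asarray(D.values, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least two tips for a PCoA")
    A = -0.5 * M**2
    row_mean = A.mean(axis=1, keepdims=True)
    col_mean = A.mean(axis=0, keepdims=True)
    B = A - row_mean - col_mean + A.mean()
    w, V = scipy.linalg.eigh(B)
    order = np.argsort(w, kind="stable")[::-1]
    w = w[order]
    V = V[:, order]
    # the centered matrix always has a (numerically) zero eigenvalue for the
    # constant vector; treat anything below a relative floor as non-positive
    floor = 1e-9 * max(abs(w[0]), abs(w[-1]), 1.0)
    pos = w > floor
    coords = V[:, pos] * np.sqrt(w[pos])
    for k in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    explained = w[pos] / w[pos].sum()
    return EigenBasis(
        eigenvalues=w,
        coordinates=coords,
        explained_fraction=explained,
        labels=list(D.labels),
    )


def select_eigenvectors(
    basis: EigenBasis, cum_threshold: float = 0.99
) -> PhyloCoordinates:
    """Retain the smallest prefix of axes reaching a cumulative fraction.

    ``cum_threshold`` is the minimum cumulative explained fraction of the
    (positive-eigenvalue) variation in the distances; axes are taken in
    descending eigenvalue order. The default 0.99 retains 99% of the
    phylogenetic structure; 0.95 is the conventional floor for eigenvector
    regression to control phylogenetic autocorrelation.
    """
    if not 0 < cum_threshold <= 1:
        raise ValueError(f"cum_threshold must be in (0, 1], got {cum_threshold}")
    cum = np.cumsum(basis.explained_fraction)
    if cum_threshold > cum[-1] + 1e-12:
        raise ValueError(
            f"requested cumulative fraction {cum_threshold} exceeds the "
            f"total available {cum[-1]:.6f}"
        )
    k = int(np.searchsorted(cum, cum_threshold - 1e-12) + 1)
    k = min(k, basis.n_positive)
    return PhyloCoordinates(
        labels=list(basis.labels),
        scores=basis.coordinates[:, :k].copy(),
        k=k,
        cum_fraction=float(cum[k - 1]),
    )


def write_eigen_sidecar(basis: EigenBasis, path) -> None:
    """JSON sidecar with eigenvalues and cumulative explained fractions."""
    payload = {
        "eigenvalues": [float(x) for x in basis.eigenvalues],
        "explained_fraction": [float(x) for x in basis.explained_fraction],
        "cumulative_fraction": [
            float(x) for x in np.cumsum(basis.explained_fraction)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
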