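"""Classical (Torgerson) multidimensional scaling for cohort visualization.

Squared Euclidean dissimilarities are double-centered and eigendecomposed;
the configuration is the eigenvectors scaled by the square roots of the
positive eigenvalues, with the first three axes exported for 3-D plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import ConfigurationError, InvalidInputError

__all__ = ["MDSEmbedding", "classical_mds", "export_embedding"]


@dataclass(eq=False)
class MDSEmbedding:
    """Configuration matrix and spectrum of a classical MDS fit."""

    coordinates: np.ndarray  # (n, n_dims) requested axes
    configuration: np.ndarray  # (n, r) full positive-eigenvalue configuration
    eigenvalues: np.ndarray  # descending, full spectrum of the centered Gram
    n_negative: int

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]


def classical_mds(
    data: np.ndarray,
    n_dims: int = 3,
    input_kind: str = "features",
) -> MDSEmbedding:
    """Torgerson MDS of a feature matrix or a precomputed distance matrix.

    ``input_kind='features'`` computes Euclidean distances first.  Negative
    eigenvalue dimensions (non-Euclidean input) are dropped with a warning.
    Reflection ambiguity is fixed by making each axis's first nonzero
    loading positive.
    """
    if n_dims < 1:
        raise ConfigurationError("n_dims must be >= 1")
    x = np.asarray(data, dtype=float)
    if input_kind == "features":
        d = squareform(pdist(x))
    elif input_kind == "distances":
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise InvalidInputError("distance matrix must be square")
        if not np.allclose(x, x.T, atol=1e-10):
            raise InvalidInputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(x), 0.0, atol=1e-10):
            raise InvalidInputError("distance matrix must have a zero diagonal")
        d = x
    else:
        raise ConfigurationError("input_kind must be 'features' or 'distances'")
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigvals[0]), 1.0) if n else 0.0
    positive = eigvals > tol
    n_negative = int(np.sum(eigvals < -tol))
    if n_negative:
        warnings.warn(
            f"dropping {n_negative} negative-eigenvalue dimension(s)", stacklevel=2
        )
    vals = eigvals[positive]
    vecs = eigvecs[:, positive]
    for c in range(vecs.shape[1]):  # deterministic reflection
        nz = np.flatnonzero(np.abs(vecs[:, c]) > 1e-12)
        if nz.size and vecs[nz[0], c] < 0:
            vecs[:, c] = -vecs[:, c]
    config = vecs * np.sqrt(vals)
    coords = np.zeros((n, n_dims))
    take = min(n_dims, config.shape[1])
    coords[:, :take] = config[:, :take]
    return MDSEmbedding(coords, config, eigvals, n_negative)


def export_embedding(
    embedding: MDSEmbedding,
    cohort: pd.DataFrame,
    path: str,
    scree_path: str | None = None,
) -> pd.DataFrame:
    """Write subject coordinates (and optionally the eigenvalue scree) as TSV."""
    if embedding.n_points != len(cohort):
        raise InvalidInputError("embedding and cohort disagree on subject count")
    coords = embedding.coordinates
    table = pd.DataFrame(
        {
            "subject_id": cohort.index,
            "x": coords[:, 0],
            "y": coords[:, 1] if coords.shape[1] > 1 else 0.0,
            "z": coords[:, 2] if coords.shape[1] > 2 else 0.0,
            "diagnosis": cohort["diagnosis"].astype(str).to_numpy(),
            "sex": cohort["sex"].astype(str).to_numpy(),
        }
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
    if scree_path is not None:
        scree = pd.DataFrame(
            {
                "component": np.arange(1, len(embedding.eigenvalues) + 1),
                "eigenvalue": embedding.eigenvalues,
            }
        )
        scree.to_csv(scree_path, sep="\t", index=False, float_format="%.12g")
    return table
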