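"""Geographic predictors: distance matrices, PCNM axes, region assignment.

PCNM (principal coordinates of neighbour matrices) turns an inter-site
distance matrix into orthogonal spatial eigenvectors usable as regression
predictors.  The construction: truncate the distance matrix at a threshold
(default: longest edge of the minimum spanning tree, so the truncated graph
stays connected), replace every distance above the threshold by four times
the threshold, then take the principal-coordinates decomposition of the
double-centred ``-0.5 * D**2`` matrix and keep the axes with positive
eigenvalues, scaled by the square root of their eigenvalue.

Coordinates are treated as planar decimal degrees (no projection), matching
common practice for country-scale spacing; a projected variant can be had by
passing projected coordinates directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .sites import REGION_OF_POPULATION

__all__ = ["DistanceMatrix", "PCNMAxes", "euclidean_distance", "pcnm", "assign_region"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled sites."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.values < 0).any() or np.diag(self.values).any():
            raise ValueError("distances must be non-negative with zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class PCNMAxes:
    """Positive-eigenvalue PCNM axes (columns of ``scores``), in descending
    eigenvalue order, scaled by sqrt(eigenvalue)."""

    labels: list
    eigenvalues: np.ndarray
    scores: np.ndarray  # sites x axes
    truncation: float

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCNM{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.labels, columns=cols)


def euclidean_distance(coords: pd.DataFrame, lat_col: str = "latitude",
                       lon_col: str = "longitude",
                       label_col: str | None = None) -> DistanceMatrix:
    """Planar Euclidean distances between sites given in decimal degrees.

    ``coords`` is a DataFrame with latitude/longitude columns; labels come
    from ``label_col`` or the index.
    """
    if len(coords) < 2:
        raise ValueError("need at least 2 sites")
    xy = coords[[lat_col, lon_col]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates")
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    labels = list(coords[label_col] if label_col else coords.index)
    return DistanceMatrix(labels, d)


def _mst_truncation(d: np.ndarray) -> float:
    mst = minimum_spanning_tree(d).toarray()
    return float(mst.max())


def pcnm(dist: DistanceMatrix, truncation: float | None = None,
         tol: float = 1e-9) -> PCNMAxes:
    """Principal coordinates of the truncated neighbour matrix.

    Raises ``ValueError("no positive axes")`` for degenerate inputs (all
    sites coincident).  Axis sign is fixed by making the first nonzero score
    of each axis positive.
    """
    d = dist.values.copy()
    if not d.any():
        raise ValueError("no positive axes")
    if truncation is None:
        truncation = _mst_truncation(d)
    mask = d > truncation
    d[mask] = 4.0 * truncation
    a = -0.5 * d ** 2
    n = a.shape[0]
    row = a.mean(axis=0)
    g = a - row[None, :] - row[:, None] + a.mean()
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol * max(abs(vals[0]), 1.0)
    if not keep.any():
        raise ValueError("no positive axes")
    vals, vecs = vals[keep], vecs[:, keep]
    scores = vecs * np.sqrt(vals)[None, :]
    # deterministic sign: first nonzero score of each axis positive
    for j in range(scores.shape[1]):
        col = scores[:, j]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            scores[:, j] = -col
    return PCNMAxes(list(dist.labels), vals, scores, float(truncation))


def assign_region(population: str, region_map: dict | None = None) -> str:
    """Map a population name to its broad geographic region."""
    mapping = REGION_OF_POPULATION if region_map is None else region_map
    try:
        return mapping[population]
    except KeyError:
        raise ValueError(f"unknown population {population!r}") from None
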