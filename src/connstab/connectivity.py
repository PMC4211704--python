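"""Fisher-z connectivity matrices, distance matrices and the
within-condition distance-connectivity relationship.

Functional connectivity between two regions is the Pearson correlation of
their time series; correlations are variance-stabilized with the Fisher
r-to-z transform (arctanh) before any averaging or modeling. All modules
share one canonical edge ordering: the upper triangle (i < j), row-major,
so an n-node parcellation has n(n-1)/2 unique edges (116 nodes -> 6670).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError
from .synthetic import Parcellation, SyntheticDataset

#: |r| is clamped here before arctanh so z stays finite
FISHER_CLAMP = 1.0 - 1e-7
SYMMETRY_TOL = 1e-10


# ---------------------------------------------------------------------------
# Edge vectorization


@dataclass(frozen=True)
class EdgeVector:
    """Upper-triangle edge values in the canonical (i < j, row-major) order."""

    values: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        expected = self.n_nodes * (self.n_nodes - 1) // 2
        if vals.shape != (expected,):
            raise InvalidArgumentError(
                f"edge vector for {self.n_nodes} nodes must have length "
                f"{expected}, got {vals.shape}"
            )
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) node indices per edge, aligned with ``values``."""
        return np.triu_indices(self.n_nodes, k=1)

    def to_matrix(self) -> np.ndarray:
        return edge_vector_to_matrix(self.values, self.n_nodes)


def upper_triangle_vector(matrix: np.ndarray) -> EdgeVector:
    """Vectorize a symmetric matrix over its strict upper triangle."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidArgumentError("matrix must be square")
    if np.max(np.abs(m - m.T)) > SYMMETRY_TOL:
        raise InvalidArgumentError(
            f"matrix asymmetric beyond {SYMMETRY_TOL:g}"
        )
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return EdgeVector(m[iu, ju], m.shape[0])


def edge_vector_to_matrix(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`upper_triangle_vector`; zero diagonal."""
    values = np.asarray(values, dtype=float)
    expected = n_nodes * (n_nodes - 1) // 2
    if values.shape != (expected,):
        raise InvalidArgumentError(
            f"need {expected} edge values for {n_nodes} nodes"
        )
    m = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    m[iu, ju] = values
    m[ju, iu] = values
    return m


def n_edges(n_nodes: int) -> int:
    """Number of unique connections among n nodes: n(n-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


# ---------------------------------------------------------------------------
# Correlation and Fisher z


def correlation_matrix(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a T x n time-series array."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise InvalidArgumentError("timeseries must be a T x n array")
    t, n = ts.shape
    if t < 3:
        raise InvalidArgumentError("need at least 3 time points")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateInputError(
            f"zero-variance time series at node index(es) {dead.tolist()}"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform, arctanh(r), with |r| clamped to 1 - 1e-7.

    Applied to a square matrix, the diagonal is set to 0 (self-connections
    are excluded throughout).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise InvalidArgumentError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(arr, -FISHER_CLAMP, FISHER_CLAMP))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    if np.isscalar(r):
        return float(z)
    return z


# ---------------------------------------------------------------------------
# Connectivity dataset


@dataclass
class ConnectivityDataset:
    """Per subject x cell symmetric Fisher-z matrices with zero diagonal.

    ``z[(group, condition)]`` is (n_subjects, n, n); the subject axis is
    aligned across the conditions of a group.
    """

    parcellation: Parcellation
    design: list[tuple[str, str]]
    z: dict[tuple[str, str], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        n = self.parcellation.n_nodes
        for cell, arr in self.z.items():
            if arr.ndim != 3 or arr.shape[1:] != (n, n):
                raise InvalidArgumentError(
                    f"cell {cell}: expected (subjects, {n}, {n}) array"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidArgumentError(f"cell {cell}: non-finite entries")
            if np.max(np.abs(arr - arr.transpose(0, 2, 1))) > 1e-8:
                raise InvalidArgumentError(f"cell {cell}: asymmetric matrices")
            if np.max(np.abs(arr[:, np.arange(n), np.arange(n)])) > 1e-12:
                raise InvalidArgumentError(f"cell {cell}: nonzero diagonal")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g, _ in self.design:
            if g not in seen:
                seen.append(g)
        return seen

    def conditions(self, group: str) -> list[str]:
        return [c for g, c in self.design if g == group]

    def n_subjects(self, group: str) -> int:
        return self.z[(group, self.conditions(group)[0])].shape[0]

    def cell_mean(self, cell: tuple[str, str]) -> np.ndarray:
        """Group-averaged Fisher-z matrix of one cell."""
        if cell not in self.z:
            raise InvalidArgumentError(f"unknown design cell {cell}")
        return self.z[cell].mean(axis=0)

    def grand_mean(self) -> np.ndarray:
        """Mean z matrix over all cells (cells weighted equally)."""
        return np.mean([self.cell_mean(c) for c in self.design], axis=0)


def connectivity_from_timeseries(dataset: SyntheticDataset) -> ConnectivityDataset:
    """Correlate each subject's series and Fisher-transform the result."""
    z = {}
    for cell, arr in dataset.timeseries.items():
        mats = [fisher_z(correlation_matrix(arr[s])) for s in range(arr.shape[0])]
        z[cell] = np.stack(mats)
    return ConnectivityDataset(dataset.parcellation, list(dataset.design), z)


# ---------------------------------------------------------------------------
# Distance


def distance_matrix(parcellation: Parcellation) -> np.ndarray:
    """Euclidean distance (mm) between all ROI centroid pairs."""
    c = parcellation.centroids
    diff = c[:, None, :] - c[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def distance_fc_correlation(
    z_matrix: np.ndarray,
    d: np.ndarray,
    method: str = "pearson",
) -> tuple[float, int]:
    """Correlation between edge strength and edge length over unique edges.

    Within a condition this is the classic negative distance-connectivity
    relationship: spatially closer ROIs are more strongly correlated.
    Returns (coefficient, number of edges used).
    """
    zv = upper_triangle_vector(z_matrix).values
    dv = upper_triangle_vector(d).values
    if zv.size != dv.size:
        raise InvalidArgumentError("matrix dimensions disagree")
    if np.ptp(zv) == 0 or np.ptp(dv) == 0:
        raise DegenerateInputError("zero variance in edges or distances")
    if method == "pearson":
        coef = stats.pearsonr(dv, zv).statistic
    elif method == "spearman":
        coef = stats.spearmanr(dv, zv).statistic
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return float(coef), int(zv.size)
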