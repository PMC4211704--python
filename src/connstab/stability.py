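"""Edge-level change versus distance: change maps and their inference.

A change map assigns each unique edge one scalar quantifying how much that
edge changed across tasks or groups — an LV salience, a bootstrap ratio, a
difference of condition correlation matrices, or the absolute value of
either. The central inferential device is the independent-pairs null:
edge-level quantities share nodes and are therefore dependent, so the
distance-change correlation is re-computed over random perfect matchings
of the nodes (floor(n/2) disjoint pairs per sample, node-disjoint edges
being independent), building a sampling distribution of correlation
coefficients from which one-tailed p-values are read off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .connectivity import (
    ConnectivityDataset,
    EdgeVector,
    distance_matrix,
    upper_triangle_vector,
)
from .errors import DegenerateInputError, InvalidArgumentError
from .pls import BootstrapResult, PlsModel
from .synthetic import Parcellation

CHANGE_KINDS = (
    "salience",
    "bootstrap_ratio",
    "correlation_difference",
    "abs_salience",
    "abs_correlation_difference",
)


@dataclass
class EdgeChangeMap:
    """Per-edge change scalar plus the matching edge distances."""

    kind: str
    values: EdgeVector
    distances: EdgeVector
    condition_pair: Optional[tuple[tuple[str, str], tuple[str, str]]] = None

    def __post_init__(self) -> None:
        if self.kind not in CHANGE_KINDS:
            raise InvalidArgumentError(f"unknown change kind {self.kind!r}")
        if self.values.n_nodes != self.distances.n_nodes:
            raise InvalidArgumentError("values/distances edge orderings differ")

    @property
    def n_nodes(self) -> int:
        return self.values.n_nodes

    def absolute(self) -> "EdgeChangeMap":
        """The |change| variant of this map, same code path downstream."""
        kind = {
            "salience": "abs_salience",
            "correlation_difference": "abs_correlation_difference",
        }.get(self.kind, self.kind if self.kind.startswith("abs_") else None)
        if kind is None:
            raise InvalidArgumentError(
                f"no absolute-value variant defined for kind {self.kind!r}"
            )
        return EdgeChangeMap(
            kind=kind,
            values=EdgeVector(np.abs(self.values.values), self.n_nodes),
            distances=self.distances,
            condition_pair=self.condition_pair,
        )


# ---------------------------------------------------------------------------
# Change-map constructors


def _distances(parcellation: Parcellation) -> EdgeVector:
    return upper_triangle_vector(distance_matrix(parcellation))


def salience_change_map(
    model: PlsModel, parcellation: Parcellation, lv: int = 0
) -> EdgeChangeMap:
    """LV saliences as the per-edge change magnitude."""
    return EdgeChangeMap(
        kind="salience",
        values=EdgeVector(model.saliences[lv], parcellation.n_nodes),
        distances=_distances(parcellation),
    )


def bootstrap_ratio_change_map(
    boot: BootstrapResult, parcellation: Parcellation, lv: int = 0
) -> EdgeChangeMap:
    """Bootstrap ratios (salience reliability) as the change measure."""
    return EdgeChangeMap(
        kind="bootstrap_ratio",
        values=EdgeVector(boot.bootstrap_ratio[lv], parcellation.n_nodes),
        distances=_distances(parcellation),
    )


def correlation_difference(
    dataset: ConnectivityDataset,
    cell_a: tuple[str, str],
    cell_b: tuple[str, str],
) -> EdgeChangeMap:
    """Group-averaged Fisher-z matrix of cell_a minus that of cell_b."""
    for cell in (cell_a, cell_b):
        if cell not in dataset.z:
            raise InvalidArgumentError(f"unknown design cell {cell}")
    diff = dataset.cell_mean(cell_a) - dataset.cell_mean(cell_b)
    return EdgeChangeMap(
        kind="correlation_difference",
        values=upper_triangle_vector(diff),
        distances=_distances(dataset.parcellation),
        condition_pair=(cell_a, cell_b),
    )


def greatest_difference_cells(
    model: PlsModel,
) -> tuple[tuple[str, str], tuple[str, str]]:
    """The two cells at the extremes of the LV1 design salience contrast."""
    u1 = model.design_saliences[:, 0]
    return model.cell_order[int(np.argmax(u1))], model.cell_order[int(np.argmin(u1))]


# ---------------------------------------------------------------------------
# Independent-pairs resampling


@dataclass
class IndependentPairsResult:
    """Sampling distribution of distance-change correlations over disjoint
    node pairs.

    se is the spread (sd) of the rho sampling distribution; se_of_mean is
    sd / sqrt(n_samples). p_greater is the proportion of rho samples > 0
    (exact zeros counted half), p_less = 1 - p_greater.
    """

    rho_samples: np.ndarray
    mean_rho: float
    se: float
    se_of_mean: float
    p_greater: float
    p_less: float
    n_pairs_per_sample: int
    n_samples: int
    method: str


def _edge_flat_index(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Canonical upper-triangle flat index of edges (i < j)."""
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return (lo * (2 * n - lo - 1)) // 2 + (hi - lo - 1)


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise InvalidArgumentError(f"unknown method {method!r}")


def independent_pairs_correlation(
    change: EdgeChangeMap,
    n_samples: int = 1000,
    seed: int = 0,
    method: str = "spearman",
    eligible: Optional[np.ndarray] = None,
    min_pairs: Optional[int] = None,
    max_redraws: int = 100,
) -> IndependentPairsResult:
    """Distance-change correlation over random perfect matchings of nodes.

    Each sample shuffles the node order (Fisher-Yates, uniform over perfect
    matchings) and pairs consecutive nodes, dropping one node when n is odd;
    the floor(n/2) matched edges share no node, so their (distance, change)
    pairs are independent. Samples with zero variance — or, when an
    ``eligible`` edge mask restricts the analysis to a stratum, with fewer
    than ``min_pairs`` eligible matched edges — are redrawn (at most
    ``max_redraws`` attempts each).
    """
    n = change.n_nodes
    if n < 4:
        raise InvalidArgumentError("need at least 4 nodes")
    if n_samples < 1:
        raise InvalidArgumentError("n_samples must be >= 1")
    if eligible is not None:
        eligible = np.asarray(eligible, dtype=bool)
        if eligible.shape != change.values.values.shape:
            raise InvalidArgumentError("eligible mask length mismatch")
    rng = np.random.default_rng(seed)
    m = n // 2
    vals = change.values.values
    dists = change.distances.values

    rhos = np.empty(n_samples)
    for k in range(n_samples):
        for attempt in range(max_redraws + 1):
            perm = rng.permutation(n)
            edges = _edge_flat_index(perm[0 : 2 * m : 2], perm[1 : 2 * m : 2], n)
            if eligible is not None:
                edges = edges[eligible[edges]]
                if edges.size < (min_pairs or 1):
                    continue
            x, y = dists[edges], vals[edges]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rhos[k] = _correlate(x, y, method)
            break
        else:
            raise DegenerateInputError(
                f"could not draw a valid matching in {max_redraws} attempts"
            )

    p_greater = float(np.mean(rhos > 0) + 0.5 * np.mean(rhos == 0))
    return IndependentPairsResult(
        rho_samples=rhos,
        mean_rho=float(rhos.mean()),
        se=float(rhos.std(ddof=1)) if n_samples > 1 else 0.0,
        se_of_mean=float(rhos.std(ddof=1) / math.sqrt(n_samples))
        if n_samples > 1
        else 0.0,
        p_greater=p_greater,
        p_less=1.0 - p_greater,
        n_pairs_per_sample=m,
        n_samples=n_samples,
        method=method,
    )


def change_distance_correlation(
    change: EdgeChangeMap, method: str = "spearman"
) -> dict:
    """All-edges distance-change correlation.

    Descriptive only: the edge-level points share nodes and are not
    independent, so no p-value is attached (the independent-pairs analysis
    carries the inference).
    """
    vals = change.values.values
    dists = change.distances.values
    if vals.size < 3:
        raise InvalidArgumentError("need at least 3 edges")
    if np.ptp(vals) == 0 or np.ptp(dists) == 0:
        raise DegenerateInputError("zero variance in change or distances")
    return {
        "coefficient": _correlate(dists, vals, method),
        "n_edges": int(vals.size),
        "method": method,
        "label": "descriptive (non-independent points)",
    }


# ---------------------------------------------------------------------------
# PCA outlier diagnostic


@dataclass
class PcaOutlierReport:
    """Displacement-from-principal-axis outlier diagnostic."""

    principal_axis: np.ndarray  # unit 2-vector in standardized coordinates
    displacements: np.ndarray
    upper_indices: np.ndarray
    lower_indices: np.ndarray
    outlier_correlation: float  # NaN when degenerate
    degenerate: bool
    tail_fraction: float


def pca_outlier_diagnostic(
    change: EdgeChangeMap,
    tail_fraction: float = 0.05,
    method: str = "pearson",
) -> PcaOutlierReport:
    """Flag points far from the primary axis of the (distance, change) cloud.

    Both columns are standardized; the principal axis is the leading
    eigenvector of their 2x2 covariance; each point gets a signed orthogonal
    displacement from that axis, and the ceil(tail_fraction * N) most
    positive and most negative displacements are flagged (index order breaks
    ties). The report carries the distance-change correlation within the
    flagged set.
    """
    x = change.distances.values
    y = change.values.values
    n_pts = x.size
    if n_pts < 20:
        raise InvalidArgumentError("need at least 20 points")
    if not 0 < tail_fraction < 0.5:
        raise InvalidArgumentError("tail_fraction must be in (0, 0.5)")

    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        k = math.ceil(tail_fraction * n_pts)
        idx = np.arange(n_pts)
        return PcaOutlierReport(
            principal_axis=np.array([1.0, 0.0]),
            displacements=np.zeros(n_pts),
            upper_indices=idx[:k],
            lower_indices=idx[:k],
            outlier_correlation=float("nan"),
            degenerate=True,
            tail_fraction=tail_fraction,
        )
    xs = (x - x.mean()) / sx
    ys = (y - y.mean()) / sy
    cov = np.cov(np.vstack([xs, ys]))
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    if axis[0] < 0:
        axis = -axis
    # signed orthogonal displacement: 2-D cross product with the axis
    disp = xs * (-axis[1]) + ys * axis[0]

    k = math.ceil(tail_fraction * n_pts)
    order = np.argsort(disp, kind="stable")
    lower = np.sort(order[:k])
    upper = np.sort(order[-k:])
    degenerate = bool(np.allclose(disp, 0.0))

    flagged = np.union1d(lower, upper)
    if degenerate or np.ptp(x[flagged]) == 0 or np.ptp(y[flagged]) == 0:
        corr = float("nan")
    else:
        corr = _correlate(x[flagged], y[flagged], method)
    return PcaOutlierReport(
        principal_axis=axis,
        displacements=disp,
        upper_indices=upper,
        lower_indices=lower,
        outlier_correlation=corr,
        degenerate=degenerate,
        tail_fraction=tail_fraction,
    )


# ---------------------------------------------------------------------------
# Density histogram


def density_histogram_2d(
    change: EdgeChangeMap, bins_x: int = 20, bins_y: int = 20
) -> dict:
    """Binned counts of (distance, change) points over a rectangular grid
    spanning the observed ranges; total count equals the edge count."""
    if bins_x < 2 or bins_y < 2:
        raise InvalidArgumentError("need at least 2 bins per axis")
    counts, xedges, yedges = np.histogram2d(
        change.distances.values, change.values.values, bins=(bins_x, bins_y)
    )
    return {"counts": counts, "x_edges": xedges, "y_edges": yedges}
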