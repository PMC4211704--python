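"""Edge stratification: functional modules, hemispheres and homotopy.

Edges are stratified three ways — within/between Louvain modules,
intra/inter hemisphere, and (among inter-hemispheric edges) homotopic
versus non-homotopic — and the distance-change analyses are re-run per
stratum. Homotopic stability is tested by pooling the inter-hemispheric
change values, taking their empirical 95% interval, and comparing the
proportion of each connection class that falls outside it: a class whose
edges rarely exceed the pooled interval changes less, i.e. is more stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError
from .stability import (
    EdgeChangeMap,
    IndependentPairsResult,
    independent_pairs_correlation,
)
from .synthetic import Parcellation

#: strata smaller than this (edges, or eligible pairs per sample) are skipped
MIN_STRATUM_EDGES = 10


# ---------------------------------------------------------------------------
# Louvain modules


@dataclass
class ModulePartition:
    """Node-to-module assignment with its modularity Q."""

    assignment: np.ndarray  # int module id per node
    q: float
    n_runs: int
    seed: int
    degenerate: bool = False  # all-zero weight matrix

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.assignment).size)


def modularity(weights: np.ndarray, assignment: np.ndarray) -> float:
    """Newman weighted modularity of a partition.

    Q = sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j) / 2m over the
    off-diagonal weight matrix A (negative weights must already be removed).
    """
    a = np.asarray(weights, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1)
    same = assignment[:, None] == assignment[None, :]
    return float(((a - np.outer(k, k) / two_m) * same).sum() / two_m)


def louvain_partition(
    z_matrix: np.ndarray,
    n_runs: int = 100,
    gamma: float = 1.0,
    seed: int = 0,
) -> ModulePartition:
    """Best-of-n_runs Louvain community detection on non-negative weights.

    Negative edge weights are zeroed (the standard treatment for modularity
    on signed functional networks when no signed null model is requested).
    The partition with the highest recomputed Q wins; ties go to the first
    occurrence in the seeded run order.
    """
    if n_runs < 1:
        raise InvalidArgumentError("n_runs must be >= 1")
    w = np.asarray(z_matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidArgumentError("weight matrix must be square")
    if np.max(np.abs(w - w.T)) > 1e-8:
        raise InvalidArgumentError("weight matrix must be symmetric")
    w = np.where(w > 0, w, 0.0)
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    if w.sum() == 0:
        return ModulePartition(
            assignment=np.zeros(n, dtype=int),
            q=0.0,
            n_runs=n_runs,
            seed=seed,
            degenerate=True,
        )

    g = nx.from_numpy_array(w)
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s) for s in ss.generate_state(n_runs) % (2**31)]
    best_q = -np.inf
    best: Optional[np.ndarray] = None
    for rs in run_seeds:
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=gamma, seed=rs
        )
        assignment = np.empty(n, dtype=int)
        for mid, members in enumerate(comms):
            for node in members:
                assignment[node] = mid
        q = modularity(w, assignment)
        if q > best_q:
            best_q, best = q, assignment
    assert best is not None
    return ModulePartition(assignment=best, q=best_q, n_runs=n_runs, seed=seed)


# ---------------------------------------------------------------------------
# Edge strata


@dataclass
class EdgeStrata:
    """Per-edge labels in canonical edge order.

    hemisphere_class: 'intra' | 'inter'; homotopy_class: 'homotopic' |
    'non_homotopic' (inter edges) | 'not_applicable' (intra edges);
    module_class: 'within' | 'between'. Medial nodes count as their own
    side, so medial-to-anything edges are inter-hemispheric only when the
    two sides differ.
    """

    hemisphere_class: np.ndarray
    homotopy_class: np.ndarray
    module_class: np.ndarray

    def mask(self, name: str) -> np.ndarray:
        """Boolean edge mask for a named stratum."""
        masks = {
            "module_within": self.module_class == "within",
            "module_between": self.module_class == "between",
            "hemisphere_intra": self.hemisphere_class == "intra",
            "hemisphere_inter": self.hemisphere_class == "inter",
            "inter_homotopic": self.homotopy_class == "homotopic",
            "inter_non_homotopic": self.homotopy_class == "non_homotopic",
        }
        if name not in masks:
            raise InvalidArgumentError(f"unknown stratum {name!r}")
        return masks[name]


STRATUM_NAMES = (
    "module_within",
    "module_between",
    "hemisphere_intra",
    "hemisphere_inter",
    "inter_homotopic",
    "inter_non_homotopic",
)


def classify_edges(
    parcellation: Parcellation, partition: Optional[ModulePartition] = None
) -> EdgeStrata:
    """Label every unique edge by hemisphere, homotopy and module class."""
    n = parcellation.n_nodes
    if partition is not None and partition.assignment.size != n:
        raise InvalidArgumentError("partition does not cover the parcellation")
    iu, ju = np.triu_indices(n, k=1)
    hemi = np.asarray(parcellation.hemisphere)
    hom = parcellation.homotope_index

    same_side = hemi[iu] == hemi[ju]
    hemisphere_class = np.where(same_side, "intra", "inter")
    homotopic = hom[iu] == ju
    homotopy_class = np.where(
        same_side, "not_applicable", np.where(homotopic, "homotopic", "non_homotopic")
    )
    if partition is not None:
        a = partition.assignment
        module_class = np.where(a[iu] == a[ju], "within", "between")
    else:
        module_class = np.full(iu.size, "within")
    return EdgeStrata(
        hemisphere_class=hemisphere_class,
        homotopy_class=homotopy_class,
        module_class=module_class,
    )


# ---------------------------------------------------------------------------
# Stratified distance-change analysis


@dataclass
class StratumResult:
    name: str
    n_edges: int
    status: str  # 'ok' | 'skipped'
    reason: Optional[str] = None
    descriptive: Optional[dict] = None
    pairs: Optional[IndependentPairsResult] = None


def stratified_distance_analysis(
    change: EdgeChangeMap,
    strata: EdgeStrata,
    n_samples: int = 1000,
    seed: int = 0,
    method: str = "spearman",
    stratum_names: tuple[str, ...] = STRATUM_NAMES,
    min_edges: int = MIN_STRATUM_EDGES,
) -> list[StratumResult]:
    """Re-run the distance-change analyses within each stratum.

    The independent-pairs resampler keeps its uniform-matching construction
    but only retains matched pairs whose edge lies in the stratum; samples
    with fewer than ``min_edges`` eligible pairs are redrawn. Strata that
    are too small — or too sparse for the restricted matching to ever keep
    enough pairs — are reported as skipped rather than failing the run.
    """
    ss = np.random.SeedSequence(seed)
    stage_seeds = [int(s) for s in ss.generate_state(len(stratum_names)) % (2**31)]
    results = []
    for name, sseed in zip(stratum_names, stage_seeds):
        mask = strata.mask(name)
        n_in = int(mask.sum())
        if n_in < min_edges:
            results.append(
                StratumResult(name, n_in, "skipped", reason="too few edges")
            )
            continue
        try:
            desc = _descriptive_within(change, mask, method)
        except DegenerateInputError as err:
            results.append(StratumResult(name, n_in, "skipped", reason=str(err)))
            continue
        try:
            pairs = independent_pairs_correlation(
                change,
                n_samples=n_samples,
                seed=sseed,
                method=method,
                eligible=mask,
                min_pairs=min_edges,
            )
        except DegenerateInputError as err:
            results.append(
                StratumResult(name, n_in, "skipped", reason=str(err),
                              descriptive=desc)
            )
            continue
        results.append(
            StratumResult(name, n_in, "ok", descriptive=desc, pairs=pairs)
        )
    return results


def _descriptive_within(
    change: EdgeChangeMap, mask: np.ndarray, method: str
) -> dict:
    """All-edges descriptive correlation restricted to a stratum."""
    vals = change.values.values[mask]
    dists = change.distances.values[mask]
    if np.ptp(vals) == 0 or np.ptp(dists) == 0:
        raise DegenerateInputError("zero variance within stratum")
    if method == "spearman":
        coef = float(stats.spearmanr(dists, vals).statistic)
    elif method == "pearson":
        coef = float(stats.pearsonr(dists, vals).statistic)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return {
        "coefficient": coef,
        "n_edges": int(vals.size),
        "method": method,
        "label": "descriptive (non-independent points)",
    }


# ---------------------------------------------------------------------------
# Homotopic stability


@dataclass
class HomotopicStabilityResult:
    proportion_non_homotopic: float
    proportion_homotopic: float
    ci_bounds: tuple[float, float]
    n_homotopic: int
    n_non_homotopic: int
    degenerate: bool
    histogram: dict  # shared bin edges + per-class counts (Fig-13E-style)


def homotopic_stability_test(
    change: EdgeChangeMap, strata: EdgeStrata, n_bins: int = 30
) -> HomotopicStabilityResult:
    """Exceedance test for homotopic stability.

    Pools all inter-hemispheric change values, takes their empirical
    2.5th/97.5th percentile interval, and reports the proportion of
    homotopic and of non-homotopic values lying outside it. Stable edges
    hug zero and rarely exceed the pooled interval.
    """
    hom_vals = change.values.values[strata.mask("inter_homotopic")]
    non_vals = change.values.values[strata.mask("inter_non_homotopic")]
    if hom_vals.size < 1 or non_vals.size < 1:
        raise InvalidArgumentError(
            "need at least one homotopic and one non-homotopic inter-"
            "hemispheric edge"
        )
    pooled = np.concatenate([hom_vals, non_vals])
    lo, hi = np.quantile(pooled, [0.025, 0.975])
    degenerate = bool(lo == hi)
    if degenerate:
        p_hom = p_non = 0.0
    else:
        p_hom = float(np.mean((hom_vals < lo) | (hom_vals > hi)))
        p_non = float(np.mean((non_vals < lo) | (non_vals > hi)))
    edges = np.histogram_bin_edges(pooled, bins=n_bins)
    return HomotopicStabilityResult(
        proportion_non_homotopic=p_non,
        proportion_homotopic=p_hom,
        ci_bounds=(float(lo), float(hi)),
        n_homotopic=int(hom_vals.size),
        n_non_homotopic=int(non_vals.size),
        degenerate=degenerate,
        histogram={
            "bin_edges": edges,
            "homotopic_counts": np.histogram(hom_vals, bins=edges)[0],
            "non_homotopic_counts": np.histogram(non_vals, bins=edges)[0],
        },
    )
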