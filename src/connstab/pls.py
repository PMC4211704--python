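"""Task partial least squares (task-PLS) on vectorized connectomes.

Mean-centered task PLS: the matrix of cell means (one row per group x
condition cell, one column per unique edge), column-centered by the grand
mean across cells, is decomposed by SVD. Each latent variable (LV) pairs a
design salience vector (a contrast over cells), a brain salience vector
(one weight per edge), and a singular value; the squared singular values
partition the cross-block covariance, so LV1 explains the most. This is
equivalent, up to column scaling, to the SVD of the covariance between the
edge data and a dummy-coded centered design matrix (asserted in tests).

Inference follows the standard resampling scheme: LV significance by
permutation of group/condition labels (p = proportion of permuted singular
values at the same position that reach the observed one), and per-edge
reliability by bootstrap resampling of subjects within group, summarized as
the bootstrap ratio (salience / bootstrap SE of the salience).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .connectivity import ConnectivityDataset, upper_triangle_vector
from .errors import InvalidArgumentError, InvalidDesignError

#: bootstrap SEs below this are floored (and the edge flagged) before ratios
SE_FLOOR = 1e-12


@dataclass
class PlsModel:
    """Latent variables of a task-PLS decomposition.

    saliences: (n_lv, n_edges), unit-norm mutually orthogonal rows.
    design_saliences: (n_cells, n_lv) contrast weights over cells.
    singular_values: non-negative, non-increasing.
    covariance_fraction: singular_value^2 / sum of squares (NaN if degenerate).
    p_values: per-LV permutation p, filled by :func:`permutation_test`.
    """

    cell_order: list[tuple[str, str]]
    saliences: np.ndarray
    design_saliences: np.ndarray
    singular_values: np.ndarray
    covariance_fraction: np.ndarray
    degenerate: bool = False
    p_values: Optional[np.ndarray] = None
    n_permutations: int = 0
    n_bootstraps: int = 0

    @property
    def n_lv(self) -> int:
        return self.singular_values.size


@dataclass
class BootstrapResult:
    """Bootstrap standard errors and ratios, per LV x edge.

    ``flagged`` marks edges whose SE hit the numerical floor; their ratios
    are not meaningful.
    """

    se: np.ndarray
    bootstrap_ratio: np.ndarray
    flagged: np.ndarray
    n_resamples: int


# ---------------------------------------------------------------------------
# Cell means and SVD


def _stacked_observations(
    dataset: ConnectivityDataset,
) -> tuple[np.ndarray, list[tuple[str, str]], list[tuple[str, int]]]:
    """All subject x cell edge vectors, with their cell and subject labels."""
    rows, cells, subjects = [], [], []
    for cell in dataset.design:
        arr = dataset.z[cell]
        for s in range(arr.shape[0]):
            rows.append(upper_triangle_vector(arr[s]).values)
            cells.append(cell)
            subjects.append((cell[0], s))
    return np.vstack(rows), cells, subjects

def _cell_means_from_rows(
    rows: np.ndarray,
    labels: list[tuple[str, str]],
    cell_order: list[tuple[str, str]],
) -> np.ndarray:
    means = np.empty((len(cell_order), rows.shape[1]))
    lab = np.array([cell_order.index(c) for c in labels])
    for k in range(len(cell_order)):
        members = lab == k
        if not members.any():
            raise InvalidDesignError(f"design cell {cell_order[k]} is empty")
        means[k] = rows[members].mean(axis=0)
    return means


def assemble_cell_means(
    dataset: ConnectivityDataset,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Cells x edges matrix of cell-mean edge vectors, column-centered by
    the grand mean across cells (mean-centered task PLS)."""
    for cell in dataset.design:
        if dataset.z[cell].shape[0] < 2:
            raise InvalidDesignError(f"cell {cell} has fewer than 2 subjects")
    rows, labels, _ = _stacked_observations(dataset)
    means = _cell_means_from_rows(rows, labels, list(dataset.design))
    centered = means - means.mean(axis=0, keepdims=True)
    return centered, list(dataset.design)


def _fix_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: per LV, the design-salience entry of
    largest magnitude is made non-negative (first index wins ties)."""
    u = u.copy()
    vt = vt.copy()
    for k in range(u.shape[1]):
        col = u[:, k]
        mags = np.abs(col)
        # ties at machine precision go to the first index, so balanced
        # two-cell contrasts get a stable sign
        lead = int(np.argmax(mags >= mags.max() * (1.0 - 1e-9)))
        if col[lead] < 0:
            u[:, k] = -col
            vt[k] = -vt[k]
    return u, vt


def pls_svd(
    centered_means: np.ndarray,
    cell_order: Optional[list[tuple[str, str]]] = None,
) -> PlsModel:
    """SVD of the centered cell-means matrix; LVs ordered by singular value."""
    m = np.asarray(centered_means, dtype=float)
    if not np.all(np.isfinite(m)):
        raise InvalidArgumentError("cell-means matrix must be finite")
    if cell_order is None:
        cell_order = [("g1", f"cell{k}") for k in range(m.shape[0])]
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    u, vt = _fix_signs(u, vt)
    total = float(np.sum(s**2))
    if total > 0:
        frac = s**2 / total
        degenerate = False
    else:
        frac = np.full_like(s, np.nan)
        degenerate = True
    return PlsModel(
        cell_order=list(cell_order),
        saliences=vt,
        design_saliences=u,
        singular_values=s,
        covariance_fraction=frac,
        degenerate=degenerate,
    )


def fit_pls(dataset: ConnectivityDataset) -> PlsModel:
    """Convenience: assemble cell means and decompose."""
    centered, order = assemble_cell_means(dataset)
    return pls_svd(centered, order)


# ---------------------------------------------------------------------------
# Permutation test


def _permuted_cell_means(
    subject_rows: dict[tuple[str, int], dict[str, np.ndarray]],
    group_slots: list[str],
    conditions_by_group: dict[str, list[str]],
    cell_order: list[tuple[str, str]],
    rng: np.random.Generator,
    mode: str,
) -> np.ndarray:
    """Cell means after one label permutation.

    mode 'full': whole subjects are relabeled across groups (group sizes
    preserved) and each subject's condition labels are shuffled.
    mode 'conditions': only the within-subject condition labels move.
    """
    subjects = list(subject_rows)
    if mode == "full":
        order = rng.permutation(len(subjects))
        assigned = [subjects[i] for i in order]
    else:
        assigned = subjects
    sums = {cell: None for cell in cell_order}
    counts = dict.fromkeys(cell_order, 0)
    for slot_idx, subj in enumerate(assigned):
        new_group = group_slots[slot_idx] if mode == "full" else subj[0]
        conds = conditions_by_group[new_group]
        own_series = list(subject_rows[subj].values())
        if len(own_series) != len(conds):
            raise InvalidDesignError(
                "group relabeling requires equal condition counts across groups"
            )
        perm = rng.permutation(len(conds))
        for pos, ci in enumerate(perm):
            cell = (new_group, conds[ci])
            vec = own_series[pos]
            if sums[cell] is None:
                sums[cell] = vec.copy()
            else:
                sums[cell] += vec
            counts[cell] += 1
    means = np.vstack([sums[c] / counts[c] for c in cell_order])
    return means - means.mean(axis=0, keepdims=True)


def permutation_test(
    dataset: ConnectivityDataset,
    n_perm: int = 500,
    seed: int = 0,
    mode: str = "full",
) -> PlsModel:
    """Permutation p-values for every LV.

    Group and condition labels are re-ordered without replacement over the
    stacked subject x cell observations, cell means are rebuilt and the SVD
    re-run; p(LV k) is the proportion of permuted position-k singular values
    >= the observed one. Returns the fitted model with ``p_values`` set.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    if mode not in ("full", "conditions"):
        raise InvalidArgumentError(f"unknown permutation mode {mode!r}")
    rows, labels, subj_labels = _stacked_observations(dataset)
    cell_order = list(dataset.design)
    if rows.shape[0] < len(cell_order):
        raise InvalidDesignError("fewer observations than design cells")
    model = fit_pls(dataset)

    # series per subject, keyed by the subject's own condition labels
    subject_rows: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for row, cell, subj in zip(rows, labels, subj_labels):
        subject_rows.setdefault(subj, {})[cell[1]] = row
    conditions_by_group = {g: dataset.conditions(g) for g in dataset.groups}
    group_slots = [subj[0] for subj in subject_rows]

    rng = np.random.default_rng(seed)
    k = model.n_lv
    exceed = np.zeros(k)
    for _ in range(n_perm):
        centered = _permuted_cell_means(
            subject_rows, group_slots, conditions_by_group, cell_order, rng, mode
        )
        s_perm = np.linalg.svd(centered, compute_uv=False)
        exceed += s_perm[:k] >= model.singular_values
    model.p_values = exceed / n_perm
    model.n_permutations = n_perm
    return model


# ---------------------------------------------------------------------------
# Bootstrap


def _procrustes_rotation(u_ref: np.ndarray, u_boot: np.ndarray) -> np.ndarray:
    """Orthogonal R minimizing ||u_boot @ R - u_ref||_F."""
    a, _, bt = np.linalg.svd(u_boot.T @ u_ref)
    return a @ bt


def bootstrap_ratios(
    dataset: ConnectivityDataset,
    model: Optional[PlsModel] = None,
    n_boot: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap standard errors of the saliences and their ratios.

    Subjects are redrawn with replacement within each group, keeping their
    condition labels; cell means are rebuilt, the SVD re-run and the
    bootstrap saliences aligned to the original by orthogonal Procrustes
    rotation of the design saliences (guards against sign/axis flips
    inflating the SE). SE is the standard deviation over resamples; the
    bootstrap ratio is salience / SE with the SE floored at 1e-12 (floored
    edges are flagged).
    """
    if model is None:
        model = fit_pls(dataset)
    for cell in dataset.design:
        if dataset.z[cell].shape[0] < 3:
            raise InvalidDesignError(f"cell {cell} has fewer than 3 subjects")
    rng = np.random.default_rng(seed)
    cell_order = list(dataset.design)
    k = model.n_lv

    # pre-vectorized per-cell subject x edges arrays
    cell_rows = {}
    for cell in cell_order:
        arr = dataset.z[cell]
        cell_rows[cell] = np.vstack(
            [upper_triangle_vector(arr[s]).values for s in range(arr.shape[0])]
        )
    groups = dataset.groups
    n_subj = {g: dataset.n_subjects(g) for g in groups}

    boots = np.empty((n_boot, k, model.saliences.shape[1]))
    for b in range(n_boot):
        idx = {g: rng.integers(0, n_subj[g], n_subj[g]) for g in groups}
        means = np.vstack(
            [cell_rows[cell][idx[cell[0]]].mean(axis=0) for cell in cell_order]
        )
        centered = means - means.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        r = _procrustes_rotation(model.design_saliences, u[:, :k])
        boots[b] = r.T @ vt[:k]

    se = boots.std(axis=0, ddof=1)
    flagged = se <= SE_FLOOR
    ratio = model.saliences / np.maximum(se, SE_FLOOR)
    model.n_bootstraps = n_boot
    return BootstrapResult(se=se, bootstrap_ratio=ratio, flagged=flagged,
                           n_resamples=n_boot)
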