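"""Readers and writers for connectivity datasets.

The MAT-v5 layout mirrors the supplementary-data convention of multi-study
connectivity releases: one cell array whose cells are experimental groups,
each cell a 4-D array ordered Conditions x Participants x Regions x Regions
of Fisher-z (or raw r) correlation matrices. Node coordinates travel in a
separate CSV table since MAT connectivity files carry no geometry.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .connectivity import ConnectivityDataset, fisher_z
from .errors import FormatError
from .synthetic import Parcellation

MAT_SYMMETRY_TOL = 1e-6


def load_parcellation_csv(path: str | Path) -> Parcellation:
    """Node table: node_id, x, y, z, hemisphere, homotope_of (blank = none)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: node table not found")
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("node_id", "x", "y", "z", "hemisphere", "homotope_of"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return Parcellation(
        tuple(str(v) for v in df["node_id"]),
        df[["x", "y", "z"]].to_numpy(dtype=float),
        tuple(str(v) for v in df["hemisphere"]),
        tuple(str(v) if str(v) else None for v in df["homotope_of"]),
    )


def _validate_matrix(m: np.ndarray, where: str) -> np.ndarray:
    """Symmetry/finiteness checks; r matrices (unit diagonal) are converted
    to Fisher z, z matrices (zero diagonal) pass through."""
    if not np.all(np.isfinite(m)):
        raise FormatError(f"{where}: non-finite entries")
    if np.max(np.abs(m - m.T)) > MAT_SYMMETRY_TOL:
        raise FormatError(f"{where}: asymmetric beyond {MAT_SYMMETRY_TOL:g}")
    m = (m + m.T) / 2.0
    diag = np.diag(m)
    if np.allclose(diag, 1.0, atol=1e-6):
        if np.max(np.abs(m)) > 1.0:
            raise FormatError(
                f"{where}: unit diagonal but entries outside [-1, 1]"
            )
        m = fisher_z(m)
    elif not np.allclose(diag, 0.0, atol=1e-6):
        raise FormatError(
            f"{where}: diagonal is neither ~1 (r matrix) nor ~0 (z matrix)"
        )
    out = np.asarray(m, dtype=float).copy()
    np.fill_diagonal(out, 0.0)
    return out


def load_matfile_dataset(
    path: str | Path,
    node_table_path: str | Path,
    var_name: Optional[str] = None,
    group_names: Optional[list[str]] = None,
    condition_names: Optional[list[str]] = None,
) -> ConnectivityDataset:
    """Read a Conditions x Participants x Regions x Regions MAT-v5 file.

    The file holds one cell array; each cell is an experimental group. Group
    and condition names default to group1.., condition1.. when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    parcellation = load_parcellation_csv(node_table_path)
    raw = loadmat(str(path))
    keys = [k for k in raw if not k.startswith("__")]
    if var_name is None:
        if len(keys) != 1:
            raise FormatError(
                f"{path}: expected one data variable, found {keys}; "
                "pass var_name"
            )
        var_name = keys[0]
    if var_name not in raw:
        raise FormatError(f"{path}: no variable {var_name!r}")
    cells = np.atleast_1d(np.squeeze(np.asarray(raw[var_name], dtype=object)))
    if cells.dtype != object:
        cells = np.array([cells], dtype=object)  # single-group plain array

    n = parcellation.n_nodes
    z: dict[tuple[str, str], np.ndarray] = {}
    design: list[tuple[str, str]] = []
    for gi, block in enumerate(cells.ravel()):
        arr = np.asarray(block, dtype=float)
        if arr.ndim != 4:
            raise FormatError(
                f"{path}: group {gi + 1} block must be 4-D "
                "(conditions x participants x regions x regions)"
            )
        n_cond, n_subj, r1, r2 = arr.shape
        if (r1, r2) != (n, n):
            raise FormatError(
                f"{path}: group {gi + 1} has {r1}x{r2} regions but the node "
                f"table lists {n}"
            )
        gname = (
            group_names[gi] if group_names is not None else f"group{gi + 1}"
        )
        for ci in range(n_cond):
            cname = (
                condition_names[ci]
                if condition_names is not None
                else f"condition{ci + 1}"
            )
            mats = np.stack(
                [
                    _validate_matrix(
                        arr[ci, si],
                        f"{path}: group {gname}, condition {cname}, "
                        f"participant {si + 1}",
                    )
                    for si in range(n_subj)
                ]
            )
            z[(gname, cname)] = mats
            design.append((gname, cname))
    return ConnectivityDataset(parcellation, design, z)


def save_matfile_dataset(
    dataset: ConnectivityDataset, path: str | Path, var_name: str = "connectivity"
) -> Path:
    """Write a ConnectivityDataset in the cell-array MAT-v5 layout
    (used for roundtrip validation; the reader is the primary interface)."""
    path = Path(path)
    groups = dataset.groups
    cell = np.empty((1, len(groups)), dtype=object)
    for gi, g in enumerate(groups):
        conds = dataset.conditions(g)
        block = np.stack([dataset.z[(g, c)] for c in conds])  # cond,subj,n,n
        cell[0, gi] = block
    savemat(str(path), {var_name: cell})
    return path


def save_parcellation_csv(parcellation: Parcellation, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "node_id": parcellation.node_ids,
            "x": parcellation.centroids[:, 0],
            "y": parcellation.centroids[:, 1],
            "z": parcellation.centroids[:, 2],
            "hemisphere": parcellation.hemisphere,
            "homotope_of": [
                p if p is not None else "" for p in parcellation.homotope_of
            ],
        }
    ).to_csv(path, index=False)
    return path
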