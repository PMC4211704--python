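"""Synthetic spatially embedded parcellations and multi-subject time series.

The generator emulates the statistical structure of multi-subject,
multi-condition ROI functional-connectivity studies:

* nodes embedded in 3-D space (mm) with left/right mirror pairs, so every
  left node has a homotopic partner at the mirror position in the x = 0 plane;
* baseline inter-regional correlation decaying exponentially with Euclidean
  distance (short-range edges stronger than long-range ones);
* elevated correlation on homotopic (mirror-pair) edges;
* a controllable group x condition effect on edge strength, whose magnitude
  profile over distance can be flat (null), increasing or decreasing
  (positive/negative controls), and which can be suppressed on homotopic
  edges to make them selectively stable;
* subject-level sampling noise from finite multivariate-normal time series.

Every stochastic operation takes an explicit seed and is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, InvalidArgumentError

#: baseline same-site correlation in the exponential distance decay
DEFAULT_R0 = 0.5
#: correlations are capped here before PSD repair so Fisher z stays finite
CORRELATION_CAP = 0.95
#: smallest eigenvalue accepted without PSD repair
PSD_TOLERANCE = -1e-8
#: minimum number of time points for estimable correlation matrices
MIN_TIMEPOINTS = 30


# ---------------------------------------------------------------------------
# Parcellation


@dataclass(frozen=True)
class Parcellation:
    """Node identities, 3-D centroids (mm), hemisphere labels and the
    homotope-partner map.

    Invariants (checked on construction): node ids unique; the homotope
    relation is symmetric and involutive; homotopic partners lie in opposite
    hemispheres.
    """

    node_ids: tuple[str, ...]
    centroids: np.ndarray  # (n, 3) float, mm
    hemisphere: tuple[str, ...]  # 'left' | 'right' | 'medial'
    homotope_of: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise InvalidArgumentError("node ids must be unique")
        cent = np.asarray(self.centroids, dtype=float)
        if cent.shape != (n, 3) or not np.all(np.isfinite(cent)):
            raise InvalidArgumentError("centroids must be a finite (n, 3) array")
        object.__setattr__(self, "centroids", cent)
        if len(self.hemisphere) != n or len(self.homotope_of) != n:
            raise InvalidArgumentError("field lengths disagree")
        for h in self.hemisphere:
            if h not in ("left", "right", "medial"):
                raise InvalidArgumentError(f"unknown hemisphere label {h!r}")
        index = {nid: i for i, nid in enumerate(self.node_ids)}
        for i, partner in enumerate(self.homotope_of):
            if partner is None:
                continue
            j = index.get(partner)
            if j is None:
                raise InvalidArgumentError(f"homotope {partner!r} is not a node")
            if self.homotope_of[j] != self.node_ids[i]:
                raise InvalidArgumentError("homotope relation must be symmetric")
            if {self.hemisphere[i], self.hemisphere[j]} != {"left", "right"}:
                raise InvalidArgumentError(
                    "homotopic partners must lie in opposite hemispheres"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    @property
    def homotope_index(self) -> np.ndarray:
        """Integer partner index per node; -1 where there is no homotope."""
        index = {nid: i for i, nid in enumerate(self.node_ids)}
        return np.array(
            [index[p] if p is not None else -1 for p in self.homotope_of],
            dtype=int,
        )

    def homotopic_edge_mask(self) -> np.ndarray:
        """Boolean (n, n) matrix marking node-and-mirror-partner edges."""
        n = self.n_nodes
        hom = self.homotope_index
        mask = np.zeros((n, n), dtype=bool)
        for i in range(n):
            if hom[i] >= 0:
                mask[i, hom[i]] = True
        return mask


def make_parcellation(
    n_pairs: int,
    n_medial: int = 0,
    extent: float = 140.0,
    seed: int = 0,
) -> Parcellation:
    """Draw a mirror-symmetric parcellation inside a cubic box.

    ``n_pairs`` left/right homotopic pairs plus ``n_medial`` midline nodes.
    Right-hemisphere x coordinates are uniform in (0, extent/2]; the left
    partner is the exact mirror image in the x = 0 plane; y and z are uniform
    in [-extent/2, extent/2]. Medial nodes sit on x = 0 and have no homotope.
    """
    if n_pairs < 1:
        raise InvalidArgumentError("n_pairs must be >= 1")
    if n_medial < 0:
        raise InvalidArgumentError("n_medial must be >= 0")
    if extent <= 0:
        raise InvalidArgumentError("extent must be > 0")
    rng = np.random.default_rng(seed)
    half = extent / 2.0

    ids: list[str] = []
    cent: list[np.ndarray] = []
    hemi: list[str] = []
    homo: list[Optional[str]] = []
    for k in range(n_pairs):
        x = rng.uniform(0.0, half)
        y, z = rng.uniform(-half, half, size=2)
        ids += [f"L{k + 1:03d}", f"R{k + 1:03d}"]
        cent += [np.array([-x, y, z]), np.array([x, y, z])]
        hemi += ["left", "right"]
        homo += [f"R{k + 1:03d}", f"L{k + 1:03d}"]
    for k in range(n_medial):
        y, z = rng.uniform(-half, half, size=2)
        ids.append(f"M{k + 1:03d}")
        cent.append(np.array([0.0, y, z]))
        hemi.append("medial")
        homo.append(None)
    return Parcellation(tuple(ids), np.vstack(cent), tuple(hemi), tuple(homo))


# ---------------------------------------------------------------------------
# Ground truth


@dataclass(frozen=True)
class GroundTruth:
    """Population parameters behind a synthetic dataset.

    decay_length
        Length scale (mm) of the exponential falloff of baseline correlation.
    homotopic_boost
        Additive correlation increment on homotopic edges (capped below 1).
    effect_map
        Per-edge condition-effect magnitude in Fisher-z units, in canonical
        upper-triangle order; None means no condition effect.
    effect_profile
        'flat' (magnitudes independent of distance), 'increasing' or
        'decreasing' (signed effect proportional to standardized distance).
    homotopic_stability
        Multiplier in [0, 1] applied to the effect on homotopic edges;
        0 makes homotopic edges perfectly stable across conditions.
    condition_weights
        Contrast weight per condition name; the z-space shift of a cell's
        population matrix is weight * effect_map. Conditions absent from the
        map get weight 0.
    r0
        Baseline correlation at zero distance.
    """

    decay_length: float = 45.0
    homotopic_boost: float = 0.2
    effect_map: Optional[np.ndarray] = None
    effect_profile: str = "flat"
    homotopic_stability: float = 0.0
    condition_weights: dict[str, float] = field(default_factory=dict)
    r0: float = DEFAULT_R0

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise InvalidArgumentError("decay_length must be > 0")
        if not 0.0 <= self.homotopic_stability <= 1.0:
            raise InvalidArgumentError("homotopic_stability must be in [0, 1]")
        if self.effect_profile not in ("flat", "increasing", "decreasing"):
            raise InvalidArgumentError(
                f"unknown effect_profile {self.effect_profile!r}"
            )
        if self.effect_map is not None:
            object.__setattr__(
                self, "effect_map", np.asarray(self.effect_map, dtype=float)
            )


def default_condition_weights(conditions: Sequence[str]) -> dict[str, float]:
    """Centered linear contrast over conditions, spanning +1/2 .. -1/2.

    For two conditions this is the classic +1/2 vs -1/2 contrast: the
    between-condition difference of population z matrices equals effect_map.
    """
    k = len(conditions)
    if k == 1:
        return {conditions[0]: 0.0}
    w = np.linspace(0.5, -0.5, k)
    return {c: float(wi) for c, wi in zip(conditions, w)}


def make_effect_map(
    parcellation: Parcellation,
    effect_profile: str = "flat",
    effect_size: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Per-edge condition-effect magnitudes (z units), canonical edge order.

    flat
        sign * half-normal(scale=effect_size), i.i.d. of distance — the null
        used for calibration: |effect| carries no distance information.
    increasing / decreasing
        effect_size * (d_ij - mean d) / sd(d), with the stated sign — a
        one-knob positive/negative control whose change map is perfectly
        (anti)monotone in distance at the population level.
    """
    from .connectivity import distance_matrix, upper_triangle_vector

    if effect_size < 0:
        raise InvalidArgumentError("effect_size must be >= 0")
    d = upper_triangle_vector(distance_matrix(parcellation)).values
    rng = np.random.default_rng(seed)
    if effect_profile == "flat":
        mag = np.abs(rng.normal(0.0, effect_size, size=d.size))
        sign = rng.choice([-1.0, 1.0], size=d.size)
        return mag * sign
    if effect_profile in ("increasing", "decreasing"):
        sd = d.std()
        if sd == 0:
            raise DegenerateInputError("all inter-node distances identical")
        z = (d - d.mean()) / sd
        return effect_size * z if effect_profile == "increasing" else -effect_size * z
    raise InvalidArgumentError(f"unknown effect_profile {effect_profile!r}")


def default_truth(
    parcellation: Parcellation,
    conditions: Sequence[str] = ("A", "B"),
    effect_profile: str = "flat",
    effect_size: float = 0.1,
    decay_length: Optional[float] = None,
    homotopic_boost: float = 0.2,
    homotopic_stability: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Convenience constructor wiring an effect map and condition contrast."""
    if decay_length is None:
        span = parcellation.centroids.max() - parcellation.centroids.min()
        decay_length = max(span, 1.0) / 3.0
    return GroundTruth(
        decay_length=decay_length,
        homotopic_boost=homotopic_boost,
        effect_map=make_effect_map(parcellation, effect_profile, effect_size, seed),
        effect_profile=effect_profile,
        homotopic_stability=homotopic_stability,
        condition_weights=default_condition_weights(list(conditions)),
    )


# ---------------------------------------------------------------------------
# Population covariance


def _repair_psd(r: np.ndarray) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to the nearest (in the
    eigenvalue-clipping sense) positive semi-definite correlation matrix."""
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    w, v = np.linalg.eigh(r)
    if w.min() >= PSD_TOLERANCE:
        return r
    w = np.clip(w, 0.0, None)
    a = (v * w) @ v.T
    diag = np.diag(a).copy()
    if np.any(diag <= 0) or not np.all(np.isfinite(a)):
        raise DegenerateInputError(
            "covariance not repairable to a PSD correlation matrix"
        )
    scale = 1.0 / np.sqrt(diag)
    a = a * np.outer(scale, scale)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def make_population_covariance(
    parcellation: Parcellation,
    truth: GroundTruth,
    cell: tuple[str, str],
) -> np.ndarray:
    """Population correlation matrix of one (group, condition) cell.

    Baseline r_ij = r0 * exp(-d_ij / decay_length), plus homotopic_boost on
    homotopic edges, capped at 0.95. The condition effect (weight *
    effect_map, homotopic edges scaled by homotopic_stability) is added in
    Fisher-z space, mapped back through tanh, then the matrix is symmetrized,
    unit-diagonal'd and PSD-repaired by eigenvalue clipping.
    """
    from .connectivity import distance_matrix, edge_vector_to_matrix

    n = parcellation.n_nodes
    d = distance_matrix(parcellation)
    r = truth.r0 * np.exp(-d / truth.decay_length)
    hom = parcellation.homotopic_edge_mask()
    r[hom] += truth.homotopic_boost
    r = np.clip(r, -CORRELATION_CAP, CORRELATION_CAP)
    np.fill_diagonal(r, 1.0)

    weight = truth.condition_weights.get(cell[1], 0.0)
    if truth.effect_map is not None and weight != 0.0:
        effect = edge_vector_to_matrix(np.asarray(truth.effect_map, float), n)
        effect[hom | hom.T] *= truth.homotopic_stability
        off = ~np.eye(n, dtype=bool)
        z = np.arctanh(np.clip(r[off], -CORRELATION_CAP, CORRELATION_CAP))
        r[off] = np.tanh(z + weight * effect[off])
    return _repair_psd(r)


# ---------------------------------------------------------------------------
# Dataset sampling


@dataclass
class SyntheticDataset:
    """Multi-subject, multi-condition time series plus their ground truth.

    ``timeseries[(group, condition)]`` is an (n_subjects, T, n) array; the
    subject axis is aligned across conditions of the same group (subject s is
    the same individual in every condition).
    """

    parcellation: Parcellation
    design: list[tuple[str, str]]
    timeseries: dict[tuple[str, str], np.ndarray]
    truth: GroundTruth
    seed: int

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g, _ in self.design:
            if g not in seen:
                seen.append(g)
        return seen

    def conditions(self, group: str) -> list[str]:
        return [c for g, c in self.design if g == group]


def sample_dataset(
    parcellation: Parcellation,
    truth: GroundTruth,
    n_subjects_per_group: int,
    n_timepoints: int,
    seed: int,
    groups: Sequence[str] = ("g1",),
    conditions: Optional[Sequence[str]] = None,
) -> SyntheticDataset:
    """Draw every subject x cell series from the cell's population MVN.

    Each series is ``n_timepoints`` independent zero-mean multivariate-normal
    samples with the cell's population correlation matrix; a single RNG
    stream seeded from ``seed`` drives all draws.
    """
    if n_timepoints < MIN_TIMEPOINTS:
        raise InvalidArgumentError(
            f"n_timepoints must be >= {MIN_TIMEPOINTS} for estimability"
        )
    if n_subjects_per_group < 1:
        raise InvalidArgumentError("n_subjects_per_group must be >= 1")
    if conditions is None:
        conditions = list(truth.condition_weights) or ["A", "B"]
    rng = np.random.default_rng(seed)
    n = parcellation.n_nodes

    design = [(g, c) for g in groups for c in conditions]
    series: dict[tuple[str, str], np.ndarray] = {}
    factors = {}
    for cell in design:
        sigma = make_population_covariance(parcellation, truth, cell)
        w, v = np.linalg.eigh(sigma)
        factors[cell] = v * np.sqrt(np.clip(w, 0.0, None))
    for g in groups:
        for c in conditions:
            cell = (g, c)
            noise = rng.standard_normal((n_subjects_per_group, n_timepoints, n))
            series[cell] = noise @ factors[cell].T
    return SyntheticDataset(parcellation, design, series, truth, seed)


# ---------------------------------------------------------------------------
# On-disk bundle (plain-text: CSV + JSON)


def save_dataset(dataset: SyntheticDataset, path: str | Path) -> Path:
    """Write a dataset bundle: nodes.csv, design.csv, per-cell time-series
    CSVs and truth.json."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    parc = dataset.parcellation
    pd.DataFrame(
        {
            "node_id": parc.node_ids,
            "x": parc.centroids[:, 0],
            "y": parc.centroids[:, 1],
            "z": parc.centroids[:, 2],
            "hemisphere": parc.hemisphere,
            "homotope_of": [p if p is not None else "" for p in parc.homotope_of],
        }
    ).to_csv(root / "nodes.csv", index=False)

    rows = []
    for (g, c), arr in dataset.timeseries.items():
        for s in range(arr.shape[0]):
            rows.append({"group": g, "condition": c, "subject": s})
            fname = f"ts_{g}_{c}_s{s:03d}.csv"
            pd.DataFrame(arr[s], columns=list(parc.node_ids)).to_csv(
                root / fname, index=False
            )
    pd.DataFrame(rows).to_csv(root / "design.csv", index=False)

    truth = dataset.truth
    payload = {
        "decay_length": truth.decay_length,
        "homotopic_boost": truth.homotopic_boost,
        "effect_map": None
        if truth.effect_map is None
        else [float(v) for v in truth.effect_map],
        "effect_profile": truth.effect_profile,
        "homotopic_stability": truth.homotopic_stability,
        "condition_weights": truth.condition_weights,
        "r0": truth.r0,
        "seed": dataset.seed,
    }
    (root / "truth.json").write_text(json.dumps(payload, indent=1))
    return root


def load_dataset(path: str | Path) -> SyntheticDataset:
    """Read a bundle written by :func:`save_dataset`."""
    root = Path(path)
    nodes_path = root / "nodes.csv"
    if not nodes_path.exists():
        raise FormatError(f"{nodes_path}: missing nodes.csv")
    nodes = pd.read_csv(nodes_path, keep_default_na=False)
    for col in ("node_id", "x", "y", "z", "hemisphere", "homotope_of"):
        if col not in nodes.columns:
            raise FormatError(f"{nodes_path}: missing column {col!r}")
    parc = Parcellation(
        tuple(str(v) for v in nodes["node_id"]),
        nodes[["x", "y", "z"]].to_numpy(dtype=float),
        tuple(str(v) for v in nodes["hemisphere"]),
        tuple(str(v) if str(v) else None for v in nodes["homotope_of"]),
    )
    design_df = pd.read_csv(root / "design.csv")
    truth_raw = json.loads((root / "truth.json").read_text())
    truth = GroundTruth(
        decay_length=truth_raw["decay_length"],
        homotopic_boost=truth_raw["homotopic_boost"],
        effect_map=None
        if truth_raw["effect_map"] is None
        else np.asarray(truth_raw["effect_map"], float),
        effect_profile=truth_raw["effect_profile"],
        homotopic_stability=truth_raw["homotopic_stability"],
        condition_weights=truth_raw["condition_weights"],
        r0=truth_raw["r0"],
    )
    series: dict[tuple[str, str], list[np.ndarray]] = {}
    design: list[tuple[str, str]] = []
    for (g, c), sub in design_df.groupby(["group", "condition"], sort=False):
        cell = (str(g), str(c))
        design.append(cell)
        mats = []
        for s in sorted(int(v) for v in sub["subject"]):
            fname = root / f"ts_{g}_{c}_s{s:03d}.csv"
            if not fname.exists():
                raise FormatError(f"{fname}: listed in design.csv but missing")
            mats.append(pd.read_csv(fname).to_numpy(dtype=float))
        series[cell] = mats
    timeseries = {cell: np.stack(mats) for cell, mats in series.items()}
    return SyntheticDataset(parc, design, timeseries, truth, truth_raw.get("seed", 0))
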