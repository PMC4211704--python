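"""Top-level pipeline: configuration, orchestration and report writing.

One master seed deterministically spawns a per-stage seed for every source
of randomness (sampling, permutations, bootstrap, independent-pairs
matchings, Louvain runs), so a run is reproducible end to end from the
config alone. Resampling defaults are 500 permutations, 500 bootstrap
resamples, 1000 independent-pairs samples and 100 Louvain runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import io as cio
from . import pls as plsmod
from . import stability as stab
from . import stratification as strat
from . import synthetic as syn
from .errors import FormatError, InvalidArgumentError

logger = logging.getLogger("connstab")

DEFAULT_CHANGE_KINDS = (
    "salience",
    "bootstrap_ratio",
    "correlation_difference",
    "abs_salience",
    "abs_correlation_difference",
)

_STAGES = ("dataset", "permutation", "bootstrap", "pairs", "louvain", "strata")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    input: a dataset-bundle directory, a .mat connectivity file (then
    node_table is required for distances), or None to simulate from the
    ``synthetic`` parameter dict.
    """

    seed: int = 0
    n_perm: int = 500
    n_boot: int = 500
    n_pairs_samples: int = 1000
    louvain_runs: int = 100
    correlation_method: str = "spearman"
    change_kinds: tuple[str, ...] = DEFAULT_CHANGE_KINDS
    input: Optional[str] = None
    node_table: Optional[str] = None
    output: Optional[str] = None
    condition_pair: Optional[tuple] = None  # override greatest-difference cells
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_perm", "n_boot", "n_pairs_samples", "louvain_runs"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be a positive count")
        if self.correlation_method not in ("spearman", "pearson"):
            raise InvalidArgumentError(
                f"unknown correlation_method {self.correlation_method!r}"
            )
        for kind in self.change_kinds:
            if kind not in stab.CHANGE_KINDS:
                raise InvalidArgumentError(f"unknown change kind {kind!r}")
        self.change_kinds = tuple(self.change_kinds)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministically spawn one sub-seed per pipeline stage."""
    ss = np.random.SeedSequence(master_seed)
    states = ss.generate_state(len(_STAGES)) % (2**31)
    return {name: int(s) for name, s in zip(_STAGES, states)}


@dataclass
class StudyReport:
    """All computed results of one run, JSON-serializable via to_dict()."""

    config: RunConfig
    cells: list[tuple[str, str]]
    distance_fc: list[dict]
    lv_table: list[dict]
    change_results: dict[str, dict]
    partition: dict
    strata_results: list[dict]
    homotopy: dict

    def to_dict(self) -> dict:
        d = {
            "config": asdict(self.config),
            "cells": [list(c) for c in self.cells],
            "distance_fc": self.distance_fc,
            "lv_table": self.lv_table,
            "change_results": self.change_results,
            "partition": self.partition,
            "strata_results": self.strata_results,
            "homotopy": self.homotopy,
        }
        return _jsonify(d)


def _jsonify(obj):
    """Convert numpy scalars/arrays and round floats to 15 significant
    digits so serialized reports are byte-stable across runs."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if np.isnan(x):
            return None
        return float(f"{x:.15g}")
    return obj


# ---------------------------------------------------------------------------
# Dataset acquisition


def _synthetic_dataset(config: RunConfig, seed: int) -> conn.ConnectivityDataset:
    p = dict(config.synthetic)
    parc = syn.make_parcellation(
        n_pairs=p.get("n_pairs", 30),
        n_medial=p.get("n_medial", 0),
        extent=p.get("extent", 140.0),
        seed=seed,
    )
    truth = syn.default_truth(
        parc,
        conditions=tuple(p.get("conditions", ("A", "B"))),
        effect_profile=p.get("effect_profile", "flat"),
        effect_size=p.get("effect_size", 0.1),
        homotopic_boost=p.get("homotopic_boost", 0.2),
        homotopic_stability=p.get("homotopic_stability", 0.0),
        seed=seed + 1,
    )
    dataset = syn.sample_dataset(
        parc,
        truth,
        n_subjects_per_group=p.get("n_subjects", 20),
        n_timepoints=p.get("n_timepoints", 200),
        seed=seed + 2,
        groups=tuple(p.get("groups", ("g1",))),
    )
    return conn.connectivity_from_timeseries(dataset)


def load_input(config: RunConfig, seed: int) -> conn.ConnectivityDataset:
    if config.input is None:
        logger.info("stage=dataset source=synthetic seed=%d", seed)
        return _synthetic_dataset(config, seed)
    path = Path(config.input)
    if path.is_dir():
        logger.info("stage=dataset source=bundle path=%s", path)
        return conn.connectivity_from_timeseries(syn.load_dataset(path))
    if path.suffix.lower() == ".mat":
        if config.node_table is None:
            raise FormatError(
                f"{path}: MAT connectivity input requires node_table — "
                "Euclidean distances need ROI centroid coordinates"
            )
        logger.info("stage=dataset source=mat path=%s", path)
        return cio.load_matfile_dataset(path, config.node_table)
    raise FormatError(f"{path}: not a dataset bundle directory or .mat file")


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute the full analysis and return (optionally write) the report."""
    seeds = stage_seeds(config.seed)
    dataset = load_input(config, seeds["dataset"])
    parc = dataset.parcellation
    d = conn.distance_matrix(parc)

    # within-condition distance-connectivity relationship, per cell
    distance_fc = []
    for cell in dataset.design:
        zbar = dataset.cell_mean(cell)
        for method in ("pearson", "spearman"):
            coef, n_e = conn.distance_fc_correlation(zbar, d, method)
            distance_fc.append(
                {
                    "group": cell[0],
                    "condition": cell[1],
                    "method": method,
                    "coefficient": coef,
                    "n_edges": n_e,
                }
            )
    logger.info("stage=connectivity cells=%d", len(dataset.design))

    # task PLS with permutation and bootstrap inference
    model = plsmod.permutation_test(
        dataset, n_perm=config.n_perm, seed=seeds["permutation"]
    )
    boot = plsmod.bootstrap_ratios(
        dataset, model, n_boot=config.n_boot, seed=seeds["bootstrap"]
    )
    logger.info(
        "stage=pls n_perm=%d n_boot=%d lv1_p=%.4f",
        config.n_perm,
        config.n_boot,
        model.p_values[0],
    )
    lv_table = [
        {
            "lv": k + 1,
            "singular_value": float(model.singular_values[k]),
            "covariance_fraction": float(model.covariance_fraction[k]),
            "p": float(model.p_values[k]),
        }
        for k in range(model.n_lv)
    ]

    # change maps
    if config.condition_pair is not None:
        cell_a, cell_b = (tuple(c) for c in config.condition_pair)
    else:
        cell_a, cell_b = stab.greatest_difference_cells(model)
    maps: dict[str, stab.EdgeChangeMap] = {}
    for kind in config.change_kinds:
        if kind == "salience":
            maps[kind] = stab.salience_change_map(model, parc)
        elif kind == "bootstrap_ratio":
            maps[kind] = stab.bootstrap_ratio_change_map(boot, parc)
        elif kind == "correlation_difference":
            maps[kind] = stab.correlation_difference(dataset, cell_a, cell_b)
        elif kind == "abs_salience":
            maps[kind] = stab.salience_change_map(model, parc).absolute()
        elif kind == "abs_correlation_difference":
            maps[kind] = stab.correlation_difference(
                dataset, cell_a, cell_b
            ).absolute()

    pair_ss = np.random.SeedSequence(seeds["pairs"])
    kind_seeds = pair_ss.generate_state(len(maps)) % (2**31)
    change_results: dict[str, dict] = {}
    for (kind, cmap), kseed in zip(maps.items(), kind_seeds):
        desc = stab.change_distance_correlation(cmap, config.correlation_method)
        pairs = stab.independent_pairs_correlation(
            cmap,
            n_samples=config.n_pairs_samples,
            seed=int(kseed),
            method=config.correlation_method,
        )
        entry = {
            "descriptive": desc,
            "independent_pairs": {
                "rho": pairs.mean_rho,
                "se": pairs.se,
                "se_of_mean": pairs.se_of_mean,
                "p_greater": pairs.p_greater,
                "p_less": pairs.p_less,
                "n_pairs_per_sample": pairs.n_pairs_per_sample,
                "n_samples": pairs.n_samples,
                "method": pairs.method,
            },
        }
        if len(cmap.values) >= 20:
            pca = stab.pca_outlier_diagnostic(cmap)
            entry["pca_outliers"] = {
                "principal_axis": pca.principal_axis,
                "outlier_correlation": pca.outlier_correlation,
                "n_flagged": int(
                    pca.upper_indices.size + pca.lower_indices.size
                ),
                "degenerate": pca.degenerate,
            }
        hist = stab.density_histogram_2d(cmap)
        entry["density"] = {
            "counts": hist["counts"],
            "x_edges": hist["x_edges"],
            "y_edges": hist["y_edges"],
        }
        if cmap.condition_pair is not None:
            entry["condition_pair"] = [list(c) for c in cmap.condition_pair]
        change_results[kind] = entry
        logger.info(
            "stage=stability kind=%s rho=%.4f p>=%.3f p<=%.3f",
            kind,
            pairs.mean_rho,
            pairs.p_greater,
            pairs.p_less,
        )

    # stratification on the first change kind
    primary_kind = config.change_kinds[0]
    partition = strat.louvain_partition(
        dataset.grand_mean(), n_runs=config.louvain_runs, seed=seeds["louvain"]
    )
    strata = strat.classify_edges(parc, partition)
    strata_res = strat.stratified_distance_analysis(
        maps[primary_kind],
        strata,
        n_samples=config.n_pairs_samples,
        seed=seeds["strata"],
        method=config.correlation_method,
    )
    strata_results = []
    for sres in strata_res:
        row = {
            "stratum": sres.name,
            "n_edges": sres.n_edges,
            "status": sres.status,
            "reason": sres.reason,
            "change_kind": primary_kind,
        }
        if sres.descriptive is not None:
            row["descriptive"] = sres.descriptive
        if sres.pairs is not None:
            row.update(
                rho=sres.pairs.mean_rho,
                se=sres.pairs.se,
                p_greater=sres.pairs.p_greater,
                p_less=sres.pairs.p_less,
            )
        strata_results.append(row)
    logger.info(
        "stage=stratification q=%.4f modules=%d",
        partition.q,
        partition.n_modules,
    )

    homot = strat.homotopic_stability_test(maps[primary_kind], strata)
    homotopy = {
        "change_kind": primary_kind,
        "proportion_non_homotopic": homot.proportion_non_homotopic,
        "proportion_homotopic": homot.proportion_homotopic,
        "ci_lower": homot.ci_bounds[0],
        "ci_upper": homot.ci_bounds[1],
        "n_homotopic": homot.n_homotopic,
        "n_non_homotopic": homot.n_non_homotopic,
        "degenerate": homot.degenerate,
        "histogram": {
            "bin_edges": homot.histogram["bin_edges"],
            "homotopic_counts": homot.histogram["homotopic_counts"],
            "non_homotopic_counts": homot.histogram["non_homotopic_counts"],
        },
    }
    logger.info(
        "stage=homotopy hom=%.4f non_hom=%.4f",
        homot.proportion_homotopic,
        homot.proportion_non_homotopic,
    )

    report = StudyReport(
        config=config,
        cells=list(dataset.design),
        distance_fc=distance_fc,
        lv_table=lv_table,
        change_results=change_results,
        partition={
            "assignment": partition.assignment,
            "node_ids": list(parc.node_ids),
            "q": partition.q,
            "n_runs": partition.n_runs,
            "n_modules": partition.n_modules,
            "degenerate": partition.degenerate,
        },
        strata_results=strata_results,
        homotopy=homotopy,
    )
    if config.output is not None:
        write_report(report, config.output)
    return report


# ---------------------------------------------------------------------------
# Report serialization


def write_report(report: StudyReport, path: str | Path) -> Path:
    """JSON master file plus fixed-column CSV tables."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    (out / "report.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n"
    )

    rows = []
    for kind, entry in payload["change_results"].items():
        ip = entry["independent_pairs"]
        rows.append(
            {
                "study": kind,
                "rho": ip["rho"],
                "SE": ip["se"],
                "p_rho_gt_0": ip["p_greater"],
                "p_rho_lt_0": ip["p_less"],
            }
        )
    pd.DataFrame(rows, columns=["study", "rho", "SE", "p_rho_gt_0", "p_rho_lt_0"]).to_csv(
        out / "table2.csv", index=False
    )

    srows = []
    for row in payload["strata_results"]:
        srows.append(
            {
                "stratum": row["stratum"],
                "n_edges": row["n_edges"],
                "status": row["status"],
                "rho": row.get("rho"),
                "SE": row.get("se"),
                "p_rho_gt_0": row.get("p_greater"),
                "p_rho_lt_0": row.get("p_less"),
            }
        )
    pd.DataFrame(
        srows,
        columns=["stratum", "n_edges", "status", "rho", "SE", "p_rho_gt_0",
                 "p_rho_lt_0"],
    ).to_csv(out / "strata.csv", index=False)

    pd.DataFrame(
        payload["lv_table"], columns=["lv", "singular_value",
                                      "covariance_fraction", "p"]
    ).to_csv(out / "lv.csv", index=False)

    h = payload["homotopy"]
    pd.DataFrame(
        [
            {
                "class": "homotopic",
                "n_edges": h["n_homotopic"],
                "proportion_exceeding": h["proportion_homotopic"],
                "ci_lower": h["ci_lower"],
                "ci_upper": h["ci_upper"],
            },
            {
                "class": "non_homotopic",
                "n_edges": h["n_non_homotopic"],
                "proportion_exceeding": h["proportion_non_homotopic"],
                "ci_lower": h["ci_lower"],
                "ci_upper": h["ci_upper"],
            },
        ],
        columns=["class", "n_edges", "proportion_exceeding", "ci_lower",
                 "ci_upper"],
    ).to_csv(out / "homotopy.csv", index=False)

    pd.DataFrame(
        {
            "node": payload["partition"]["node_ids"],
            "module": payload["partition"]["assignment"],
        }
    ).to_csv(out / "partition.csv", index=False)
    return out


def read_report(path: str | Path) -> dict:
    """Load the JSON master file of a written report."""
    return json.loads((Path(path) / "report.json").read_text())
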