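"""Replicate-level simulation studies used to validate the pipeline.

Each study generates many synthetic datasets under fixed conditions —
60 nodes (30 mirror pairs), 20 subjects per group, 2 conditions, 200 time
points — runs the relevant stage of the pipeline on every replicate, and
summarizes recovery or calibration rates. The flat effect profile is the
null for distance dependence (effect magnitudes i.i.d. of distance); the
increasing profile is the positive control.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import connectivity as conn
from . import pls as plsmod
from . import stability as stab
from . import stratification as strat
from . import synthetic as syn

STUDY_N_PAIRS = 30
STUDY_EXTENT = 140.0
STUDY_SUBJECTS = 20
STUDY_TIMEPOINTS = 200
STUDY_EFFECT_SIZE = 0.1


def _replicate(
    seed: int,
    effect_profile: str,
    effect_size: float = STUDY_EFFECT_SIZE,
    homotopic_stability: float = 0.0,
) -> tuple[conn.ConnectivityDataset, syn.GroundTruth]:
    """One synthetic study: fixed-size parcellation, fresh effect map and
    subject sample per replicate."""
    parc = syn.make_parcellation(STUDY_N_PAIRS, 0, STUDY_EXTENT, seed=seed)
    truth = syn.default_truth(
        parc,
        effect_profile=effect_profile,
        effect_size=effect_size,
        homotopic_stability=homotopic_stability,
        seed=seed + 1,
    )
    dataset = syn.sample_dataset(
        parc, truth, STUDY_SUBJECTS, STUDY_TIMEPOINTS, seed=seed + 2
    )
    return conn.connectivity_from_timeseries(dataset), truth


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % 2**30]


def independent_pairs_calibration(
    n_replicates: int = 50,
    n_samples: int = 1000,
    seed: int = 0,
    effect_profile: str = "flat",
) -> dict:
    """Independent-pairs test over replicate synthetic studies.

    Under the flat profile this calibrates the null: the two-sided rejection
    rate (min(p_greater, p_less) < 0.025) should sit near 0.05 and mean
    |rho| should be small. Under the increasing profile it measures power
    and the directional rate p_less < 0.025.
    """
    seeds = _spawn(seed, 2 * n_replicates)
    rejections, directional, mean_abs_rho = [], [], []
    for k in range(n_replicates):
        cds, _truth = _replicate(seeds[2 * k], effect_profile)
        model = plsmod.fit_pls(cds)
        cmap = stab.salience_change_map(model, cds.parcellation)
        res = stab.independent_pairs_correlation(
            cmap, n_samples=n_samples, seed=seeds[2 * k + 1]
        )
        rejections.append(min(res.p_greater, res.p_less) < 0.025)
        directional.append(res.p_less < 0.025)
        mean_abs_rho.append(abs(res.mean_rho))
    mean_abs_rho = np.asarray(mean_abs_rho)
    return {
        "n_replicates": n_replicates,
        "two_sided_rejection_rate": float(np.mean(rejections)),
        "directional_rejection_rate": float(np.mean(directional)),
        "mean_abs_rho": float(mean_abs_rho.mean()),
        "frac_abs_rho_below_0.1": float(np.mean(mean_abs_rho < 0.1)),
    }


def pls_recovery_study(
    n_replicates: int = 20,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Recovery of a planted 2-condition contrast by LV1.

    Reports the mean correlation between LV1 saliences and the planted
    effect map and the fraction of replicates with LV1 permutation
    p < 0.05 (statistical power under a moderate flat-profile effect).
    """
    seeds = _spawn(seed, 2 * n_replicates)
    corrs, detected = [], []
    for k in range(n_replicates):
        cds, truth = _replicate(seeds[2 * k], "flat")
        model = plsmod.permutation_test(cds, n_perm=n_perm, seed=seeds[2 * k + 1])
        corrs.append(
            stats.pearsonr(model.saliences[0], truth.effect_map).statistic
        )
        detected.append(model.p_values[0] < 0.05)
    return {
        "n_replicates": n_replicates,
        "mean_salience_recovery_correlation": float(np.mean(corrs)),
        "min_salience_recovery_correlation": float(np.min(corrs)),
        "lv1_detection_rate": float(np.mean(detected)),
    }


def pls_null_calibration(
    n_replicates: int = 200,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """False-positive rate of the LV1 permutation test under no effect."""
    seeds = _spawn(seed, 2 * n_replicates)
    parc = syn.make_parcellation(STUDY_N_PAIRS, 0, STUDY_EXTENT, seed=seed)
    truth = syn.GroundTruth(condition_weights={"A": 0.0, "B": 0.0})
    hits = []
    for k in range(n_replicates):
        dataset = syn.sample_dataset(
            parc, truth, STUDY_SUBJECTS, STUDY_TIMEPOINTS, seed=seeds[2 * k]
        )
        cds = conn.connectivity_from_timeseries(dataset)
        model = plsmod.permutation_test(cds, n_perm=n_perm, seed=seeds[2 * k + 1])
        hits.append(model.p_values[0] < 0.05)
    return {
        "n_replicates": n_replicates,
        "false_positive_rate": float(np.mean(hits)),
    }


def homotopic_stability_study(
    n_replicates: int = 50,
    seed: int = 0,
    homotopic_stability: float = 0.0,
) -> dict:
    """Exceedance-proportion recovery for perfectly stable homotopic edges.

    With homotopic_stability = 0 the condition effect is removed from
    homotopic edges, so their change saliences hug zero; the proportion of
    homotopic edges outside the pooled inter-hemispheric 95% interval
    should fall below the non-homotopic proportion in most replicates.
    """
    seeds = _spawn(seed, n_replicates)
    hom_props, non_props, success = [], [], []
    for k in range(n_replicates):
        cds, _truth = _replicate(
            seeds[k], "flat", homotopic_stability=homotopic_stability
        )
        model = plsmod.fit_pls(cds)
        cmap = stab.salience_change_map(model, cds.parcellation)
        strata = strat.classify_edges(cds.parcellation)
        res = strat.homotopic_stability_test(cmap, strata)
        hom_props.append(res.proportion_homotopic)
        non_props.append(res.proportion_non_homotopic)
        success.append(res.proportion_homotopic < res.proportion_non_homotopic)
    return {
        "n_replicates": n_replicates,
        "mean_proportion_homotopic": float(np.mean(hom_props)),
        "mean_proportion_non_homotopic": float(np.mean(non_props)),
        "success_rate": float(np.mean(success)),
    }


def distance_decay_recovery(
    n_replicates: int = 50,
    n_timepoints: int = STUDY_TIMEPOINTS,
    seed: int = 0,
) -> dict:
    """Fraction of replicate datasets whose empirical distance-z
    correlation is negative (the within-condition decay signature)."""
    seeds = _spawn(seed, n_replicates)
    negative = []
    for k in range(n_replicates):
        parc = syn.make_parcellation(STUDY_N_PAIRS, 0, STUDY_EXTENT, seed=seeds[k])
        truth = syn.GroundTruth(
            decay_length=STUDY_EXTENT / 3.0,
            condition_weights={"A": 0.0},
        )
        dataset = syn.sample_dataset(
            parc, truth, 1, n_timepoints, seed=seeds[k] + 1, conditions=("A",)
        )
        cds = conn.connectivity_from_timeseries(dataset)
        d = conn.distance_matrix(parc)
        coef, _ = conn.distance_fc_correlation(cds.cell_mean(("g1", "A")), d)
        negative.append(coef < 0)
    return {
        "n_replicates": n_replicates,
        "negative_rate": float(np.mean(negative)),
    }
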