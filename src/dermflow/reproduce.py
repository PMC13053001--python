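"""End-to-end reproduction of the published cost and waiting-time results.

This module wires the other modules together: build the baseline
configurations, run the cost-comparison analysis (deterministic, PSA, DSA),
calibrate each arm's stage delays to the published waiting-time anchors,
run five 1-year simulation replications per arm, and assemble the headline
quantities — arm-level weighted communication times, clinical- and
histopathological-diagnosis means, and the three incremental deltas.

Three separate calibration scenarios are used, one per endpoint family,
because the published per-pathway communication means and the arm-level
histopathology means are not mutually consistent as outputs of a single
parameterisation (communication cannot precede histopathology for the same
patients); each scenario anchors its own endpoint and reports only that
endpoint, leaving the published tension visible rather than resolving it.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from . import calibration as cal
from . import costs as cm
from .config import (
    CCA_DISTRIBUTION,
    DES_DISTRIBUTION,
    N_REFERRALS_COMPARATOR,
    N_REFERRALS_INTERVENTION,
    default_arm_config,
)
from .des import incremental_times, replicate, weighted_average_time
from .pathways import ArmDistribution, COMPARATOR, INTERVENTION

ARMS = (INTERVENTION, COMPARATOR)


def _seed_pool(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def biopsy_share_reduction(distributions: dict[str, dict[str, float]]) -> float:
    """Percentage-point drop in biopsy-reliant referral share, comparator
    minus intervention, for a named distribution set."""
    comp = 100.0 * distributions[COMPARATOR].get("G", 0.0)
    intv = 100.0 * sum(distributions[INTERVENTION].get(p, 0.0) for p in ("C", "D"))
    return comp - intv


def reproduce_costs(seed: int, n_iter: int = 1000) -> dict[str, Any]:
    """Cost-comparison analysis: arm means, PSA, overall saving, t test, DSA."""
    params = cm.default_cost_params("cca")
    intervention_mean = cm.arm_mean_cost(params.distributions[INTERVENTION],
                                         params.unit_costs)
    comparator_mean = cm.arm_mean_cost(params.distributions[COMPARATOR],
                                       params.unit_costs)
    det = cm.incremental_saving(comparator_mean, intervention_mean)
    psa = cm.run_psa(params, n_iter=n_iter, seed=seed)

    rng = np.random.default_rng(_seed_pool(seed, 2)[1])
    costs_i = cm.sample_patient_costs(
        params.distributions[INTERVENTION], params.unit_costs,
        N_REFERRALS_INTERVENTION, rng, staff_cv=0.12,
    )
    costs_c = cm.sample_patient_costs(
        params.distributions[COMPARATOR], params.unit_costs,
        N_REFERRALS_COMPARATOR, rng, staff_cv=0.12,
    )
    t_stat, p_value = cm.welch_t_test(costs_c, costs_i)

    tornado = {
        name: cm.run_dsa(params, name, low, high)
        for name, (low, high) in {
            "unit_cost.G": (params.unit_costs["G"] * 0.8, params.unit_costs["G"] * 1.2),
            "unit_cost.D": (params.unit_costs["D"] * 0.8, params.unit_costs["D"] * 1.2),
            "biopsy_offset": (0.0, 1.0),
        }.items()
    }
    return {
        "intervention_mean": intervention_mean,
        "comparator_mean": comparator_mean,
        "deterministic_saving": det,
        "psa_mean_saving": psa.mean,
        "psa_ci95": list(psa.ci95),
        "psa_prob_saving_positive": psa.prob_saving_positive,
        "psa_n_iter": psa.n_iter,
        "overall_saving": cm.total_saving(psa.mean, params.n_referrals),
        "overall_ci95": [cm.total_saving(b, params.n_referrals) for b in psa.ci95],
        "n_referrals": params.n_referrals,
        "welch_t": t_stat,
        "welch_p": p_value,
        "tornado": {k: list(v) for k, v in tornado.items()},
        "biopsy_share_reduction_pct": {
            "cca": biopsy_share_reduction(CCA_DISTRIBUTION),
            "des": biopsy_share_reduction(DES_DISTRIBUTION),
        },
    }


def _calibrated_runs(
    scenario: str,
    seed: int,
    n_reps: int,
    annual_volume: float,
    calib_reps: int,
):
    """Calibrate both arms for one endpoint scenario and run fresh
    replications; returns arm -> (pooled log, summary, report)."""
    target_fns = {
        "communication": cal.comm_calibration_targets,
        "clinical": cal.clinical_calibration_targets,
        "histopath": cal.histopath_calibration_targets,
    }
    seeds = _seed_pool(seed, 4)
    out = {}
    for i, arm in enumerate(ARMS):
        config = default_arm_config(arm, "des", annual_volume=annual_volume)
        calibrated, report = cal.calibrate_arm(
            config, target_fns[scenario](arm), seed=seeds[i], n_reps=calib_reps
        )
        log, summary = replicate(calibrated, n_runs=n_reps, master_seed=seeds[2 + i])
        out[arm] = (log, summary, report)
    return out


def reproduce_des(
    seed: int,
    n_reps: int = 5,
    annual_volume: float = 3000.0,
    calib_reps: int = 5,
) -> dict[str, Any]:
    """Calibrated DES reproduction of the waiting-time tables.

    Runs the three calibration scenarios (communication, clinical
    diagnosis, histopathological diagnosis), five fresh 1-year
    replications per arm each, and assembles weighted arm means, pooled
    endpoint means and comparator-minus-intervention deltas.
    """
    scen_seeds = _seed_pool(seed, 3)
    results: dict[str, Any] = {"n_replications": n_reps,
                               "annual_volume": annual_volume}

    runs = _calibrated_runs("communication", scen_seeds[0], n_reps,
                            annual_volume, calib_reps)
    comm: dict[str, Any] = {}
    for arm in ARMS:
        log, summary, report = runs[arm]
        pw_means = {
            pid: (st["communication"].mean, st["communication"].se)
            for pid, st in summary.pathway_endpoints.items()
            if "communication" in st
        }
        dist = ArmDistribution(dict(DES_DISTRIBUTION[arm]))
        wmean, wse = weighted_average_time(pw_means, dist)
        comm[arm] = {
            "weighted_mean": wmean,
            "weighted_se": wse,
            "pooled_mean": summary.endpoints["communication"].mean,
            "pooled_se": summary.endpoints["communication"].se,
            "max": summary.endpoints["communication"].max,
            "pathway_means": {p: m for p, (m, _) in pw_means.items()},
            "n_patients": summary.n_patients,
            "calibration_converged": report.converged,
        }
    delta, ci = incremental_times(
        runs[INTERVENTION][1], runs[COMPARATOR][1]
    )["communication"]
    comm["delta_pooled"] = {"mean": delta, "ci95": list(ci)}
    comm["delta_weighted"] = (
        comm[COMPARATOR]["weighted_mean"] - comm[INTERVENTION]["weighted_mean"]
    )
    results["communication"] = comm

    for scenario, endpoint, sidx in (
        ("clinical", "clinical_diagnosis", 1),
        ("histopath", "histopath_diagnosis", 2),
    ):
        runs = _calibrated_runs(scenario, scen_seeds[sidx], n_reps,
                                annual_volume, calib_reps)
        block: dict[str, Any] = {}
        for arm in ARMS:
            _, summary, report = runs[arm]
            st = summary.endpoints[endpoint]
            block[arm] = {
                "pooled_mean": st.mean,
                "pooled_se": st.se,
                "ci95": list(st.ci95),
                "max": st.max,
                "n": st.n,
                "calibration_converged": report.converged,
            }
        delta, ci = incremental_times(
            runs[INTERVENTION][1], runs[COMPARATOR][1]
        )[endpoint]
        block["delta_pooled"] = {"mean": delta, "ci95": list(ci)}
        results[scenario] = block

    return results


def reproduce_all(
    seed: int,
    n_reps: int = 5,
    annual_volume: float = 3000.0,
    psa_iterations: int = 1000,
    skip_des: bool = False,
) -> dict[str, Any]:
    """Full reproduction: cost analysis plus (optionally) the DES tables."""
    seeds = _seed_pool(seed, 2)
    out: dict[str, Any] = {
        "seed": seed,
        "cost": reproduce_costs(seeds[0], n_iter=psa_iterations),
    }
    if not skip_des:
        out["des"] = reproduce_des(seeds[1], n_reps=n_reps,
                                   annual_volume=annual_volume)
    return out


def acceptance_targets(results: dict[str, Any]) -> dict[str, dict[str, float]]:
    """Map a full reproduction result onto the headline target quantities."""
    cost = results["cost"]
    out = {
        "t3": {"value": cost["psa_mean_saving"], "n": cost["psa_n_iter"]},
    }
    if "des" in results:
        des = results["des"]
        comm = des["communication"]
        n_pool = (comm[INTERVENTION]["n_patients"]
                  + comm[COMPARATOR]["n_patients"])
        out.update(
            {
                "t5": {"value": comm[INTERVENTION]["weighted_mean"],
                       "n": comm[INTERVENTION]["n_patients"]},
                "t6": {"value": comm[COMPARATOR]["weighted_mean"],
                       "n": comm[COMPARATOR]["n_patients"]},
                "t7": {"value": comm["delta_pooled"]["mean"], "n": n_pool},
                "t8": {"value": des["clinical"]["delta_pooled"]["mean"],
                       "n": n_pool},
                "t9": {"value": des["histopath"]["delta_pooled"]["mean"],
                       "n": (des["histopath"][INTERVENTION]["n"]
                             + des["histopath"][COMPARATOR]["n"])},
                "t10": {"value": des["clinical"][INTERVENTION]["pooled_mean"],
                        "n": comm[INTERVENTION]["n_patients"]},
            }
        )
    return out
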