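"""Cost-comparison analysis of the two referral arms.

The analysis is a budgetary comparison of direct medical costs from
referral to diagnosis (staff labour, diagnostic-biopsy procedures and
platform licensing), with no utility weighting.  Each arm's mean cost per
referral is the pathway-proportion-weighted sum of per-pathway unit costs,

    C_arm = sum_i p_i * c_i,

and the incremental saving is ``C_comparator - C_intervention`` (positive
values favour the teledermatology arm).  Uncertainty is handled two ways:

* a probabilistic sensitivity analysis (PSA) that redraws the unit costs
  from their uncertainty distributions for a fixed number of Monte-Carlo
  iterations and summarises the per-iteration saving (mean, percentile
  95% CI, probability the saving is positive); and
* a one-way deterministic sensitivity analysis (DSA) that fixes a single
  parameter at a low and a high bound, everything else at baseline, giving
  one tornado-diagram entry per parameter.

A Welch (unequal-variance) two-sample t test compares patient-level cost
samples between arms; Student's pooled-variance variant is available via
``equal_var=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pathways import ArmDistribution, COMPARATOR, INTERVENTION


@dataclass(frozen=True)
class UncertaintySpec:
    """Uncertainty on one scalar parameter for the PSA.

    ``family`` is ``"normal"`` (truncated at zero: costs cannot be
    negative) or ``"gamma"`` (moment-matched shape/scale).  ``se`` is the
    standard error on the parameter's baseline value.
    """

    family: str = "normal"
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "gamma"):
            raise ValueError(f"unsupported uncertainty family: {self.family!r}")
        if self.se < 0:
            raise ValueError("se must be non-negative")

    def sample(self, baseline: float, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.se == 0.0:
            return np.full(size, baseline)
        if self.family == "normal":
            return np.maximum(rng.normal(baseline, self.se, size), 0.0)
        shape = (baseline / self.se) ** 2
        scale = self.se**2 / baseline
        return rng.gamma(shape, scale, size)


@dataclass
class CostModelParams:
    """Inputs of the cost-comparison analysis.

    ``unit_costs`` maps pathway id → GBP; ``distributions`` maps arm →
    :class:`ArmDistribution`; ``psa_specs`` maps pathway id → uncertainty
    spec (default: normal, SE = 12% of the unit cost, truncated at zero,
    with pathway proportions held fixed).
    """

    unit_costs: dict[str, float]
    distributions: dict[str, ArmDistribution]
    n_referrals: int = 563
    psa_specs: dict[str, UncertaintySpec] = field(default_factory=dict)
    inflation_index: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, c in self.unit_costs.items():
            if c < 0:
                raise ValueError(f"negative unit cost for pathway {pid}")
        if self.n_referrals <= 0:
            raise ValueError("n_referrals must be positive")
        if not self.psa_specs:
            self.psa_specs = {
                pid: UncertaintySpec("normal", 0.12 * c)
                for pid, c in self.unit_costs.items()
            }


def default_cost_params(distribution: str = "cca") -> CostModelParams:
    """Baseline cost-model parameters from the published pathway table."""
    from .config import CCA_DISTRIBUTION, DES_DISTRIBUTION, N_REFERRALS_INTERVENTION, UNIT_COSTS

    dists = {"cca": CCA_DISTRIBUTION, "des": DES_DISTRIBUTION}[distribution]
    return CostModelParams(
        unit_costs=dict(UNIT_COSTS),
        distributions={arm: ArmDistribution(dict(d)) for arm, d in dists.items()},
        n_referrals=N_REFERRALS_INTERVENTION,
    )


@dataclass(frozen=True)
class PSAResult:
    """Output of the probabilistic sensitivity analysis."""

    per_iteration_savings: np.ndarray
    mean: float
    ci95: tuple[float, float]
    prob_saving_positive: float
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        eps = 1e-9 * max(1.0, abs(self.mean))
        if not (lo - eps <= self.mean <= hi + eps):
            raise ValueError("PSA mean outside its percentile CI")
        if not 0.0 <= self.prob_saving_positive <= 1.0:
            raise ValueError("prob_saving_positive out of [0, 1]")


# ---------------------------------------------------------------------------
# Elementary operations


def activity_cost(duration: float, rate: float, add_on: float = 0.0) -> float:
    """Cost of one activity: pro-rated staff time plus a tariff add-on.

    ``duration`` in minutes, ``rate`` in GBP/hour, ``add_on`` in GBP
    (procedure tariff and/or licensing allocation).
    """
    if duration < 0 or rate < 0 or add_on < 0:
        raise ValueError("activity_cost inputs must be non-negative")
    return duration / 60.0 * rate + add_on


def arm_mean_cost(dist: ArmDistribution, unit_costs: dict[str, float]) -> float:
    """Weighted mean cost per referral for one arm: ``sum_i p_i * c_i``."""
    missing = [pid for pid in dist.proportions if pid not in unit_costs]
    if missing:
        raise KeyError(f"no unit cost for pathway(s): {missing}")
    return sum(p * unit_costs[pid] for pid, p in dist.items())


def incremental_saving(comparator_mean: float, intervention_mean: float) -> float:
    """Comparator minus intervention mean cost; positive values are savings."""
    if not (math.isfinite(comparator_mean) and math.isfinite(intervention_mean)):
        raise ValueError("arm means must be finite")
    return comparator_mean - intervention_mean


def total_saving(per_referral: float, n_referrals: int) -> float:
    """Scale a per-referral saving to a cohort total."""
    if n_referrals < 0:
        raise ValueError("n_referrals must be non-negative")
    return per_referral * n_referrals


def welch_t_test(
    costs_a: np.ndarray, costs_b: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t test on per-patient cost samples.

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled (Student) variant.  Degenerate zero-variance samples are
    rejected rather than silently producing infinite statistics.
    """
    a = np.asarray(costs_a, dtype=float)
    b = np.asarray(costs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("both samples are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def inflate_cost(
    cost: float, from_year: int, to_year: int, index: dict[int, float]
) -> float:
    """Re-express a cost at another year's prices via an inflation index."""
    for year in (from_year, to_year):
        if year not in index:
            raise KeyError(f"year {year} missing from inflation index")
    return cost * index[to_year] / index[from_year]


# ---------------------------------------------------------------------------
# Sensitivity analyses


def deterministic_saving(params: CostModelParams) -> float:
    """Baseline incremental saving per referral (no uncertainty)."""
    return incremental_saving(
        arm_mean_cost(params.distributions[COMPARATOR], params.unit_costs),
        arm_mean_cost(params.distributions[INTERVENTION], params.unit_costs),
    )


def run_psa(params: CostModelParams, n_iter: int = 1000, seed: int = 0) -> PSAResult:
    """Probabilistic sensitivity analysis of the incremental saving.

    Each iteration redraws every unit cost from its uncertainty spec
    (pathway proportions stay fixed), recomputes both arm means and the
    saving.  Reproducible: the same seed yields bit-identical draws.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    ids = sorted(params.unit_costs)
    draws = {
        pid: params.psa_specs.get(pid, UncertaintySpec(se=0.0)).sample(
            params.unit_costs[pid], rng, n_iter
        )
        for pid in ids
    }
    comp = params.distributions[COMPARATOR]
    intv = params.distributions[INTERVENTION]
    savings = np.zeros(n_iter)
    for pid, p in comp.items():
        savings += p * draws[pid]
    for pid, p in intv.items():
        savings -= p * draws[pid]
    lo, hi = np.percentile(savings, [2.5, 97.5])
    return PSAResult(
        per_iteration_savings=savings,
        mean=float(savings.mean()),
        ci95=(float(lo), float(hi)),
        prob_saving_positive=float(np.mean(savings > 0)),
        n_iter=n_iter,
        seed=seed,
    )


def _apply_parameter(params: CostModelParams, parameter: str, value: float) -> CostModelParams:
    """Return a copy of ``params`` with one named parameter set to ``value``.

    Supported names: ``"unit_cost.<pathway>"``, ``"n_referrals"``, and the
    scenario knob ``"biopsy_offset"`` — the fraction of intervention-arm
    biopsy-reliant mass (pathways C and D) re-routed to the non-biopsy
    pathways in proportion to their baseline shares.
    """
    import copy

    new = copy.deepcopy(params)
    if parameter.startswith("unit_cost."):
        pid = parameter.split(".", 1)[1]
        if pid not in new.unit_costs:
            raise KeyError(f"unknown pathway in parameter: {pid!r}")
        new.unit_costs[pid] = value
    elif parameter == "n_referrals":
        new.n_referrals = int(value)
    elif parameter == "biopsy_offset":
        if not 0.0 <= value <= 1.0:
            raise ValueError("biopsy_offset fraction must be in [0, 1]")
        props = dict(new.distributions[INTERVENTION].proportions)
        biopsy = [pid for pid in ("C", "D") if pid in props]
        others = [pid for pid in props if pid not in biopsy]
        moved = sum(props[pid] * value for pid in biopsy)
        other_mass = sum(props[pid] for pid in others)
        for pid in biopsy:
            props[pid] *= 1.0 - value
        for pid in others:
            props[pid] += moved * props[pid] / other_mass
        new.distributions[INTERVENTION] = ArmDistribution(props)
    else:
        raise KeyError(f"unknown DSA parameter: {parameter!r}")
    return new


def run_dsa(
    params: CostModelParams, parameter: str, low: float, high: float
) -> tuple[float, float]:
    """One-way deterministic sensitivity analysis: one tornado entry.

    Recomputes the deterministic saving with ``parameter`` fixed at each
    bound, all other inputs at baseline; returns ``(saving_at_low,
    saving_at_high)``.
    """
    if low > high:
        raise ValueError("low bound exceeds high bound")
    return (
        deterministic_saving(_apply_parameter(params, parameter, low)),
        deterministic_saving(_apply_parameter(params, parameter, high)),
    )


def sample_patient_costs(
    dist: ArmDistribution,
    unit_costs: dict[str, float],
    n: int,
    rng: np.random.Generator,
    staff_cv: float = 0.0,
) -> np.ndarray:
    """Per-patient cost sample for an arm: pathway label then its unit cost.

    ``staff_cv`` adds multiplicative lognormal noise emulating variable
    staff involvement per patient (0 = every patient on a pathway costs
    exactly its unit cost).
    """
    norm = dist.normalized()
    ids = sorted(norm)
    probs = np.array([norm[pid] for pid in ids])
    labels = rng.choice(len(ids), size=n, p=probs)
    costs = np.array([unit_costs[ids[k]] for k in labels], dtype=float)
    if staff_cv > 0:
        sigma = math.sqrt(math.log1p(staff_cv**2))
        costs *= rng.lognormal(-(sigma**2) / 2.0, sigma, size=n)
    return costs
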