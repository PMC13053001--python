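"""Shipped baseline configurations and YAML (de)serialisation.

The package ships two named pathway distributions per arm — the cost
analysis distribution (``"cca"``) and the one used by the discrete event
simulation (``"des"``), which differs because the simulation drew on six
additional months of intervention-arm data — plus published per-pathway
unit costs (GBP, 2023 prices).

The baseline inter-stage delay means are chosen so that, in the
no-congestion limit, per-pathway referral-to-communication means equal the
published per-pathway anchors (see :mod:`dermflow.calibration`); the split
of each anchored total into booking, biopsy, histopathology and
communication waits is a documented modelling choice, since only the
totals are published.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .pathways import (
    Activity,
    ArmConfig,
    ArmDistribution,
    ArrivalProcess,
    CommunicationMethod,
    COMPARATOR,
    DelaySpec,
    INTERVENTION,
    PathwayDefinition,
    Stage,
    StaffRole,
    default_comm_methods,
    default_roles,
)

#: Per-pathway unit costs, GBP at 2023 prices.
UNIT_COSTS: dict[str, float] = {
    "A": 55.0,
    "B": 219.0,
    "C": 371.0,
    "D": 542.0,
    "E": 137.0,
    "F": 163.0,
    "G": 364.0,
}

#: Referral fractions used in the cost-comparison analysis.
CCA_DISTRIBUTION = {
    INTERVENTION: {"A": 0.44, "B": 0.21, "C": 0.17, "D": 0.14, "E": 0.03},
    COMPARATOR: {"F": 0.51, "G": 0.49},
}

#: Referral fractions used in the discrete event simulation.
DES_DISTRIBUTION = {
    INTERVENTION: {"A": 0.53, "B": 0.24, "C": 0.05, "D": 0.17, "E": 0.01},
    COMPARATOR: {"F": 0.52, "G": 0.48},
}

#: Intervention cohort size over the cost-analysis window.
N_REFERRALS_INTERVENTION = 563
#: Synthetic comparator cohort size (retrospective records).
N_REFERRALS_COMPARATOR = 4011

# --- activities -----------------------------------------------------------

_ACTIVITIES = {
    "image_capture": Activity("image_capture", duration=20.0, role="HCA_Band3"),
    "remote_review": Activity("remote_review", duration=4.97, role="Consultant"),
    "f2f_consult": Activity("f2f_consult", duration=20.0, role="Consultant"),
    "f2f_followup": Activity("f2f_followup", duration=15.0, role="Consultant"),
    "biopsy": Activity("biopsy", duration=30.0, role="Consultant"),
    "histopathology": Activity("histopathology", duration=20.0, role="Band9"),
    "biopsy_cancellation": Activity("biopsy_cancellation", duration=5.0, role="Band5"),
    "communication": Activity("communication", duration=0.0, role=None),
}


def _stage(name: str, mean: float, cv: float = 0.5, endpoint: str | None = None) -> Stage:
    return Stage(_ACTIVITIES[name], DelaySpec(mean=mean, cv=cv), endpoint=endpoint)


# Baseline stage-delay means (days).  Totals to each endpoint reproduce the
# published per-pathway anchors in the no-congestion limit.
def _intervention_pathways() -> dict[str, PathwayDefinition]:
    common = lambda: (  # noqa: E731 - tiny local factory
        _stage("image_capture", 5.00),
        _stage("remote_review", 2.36, endpoint="clinical_diagnosis"),
    )
    return {
        "A": PathwayDefinition(
            "A", INTERVENTION,
            common() + (_stage("communication", 0.64, endpoint="communication"),),
            unit_cost=UNIT_COSTS["A"],
        ),
        "B": PathwayDefinition(
            "B", INTERVENTION,
            common() + (
                _stage("f2f_followup", 4.00),
                _stage("communication", 1.45, endpoint="communication"),
            ),
            unit_cost=UNIT_COSTS["B"],
        ),
        "C": PathwayDefinition(
            "C", INTERVENTION,
            common() + (
                _stage("f2f_followup", 4.00),
                _stage("biopsy", 20.00),
                _stage("histopathology", 18.00, endpoint="histopath_diagnosis"),
                _stage("communication", 3.04, endpoint="communication"),
            ),
            unit_cost=UNIT_COSTS["C"], biopsy_reliant=True,
        ),
        "D": PathwayDefinition(
            "D", INTERVENTION,
            common() + (
                _stage("biopsy", 22.00),
                _stage("histopathology", 20.00, endpoint="histopath_diagnosis"),
                _stage("communication", 3.04, endpoint="communication"),
            ),
            unit_cost=UNIT_COSTS["D"], biopsy_reliant=True,
        ),
        "E": PathwayDefinition(
            "E", INTERVENTION,
            common() + (
                _stage("biopsy_cancellation", 4.00),
                _stage("communication", 1.45, endpoint="communication"),
            ),
            unit_cost=UNIT_COSTS["E"],
        ),
    }


def _comparator_pathways() -> dict[str, PathwayDefinition]:
    consult = _stage("f2f_consult", 17.27, endpoint="clinical_diagnosis")
    return {
        "F": PathwayDefinition(
            "F", COMPARATOR,
            (consult, _stage("communication", 2.41, endpoint="communication")),
            unit_cost=UNIT_COSTS["F"],
        ),
        "G": PathwayDefinition(
            "G", COMPARATOR,
            (
                consult,
                _stage("biopsy", 45.00),
                _stage("histopathology", 63.80, endpoint="histopath_diagnosis"),
                _stage("communication", 5.03, endpoint="communication"),
            ),
            unit_cost=UNIT_COSTS["G"], biopsy_reliant=True,
        ),
    }


_DEFAULT_STAFFING = {"HCA_Band3": 2, "Band5": 1, "Band9": 2, "Consultant": 3, "GP": 1}

_DEFAULT_COMM_MIX = {
    INTERVENTION: {"email": 0.60, "letter": 0.20, "telephone": 0.15,
                   "f2f_appointment": 0.05},
    COMPARATOR: {"letter": 0.60, "telephone": 0.15, "f2f_appointment": 0.20,
                 "email": 0.05},
}


def default_arm_config(
    arm: str,
    distribution: str = "des",
    annual_volume: float = 3000.0,
) -> ArmConfig:
    """The shipped baseline configuration for one arm.

    ``distribution`` selects the named referral-fraction set: ``"des"``
    (simulation baseline) or ``"cca"`` (cost-analysis baseline).  The
    default annual volume pro-rates the comparator cohort (4011 referrals
    over 16 months) to a 1-year horizon, matched across arms for
    comparability.
    """
    dists = {"des": DES_DISTRIBUTION, "cca": CCA_DISTRIBUTION}
    if distribution not in dists:
        raise ValueError(f"unknown distribution set {distribution!r}")
    if arm == INTERVENTION:
        pathways = _intervention_pathways()
    elif arm == COMPARATOR:
        pathways = _comparator_pathways()
    else:
        raise ValueError(f"unknown arm {arm!r}")
    mix = _DEFAULT_COMM_MIX[arm]
    return ArmConfig(
        arm=arm,
        pathways=pathways,
        distribution=ArmDistribution(dict(dists[distribution][arm])),
        staffing=dict(_DEFAULT_STAFFING),
        arrivals=ArrivalProcess(annual_volume=annual_volume),
        comm_mix={pid: dict(mix) for pid in pathways},
    )


# --- YAML round trip ------------------------------------------------------


def arm_config_to_dict(config: ArmConfig) -> dict:
    """A plain-dict (YAML/JSON-safe) view of an :class:`ArmConfig`."""
    return {
        "schema_version": 1,
        "arm": config.arm,
        "weekend_fraction": config.weekend_fraction,
        "staffing": dict(config.staffing),
        "roles": {n: asdict(r) for n, r in config.roles.items()},
        "arrivals": {
            "annual_volume": config.arrivals.annual_volume,
            "monthly_weights": list(config.arrivals.monthly_weights),
        },
        "comm_methods": {n: asdict(m) for n, m in config.comm_methods.items()},
        "comm_mix": {pid: dict(m) for pid, m in config.comm_mix.items()},
        "pathways": [
            {
                "id": pw.id,
                "proportion": config.distribution.proportions.get(pw.id, 0.0),
                "unit_cost": pw.unit_cost,
                "biopsy_reliant": pw.biopsy_reliant,
                "stages": [
                    {
                        "activity": asdict(s.activity),
                        "delay": asdict(s.delay),
                        "endpoint": s.endpoint,
                    }
                    for s in pw.stages
                ],
            }
            for pw in config.pathways.values()
        ],
    }


def arm_config_from_dict(data: dict) -> ArmConfig:
    """Inverse of :func:`arm_config_to_dict`."""
    pathways: dict[str, PathwayDefinition] = {}
    proportions: dict[str, float] = {}
    for pd in data["pathways"]:
        stages = tuple(
            Stage(
                Activity(**s["activity"]),
                DelaySpec(**s["delay"]),
                endpoint=s.get("endpoint"),
            )
            for s in pd["stages"]
        )
        pathways[pd["id"]] = PathwayDefinition(
            pd["id"], data["arm"], stages,
            unit_cost=pd.get("unit_cost", 0.0),
            biopsy_reliant=pd.get("biopsy_reliant", False),
        )
        proportions[pd["id"]] = pd["proportion"]
    return ArmConfig(
        arm=data["arm"],
        pathways=pathways,
        distribution=ArmDistribution(proportions),
        roles={n: StaffRole(**r) for n, r in data.get("roles", {}).items()}
        or default_roles(),
        staffing=dict(data.get("staffing", {})),
        weekend_fraction=data.get("weekend_fraction", 0.7),
        arrivals=ArrivalProcess(
            annual_volume=data["arrivals"]["annual_volume"],
            monthly_weights=tuple(data["arrivals"].get("monthly_weights", [1.0] * 12)),
        ),
        comm_methods={
            n: CommunicationMethod(**m)
            for n, m in data.get("comm_methods", {}).items()
        }
        or default_comm_methods(),
        comm_mix={pid: dict(m) for pid, m in data.get("comm_mix", {}).items()},
    )


def save_arm_config(config: ArmConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(arm_config_to_dict(config), fh, sort_keys=False)


def load_arm_config(path) -> ArmConfig:
    with open(path) as fh:
        return arm_config_from_dict(yaml.safe_load(fh))
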