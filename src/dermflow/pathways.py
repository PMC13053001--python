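"""Domain types and the routing graph for urgent suspected skin-cancer pathways.

Two arms of care are modelled.  In the *intervention* arm a community-based
store-and-forward teledermatology service routes referrals through image
capture at a community diagnostic centre followed by remote consultant
review, giving five pathways:

* ``A`` — image capture, remote review, discharge;
* ``B`` — image capture, remote review, face-to-face follow-up, discharge;
* ``C`` — image capture, remote review, face-to-face follow-up, diagnostic
  biopsy, histopathology;
* ``D`` — image capture, remote review, direct diagnostic biopsy,
  histopathology;
* ``E`` — a diagnostic biopsy scheduled and then cancelled (no
  histopathology endpoint).

In the *comparator* (standard-of-care) arm every referral attends a
face-to-face consultant clinic and is either discharged (pathway ``F``) or
proceeds to a diagnostic biopsy and histopathology (pathway ``G``).

Pathways are defined purely structurally — an ordered list of staffed
activities with inter-stage waiting-time distributions — so alternative
clinical interpretations can be expressed in configuration without code
changes.  All timestamps are measured in days since the patient's own
referral instant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx

INTERVENTION = "intervention"
COMPARATOR = "comparator"

#: Waiting-time endpoints recorded for every simulated patient.
ENDPOINTS = ("clinical_diagnosis", "histopath_diagnosis", "communication")

BIOPSY_RELIANT = frozenset({"C", "D", "G"})
INTERVENTION_PATHWAYS = ("A", "B", "C", "D", "E")
COMPARATOR_PATHWAYS = ("F", "G")


@dataclass(frozen=True)
class StaffRole:
    """A staff grade with an hourly cost and weekend availability.

    ``hourly_rate`` is GBP per hour at 2023 prices (cost-norm style rates
    including overheads).  GPs do not work weekend shifts.
    """

    name: str
    hourly_rate: float
    weekend_available: bool = True

    def __post_init__(self) -> None:
        if self.hourly_rate <= 0:
            raise ValueError(f"hourly_rate must be positive, got {self.hourly_rate}")
        if self.name == "GP" and self.weekend_available:
            raise ValueError("GP staff are not available at weekends")


def default_roles() -> dict[str, StaffRole]:
    """NHS staff grades used across both arms, with 2023 hourly cost norms."""
    return {
        "HCA_Band3": StaffRole("HCA_Band3", 29.0),
        "Band5": StaffRole("Band5", 41.0),
        "Band9": StaffRole("Band9", 104.0),
        "Consultant": StaffRole("Consultant", 122.0),
        "GP": StaffRole("GP", 76.0, weekend_available=False),
    }


@dataclass(frozen=True)
class Activity:
    """A staffed (or unstaffed) clinical activity.

    duration is in minutes of staff time; ``role`` names the StaffRole that
    must serve it, or ``None`` for activities that consume no staffed
    capacity (e.g. a letter landing on a doormat).  ``procedure_cost`` is a
    tariff add-on (e.g. the diagnostic-biopsy procedure) and
    ``license_cost`` a platform-licensing allocation, both GBP.
    """

    name: str
    duration: float = 0.0
    role: str | None = None
    procedure_cost: float = 0.0
    license_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.procedure_cost < 0:
            raise ValueError("procedure_cost must be non-negative")
        if self.license_cost < 0:
            raise ValueError("license_cost must be non-negative")


@dataclass(frozen=True)
class DelaySpec:
    """An inter-stage waiting-time distribution, parameterised by mean and CV.

    ``family`` is ``"lognormal"`` (default: non-negative, right-skewed,
    the usual shape for clinic waiting times) or ``"fixed"`` (point mass).
    A CV of zero collapses either family to a point mass at the mean.
    """

    mean: float
    cv: float = 0.5
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("delay mean must be non-negative")
        if self.cv < 0:
            raise ValueError("delay cv must be non-negative")
        if self.family not in ("lognormal", "fixed"):
            raise ValueError(f"unsupported delay family: {self.family!r}")


@dataclass(frozen=True)
class Stage:
    """One step of a pathway: a wait (``delay``) followed by an activity.

    ``endpoint`` optionally tags the activity's completion time as one of
    the recorded waiting-time endpoints.
    """

    activity: Activity
    delay: DelaySpec
    endpoint: str | None = None

    def __post_init__(self) -> None:
        if self.endpoint is not None and self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint tag: {self.endpoint!r}")

    @property
    def name(self) -> str:
        return self.activity.name


@dataclass(frozen=True)
class PathwayDefinition:
    """One of pathways A–G: an arm label, an ordered stage list and a unit cost."""

    id: str
    arm: str
    stages: tuple[Stage, ...]
    unit_cost: float = 0.0
    biopsy_reliant: bool = False

    def __post_init__(self) -> None:
        if self.arm not in (INTERVENTION, COMPARATOR):
            raise ValueError(f"unknown arm: {self.arm!r}")
        if self.unit_cost < 0:
            raise ValueError("unit_cost must be non-negative")
        if not self.stages or self.stages[-1].endpoint != "communication":
            raise ValueError(
                f"pathway {self.id}: the final stage must carry the "
                "'communication' endpoint (patients exit at communication)"
            )
        has_histo = any(s.endpoint == "histopath_diagnosis" for s in self.stages)
        if self.biopsy_reliant != has_histo:
            raise ValueError(
                f"pathway {self.id}: biopsy_reliant={self.biopsy_reliant} but "
                f"histopathology endpoint {'present' if has_histo else 'absent'}"
            )

    def stage_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.stages)

    def total_delay_mean(self, upto_endpoint: str = "communication") -> float:
        """Sum of configured delay means up to (and including) an endpoint stage."""
        total = 0.0
        for s in self.stages:
            total += s.delay.mean
            if s.endpoint == upto_endpoint:
                return total
        raise ValueError(f"pathway {self.id} has no endpoint {upto_endpoint!r}")


@dataclass(frozen=True)
class ArmDistribution:
    """Fractions of referrals routed to each pathway of an arm.

    Fractions must sum to 1 up to printed-table rounding: published
    percentage tables round to whole percent and can leave a deficit of up
    to 1.5 percentage points (the cost-analysis intervention shares sum to
    99%).  Weighted sums use the fractions as given; anywhere a true
    probability vector is required (routing, sampling) the
    :meth:`normalized` view is used.
    """

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        for pid, p in self.proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for {pid} out of [0, 1]: {p}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 0.015:
            raise ValueError(f"pathway proportions sum to {total}, expected 1")

    def items(self):
        return self.proportions.items()

    def __getitem__(self, pid: str) -> float:
        return self.proportions[pid]

    def normalized(self) -> dict[str, float]:
        """Proportions rescaled to sum to exactly 1."""
        total = sum(self.proportions.values())
        return {pid: p / total for pid, p in self.proportions.items()}


@dataclass(frozen=True)
class CommunicationMethod:
    """A way of conveying the diagnosis, with a delay multiplier.

    ``rel_mean`` scales the pathway's configured communication delay: when a
    method is sampled for a patient, its delay mean is the pathway mean
    rescaled so that the mixture mean across methods equals the configured
    pathway communication delay exactly.
    """

    name: str
    rel_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("letter", "email", "telephone", "f2f_appointment"):
            raise ValueError(f"unknown communication method: {self.name!r}")
        if self.rel_mean <= 0:
            raise ValueError("rel_mean must be positive")


def default_comm_methods() -> dict[str, CommunicationMethod]:
    return {
        "letter": CommunicationMethod("letter", 1.5),
        "email": CommunicationMethod("email", 0.3),
        "telephone": CommunicationMethod("telephone", 0.5),
        "f2f_appointment": CommunicationMethod("f2f_appointment", 3.0),
    }


@dataclass(frozen=True)
class ArrivalProcess:
    """A seasonal Poisson referral stream over a 1-year horizon.

    ``monthly_weights`` are 12 non-negative relative intensities,
    normalised to sum to 12 (all ones = uniform inflow).
    """

    annual_volume: float
    monthly_weights: tuple[float, ...] = (1.0,) * 12

    def __post_init__(self) -> None:
        if self.annual_volume <= 0:
            raise ValueError("annual_volume must be positive")
        if len(self.monthly_weights) != 12:
            raise ValueError("monthly_weights must have 12 entries")
        if any(w < 0 for w in self.monthly_weights):
            raise ValueError("monthly weights must be non-negative")
        if sum(self.monthly_weights) <= 0:
            raise ValueError("monthly weights must not all be zero")

    def normalized_weights(self) -> tuple[float, ...]:
        s = sum(self.monthly_weights)
        return tuple(12.0 * w / s for w in self.monthly_weights)


@dataclass
class ArmConfig:
    """Everything needed to simulate one arm.

    Combines the pathway definitions and routing distribution with the
    staffing levels, the arrival process and the communication-method mix.
    """

    arm: str
    pathways: dict[str, PathwayDefinition]
    distribution: ArmDistribution
    roles: dict[str, StaffRole] = field(default_factory=default_roles)
    staffing: dict[str, int] = field(default_factory=dict)
    weekend_fraction: float = 0.7
    arrivals: ArrivalProcess = field(
        default_factory=lambda: ArrivalProcess(annual_volume=3000.0)
    )
    comm_methods: dict[str, CommunicationMethod] = field(
        default_factory=default_comm_methods
    )
    #: per-pathway mix of communication methods (fractions summing to 1)
    comm_mix: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid in self.distribution.proportions:
            if pid not in self.pathways:
                raise ValueError(f"unknown pathway id in distribution: {pid!r}")
        for pw in self.pathways.values():
            for s in pw.stages:
                if s.activity.role is not None and s.activity.role not in self.roles:
                    raise ValueError(
                        f"stage {s.name!r} references undefined role "
                        f"{s.activity.role!r}"
                    )
        for pid, mix in self.comm_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"communication mix for {pid} sums to {total}")
            for m in mix:
                if m not in self.comm_methods:
                    raise ValueError(f"unknown communication method {m!r}")

    def with_pathways(self, pathways: dict[str, PathwayDefinition]) -> "ArmConfig":
        """A copy of this config with the pathway map replaced."""
        return replace(self, pathways=pathways)

    def scale_delays(
        self,
        factor: float,
        pathway_ids: set[str] | None = None,
        stage_names: set[str] | None = None,
    ) -> "ArmConfig":
        """A copy with selected inter-stage delay means multiplied by ``factor``.

        ``pathway_ids`` / ``stage_names`` of None select everything; this is
        the knob the calibrator bisects on.
        """
        new = {}
        for pid, pw in self.pathways.items():
            if pathway_ids is not None and pid not in pathway_ids:
                new[pid] = pw
                continue
            stages = tuple(
                replace(s, delay=replace(s.delay, mean=s.delay.mean * factor))
                if (stage_names is None or s.name in stage_names)
                else s
                for s in pw.stages
            )
            new[pid] = replace(pw, stages=stages)
        return self.with_pathways(new)


# ---------------------------------------------------------------------------
# Routing graph


def build_pathway_graph(arm_config: ArmConfig) -> nx.DiGraph:
    """Build the directed acyclic stage network for an arm.

    Pathways sharing a common prefix of stage names are merged into shared
    nodes (e.g. both comparator pathways share the single face-to-face
    consult node, which then branches to discharge or biopsy).  Edges carry
    conditional branch probabilities; every referral reaches exactly one
    terminal communication node, whose ``pathway`` attribute names the
    PathwayDefinition it realises.

    Raises ``ValueError`` for an unknown pathway id or proportions not
    summing to one (enforced by :class:`ArmDistribution`).
    """
    g = nx.DiGraph()
    root = "referral"
    g.add_node(root, kind="referral")

    # Absolute reach probability of every stage-name prefix.
    prefix_mass: dict[tuple[str, ...], float] = {(): 1.0}
    for pid, p in arm_config.distribution.normalized().items():
        pw = arm_config.pathways[pid]
        names = pw.stage_names()
        for k in range(1, len(names) + 1):
            prefix = names[:k]
            prefix_mass[prefix] = prefix_mass.get(prefix, 0.0) + p
            node = "/".join(prefix)
            if not g.has_node(node):
                stage = pw.stages[k - 1]
                g.add_node(node, stage=stage.name, endpoint=stage.endpoint)
        terminal = "/".join(names)
        g.nodes[terminal]["pathway"] = pid

    for prefix, mass in prefix_mass.items():
        if not prefix:
            continue
        parent = root if len(prefix) == 1 else "/".join(prefix[:-1])
        parent_mass = prefix_mass[prefix[:-1]]
        if parent_mass <= 0:
            continue
        g.add_edge(parent, "/".join(prefix), probability=mass / parent_mass)

    if not nx.is_directed_acyclic_graph(g):  # pragma: no cover - defensive
        raise ValueError("pathway graph is not acyclic")
    return g


def enumerate_path_probabilities(graph: nx.DiGraph) -> dict[str, float]:
    """Product of edge probabilities along each root-to-terminal path.

    Returns a map pathway id → absolute probability; by construction it
    recovers the configured :class:`ArmDistribution` (restricted to
    pathways with positive mass).
    """
    probs: dict[str, float] = {}
    for node, data in graph.nodes(data=True):
        if "pathway" not in data:
            continue
        for path in nx.all_simple_paths(graph, "referral", node):
            p = math.prod(
                graph.edges[a, b]["probability"] for a, b in zip(path, path[1:])
            )
            probs[data["pathway"]] = probs.get(data["pathway"], 0.0) + p
    return probs
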