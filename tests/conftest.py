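"""Shared fixtures: small synthetic arm configurations for fast tests."""

from __future__ import annotations

import pytest

from dermflow.pathways import (
    Activity,
    ArmConfig,
    ArmDistribution,
    ArrivalProcess,
    DelaySpec,
    INTERVENTION,
    PathwayDefinition,
    Stage,
)


def chain_config(
    delays: tuple[float, ...],
    durations: tuple[float, ...] | None = None,
    roles: tuple[str | None, ...] | None = None,
    cv: float = 0.0,
    annual_volume: float = 200.0,
    staffing: dict[str, int] | None = None,
    pathway_id: str = "A",
    endpoint_tags: dict[int, str] | None = None,
) -> ArmConfig:
    """A single-pathway arm whose stages form one linear chain.

    By default every stage is unstaffed with a deterministic (CV = 0)
    delay, the last stage is the communication event, and the
    second-to-last carries the clinical-diagnosis tag.
    """
    n = len(delays)
    durations = durations or (0.0,) * n
    roles = roles or (None,) * n
    endpoint_tags = endpoint_tags or {n - 2: "clinical_diagnosis"}
    stages = []
    for i, (d, dur, role) in enumerate(zip(delays, durations, roles)):
        endpoint = "communication" if i == n - 1 else endpoint_tags.get(i)
        name = "communication" if i == n - 1 else f"stage_{i}"
        stages.append(
            Stage(
                Activity(name, duration=dur, role=role),
                DelaySpec(mean=d, cv=cv),
                endpoint=endpoint,
            )
        )
    return ArmConfig(
        arm=INTERVENTION,
        pathways={pathway_id: PathwayDefinition(pathway_id, INTERVENTION, tuple(stages))},
        distribution=ArmDistribution({pathway_id: 1.0}),
        staffing=staffing or {"Consultant": 1, "HCA_Band3": 1, "Band5": 1,
                              "Band9": 1, "GP": 1},
        arrivals=ArrivalProcess(annual_volume=annual_volume),
        comm_mix={},
    )


@pytest.fixture
def linear_chain():
    """Deterministic 2 d + 0.1 d + 1 d unstaffed chain."""
    return chain_config((2.0, 0.1, 1.0))
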