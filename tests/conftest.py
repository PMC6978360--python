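"""Shared fixtures: tiny hand-built groups and module-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from oadiff import event_io, oada, obs_networks, synth

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from oadiff.event_io import Individual, ManipulationEvent


def make_roster(n: int, group: str = "G", mothers: dict[str, str] | None = None) -> list[Individual]:
    """n individuals, alternating sex/age, ranks 1..n in id order."""
    mothers = mothers or {}
    out = []
    for i in range(n):
        ind_id = f"{group}{i + 1}"
        out.append(
            Individual(
                id=ind_id,
                group=group,
                sex="female" if i % 2 == 0 else "male",
                age_class="adult" if i % 3 == 0 else "juvenile",
                rank=i + 1,
                mother_id=mothers.get(ind_id),
            )
        )
    return out


def make_event(idx, t, actor, technique="lift", outcome="success", observers=(),
               group="G", session="S1"):
    return ManipulationEvent(
        event_index=idx,
        session_id=session,
        time_s=float(t),
        group=group,
        actor_id=actor,
        technique=technique,
        outcome=outcome,
        observer_ids=frozenset(observers),
    )


@pytest.fixture(scope="session")
def small_config() -> synth.SimulationConfig:
    """One 12-individual group, short horizon: fast but non-trivial dynamics."""
    return synth.SimulationConfig(
        groups=(synth.GroupSpec("G", 1, 3, 4, 4, n_sessions=6, session_length_s=2000.0,
                                p_attend=0.3),),
        s={"OS": 0.6, "CO": 0.0},
        lambda0=4e-5,  # hot asocial baseline so the short horizon still diffuses
        mu=6e-3,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config) -> synth.SimulatedExperiment:
    return synth.simulate(small_config, seed=11)


@pytest.fixture(scope="session")
def study_scale_experiment() -> synth.SimulatedExperiment:
    """Default study-scale conditions (two groups, 28 + 12)."""
    return synth.simulate(synth.SimulationConfig(), seed=7)


def oada_data_from(exp: synth.SimulatedExperiment) -> oada.OadaData:
    datasets = event_io.build_diffusion_dataset(exp.events, exp.roster)
    nets = obs_networks.build_dynamic_network(exp.events, exp.roster)
    comps = {g: oada.os_co_components(nets[g]) for g in datasets}
    return oada.prepare_oada_data(list(datasets.values()), comps)
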