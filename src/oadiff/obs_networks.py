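"""Dynamic observation networks, bias partitions and the naive-rate sociogram.

The dynamic observation network stores, for every ordered pair (observer i,
demonstrator j) and option l, the experiment-clock times at which i watched
j succeed with l.  Its query ``o(i, j, l, t)`` -- the number of such
observations strictly before t -- is the network connection the diffusion
analysis scales by the social-transmission parameter s.  Only successful
openings create observation ties by default; attempts rarely express a
technique and are excluded unless ``count_attempts`` is set (attempts with
technique ``none`` never count, having no option).

``partition_network`` splits a network into mutually exclusive components by
a demonstrator/observer attribute pair (rank direction, demonstrator sex,
age-class pairing, or kin relation), so that transmission rates along each
pathway can carry their own s parameter.  ``sociogram_rates`` computes the
average rate at which each observer watched each demonstrator while still
naive, the edge weight of the descriptive sociogram.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataValidationError
from .event_io import (
    OPTIONS,
    DiffusionDataset,
    Individual,
    ManipulationEvent,
    experiment_clock,
    roster_by_id,
    sort_events,
    technique_option,
)

BIASES = ("rank", "sex", "age", "kin")


@dataclass
class DynamicObservationNetwork:
    """Time-indexed cumulative observation counts o(i, j, l, t) for one group."""

    group: str
    times: dict[tuple[str, str, str], list[float]] = field(default_factory=dict)

    def add(self, observer: str, demonstrator: str, option: str, t: float) -> None:
        if observer == demonstrator:
            raise DataValidationError("self-observation is not allowed")
        self.times.setdefault((observer, demonstrator, option), []).append(t)

    def count(self, observer: str, demonstrator: str, option: str, t: float) -> int:
        """Observations of ``demonstrator`` succeeding with ``option`` strictly before t."""
        ts = self.times.get((observer, demonstrator, option))
        return bisect_left(ts, t) if ts else 0

    def exposure(self, observer: str, option: str, t: float) -> int:
        """Total observations by ``observer`` of anyone succeeding with ``option`` before t."""
        return sum(
            bisect_left(ts, t)
            for (i, _j, l), ts in self.times.items()
            if i == observer and l == option
        )

    def total(self) -> int:
        return sum(len(ts) for ts in self.times.values())


def build_dynamic_network(
    events: Sequence[ManipulationEvent],
    roster: Sequence[Individual],
    technique_pooling: str = "strict",
    count_attempts: bool = False,
) -> dict[str, DynamicObservationNetwork]:
    """Build one dynamic observation network per group from an event log.

    For every success by j with option l, one timestamp is appended to
    (i, j, l) for each listed observer i, at the event's experiment-clock
    time.  Observers are credited regardless of whether they are already
    informed (informed individuals simply never re-enter a risk set).
    """
    by_id = roster_by_id(roster)
    events = sort_events(events)
    timed, _ = experiment_clock(events)
    nets = {g: DynamicObservationNetwork(g) for g in sorted({i.group for i in roster})}
    for ev, t in timed:
        if ev.outcome != "success" and not count_attempts:
            continue
        option = technique_option(ev.technique, technique_pooling)
        if option is None:
            continue
        net = nets[by_id[ev.actor_id].group]
        for obs in ev.observer_ids:
            net.add(obs, ev.actor_id, option, t)
    for net in nets.values():
        for ts in net.times.values():
            ts.sort()
    return nets


# ---------------------------------------------------------------------------
# bias partitions
# ---------------------------------------------------------------------------


def bias_component_names(bias: str) -> tuple[str, ...]:
    if bias == "rank":
        return ("HL", "LH")
    if bias == "sex":
        return ("from_female", "from_male")
    if bias == "age":
        return ("adult_to_adult", "adult_to_juvenile", "juvenile_to_adult", "juvenile_to_juvenile")
    if bias == "kin":
        return ("mother_to_offspring", "offspring_to_mother", "siblings", "nonkin")
    raise ValueError(f"unknown bias {bias!r}; expected one of {BIASES}")


def component_of(bias: str, observer: Individual, demonstrator: Individual) -> str:
    """Assign the (observer, demonstrator) dyad to its bias component.

    Rank uses the integer rank numbers (1 = highest): a demonstrator with a
    smaller rank number than the observer transmits on the higher-to-lower
    (HL) pathway.  Kin classes need known mother links; dyads with unknown
    maternity fall into ``nonkin``.
    """
    if bias == "rank":
        if demonstrator.rank == observer.rank:
            raise DataValidationError("tied ranks cannot be partitioned by rank bias")
        return "HL" if demonstrator.rank < observer.rank else "LH"
    if bias == "sex":
        return f"from_{demonstrator.sex}"
    if bias == "age":
        return f"{demonstrator.age_class}_to_{observer.age_class}"
    if bias == "kin":
        if observer.mother_id is not None and observer.mother_id == demonstrator.id:
            return "mother_to_offspring"
        if demonstrator.mother_id is not None and demonstrator.mother_id == observer.id:
            return "offspring_to_mother"
        if (
            observer.mother_id is not None
            and demonstrator.mother_id is not None
            and observer.mother_id == demonstrator.mother_id
        ):
            return "siblings"
        return "nonkin"
    raise ValueError(f"unknown bias {bias!r}; expected one of {BIASES}")


@dataclass(frozen=True)
class NetworkPartition:
    bias: str
    components: Mapping[str, DynamicObservationNetwork]


def partition_network(
    net: DynamicObservationNetwork, roster: Sequence[Individual], bias: str
) -> NetworkPartition:
    """Split a network into mutually exclusive, exhaustive bias components.

    Every (observer, demonstrator, option) timestamp list lands wholesale in
    exactly one component, so component counts sum to the unpartitioned
    count at every (i, j, l, t).
    """
    by_id = roster_by_id(roster)
    comps = {name: DynamicObservationNetwork(net.group) for name in bias_component_names(bias)}
    for (i, j, l), ts in net.times.items():
        name = component_of(bias, by_id[i], by_id[j])
        comps[name].times[(i, j, l)] = list(ts)
    return NetworkPartition(bias, comps)


# ---------------------------------------------------------------------------
# sociogram
# ---------------------------------------------------------------------------


def sociogram_rates(
    dataset: DiffusionDataset, net: DynamicObservationNetwork
) -> pd.DataFrame:
    """Average naive observation rate per dyad (observer, demonstrator).

    Numerator: times the observer watched the demonstrator solve with lift
    before the observer learned lift, plus the same for pull.  Denominator
    ("cumulative solving time"): per option, the experiment-clock span from
    the group's first success with that option until the observer's own
    acquisition of it (or the end of observation), summed over both options.
    Dyads with no naive observation are omitted; a zero denominator with a
    nonzero numerator cannot occur (observations require a prior success).
    """
    rows = []
    acq_time = {
        (a.individual_id, a.option): a.time_s for a in dataset.acquisitions
    }
    for observer in dataset.individuals:
        cutoffs = {
            l: acq_time.get((observer, l), dataset.end_time) for l in OPTIONS
        }
        denom = 0.0
        for l in OPTIONS:
            start = dataset.first_option_success_time.get(l)
            if start is not None:
                denom += max(0.0, cutoffs[l] - start)
        if denom <= 0:
            continue
        for demonstrator in dataset.individuals:
            if demonstrator == observer:
                continue
            num = sum(net.count(observer, demonstrator, l, cutoffs[l]) for l in OPTIONS)
            if num > 0:
                rows.append(
                    {
                        "observer": observer,
                        "demonstrator": demonstrator,
                        "rate_per_s": num / denom,
                    }
                )
    return pd.DataFrame(rows, columns=["observer", "demonstrator", "rate_per_s"])
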