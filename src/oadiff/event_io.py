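"""Reading, validation and assembly of open-diffusion experiment data.

An open-diffusion experiment records, for two free-living groups, every
manipulation of a two-option puzzle task: who acted, which technique was used
(``lift`` or ``pull``, plus the rarer ``return_lift``/``return_pull``
variants), whether the manipulation succeeded, and which group members were
watching.  This module turns three delimited text tables -- a roster of
individuals, a manipulation-event log and a dyadic agonistic win/loss matrix
-- into the validated in-memory objects the rest of the pipeline consumes,
and assembles the per-group :class:`DiffusionDataset` (ordered first-success
acquisition events plus standardized individual-level covariates) on which
the order-of-acquisition diffusion analysis operates.

Time handling: the event log stores seconds within each experimental
session.  Sessions are concatenated into one "experiment clock" per group in
which inter-session gaps are excised, because exposure opportunities and
solving-time denominators are only defined on observable (in-session) time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError

log = logging.getLogger(__name__)

OPTIONS = ("lift", "pull")
TECHNIQUES = ("lift", "pull", "return_lift", "return_pull", "none")
SEXES = ("female", "male")
AGE_CLASSES = ("adult", "juvenile")
ILV_NAMES = ("sex", "age", "rank")

#: Sign conventions for the binary individual-level variables, applied
#: before standardization: female/adult coded +1, male/juvenile coded -1.
#: Rank enters as the integer rank (1 = highest), so after standardization a
#: more negative value means a more dominant individual.
ILV_CODING = {
    "sex": {"female": 1.0, "male": -1.0},
    "age": {"adult": 1.0, "juvenile": -1.0},
}


@dataclass(frozen=True)
class Individual:
    """One group member with its individual-level variables and kin link."""

    id: str
    group: str
    sex: str
    age_class: str
    rank: int
    mother_id: str | None = None


@dataclass(frozen=True)
class ManipulationEvent:
    """One timestamped interaction with a box.

    ``time_s`` is seconds within the event's session.  ``observer_ids`` are
    the attending individuals (actor excluded).  ``technique`` is ``none``
    for attempts whose technique could not be expressed.
    """

    event_index: int
    session_id: str
    time_s: float
    group: str
    actor_id: str
    technique: str
    outcome: str
    observer_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class AgonisticMatrix:
    """Dyadic winner/loser counts; ``wins[a, b]`` = times a beat b."""

    individuals: tuple[str, ...]
    wins: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wins)
        n = len(self.individuals)
        if w.shape != (n, n):
            raise DataValidationError(
                f"agonistic matrix shape {w.shape} does not match {n} ids"
            )
        if np.any(np.diag(w) != 0):
            raise DataValidationError("agonistic matrix has nonzero diagonal")
        if np.any(w < 0):
            raise DataValidationError("agonistic matrix has negative counts")


@dataclass(frozen=True)
class Acquisition:
    """First success of one individual with one option."""

    individual_id: str
    option: str
    event_index: int
    time_s: float  # experiment-clock seconds
    order: int  # 1-based within group, both options pooled


@dataclass
class DiffusionDataset:
    """Per-group ordered acquisition data feeding the OADA likelihood.

    ``ilv`` holds the standardized covariates (columns ``sex``, ``age``,
    ``rank``), centred on zero with a range of one, computed over the whole
    group roster.  ``first_any`` maps an individual to the experiment-clock
    time of its first acquisition of either option, which drives the
    time-varying "other option solved" indicator.
    """

    group: str
    individuals: tuple[str, ...]
    acquisitions: list[Acquisition]
    ilv: pd.DataFrame
    end_time: float
    first_option_success_time: dict[str, float]
    first_any: dict[str, float]
    n_time_ties: int = 0
    last_seen: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def other_option_solved(self, individual_id: str, t: float) -> int:
        """1 if ``individual_id`` had acquired either option strictly before ``t``."""
        t0 = self.first_any.get(individual_id)
        return int(t0 is not None and t0 < t)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_ROSTER_COLUMNS = ("id", "group", "sex", "age_class", "rank")


def read_roster(path: str | Path) -> list[Individual]:
    """Read and validate a roster CSV.

    Required columns: ``id, group, sex, age_class, rank``; optional
    ``mother_id``.  Ranks must form a permutation of ``1..N`` within each
    group and a non-empty ``mother_id`` must name another member of the same
    group.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"roster missing required columns: {missing}")
    individuals: list[Individual] = []
    for line, row in df.iterrows():
        mother = row.get("mother_id")
        if mother is not None and (pd.isna(mother) or str(mother).strip() == ""):
            mother = None
        sex, age = str(row["sex"]), str(row["age_class"])
        if sex not in SEXES:
            raise DataValidationError(f"roster line {line}: unknown sex {sex!r}")
        if age not in AGE_CLASSES:
            raise DataValidationError(f"roster line {line}: unknown age_class {age!r}")
        try:
            rank = int(row["rank"])
        except (TypeError, ValueError) as exc:
            raise DataValidationError(f"roster line {line}: bad rank {row['rank']!r}") from exc
        individuals.append(
            Individual(str(row["id"]), str(row["group"]), sex, age, rank, mother)
        )
    validate_roster(individuals)
    return individuals


def validate_roster(individuals: Sequence[Individual]) -> None:
    by_group: dict[str, list[Individual]] = {}
    for ind in individuals:
        by_group.setdefault(ind.group, []).append(ind)
    for group, members in by_group.items():
        ids = [m.id for m in members]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DataValidationError(f"group {group}: duplicate ids {sorted(dupes)}")
        ranks = sorted(m.rank for m in members)
        expected = list(range(1, len(members) + 1))
        if ranks != expected:
            missing = sorted(set(expected) - set(ranks))
            extra = sorted({r for r in ranks if ranks.count(r) > 1} | (set(ranks) - set(expected)))
            raise DataValidationError(
                f"group {group}: ranks are not a permutation of 1..{len(members)} "
                f"(missing {missing}, duplicated/out-of-range {extra})"
            )
        id_set = set(ids)
        for m in members:
            if m.mother_id is not None and m.mother_id not in id_set:
                raise DataValidationError(
                    f"group {group}: {m.id} has unknown mother_id {m.mother_id!r}"
                )
            if m.rank < 1:
                raise DataValidationError(f"group {group}: {m.id} has non-positive rank")


def roster_by_id(individuals: Sequence[Individual]) -> dict[str, Individual]:
    return {ind.id: ind for ind in individuals}


_EVENT_COLUMNS = (
    "event_index",
    "session_id",
    "time_s",
    "group",
    "actor_id",
    "technique",
    "outcome",
    "observer_ids",
)


def read_events(path: str | Path, roster: Sequence[Individual]) -> list[ManipulationEvent]:
    """Read a manipulation-event CSV and resolve all ids against ``roster``.

    Events are returned sorted by (session id, time within session, file
    order); equal times keep file order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"event log missing required columns: {missing}")
    by_id = roster_by_id(roster)
    events: list[ManipulationEvent] = []
    for line, row in df.iterrows():
        obs_raw = row["observer_ids"].strip()
        observers = frozenset(s for s in (p.strip() for p in obs_raw.split(";")) if s) if obs_raw else frozenset()
        ev = ManipulationEvent(
            event_index=int(row["event_index"]),
            session_id=str(row["session_id"]),
            time_s=float(row["time_s"]),
            group=str(row["group"]),
            actor_id=str(row["actor_id"]),
            technique=str(row["technique"]),
            outcome=str(row["outcome"]),
            observer_ids=observers,
        )
        _validate_event(ev, by_id, line)
        events.append(ev)
    return sort_events(events)


def _validate_event(ev: ManipulationEvent, by_id: Mapping[str, Individual], line: int) -> None:
    if ev.actor_id not in by_id:
        raise DataValidationError(f"event line {line}: unknown actor id {ev.actor_id!r}")
    for o in ev.observer_ids:
        if o not in by_id:
            raise DataValidationError(f"event line {line}: unknown observer id {o!r}")
    if ev.actor_id in ev.observer_ids:
        raise DataValidationError(f"event line {line}: actor {ev.actor_id!r} listed as observer")
    if ev.time_s < 0:
        raise DataValidationError(f"event line {line}: negative time {ev.time_s}")
    if ev.technique not in TECHNIQUES:
        raise DataValidationError(f"event line {line}: unknown technique {ev.technique!r}")
    if ev.outcome not in ("success", "attempt"):
        raise DataValidationError(f"event line {line}: unknown outcome {ev.outcome!r}")
    if ev.outcome == "success" and ev.technique == "none":
        raise DataValidationError(f"event line {line}: success with technique 'none'")


def sort_events(events: Sequence[ManipulationEvent]) -> list[ManipulationEvent]:
    """Stable sort by (group, session id, time); ties keep input order.

    Session ids must sort chronologically (e.g. zero-padded or date-based),
    since event times are recorded within sessions; this makes the pipeline
    independent of the row order of the event file.
    """
    return sorted(events, key=lambda ev: (ev.group, ev.session_id, ev.time_s))


def write_events(events: Sequence[ManipulationEvent], path: str | Path) -> None:
    rows = [
        {
            "event_index": ev.event_index,
            "session_id": ev.session_id,
            "time_s": ev.time_s,
            "group": ev.group,
            "actor_id": ev.actor_id,
            "technique": ev.technique,
            "outcome": ev.outcome,
            "observer_ids": ";".join(sorted(ev.observer_ids)),
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=list(_EVENT_COLUMNS)).to_csv(path, index=False)


def write_roster(individuals: Sequence[Individual], path: str | Path) -> None:
    rows = [
        {
            "id": ind.id,
            "group": ind.group,
            "sex": ind.sex,
            "age_class": ind.age_class,
            "rank": ind.rank,
            "mother_id": ind.mother_id or "",
        }
        for ind in individuals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_agonistic_matrix(path: str | Path) -> AgonisticMatrix:
    """Read a square win-count CSV whose first row/column hold the ids."""
    df = pd.read_csv(path, index_col=0)
    ids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != ids:
        raise DataValidationError("agonistic matrix row and column ids differ")
    return AgonisticMatrix(ids, df.to_numpy(dtype=float).astype(int))


# ---------------------------------------------------------------------------
# experiment clock
# ---------------------------------------------------------------------------


def experiment_clock(
    events: Sequence[ManipulationEvent],
) -> tuple[list[tuple[ManipulationEvent, float]], dict[str, float]]:
    """Map session-local times onto one concatenated clock per group.

    Sessions are taken in order of first appearance; within each session the
    clock runs from the session's earliest event to its latest, and the next
    session starts where the previous one ended (gaps excised).  Returns the
    events (input order preserved) paired with their experiment-clock time,
    and the total clock duration per group.
    """
    sessions: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for ev in events:
        key = (ev.group, ev.session_id)
        if key not in sessions:
            sessions[key] = []
            order.append(key)
        sessions[key].append(ev.time_s)
    offset: dict[tuple[str, str], float] = {}
    start: dict[tuple[str, str], float] = {}
    total: dict[str, float] = {}
    for key in order:
        group = key[0]
        t = sessions[key]
        start[key] = min(t)
        offset[key] = total.get(group, 0.0)
        total[group] = offset[key] + (max(t) - min(t))
    timed = [
        (ev, offset[(ev.group, ev.session_id)] + ev.time_s - start[(ev.group, ev.session_id)])
        for ev in events
    ]
    return timed, total


def technique_option(technique: str, technique_pooling: str = "strict") -> str | None:
    """Map a recorded technique onto an analysis option, or None.

    Under ``strict`` pooling only plain ``lift``/``pull`` successes count;
    under ``pool_return_variants`` the ``return_*`` techniques are folded
    into their base option.
    """
    if technique in OPTIONS:
        return technique
    if technique_pooling == "pool_return_variants":
        if technique == "return_lift":
            return "lift"
        if technique == "return_pull":
            return "pull"
    elif technique_pooling != "strict":
        raise ValueError(f"unknown technique_pooling {technique_pooling!r}")
    return None


# ---------------------------------------------------------------------------
# diffusion dataset assembly
# ---------------------------------------------------------------------------


def standardize_ilvs(members: Sequence[Individual]) -> pd.DataFrame:
    """Standardize the sex/age/rank covariates over one group.

    Each variable is coded numerically (see :data:`ILV_CODING`), mean-centred
    and divided by its range, giving values centred on zero with a range of
    one.  A variable constant within the group is set to zero.
    """
    raw = pd.DataFrame(
        {
            "sex": [ILV_CODING["sex"][m.sex] for m in members],
            "age": [ILV_CODING["age"][m.age_class] for m in members],
            "rank": [float(m.rank) for m in members],
        },
        index=[m.id for m in members],
    )
    out = {}
    for col in raw:
        x = raw[col].to_numpy(dtype=float)
        rng = x.max() - x.min()
        out[col] = np.zeros_like(x) if rng == 0 else (x - x.mean()) / rng
    return pd.DataFrame(out, index=raw.index)


def build_diffusion_dataset(
    events: Sequence[ManipulationEvent],
    roster: Sequence[Individual],
    technique_pooling: str = "strict",
    censor_at_last_session: bool = False,
) -> dict[str, DiffusionDataset]:
    """Assemble one :class:`DiffusionDataset` per roster group.

    The acquisition order is defined by each individual's first successful
    opening per option (ties in experiment-clock time broken by event order,
    their incidence reported in ``n_time_ties``).  With
    ``censor_at_last_session`` each individual's last appearance (as actor or
    observer) is recorded so inference can drop it from later risk sets.
    """
    validate_roster(roster)
    events = sort_events(events)
    timed, total = experiment_clock(events)
    groups = sorted({ind.group for ind in roster})
    members = {g: [ind for ind in roster if ind.group == g] for g in groups}

    acquired: dict[str, dict[tuple[str, str], Acquisition]] = {g: {} for g in groups}
    first_opt: dict[str, dict[str, float]] = {g: {} for g in groups}
    first_any: dict[str, dict[str, float]] = {g: {} for g in groups}
    last_seen: dict[str, dict[str, float]] = {g: {} for g in groups}

    for ev, t in timed:
        g = ev.group
        if g not in acquired:
            raise DataValidationError(f"event {ev.event_index}: unknown group {g!r}")
        for who in (ev.actor_id, *ev.observer_ids):
            last_seen[g][who] = t
        if ev.outcome != "success":
            continue
        option = technique_option(ev.technique, technique_pooling)
        if option is None:
            continue
        first_opt[g].setdefault(option, t)
        key = (ev.actor_id, option)
        if key not in acquired[g]:
            acquired[g][key] = Acquisition(ev.actor_id, option, ev.event_index, t, order=0)
            first_any[g].setdefault(ev.actor_id, t)

    datasets: dict[str, DiffusionDataset] = {}
    for g in groups:
        acqs = sorted(acquired[g].values(), key=lambda a: (a.time_s, a.event_index))
        acqs = [replace(a, order=i + 1) for i, a in enumerate(acqs)]
        times = [a.time_s for a in acqs]
        n_ties = sum(1 for i in range(1, len(times)) if times[i] == times[i - 1])
        if not acqs:
            log.warning("group %s: zero successful acquisitions", g)
        if n_ties:
            log.info("group %s: %d tied acquisition times broken by event order", g, n_ties)
        datasets[g] = DiffusionDataset(
            group=g,
            individuals=tuple(m.id for m in members[g]),
            acquisitions=acqs,
            ilv=standardize_ilvs(members[g]),
            end_time=total.get(g, 0.0),
            first_option_success_time=first_opt[g],
            first_any=first_any[g],
            n_time_ties=n_ties,
            last_seen=last_seen[g] if censor_at_last_session else {},
            metadata={
                "technique_pooling": technique_pooling,
                "ilv_coding": "female/adult=+1, male/juvenile=-1; rank 1=highest; "
                "(x-mean)/range per group",
                "censor_at_last_session": censor_at_last_session,
            },
        )
    return datasets
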