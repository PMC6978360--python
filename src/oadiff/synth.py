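"""Generative simulator of open-diffusion experiments.

The simulator inverts the OADA rate model: naive (individual, option) pairs
acquire at absolute rate lambda0 * R_il(t), where R_il is the same relative
rate the inference machinery evaluates (asocial baseline 1, per-observation
social increments through one or more network components, ILV effects, and
the other-option-solved asocial boost).  Informed individuals go on
demonstrating: they emit success events as a Poisson process of rate mu,
choosing among the options they know; fully naive individuals emit
fruitless attempts at a lower rate.  Every success samples an observer set
(independent attendance, optionally rank-tilted), and each observation
increments the simulator's internal exposure ledger -- the ground truth the
dynamic-network builder must reproduce cell for cell.

Each acquisition carries a truth label (asocial or the network component
that caused it), drawn proportionally to the rate components at the instant
of acquisition, so estimator output (e.g. % of acquisitions by pathway) can
be compared against the generative truth.

Event times are produced by competing exponential clocks on a concatenated
observable-time axis, then sliced into sessions of fixed length so the
inter-session clock handling of the event reader is exercised.  The default
configuration mirrors the scale of the field study that motivates the
package: groups of 28 and 12 monkeys, 17 and 12 sessions, option-specific
social transmission s_OS = 0.25 with no cross-option transmission, and a
30-fold asocial boost for the second option.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .event_io import (
    OPTIONS,
    Individual,
    ManipulationEvent,
    sort_events,
    standardize_ilvs,
    write_events,
    write_roster,
)
from .obs_networks import bias_component_names, component_of


@dataclass(frozen=True)
class GroupSpec:
    """Composition and session structure of one simulated group."""

    name: str
    n_adult_males: int = 2
    n_adult_females: int = 6
    n_juvenile_males: int = 12
    n_juvenile_females: int = 8
    n_sessions: int = 17
    session_length_s: float = 4886.0  # ~81.4 min
    p_attend: float | None = None  # overrides SimulationConfig.p_attend per group
    seed_rank1_options: tuple[str, ...] = ()  # options known at t=0 by the top-ranked member

    @property
    def n(self) -> int:
        return (
            self.n_adult_males
            + self.n_adult_females
            + self.n_juvenile_males
            + self.n_juvenile_females
        )

    @property
    def horizon_s(self) -> float:
        return self.n_sessions * self.session_length_s


@dataclass
class SimulationConfig:
    """Study conditions for one simulated open-diffusion experiment."""

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("NH", p_attend=0.06),
        GroupSpec("KB", 1, 6, 5, 0, n_sessions=12, session_length_s=3721.0, p_attend=0.35),
    )
    pathway: str = "os_co"  # 'os_co' or a bias name: rank/sex/age/kin
    s: Mapping[str, float] = field(default_factory=lambda: {"OS": 0.25, "CO": 0.0})
    beta_social: Mapping[str, float] = field(default_factory=dict)
    beta_asocial: Mapping[str, float] = field(default_factory=dict)
    gamma_other_option: float = math.log(30.0)
    delta_option: float = 0.0
    lambda0: float = 3e-6  # asocial baseline, acquisitions /s per (individual, option)
    mu: float = 1.5e-3  # success rate /s per informed individual
    attempt_rate: float = 2e-4  # attempt rate /s per fully naive individual
    p_attend: float = 0.12  # per-event attendance probability of each non-actor
    attend_rank_coef: float = 0.0  # >0 tilts attendance toward watching anyone more if observer high-ranked
    attend_affinity_sd: float = 1.0  # sd (log scale) of the per-dyad attendance multiplier
    option_fidelity: float = 0.9  # prob. a two-option knower re-uses its first-learned option
    p_return_variant: float = 0.0  # fraction of successes relabelled return_lift/return_pull
    initial_informed: Mapping[str, Mapping[str, tuple[str, ...]]] = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class AcquisitionTruth:
    group: str
    individual_id: str
    option: str
    time_s: float  # concatenated observable-time clock
    order: int  # 1-based within group, both options pooled
    pathway: str  # 'asocial' or a component name
    exposures: dict[str, float]  # per component, at the acquisition instant


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    roster: list[Individual]
    events: list[ManipulationEvent]
    truth: list[AcquisitionTruth]
    ledger: dict[str, dict[tuple[str, str, str], int]]  # group -> (obs, dem, option) -> count
    first_success: dict[str, dict[tuple[str, str], float]]  # group -> (id, option) -> clock time

    def truth_orders(self, group: str) -> list[tuple[str, str]]:
        """(individual, option) in ground-truth first-success order."""
        fs = self.first_success[group]
        return [k for k, _t in sorted(fs.items(), key=lambda kv: kv[1])]


def _component_defs(config: SimulationConfig):
    if config.pathway == "os_co":
        return [("OS", False, None), ("CO", True, None)]
    return [(name, False, config.pathway) for name in bias_component_names(config.pathway)]


def build_group_roster(spec: GroupSpec, rng: np.random.Generator) -> list[Individual]:
    """Seeded roster: ids, shuffled ranks, juveniles linked to adult-female mothers."""
    classes = (
        [("male", "adult")] * spec.n_adult_males
        + [("female", "adult")] * spec.n_adult_females
        + [("male", "juvenile")] * spec.n_juvenile_males
        + [("female", "juvenile")] * spec.n_juvenile_females
    )
    ranks = rng.permutation(spec.n) + 1
    ids = [f"{spec.name}{i + 1:02d}" for i in range(spec.n)]
    mothers = [i for i, (s, a) in enumerate(classes) if s == "female" and a == "adult"]
    roster = []
    for i, (sex, age) in enumerate(classes):
        mother = None
        if age == "juvenile" and mothers:
            mother = ids[int(rng.choice(mothers))]
        roster.append(Individual(ids[i], spec.name, sex, age, int(ranks[i]), mother))
    return roster


def _simulate_group(
    spec: GroupSpec,
    roster: list[Individual],
    config: SimulationConfig,
    rng: np.random.Generator,
):
    n = spec.n
    ids = [ind.id for ind in roster]
    z = standardize_ilvs(roster)
    comps = _component_defs(config)
    C = len(comps)
    s_vec = np.array([config.s.get(name, 0.0) for name, _, _ in comps])
    bs = np.array([config.beta_social.get(v, 0.0) for v in ("sex", "age", "rank")])
    ba = np.array([config.beta_asocial.get(v, 0.0) for v in ("sex", "age", "rank")])
    zs = z.to_numpy() @ bs
    za = z.to_numpy() @ ba
    gamma, delta = config.gamma_other_option, config.delta_option

    # dyad -> component index (bias pathways only; OS/CO assign by option)
    comp_idx = np.zeros((n, n), dtype=int)
    if comps[0][2] is not None:
        bias = comps[0][2]
        names = [c[0] for c in comps]
        for i, obs in enumerate(roster):
            for j, dem in enumerate(roster):
                if i != j:
                    comp_idx[i, j] = names.index(component_of(bias, obs, dem))

    known = np.zeros((n, 2), dtype=bool)
    first_option = np.full(n, -1, dtype=int)  # index of each individual's first-learned option
    expo = np.zeros((C, n, 2))
    ledger: dict[tuple[str, str, str], int] = {}
    seeded = dict(config.initial_informed.get(spec.name, {}))
    if spec.seed_rank1_options:
        top = ids[int(np.argmin([ind.rank for ind in roster]))]
        seeded[top] = tuple(seeded.get(top, ())) + tuple(spec.seed_rank1_options)
    for ind_id, opts in seeded.items():
        for opt in opts:
            known[ids.index(ind_id), OPTIONS.index(opt)] = True
            if first_option[ids.index(ind_id)] < 0:
                first_option[ids.index(ind_id)] = OPTIONS.index(opt)

    base_attend = spec.p_attend if spec.p_attend is not None else config.p_attend
    attend_obs = base_attend * np.exp(config.attend_rank_coef * z["rank"].to_numpy())
    # dyadic affinity: who watches whom is strongly structured in the field
    # (spatial clustering, kin proximity); lognormal multipliers, mean ~1
    sd = config.attend_affinity_sd
    affinity = (
        np.exp(rng.normal(-0.5 * sd * sd, sd, size=(n, n))) if sd > 0 else np.ones((n, n))
    )
    attend_p = np.clip(attend_obs[:, None] * affinity, 0.0, 1.0)  # [observer, actor]
    is_pull_row = np.array([0.0, 1.0])

    events: list[tuple[float, str, str, str, frozenset[str]]] = []  # t, actor, technique, outcome, observers
    truth: list[AcquisitionTruth] = []
    first_success: dict[tuple[str, str], float] = {}
    T = spec.horizon_s
    t = 0.0
    order = 0

    def observers_of(actor_idx: int) -> list[int]:
        draws = rng.random(n) < attend_p[:, actor_idx]
        draws[actor_idx] = False
        return list(np.flatnonzero(draws))

    def record_success(actor_idx: int, opt_idx: int, t: float):
        nonlocal events
        opt = OPTIONS[opt_idx]
        technique = opt
        if config.p_return_variant > 0 and rng.random() < config.p_return_variant:
            technique = f"return_{opt}"
        obs = observers_of(actor_idx)
        events.append(
            (t, ids[actor_idx], technique, "success", frozenset(ids[o] for o in obs))
        )
        first_success.setdefault((ids[actor_idx], opt), t)
        for o in obs:
            ledger[(ids[o], ids[actor_idx], opt)] = (
                ledger.get((ids[o], ids[actor_idx], opt), 0) + 1
            )
            for k, (_name, cross, bias) in enumerate(comps):
                if bias is not None and comp_idx[o, actor_idx] != k:
                    continue
                expo[k, o, 1 - opt_idx if cross else opt_idx] += 1.0

    while True:
        solved = known.any(axis=1).astype(float)
        asoc = np.exp(za[:, None] + gamma * solved[:, None] + delta * is_pull_row[None, :])
        social = (s_vec[:, None, None] * expo).sum(axis=0) * np.exp(zs)[:, None]
        R = social + asoc
        naive = ~known
        acq_rates = config.lambda0 * R * naive
        informed = known.any(axis=1)
        manip_rates = np.where(informed, config.mu, 0.0)
        attempt_rates = np.where(~informed, config.attempt_rate, 0.0)
        rates = np.concatenate([acq_rates.ravel(), manip_rates, attempt_rates])
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= T:
            break
        choice = rng.choice(len(rates), p=rates / total)
        if choice < 2 * n:
            i, l = divmod(int(choice), 2)
            # truth label before this event updates any exposure
            # expo[k, i, l] is already the count relevant to acquiring l via
            # component k (cross-option components are filled option-flipped)
            w_asoc = asoc[i, l]
            w_comp = s_vec * expo[:, i, l] * np.exp(zs[i])
            weights = np.concatenate([[w_asoc], w_comp])
            lab = rng.choice(1 + C, p=weights / weights.sum())
            pathway = "asocial" if lab == 0 else comps[lab - 1][0]
            exposures = {
                name: float(expo[k, i, l]) for k, (name, _cross, _b) in enumerate(comps)
            }
            order += 1
            truth.append(
                AcquisitionTruth(
                    spec.name, ids[i], OPTIONS[l], t, order, pathway, exposures
                )
            )
            known[i, l] = True
            if first_option[i] < 0:
                first_option[i] = l
            record_success(i, l, t)
        elif choice < 3 * n:
            i = int(choice) - 2 * n
            opts = np.flatnonzero(known[i])
            if len(opts) == 2:
                # per-individual sticky technique preference: re-use the
                # first-learned option with probability option_fidelity
                pref = first_option[i]
                l = pref if rng.random() < config.option_fidelity else 1 - pref
            else:
                l = int(opts[0])
            record_success(i, l, t)
        else:
            i = int(choice) - 3 * n
            obs = observers_of(i)
            events.append((t, ids[i], "none", "attempt", frozenset(ids[o] for o in obs)))

    # slice the concatenated clock into sessions
    out_events = []
    for tt, actor, technique, outcome, obs in events:
        s_idx = min(int(tt // spec.session_length_s), spec.n_sessions - 1)
        out_events.append(
            ManipulationEvent(
                event_index=-1,
                session_id=f"{spec.name}_S{s_idx + 1:02d}",
                time_s=tt - s_idx * spec.session_length_s,
                group=spec.name,
                actor_id=actor,
                technique=technique,
                outcome=outcome,
                observer_ids=obs,
            )
        )
    return out_events, truth, ledger, first_success


def simulate(config: SimulationConfig, seed: int | None = None) -> SimulatedExperiment:
    """Run one experiment; fully deterministic given the seed."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    group_seeds = root.spawn(len(config.groups))
    roster: list[Individual] = []
    events: list[ManipulationEvent] = []
    truth: list[AcquisitionTruth] = []
    ledger: dict[str, dict] = {}
    first_success: dict[str, dict] = {}
    for spec, gseed in zip(config.groups, group_seeds):
        rng = np.random.default_rng(gseed)
        g_roster = build_group_roster(spec, rng)
        g_events, g_truth, g_ledger, g_first = _simulate_group(spec, g_roster, config, rng)
        roster.extend(g_roster)
        events.extend(g_events)
        truth.extend(g_truth)
        ledger[spec.name] = g_ledger
        first_success[spec.name] = g_first
    events = [
        ManipulationEvent(
            event_index=i,
            session_id=ev.session_id,
            time_s=ev.time_s,
            group=ev.group,
            actor_id=ev.actor_id,
            technique=ev.technique,
            outcome=ev.outcome,
            observer_ids=ev.observer_ids,
        )
        for i, ev in enumerate(events)
    ]
    return SimulatedExperiment(config, roster, sort_events(events), truth, ledger, first_success)


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------


def write_experiment(exp: SimulatedExperiment, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write roster/events CSVs in the event_io dialect plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out / f"{prefix}roster.csv",
        "events": out / f"{prefix}events.csv",
        "truth": out / f"{prefix}truth.json",
    }
    write_roster(exp.roster, paths["roster"])
    write_events(exp.events, paths["events"])
    truth_doc = {
        "seed": exp.config.seed,
        "pathway": exp.config.pathway,
        "s": dict(exp.config.s),
        "acquisitions": [asdict(a) for a in exp.truth],
        "first_success": {
            g: [[i, o, t] for (i, o), t in sorted(fs.items(), key=lambda kv: kv[1])]
            for g, fs in exp.first_success.items()
        },
        "ledger": {
            g: [[i, j, l, c] for (i, j, l), c in sorted(led.items())]
            for g, led in exp.ledger.items()
        },
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1))
    return paths


def fixture_configs(seed: int = 20) -> dict[str, SimulationConfig]:
    """Canonical scenario set used across the test suite."""
    return {
        "asocial": SimulationConfig(s={"OS": 0.0, "CO": 0.0}, seed=seed),
        "strong_os": SimulationConfig(s={"OS": 1.0, "CO": 0.0}, seed=seed + 1),
        "mixed_os_co": SimulationConfig(s={"OS": 0.3, "CO": 0.15}, seed=seed + 2),
        # top-ranked innovator (as in the field study), so the HL-biased
        # diffusion flows down the hierarchy
        "rank_hl": SimulationConfig(
            pathway="rank",
            s={"HL": 1.0, "LH": 0.02},
            groups=(
                GroupSpec("NH", p_attend=0.06, seed_rank1_options=("lift",)),
                GroupSpec("KB", 1, 6, 5, 0, n_sessions=12, session_length_s=3721.0,
                          p_attend=0.35, seed_rank1_options=("pull",)),
            ),
            seed=seed + 3,
        ),
    }


def make_fixture_suite(out_dir: str | Path, seed: int = 20) -> dict[str, dict[str, Path]]:
    """Write the canonical fixture scenarios (>= 4 logs with truth sidecars)."""
    out = Path(out_dir)
    suite = {}
    for name, config in fixture_configs(seed).items():
        exp = simulate(config)
        suite[name] = write_experiment(exp, out / name)
    return suite
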