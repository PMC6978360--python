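"""Per-individual option-preference tests and manipulation-rate tables.

Preference: an exact two-sided binomial test of an individual's successful
lift vs pull counts against p0 = 0.5.  Rate tables: per-individual counts of
manipulations, successes and observations together with the informed
exposure time (seconds of experiment clock from the individual's first
success to the end of observation), which enters downstream Poisson-family
regressions as a log offset.  Those regressions are routine and delegated
to statsmodels; this module's contract ends at correct counts and offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .event_io import (
    DiffusionDataset,
    Individual,
    ManipulationEvent,
    experiment_clock,
    roster_by_id,
    sort_events,
    technique_option,
)


@dataclass(frozen=True)
class PreferenceTest:
    individual_id: str
    n_lift: int
    n_pull: int
    p_value: float
    preferred: str  # 'lift' | 'pull' | 'none'


def binomial_preference(
    n_lift: int, n_pull: int, alpha: float = 0.05, individual_id: str = ""
) -> PreferenceTest:
    """Exact two-sided binomial test of lift vs pull use (p0 = 0.5)."""
    n = n_lift + n_pull
    if n < 1:
        raise ValueError("preference test needs at least one success")
    p = float(binomtest(n_lift, n, 0.5, alternative="two-sided").pvalue)
    if p < alpha and n_lift != n_pull:
        preferred = "lift" if n_lift > n_pull else "pull"
    else:
        preferred = "none"
    return PreferenceTest(individual_id, n_lift, n_pull, p, preferred)


def preference_table(
    events: Sequence[ManipulationEvent],
    roster: Sequence[Individual],
    technique_pooling: str = "strict",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-individual preference tests over all successful openings."""
    counts: dict[str, dict[str, int]] = {}
    for ev in events:
        if ev.outcome != "success":
            continue
        option = technique_option(ev.technique, technique_pooling)
        if option is None:
            continue
        counts.setdefault(ev.actor_id, {"lift": 0, "pull": 0})[option] += 1
    rows = []
    for ind in roster:
        c = counts.get(ind.id)
        if c is None or c["lift"] + c["pull"] == 0:
            continue
        t = binomial_preference(c["lift"], c["pull"], alpha, ind.id)
        rows.append(
            {
                "id": ind.id,
                "group": ind.group,
                "n_lift": t.n_lift,
                "n_pull": t.n_pull,
                "p_value": t.p_value,
                "preferred": t.preferred,
            }
        )
    return pd.DataFrame(rows, columns=["id", "group", "n_lift", "n_pull", "p_value", "preferred"])


def group_preference(
    events: Sequence[ManipulationEvent],
    group: str,
    technique_pooling: str = "strict",
    alpha: float = 0.05,
) -> PreferenceTest:
    """Group-level preference pooling all successful openings across members."""
    n_lift = n_pull = 0
    for ev in events:
        if ev.group != group or ev.outcome != "success":
            continue
        option = technique_option(ev.technique, technique_pooling)
        if option == "lift":
            n_lift += 1
        elif option == "pull":
            n_pull += 1
    return binomial_preference(n_lift, n_pull, alpha, individual_id=group)


def rate_tables(
    events: Sequence[ManipulationEvent],
    datasets: dict[str, DiffusionDataset],
    roster: Sequence[Individual],
) -> pd.DataFrame:
    """Per-individual counts and exposure-time offsets.

    Manipulation and success counts are restricted to each individual's
    informed period (at or after its first success); observation counts run
    over the whole experiment.  ``offset_log_s`` is log(informed exposure
    time); individuals never informed get zero informed counts, a zero
    exposure time and no offset (excluded from rate regressions).
    """
    by_id = roster_by_id(roster)
    timed, _total = experiment_clock(sort_events(events))
    first = {g: ds.first_any for g, ds in datasets.items()}
    manip = {i.id: 0 for i in roster}
    succ = {i.id: 0 for i in roster}
    obs = {i.id: 0 for i in roster}
    for ev, t in timed:
        g = ev.group
        t0 = first.get(g, {}).get(ev.actor_id)
        if t0 is not None and t >= t0:
            manip[ev.actor_id] += 1
            if ev.outcome == "success":
                succ[ev.actor_id] += 1
        for o in ev.observer_ids:
            obs[o] += 1
    rows = []
    for ind in roster:
        ds = datasets.get(ind.group)
        end = ds.end_time if ds is not None else 0.0
        t0 = first.get(ind.group, {}).get(ind.id)
        informed_t = max(0.0, end - t0) if t0 is not None else 0.0
        rows.append(
            {
                "id": ind.id,
                "group": ind.group,
                "rank": ind.rank,
                "manipulation_count": manip[ind.id],
                "success_count": succ[ind.id],
                "observation_count": obs[ind.id],
                "informed_exposure_time_s": informed_t,
                "naive_exposure_time_s": (t0 if t0 is not None else end),
                "offset_log_s": np.log(informed_t) if informed_t > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fit_rate_glm(table: pd.DataFrame, response: str = "success_count"):
    """Quasi-Poisson GLM of a count on rank and group with the log-time offset.

    Standard regression on the assembled table (informed individuals only);
    returns the fitted statsmodels results object.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = table.dropna(subset=["offset_log_s"]).copy()
    if sub.empty or sub["group"].nunique() < 1:
        raise ValueError("no informed individuals to regress on")
    formula = f"{response} ~ rank + C(group)" if sub["group"].nunique() > 1 else f"{response} ~ rank"
    model = smf.glm(
        formula,
        data=sub,
        family=sm.families.Poisson(),
        offset=sub["offset_log_s"],
    )
    res = model.fit(scale="X2")  # quasi-Poisson: Pearson-chi2 dispersion
    return res
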