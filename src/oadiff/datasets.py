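"""Bundled reference tables.

The package ships the printed composition table of the two study groups of
vervet monkeys, Noha (NH, 28 individuals) and Kubu (KB, 11 individuals
listed): individual, age class (sub-adults coded ``juvenile``), sex,
dominance rank (1 = highest, from the I&SI ordering of agonistic data),
number of observers recorded over the experiment, and the acquisition
orders -- first success with either option, and per-option orders for lift
and pull.  ``NA`` cells (individuals that never opened a box) are empty.

The table carries no maternity information, so kin-bias analyses cannot be
run on it; it mainly serves desk-scale checks (who learned, in what order)
and as a template roster for the simulator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .event_io import Individual, validate_roster


def load_study_table() -> pd.DataFrame:
    """Return the two-group composition table as a DataFrame."""
    with resources.files("oadiff").joinpath("data/study_groups.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    for col in ("first_success_order", "lift_order", "pull_order", "n_observers"):
        df[col] = df[col].astype("Int64")
    df["opportunistic"] = df["opportunistic"].astype(bool)
    return df


def load_study_roster() -> list[Individual]:
    """Return the composition table as a validated roster."""
    df = load_study_table()
    roster = [
        Individual(
            id=str(r.id),
            group=str(r.group),
            sex=str(r.sex),
            age_class=str(r.age_class),
            rank=int(r.rank),
        )
        for r in df.itertuples()
    ]
    validate_roster(roster)
    return roster


def acquisition_counts(df: pd.DataFrame | None = None) -> dict[str, tuple[int, int]]:
    """Per group: (individuals with a first-success order, individuals listed)."""
    if df is None:
        df = load_study_table()
    out: dict[str, tuple[int, int]] = {}
    for group, sub in df.groupby("group"):
        out[str(group)] = (int(sub["first_success_order"].notna().sum()), len(sub))
    return out
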