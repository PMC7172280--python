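"""Reproductive-value-weighted individual fitness and derived covariates.

Individual fitness over one annual time step is the individual's own
survival, weighted by the reproductive value of the state it then occupies,
plus half of each of its genetic offspring that survive to the next census,
weighted by the reproductive value of the state *they* then occupy:

    W_i = J_i * v(state_i, sex_i) + 1/2 * sum_y J_y * v(state_y, sex_y)

Over the first three years of life the same bookkeeping accumulates the
offspring terms across seasons t0..t0+3, while the individual's own-survival
term collapses to a single indicator of surviving the whole period, valued
at the state occupied at t0+3:

    W_{i,0..3} = J_{i,0..3} * v(state_{i,t3}, sex_i)
                 + 1/2 * sum_t sum_y J_{y,t} * v(state_{y,t}, sex_y)

Fitness is in units of the reproductive value of a dominant female breeder
(v is scaled so v(dominant, female) = 1).  The resulting distribution is
bimodal: a point mass at exactly zero (birds that die before contributing)
plus positive non-integer values.

In this implementation offspring hatched in season t are credited to the
parent in season t with J_y = survival of the offspring to the census at
t+1 and v evaluated at the state the offspring then occupies (typically
subordinate/helper).  The t = t0 term of the outer sum is retained for
completeness but is structurally zero for focal offspring, since nestlings
do not breed in their hatch season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from wrenfit.demography import ReproductiveValues

HORIZON = 3  # years over which early-life fitness is accumulated


@dataclass
class OffspringContribution:
    """One genetic offspring of the focal individual in one season."""

    season: int  # offset from the focal bird's t0 (0..HORIZON)
    survived: bool  # J_y: alive at the next annual census
    stage: str | None  # state occupied at that next census (None if dead)
    sex: str | None = None


@dataclass
class LifeHistoryRecord:
    """Per-individual life history over seasons t0..t0+3.

    ``survival[t]`` is the J indicator at season offset t (1 = alive at the
    census); ``states[t]`` the (stage, sex) then occupied, None once dead.
    Offspring are listed in the season they were produced.
    """

    id: object
    sex: str
    cohort_year: int
    survival: list[int]
    states: list[tuple[str, str] | None]
    offspring: list[OffspringContribution] = field(default_factory=list)

    def validate(self) -> None:
        j = np.asarray(self.survival)
        if ((np.diff(j) > 0)).any():
            raise ValueError(f"{self.id!r}: survival indicator increases (resurrection)")
        for off in self.offspring:
            if off.season < len(self.survival) and self.survival[off.season] == 0:
                raise ValueError(f"{self.id!r}: offspring listed in a season after death")


@dataclass(frozen=True)
class FitnessRecord:
    id: object
    W: float

    @property
    def zero_flag(self) -> bool:
        return self.W == 0.0


def _v(rv: ReproductiveValues, stage: str, sex: str) -> float:
    try:
        return rv.v[(stage, sex)]
    except KeyError as exc:
        raise KeyError(f"no reproductive value for state {(stage, sex)!r}") from exc


def annual_fitness(
    survived: bool,
    stage: str | None,
    sex: str,
    offspring: list[OffspringContribution],
    rv: ReproductiveValues,
) -> float:
    """One-season individual fitness W = J*v(own state) + 1/2 sum J_y v(offspring state)."""
    w = 0.0
    if survived:
        w += _v(rv, stage, sex)
    for off in offspring:
        if off.survived:
            w += 0.5 * _v(rv, off.stage, off.sex)
    return w


def three_year_fitness(record: LifeHistoryRecord, rv: ReproductiveValues) -> FitnessRecord:
    """Fitness over the first three years of life (seasons t0..t0+3)."""
    record.validate()
    w = 0.0
    survived_all = len(record.survival) > HORIZON and all(
        record.survival[t] for t in range(HORIZON + 1)
    )
    if survived_all:
        state_t3 = record.states[HORIZON]
        if state_t3 is None:
            raise ValueError(f"{record.id!r}: alive at t3 but state missing")
        w += _v(rv, state_t3[0], record.sex)
    for off in record.offspring:
        if off.season <= HORIZON and off.survived:
            w += 0.5 * _v(rv, off.stage, off.sex)
    return FitnessRecord(id=record.id, W=w)


def year_quality(nests: pd.DataFrame) -> pd.DataFrame:
    """Yearly mean number of fledglings per group, with a good/poor label.

    A year is "poor" iff its mean fledgling production is strictly below
    the across-year mean of those yearly means.  Requires columns
    ``year`` and ``fledged`` (fledglings per nest); production is summed
    per group-year first when a ``territory`` column is present.
    """
    if len(nests) == 0:
        raise ValueError("empty nests table; cannot compute year quality")
    if "territory" in nests.columns:
        per_group = nests.groupby(["year", "territory"])["fledged"].sum().reset_index()
    else:
        per_group = nests[["year", "fledged"]]
    yearly = per_group.groupby("year")["fledged"].mean().rename("mean_fledged").reset_index()
    grand = yearly["mean_fledged"].mean()
    yearly["poor"] = yearly["mean_fledged"] < grand
    return yearly


def body_condition(measurements: pd.DataFrame) -> pd.DataFrame:
    """Residual body condition and residual size per nestling.

    condition = residuals of OLS mass ~ tarsus + age;
    size      = residuals of OLS tarsus ~ age.
    Requires columns mass, tarsus, age; rows with any missing value get NaN
    residuals.  At least 3 complete rows are required.
    """
    needed = ["mass", "tarsus", "age"]
    for col in needed:
        if col not in measurements.columns:
            raise ValueError(f"measurements lack column {col!r}")
    ok = measurements[needed].notna().all(axis=1)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete nestling measurements")
    sub = measurements.loc[ok]
    X1 = sm.add_constant(sub[["tarsus", "age"]].to_numpy())
    cond = sm.OLS(sub["mass"].to_numpy(), X1).fit().resid
    X2 = sm.add_constant(sub[["age"]].to_numpy())
    size = sm.OLS(sub["tarsus"].to_numpy(), X2).fit().resid
    out = pd.DataFrame(index=measurements.index, columns=["condition", "size"], dtype=float)
    out.loc[ok, "condition"] = cond
    out.loc[ok, "size"] = size
    return out


def build_life_history(
    individuals: pd.DataFrame,
    states: pd.DataFrame,
    parentage: pd.DataFrame,
    cohort_ids,
) -> list[LifeHistoryRecord]:
    """Assemble per-offspring life-history records from the annual tables.

    ``individuals``: id, sex, cohort_year (hatch year).  ``states``:
    long-format id, year, stage, sex, alive.  ``parentage``: offspring,
    genetic_dam, genetic_sire, year.  For each focal bird in
    ``cohort_ids``, offspring it produced in seasons t0..t0+3 are credited
    with their own first-year survival and next-census state.
    """
    sex_of = dict(zip(individuals["id"], individuals["sex"]))
    cohort_of = dict(zip(individuals["id"], individuals["cohort_year"]))
    state_of: dict = {}
    alive_of: dict = {}
    for row in states.itertuples():
        state_of[(row.id, row.year)] = (row.stage, row.sex)
        alive_of[(row.id, row.year)] = bool(row.alive)

    kids: dict = {}
    for row in parentage.itertuples():
        for parent in (row.genetic_dam, row.genetic_sire):
            if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                continue
            kids.setdefault(parent, []).append((row.offspring, row.year))

    records = []
    for ind in cohort_ids:
        t0 = cohort_of[ind]
        surv, sts = [], []
        for t in range(HORIZON + 1):
            alive = alive_of.get((ind, t0 + t), False)
            surv.append(1 if alive else 0)
            sts.append(state_of.get((ind, t0 + t)) if alive else None)
        offs = []
        for kid, yr in kids.get(ind, []):
            t = yr - t0
            if 0 <= t <= HORIZON:
                kid_alive = alive_of.get((kid, yr + 1), False)
                kid_state = state_of.get((kid, yr + 1)) if kid_alive else None
                offs.append(
                    OffspringContribution(
                        season=t,
                        survived=kid_alive,
                        stage=kid_state[0] if kid_state else None,
                        sex=sex_of.get(kid),
                    )
                )
        records.append(
            LifeHistoryRecord(
                id=ind,
                sex=sex_of[ind],
                cohort_year=t0,
                survival=surv,
                states=sts,
                offspring=offs,
            )
        )
    return records


def fitness_table(
    individuals: pd.DataFrame,
    states: pd.DataFrame,
    parentage: pd.DataFrame,
    cohort_ids,
    rv: ReproductiveValues,
) -> pd.DataFrame:
    """Three-year fitness for every focal bird in ``cohort_ids``."""
    records = build_life_history(individuals, states, parentage, cohort_ids)
    rows = [(rec.id, three_year_fitness(rec, rv).W) for rec in records]
    out = pd.DataFrame(rows, columns=["id", "W"])
    out["zero_flag"] = out["W"] == 0.0
    return out
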