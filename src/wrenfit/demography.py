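"""Two-sex stage-structured projection matrix and reproductive values.

The life cycle has three stages — fledgling (first year after fledging),
subordinate (helper), dominant (pair-bonded breeder) — for each sex, giving
a 6-state annual matrix model under a pre-breeding census.  Transitions are
parameterised by per-state annual survival, the probability (conditional on
survival) of holding a dominant position next year, and per-state expected
numbers of genetic fledglings; each genetic fledgling is credited half to
its mother and half to its father, so fecundity entries carry a factor 1/2.

Reproductive values v are the left eigenvector of the dominant eigenvalue
lambda of the projection matrix, scaled so the dominant female has v = 1;
individual fitness downstream is therefore expressed in units of the
reproductive value of a dominant female breeder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("fledgling", "subordinate", "dominant")
SEXES = ("female", "male")
#: canonical state order of the 6-state model
STATES: tuple[tuple[str, str], ...] = tuple((st, sx) for sx in SEXES for st in STAGES)


def state_index(stage: str, sex: str) -> int:
    return STATES.index((stage, sex))


@dataclass
class LifeCycleSpec:
    """Components of the two-sex life-cycle graph.

    All dicts are keyed by (stage, sex).  ``survival`` is annual survival;
    ``to_dominant`` is the probability of being dominant next year
    conditional on survival (survivors not becoming dominant become
    subordinate); ``fledglings`` is the expected number of genetic
    fledglings produced per year by an individual in that state, split by
    offspring sex via ``offspring_sex_ratio`` (proportion female).
    """

    survival: dict = field(default_factory=dict)
    to_dominant: dict = field(default_factory=dict)
    fledglings: dict = field(default_factory=dict)
    offspring_sex_ratio: float = 0.5

    def validate(self) -> None:
        for key, p in {**self.survival, **self.to_dominant}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1] for state {key}: {p}")
        for key, m in self.fledglings.items():
            if m < 0:
                raise ValueError(f"negative fecundity for state {key}: {m}")
        if not 0.0 <= self.offspring_sex_ratio <= 1.0:
            raise ValueError("offspring sex ratio must be a probability")


@dataclass
class ReproductiveValues:
    """State- and sex-dependent reproductive values and the growth rate."""

    v: dict  # (stage, sex) -> value; v[(dominant, female)] == 1
    lam: float

    def value(self, stage: str, sex: str) -> float:
        return self.v[(stage, sex)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(st, sx, self.v[(st, sx)]) for st, sx in STATES],
            columns=["stage", "sex", "v"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, lam: float = float("nan")) -> "ReproductiveValues":
        v = {(row.stage, row.sex): float(row.v) for row in frame.itertuples()}
        return cls(v=v, lam=lam)


def build_projection_matrix(spec: LifeCycleSpec) -> np.ndarray:
    """Assemble the 6x6 annual projection matrix A (columns = current state).

    Survival/transition block: an individual in state (stage, sex) survives
    with probability s and then occupies dominant (prob t) or subordinate
    (prob 1-t) — fledglings never remain fledglings.  Fecundity block: each
    state contributes 1/2 of its expected genetic fledglings to the two
    fledgling rows, split by offspring sex.
    """
    spec.validate()
    n = len(STATES)
    A = np.zeros((n, n))
    for j, (stage, sex) in enumerate(STATES):
        s = spec.survival.get((stage, sex), 0.0)
        t = spec.to_dominant.get((stage, sex), 0.0)
        if s > 0.0:
            A[state_index("dominant", sex), j] += s * t
            A[state_index("subordinate", sex), j] += s * (1.0 - t)
        m = spec.fledglings.get((stage, sex), 0.0)
        if m > 0.0:
            q = spec.offspring_sex_ratio
            A[state_index("fledgling", "female"), j] += 0.5 * m * q
            A[state_index("fledgling", "male"), j] += 0.5 * m * (1.0 - q)
    if (A < 0).any():
        raise ValueError("projection matrix has negative entries")
    if not A.any():
        raise ValueError("projection matrix is identically zero")
    return A


def _dominant_eigenpair(A: np.ndarray, left: bool, rtol: float = 1e-10):
    """Dominant (lambda, vector) via full decomposition, power iteration fallback."""
    M = A.T if left else A
    vals, vecs = np.linalg.eig(M)
    i = int(np.argmax(vals.real))
    lam = vals[i]
    vec = vecs[:, i]
    if abs(lam.imag) > rtol * max(abs(lam), 1.0) or np.abs(vec.imag).max() > 1e-8:
        lam, vec = _power_iteration(M)
    else:
        lam, vec = lam.real, vec.real
    if lam <= 0:
        raise np.linalg.LinAlgError("dominant eigenvalue is not positive")
    # sign-normalise: Perron vector of a non-negative matrix is one-signed
    if vec.sum() < 0:
        vec = -vec
    if (vec < -1e-8 * np.abs(vec).max()).any():
        lam, vec = _power_iteration(M)
    resid = np.linalg.norm(M @ vec - lam * vec) / np.linalg.norm(vec)
    if resid > rtol * max(lam, 1.0):
        raise np.linalg.LinAlgError(
            f"dominant eigenpair residual {resid:.2e} exceeds tolerance; "
            "matrix may have a defective or non-simple dominant eigenvalue"
        )
    return float(lam), np.clip(vec, 0.0, None)


def _power_iteration(M: np.ndarray, steps: int = 10000, tol: float = 1e-14):
    x = np.ones(M.shape[0])
    lam = 0.0
    for _ in range(steps):
        y = M @ x
        lam_new = np.linalg.norm(y)
        if lam_new == 0.0:
            raise np.linalg.LinAlgError("power iteration collapsed to zero")
        y = y / lam_new
        if np.linalg.norm(y - x) < tol:
            x, lam = y, lam_new
            break
        x, lam = y, lam_new
    return float(lam), x


def reproductive_values(A: np.ndarray, rtol: float = 1e-10) -> ReproductiveValues:
    """Reproductive values: the left eigenvector of the dominant eigenvalue.

    Scaled so that v(dominant, female) = 1 for a 6-state matrix in the
    canonical :data:`STATES` order; for matrices of other sizes the vector
    is scaled by its last entry if nonzero, else left sum-normalised, and
    returned keyed by integer state index.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("projection matrix must be square")
    lam, v = _dominant_eigenpair(A, left=True, rtol=rtol)
    if A.shape[0] == len(STATES):
        ref = v[state_index("dominant", "female")]
        if ref <= 0:
            raise ValueError("dominant-female reproductive value is zero; cannot scale")
        v = v / ref
        vdict = {state: v[i] for i, state in enumerate(STATES)}
    else:
        ref = v[-1]
        v = v / ref if ref > 0 else v / v.sum()
        vdict = {i: v[i] for i in range(len(v))}
    return ReproductiveValues(v=vdict, lam=lam)


def stable_distribution(A: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Stable state distribution: right dominant eigenvector, sum-normalised."""
    A = np.asarray(A, dtype=float)
    _, w = _dominant_eigenpair(A, left=False, rtol=rtol)
    return w / w.sum()


def default_lifecycle() -> LifeCycleSpec:
    """A plausible fairy-wren-like parameterisation used as the simulator's
    demographic backbone: moderate first-year survival, high adult survival,
    helpers queueing for dominant vacancies, and dominants doing nearly all
    of the (genetic) reproduction, with subordinate males siring a little
    extra-pair paternity."""
    surv, todom, fled = {}, {}, {}
    for sex in SEXES:
        surv[("fledgling", sex)] = 0.45
        surv[("subordinate", sex)] = 0.70
        surv[("dominant", sex)] = 0.78
        todom[("fledgling", sex)] = 0.10
        todom[("subordinate", sex)] = 0.30
        todom[("dominant", sex)] = 0.97
        fled[("fledgling", sex)] = 0.0
        fled[("subordinate", sex)] = 0.10 if sex == "male" else 0.0
        fled[("dominant", sex)] = 1.3 if sex == "female" else 1.2
    return LifeCycleSpec(survival=surv, to_dominant=todom, fledglings=fled)


def estimate_lifecycle(
    individuals: pd.DataFrame,
    parentage: pd.DataFrame,
    states: pd.DataFrame,
    fledged_ids=None,
) -> LifeCycleSpec:
    """Estimate life-cycle components from annual state records.

    ``states`` is long-format: id, year, stage, sex, alive (the bird's
    state at each annual census while alive).  Survival and
    transition-to-dominant rates come from year-to-year state pairs;
    per-state genetic fledgling production comes from ``parentage``
    restricted to offspring that fledged (``fledged_ids``), each credited
    to the dam's and the sire's state in the offspring's hatch year.
    States never observed keep rate 0.
    """
    spec = LifeCycleSpec()
    states = states.sort_values(["id", "year"])
    nxt = states.groupby("id").shift(-1)
    cur = states
    has_next = nxt["year"].notna() & (nxt["year"] == cur["year"] + 1)
    surv_n: dict = {}
    surv_k: dict = {}
    dom_n: dict = {}
    dom_k: dict = {}
    for (stage, sex), grp in cur[has_next].groupby(["stage", "sex"]):
        alive_next = nxt.loc[grp.index, "alive"].astype(bool)
        surv_n[(stage, sex)] = len(grp)
        surv_k[(stage, sex)] = int(alive_next.sum())
        surv_idx = grp.index[alive_next]
        dom_n[(stage, sex)] = len(surv_idx)
        dom_k[(stage, sex)] = int((nxt.loc[surv_idx, "stage"] == "dominant").sum())
    for key in surv_n:
        spec.survival[key] = surv_k[key] / surv_n[key] if surv_n[key] else 0.0
        spec.to_dominant[key] = dom_k[key] / dom_n[key] if dom_n.get(key) else 0.0
    # fecundity: genetic fledglings credited to each parent's current state
    par = parentage
    if fledged_ids is not None:
        par = par[par["offspring"].isin(set(fledged_ids))]
    state_of = {(r.id, r.year): (r.stage, r.sex) for r in states.itertuples()}
    year_of = dict(zip(parentage["offspring"], parentage["year"])) if "year" in parentage else {}
    counts: dict = {}
    for row in par.itertuples():
        yr = getattr(row, "year", year_of.get(row.offspring))
        for parent in (row.genetic_dam, row.genetic_sire):
            if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                continue
            st = state_of.get((parent, yr))
            if st is not None:
                counts[st] = counts.get(st, 0) + 1
    exposures = cur.groupby(["stage", "sex"]).size().to_dict()
    for key, n_state_years in exposures.items():
        spec.fledglings[key] = counts.get(key, 0) / n_state_years
    return spec
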