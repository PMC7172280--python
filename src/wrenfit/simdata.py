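"""Seeded synthetic cooperatively-breeding populations with known truth.

The generator emulates the social and genetic structure the downstream
analysis assumes: a ring of territories each held by a dominant pair plus
up to eight subordinate helpers of either sex; high whole-brood nest
predation; clutches of 1-3; very high extra-pair paternity (~58% of
offspring at baseline) whose odds increase with the kinship of the social
pair; hypervariable microsatellite genotypes (7-8 loci, ~30 alleles)
transmitted Mendelianly; and strong natal philopatry — offspring stay as
helpers and fill dominant vacancies preferentially near home, which is
what makes incestuous social pairings (and hence inbreeding) arise
endogenously rather than by fiat.

Inbreeding depression is injected as a configurable *threshold* effect on
true pedigree f: offspring above the threshold can suffer reduced nestling
body condition, reduced first-year survival, and (as adults) reduced
reproduction.  The truth table records each offspring's pedigree f, the
social pair's pedigree kinship, and the effect sizes used, so injected
effects are recoverable by the inference stage.

All randomness flows from a single seed through one numpy Generator;
identical configurations yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from wrenfit.pedigree import Pedigree
from wrenfit.relatedness import MISSING, GenotypeTable

FLEDGLING, SUBORDINATE, DOMINANT = "fledgling", "subordinate", "dominant"
MAX_HELPERS = 8


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class InbreedingEffects:
    """Threshold inbreeding-depression effects, applied when true pedigree
    f exceeds ``f_threshold`` (the lower edge of the half-sib bin)."""

    f_threshold: float = 0.10
    condition_delta: float = 0.0  # grams, added to nestling mass
    first_year_survival_delta: float = 0.0  # additive probability offset
    reproduction_multiplier: float = 1.0  # thins eggs of inbred mothers / EP siring


@dataclass(frozen=True)
class SimConfig:
    """Everything the population generator needs; defaults describe the
    study conditions the pipeline is meant for."""

    n_territories: int = 70
    n_years: int = 12  # genotyped cohort years
    burnin_years: int = 5  # pre-cohort years so kin structure can develop
    followup_years: int = 3  # extra seasons so the last cohort gets 3-year fitness
    loci: tuple = tuple(
        (f"msat{i + 1}", 30, tuple([1.0 / 30] * 30)) for i in range(8)
    )  # (name, n_alleles, frequency vector)
    epp_rate_base: float = 0.58
    epp_kin_multiplier: float = 8.0  # EPP odds ratio at k = 0.25 vs k = 0
    nest_predation_rate: float = 0.70
    predation_year_sd: float = 0.5  # logit-scale annual environment effect
    clutch_size_probs: tuple = (0.25, 0.50, 0.25)  # sizes 1, 2, 3
    broods_per_female: int = 1
    survival: tuple = (
        ((FLEDGLING, "female"), 0.45),
        ((FLEDGLING, "male"), 0.45),
        ((SUBORDINATE, "female"), 0.85),
        ((SUBORDINATE, "male"), 0.85),
        ((DOMINANT, "female"), 0.78),
        ((DOMINANT, "male"), 0.78),
    )
    helper_count_distribution: tuple = (0.10, 0.20, 0.25, 0.18, 0.12, 0.07, 0.04, 0.025, 0.015)
    dispersal_decay: float = 0.5  # ring-distance decay for vacancy filling
    ep_sire_decay: float = 2.0  # ring-distance decay for extra-pair sires
    immigration_rate: float = 0.3  # chance an unfillable vacancy attracts an immigrant
    offspring_sex_ratio: float = 0.5  # proportion female
    inbreeding_effects: InbreedingEffects = InbreedingEffects()
    # nestling measurement model (age in days, tarsus mm, mass g)
    measure_age_mean: float = 8.0
    measure_age_sd: float = 0.75
    tarsus_intercept: float = 8.0
    tarsus_age_slope: float = 0.45
    tarsus_sd: float = 0.5
    mass_intercept: float = 2.0
    mass_tarsus_slope: float = 0.8
    mass_age_slope: float = 0.10
    mass_helper_effect: float = 0.05  # grams per helper
    mass_sd: float = 0.5
    seed: int = 0

    def survival_of(self, stage: str, sex: str) -> float:
        return dict(self.survival)[(stage, sex)]

    def validate(self) -> None:
        if self.n_territories < 1:
            raise ConfigurationError("need at least one territory")
        if self.n_years < 1 or self.burnin_years < 0 or self.followup_years < 0:
            raise ConfigurationError("year counts must be non-negative (n_years >= 1)")
        probs = [
            self.epp_rate_base,
            self.nest_predation_rate,
            self.immigration_rate,
            self.offspring_sex_ratio,
        ] + [p for _, p in self.survival]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability out of [0,1]: {p}")
        if self.epp_kin_multiplier < 1.0:
            raise ConfigurationError("epp_kin_multiplier must be >= 1")
        for name, k, freqs in self.loci:
            freqs = np.asarray(freqs, dtype=float)
            if len(freqs) != k or (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"allele frequencies for locus {name!r} must be {k} values summing to 1"
                )
        if len(self.clutch_size_probs) != 3 or abs(sum(self.clutch_size_probs) - 1.0) > 1e-9:
            raise ConfigurationError("clutch_size_probs must be 3 values (sizes 1-3) summing to 1")
        hd = np.asarray(self.helper_count_distribution, dtype=float)
        if len(hd) != MAX_HELPERS + 1 or (hd < 0).any() or abs(hd.sum() - 1.0) > 1e-9:
            raise ConfigurationError("helper_count_distribution must cover 0-8 and sum to 1")
        eff = self.inbreeding_effects
        if not 0.0 <= eff.reproduction_multiplier <= 1.0:
            raise ConfigurationError("reproduction_multiplier must be in [0,1]")


@dataclass
class SyntheticDataset:
    """Tables produced by one simulation run.

    ``individuals``: id, sex, cohort_year, immigrant flag.
    ``states``: long-format id, year, stage, sex, alive (recorded while alive).
    ``nests``: nest, year, territory, mother, social_father, brood_size,
    helpers_female, helpers_male, predated, fledged.
    ``parentage``: offspring, year, nest, genetic_dam, genetic_sire,
    social_dam, social_sire, epp, fledged.
    ``measurements``: nestling biometrics (id, nest, age, tarsus, mass).
    ``truth``: per-offspring pedigree ground truth and the injected effect
    sizes.  ``genotypes``: a :class:`GenotypeTable` over everyone.
    """

    config: SimConfig
    individuals: pd.DataFrame
    states: pd.DataFrame
    nests: pd.DataFrame
    parentage: pd.DataFrame
    measurements: pd.DataFrame
    truth: pd.DataFrame
    genotypes: GenotypeTable
    pedigree: Pedigree = field(repr=False, default=None)

    @property
    def cohort_ids(self) -> list:
        """Offspring of the genotyped cohort years (the analysis sample)."""
        cfg = self.config
        last = cfg.burnin_years + cfg.n_years
        sel = (self.parentage["year"] >= cfg.burnin_years) & (self.parentage["year"] < last)
        return list(self.parentage.loc[sel, "offspring"])

    def realized_epp_rate(self) -> float:
        return float(self.parentage["epp"].mean())


def transmit_genotypes(dam_genotype, sire_genotype, rng) -> np.ndarray:
    """Mendelian transmission: one uniformly chosen allele per parent per locus.

    A parent missing at a locus (allele code 0) yields a missing offspring
    genotype (0, 0) at that locus.
    """
    dam = np.asarray(dam_genotype, dtype=np.int64)
    sire = np.asarray(sire_genotype, dtype=np.int64)
    if dam.shape != sire.shape or dam.ndim != 2 or dam.shape[1] != 2:
        raise ValueError("parent genotypes must both be (n_loci, 2) arrays")
    L = dam.shape[0]
    pick_d = rng.integers(0, 2, size=L)
    pick_s = rng.integers(0, 2, size=L)
    child = np.stack([dam[np.arange(L), pick_d], sire[np.arange(L), pick_s]], axis=1)
    bad = (dam == MISSING).any(axis=1) | (sire == MISSING).any(axis=1)
    child[bad] = MISSING
    return child


class _Bird:
    __slots__ = (
        "id", "sex", "cohort", "stage", "territory", "alive", "inbred", "immigrant", "fledged",
    )

    def __init__(self, id, sex, cohort, stage, territory, inbred=False, immigrant=False):
        self.id = id
        self.sex = sex
        self.cohort = cohort
        self.stage = stage
        self.territory = territory
        self.alive = True
        self.inbred = inbred
        self.immigrant = immigrant
        self.fledged = stage != FLEDGLING  # nestlings must fledge; adults already did


class _Simulator:
    def __init__(self, config: SimConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.ped = Pedigree()
        self.birds: dict[int, _Bird] = {}
        self.geno: dict[int, np.ndarray] = {}
        self.next_id = 1
        self.loci = [name for name, _, _ in config.loci]
        self.freqs = [np.asarray(f, dtype=float) for _, _, f in config.loci]
        T = config.n_territories
        self.dom = {("female", t): None for t in range(T)}
        self.dom.update({("male", t): None for t in range(T)})
        # output accumulators
        self.state_rows: list = []
        self.nest_rows: list = []
        self.parent_rows: list = []
        self.measure_rows: list = []
        self.truth_rows: list = []
        self.next_nest = 1

    # -- plumbing ---------------------------------------------------------
    def _founder_genotype(self) -> np.ndarray:
        return np.stack(
            [self.rng.choice(len(f), size=2, p=f) + 1 for f in self.freqs]
        ).astype(np.int64)

    def _new_bird(self, sex, cohort, stage, territory, dam=None, sire=None, immigrant=False):
        bid = self.next_id
        self.next_id += 1
        self.ped.add(bid, dam, sire)
        if dam is None:
            self.geno[bid] = self._founder_genotype()
            inbred = False
        else:
            self.geno[bid] = transmit_genotypes(self.geno[dam], self.geno[sire], self.rng)
            inbred = self.ped.inbreeding(bid) > self.cfg.inbreeding_effects.f_threshold
        bird = _Bird(bid, sex, cohort, stage, territory, inbred=inbred, immigrant=immigrant)
        self.birds[bid] = bird
        return bird

    def _ring_distance(self, t1: int, t2: int) -> int:
        T = self.cfg.n_territories
        d = abs(t1 - t2)
        return min(d, T - d)

    def _helpers_on(self, territory: int):
        return [
            b
            for b in self.birds.values()
            if b.alive and b.stage == SUBORDINATE and b.territory == territory
        ]

    # -- initialisation ---------------------------------------------------
    def initialise(self) -> None:
        cfg = self.cfg
        for t in range(cfg.n_territories):
            dam = self._new_bird("female", -1, DOMINANT, t)
            sire = self._new_bird("male", -1, DOMINANT, t)
            self.dom[("female", t)] = dam.id
            self.dom[("male", t)] = sire.id
            n_help = int(self.rng.choice(MAX_HELPERS + 1, p=cfg.helper_count_distribution))
            for _ in range(n_help):
                sex = "female" if self.rng.random() < cfg.offspring_sex_ratio else "male"
                self._new_bird(sex, -1, SUBORDINATE, t, dam=dam.id, sire=sire.id)

    # -- one breeding season ----------------------------------------------
    def _epp_prob(self, k_social: float) -> float:
        cfg = self.cfg
        return float(
            expit(logit(cfg.epp_rate_base) + np.log(cfg.epp_kin_multiplier) * k_social / 0.25)
        )

    def _sample_ep_sire(self, territory: int):
        cfg = self.cfg
        cands, weights = [], []
        for t in range(cfg.n_territories):
            if t == territory:
                continue
            male = self.dom[("male", t)]
            if male is None:
                continue
            w = np.exp(-self._ring_distance(territory, t) / cfg.ep_sire_decay)
            if self.birds[male].inbred:
                w *= cfg.inbreeding_effects.reproduction_multiplier
            cands.append(male)
            weights.append(w)
        if not cands or sum(weights) == 0:
            return None
        weights = np.asarray(weights) / np.sum(weights)
        return int(self.rng.choice(cands, p=weights))

    def breed(self, year: int, emit: bool) -> None:
        cfg = self.cfg
        pred_year = float(
            expit(logit(cfg.nest_predation_rate) + self.rng.normal(0.0, cfg.predation_year_sd))
        )
        for t in range(cfg.n_territories):
            mother = self.dom[("female", t)]
            father = self.dom[("male", t)]
            if mother is None or father is None:
                continue
            helpers = self._helpers_on(t)
            n_hf = sum(1 for b in helpers if b.sex == "female")
            n_hm = len(helpers) - n_hf
            k_social = self.ped.kinship(mother, father)
            p_ep = self._epp_prob(k_social)
            for _ in range(cfg.broods_per_female):
                nest = self.next_nest
                self.next_nest += 1
                clutch = int(self.rng.choice((1, 2, 3), p=cfg.clutch_size_probs))
                predated = bool(self.rng.random() < pred_year)
                kids = []
                for _egg in range(clutch):
                    if (
                        self.birds[mother].inbred
                        and self.rng.random() >= cfg.inbreeding_effects.reproduction_multiplier
                    ):
                        continue  # egg lost to the mother's inbreeding penalty
                    is_ep = bool(self.rng.random() < p_ep)
                    sire = self._sample_ep_sire(t) if is_ep else father
                    if sire is None:
                        sire = father
                    sex = "female" if self.rng.random() < cfg.offspring_sex_ratio else "male"
                    kid = self._new_bird(sex, year, FLEDGLING, t, dam=mother, sire=sire)
                    kids.append((kid, sire))
                fledged = 0 if predated else len(kids)
                if emit:
                    self.nest_rows.append(
                        (nest, year, t, mother, father, len(kids), n_hf, n_hm, predated, fledged)
                    )
                for kid, sire in kids:
                    kid.fledged = not predated  # type: ignore[attr-defined]
                    if not emit:
                        continue
                    f_true = self.ped.inbreeding(kid.id)
                    eff = cfg.inbreeding_effects
                    self.parent_rows.append(
                        (
                            kid.id,
                            year,
                            nest,
                            mother,
                            sire,
                            mother,
                            father,
                            sire != father,
                            not predated,
                        )
                    )
                    self.truth_rows.append(
                        (
                            kid.id,
                            f_true,
                            k_social,
                            sire != father,
                            kid.inbred,
                            eff.f_threshold,
                            eff.condition_delta,
                            eff.first_year_survival_delta,
                            eff.reproduction_multiplier,
                        )
                    )
                    age = max(float(self.rng.normal(cfg.measure_age_mean, cfg.measure_age_sd)), 1.0)
                    tarsus = float(
                        self.rng.normal(cfg.tarsus_intercept + cfg.tarsus_age_slope * age, cfg.tarsus_sd)
                    )
                    mass = float(
                        self.rng.normal(
                            cfg.mass_intercept
                            + cfg.mass_tarsus_slope * tarsus
                            + cfg.mass_age_slope * age
                            + cfg.mass_helper_effect * len(helpers)
                            + (eff.condition_delta if kid.inbred else 0.0),
                            cfg.mass_sd,
                        )
                    )
                    self.measure_rows.append((kid.id, nest, year, age, tarsus, mass))

    # -- mortality, promotion, dispersal ----------------------------------
    def survive_and_promote(self, year: int) -> None:
        cfg = self.cfg
        # mortality (fledglings of this season included; unfledged die)
        for b in list(self.birds.values()):
            if not b.alive:
                continue
            if b.stage == FLEDGLING and b.cohort == year:
                if not getattr(b, "fledged", False):
                    b.alive = False
                    continue
                s = cfg.survival_of(FLEDGLING, b.sex)
                if b.inbred:
                    s = min(max(s + cfg.inbreeding_effects.first_year_survival_delta, 0.0), 1.0)
            else:
                s = cfg.survival_of(b.stage, b.sex)
            if self.rng.random() >= s:
                b.alive = False
        # clear vacated dominant slots
        for key, bid in self.dom.items():
            if bid is not None and not self.birds[bid].alive:
                self.dom[key] = None
        # survivors age into subordinates (unless they hold a dominant slot)
        held = {bid for bid in self.dom.values() if bid is not None}
        for b in self.birds.values():
            if b.alive and b.stage == FLEDGLING:
                b.stage = SUBORDINATE
            if b.alive and b.stage == DOMINANT and b.id not in held:
                b.stage = SUBORDINATE  # deposed (should not normally happen)
        # fill vacancies: philopatric helpers first, then immigrants
        for sex in ("female", "male"):
            vacancies = [t for t in range(cfg.n_territories) if self.dom[(sex, t)] is None]
            vacancies = [vacancies[i] for i in self.rng.permutation(len(vacancies))]
            for t in vacancies:
                cands = [
                    b
                    for b in self.birds.values()
                    if b.alive and b.stage == SUBORDINATE and b.sex == sex
                ]
                if cands:
                    w = np.array(
                        [
                            np.exp(-self._ring_distance(b.territory, t) / cfg.dispersal_decay)
                            for b in cands
                        ]
                    )
                    chosen = cands[int(self.rng.choice(len(cands), p=w / w.sum()))]
                    chosen.stage = DOMINANT
                    chosen.territory = t
                    self.dom[(sex, t)] = chosen.id
                elif self.rng.random() < cfg.immigration_rate:
                    imm = self._new_bird(sex, year, DOMINANT, t, immigrant=True)
                    self.dom[(sex, t)] = imm.id
        # helper cap: supernumerary helpers emigrate out of the study area
        for t in range(cfg.n_territories):
            helpers = self._helpers_on(t)
            if len(helpers) > MAX_HELPERS:
                order = self.rng.permutation(len(helpers))
                for i in order[MAX_HELPERS:]:
                    helpers[i].alive = False

    def record_states(self, year: int) -> None:
        # census: everyone alive this season; current-season nestlings count
        # as fledglings only if their nest was not predated, so estimated
        # fledgling survival is survival *after* fledging
        for b in self.birds.values():
            if not b.alive:
                continue
            if b.stage == FLEDGLING and b.cohort == year and not getattr(b, "fledged", False):
                continue
            self.state_rows.append((b.id, year, b.stage, b.sex, True))

    # -- main loop ---------------------------------------------------------
    def run(self) -> SyntheticDataset:
        cfg = self.cfg
        self.initialise()
        total = cfg.burnin_years + cfg.n_years + cfg.followup_years
        first_cohort = cfg.burnin_years
        for year in range(total):
            # parentage/truth are emitted for follow-up seasons too, so the
            # offspring that cohort birds produce at ages 1-3 are recorded;
            # the analysis sample itself is the cohort window (cohort_ids)
            emit = year >= first_cohort
            self.breed(year, emit=emit)
            if year >= first_cohort:
                self.record_states(year)
            self.survive_and_promote(year)
        return self._collect()

    def _collect(self) -> SyntheticDataset:
        individuals = pd.DataFrame(
            [
                (b.id, b.sex, b.cohort, b.immigrant)
                for b in self.birds.values()
            ],
            columns=["id", "sex", "cohort_year", "immigrant"],
        )
        states = pd.DataFrame(
            self.state_rows, columns=["id", "year", "stage", "sex", "alive"]
        )
        nests = pd.DataFrame(
            self.nest_rows,
            columns=[
                "nest",
                "year",
                "territory",
                "mother",
                "social_father",
                "brood_size",
                "helpers_female",
                "helpers_male",
                "predated",
                "fledged",
            ],
        )
        parentage = pd.DataFrame(
            self.parent_rows,
            columns=[
                "offspring",
                "year",
                "nest",
                "genetic_dam",
                "genetic_sire",
                "social_dam",
                "social_sire",
                "epp",
                "fledged",
            ],
        )
        measurements = pd.DataFrame(
            self.measure_rows, columns=["id", "nest", "year", "age", "tarsus", "mass"]
        )
        truth = pd.DataFrame(
            self.truth_rows,
            columns=[
                "offspring",
                "f_true",
                "k_social_true",
                "epp",
                "inbred_true",
                "f_threshold",
                "condition_delta",
                "first_year_survival_delta",
                "reproduction_multiplier",
            ],
        )
        ids = sorted(self.geno)
        genotypes = GenotypeTable(ids, self.loci, np.stack([self.geno[i] for i in ids]))
        return SyntheticDataset(
            config=self.cfg,
            individuals=individuals,
            states=states,
            nests=nests,
            parentage=parentage,
            measurements=measurements,
            truth=truth,
            genotypes=genotypes,
            pedigree=self.ped,
        )


def simulate_population(config: SimConfig) -> SyntheticDataset:
    """Run one seeded population simulation (see module docstring)."""
    return _Simulator(config).run()


def null_effects_config(**overrides) -> SimConfig:
    """Default study conditions with no injected inbreeding depression."""
    return replace(SimConfig(), **overrides)


def inbreeding_depression_config(fitness_reduction: float = 0.75, **overrides) -> SimConfig:
    """Study conditions with a threshold fitness cost of inbreeding.

    The cost is injected through first-year survival: every route to
    nonzero three-year fitness passes through surviving the first year, so
    multiplying inbred first-year survival by (1 - fitness_reduction)
    scales expected fitness of inbred offspring by the same factor.
    """
    base = SimConfig(**overrides)
    s_fy = base.survival_of(FLEDGLING, "female")
    eff = InbreedingEffects(
        f_threshold=0.10,
        condition_delta=-0.5,
        first_year_survival_delta=-fitness_reduction * s_fy,
        reproduction_multiplier=1.0,
    )
    return replace(base, inbreeding_effects=eff)
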