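"""Synthetic-population generator: determinism, Mendelian consistency,
EPP calibration, and pedigree ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from wrenfit.pedigree import Pedigree
from wrenfit.simdata import (
    ConfigurationError,
    InbreedingEffects,
    SimConfig,
    simulate_population,
    transmit_genotypes,
)


class TestConfigValidation:
    def test_zero_territories_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_territories=0).validate()

    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(nest_predation_rate=1.4).validate()

    def test_bad_frequency_vector_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(loci=(("L1", 2, (0.6, 0.3)),)).validate()

    def test_clutch_sizes_limited_to_1_to_3(self, small_dataset):
        assert set(small_dataset.nests["brood_size"]) <= {0, 1, 2, 3}

    def test_helper_counts_within_0_to_8(self, small_dataset):
        helpers = small_dataset.nests["helpers_female"] + small_dataset.nests["helpers_male"]
        assert helpers.between(0, 8).all()


class TestDeterminism:
    def test_same_seed_same_dataset(self, small_config):
        d1 = simulate_population(small_config)
        d2 = simulate_population(small_config)
        for attr in ("individuals", "states", "nests", "parentage", "truth"):
            pd.testing.assert_frame_equal(getattr(d1, attr), getattr(d2, attr))
        assert np.array_equal(d1.genotypes.alleles, d2.genotypes.alleles)

    def test_different_seed_differs(self, small_config, small_dataset):
        import dataclasses

        other = simulate_population(dataclasses.replace(small_config, seed=99))
        assert not np.array_equal(other.genotypes.alleles, small_dataset.genotypes.alleles)


class TestMendelianTransmission:
    def test_homozygous_parents_force_genotype(self):
        rng = np.random.default_rng(0)
        child = transmit_genotypes([[1, 1]], [[2, 2]], rng)
        assert sorted(child[0]) == [1, 2]

    def test_heterozygous_cross_ratio_1_2_1(self):
        rng = np.random.default_rng(1)
        n = 4000
        counts = {0: 0, 1: 0, 2: 0}  # number of '2' alleles
        for _ in range(n):
            child = transmit_genotypes([[1, 2]], [[1, 2]], rng)[0]
            counts[int((child == 2).sum())] += 1
        stat, p = chisquare([counts[0], counts[1], counts[2]], [n / 4, n / 2, n / 4])
        assert p > 1e-4

    def test_four_allele_cross_uniform_over_four_genotypes(self):
        rng = np.random.default_rng(2)
        seen = {(1, 3): 0, (1, 4): 0, (2, 3): 0, (2, 4): 0}
        n = 4000
        for _ in range(n):
            child = transmit_genotypes([[1, 2]], [[3, 4]], rng)[0]
            seen[tuple(sorted(child))] += 1
        stat, p = chisquare(list(seen.values()))
        assert p > 1e-4

    def test_missing_parent_locus_gives_missing_offspring(self):
        rng = np.random.default_rng(3)
        child = transmit_genotypes([[0, 0], [1, 2]], [[3, 4], [3, 4]], rng)
        assert tuple(child[0]) == (0, 0)
        assert child[1].min() > 0

    def test_all_simulated_offspring_mendelian_consistent(self, small_dataset):
        ds = small_dataset
        gt = ds.genotypes
        for row in ds.parentage.itertuples():
            kid = gt.genotype(row.offspring)
            dam = gt.genotype(row.genetic_dam)
            sire = gt.genotype(row.genetic_sire)
            for L in range(kid.shape[0]):
                a, b = kid[L]
                ok = (a in dam[L] and b in sire[L]) or (b in dam[L] and a in sire[L])
                assert ok, f"offspring {row.offspring} locus {L} not Mendelian"


@pytest.fixture(scope="module")
def flat_epp_dataset():
    # ~5000 offspring, kin multiplier 1: realized EPP must sit within
    # the 3-SE binomial band around the configured 0.58
    cfg = SimConfig(
        n_territories=150, n_years=18, burnin_years=3, followup_years=0,
        epp_kin_multiplier=1.0, seed=7,
    )
    return simulate_population(cfg)


class TestEppStructure:

    def test_realized_epp_within_band(self, flat_epp_dataset):
        n = len(flat_epp_dataset.parentage)
        assert n > 3000
        se = np.sqrt(0.58 * 0.42 / n)
        assert abs(flat_epp_dataset.realized_epp_rate() - 0.58) < 3 * se

    def test_epp_flag_iff_sires_differ(self, small_dataset):
        par = small_dataset.parentage
        assert (par["epp"] == (par["genetic_sire"] != par["social_sire"])).all()

    def test_epp_monotone_in_social_pair_kinship(self):
        cfg = SimConfig(n_territories=80, n_years=10, burnin_years=4, seed=21)
        tr = simulate_population(cfg).truth
        rates = []
        for lo, hi in [(-0.01, 0.04), (0.04, 0.16), (0.16, 0.5)]:
            sel = (tr["k_social_true"] > lo) & (tr["k_social_true"] <= hi)
            if sel.sum() >= 20:
                rates.append(tr.loc[sel, "epp"].mean())
        assert len(rates) >= 2
        assert all(a <= b + 1e-9 for a, b in zip(rates, rates[1:]))

    def test_ep_sires_are_dominants_of_other_groups(self, small_dataset):
        ds = small_dataset
        nests = ds.nests.set_index("nest")
        epo = ds.parentage[ds.parentage["epp"]]
        assert (epo["genetic_sire"] != epo["social_sire"]).all()


class TestGroundTruth:
    def test_truth_f_equals_pedigree_kinship_of_parents(self, small_dataset):
        ds = small_dataset
        for row in ds.truth.sample(50, random_state=0).itertuples():
            par = ds.parentage.set_index("offspring").loc[row.offspring]
            f = ds.pedigree.kinship(par["genetic_dam"], par["genetic_sire"])
            assert row.f_true == pytest.approx(f)

    def test_fullsib_wpo_f_quarter_epo_unrelated_zero(self):
        # canonical oracle: WPO of a full-sib pair have f = 0.25; EPO sired
        # by an unrelated male have f = 0
        ped = Pedigree()
        ped.add("gm"), ped.add("gp"), ped.add("stranger")
        ped.add("sis", "gm", "gp")
        ped.add("bro", "gm", "gp")
        ped.add("wpo", "sis", "bro")
        ped.add("epo", "sis", "stranger")
        assert ped.inbreeding("wpo") == pytest.approx(0.25)
        assert ped.inbreeding("epo") == 0.0
        assert ped.relatedness("sis", "bro") == pytest.approx(0.5)

    def test_null_effects_leave_inbred_fitness_unchanged(self):
        # with all inbreeding effects off, inbred and non-inbred offspring
        # fledge-survival should differ only by Monte-Carlo error
        cfg = SimConfig(n_territories=80, n_years=12, burnin_years=4, seed=13)
        ds = simulate_population(cfg)
        par = ds.parentage.set_index("offspring")
        tr = ds.truth.set_index("offspring")
        alive = {(r.id, r.year) for r in ds.states.itertuples()}
        fledged = par[par["fledged"].astype(bool)]
        surv = pd.Series(
            {i: ((i, par.loc[i, "year"] + 1) in alive) for i in fledged.index}
        )
        inb = tr.loc[fledged.index, "inbred_true"].astype(bool).values
        if inb.sum() >= 25:
            p1, p0 = surv[inb].mean(), surv[~inb].mean()
            se = np.sqrt(p0 * (1 - p0) * (1 / inb.sum() + 1 / (~inb).sum()))
            assert abs(p1 - p0) < 3.5 * se

    def test_injected_survival_effect_realised(self):
        eff = InbreedingEffects(f_threshold=0.10, first_year_survival_delta=-0.3375)
        cfg = SimConfig(n_territories=80, n_years=12, burnin_years=4, seed=13,
                        inbreeding_effects=eff)
        ds = simulate_population(cfg)
        par = ds.parentage.set_index("offspring")
        tr = ds.truth.set_index("offspring")
        alive = {(r.id, r.year) for r in ds.states.itertuples()}
        fledged = par[par["fledged"].astype(bool)]
        surv = pd.Series(
            {i: ((i, par.loc[i, "year"] + 1) in alive) for i in fledged.index}
        )
        inb = tr.loc[fledged.index, "inbred_true"].astype(bool).values
        assert surv[inb].mean() < 0.6 * surv[~inb].mean()
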