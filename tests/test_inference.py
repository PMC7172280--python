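"""Hurdle model, AICc selection machinery, Wilcoxon, and paired tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrenfit.inference import (
    ModelSpec,
    aicc,
    all_subset_selection,
    fit_hurdle,
    paired_halfsib_table,
    wilcoxon_paired,
)


def _hurdle_data(rng, n=400, zero_beta=0.0, pos_beta=0.0):
    """Hurdle-world data: logistic zero process + Gaussian positive part."""
    g = rng.integers(0, 40, n)
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-0.5 + zero_beta * x)))
    pos = rng.random(n) < p
    y = np.where(pos, np.abs(1.0 + pos_beta * x + rng.normal(0, 0.5, n)) + 0.05, 0.0)
    return pd.DataFrame({"W": y, "x": x, "mother": g, "nest": g * 10 + rng.integers(0, 3, n)})


class TestAicc:
    def test_formula_arithmetic(self):
        # -2(-200) + 2*5 + 2*5*6/(100-5-1) = 410.63829787...
        assert aicc(-200.0, 5, 100) == pytest.approx(410.63829787234, rel=1e-10)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)

    def test_zero_parameters_no_correction(self):
        assert aicc(-10.0, 0, 5) == pytest.approx(20.0)

    def test_correction_positive_for_finite_n(self):
        assert aicc(-10.0, 2, 30) > -2 * -10.0 + 2 * 2

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestHurdle:
    def test_joint_loglik_is_exact_sum_of_parts(self):
        rng = np.random.default_rng(0)
        data = _hurdle_data(rng)
        fit = fit_hurdle(data, ModelSpec("W", "hurdle", ("x",), ("mother",)))
        assert fit.loglik == fit.binary.loglik + fit.positive.loglik
        assert fit.k == fit.binary.k + fit.positive.k

    def test_all_positive_response_rejected(self):
        rng = np.random.default_rng(1)
        data = _hurdle_data(rng)
        data["W"] = data["W"] + 1.0
        with pytest.raises(ValueError, match="no zeros"):
            fit_hurdle(data, ModelSpec("W", "hurdle", ("x",)))

    def test_too_few_positive_rows_refused(self):
        rng = np.random.default_rng(2)
        data = _hurdle_data(rng, n=60)
        data.loc[data.index[8:], "W"] = 0.0
        with pytest.raises(ValueError, match="positive rows"):
            fit_hurdle(data, ModelSpec("W", "hurdle", ("x",)))

    def test_effect_only_on_zero_probability_lands_in_part_one(self):
        # covariate drives only whether fitness is nonzero: part 1 detects
        # it, part 2 stays near null (type-I control on the magnitude part)
        rng = np.random.default_rng(3)
        data = _hurdle_data(rng, n=1500, zero_beta=1.0, pos_beta=0.0)
        fit = fit_hurdle(data, ModelSpec("W", "hurdle", ("x",), ("mother",)))
        b1 = fit.binary.beta[fit.binary.beta_names.index("x")]
        b2 = fit.positive.beta[fit.positive.beta_names.index("x")]
        assert b1 > 0.5
        assert abs(b2) < 0.15


class TestAllSubsetSelection:
    def test_enumerates_all_subsets(self):
        rng = np.random.default_rng(4)
        data = _hurdle_data(rng, n=300)
        data["z"] = rng.normal(size=len(data))
        base = ModelSpec("W", "hurdle", (), ("mother",))
        sel = all_subset_selection(data, base, ["x", "z"])
        assert len(sel.table) == 4

    def test_exclusive_forms_never_cooccur(self):
        rng = np.random.default_rng(5)
        data = _hurdle_data(rng, n=300)
        data["x_thresh"] = (data["x"] > 0).astype(float)
        base = ModelSpec("W", "hurdle", (), ("mother",))
        sel = all_subset_selection(data, base, ["x", "x_thresh"], [("x", "x_thresh")])
        assert len(sel.table) == 3  # null, linear, threshold
        for terms in sel.table["terms"]:
            assert not ({"x", "x_thresh"} <= set(terms))

    def test_weights_sum_to_one_and_best_delta_zero(self):
        rng = np.random.default_rng(6)
        data = _hurdle_data(rng, n=300)
        sel = all_subset_selection(data, ModelSpec("W", "hurdle", (), ("mother",)), ["x"])
        assert sel.table["weight"].sum() == pytest.approx(1.0)
        assert sel.table["delta"].iloc[0] == 0.0
        assert sel.table["aicc"].is_monotonic_increasing

    def test_true_threshold_beats_linear_form(self):
        # when the generating effect is a step, the threshold predictor
        # should win the AICc comparison in most replicates
        rng = np.random.default_rng(7)
        wins = 0
        reps = 12
        for _ in range(reps):
            n = 500
            x = rng.normal(size=n)
            flag = (x > 1.0).astype(float)
            p = 1 / (1 + np.exp(-(0.0 - 2.0 * flag)))
            pos = rng.random(n) < p
            y = np.where(pos, np.abs(rng.normal(1, 0.4, n)) + 0.05, 0.0)
            data = pd.DataFrame(
                {"W": y, "x": x, "flag": flag, "mother": rng.integers(0, 50, n)}
            )
            base = ModelSpec("W", "hurdle", (), ("mother",))
            sel = all_subset_selection(data, base, ["x", "flag"], [("x", "flag")])
            tab = sel.table.set_index("terms")
            if tab.loc[[("flag",)], "aicc"].iloc[0] < tab.loc[[("x",)], "aicc"].iloc[0]:
                wins += 1
        assert wins >= 0.75 * reps


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0 and res.n_used == 0

    def test_three_pair_exact_one_sided(self):
        # all three differences negative: V = 0, one-sided p = 1/8
        res = wilcoxon_paired([1, 2, 3], [2, 4, 6], alternative="less")
        assert res.V == 0.0
        assert res.p == pytest.approx(0.125)

    def test_exact_matches_full_sign_enumeration(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        res = wilcoxon_paired(a, b)
        d = a - b
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        total = 0
        count_le = 0
        count_ge = 0
        v_obs = ranks[d > 0].sum()
        for signs in itertools.product([0, 1], repeat=15):
            v = ranks[np.array(signs, dtype=bool)].sum()
            total += 1
            count_le += v <= v_obs
            count_ge += v >= v_obs
        p_exact = min(1.0, 2.0 * min(count_le / total, count_ge / total))
        assert res.method == "exact"
        assert res.p == pytest.approx(p_exact, rel=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_exact_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ours = wilcoxon_paired(a, b)
        ref = scipy_wilcoxon(a, b, zero_method="wilcox", method="exact")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_with_ties(self):
        a = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        b = a - np.array([1.0, 1, 1, 1, -1, -1, 2, 2])  # tied |differences|
        res = wilcoxon_paired(a, b)
        assert res.method == "normal"
        assert 0.0 < res.p <= 1.0


class TestPairedHalfsibs:
    def _offspring(self):
        return pd.DataFrame(
            {
                "id": list("abcdefg"),
                "nest": [1, 1, 2, 2, 2, 3, 3],
                "epp": [1, 0, 1, 1, 0, 0, 0],
                "W": [0.1, 0.2, 0.0, 0.3, 0.4, 0.5, 0.6],
            }
        )

    def test_one_pair_per_mixed_brood(self):
        tab = paired_halfsib_table(self._offspring(), ["W"], seed=0)
        assert set(tab["nest"]) == {1, 2}  # nest 3 is all-WPO, excluded
        row1 = tab.set_index("nest").loc[1]
        assert row1["epo_id"] == "a" and row1["wpo_id"] == "b"

    def test_random_choice_is_seeded(self):
        t1 = paired_halfsib_table(self._offspring(), ["W"], seed=42)
        t2 = paired_halfsib_table(self._offspring(), ["W"], seed=42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_no_mixed_broods_warns_empty(self):
        df = self._offspring()
        df["epp"] = 0
        with pytest.warns(UserWarning, match="no mixed"):
            tab = paired_halfsib_table(df, ["W"], seed=0)
        assert tab.empty
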