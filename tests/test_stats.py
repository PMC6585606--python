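"""Tests for the behavioral-statistics layer, with brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from limbselect import (
    chi_squared,
    classify_handedness,
    generate_fixture_cohort,
    mcnemar,
    proportion_table,
    to_preferred_frame,
)


def pearson_chi2_oracle(table):
    """Textbook Pearson statistic, computed cell by cell from marginals."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = rows[i] * cols[j] / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat, (table.shape[0] - 1) * (table.shape[1] - 1)


def exact_mcnemar_oracle(b, c):
    """Doubled binomial tail by direct summation over discordant pairs."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(n, j) * 0.5 ** n for j in range(k + 1))
    return min(1.0, 2.0 * tail)


class TestClassifyHandedness:
    @pytest.mark.parametrize(
        "selections, expected",
        [
            (["right", "right", "left"], "right"),
            (["left", "left", "left"], "left"),
            (["left", "right", "both"], "undetermined"),
            (["both", "both"], "undetermined"),
            (["left", "both", "both"], "left"),  # 'both' counts toward neither
        ],
    )
    def test_majority_rule(self, selections, expected):
        assert classify_handedness(selections) == expected

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            classify_handedness([])
        with pytest.raises(ValueError):
            classify_handedness(["right", "foot"])


class TestPreferredFrame:
    def records(self):
        return pd.DataFrame(
            {
                "participant": [1, 1, 2, 2],
                "age_group": ["14mo"] * 4,
                "condition": ["control", "test"] * 2,
                "trial": ["N1", "N1"] * 2,
                "hand": ["right", "left", "right", "both"],
                "handedness": ["right", "right", "left", "left"],
            }
        )

    def test_mapping_through_handedness(self):
        out = to_preferred_frame(self.records())
        assert list(out.hand) == ["P", "NP", "NP", "both"]

    def test_unknown_handedness_listed(self):
        df = self.records()
        df.loc[df.participant == 2, "handedness"] = "unknown"
        with pytest.raises(ValueError, match=r"\[2\]"):
            to_preferred_frame(df)

    def test_frame_invariance_across_handedness_mix(self):
        """All-preferred use maps to proportion 1.0 regardless of the
        left/right-hander mix."""
        recs = generate_fixture_cohort(
            20, {(c, t): 1.0 for c in ("control", "test")
                 for t in ("T1", "T2", "T3", "T4", "N1", "N2")},
            seed=5, p_right_handed=0.5)
        table = proportion_table(to_preferred_frame(recs),
                                 groupby=("condition",))
        assert (table.prop_preferred == 1.0).all()

    @given(st.integers(min_value=0, max_value=2 ** 20))
    @settings(deadline=None, max_examples=30)
    def test_transform_inverts_under_handedness_flip(self, seed):
        """Mapping left/right -> P/NP and back through each participant's
        handedness restores the original labels exactly."""
        recs = generate_fixture_cohort(6, {}, seed=seed)
        pref = to_preferred_frame(recs)
        hand_map = recs.drop_duplicates("participant").set_index(
            "participant")["handedness"].to_dict()
        restored = pref.copy()
        dom = restored["participant"].map(hand_map)
        nondom = dom.map({"left": "right", "right": "left"})
        restored["hand"] = np.select(
            [pref["hand"] == "P", pref["hand"] == "NP"],
            [dom, nondom], default="both")
        pd.testing.assert_frame_equal(restored, recs)


class TestChiSquared:
    def test_uniform_goodness_of_fit(self):
        stat, df, p = chi_squared([[25, 25]])
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        stat, df, _ = chi_squared([[10, 20], [20, 10]], corrected=False)
        assert stat == pytest.approx(20.0 / 3.0, rel=1e-6)
        assert df == 1

    def test_3x2_against_oracle(self):
        table = [[30, 12], [37, 1], [52, 0]]
        stat, df, _ = chi_squared(table)
        want, want_df = pearson_chi2_oracle(table)
        assert df == want_df == 2
        assert stat == pytest.approx(want, rel=1e-9)

    @given(
        st.lists(
            st.lists(st.integers(min_value=1, max_value=30),
                     min_size=2, max_size=3),
            min_size=2, max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_on_random_tables(self, rows):
        stat, df, _ = chi_squared(rows, corrected=False)
        want, want_df = pearson_chi2_oracle(rows)
        assert df == want_df
        assert stat == pytest.approx(want, rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [3, 4]])


class TestMcNemar:
    def test_hand_computed_exact(self):
        # b=5 discordant one way, c=0 the other: p = 2 * 0.5^5
        pairs = [(1, 0)] * 5 + [(1, 1)] * 10
        res = mcnemar(pairs)
        assert (res["b"], res["c"]) == (5, 0)
        assert res["p"] == pytest.approx(0.0625)

    def test_symmetric_and_degenerate(self):
        assert mcnemar([(1, 0), (0, 1)])["p"] == pytest.approx(1.0)
        assert mcnemar([(1, 1), (0, 0)])["p"] == 1.0

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 10))
    @settings(deadline=None, max_examples=60)
    def test_exact_matches_binomial_summation(self, b, c, concordant):
        pairs = [(1, 0)] * b + [(0, 1)] * c + [(1, 1)] * concordant
        if not pairs:
            pairs = [(1, 1)]
            b = c = 0
        res = mcnemar(pairs)
        assert res["p"] == pytest.approx(exact_mcnemar_oracle(b, c), rel=1e-9)

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(0)
        for _ in range(20):
            pairs = rng.integers(0, 2, size=(25, 2))
            res = mcnemar(pairs)
            table = [
                [np.sum((pairs[:, 0] == 1) & (pairs[:, 1] == 1)), res["b"]],
                [res["c"], np.sum((pairs[:, 0] == 0) & (pairs[:, 1] == 0))],
            ]
            want = sm_mcnemar(table, exact=True).pvalue
            assert res["p"] == pytest.approx(float(want), rel=1e-9)

    def test_chi2_approximation_mode(self):
        res = mcnemar([(1, 0)] * 30 + [(0, 1)] * 10, exact=False)
        assert res["statistic"] == pytest.approx((30 - 10) ** 2 / 40)
        assert res["method"] == "chi2"

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            mcnemar([])


class TestProportionTable:
    def test_bernoulli_half(self):
        recs = to_preferred_frame(generate_fixture_cohort(800, {}, seed=11))
        table = proportion_table(recs, groupby=("condition",))
        # 800 participants x 6 trials per condition; 3 SE band around 0.5
        se = 0.5 / np.sqrt(4800)
        assert table.prop_preferred.between(0.5 - 3 * se, 0.5 + 3 * se).all()

    def test_both_excluded_and_flagged(self):
        recs = pd.DataFrame(
            {
                "participant": [1, 2, 3, 4],
                "age_group": ["g"] * 4,
                "condition": ["control"] * 4,
                "trial": ["N1"] * 4,
                "hand": ["P", "P", "NP", "both"],
                "handedness": ["right"] * 4,
            }
        )
        table = proportion_table(recs, groupby=("trial",))
        assert table.n.iloc[0] == 3
        assert table.n_both.iloc[0] == 1
        assert table.prop_preferred.iloc[0] == pytest.approx(2 / 3)

    def test_requires_preferred_frame(self):
        recs = pd.DataFrame(
            {"participant": [1], "age_group": ["g"], "condition": ["control"],
             "trial": ["N1"], "hand": ["left"], "handedness": ["right"]}
        )
        with pytest.raises(ValueError):
            proportion_table(recs)


class TestFixtureCohort:
    def test_deterministic_probabilities(self):
        probs = {("control", t): 1.0 for t in ("T1", "T2", "T3", "T4", "N1", "N2")}
        probs.update({("test", t): 0.0 for t in ("T1", "T2", "T3", "T4", "N1", "N2")})
        recs = to_preferred_frame(generate_fixture_cohort(15, probs, seed=2))
        ctrl = recs[recs.condition == "control"]
        test = recs[recs.condition == "test"]
        assert (ctrl.hand == "P").all()
        assert (test.hand == "NP").all()

    def test_reproducible_from_seed(self):
        a = generate_fixture_cohort(10, {}, seed=8)
        b = generate_fixture_cohort(10, {}, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            generate_fixture_cohort(5, {("control", "N1"): 1.5}, seed=0)

    def test_mcnemar_power_on_subgroup_sized_fixture(self):
        """A fixture mirroring the filtered youngest subgroup (control N1
        always preferred, test N1 preferred with p=0.57) yields a
        significant McNemar test in most replicates at n=20."""
        probs = {("control", "N1"): 1.0, ("test", "N1"): 0.57}
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            recs = to_preferred_frame(generate_fixture_cohort(20, probs, seed=seed))
            n1 = recs[recs.trial == "N1"]
            wide = n1.pivot(index="participant", columns="condition", values="hand")
            pairs = [(row["control"] == "P", row["test"] == "P")
                     for _, row in wide.iterrows()]
            if mcnemar(pairs)["p"] < 0.05 :
                rejections += 1
        # analytic power: P(Binom(20, 0.43) >= 6) ~ 0.87
        assert rejections / n_rep > 0.7
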