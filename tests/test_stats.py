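"""ANOVA decompositions, Fisher's LSD, compact letter display."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import vasculometry as vm
from vasculometry.stats import _compact_letters


def _balanced_2x2():
    """Cell means 10 + alpha_i + beta_j (alpha = -1/+1, beta = -2/+2),
    replicates at cell mean +-1: SS_A = 8, SS_B = 32, SS_AB = 0, SS_err = 8."""
    rows = []
    for ai, al in zip(["a1", "a2"], [-1, 1]):
        for bi, be in zip(["b1", "b2"], [-2, 2]):
            for r in (-1, 1):
                rows.append({"A": ai, "B": bi, "y": 10 + al + be + r})
    return pd.DataFrame(rows)


class TestAnova:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"y": rng.standard_normal(12) + np.repeat([0, 1], 6),
             "g": np.repeat(["A", "B"], 6)}
        )
        res = vm.anova(df, "y", ["g"])
        t, p_t = sps.ttest_ind(df[df.g == "A"].y, df[df.g == "B"].y)
        assert res.effects.loc["g", "F"] == pytest.approx(t**2, rel=1e-10)
        assert res.effects.loc["g", "p"] == pytest.approx(p_t, rel=1e-10)

    def test_balanced_2x2_hand_computation(self):
        res = vm.anova(_balanced_2x2(), "y", ["A", "B"], interaction=True)
        assert res.effects.loc["A", "sum_sq"] == pytest.approx(8.0, abs=1e-9)
        assert res.effects.loc["B", "sum_sq"] == pytest.approx(32.0, abs=1e-9)
        assert res.effects.loc["A x B", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert res.mse == pytest.approx(2.0)
        assert res.df_error == 4
        # components sum to total SS in the balanced design
        total = ((res.data["y"] - res.data["y"].mean()) ** 2).sum()
        parts = res.effects["sum_sq"].sum() + res.mse * res.df_error
        assert parts == pytest.approx(total, rel=1e-12)

    def test_one_way_matches_reference_implementation(self):
        """F and p identical to scipy.stats.f_oneway on balanced data."""
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"y": rng.standard_normal(30) + np.repeat([0, 0.5, 1.2], 10),
             "g": np.repeat(list("XYZ"), 10)}
        )
        res = vm.anova(df, "y", ["g"])
        F, p = sps.f_oneway(*[df[df.g == g].y for g in "XYZ"])
        assert res.effects.loc["g", "F"] == pytest.approx(F, abs=1e-10)
        assert res.effects.loc["g", "p"] == pytest.approx(p, abs=1e-10)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"y": rng.standard_normal(18), "g": np.repeat(list("PQR"), 6)}
        )
        res1 = vm.anova(df, "y", ["g"])
        relabel = {"P": "R", "Q": "P", "R": "Q"}
        df2 = df.assign(g=df.g.map(relabel))
        res2 = vm.anova(df2, "y", ["g"])
        assert res1.effects.loc["g", "F"] == pytest.approx(
            res2.effects.loc["g", "F"], rel=1e-12
        )
        # row order is irrelevant too
        res3 = vm.anova(df.sample(frac=1, random_state=0), "y", ["g"])
        assert res1.effects.loc["g", "F"] == pytest.approx(
            res3.effects.loc["g", "F"], rel=1e-12
        )

    def test_unbalanced_two_way_runs_with_both_ss_types(self):
        rng = np.random.default_rng(5)
        rows = []
        for c in ["cv1", "cv2", "cv3"]:
            for p in ["receptacle", "brush"]:
                n = 3 if (c == "cv1" and p == "brush") else 4
                for _ in range(n):
                    rows.append({"c": c, "p": p, "y": rng.standard_normal()})
        df = pd.DataFrame(rows)
        r3 = vm.anova(df, "y", ["c", "p"], interaction=True, ss_type=3)
        r2 = vm.anova(df, "y", ["c", "p"], interaction=True, ss_type=2)
        assert set(r3.effects.index) == {"c", "p", "c x p"}
        assert r3.df_error == r2.df_error == len(df) - 6

    def test_design_errors(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["A", "A"]})
        with pytest.raises(ValueError):
            vm.anova(df, "y", ["g"])
        with pytest.raises(ValueError):
            vm.anova(df, "y", ["g"], interaction=True)


class TestFisherLsd:
    def test_two_group_p_equals_omnibus(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"y": rng.standard_normal(10), "g": np.repeat(["A", "B"], 5)}
        )
        res = vm.anova(df, "y", ["g"])
        lsd = vm.fisher_lsd(res, "g", require_significant=False)
        assert lsd.pairwise["p"].iloc[0] == pytest.approx(
            res.p_value("g"), rel=1e-12
        )

    def test_letters_for_one_shifted_group(self):
        df = pd.DataFrame(
            {"y": [1, 1.01, 0.99, 1.02, 1.0, 0.98, 5, 5.01, 4.99],
             "g": np.repeat(["g1", "g2", "g3"], 3)}
        )
        res = vm.anova(df, "y", ["g"])
        lsd = vm.fisher_lsd(res, "g")
        assert lsd.letters == {"g1": "a", "g2": "a", "g3": "b"}

    def test_gate_refuses_nonsignificant_omnibus(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame(
            {"y": rng.standard_normal(12), "g": np.repeat(list("ABC"), 4)}
        )
        res = vm.anova(df, "y", ["g"])
        assert res.p_value("g") > 0.05
        with pytest.raises(ValueError, match="omnibus"):
            vm.fisher_lsd(res, "g")
        # override runs
        lsd = vm.fisher_lsd(res, "g", require_significant=False)
        assert len(lsd.pairwise) == 3

    def test_pair_order_symmetry(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {"y": rng.standard_normal(12) + np.repeat([0, 2, 4], 4),
             "g": np.repeat(list("ABC"), 4)}
        )
        res = vm.anova(df, "y", ["g"])
        lsd = vm.fisher_lsd(res, "g", require_significant=False)
        pw = lsd.pairwise.set_index(["group_1", "group_2"])
        # every unordered pair appears once; diff antisymmetry is internal
        assert len(pw) == 3
        assert set(pw.index) == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_null_calibration_per_pair(self):
        """Unadjusted LSD per-pair type-I error is ~alpha under the null."""
        rej = {("A", "B"): 0, ("A", "C"): 0, ("B", "C"): 0}
        n_sims = 400
        for s in range(n_sims):
            rng = np.random.default_rng(50_000 + s)
            df = pd.DataFrame(
                {"y": rng.standard_normal(12), "g": np.repeat(list("ABC"), 4)}
            )
            res = vm.anova(df, "y", ["g"])
            lsd = vm.fisher_lsd(res, "g", require_significant=False)
            for r in lsd.pairwise.itertuples(index=False):
                if r.significant:
                    rej[(r.group_1, r.group_2)] += 1
        se = np.sqrt(0.05 * 0.95 / n_sims)
        for pair, count in rej.items():
            assert abs(count / n_sims - 0.05) < 3 * se, pair


class TestTukey:
    def test_tukey_more_conservative_than_lsd(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {"y": rng.standard_normal(15) + np.repeat([0, 0.8, 1.6], 5),
             "g": np.repeat(list("ABC"), 5)}
        )
        res = vm.anova(df, "y", ["g"])
        lsd = vm.fisher_lsd(res, "g", require_significant=False)
        hsd = vm.tukey_hsd(res, "g")
        merged = lsd.pairwise.merge(
            hsd.pairwise, on=["group_1", "group_2"], suffixes=("_lsd", "_hsd")
        )
        assert (merged["p_hsd"] >= merged["p_lsd"] - 1e-12).all()

    def test_tukey_matches_scipy(self):
        """Balanced one-way Tukey p-values agree with scipy.stats.tukey_hsd."""
        rng = np.random.default_rng(11)
        groups = [rng.standard_normal(6) + mu for mu in (0, 1, 2)]
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat(list("ABC"), 6)}
        )
        res = vm.anova(df, "y", ["g"])
        mine = vm.tukey_hsd(res, "g").pairwise.set_index(["group_1", "group_2"])
        ref = sps.tukey_hsd(*groups)
        for (i, gi), (j, gj) in [((0, "A"), (1, "B")), ((0, "A"), (2, "C")), ((1, "B"), (2, "C"))]:
            assert mine.loc[(gi, gj), "p"] == pytest.approx(
                ref.pvalue[i, j], abs=1e-9
            )


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        letters = _compact_letters(["x", "y", "z"], set())
        assert set(letters.values()) == {"a"}

    def test_all_different_distinct_letters(self):
        letters = _compact_letters(
            ["x", "y", "z"], {("x", "y"), ("x", "z"), ("y", "z")}
        )
        assert len(set(letters.values())) == 3

    def test_chain_structure(self):
        # x != z, but y bridges both
        letters = _compact_letters(["x", "y", "z"], {("x", "z")})
        assert letters["x"] != letters["z"]
        assert set(letters["y"]) == set(letters["x"] + letters["z"])

    def test_deterministic(self):
        diff = {("a", "c"), ("b", "d")}
        l1 = _compact_letters(["a", "b", "c", "d"], diff)
        l2 = _compact_letters(["a", "b", "c", "d"], diff)
        assert l1 == l2
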