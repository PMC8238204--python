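"""Cox screening, survival forests, C-index, repeated holdout, comparisons."""

import numpy as np
import pandas as pd
import pytest

from prer.survival import (
    ModelResult,
    SplitScheme,
    SurvivalData,
    compare_representations,
    concordance_index,
    cox_univariate_filter,
    fit_survival_forest,
    repeated_holdout,
    univariate_cox_table,
)

from conftest import random_survival


def brute_force_cindex(risk, time, event):
    """Independent oracle: enumerate all pairs, Harrell's definition."""
    num = den = 0.0
    n = len(risk)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            if time[a] < time[b] and event[a]:
                den += 1
                if risk[a] > risk[b]:
                    num += 1
                elif risk[a] == risk[b]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestSurvivalData:
    def test_validation(self):
        with pytest.raises(ValueError):
            SurvivalData([1.0, -1.0], [1, 0])
        with pytest.raises(ValueError):
            SurvivalData([1.0, 2.0], [1])

    def test_subset(self):
        sd = SurvivalData([1.0, 2.0, 3.0], [1, 0, 1], ["a", "b", "c"])
        sub = sd.subset(np.array([2, 0]))
        assert sub.time.tolist() == [3.0, 1.0] and sub.n_events == 2


class TestConcordanceIndex:
    def test_perfect_reversal(self):
        sd = SurvivalData([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index(np.array([4, 3, 2, 1]), sd) == 1.0

    def test_all_equal_risks(self):
        sd = SurvivalData([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index(np.zeros(4), sd) == 0.5

    def test_hand_enumerated_censored_example(self):
        # times (1,2,3,4), events (1,1,0,1), risks (4,3,2,1):
        # comparable pairs (1,2),(1,3),(1,4),(2,3),(2,4) all concordant -> 1.0
        sd = SurvivalData([1, 2, 3, 4], [1, 1, 0, 1])
        risk = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance_index(risk, sd) == brute_force_cindex(
            risk, sd.time, sd.event
        )

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(5, 30))
            sd = random_survival(rng, n)
            risk = rng.normal(size=n).round(1)  # rounding induces risk ties
            assert concordance_index(risk, sd) == pytest.approx(
                brute_force_cindex(risk, sd.time, sd.event)
            )

    def test_negation_complement_without_ties(self):
        rng = np.random.default_rng(11)
        sd = random_survival(rng, 40)
        risk = rng.normal(size=40)  # continuous -> no ties a.s.
        assert concordance_index(risk, sd) + concordance_index(-risk, sd) == pytest.approx(1.0)

    def test_no_comparable_pairs_errors(self):
        sd = SurvivalData([1.0, 2.0], [0, 0])
        with pytest.raises(Exception):
            concordance_index(np.array([1.0, 2.0]), sd)


class TestUnivariateCox:
    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(12)
        n = 80
        X = pd.DataFrame(
            {
                "cont": rng.normal(size=n),
                "bin": rng.choice([-1.0, 1.0], size=n),
                "weak": rng.normal(size=n) * 0.1,
            }
        )
        # outcome depends on 'cont' so coefficients are non-trivial
        t = np.random.default_rng(13).exponential(np.exp(-0.8 * X["cont"]))
        # duplicate a few times to create tied event times (Efron path)
        t = np.round(t, 1) + 1e-3
        e = np.random.default_rng(14).random(n) > 0.25
        sd = SurvivalData(t, e)
        ours = univariate_cox_table(X, sd)
        for col in X.columns:
            cph = CoxPHFitter()
            df = pd.DataFrame({"t": t, "e": e.astype(int), col: X[col]})
            cph.fit(df, duration_col="t", event_col="e")
            assert ours.loc[col, "coef"] == pytest.approx(
                cph.params_[col], rel=1e-4, abs=1e-6
            )
            assert ours.loc[col, "p"] == pytest.approx(
                cph.summary.loc[col, "p"], rel=1e-3, abs=1e-8
            )

    def test_constant_feature_excluded(self):
        rng = np.random.default_rng(15)
        sd = random_survival(rng, 50)
        X = pd.DataFrame({"flat": np.ones(50), "ok": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="degenerate"):
            retained = cox_univariate_filter(X, sd, alpha=1.0)
        assert retained == ["ok"]

    def test_alpha_one_retains_all_nondegenerate(self):
        rng = np.random.default_rng(16)
        sd = random_survival(rng, 60)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        assert cox_univariate_filter(X, sd, alpha=1.0) == list("abcd")

    def test_signal_feature_power(self):
        # hazard = exp(z), n=300, ~20% censoring: the signal feature should
        # pass the 0.05 screen in at least 95% of simulations
        hits = 0
        n_sim = 40
        for s in range(n_sim):
            rng = np.random.default_rng(100 + s)
            z = rng.normal(size=300)
            t = rng.exponential(np.exp(-z))
            c = rng.uniform(0, np.quantile(t, 0.97) * 2.5, size=300)
            sd = SurvivalData(np.minimum(t, c) + 1e-9, t <= c)
            X = pd.DataFrame({"z": z, "noise": rng.normal(size=300)})
            if "z" in cox_univariate_filter(X, sd, alpha=0.05):
                hits += 1
        assert hits / n_sim >= 0.95

    def test_empty_retention_instructs_fallback(self):
        rng = np.random.default_rng(17)
        sd = random_survival(rng, 40)
        X = pd.DataFrame({"n1": rng.normal(size=40)})
        with pytest.raises(ValueError, match="fall back"):
            cox_univariate_filter(X, sd, alpha=1e-12)


class TestSurvivalForest:
    def test_perfect_binary_separator_reaches_oracle_ceiling(self):
        # a single binary feature ties the risks within each group, so the
        # ceiling on Harrell's C is the C of the true group label itself;
        # the forest must get within 0.02 of that oracle ceiling
        rng = np.random.default_rng(18)
        n = 200
        z = rng.choice([-1.0, 1.0], size=n)
        t = rng.exponential(np.exp(-2.0 * z)) + 1e-9
        sd = SurvivalData(t, np.ones(n, dtype=bool))
        X = pd.DataFrame({"z": z})
        tr, te = np.arange(150), np.arange(150, n)
        model = fit_survival_forest(X.iloc[tr], sd.subset(tr), n_trees=100, seed=0)
        risk = model.predict(X.iloc[te].to_numpy())
        ceiling = concordance_index(z[te], sd.subset(te))
        assert concordance_index(risk, sd.subset(te)) >= ceiling - 0.02

    def test_continuous_perfect_predictor(self):
        # with a continuous, strongly prognostic feature the held-out C-index
        # clears 0.9
        rng = np.random.default_rng(28)
        n = 200
        z = rng.normal(size=n)
        t = np.exp(-z)  # survival strictly decreasing in the feature
        sd = SurvivalData(t, np.ones(n, dtype=bool))
        X = pd.DataFrame({"z": z})
        tr, te = np.arange(150), np.arange(150, n)
        model = fit_survival_forest(X.iloc[tr], sd.subset(tr), n_trees=100, seed=0)
        risk = model.predict(X.iloc[te].to_numpy())
        assert concordance_index(risk, sd.subset(te)) >= 0.9

    def test_pure_noise_near_half(self):
        rng = np.random.default_rng(19)
        cs = []
        for s in range(30):
            n = 120
            X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
            sd = random_survival(rng, n, censor=0.2)
            model = fit_survival_forest(X.iloc[:90], sd.subset(np.arange(90)),
                                        n_trees=50, seed=s)
            risk = model.predict(X.iloc[90:].to_numpy())
            cs.append(concordance_index(risk, sd.subset(np.arange(90, n))))
        assert abs(np.mean(cs) - 0.5) <= 0.05

    def test_determinism(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        sd = random_survival(rng, 60)
        m1 = fit_survival_forest(X, sd, n_trees=50, seed=7)
        m2 = fit_survival_forest(X, sd, n_trees=50, seed=7)
        np.testing.assert_array_equal(m1.predict(X.to_numpy()), m2.predict(X.to_numpy()))

    def test_all_censored_errors(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        sd = SurvivalData(np.arange(1.0, 11.0), np.zeros(10))
        with pytest.raises(ValueError):
            fit_survival_forest(X, sd)


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(21)
    n = 120
    z = rng.choice([-1.0, 1.0], size=n)
    X = pd.DataFrame({"z": z, "n1": rng.normal(size=n), "n2": rng.normal(size=n)})
    t = rng.exponential(np.exp(-1.2 * z)) + 1e-9
    e = rng.random(n) > 0.2
    return X, SurvivalData(t, e)


class TestRepeatedHoldout:
    def test_repeat_count(self, cohort):
        X, sd = cohort
        res = repeated_holdout(X, sd, SplitScheme(repeats=3, seed=5), n_trees=25)
        assert res.cindices.shape == (3,)
        assert np.all((res.cindices >= 0) & (res.cindices <= 1))

    def test_determinism(self, cohort):
        X, sd = cohort
        scheme = SplitScheme(repeats=3, seed=5)
        a = repeated_holdout(X, sd, scheme, n_trees=25)
        b = repeated_holdout(X, sd, scheme, n_trees=25)
        np.testing.assert_array_equal(a.cindices, b.cindices)

    def test_no_test_leakage_into_screen(self, cohort):
        # the retained feature lists must be computable from train data only:
        # shuffling test-fold outcomes must not change which features are kept
        X, sd = cohort
        scheme = SplitScheme(repeats=2, seed=9)
        base = repeated_holdout(X, sd, scheme, n_trees=25)
        seeds = scheme.split_seeds()
        from prer.survival import _draw_split

        for rep, ssd in enumerate(seeds):
            tr, te = _draw_split(sd.n, 0.8, ssd)
            shuffled = sd.time.copy()
            rng = np.random.default_rng(0)
            shuffled[te] = rng.permutation(shuffled[te])
            sd2 = SurvivalData(shuffled, sd.event)
            res2 = repeated_holdout(X, sd2, scheme, n_trees=25)
            assert res2.retained[rep] == base.retained[rep]

    def test_duplicated_columns_similar_mean(self, cohort):
        X, sd = cohort
        scheme = SplitScheme(repeats=20, seed=3)
        single = repeated_holdout(X[["z"]], sd, scheme, n_trees=50, cox_alpha=1.0)
        dup = pd.concat([X[["z"]]] * 2, axis=1)
        dup.columns = ["z", "z_copy"]
        doubled = repeated_holdout(dup, sd, scheme, n_trees=50, cox_alpha=1.0)
        assert abs(single.cindices.mean() - doubled.cindices.mean()) <= 0.02


class TestCompareRepresentations:
    def _result(self, name, cindices, scheme):
        return ModelResult(name=name, cindices=np.asarray(cindices, dtype=float),
                           retained=[], scheme=scheme)

    def test_identical_vectors_tie(self):
        scheme = SplitScheme(repeats=10, seed=0)
        c = np.linspace(0.5, 0.7, 10)
        rep = compare_representations(
            {"a": self._result("a", c, scheme), "b": self._result("b", c, scheme)}
        )
        assert rep.loc[0, "verdict"] == "tie" and rep.loc[0, "p_a_gt_b"] == 1.0

    def test_uniform_shift_wins(self):
        scheme = SplitScheme(repeats=100, seed=0)
        rng = np.random.default_rng(22)
        b = rng.uniform(0.5, 0.7, size=100)
        rep = compare_representations(
            {"a": self._result("a", b + 0.05, scheme), "b": self._result("b", b, scheme)}
        )
        assert rep.loc[0, "verdict"] == "win"
        assert rep.loc[0, "p_adj_a_gt_b"] < 0.05

    def test_bh_step_up_hand_example(self):
        # Benjamini-Hochberg on (0.01, 0.02, 0.03, 0.04), m = 4:
        # step-up gives 0.04 for every hypothesis
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_geq_raw(self):
        scheme = SplitScheme(repeats=30, seed=1)
        rng = np.random.default_rng(23)
        res = {
            k: self._result(k, rng.uniform(0.4, 0.8, 30), scheme) for k in "abc"
        }
        rep = compare_representations(res)
        assert (rep["p_adj_a_gt_b"] >= rep["p_a_gt_b"] - 1e-12).all()
        assert len(rep) == 3  # C(3,2) unordered pairs

    def test_unpaired_scheme_rejected(self):
        r1 = self._result("a", np.full(10, 0.6), SplitScheme(repeats=10, seed=0))
        r2 = self._result("b", np.full(10, 0.6), SplitScheme(repeats=10, seed=1))
        with pytest.raises(ValueError, match="shared split scheme"):
            compare_representations({"a": r1, "b": r2})
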