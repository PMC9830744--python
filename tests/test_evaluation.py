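import numpy as np
import pytest
from sksurv.metrics import concordance_index_censored

import survens as sv
from survens.evaluation import parse_aggregator, parse_threshold

from conftest import make_dataset


def brute_force_cindex(time, event, risk):
    conc, comp = 0.0, 0
    m = len(time)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            if (time[i] < time[j] and event[i] == 1) or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0
            ):
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc / comp


class TestConcordance:
    def test_perfect(self):
        assert sv.concordance_index([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0

    def test_hand_enumeration_with_censoring(self):
        assert sv.concordance_index([1, 2, 3], [1, 0, 1], [3, 1, 2]) == 1.0

    def test_all_tied_risks(self):
        assert sv.concordance_index([1, 2, 3], [1, 1, 1], [5, 5, 5]) == 0.5

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError, match="comparable"):
            sv.concordance_index([1, 2], [0, 1], [1, 2])

    def test_matches_brute_force_and_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = int(rng.integers(5, 30))
            time = np.round(rng.exponential(1, m), 2) + 0.01
            event = rng.integers(0, 2, m)
            if event.sum() == 0:
                event[0] = 1
            risk = np.round(rng.normal(size=m), 1)
            c = sv.concordance_index(time, event, risk)
            assert c == pytest.approx(brute_force_cindex(time, event, risk))
            ref = concordance_index_censored(event.astype(bool), time, risk)[0]
            # the library counts event-event time ties differently only
            # when they occur; rounded times make them possible, so allow
            # comparison on tie-free draws
            if len(np.unique(time)) == m:
                assert c == pytest.approx(ref)


class TestEuclideanScore:
    def test_values(self):
        assert sv.euclidean_score(0, 0) == 0
        assert sv.euclidean_score(0.6, 0.8) == pytest.approx(1.0)
        assert sv.euclidean_score(1, 1) == pytest.approx(np.sqrt(2))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sv.euclidean_score(np.nan, 0.5)


class TestRidgeCox:
    def test_true_linear_predictor_scores_high(self):
        rng = np.random.default_rng(1)
        m = 400
        x = rng.normal(size=m)
        t = rng.exponential(np.exp(-1.5 * x)) + 0.001
        ds = make_dataset({"x": ("continuous", x)}, t, np.ones(m))
        train, test = ds.subset_rows(range(200)), ds.subset_rows(range(200, 400))
        scorer = sv.fit_ridge_cox(train, {"x"})
        c = sv.concordance_index(test.time, test.event, scorer(test))
        truth_c = sv.concordance_index(test.time, test.event, test.features["x"])
        assert abs(c - truth_c) < 0.02

    def test_huge_penalty_gives_chance_concordance(self):
        rng = np.random.default_rng(2)
        m = 100
        x = rng.normal(size=m)
        t = rng.exponential(np.exp(-x)) + 0.001
        ds = make_dataset({"x": ("continuous", x)}, t, np.ones(m))
        scorer = sv.fit_ridge_cox(ds, {"x"}, alpha=1e9)
        risks = scorer(ds)
        assert np.ptp(risks) < 1e-4  # coefficients shrunk to ~0

    def test_duplicate_features_share_weight(self):
        rng = np.random.default_rng(3)
        m = 150
        x = rng.normal(size=m)
        t = rng.exponential(np.exp(-x)) + 0.001
        ds = make_dataset(
            {"a": ("continuous", x), "b": ("continuous", x.copy())}, t, np.ones(m)
        )
        from survens.datasets import design_matrix
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv

        model = CoxPHSurvivalAnalysis(alpha=1.0)
        X, _ = design_matrix(ds)
        model.fit(X, Surv.from_arrays(np.ones(m, bool), t))
        assert model.coef_[0] == pytest.approx(model.coef_[1], rel=1e-6)

    def test_empty_selection_rejected(self, tiny_ds):
        with pytest.raises(ValueError):
            sv.fit_ridge_cox(tiny_ds, set())


class TestIdentifierParsing:
    def test_aggregators(self):
        assert parse_aggregator("MR") == ("MR", None)
        assert parse_aggregator("RRA:0.15") == ("RRA", 0.15)
        assert parse_aggregator("RRA15") == ("RRA", 0.15)
        assert parse_aggregator("rra05") == ("RRA", 0.05)
        with pytest.raises(ValueError):
            parse_aggregator("median")

    def test_thresholds(self):
        assert parse_threshold(None) == (None, None)
        assert parse_threshold("fixed:0.25") == ("fixed", 0.25)
        assert parse_threshold("q75") == ("q75", None)
        with pytest.raises(ValueError):
            parse_threshold("gap")


@pytest.fixture(scope="module")
def small_cohort():
    cfg = sv.SimulationConfig(
        m=120, p_continuous=10, p_boolean=3, p_categorical=2,
        n_relevant=3, beta=1.2, target_censoring=0.4, seed=21,
    )
    return sv.generate(cfg)


class TestRunExperiment:
    def test_subset_and_cindex_counts(self, small_cohort):
        ds, _ = small_cohort
        res = sv.run_experiment(ds, "lasso", "RRA:0.15", None, B=4, folds=3,
                                repeats=2, probes=False, seed=1)
        assert len(res.subsets) == 6
        assert len(res.c_indexes) == 6
        assert all(0 <= c <= 1 for c in res.c_indexes)
        assert res.score == pytest.approx(
            np.hypot(res.stability, res.mean_c_index)
        )

    def test_end_to_end_determinism(self, small_cohort):
        ds, _ = small_cohort
        kw = dict(B=3, folds=2, repeats=2, probes=True, seed=5)
        a = sv.run_experiment(ds, "lasso", "MW", "probe", **kw)
        b = sv.run_experiment(ds, "lasso", "MW", "probe", **kw)
        assert a.to_json() == b.to_json()

    def test_self_thresholding_rejects_threshold(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError, match="own thresholding"):
            sv.run_experiment(ds, "lasso", "TA", "q75", B=2, folds=2, repeats=1)

    def test_score_aggregator_requires_threshold(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError, match="threshold"):
            sv.run_experiment(ds, "lasso", "MW", None, B=2, folds=2, repeats=1)

    def test_probe_threshold_requires_probes(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError, match="probe"):
            sv.run_experiment(ds, "lasso", "MW", "probe", probes=False,
                              B=2, folds=2, repeats=1)

    def test_strong_signal_beats_chance(self, small_cohort):
        ds, _ = small_cohort
        res = sv.run_experiment(ds, "lasso", "TA", None, B=4, folds=3,
                                repeats=1, probes=False, seed=2)
        assert res.mean_c_index > 0.6

    def test_cindex_margin_grows_with_effect_size(self):
        means = {}
        for beta in (0.0, 1.5):
            cfg = sv.SimulationConfig(m=150, p_continuous=10, p_boolean=2,
                                      p_categorical=1, n_relevant=3, beta=beta,
                                      target_censoring=0.3, seed=13)
            ds, _ = sv.generate(cfg)
            res = sv.run_experiment(ds, "lasso", "TA", None, B=4, folds=3,
                                    repeats=1, probes=False, seed=0)
            means[beta] = res.mean_c_index
        assert means[1.5] > means[0.0] + 0.1
        assert abs(means[0.0] - 0.5) < 0.12

    def test_probes_never_reach_final_subsets(self, small_cohort):
        ds, _ = small_cohort
        res = sv.run_experiment(ds, "unicox", "MR", "probe", B=3, folds=2,
                                repeats=1, probes=True, seed=3)
        for s in res.subsets:
            assert all(not sv.is_probe_name(n) for n in s)

    def test_normalization_leakage_guard(self, small_cohort):
        # train-fitted parameters must not move when test rows change
        ds, _ = small_cohort
        splits = sv.make_cv_splits(ds.m, ds.event, k=3, repeats=1, seed=0)
        split = splits[0]
        params = sv.fit_normalization(ds, split.train_rows)
        tampered = ds.features.copy()
        tampered.iloc[split.test_rows, 0] += 100.0
        ds2 = sv.SurvivalDataset(tampered, list(ds.meta), ds.time.copy(), ds.event.copy())
        params2 = sv.fit_normalization(ds2, split.train_rows)
        assert params.mean == params2.mean and params.sd == params2.sd


class TestRunIndividual:
    def test_sparse_rejects_threshold(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError, match="own subset"):
            sv.run_individual(ds, "lasso", "fixed:0.1", folds=2, repeats=1)

    def test_filter_requires_threshold(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError, match="requires a threshold"):
            sv.run_individual(ds, "unicox", None, folds=2, repeats=1)

    def test_fixed_fraction_subset_sizes(self, small_cohort):
        ds, _ = small_cohort  # 15 features; 25% -> round-half-up(3.75) = 4
        res = sv.run_individual(ds, "unicox", "fixed:0.25", folds=2, repeats=1, seed=4)
        assert all(len(s) == 4 for s in res.subsets)

    def test_determinism(self, small_cohort):
        ds, _ = small_cohort
        a = sv.run_individual(ds, "lasso", None, folds=2, repeats=1, seed=9)
        b = sv.run_individual(ds, "lasso", None, folds=2, repeats=1, seed=9)
        assert a.to_json() == b.to_json()


class TestConsensus:
    def _result(self, subsets, score):
        return sv.ExperimentResult(
            selector_id="s", aggregator_id="MW", threshold_id="q75", seed=0,
            folds=len(subsets), repeats=1, B=2, probes=False,
            subsets=[sorted(s) for s in subsets], c_indexes=[0.5] * len(subsets),
            mean_c_index=score / 2, stability=score / 2, score=score,
        )

    def test_unanimous_feature_frequency_one(self):
        results = [self._result([["a", "b"], ["a"]], 1.0) for _ in range(10)]
        out = dict(sv.consensus_features(results, top_n=10))
        assert out["a"] == 1.0
        assert "b" not in out  # in exactly half the folds, not a majority

    def test_minority_feature_excluded(self):
        strong = [self._result([["a"], ["a"]], 1.0) for _ in range(6)]
        weak = [self._result([["z"], ["z"]], 0.9) for _ in range(4)]
        out = dict(sv.consensus_features(strong + weak, top_n=10, min_fraction=0.5))
        assert "a" in out and "z" not in out

    def test_raising_min_fraction_shrinks_output(self):
        rng = np.random.default_rng(5)
        results = []
        for i in range(10):
            subs = [["a"] + (["b"] if rng.uniform() < 0.6 else []) for _ in range(5)]
            results.append(self._result(subs, 1.0 - 0.01 * i))
        lo = {f for f, _ in sv.consensus_features(results, min_fraction=0.5)}
        hi = {f for f, _ in sv.consensus_features(results, min_fraction=0.8)}
        assert hi <= lo

    def test_fewer_results_than_top_n_warns(self):
        results = [self._result([["a"], ["a"]], 1.0)] * 3
        with pytest.warns(UserWarning, match="using all"):
            out = sv.consensus_features(results, top_n=10)
        assert out[0][0] == "a"
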