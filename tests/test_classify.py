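import numpy as np
import pandas as pd
import pytest

from looptrax.classify import (
    ClassifierSpec,
    consensus_importance,
    loo_tune,
    permutation_test,
)
from looptrax.cohort_io import Cohort, CohortSchema, PhenotypeRecord, VariableSchema


def _make_cohort(y, feature_cols):
    names = list(feature_cols)
    variables = (
        VariableSchema(name="resp", role="outcome",
                       levels=tuple(sorted(set(y) - {"unknown"})),
                       missing_codes=("unknown",)),
    ) + tuple(
        VariableSchema(name=n, role="E18.5", levels=tuple(sorted(set(feature_cols[n]))),
                       missing_codes=("unknown",))
        for n in names
    )
    schema = CohortSchema(variables=variables)
    records = tuple(
        PhenotypeRecord(
            subject_id=f"S{i}", looping_class="unknown",
            features={"resp": y[i], **{n: feature_cols[n][i] for n in names}},
        )
        for i in range(len(y))
    )
    return Cohort(records=records, schema=schema)


def _noise_cols(rng, n, k, prefix="noise"):
    return {
        f"{prefix}{j}": [str(x) for x in rng.integers(0, 3, size=n)] for j in range(k)
    }


SMALL = ClassifierSpec(mtry_grid=(2,), trees_grid=(60,), seed=0)


class TestLOOTune:
    def test_separable_predictor_gives_perfect_loo_accuracy(self):
        rng = np.random.default_rng(0)
        n = 30
        y = ["a" if i % 2 else "b" for i in range(n)]
        cols = {"signal": ["x" if v == "a" else "y" for v in y], **_noise_cols(rng, n, 2)}
        cohort = _make_cohort(y, cols)
        best, allres = loo_tune(
            cohort, "resp", list(cols),
            ClassifierSpec(mtry_grid=(1, 3), trees_grid=(60,), seed=1),
        )
        assert all(r.accuracy == 1.0 for r in allres)

    def test_one_prediction_per_sample(self):
        rng = np.random.default_rng(1)
        n = 20
        y = [str(x) for x in rng.integers(0, 2, size=n)]
        cohort = _make_cohort(y, _noise_cols(rng, n, 3))
        best, allres = loo_tune(cohort, "resp", [f"noise{j}" for j in range(3)], SMALL)
        for r in allres:
            assert len(r.predictions) == n

    def test_unknown_response_rejected(self):
        rng = np.random.default_rng(2)
        y = ["a"] * 5 + ["b"] * 5 + ["unknown"]
        cols = _noise_cols(rng, 11, 2)
        with pytest.raises(ValueError, match="unknown response"):
            loo_tune(_make_cohort(y, cols), "resp", list(cols), SMALL)

    def test_null_data_loo_accuracy_near_chance(self):
        """With a response independent of all predictors, the best tuned LOO
        accuracy stays within Monte-Carlo range of chance (no optimism leak)."""
        rng = np.random.default_rng(3)
        n = 120
        y = [str(x) for x in rng.integers(0, 2, size=n)]
        cols = _noise_cols(rng, n, 4)
        best, _ = loo_tune(
            _make_cohort(y, cols), "resp", list(cols),
            ClassifierSpec(mtry_grid=(2,), trees_grid=(50,), seed=4),
        )
        freqs = np.unique([float(v) for v in y], return_counts=True)[1] / n
        null_mean = float((freqs**2).sum())
        se = np.sqrt(null_mean * (1 - null_mean) / n)
        assert best[0].accuracy < null_mean + 4 * se


class TestConsensusImportance:
    def test_single_model_returns_its_ranking(self):
        rng = np.random.default_rng(5)
        n = 40
        y = ["a" if i % 2 else "b" for i in range(n)]
        cols = {"signal": ["x" if v == "a" else "y" for v in y], **_noise_cols(rng, n, 2)}
        best, _ = loo_tune(_make_cohort(y, cols), "resp", list(cols), SMALL)
        ranking = consensus_importance(best[:1])
        assert list(ranking.index) == list(best[0].importances.sort_values(ascending=False).index)

    def test_average_of_tied_models_with_stable_name_order(self):
        a = pd.Series({"f1": 0.6, "f2": 0.4})
        b = pd.Series({"f1": 0.4, "f2": 0.6})
        results = [
            type("R", (), {"importances": a})(),
            type("R", (), {"importances": b})(),
        ]
        ranking = consensus_importance(results)
        assert ranking["f1"] == pytest.approx(0.5) and ranking["f2"] == pytest.approx(0.5)
        assert list(ranking.index) == ["f1", "f2"]  # tie broken by name

    def test_planted_predictor_ranks_first_across_seeds(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            n = 90
            y = ["a" if b else "b" for b in rng.random(n) < 0.5]
            signal = [
                ("x" if v == "a" else "y") if rng.random() < 0.9 else ("y" if v == "a" else "x")
                for v in y
            ]
            cols = {"signal": signal, **_noise_cols(rng, n, 13)}
            best, _ = loo_tune(
                _make_cohort(y, cols), "resp", list(cols),
                ClassifierSpec(mtry_grid=(4,), trees_grid=(50,), seed=seed),
            )
            if consensus_importance(best).index[0] == "signal":
                hits += 1
        assert hits >= int(0.95 * n_seeds)


class TestPermutationTest:
    def test_mean_null_accuracy_matches_squared_frequencies(self):
        rng = np.random.default_rng(7)
        n = 40
        y = [str(x) for x in rng.integers(0, 4, size=n)]
        cols = _noise_cols(rng, n, 3)
        perm = permutation_test(
            _make_cohort(y, cols), "resp", list(cols), mtry=2, n_trees=50, B=4000, seed=1
        )
        # expectation of matching a uniformly drawn training-fold label
        _, counts = np.unique(y, return_counts=True)
        expected = float(sum(c * (c - 1) for c in counts)) / (n * (n - 1))
        se = perm.null_accuracies.std(ddof=1) / np.sqrt(perm.B)
        assert abs(perm.mean_null_accuracy - expected) < 3 * se

    def test_held_out_label_never_among_candidates(self):
        """A label carried by exactly one sample can never be matched by a
        draw from its own training fold: its per-fold hit probability is 0."""
        rng = np.random.default_rng(8)
        y = ["solo"] + ["a"] * 10 + ["b"] * 10
        cols = _noise_cols(rng, 21, 2)
        perm = permutation_test(
            _make_cohort(y, cols), "resp", list(cols), mtry=1, n_trees=30, B=2000, seed=2
        )
        # if the null ever matched 'solo', accuracy could reach 1.0; the
        # maximum attainable null accuracy excludes that one sample
        assert perm.null_accuracies.max() <= 20 / 21 + 1e-12

    def test_separable_data_p_zero_with_add_one_variant(self):
        rng = np.random.default_rng(9)
        n = 24
        y = ["a" if i % 2 else "b" for i in range(n)]
        cols = {"signal": ["x" if v == "a" else "y" for v in y]}
        perm = permutation_test(
            _make_cohort(y, cols), "resp", ["signal"], mtry=1, n_trees=60, B=3000, seed=3
        )
        assert perm.observed_accuracy == 1.0
        assert perm.p_empirical == 0.0
        assert perm.p_add_one == pytest.approx(1 / 3001)

    def test_observed_accuracy_reproducible_under_seed(self):
        rng = np.random.default_rng(10)
        n = 30
        y = [str(x) for x in rng.integers(0, 2, size=n)]
        cols = _noise_cols(rng, n, 3)
        cohort = _make_cohort(y, cols)
        a = permutation_test(cohort, "resp", list(cols), mtry=2, n_trees=40, B=500, seed=5)
        b = permutation_test(cohort, "resp", list(cols), mtry=2, n_trees=40, B=500, seed=5)
        assert a.observed_accuracy == b.observed_accuracy
        assert np.array_equal(a.null_accuracies, b.null_accuracies)

    def test_invalid_B_rejected(self, cohort):
        with pytest.raises(ValueError, match="B"):
            permutation_test(cohort, "looping_class", ["apex_position"], 1, 10, B=0)
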