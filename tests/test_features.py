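"""Feature-table conditioning: presence filter, reference scaling, PQN,
KNN imputation, glog — each against its independent oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmanmr import features as ft


def make_table(values, groups=None, positions=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    idx = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(values, index=idx)
    pos = np.arange(p, dtype=float) if positions is None else np.asarray(positions)
    g = pd.Series(groups, index=idx, name="group") if groups is not None else None
    return ft.FeatureTable(values=df, positions=pos, groups=g)


class TestPresenceFilter:
    def make_9v9(self, obs_a, obs_b):
        """One feature observed obs_a/9 times in A and obs_b/9 in B."""
        col = np.full(18, np.nan)
        col[:obs_a] = 1.0
        col[9 : 9 + obs_b] = 1.0
        values = np.column_stack([np.ones(18), col])
        return make_table(values, groups=["A"] * 9 + ["B"] * 9)

    def test_eight_of_nine_in_one_group_is_kept(self):
        table = self.make_9v9(8, 0)  # 8/9 = 0.889 >= 0.8 in group A
        out = ft.presence_filter(table, min_frac=0.8)
        assert out.n_features == 2

    def test_seven_of_nine_in_both_groups_is_removed(self):
        table = self.make_9v9(7, 7)  # 7/9 = 0.778 < 0.8 everywhere
        out = ft.presence_filter(table, min_frac=0.8)
        assert out.n_features == 1

    def test_zero_threshold_is_identity(self):
        table = self.make_9v9(1, 0)
        out = ft.presence_filter(table, min_frac=0.0)
        assert out.n_features == table.n_features

    def test_both_groups_rule_is_stricter(self):
        table = self.make_9v9(9, 7)
        assert ft.presence_filter(table, rule="any").n_features == 2
        assert ft.presence_filter(table, rule="all").n_features == 1

    def test_invalid_fraction_rejected(self):
        table = self.make_9v9(9, 9)
        with pytest.raises(ValueError):
            ft.presence_filter(table, min_frac=1.5)


class TestReferenceScaling:
    def test_sample_divided_by_its_reference_value(self):
        table = make_table([[2.0, 4.0, 6.0], [1.0, 3.0, 5.0]],
                           positions=[6.0, 2.0, 3.0])
        out = ft.scale_to_reference_feature(table, ref_position=6.0)
        np.testing.assert_allclose(out.values.iloc[0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(out.values.iloc[1], [1.0, 3.0, 5.0])
        # the reference column collapses to ones
        np.testing.assert_allclose(out.values.iloc[:, 0], 1.0)

    def test_nonpositive_reference_names_the_sample(self):
        table = make_table([[2.0, 4.0], [0.0, 3.0]], positions=[6.0, 2.0])
        with pytest.raises(ValueError, match="s1"):
            ft.scale_to_reference_feature(table, ref_position=6.0)

    def test_missing_reference_feature_rejected(self):
        table = make_table([[2.0, 4.0]], positions=[1.0, 2.0])
        with pytest.raises(KeyError):
            ft.scale_to_reference_feature(table, ref_position=6.0)


def pqn_factors_bruteforce(X, max_iter=500, tol=1e-12):
    """Exhaustive median-of-quotients oracle, hand loops only.

    Applies the textbook PQN map (median reference spectrum, median of
    observed quotients) repeatedly until self-consistent, mirroring the
    normalization's fixpoint definition but sharing no code with it.
    """
    X = [[v for v in row] for row in np.asarray(X, dtype=float)]
    n, p = len(X), len(X[0])
    totals = [1.0] * n
    for _ in range(max_iter):
        reference = []
        for j in range(p):
            col = [X[i][j] for i in range(n) if not math.isnan(X[i][j])]
            reference.append(float(np.median(col)) if col else float("nan"))
        factors = []
        for i in range(n):
            quotients = []
            for j in range(p):
                if (math.isnan(X[i][j]) or math.isnan(reference[j])
                        or reference[j] == 0):
                    continue
                quotients.append(X[i][j] / reference[j])
            factors.append(float(np.median(quotients)))
        for i in range(n):
            totals[i] *= factors[i]
            for j in range(p):
                X[i][j] /= factors[i]
        if max(abs(f - 1.0) for f in factors) < tol:
            break
    return np.array(totals)


class TestPQN:
    def test_identical_samples_are_left_alone(self):
        row = [1.0, 2.0, 3.0, 4.0]
        table = make_table([row, row, row])
        out, factors = ft.pqn_normalize(table)
        np.testing.assert_allclose(factors, 1.0)
        np.testing.assert_allclose(out.matrix(), table.matrix())

    def test_global_dilution_recovered(self):
        base = np.array([[1.0, 2.0, 3.0, 4.0]])
        X = np.vstack([base, base, 3.0 * base])
        out, factors = ft.pqn_normalize(make_table(X))
        assert factors.iloc[2] == pytest.approx(3.0)
        np.testing.assert_allclose(out.matrix()[2], base[0])

    def test_matches_bruteforce_oracle_with_missing_cell(self):
        X = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, np.nan, 6.0, 8.0],
            [0.5, 1.0, 1.5, 2.0],
        ])
        _, factors = ft.pqn_normalize(make_table(X))
        np.testing.assert_allclose(factors.to_numpy(), pqn_factors_bruteforce(X))

    def test_idempotence_factors_all_one(self):
        rng = np.random.default_rng(5)
        X = rng.lognormal(0, 1, (6, 12))
        once, _ = ft.pqn_normalize(make_table(X))
        _, factors = ft.pqn_normalize(once)
        np.testing.assert_allclose(factors.to_numpy(), 1.0, atol=1e-9)

    def test_insufficient_shared_features_rejected(self):
        X = np.array([
            [1.0, 2.0, 3.0],
            [1.0, np.nan, np.nan],
            [1.0, 2.0, 3.0],
        ])
        with pytest.raises(ValueError, match="shares only"):
            ft.pqn_normalize(make_table(X))


class TestKNNImpute:
    def test_complete_table_returned_unchanged(self):
        X = np.arange(12.0).reshape(3, 4) + 1
        out = ft.knn_impute(make_table(X), k=2)
        np.testing.assert_array_equal(out.matrix(), X)

    def test_duplicate_feature_imputes_exactly(self):
        """Feature B duplicates A except one missing cell; k=1 copies A."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X = np.column_stack([a, a, np.linspace(10, 50, 5)])
        X[2, 1] = np.nan
        out = ft.knn_impute(make_table(X), k=1)
        assert out.matrix()[2, 1] == a[2]

    def test_fallback_to_feature_mean_when_neighbours_exhausted(self):
        X = np.array([
            [1.0, 10.0],
            [2.0, np.nan],
            [3.0, 30.0],
        ])
        out = ft.knn_impute(make_table(X), k=5)  # only 1 candidate < k
        assert out.matrix()[1, 1] == pytest.approx(20.0)

    def test_all_missing_feature_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="entirely missing"):
            ft.knn_impute(make_table(X))


class TestGlog:
    def test_zero_lambda_reduces_to_log2x(self):
        for x in (0.1, 1.0, 7.5):
            assert ft.glog_transform(x, 0.0) == pytest.approx(math.log(2 * x))

    def test_zero_x_gives_half_log_lambda(self):
        for lam in (0.25, 1.0, 9.0):
            assert ft.glog_transform(0.0, lam) == pytest.approx(0.5 * math.log(lam))

    def test_negative_x_with_zero_lambda_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            ft.glog_transform(-1.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(lam=st.floats(1e-12, 1e6), scale=st.floats(1e-6, 1e6))
    def test_strictly_increasing_in_x(self, lam, scale):
        x = np.linspace(-3, 3, 41) * scale
        g = ft.glog_transform(x, lam)
        assert np.all(np.diff(g) > 0)

    def test_stable_for_large_negative_x_small_lambda(self):
        g = ft.glog_transform(-30.0, 1e-16)
        assert np.isfinite(g)
        # agrees with the exact identity ln(lambda) - ln(sqrt(..)-x)
        exact = math.log(1e-16) - math.log(math.sqrt(900.0 + 1e-16) + 30.0)
        assert g == pytest.approx(exact, rel=1e-12)


class TestGlogLambda:
    def two_component_block(self, seed=0, add_sd=0.3, mult_sd=0.15,
                            n_reps=8, n_feat=40):
        """Replicates under the additive+multiplicative error model."""
        rng = np.random.default_rng(seed)
        means = rng.lognormal(1.0, 1.2, n_feat)
        X = (means[None, :] * np.exp(rng.normal(0, mult_sd, (n_reps, n_feat)))
             + rng.normal(0, add_sd, (n_reps, n_feat)))
        return X

    def test_matches_grid_search_oracle_within_one_order(self):
        X = self.two_component_block()
        lam = ft.estimate_glog_lambda(X)
        scale = float(np.median(np.abs(X)))
        grid = np.logspace(math.log10(1e-12 * scale**2),
                           math.log10(1e12 * scale**2), 200)
        objective = [ft._heterogeneity(X, g) for g in grid]
        lam_grid = grid[int(np.argmin(objective))]
        assert abs(math.log10(lam) - math.log10(lam_grid)) <= 1.0

    def test_chosen_lambda_beats_endpoints(self):
        X = self.two_component_block(seed=3)
        lam = ft.estimate_glog_lambda(X)
        scale = float(np.median(np.abs(X)))
        mid = ft._heterogeneity(X, lam)
        assert mid <= ft._heterogeneity(X, 1e-12 * scale**2)
        assert mid <= ft._heterogeneity(X, 1e12 * scale**2)

    def test_invariant_to_feature_permutation(self):
        X = self.two_component_block(seed=1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[1])
        lam1 = ft.estimate_glog_lambda(X)
        lam2 = ft.estimate_glog_lambda(X[:, perm])
        assert lam2 == pytest.approx(lam1, rel=1e-6)

    def test_zero_variance_block_returns_lower_bound_with_warning(self):
        X = np.ones((4, 6))
        with pytest.warns(RuntimeWarning, match="zero variance"):
            lam = ft.estimate_glog_lambda(X)
        assert lam == pytest.approx(1e-12, rel=1e-6)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="3 replicate"):
            ft.estimate_glog_lambda(np.ones((2, 5)))


class TestPipelineOrder:
    def noisy_table(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(0, 0.3, (8, 6))
        return make_table(X, groups=["PA"] * 4 + ["PPGL"] * 4,
                          positions=[6.0, 1.0, 2.0, 3.0, 4.0, 5.0])

    def test_chain_runs_in_order_and_logs(self):
        table = self.noisy_table()
        out, log = ft.condition_table(table, ref_position=6.0,
                                      replicate_group="PA", k=2)
        assert out.history == ["presence_filter", "scale_to_reference",
                               "pqn", "knn_impute", "glog"]
        assert log["n_features_after_presence"] == 6
        assert log["glog_lambda"] > 0

    def test_earlier_stage_after_later_stage_raises(self):
        table = self.noisy_table()
        normalized, _ = ft.pqn_normalize(table)
        with pytest.raises(ft.PipelineOrderError, match="order"):
            ft.presence_filter(normalized)
        with pytest.raises(ft.PipelineOrderError):
            ft.scale_to_reference_feature(normalized, ref_position=6.0)

    def test_same_stage_can_be_repeated(self):
        table = self.noisy_table()
        once, _ = ft.pqn_normalize(table)
        again, factors = ft.pqn_normalize(once)  # idempotence check path
        np.testing.assert_allclose(factors.to_numpy(), 1.0, atol=1e-9)

    def test_glog_requires_complete_table(self):
        X = np.array([[1.0, np.nan], [2.0, 1.0], [3.0, 2.0], [1.0, 1.0]])
        table = make_table(X, groups=["PA", "PA", "PA", "PPGL"])
        with pytest.raises(ValueError, match="complete"):
            ft.glog_table(table, replicate_group="PA")


class TestFeatureTableIO:
    def test_csv_round_trip(self, tmp_path):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [4.0, 5.0]])
        table = make_table(X, groups=["PA", "PA", "PPGL"], positions=[6.0, 1.5])
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = ft.FeatureTable.read_csv(path)
        np.testing.assert_allclose(back.matrix(), X)
        np.testing.assert_allclose(back.positions, [6.0, 1.5])
        assert list(back.groups) == ["PA", "PA", "PPGL"]


class TestEstimatorProtocol:
    def test_get_set_params_round_trip(self):
        est = ft.PresenceFilter(min_frac=0.7)
        assert est.get_params() == {"min_frac": 0.7, "rule": "any"}
        est.set_params(min_frac=0.9)
        assert est.min_frac == 0.9
        with pytest.raises(ValueError):
            est.set_params(nonsense=1)

    def test_transformers_compose_with_sklearn_pipeline(self):
        from sklearn.pipeline import Pipeline

        rng = np.random.default_rng(0)
        X = rng.lognormal(0, 0.3, (6, 5))
        pipe = Pipeline([
            ("pqn", ft.PQNNormalizer()),
            ("glog", ft.GlogTransformer(lam=1.0)),
        ])
        out = pipe.fit_transform(X)
        assert out.shape == X.shape
        assert np.all(np.isfinite(out))
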