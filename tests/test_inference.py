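"""MCCV partitioning, influence scoring, leave-one-gene-out inference, filtering."""

import numpy as np
import pandas as pd
import pytest

from anni import (
    AnniConfig,
    ExpressionMatrix,
    InteractionScoreMatrix,
    MLPModel,
    infer_all,
    infer_single_target,
    influence_scores,
    mccv_split,
    minmax_scale,
    pearson_filter,
    pearson_r,
    train_mlp,
)
from anni.inference import _target_seed_sequence
from anni.mlp import forward


class TestMccvSplit:
    @pytest.mark.parametrize(
        "n, expected",
        [(100, (60, 20, 20)), (10, (6, 2, 2)), (88, (54, 17, 17)), (5, (3, 1, 1))],
    )
    def test_partition_sizes_floor_with_remainder_to_training(self, n, expected):
        part = mccv_split(n, (0.6, 0.2, 0.2), seed=1)
        assert (part.train_idx.size, part.test_idx.size, part.val_idx.size) == expected

    def test_partitions_disjoint_and_cover_all_samples(self):
        for seed in range(50):
            part = mccv_split(37, seed=seed)
            combined = np.concatenate([part.train_idx, part.test_idx, part.val_idx])
            assert sorted(combined) == list(range(37))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mccv_split(4)

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            mccv_split(6, (0.98, 0.01, 0.01), seed=0)


class TestInfluenceScores:
    def test_cancellation_across_hidden_paths(self):
        model = MLPModel(np.array([[1.0, -1.0], [0.0, 0.0]]), np.array([0.5, 0.5, 0.3]))
        assert influence_scores(model) == pytest.approx([0.0])

    def test_all_positive_weights_give_positive_score(self, rng):
        model = MLPModel.initialize(4, 2, rng, (0.1, 1.0))
        assert (influence_scores(model) > 0).all()

    def test_bias_weights_excluded(self, rng):
        model = MLPModel.initialize(3, 2, rng)
        scores = influence_scores(model)
        model.w_ih[-1] += 100.0  # hidden biases
        model.w_ho[-1] += 100.0  # output bias
        assert influence_scores(model) == pytest.approx(scores)

    def test_sign_agrees_with_output_sensitivity(self, rng):
        """For a trained monotone mapping, the connection-weight score sign
        matches the finite-difference sensitivity of the output at the centroid."""
        X = rng.uniform(0, 1, (60, 2))
        d = 1 / (1 + np.exp(-(3.0 * X[:, 0] - 3.0 * X[:, 1])))
        model, _ = train_mlp(X, d, AnniConfig(epochs=200), seed=8)
        centroid = X.mean(axis=0)
        eps = 1e-4
        for i, score in enumerate(influence_scores(model)):
            xp, xm = centroid.copy(), centroid.copy()
            xp[i] += eps
            xm[i] -= eps
            sensitivity = forward(model, xp)[1] - forward(model, xm)[1]
            assert np.sign(score) == np.sign(sensitivity)


class TestInferSingleTarget:
    def test_single_model_run_equals_its_influence_scores(self, small_panel):
        """With one reshuffle and one repeat the mean is the single model."""
        m, _ = small_panel
        cfg = AnniConfig(n_reshuffles=1, n_repeats=1, rng_seed=3)
        scores, _ = infer_single_target(m, "F002", cfg)

        # independently reproduce the one trained model from the seed chain
        predictors = sorted(g for g in m.gene_ids if g != "F002")
        X = m.values[predictors].to_numpy()
        d = m.values["F002"].to_numpy()
        root = _target_seed_sequence(cfg.rng_seed, "F002")
        (reshuffle,) = root.spawn(1)
        part_seq, model_seq = reshuffle.spawn(2)
        part = mccv_split(len(d), cfg.split_ratios, np.random.default_rng(part_seq))
        model, _ = train_mlp(
            X[part.train_idx], d[part.train_idx], cfg,
            np.random.default_rng(model_seq),
            monitor=(X[part.test_idx], d[part.test_idx]),
        )
        assert scores.to_numpy() == pytest.approx(influence_scores(model), abs=0)

    def test_column_permutation_leaves_scores_unchanged(self, small_panel):
        m, _ = small_panel
        cfg = AnniConfig(n_reshuffles=2, n_repeats=2, rng_seed=7)
        base, base_mse = infer_single_target(m, "F003", cfg)
        perm = np.random.default_rng(0).permutation(m.n_genes)
        permuted = ExpressionMatrix(m.values.iloc[:, perm].copy(), scaled=True)
        other, other_mse = infer_single_target(permuted, "F003", cfg)
        assert (base.reindex(other.index).to_numpy() == other.to_numpy()).all()
        assert base_mse == other_mse

    def test_same_seed_gives_identical_output(self, small_panel):
        m, _ = small_panel
        cfg = AnniConfig(n_reshuffles=2, n_repeats=1, rng_seed=5)
        s1, v1 = infer_single_target(m, "F001", cfg)
        s2, v2 = infer_single_target(m, "F001", cfg)
        assert (s1.to_numpy() == s2.to_numpy()).all() and v1 == v2

    def test_unknown_target_rejected(self, small_panel):
        with pytest.raises(KeyError):
            infer_single_target(small_panel[0], "NOPE", AnniConfig())

    def test_unscaled_matrix_rejected(self, rng):
        from conftest import random_expression

        with pytest.raises(ValueError, match="scaled"):
            infer_single_target(random_expression(rng), "g0", AnniConfig())


class TestInferAll:
    def test_three_genes_give_six_entries(self, small_panel, fast_cfg):
        m, _ = small_panel
        three = ExpressionMatrix(m.values.iloc[:, :3].copy(), scaled=True)
        result = infer_all(three, fast_cfg)
        assert result.n_defined == 6
        assert np.isnan(np.diagonal(result.scores.to_numpy())).all()

    def test_aggregates_expected_number_of_models(self, small_panel):
        """Each off-diagonal entry is the mean of n_reshuffles x n_repeats scores;
        halving the repeats changes the mean unless all models agree."""
        m, _ = small_panel
        cfg = AnniConfig(n_reshuffles=2, n_repeats=2, rng_seed=1, epochs=30)
        full, _ = infer_single_target(m, "F001", cfg)
        # manually re-average the four models and compare
        predictors = sorted(g for g in m.gene_ids if g != "F001")
        X = m.values[predictors].to_numpy()
        d = m.values["F001"].to_numpy()
        root = _target_seed_sequence(cfg.rng_seed, "F001")
        acc = np.zeros(len(predictors))
        count = 0
        for reshuffle in root.spawn(cfg.n_reshuffles):
            seqs = reshuffle.spawn(cfg.n_repeats + 1)
            part = mccv_split(len(d), cfg.split_ratios, np.random.default_rng(seqs[0]))
            for child in seqs[1:]:
                mdl, _ = train_mlp(
                    X[part.train_idx], d[part.train_idx], cfg,
                    np.random.default_rng(child),
                    monitor=(X[part.test_idx], d[part.test_idx]),
                )
                acc += influence_scores(mdl)
                count += 1
        assert count == 4
        assert full.to_numpy() == pytest.approx(acc / count, rel=1e-12)

    def test_planted_driver_outscored_noise(self):
        """A target that is a monotone function of gene A scores A above an
        independent noise gene in nearly all seeded runs."""
        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            target = np.tanh(a) + 0.05 * rng.normal(size=50)
            df = pd.DataFrame({"A": a, "B": b, "T": target},
                              index=[f"s{i}" for i in range(50)])
            m = minmax_scale(ExpressionMatrix(df))
            cfg = AnniConfig(n_reshuffles=2, n_repeats=1, rng_seed=seed, epochs=100)
            scores, _ = infer_single_target(m, "T", cfg)
            wins += abs(scores["A"]) > abs(scores["B"])
        assert wins >= 0.95 * n_runs


class TestPearson:
    def test_perfect_and_anti_correlation(self, rng):
        x = rng.normal(size=20)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_formula(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        xm, ym = x - x.mean(), y - y.mean()
        brute = (xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
        assert pearson_r(x, y) == pytest.approx(brute, rel=1e-12)

    def test_zero_variance_flagged_as_nan(self):
        assert np.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [3.0, 4.0])


class TestPearsonFilter:
    def _scores_for(self, m):
        g = m.n_genes
        vals = np.arange(g * g, dtype=float).reshape(g, g) + 1.0
        np.fill_diagonal(vals, np.nan)
        scores = pd.DataFrame(vals, index=m.gene_ids, columns=m.gene_ids)
        return InteractionScoreMatrix(scores, pd.Series(0.0, index=m.gene_ids))

    def test_zero_cutoff_removes_nothing(self, rng):
        from conftest import random_expression

        m = random_expression(rng, n_samples=20, n_genes=4)
        s = self._scores_for(m)
        kept = pearson_filter(s, m, cutoff=0.0)
        assert int(kept.kept.to_numpy().sum()) == 12  # all off-diagonal

    def test_proportional_genes_survive_default_cutoff(self, rng):
        base = rng.normal(size=30)
        df = pd.DataFrame({
            "a": base, "b": 2.0 * base + 1.0, "c": rng.normal(size=30),
        }, index=[f"s{i}" for i in range(30)])
        m = ExpressionMatrix(df)
        s = self._scores_for(m)
        filtered = pearson_filter(s, m, cutoff=0.7)
        assert filtered.kept.loc["a", "b"] and filtered.kept.loc["b", "a"]
        assert filtered.expression_r.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_noise_mostly_removed(self, rng):
        from conftest import random_expression

        m = random_expression(rng, n_samples=100, n_genes=40)
        s = self._scores_for(m)
        filtered = pearson_filter(s, m, cutoff=0.7)
        frac_kept = filtered.kept.to_numpy().sum() / (40 * 39)
        assert frac_kept <= 0.01

    def test_removed_entries_masked_not_dropped(self, rng):
        from conftest import random_expression

        m = random_expression(rng, n_samples=50, n_genes=4)
        s = self._scores_for(m)
        filtered = pearson_filter(s, m, cutoff=0.99)
        assert filtered.scores.shape == s.scores.shape
        assert filtered.n_defined <= s.n_defined


class TestInteractionScoreMatrix:
    def test_diagonal_must_be_masked(self):
        df = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            InteractionScoreMatrix(df, pd.Series(0.0, index=["a", "b"]))

    def test_dense_tsv_round_trip(self, tmp_path):
        vals = np.array([[np.nan, 1.5], [-0.25, np.nan]])
        s = InteractionScoreMatrix(
            pd.DataFrame(vals, index=["a", "b"], columns=["a", "b"]),
            pd.Series([0.1, 0.2], index=["a", "b"]),
        )
        s.write_dense(tmp_path / "scores.tsv")
        back = InteractionScoreMatrix.read_dense(tmp_path / "scores.tsv")
        assert back.gene_ids == ["a", "b"]
        assert back.scores.loc["b", "a"] == -0.25
        assert np.isnan(back.scores.loc["a", "a"])

    def test_long_frame_has_all_ordered_pairs(self):
        vals = np.full((3, 3), 2.0)
        np.fill_diagonal(vals, np.nan)
        s = InteractionScoreMatrix(
            pd.DataFrame(vals, index=list("abc"), columns=list("abc")),
            pd.Series(0.0, index=list("abc")),
        )
        long = s.to_long_frame()
        assert len(long) == 6
        assert long["kept"].all()
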