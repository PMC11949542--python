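import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nnembed.exceptions import (
    ConfigurationError,
    DimensionError,
    StatisticsError,
    UndefinedValueError,
)
from nnembed.nne import (
    DEFAULT_DEPTHS,
    DEFAULT_MIDDLE_SIZES,
    NNEArchitecture,
    TrainingConfig,
    accuracy,
    bce_loss,
    build_layer_sizes,
    compare_middle_sizes,
    error_rate,
    extract_features,
    grid_survey,
    reconstruct,
    summarize_survey,
    tp_accuracy,
    train,
)
from .conftest import random_digraph


class TestBuildLayerSizes:
    def test_study_architecture(self):
        assert build_layer_sizes(100, 3, 13) == [100, 71, 42, 13, 42, 71, 100]

    def test_small_taper(self):
        assert build_layer_sizes(10, 2, 2) == [10, 6, 2, 6, 10]

    def test_degenerate_taper_all_equal(self):
        assert build_layer_sizes(7, 4, 7) == [7] * 9

    def test_middle_larger_than_input_rejected(self):
        with pytest.raises(ConfigurationError):
            build_layer_sizes(10, 2, 11)

    @settings(derandomize=True, max_examples=1000)
    @given(
        input_size=st.integers(2, 500),
        depth=st.integers(1, 12),
        middle_ratio=st.floats(0.0, 1.0),
    )
    def test_palindromic_and_monotone(self, input_size, depth, middle_ratio):
        middle = max(1, int(middle_ratio * input_size))
        sizes = build_layer_sizes(input_size, depth, middle)
        assert sizes == sizes[::-1]
        assert sizes[0] == sizes[-1] == input_size
        assert min(sizes) == sizes[depth] == middle
        encoder = sizes[: depth + 1]
        assert all(a >= b for a, b in zip(encoder, encoder[1:]))


class TestBceLoss:
    def test_analytic_half(self):
        assert bce_loss(np.array([1.0]), np.array([0.5])) == pytest.approx(np.log(2))

    def test_two_sample_case(self):
        got = bce_loss(np.array([1.0, 0.0]), np.array([0.8, 0.2]))
        assert got == pytest.approx(-(np.log(0.8) + np.log(0.8)) / 2)

    def test_perfect_prediction_at_clipping_floor(self):
        y = np.array([1.0, 0.0, 1.0])
        assert bce_loss(y, y) < 1e-6

    def test_matches_elementwise_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.integers(0, 2, size=64).astype(float)
            p = rng.uniform(0.01, 0.99, size=64)
            oracle = -np.mean([
                yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for yi, pi in zip(y, p)
            ])
            assert bce_loss(y, p) == pytest.approx(oracle, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            bce_loss(np.zeros(3), np.full(4, 0.5))


class TestAccuracyMetrics:
    def test_perfect_reconstruction(self):
        a = random_digraph(10, 0.3, seed=0).adjacency
        assert accuracy(a, a) == 1.0
        assert tp_accuracy(a, a) == 100.0

    def test_offdiagonal_complement_is_zero(self):
        a = random_digraph(10, 0.3, seed=1).adjacency
        assert accuracy(1 - a, a) == 0.0  # every off-diagonal cell flipped

    def test_counting_example(self):
        orig = np.zeros((10, 10), dtype=int)
        recon = orig.copy()
        idx = [(i, (i + 1) % 10) for i in range(9)]  # 9 off-diagonal cells
        for i, j in idx:
            recon[i, j] = 1
        assert accuracy(recon, orig) == pytest.approx(81 / 90)

    def test_tp_accuracy_hand_count(self):
        orig = np.zeros((5, 5), int)
        orig[0, 1] = orig[1, 2] = orig[2, 3] = orig[3, 4] = 1  # 4 edges
        recon = orig.copy()
        recon[3, 4] = 0  # recover 3 of 4
        assert tp_accuracy(recon, orig) == 75.0

    def test_tp_accuracy_all_missed(self):
        orig = random_digraph(8, 0.3, seed=2).adjacency
        assert tp_accuracy(np.zeros_like(orig), orig) == 0.0

    def test_tp_accuracy_undefined_without_edges(self):
        with pytest.raises(UndefinedValueError):
            tp_accuracy(np.zeros((4, 4), int), np.zeros((4, 4), int))

    def test_error_rate_complements_accuracy(self):
        a = random_digraph(10, 0.3, seed=3).adjacency
        b = random_digraph(10, 0.3, seed=4).adjacency
        assert error_rate(b, a) == pytest.approx(1 - accuracy(b, a), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            accuracy(np.zeros((3, 3)), np.zeros((4, 4)))


@pytest.fixture(scope="module")
def tiny_training_run():
    """A small but real training run shared across contract tests."""
    nets = [random_digraph(20, 0.15, seed=i) for i in range(6)]
    arch = NNEArchitecture(20, 2, 5)
    cfg = TrainingConfig(max_epochs=150, patience=20, seed=0)
    model = train(nets[:4], nets[4:], arch, cfg)
    return nets, arch, cfg, model


class TestTraining:
    def test_loss_decreases_and_stays_finite(self, tiny_training_run):
        _, _, _, model = tiny_training_run
        h = model.history
        assert np.isfinite(h["train_loss"]).all()
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]

    def test_early_stopping_within_budget(self, tiny_training_run):
        _, _, cfg, model = tiny_training_run
        assert model.stopped_epoch <= cfg.max_epochs
        assert len(model.history) <= cfg.max_epochs

    def test_deterministic_given_seed(self, tiny_training_run):
        nets, arch, cfg, model = tiny_training_run
        rerun = train(nets[:4], nets[4:], arch, cfg)
        assert rerun.history["train_loss"].iloc[-1] == model.history["train_loss"].iloc[-1]
        feats_a = extract_features(model, nets[0]).values
        feats_b = extract_features(rerun, nets[0]).values
        np.testing.assert_array_equal(feats_a, feats_b)

    def test_empty_validation_rejected(self, tiny_training_run):
        nets, arch, cfg, _ = tiny_training_run
        with pytest.raises(ConfigurationError):
            train(nets[:4], [], arch, cfg)

    def test_mismatched_network_size_rejected(self, tiny_training_run):
        nets, arch, cfg, _ = tiny_training_run
        bad = random_digraph(21, 0.15, seed=99)
        with pytest.raises(DimensionError):
            train([bad], nets[4:], arch, cfg)


class TestReconstructAndFeatures:
    def test_threshold_boundary_counts_as_one(self, tiny_training_run):
        # the binarisation rule is p >= threshold -> 1
        nets, _, _, model = tiny_training_run
        recon, p = reconstruct(model, nets[0])
        expected = (p >= 0.5).astype(int)
        np.fill_diagonal(expected, 0)
        np.testing.assert_array_equal(recon.adjacency, expected)

    def test_probabilities_in_open_unit_interval(self, tiny_training_run):
        nets, _, _, model = tiny_training_run
        _, p = reconstruct(model, nets[0])
        assert ((p > 0) & (p < 1)).all()

    def test_feature_shape_and_nonnegativity(self, tiny_training_run):
        nets, arch, _, model = tiny_training_run
        fm = extract_features(model, nets[0])
        assert fm.values.shape == (20, arch.middle_size)
        assert (fm.values >= 0).all()  # ReLU middle layer

    def test_feature_extraction_deterministic(self, tiny_training_run):
        nets, _, _, model = tiny_training_run
        a = extract_features(model, nets[1]).values
        b = extract_features(model, nets[1]).values
        np.testing.assert_array_equal(a, b)

    def test_wrong_size_rejected(self, tiny_training_run):
        _, _, _, model = tiny_training_run
        with pytest.raises(DimensionError):
            reconstruct(model, random_digraph(21, 0.2, seed=0))


class TestGridSurvey:
    def test_small_grid_yields_full_table(self):
        nets = [random_digraph(15, 0.2, seed=i) for i in range(6)]
        cfg = TrainingConfig(max_epochs=30, patience=10, seed=0)
        table = grid_survey(nets, depths=[1, 2], middle_sizes=[2, 5],
                            config=cfg, n_folds=3)
        assert len(table) == 2 * 2 * 3
        assert np.isfinite(table["loss"]).all()
        summary = summarize_survey(table)
        assert len(summary) == 4

    def test_default_grids_match_study_ranges(self):
        assert DEFAULT_DEPTHS == tuple(range(3, 12))
        assert DEFAULT_MIDDLE_SIZES == tuple(range(1, 30, 2))

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            grid_survey([], depths=[], middle_sizes=[1])


class TestCompareMiddleSizes:
    def test_identical_groups_nonsignificant(self):
        data = {1: [0.5, 0.5, 0.5, 0.5], 13: [0.5, 0.5, 0.5, 0.5]}
        out = compare_middle_sizes(data)
        assert out["p_corrected"].iloc[0] == pytest.approx(1.0)
        assert out["significance"].iloc[0] == "n.s."

    def test_separated_groups_strongly_significant(self):
        rng = np.random.default_rng(0)
        data = {
            1: (1 + rng.normal(scale=1e-3, size=4)).tolist(),
            13: (2 + rng.normal(scale=1e-3, size=4)).tolist(),
        }
        out = compare_middle_sizes(data)
        assert out["p_raw"].iloc[0] < 0.01
        assert out["significance"].iloc[0] == "***"

    def test_bonferroni_multiplies_by_comparison_count(self):
        rng = np.random.default_rng(1)
        data = {m: (0.5 + rng.normal(scale=0.05, size=5)).tolist() for m in (1, 3, 5, 7)}
        out = compare_middle_sizes(data, correction="bonferroni")
        for _, row in out.iterrows():
            assert row["p_corrected"] == pytest.approx(min(1.0, 3 * row["p_raw"]))

    def test_single_observation_group_rejected(self):
        with pytest.raises(StatisticsError):
            compare_middle_sizes({1: [0.5], 13: [0.6, 0.7]})
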