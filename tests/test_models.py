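import numpy as np
import pytest

import cohortnet as cn
from cohortnet.models import (
    EPS,
    ModelConfig,
    TrainSchedule,
    _loss_and_grad,
    lill_word_mask,
    make_stream_source,
)
from cohortnet.streams import Annotation, OutputCoding
from tests.conftest import toy_lexicon


@pytest.fixture(scope="module")
def tiny_coding():
    lex = toy_lexicon([(0, 1), (1, 2)], n_talkers=1)
    return lex, OutputCoding.localist(lex)


class TestCountParameters:
    @pytest.mark.parametrize(
        "layers, expected",
        [
            ([512], 1_181_696),
            ([320, 320], 1_313_280),
            ([256, 256, 256], 1_379_328),
            ([192, 192, 192, 192], 1_084_416),
        ],
    )
    def test_printed_counts(self, layers, expected):
        assert cn.count_parameters(layers, input_dim=64) == expected

    def test_minimal(self):
        assert cn.count_parameters([1], input_dim=1) == 12

    def test_matches_constructed_model(self, tiny_coding):
        lex, coding = tiny_coding
        cfg = ModelConfig(coding=coding, layer_sizes=[5, 3], input_dim=4)
        model = cn.build_model(cfg)
        brute = sum(
            layer.W.size + layer.b.size for layer in model.layers
        )  # excludes output head
        assert brute == cn.count_parameters(cfg) == model.core_parameter_count


class TestBceLoss:
    def test_perfect_prediction_near_zero(self):
        y = np.array([[1.0], [0.0]])
        yh = np.array([[1.0 - EPS], [EPS]])
        assert cn.bce_loss(y, yh) == pytest.approx(0.0, abs=1e-5)

    def test_uninformative_is_ln2(self):
        y = np.array([[1.0], [0.0]])
        yh = np.full((2, 1), 0.5)
        assert cn.bce_loss(y, yh) == pytest.approx(np.log(2), rel=1e-12)

    def test_all_zero_targets(self):
        y = np.zeros((3, 4))
        assert cn.bce_loss(y, np.full((3, 4), EPS)) == pytest.approx(0.0, abs=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cn.bce_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestLillLoss:
    def test_c1_reduces_to_bce(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = (rng.random((5, 8)) < 0.3).astype(float)
            yh = rng.uniform(0.01, 0.99, (5, 8))
            mask = rng.random(8) < 0.5
            assert cn.lill_loss(y, yh, 1.0, mask) == pytest.approx(
                cn.bce_loss(y, yh), rel=1e-12
            )

    def test_hand_computed_masked_value(self):
        # masked frame, y=(1,0), yhat=(0.5,0.5), c=2 -> (3/4) ln 2
        y = np.array([[1.0], [0.0]])
        yh = np.full((2, 1), 0.5)
        mask = np.array([True])
        assert cn.lill_loss(y, yh, 2.0, mask) == pytest.approx(0.75 * np.log(2))

    def test_large_c_limit(self):
        y = np.array([[1.0], [0.0]])
        yh = np.full((2, 1), 0.5)
        mask = np.array([True])
        assert cn.lill_loss(y, yh, 1e12, mask) == pytest.approx(
            0.5 * np.log(2), rel=1e-6
        )

    def test_non_increasing_in_c(self):
        rng = np.random.default_rng(1)
        y = (rng.random((6, 10)) < 0.2).astype(float)
        yh = rng.uniform(0.05, 0.95, (6, 10))
        mask = np.ones(10, bool)
        losses = [cn.lill_loss(y, yh, c, mask) for c in (1, 2, 8, 64, 1024)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_unmasked_frames_use_standard_loss(self):
        y = np.array([[1.0], [0.0]])
        yh = np.full((2, 1), 0.5)
        assert cn.lill_loss(y, yh, 64.0, np.array([False])) == pytest.approx(
            cn.bce_loss(y, yh)
        )

    def test_c_below_one_rejected(self):
        with pytest.raises(ValueError):
            cn.lill_loss(np.zeros((1, 1)), np.full((1, 1), 0.5), 0.5)

    def test_gradient_scales_nontarget_by_inv_c(self, tiny_coding):
        # finite-difference check: on masked frames the non-target gradient
        # is (1/c) times the bce gradient; target gradient is unchanged
        lex, coding = tiny_coding
        cfg_b = ModelConfig(coding=coding, layer_sizes=[3], input_dim=4, loss="bce")
        cfg_l = ModelConfig(
            coding=coding, layer_sizes=[3], input_dim=4, loss="lill", c=4.0
        )
        rng = np.random.default_rng(2)
        y = np.zeros((1, 3, 2))
        y[0, :, 0] = 1.0
        yh = rng.uniform(0.2, 0.8, (1, 3, 2))
        mask = np.ones((1, 3), bool)
        _, dz_b = _loss_and_grad(cfg_b, y, yh, mask)
        _, dz_l = _loss_and_grad(cfg_l, y, yh, mask)
        assert np.allclose(dz_l[0, :, 0], dz_b[0, :, 0])  # target terms
        assert np.allclose(dz_l[0, :, 1], dz_b[0, :, 1] / 4.0)  # non-target


class TestLillWordMask:
    def test_guard_excludes_last_100ms(self):
        mask = lill_word_mask([Annotation(0, 0, 5, 30)], 40)
        assert mask[5:20].all() and not mask[20:].any() and not mask[:5].any()

    def test_short_word_empty_mask(self):
        mask = lill_word_mask([Annotation(0, 0, 5, 14)], 20)
        assert not mask.any()


class TestBuildModel:
    def test_localist_output_dim(self, small_lexicon):
        coding = OutputCoding.localist(small_lexicon)
        model = cn.build_model(ModelConfig(coding=coding, layer_sizes=[8]))
        assert model.head.W.shape == (8, len(small_lexicon))
        assert model.head.activation == "sigmoid"

    def test_semantic_linear_head(self, small_lexicon):
        coding = OutputCoding.semantic(small_lexicon, dim=50, seed=0)
        model = cn.build_model(
            ModelConfig(coding=coding, layer_sizes=[8], loss="mse")
        )
        assert model.head.W.shape[1] == 50
        assert model.head.activation == "linear"

    def test_srv_sigmoid_head(self, small_lexicon):
        coding = OutputCoding.srv(small_lexicon, 300, 10, seed=0)
        model = cn.build_model(ModelConfig(coding=coding, layer_sizes=[8]))
        assert model.head.W.shape[1] == 300

    def test_invalid_combinations_raise(self, small_lexicon):
        semantic = OutputCoding.semantic(small_lexicon, 50, 0)
        localist = OutputCoding.localist(small_lexicon)
        with pytest.raises(ValueError):
            ModelConfig(coding=semantic, loss="lill", c=64)
        with pytest.raises(ValueError):
            ModelConfig(coding=semantic, loss="bce")
        with pytest.raises(ValueError):
            ModelConfig(coding=localist, loss="mse")


class TestRunModel:
    def test_segment_concatenation_invariance(self, small_lexicon, small_tokens):
        coding = OutputCoding.localist(small_lexicon)
        model = cn.build_model(ModelConfig(coding=coding, layer_sizes=[6, 4], seed=1))
        stream = cn.build_training_stream(small_tokens, 500, seed=0)
        full_out, full_trace = cn.run_model(model, stream)
        seg_out, seg_trace = cn.run_model(model, stream, segment_frames=120)
        assert np.allclose(full_out, seg_out, atol=1e-12)
        for a, b in zip(full_trace, seg_trace):
            assert np.allclose(a, b, atol=1e-12)

    def test_output_range_and_shapes(self, small_lexicon, small_tokens):
        coding = OutputCoding.localist(small_lexicon)
        model = cn.build_model(ModelConfig(coding=coding, layer_sizes=[6], seed=1))
        stream = cn.build_training_stream(small_tokens, 300, seed=0)
        out, trace = cn.run_model(model, stream)
        assert out.shape == (len(small_lexicon), 300)
        assert np.all((out > 0) & (out < 1))  # sigmoid range
        assert trace[0].shape == (6, 300)


class TestTrain:
    @pytest.fixture(scope="class")
    def trained(self):
        lex = cn.build_lexicon(4, 4, (2, 3), 0.0, seed=0, n_talkers=1)
        from cohortnet.lexicon import synthesize_all_tokens

        tokens = synthesize_all_tokens(lex, 0)
        coding = OutputCoding.localist(lex)
        source = make_stream_source(tokens, coding, snr_db=20.0)
        cfg = ModelConfig(coding=coding, layer_sizes=[16], seed=0)
        model = cn.build_model(cfg)
        sched = TrainSchedule(
            batch_size=4, chunk_frames=100, steps_per_epoch=4, max_epochs=30, lr=5e-3
        )
        history = cn.train(model, source, sched, seed=1)
        return model, history, (source, sched, cfg)

    def test_loss_decreases(self, trained):
        _, history, _ = trained
        assert history["best_loss"] < history["loss"][0]

    def test_weights_restored_to_best(self, trained):
        _, history, _ = trained
        assert history["best_loss"] == min(history["loss"])

    def test_same_seed_identical_history(self, trained):
        _, history, (source, sched, cfg) = trained
        model2 = cn.build_model(cfg)
        history2 = cn.train(model2, source, sched, seed=1)
        assert history["loss"] == history2["loss"]

    def test_missing_targets_rejected(self, small_tokens, small_lexicon):
        stream = cn.build_training_stream(small_tokens, 400, seed=0)
        coding = OutputCoding.localist(small_lexicon)
        model = cn.build_model(ModelConfig(coding=coding, layer_sizes=[4]))
        sched = TrainSchedule(batch_size=2, chunk_frames=50, steps_per_epoch=2,
                              max_epochs=1)
        with pytest.raises(ValueError, match="targets"):
            cn.train(model, stream, sched, seed=0)
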