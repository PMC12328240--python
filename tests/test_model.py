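"""Classifier head: forward pass, masking, loss, training, fine-tuning."""

import numpy as np
import pytest

from dominsert.corpus import LABEL_POSITIVE, LABEL_UNKNOWN, LabelVector
from dominsert.encoding import EncodedSequence, FixtureEmbedder
from dominsert.model import (
    Adam,
    Checkpoint,
    ExperimentalPoint,
    MaskSample,
    ModelError,
    ModelParams,
    TrainConfig,
    TrainingExample,
    fine_tune,
    forward,
    forward_logits,
    init_params,
    load_checkpoint,
    masked_loss,
    points_loss,
    sample_mask,
    save_checkpoint,
    train,
)


def labels_with_positives(L, positives):
    return LabelVector(
        L,
        tuple(
            LABEL_POSITIVE if i in positives else LABEL_UNKNOWN
            for i in range(L)
        ),
    )


def zero_params(D=8, H=4):
    return ModelParams(
        np.zeros((D, H)), np.zeros(H), np.zeros((H, 2)), np.zeros(2)
    )


class TestForward:
    def test_zero_parameters_score_half_everywhere(self):
        enc = EncodedSequence("x", np.random.default_rng(0).normal(size=(7, 8)), "e")
        _, scores = forward(zero_params(), enc)
        np.testing.assert_allclose(scores, 0.5)

    def test_scores_are_probabilities(self):
        rng = np.random.default_rng(1)
        params = init_params(8, 4, seed=1)
        enc = EncodedSequence("x", rng.normal(size=(30, 8)) * 10, "e")
        logits, scores = forward(params, enc)
        assert np.all((scores > 0) & (scores < 1))
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_handrolled_reference_arithmetic(self):
        rng = np.random.default_rng(2)
        D, H, L = 6, 5, 11
        params = init_params(D, H, seed=2)
        X = rng.normal(size=(L, D))
        logits = forward_logits(params, X)
        ref = np.empty((L, 2))
        for i in range(L):  # deliberately scalar reference computation
            h = np.maximum(X[i] @ params.W1 + params.b1, 0.0)
            ref[i] = h @ params.W2 + params.b2
        np.testing.assert_allclose(logits, ref, atol=1e-6)

    def test_dimension_mismatch_raises(self):
        enc = EncodedSequence("x", np.zeros((3, 9)), "e")
        with pytest.raises(ModelError, match="dimension"):
            forward(zero_params(D=8), enc)


class TestSampleMask:
    def test_mask_covers_positives_plus_one_unknown(self):
        labels = labels_with_positives(10, {4, 5, 6})
        mask = sample_mask(labels, np.random.default_rng(0))
        assert mask.positive_indices == (4, 5, 6)
        assert len(mask.indices) == 4
        assert mask.negative_index in {0, 1, 2, 3, 7, 8, 9}

    def test_deterministic_under_fixed_seed(self):
        labels = labels_with_positives(50, {10, 11, 12})
        a = sample_mask(labels, np.random.default_rng(42)).negative_index
        b = sample_mask(labels, np.random.default_rng(42)).negative_index
        assert a == b

    def test_degenerate_all_positive_sequence_rejected(self):
        with pytest.raises(ModelError, match="unknown"):
            sample_mask(labels_with_positives(3, {0, 1, 2}), np.random.default_rng(0))

    def test_negative_sampling_is_uniform(self):
        labels = labels_with_positives(20, {9, 10, 11})
        unknowns = labels.unknown_indices
        rng = np.random.default_rng(7)
        draws = np.array(
            [sample_mask(labels, rng).negative_index for _ in range(5000)]
        )
        counts = np.array([(draws == u).sum() for u in unknowns])
        expected = 5000 / len(unknowns)
        sigma = np.sqrt(5000 * (1 / len(unknowns)) * (1 - 1 / len(unknowns)))
        assert np.all(np.abs(counts - expected) <= 3 * sigma)


def reference_masked_ce(logits, mask):
    """Independent per-position cross-entropy (scalar math, no sharing)."""
    total = 0.0
    for i, t in zip(mask.indices, mask.targets):
        z = logits[i]
        p = np.exp(z[t]) / (np.exp(z[0]) + np.exp(z[1]))
        total += -np.log(p)
    return total / len(mask.indices)


class TestMaskedLoss:
    def test_confident_correct_prediction_has_zero_loss(self):
        labels = labels_with_positives(6, {2, 3})
        mask = MaskSample((2, 3), 5)
        logits = np.zeros((6, 2))
        logits[[2, 3], 1] = 50.0  # tolerant class
        logits[5, 0] = 50.0
        assert masked_loss(logits, labels, mask) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_logits_give_ln2(self):
        labels = labels_with_positives(6, {2, 3})
        mask = MaskSample((2, 3), 5)
        assert masked_loss(np.zeros((6, 2)), labels, mask) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_matches_reference_on_random_cases(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            L = int(rng.integers(4, 40))
            j = int(rng.integers(1, L - 1))
            positives = tuple(p for p in (j - 1, j, j + 1) if 0 <= p < L)
            labels = labels_with_positives(L, set(positives))
            unknowns = labels.unknown_indices
            mask = MaskSample(positives, int(rng.choice(unknowns)))
            logits = rng.normal(size=(L, 2)) * 3
            assert masked_loss(logits, labels, mask) == pytest.approx(
                reference_masked_ce(logits, mask), abs=1e-9
            )

    def test_non_masked_positions_contribute_exactly_zero(self):
        rng = np.random.default_rng(4)
        labels = labels_with_positives(12, {5, 6, 7})
        mask = MaskSample((5, 6, 7), 1)
        logits = rng.normal(size=(12, 2))
        base = masked_loss(logits, labels, mask)
        for i in set(range(12)) - set(mask.indices):
            bumped = logits.copy()
            bumped[i] += 100.0
            assert masked_loss(bumped, labels, mask) == base

    def test_loss_ordering_correct_uniform_wrong(self):
        labels = labels_with_positives(8, {3, 4})
        mask = MaskSample((3, 4), 0)
        correct, wrong = np.zeros((8, 2)), np.zeros((8, 2))
        correct[[3, 4], 1] = 5.0
        correct[0, 0] = 5.0
        wrong[[3, 4], 0] = 5.0
        wrong[0, 1] = 5.0
        uniform = np.zeros((8, 2))
        assert (
            masked_loss(correct, labels, mask)
            < masked_loss(uniform, labels, mask)
            < masked_loss(wrong, labels, mask)
        )

    def test_positive_free_mask_rejected(self):
        with pytest.raises(ModelError, match="positive"):
            MaskSample((), 0)
        with pytest.raises(ModelError, match="collides"):
            MaskSample((0, 1), 1)


def toy_examples(n=12, L=30, D=8, seed=0):
    rng = np.random.default_rng(seed)
    prov = FixtureEmbedder(dimension=D, seed=seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = []
    for i in range(n):
        m = int(rng.integers(3, L - 8))
        seq = "".join(rng.choice(aa, size=L))
        seq = seq[:m] + "GSGSG" + seq[m + 5 :]
        j = m + 3
        labels = labels_with_positives(L, {j - 1, j, j + 1})
        out.append(
            TrainingExample(f"T{i}", prov.embed(seq), labels, prov.encoder_id)
        )
    return out


class TestTraining:
    def test_zero_step_config_rejected(self):
        with pytest.raises(ModelError):
            TrainConfig(total_steps=0)

    def test_same_seed_gives_bitwise_identical_checkpoints(self):
        examples = toy_examples()
        cfg = TrainConfig(total_steps=60, checkpoint_every=30, seed=5)
        (ck_a, log_a) = train(examples, cfg)
        (ck_b, log_b) = train(examples, cfg)
        assert log_a.losses == log_b.losses
        for name in ("W1", "b1", "W2", "b2"):
            np.testing.assert_array_equal(
                getattr(ck_a[-1].params, name), getattr(ck_b[-1].params, name)
            )

    def test_mixed_encoders_fail_before_step_one(self):
        examples = toy_examples()
        rogue = TrainingExample(
            "rogue",
            examples[0].matrix,
            examples[0].labels,
            "some-other-encoder",
        )
        with pytest.raises(ModelError, match="one encoder"):
            train(examples + [rogue], TrainConfig(total_steps=5, seed=0))

    def test_training_reduces_loss_and_reports_validation_auroc(self):
        examples = toy_examples(n=40, seed=2)
        cfg = TrainConfig(
            total_steps=400, checkpoint_every=200, seed=2, hidden_dim=64,
            learning_rate=1e-4,
        )
        checkpoints, log = train(examples[:30], cfg, examples[30:])
        assert np.mean(log.losses[:50]) > np.mean(log.losses[-50:])
        assert checkpoints[-1].validation_auroc is not None
        assert 0.0 <= checkpoints[-1].validation_auroc <= 1.0

    def test_checkpoint_ladder_and_file_round_trip(self, tmp_path):
        examples = toy_examples()
        cfg = TrainConfig(total_steps=50, checkpoint_every=20, seed=1)
        checkpoints, _ = train(examples, cfg, checkpoint_dir=tmp_path)
        assert [c.step for c in checkpoints] == [20, 40, 50]
        loaded = load_checkpoint(tmp_path / "step000050")
        for name in ("W1", "b1", "W2", "b2"):
            np.testing.assert_array_equal(
                getattr(loaded.params, name),
                getattr(checkpoints[-1].params, name),
            )
        assert loaded.step == 50


class TestFineTune:
    def make_points_and_encodings(self, flip=False, seed=0):
        examples = toy_examples(n=10, seed=seed)
        encodings = {ex.accession: ex.matrix for ex in examples}
        points = []
        for ex in examples:
            positives = set(ex.labels.positive_indices)
            for i in sorted(positives):
                points.append(
                    ExperimentalPoint(ex.accession, i, tolerated=not flip)
                )
            for i in list(ex.labels.unknown_indices)[:3]:
                points.append(
                    ExperimentalPoint(ex.accession, i, tolerated=flip)
                )
        return points, encodings, examples

    def test_zero_steps_leave_parameters_unchanged(self):
        points, encodings, _ = self.make_points_and_encodings()
        params = init_params(8, 16, seed=3)
        tuned = fine_tune(
            params, [], encodings, TrainConfig(total_steps=1, seed=0)
        )
        for name in ("W1", "b1", "W2", "b2"):
            np.testing.assert_array_equal(
                getattr(tuned, name), getattr(params, name)
            )

    def test_out_of_range_point_rejected(self):
        points, encodings, _ = self.make_points_and_encodings()
        bad = [ExperimentalPoint(points[0].accession, 10_000, True)]
        with pytest.raises(ModelError, match="outside"):
            fine_tune(
                init_params(8, 16, seed=0),
                bad,
                encodings,
                TrainConfig(total_steps=1, seed=0),
            )

    def test_truth_consistent_points_do_not_hurt_heldout_auroc(self):
        from dominsert.model import _validation_auroc

        train_ex = toy_examples(n=40, seed=6)
        cfg = TrainConfig(
            total_steps=300, checkpoint_every=300, seed=6, hidden_dim=64,
            learning_rate=1e-4,
        )
        checkpoints, _ = train(train_ex[:25], cfg)
        params = checkpoints[-1].params
        held = train_ex[25:]
        before = _validation_auroc(params, held)
        points, encodings, _ = self.make_points_and_encodings(seed=6)
        tuned = fine_tune(
            params,
            points,
            encodings,
            TrainConfig(total_steps=100, seed=6, learning_rate=1e-4),
        )
        after = _validation_auroc(tuned, held)
        assert after >= before - 0.02

    def test_label_flipped_points_loss_decreases_over_first_steps(self):
        """Optimization sanity: the loss on the (flipped) targets falls."""
        points, encodings, _ = self.make_points_and_encodings(flip=True)
        params = init_params(8, 32, seed=4)
        losses = [points_loss(params, points, encodings)]
        current = params
        for step in range(50):
            current = fine_tune(
                current,
                points,
                encodings,
                TrainConfig(total_steps=1, seed=step, learning_rate=1e-3),
            )
            losses.append(points_loss(current, points, encodings))
        assert losses[-1] < losses[0]
        # overwhelmingly monotone step-to-step
        decreasing = sum(b <= a for a, b in zip(losses, losses[1:]))
        assert decreasing >= 45


class TestAdamAndInit:
    def test_initialization_is_seeded_and_fan_in_scaled(self):
        a = init_params(100, 50, seed=8)
        b = init_params(100, 50, seed=8)
        np.testing.assert_array_equal(a.W1, b.W1)
        assert a.W1.std() == pytest.approx(np.sqrt(2 / 100), rel=0.1)
        np.testing.assert_array_equal(a.b1, 0.0)

    def test_adam_moves_against_gradient(self):
        params = init_params(4, 3, seed=0)
        opt = Adam(params, learning_rate=0.1)
        before = params.W1.copy()
        grads = {
            "W1": np.ones_like(params.W1),
            "b1": np.zeros_like(params.b1),
            "W2": np.zeros_like(params.W2),
            "b2": np.zeros_like(params.b2),
        }
        opt.step(params, grads)
        assert np.all(params.W1 < before)
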