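"""Distillation loss oracles, invariances, gradient checks, training loops."""

import math

import numpy as np
import pytest

from vadistill import nn
from vadistill.distill import (
    DistillConfig,
    early_stop,
    feature_hint_loss,
    make_hint_regressor,
    relational_loss,
    rkd_angle_loss,
    rkd_distance_loss,
    soft_target_loss,
    task_loss,
    train_student,
    train_teacher,
)
from vadistill.errors import InvalidArgumentError
from vadistill.nn.tensor import Tensor

from test_nn import numeric_grad


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


class TestTaskLoss:
    def test_logit_zero_label_one(self):
        loss = task_loss(Tensor(np.array([0.0])), np.array([1.0]))
        assert loss.item() == pytest.approx(math.log(2), rel=1e-9)

    def test_saturation(self):
        loss = task_loss(Tensor(np.array([20.0])), np.array([1.0]))
        assert loss.item() < 1e-8

    def test_batch_mean_contract(self):
        single = task_loss(Tensor(np.array([1.3])), np.array([0.0])).item()
        sym = task_loss(Tensor(np.array([1.3, -1.3])), np.array([0.0, 1.0])).item()
        assert sym == pytest.approx(single, rel=1e-9)

    def test_empty_batch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            task_loss(Tensor(np.array([])), np.array([]))


class TestSoftTargetLoss:
    def test_equal_logits_reduce_to_alpha_task(self):
        z = np.array([0.7, -1.2, 2.0])
        y = np.array([1.0, 0.0, 1.0])
        for temp in (1.0, 5.0):
            for alpha in (0.2, 0.9):
                total = soft_target_loss(Tensor(z), z, y, temp, alpha).item()
                expected = alpha * task_loss(Tensor(z), y).item()
                assert total == pytest.approx(expected, abs=1e-12)

    def test_alpha_one_is_task_loss(self):
        z_s, z_t = np.array([0.3, -0.5]), np.array([2.0, 1.0])
        y = np.array([1.0, 0.0])
        total = soft_target_loss(Tensor(z_s), z_t, y, 5.0, 1.0).item()
        assert total == pytest.approx(task_loss(Tensor(z_s), y).item(), abs=1e-12)

    def test_scalar_oracle(self):
        # independent term-by-term evaluation of the Bernoulli-KL formula
        z_t, z_s, y, temp, alpha = 2.0, 0.0, 1.0, 5.0, 0.2
        p_t = sigmoid(z_t / temp)
        p_s = sigmoid(z_s / temp)
        kl = p_t * math.log(p_t / p_s) + (1 - p_t) * math.log((1 - p_t) / (1 - p_s))
        expected = alpha * math.log(2) + (1 - alpha) * temp**2 * kl
        got = soft_target_loss(
            Tensor(np.array([z_s])), np.array([z_t]), np.array([y]), temp, alpha
        ).item()
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(0.5307692802114574, rel=1e-9)  # frozen oracle value

    def test_distill_term_monotone_in_gap(self):
        y = np.array([1.0])
        vals = [
            soft_target_loss(Tensor(np.array([2.0 - gap])), np.array([2.0]), y, 5.0, 0.0).item()
            for gap in (2.0, 1.0, 0.5, 0.1, 0.0)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.0, abs=1e-12)

    def test_bad_temperature(self):
        with pytest.raises(InvalidArgumentError):
            soft_target_loss(Tensor(np.array([0.0])), np.array([0.0]), np.array([1.0]), 0.0)


class TestFeatureHintLoss:
    def test_identity_zero(self):
        guide = Tensor(np.random.default_rng(0).normal(size=(2, 3, 4, 4)))
        assert feature_hint_loss(guide, guide.data.copy(), nn.Identity()).item() == 0.0

    def test_constant_offset_closed_form(self):
        guide = Tensor(np.random.default_rng(1).normal(size=(2, 3, 4, 4)))
        c = 0.7
        loss = feature_hint_loss(guide, guide.data + c, nn.Identity()).item()
        assert loss == pytest.approx(0.5 * c * c, rel=1e-9)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        guide = rng.normal(size=(1, 2, 2, 2))
        hint = rng.normal(size=(1, 2, 2, 2))
        # oracle: brute-force sum over all 8 elements
        expected = 0.5 * np.mean([(guide.ravel()[i] - hint.ravel()[i]) ** 2 for i in range(8)])
        got = feature_hint_loss(Tensor(guide), hint, nn.Identity()).item()
        assert got == pytest.approx(expected, rel=1e-12)

    def test_regressor_resizes_shapes(self):
        rng = np.random.default_rng(3)
        guide = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        hint = rng.normal(size=(2, 6, 16, 16)).astype(np.float32)
        reg = make_hint_regressor(guide.shape, hint.shape, rng)
        loss = feature_hint_loss(guide, hint, reg)
        assert np.isfinite(loss.item())

    def test_shape_mismatch_rejected(self):
        guide = Tensor(np.zeros((1, 2, 4, 4)))
        with pytest.raises(InvalidArgumentError):
            feature_hint_loss(guide, np.zeros((1, 3, 4, 4)), nn.Identity())


def random_similarity(rng, d):
    """Random rotation + uniform scale + translation in R^d."""
    a = rng.normal(size=(d, d))
    q, _ = np.linalg.qr(a)
    return 2.7 * q, rng.normal(size=d) * 3.0


class TestRkdDistance:
    def test_equal_embeddings_zero(self):
        e = np.random.default_rng(0).normal(size=(5, 3))
        assert rkd_distance_loss(Tensor(e), e).item() == pytest.approx(0.0, abs=1e-12)

    def test_similarity_invariance(self):
        rng = np.random.default_rng(1)
        e = rng.normal(size=(6, 4))
        scale_shift = 3.0 * e + 1.5
        assert rkd_distance_loss(Tensor(scale_shift), e).item() == pytest.approx(0.0, abs=1e-9)
        rot, trans = random_similarity(rng, 4)
        assert rkd_distance_loss(Tensor(e @ rot.T + trans), e).item() == pytest.approx(
            0.0, abs=1e-9
        )

    def test_three_point_hand_enumeration(self):
        # student: (0,0), (3,0), (0,4); teacher: (0,0), (1,0), (0,1)
        es = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        et = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        # oracle: enumerate the 3 pairs by hand
        ds = [3.0, 4.0, 5.0]
        dt = [1.0, 1.0, math.sqrt(2)]
        mus, mut = sum(ds) / 3, sum(dt) / 3
        def huber(x):
            return 0.5 * x * x if abs(x) <= 1 else abs(x) - 0.5
        expected = np.mean([huber(s / mus - t / mut) for s, t in zip(ds, dt)])
        got = rkd_distance_loss(Tensor(es), et).item()
        assert got == pytest.approx(expected, rel=1e-7)

    def test_identical_points_zero(self):
        e = np.ones((4, 2))
        assert rkd_distance_loss(Tensor(e), np.random.default_rng(0).normal(size=(4, 2))).item() == 0.0

    def test_batch_of_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rkd_distance_loss(Tensor(np.ones((1, 2))), np.ones((1, 2)))


class TestRkdAngle:
    def test_equal_embeddings_zero(self):
        e = np.random.default_rng(0).normal(size=(5, 3))
        assert rkd_angle_loss(Tensor(e), e).item() == pytest.approx(0.0, abs=1e-10)

    def test_similarity_invariance(self):
        rng = np.random.default_rng(1)
        e = rng.normal(size=(5, 3))
        rot, trans = random_similarity(rng, 3)
        assert rkd_angle_loss(Tensor(e @ rot.T + trans), e).item() == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_vs_collinear_hand_computation(self):
        # teacher: right angle at the origin vertex; student: collinear points
        et = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        es = np.array([[1.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        # oracle: enumerate ordered distinct triples (i, j, k), i != k
        def cosines(e):
            out = {}
            for j in range(3):
                for i in range(3):
                    for k in range(3):
                        if len({i, j, k}) != 3:
                            continue
                        u = e[i] - e[j]
                        v = e[k] - e[j]
                        out[(i, j, k)] = float(
                            u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                        )
            return out
        ct, cs = cosines(et), cosines(es)
        def huber(x):
            return 0.5 * x * x if abs(x) <= 1 else abs(x) - 0.5
        expected = np.mean([huber(cs[k] - ct[k]) for k in ct])
        got = rkd_angle_loss(Tensor(es), et).item()
        assert got == pytest.approx(expected, rel=1e-7)

    def test_batch_of_two_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rkd_angle_loss(Tensor(np.ones((2, 2))), np.ones((2, 2)))


class TestRelationalLoss:
    def test_alpha_one_is_task(self):
        rng = np.random.default_rng(0)
        z = Tensor(rng.normal(size=4))
        es, et = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        got = relational_loss(z, Tensor(es), et, y, alpha=1.0).item()
        assert got == pytest.approx(task_loss(z, y).item(), abs=1e-12)

    def test_similarity_transform_reduces_to_alpha_task(self):
        rng = np.random.default_rng(1)
        z = Tensor(rng.normal(size=5))
        et = rng.normal(size=(5, 3))
        rot, trans = random_similarity(rng, 3)
        es = et @ rot.T + trans
        y = np.ones(5)
        got = relational_loss(z, Tensor(es), et, y, alpha=0.3).item()
        assert got == pytest.approx(0.3 * task_loss(z, y).item(), abs=1e-9)

    def test_composition_oracle(self):
        rng = np.random.default_rng(2)
        z = Tensor(rng.normal(size=4))
        es, et = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        y = np.array([0.0, 1.0, 1.0, 0.0])
        alpha, ld, la = 0.2, 1.0, 2.0
        expected = alpha * task_loss(z, y).item() + (1 - alpha) * (
            ld * rkd_distance_loss(Tensor(es), et).item()
            + la * rkd_angle_loss(Tensor(es), et).item()
        )
        got = relational_loss(z, Tensor(es), et, y, alpha, ld, la).item()
        assert got == pytest.approx(expected, rel=1e-9)


class TestLossGradients:
    """Finite-difference agreement to 1e-4 relative error on 3-sample batches."""

    def _check(self, build, x0, rtol=1e-4):
        x = Tensor(x0.astype(np.float64), requires_grad=True)
        build(x).backward()
        num = numeric_grad(lambda a: build(Tensor(a.astype(np.float64))).item(), x0.copy())
        np.testing.assert_allclose(x.grad, num, rtol=rtol, atol=1e-8)

    def test_task_loss_grad(self):
        y = np.array([1.0, 0.0, 1.0])
        self._check(lambda z: task_loss(z, y), np.array([0.3, -1.0, 2.0]))

    def test_soft_target_grad(self):
        y = np.array([1.0, 0.0, 1.0])
        zt = np.array([2.0, -1.0, 0.5])
        self._check(
            lambda z: soft_target_loss(z, zt, y, 5.0, 0.2), np.array([0.1, -0.4, 1.0])
        )

    def test_feature_hint_grad(self):
        rng = np.random.default_rng(0)
        hint = rng.normal(size=(3, 2, 2, 2))
        self._check(
            lambda g: feature_hint_loss(g, hint, nn.Identity()),
            rng.normal(size=(3, 2, 2, 2)),
        )

    def test_rkd_distance_grad(self):
        rng = np.random.default_rng(1)
        et = rng.normal(size=(3, 4))
        self._check(lambda e: rkd_distance_loss(e, et), rng.normal(size=(3, 4)))

    def test_rkd_angle_grad(self):
        rng = np.random.default_rng(2)
        et = rng.normal(size=(3, 4))
        self._check(lambda e: rkd_angle_loss(e, et), rng.normal(size=(3, 4)))


class TestEarlyStop:
    def test_patience_three_examples(self):
        stop, best = early_stop([1.0, 0.9, 0.91, 0.92, 0.93], patience=3)
        assert stop and best == 2
        stop, best = early_stop([1.0, 0.9, 0.91, 0.92], patience=3)
        assert not stop

    def test_strictly_decreasing_never_stops(self):
        losses = list(np.linspace(1.0, 0.1, 50))
        for i in range(1, 51):
            stop, best = early_stop(losses[:i], patience=3)
            assert not stop and best == i

    def test_immediate_plateau(self):
        stop, best = early_stop([1.0, 1.1, 1.2, 1.3], patience=3)
        assert stop and best == 1

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            early_stop([], patience=3)


class TestConfigValidation:
    def test_bounds(self):
        with pytest.raises(InvalidArgumentError):
            DistillConfig(temperature=0.0)
        with pytest.raises(InvalidArgumentError):
            DistillConfig(alpha=1.5)
        with pytest.raises(InvalidArgumentError):
            DistillConfig(patience=0)
        with pytest.raises(InvalidArgumentError):
            DistillConfig(method="magic")

    def test_defaults_match_protocol(self):
        c = DistillConfig()
        assert (c.temperature, c.alpha, c.learning_rate, c.batch_size) == (5.0, 0.2, 0.001, 32)
        assert (c.max_epochs, c.patience) == (50, 3)


# ---------------------------------------------------------------------------
# training loops on toy features
# ---------------------------------------------------------------------------


def toy_feature_data(n=48, seed=0, signal_gain=2.0):
    """Linearly separable toy 'features': class 1 carries a bright band."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, size=(n, 1, 128, 128)).astype(np.float32)
    y = np.arange(n) % 2
    x[y == 1, 0, 30:50, :] += signal_gain
    split = np.array(["train"] * (n // 2) + ["val"] * (n // 4) + ["test"] * (n - n // 2 - n // 4))
    return {"features": x, "labels": y.astype(np.int64), "split": split}


def auc_of(model, data, split):
    from vadistill.evaluate import auc_score, predict_scores

    scores, labels = predict_scores(model, data, split)
    return auc_score(labels, scores)


@pytest.fixture(scope="module")
def toy_data():
    return toy_feature_data()


@pytest.fixture(scope="module")
def small_teacher(toy_data):
    """student3 standing in for the heavyweight teacher in loop tests."""
    from vadistill.models import build_student

    teacher = build_student(3, seed=1)
    cfg = DistillConfig(method="none", max_epochs=6, seed=1)
    train_student(teacher, teacher, toy_data, cfg)
    return teacher


class TestTrainingLoops:
    def test_student_trains_on_separable_toy(self, toy_data):
        from vadistill.models import build_student

        # small batches: varied batch composition keeps batch-norm honest and
        # lets eval-mode running statistics track the training distribution
        student = build_student(4, seed=0)
        cfg = DistillConfig(method="none", batch_size=8, max_epochs=16, patience=16, seed=0)
        result = train_student(student, student, toy_data, cfg)
        assert result.stopped_epoch <= 16
        assert auc_of(student, toy_data, "train") > 0.99

    def test_alpha_one_trajectory_matches_no_distillation(self, toy_data, small_teacher):
        from vadistill.models import build_student

        curves = {}
        for method in ("none", "soft_target", "relational"):
            student = build_student(4, seed=7)
            cfg = DistillConfig(method=method, alpha=1.0, max_epochs=2, seed=7)
            result = train_student(student, small_teacher, toy_data, cfg)
            curves[method] = (result.train_losses, result.val_losses)
        assert curves["soft_target"] == curves["none"]
        assert curves["relational"] == curves["none"]

    def test_determinism_same_seed(self, toy_data, small_teacher):
        from vadistill.models import build_student

        runs = []
        for _ in range(2):
            student = build_student(4, seed=3)
            cfg = DistillConfig(method="soft_target", max_epochs=2, seed=3)
            runs.append(train_student(student, small_teacher, toy_data, cfg).train_losses)
        assert runs[0] == runs[1]

    def test_teacher_frozen_during_distillation(self, toy_data, small_teacher):
        from vadistill.models import build_student

        before = {k: v.copy() for k, v in small_teacher.state_dict().items()}
        student = build_student(4, seed=5)
        cfg = DistillConfig(method="relational", max_epochs=2, seed=5)
        train_student(student, small_teacher, toy_data, cfg)
        after = small_teacher.state_dict()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])

    def test_feature_based_method_runs(self, toy_data, small_teacher):
        from vadistill.models import build_student

        student = build_student(4, seed=9)
        cfg = DistillConfig(method="feature_based", max_epochs=2, seed=9)
        result = train_student(student, small_teacher, toy_data, cfg)
        assert len(result.train_losses) == result.stopped_epoch
        assert all(np.isfinite(result.train_losses))

    def test_stopped_epoch_bound(self, toy_data):
        from vadistill.models import build_student

        student = build_student(4, seed=11)
        cfg = DistillConfig(method="none", max_epochs=3, seed=11)
        result = train_student(student, student, toy_data, cfg)
        assert result.stopped_epoch <= 3
        assert result.best_epoch <= result.stopped_epoch


class TestTrainTeacher:
    def test_teacher_learns_separable_toy(self, toy_data):
        cfg = DistillConfig(method="none", max_epochs=4, patience=2, seed=0)
        model, result = train_teacher(toy_data, cfg)
        assert result.stopped_epoch <= 4
        assert auc_of(model, toy_data, "train") > 0.99
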