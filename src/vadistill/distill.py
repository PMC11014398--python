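"""Teacher training and the three knowledge-distillation objectives.

Objectives
----------
* soft target: Bernoulli softening of both logits at temperature T, with the
  KL between teacher and student softened distributions scaled by T^2 and
  blended with the task loss by alpha;
* feature hint: an L2 regression of a student "guide" feature map (through a
  learned 1x1-conv regressor, bilinearly resized if needed) onto a frozen
  teacher "hint" map;
* relational: batch-normalized pairwise-distance and triple-wise-angle
  structure matching with a delta=1 Huber penalty.

The training protocol follows the reference recipe: Adam at learning rate
0.001, batch size 32, at most 50 epochs, early stopping with patience 3 on
the validation task loss, T = 5, alpha = 0.2.  Runs are deterministic given
a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import nn
from .errors import InvalidArgumentError
from .models import build_teacher, forward_with_taps
from .nn.tensor import Tensor, no_grad, where

__all__ = [
    "DistillConfig",
    "TrainResult",
    "task_loss",
    "soft_target_loss",
    "feature_hint_loss",
    "make_hint_regressor",
    "rkd_distance_loss",
    "rkd_angle_loss",
    "relational_loss",
    "early_stop",
    "train_teacher",
    "train_student",
]

Method = Literal["soft_target", "feature_based", "relational", "none"]


@dataclass
class DistillConfig:
    method: Method = "soft_target"
    temperature: float = 5.0
    alpha: float = 0.2
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 3
    seed: int = 0
    teacher_tap: str | None = None  # defaults to each model's registered mid tap
    student_tap: str | None = None
    lambda_d: float = 1.0
    lambda_a: float = 2.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise InvalidArgumentError(f"temperature must be > 0, got {self.temperature}")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidArgumentError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.patience < 1:
            raise InvalidArgumentError(f"patience must be >= 1, got {self.patience}")
        if self.method not in ("soft_target", "feature_based", "relational", "none"):
            raise InvalidArgumentError(f"unknown distillation method {self.method!r}")


@dataclass
class TrainResult:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    stopped_epoch: int
    best_state: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if self.val_losses:
            best = min(self.val_losses[: self.stopped_epoch])
            assert abs(self.val_losses[self.best_epoch - 1] - best) < 1e-12


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def task_loss(student_logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from raw logits (numerically stable form)."""
    labels = np.asarray(labels, dtype=student_logits.dtype)
    if labels.size == 0:
        raise InvalidArgumentError("task_loss requires a non-empty batch")
    if student_logits.shape != labels.shape:
        raise InvalidArgumentError("logits and labels must have equal length")
    z = student_logits
    # max(z,0) - z*y + log(1 + exp(-|z|))
    return (z.relu() - z * Tensor(labels) + (-(z.abs())).softplus()).mean()


def soft_target_loss(
    student_logits: Tensor,
    teacher_logits: np.ndarray,
    labels: np.ndarray,
    temperature: float = 5.0,
    alpha: float = 0.2,
) -> Tensor:
    """alpha * BCE + (1 - alpha) * T^2 * KL(Bern(sig(z_t/T)) || Bern(sig(z_s/T))).

    Teacher probabilities are constants (no gradient flows to the teacher).
    """
    if temperature <= 0:
        raise InvalidArgumentError(f"temperature must be > 0, got {temperature}")
    t = float(temperature)
    zt = np.asarray(teacher_logits, dtype=np.float64) / t
    with np.errstate(over="ignore"):
        p_t = np.where(zt >= 0, 1 / (1 + np.exp(-zt)), np.exp(zt) / (1 + np.exp(zt)))
    # teacher entropy term of the KL, constant wrt the student
    from scipy.special import xlogy

    const = xlogy(p_t, p_t) + xlogy(1 - p_t, 1 - p_t)
    zs = student_logits * (1.0 / t)
    # -p_t*log p_s = p_t*softplus(-z_s/T); -(1-p_t)*log(1-p_s) = (1-p_t)*softplus(z_s/T)
    kl = (
        Tensor(const.astype(np.float64))
        + Tensor(p_t) * (-zs).softplus()
        + Tensor(1 - p_t) * zs.softplus()
    )
    distill = kl.mean() * (t * t)
    return task_loss(student_logits, labels) * alpha + distill * (1.0 - alpha)


def make_hint_regressor(
    guide_shape: tuple[int, ...], hint_shape: tuple[int, ...], rng: np.random.Generator
) -> nn.Module:
    """1x1-conv channel regressor plus bilinear resize from guide to hint shape."""
    return nn.Sequential(
        nn.Conv2d(guide_shape[1], hint_shape[1], 1, rng=rng),
        nn.BilinearResize((hint_shape[2], hint_shape[3])),
    )


def feature_hint_loss(guide_map: Tensor, hint_map, regressor: nn.Module) -> Tensor:
    """Half mean squared error between the hint map and the regressed guide map."""
    hint = hint_map if isinstance(hint_map, Tensor) else Tensor(np.asarray(hint_map))
    regressed = regressor(guide_map)
    if regressed.shape != hint.shape:
        raise InvalidArgumentError(
            f"regressed guide shape {regressed.shape} does not match hint {hint.shape}"
        )
    diff = regressed - hint.detach()
    return (diff * diff).mean() * 0.5


def _huber(x: Tensor, delta: float = 1.0) -> Tensor:
    a = x.abs()
    return where(a.data <= delta, x * x * 0.5, a * delta - 0.5 * delta * delta)


def _pairwise_idx(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def rkd_distance_loss(student_emb: Tensor, teacher_emb: np.ndarray) -> Tensor:
    """Huber loss between mean-normalized pairwise distance structures.

    psi(e_i, e_j) = ||e_i - e_j|| / mu with mu the mean pairwise distance in
    the batch, computed separately for student and teacher; the loss averages
    Huber(psi_t, psi_s) over unordered pairs.  Invariant to similarity
    transforms (translation, rotation, uniform scaling) of either embedding
    set.  A batch whose points are all identical yields 0.
    """
    n = student_emb.shape[0]
    if n < 2:
        raise InvalidArgumentError("rkd_distance_loss requires a batch of at least 2")
    et = np.asarray(teacher_emb, dtype=np.float64)
    iu, ju = _pairwise_idx(n)
    d_t = np.linalg.norm(et[iu] - et[ju], axis=1)
    mu_t = d_t.mean()
    es_data = student_emb.data
    if mu_t == 0.0 or np.allclose(es_data, es_data[0]):
        return Tensor(np.zeros(()))
    psi_t = d_t / mu_t

    diff = student_emb[iu] - student_emb[ju]
    d_s = ((diff * diff).sum(axis=1) + 1e-12).sqrt()
    mu_s = d_s.mean()
    psi_s = d_s / mu_s
    return _huber(psi_s - Tensor(psi_t)).mean()


def rkd_angle_loss(student_emb: Tensor, teacher_emb: np.ndarray) -> Tensor:
    """Huber loss between triple-wise angle structures (cosines at vertex j).

    For each ordered triple of distinct indices (i, j, k) the cosine of the
    angle at vertex j is compared between teacher and student; triples with a
    zero-length arm (on either side) contribute 0.  Invariant to similarity
    transforms of either embedding set.
    """
    n = student_emb.shape[0]
    if n < 3:
        raise InvalidArgumentError("rkd_angle_loss requires a batch of at least 3")
    et = np.asarray(teacher_emb, dtype=np.float64)
    diff_t = et[:, None, :] - et[None, :, :]
    norm_t = np.linalg.norm(diff_t, axis=2)
    unit_t = diff_t / np.where(norm_t > 0, norm_t, 1.0)[:, :, None]
    cos_t = np.einsum("ijd,kjd->jik", unit_t, unit_t)

    es = student_emb
    d = es.shape[1]
    diff_s = es.reshape(n, 1, d) - es.reshape(1, n, d)
    norm_sq = (diff_s * diff_s).sum(axis=2, keepdims=True)
    norm_s = (norm_sq + 1e-12).sqrt()
    unit_s = diff_s / norm_s
    # cos_s[j, i, k] = <unit(i - j), unit(k - j)>
    u_j = unit_s.transpose(1, 0, 2)  # (j, i, d)
    cos_s = u_j @ u_j.transpose(0, 2, 1)

    idx = np.arange(n)
    distinct = (
        (idx[None, :, None] != idx[:, None, None])  # i != j
        & (idx[None, None, :] != idx[:, None, None])  # k != j
        & (idx[None, :, None] != idx[None, None, :])  # i != k
    )
    arm_ok_t = (norm_t.T > 0)[:, :, None] & (norm_t.T > 0)[:, None, :]
    ns = np.squeeze(norm_sq.data if isinstance(norm_sq, Tensor) else norm_sq, axis=2)
    arm_ok_s = (ns.T > 1e-24)[:, :, None] & (ns.T > 1e-24)[:, None, :]
    mask = (distinct & arm_ok_t & arm_ok_s).astype(np.float64)
    total = mask.sum()
    if total == 0:
        return Tensor(np.zeros(()))
    penal = _huber(cos_s - Tensor(cos_t)) * Tensor(mask)
    return penal.sum() * (1.0 / total)


def relational_loss(
    student_logits: Tensor,
    student_emb: Tensor,
    teacher_emb: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.2,
    lambda_d: float = 1.0,
    lambda_a: float = 2.0,
) -> Tensor:
    rel = rkd_distance_loss(student_emb, teacher_emb) * lambda_d + rkd_angle_loss(
        student_emb, teacher_emb
    ) * lambda_a
    return task_loss(student_logits, labels) * alpha + rel * (1.0 - alpha)


# ---------------------------------------------------------------------------
# early stopping and training loops
# ---------------------------------------------------------------------------


def early_stop(val_losses: list[float], patience: int = 3) -> tuple[bool, int]:
    """(stop?, best_epoch) after ``patience`` epochs without strict improvement."""
    if not val_losses:
        raise InvalidArgumentError("early_stop requires at least one completed epoch")
    best_idx = int(np.argmin(val_losses))
    best_epoch = best_idx + 1
    return (len(val_losses) - best_epoch) >= patience, best_epoch


def _split_indices(data: dict, split: str) -> np.ndarray:
    idx = np.flatnonzero(data["split"] == split)
    if idx.size == 0:
        raise InvalidArgumentError(f"split {split!r} is empty")
    return idx


def _batched_eval_loss(model: nn.Module, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    model.eval()
    losses, weights = [], []
    with no_grad():
        for lo in range(0, x.shape[0], batch):
            xb = Tensor(x[lo : lo + batch])
            logits = model(xb)
            losses.append(task_loss(logits, y[lo : lo + batch]).item())
            weights.append(xb.shape[0])
    return float(np.average(losses, weights=weights))


def _run_training(
    model: nn.Module,
    extra_params: list,
    data: dict,
    config: DistillConfig,
    batch_loss_fn,
) -> TrainResult:
    train_idx = _split_indices(data, "train")
    val_idx = _split_indices(data, "val")
    x, y = data["features"], data["labels"].astype(np.float64)
    optimizer = nn.Adam(model.parameters() + extra_params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_state: dict = {}
    best_epoch = 0
    stopped_epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        perm = rng.permutation(train_idx)
        epoch_losses, weights = [], []
        for lo in range(0, perm.size, config.batch_size):
            sel = perm[lo : lo + config.batch_size]
            if sel.size < 2:
                continue  # batch-norm needs more than one sample
            xb = Tensor(x[sel])
            loss = batch_loss_fn(xb, y[sel], sel)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
            weights.append(sel.size)
        train_losses.append(float(np.average(epoch_losses, weights=weights)))
        val_losses.append(
            _batched_eval_loss(model, x[val_idx], y[val_idx], config.batch_size)
        )
        stopped_epoch = epoch
        stop, best_epoch = early_stop(val_losses, config.patience)
        if val_losses[-1] < min(val_losses[:-1], default=np.inf):
            best_state = model.state_dict()
        if stop:
            break
    if best_state:
        model.load_state_dict(best_state)
    model.eval()
    return TrainResult(train_losses, val_losses, best_epoch, stopped_epoch, best_state)


def train_teacher(data: dict, config: DistillConfig | None = None) -> tuple[nn.Module, TrainResult]:
    """Train the teacher on featurized data (task loss only); returns best model."""
    config = config or DistillConfig(method="none")
    model = build_teacher(seed=config.seed)

    def batch_loss(xb: Tensor, yb: np.ndarray, sel: np.ndarray) -> Tensor:
        return task_loss(model(xb), yb)

    result = _run_training(model, [], data, config, batch_loss)
    return model, result


def _precompute_teacher(
    teacher: nn.Module, x: np.ndarray, idx: np.ndarray, config: DistillConfig, taps: tuple[str, ...]
):
    """Frozen-teacher outputs on the training rows (eval mode, constants)."""
    teacher.eval()
    logits = np.zeros(x.shape[0], dtype=np.float64)
    tap_maps: dict[int, np.ndarray] = {}
    embeddings: np.ndarray | None = None
    with no_grad():
        return _precompute_loop(teacher, x, idx, config, taps, logits, tap_maps, embeddings)


def _precompute_loop(teacher, x, idx, config, taps, logits, tap_maps, embeddings):
    for lo in range(0, idx.size, config.batch_size):
        sel = idx[lo : lo + config.batch_size]
        z, maps, emb = forward_with_taps(teacher, Tensor(x[sel]), taps)
        logits[sel] = z.data
        if taps:
            m = maps[taps[0]].data
            for i, row in zip(sel, m):
                tap_maps[int(i)] = row
        if embeddings is None:
            embeddings = np.zeros((x.shape[0], emb.shape[1]), dtype=np.float64)
        embeddings[sel] = emb.data
    return logits, tap_maps, embeddings


def train_student(
    student: nn.Module,
    teacher: nn.Module,
    data: dict,
    config: DistillConfig,
) -> TrainResult:
    """Distill a student from a frozen teacher with the configured objective.

    The teacher runs in eval mode and receives no gradient; its logits /
    hint maps / embeddings over the training split are precomputed once.
    Validation is monitored on the task loss only, so runs are comparable
    across methods.
    """
    train_idx = _split_indices(data, "train")
    x, y = data["features"], data["labels"].astype(np.float64)
    teacher_tap = config.teacher_tap or getattr(teacher, "default_tap", None)
    student_tap = config.student_tap or getattr(student, "default_tap", None)

    taps: tuple[str, ...] = ()
    if config.method == "feature_based":
        if teacher_tap not in teacher.tap_names():
            raise InvalidArgumentError(f"teacher tap {teacher_tap!r} is not registered")
        if student_tap not in student.tap_names():
            raise InvalidArgumentError(f"student tap {student_tap!r} is not registered")
        taps = (teacher_tap,)

    need_teacher = config.method in ("soft_target", "feature_based", "relational")
    logits_t = maps_t = emb_t = None
    if need_teacher:
        logits_t, maps_t, emb_t = _precompute_teacher(teacher, x, train_idx, config, taps)

    regressor_params: list = []
    regressor: nn.Module | None = None
    if config.method == "feature_based":
        probe = Tensor(x[train_idx[:2]])
        _, smaps, _ = forward_with_taps(student.eval(), probe, (student_tap,))
        guide_shape = smaps[student_tap].shape
        hint_shape = (1, *maps_t[int(train_idx[0])].shape)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
        regressor = make_hint_regressor(guide_shape, hint_shape, rng)
        regressor_params = regressor.parameters()

    def batch_loss(xb: Tensor, yb: np.ndarray, sel: np.ndarray) -> Tensor:
        if config.method == "none":
            return task_loss(student(xb), yb)
        if config.method == "soft_target":
            logits = student(xb)
            return soft_target_loss(
                logits, logits_t[sel], yb, config.temperature, config.alpha
            )
        if config.method == "feature_based":
            logits, smaps, _ = forward_with_taps(student, xb, (student_tap,))
            hint = np.stack([maps_t[int(i)] for i in sel])
            hint_term = feature_hint_loss(smaps[student_tap], hint, regressor)
            return task_loss(logits, yb) * config.alpha + hint_term * (1.0 - config.alpha)
        # relational
        logits, _, emb = forward_with_taps(student, xb, ())
        return relational_loss(
            logits, emb, emb_t[sel], yb, config.alpha, config.lambda_d, config.lambda_a
        )

    return _run_training(student, regressor_params, data, config, batch_loss)
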