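"""Model zoo: VGG11-style teacher, four inverted-residual students, profiler.

The teacher is a VGG11 layout adapted to 1x128x128 inputs: eight 3x3 conv
layers (64/128/256/256/512/512/512/512) each followed by batch norm and
ReLU, five max-pools, and a fully connected head 8192 -> 4096 -> 4096 -> 1
with dropout on both hidden layers.  Students are 3x3-only, ReLU-only
inverted-residual bottleneck stacks (squeeze-excite where configured) whose
block tables ship in ``configs/students.yaml``, ending in an adaptive
average pool, two 1x1 convolutions and a flatten to a single logit.

The profiler reports parameter counts, multiply-accumulate counts, a
"table" FLOP figure (MACs plus documented elementwise costs — see
:func:`count_macs`), memory as params x 4 bytes, and wall-clock inference
time over repeated single-input trials.
"""

from __future__ import annotations

import importlib.resources
import json
import time
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import nn
from .errors import InvalidArgumentError
from .nn.tensor import Tensor, no_grad

__all__ = [
    "Bottleneck",
    "Teacher",
    "Student",
    "EfficiencyProfile",
    "build_teacher",
    "build_student",
    "build_model",
    "load_student_tables",
    "forward_with_taps",
    "count_parameters",
    "count_macs",
    "profile",
    "MODEL_NAMES",
]

MODEL_NAMES = ("teacher", "student1", "student2", "student3", "student4")

INPUT_SHAPE = (1, 128, 128)


def load_student_tables() -> dict:
    text = (
        importlib.resources.files("vadistill") / "configs" / "students.yaml"
    ).read_text()
    return yaml.safe_load(text)["students"]


class Bottleneck(nn.Module):
    """Inverted residual: 1x1 expand -> 3x3 depthwise -> [SE] -> 1x1 project.

    The expansion conv is omitted when ``exp == in_ch`` (first-block
    convention).  A residual connection is used when stride is 1 and the
    channel count is preserved.
    """

    def __init__(
        self,
        in_ch: int,
        exp_ch: int,
        out_ch: int,
        se: bool,
        stride: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        if exp_ch < in_ch:
            raise InvalidArgumentError("expansion channels must be >= input channels")
        if stride not in (1, 2):
            raise InvalidArgumentError("bottleneck stride must be 1 or 2")
        self.in_ch, self.exp_ch, self.out_ch = in_ch, exp_ch, out_ch
        self.stride = stride
        self.use_residual = stride == 1 and in_ch == out_ch
        if exp_ch != in_ch:
            self.expand = nn.Conv2d(in_ch, exp_ch, 1, bias=False, rng=rng)
            self.expand_bn = nn.BatchNorm2d(exp_ch)
        else:
            self.expand = None
            self.expand_bn = None
        self.depthwise = nn.Conv2d(
            exp_ch, exp_ch, 3, stride=stride, padding=1, groups=exp_ch, bias=False, rng=rng
        )
        self.dw_bn = nn.BatchNorm2d(exp_ch)
        self.se = nn.SqueezeExcite(exp_ch, rng=rng) if se else None
        self.project = nn.Conv2d(exp_ch, out_ch, 1, bias=False, rng=rng)
        self.project_bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        if self.expand is not None:
            h = self.expand_bn(self.expand(h)).relu()
        h = self.dw_bn(self.depthwise(h)).relu()
        if self.se is not None:
            h = self.se(h)
        h = self.project_bn(self.project(h))
        if self.use_residual:
            h = h + x
        return h


class Teacher(nn.Module):
    """Customized VGG11-BN binary classifier for 1x128x128 log-Mel grids."""

    CONV_PLAN = [(1, 64), "M", (64, 128), "M", (128, 256), (256, 256), "M",
                 (256, 512), (512, 512), "M", (512, 512), (512, 512), "M"]

    def __init__(self, seed: int = 0, dropout: float = 0.5):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        stages: list[tuple[str, nn.Module]] = []
        conv_i, pool_i = 0, 0
        for item in self.CONV_PLAN:
            if item == "M":
                pool_i += 1
                stages.append((f"pool{pool_i}", nn.MaxPool2d()))
            else:
                conv_i += 1
                cin, cout = item
                stages.append(
                    (
                        f"conv{conv_i}",
                        nn.Sequential(
                            nn.Conv2d(cin, cout, 3, padding=1, rng=rng),
                            nn.BatchNorm2d(cout),
                            nn.ReLU(),
                        ),
                    )
                )
        self.features = nn.Sequential(*[m for _, m in stages])
        self._stage_names = [name for name, _ in stages]
        self.flatten = nn.Flatten()
        drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self.fc1 = nn.Linear(512 * 4 * 4, 4096, rng=rng)
        self.drop1 = nn.Dropout(dropout, rng=drop_rng)
        self.fc2 = nn.Linear(4096, 4096, rng=rng)
        self.drop2 = nn.Dropout(dropout, rng=drop_rng)
        self.fc3 = nn.Linear(4096, 1, rng=rng)
        self.embedding_dim = 4096
        self.default_tap = "pool3"

    def tap_names(self) -> list[str]:
        return list(self._stage_names)

    def forward_with_taps(self, x: Tensor, taps: tuple[str, ...] = ()):
        unknown = set(taps) - set(self._stage_names)
        if unknown:
            raise InvalidArgumentError(f"unregistered tap name(s): {sorted(unknown)}")
        tap_maps: dict[str, Tensor] = {}
        h = x
        for name, module in zip(self._stage_names, self.features):
            h = module(h)
            if name in taps:
                tap_maps[name] = h
        h = self.flatten(h)
        h = self.drop1(self.fc1(h).relu())
        emb = self.fc2(h).relu()
        logits = self.fc3(self.drop2(emb)).reshape(-1)
        return logits, tap_maps, emb

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_with_taps(x)[0]


class Student(nn.Module):
    """Inverted-residual bottleneck classifier built from a block table."""

    def __init__(self, name: str, table: dict, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        self.name = name
        stem_ch = int(table["stem"])
        self.stem = nn.Sequential(
            nn.Conv2d(1, stem_ch, 3, stride=2, padding=1, bias=False, rng=rng),
            nn.BatchNorm2d(stem_ch),
            nn.ReLU(),
        )
        blocks = []
        in_ch = stem_ch
        for row in table["blocks"]:
            blocks.append(
                Bottleneck(in_ch, int(row["exp"]), int(row["out"]), bool(row["se"]), int(row["stride"]), rng)
            )
            in_ch = int(row["out"])
        self.blocks = blocks
        self.pool = nn.GlobalAvgPool()
        hidden = int(table["head_hidden"])
        self.head1 = nn.Conv2d(in_ch, hidden, 1, rng=rng)
        self.head2 = nn.Conv2d(hidden, 1, 1, rng=rng)
        self.flatten = nn.Flatten()
        self.embedding_dim = hidden
        self._tap_names = ["stem"] + [f"block{i + 1}" for i in range(len(blocks))]
        self.default_tap = f"block{(len(blocks) + 1) // 2}"

    def tap_names(self) -> list[str]:
        return list(self._tap_names)

    def forward_with_taps(self, x: Tensor, taps: tuple[str, ...] = ()):
        unknown = set(taps) - set(self._tap_names)
        if unknown:
            raise InvalidArgumentError(f"unregistered tap name(s): {sorted(unknown)}")
        tap_maps: dict[str, Tensor] = {}
        h = self.stem(x)
        if "stem" in taps:
            tap_maps["stem"] = h
        for i, block in enumerate(self.blocks):
            h = block(h)
            name = f"block{i + 1}"
            if name in taps:
                tap_maps[name] = h
        h = self.pool(h)
        emb = self.head1(h).relu()
        logits = self.flatten(self.head2(emb)).reshape(-1)
        return logits, tap_maps, self.flatten(emb)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_with_taps(x)[0]


def build_teacher(seed: int = 0) -> Teacher:
    return Teacher(seed=seed)


def build_student(variant: int | str, seed: int = 0) -> Student:
    if isinstance(variant, str):
        name = variant if variant.startswith("student") else f"student{variant}"
    else:
        name = f"student{variant}"
    tables = load_student_tables()
    if name not in tables:
        raise InvalidArgumentError(f"unknown student variant {variant!r}")
    return Student(name, tables[name], seed=seed)


def build_model(name: str, seed: int = 0) -> nn.Module:
    if name == "teacher":
        return build_teacher(seed)
    return build_student(name, seed)


def forward_with_taps(model: nn.Module, x: Tensor, taps: tuple[str, ...] = ()):
    """(logits, {tap: feature map}, pre-logit embedding) for teacher or student."""
    return model.forward_with_taps(x, taps)


def count_parameters(model: nn.Module) -> int:
    """Total element count over all trainable arrays."""
    return model.num_parameters()


# ---------------------------------------------------------------------------
# operation counting
# ---------------------------------------------------------------------------

# Documented elementwise costs (ops per element) used by the table convention:
# bias add 1, batch norm 2 (scale+shift), ReLU 1, max-pool 3 (2x2 window
# comparisons), global average pool 1 per input element, sigmoid 4, SE or
# residual elementwise multiply/add 1.
_SIGMOID_OPS = 4


def _count_module(module: nn.Module, shape: tuple[int, int, int]):
    """Return (macs, elemwise_ops, out_shape) for one module at ``shape`` (C,H,W)."""
    c, h, w = shape
    if isinstance(module, nn.Sequential):
        macs = elems = 0
        for sub in module:
            m, e, shape = _count_module(sub, shape)
            macs += m
            elems += e
        return macs, elems, shape
    if isinstance(module, nn.Conv2d):
        oh = (h + 2 * module.padding - module.kernel_size) // module.stride + 1
        ow = (w + 2 * module.padding - module.kernel_size) // module.stride + 1
        out_elems = module.out_channels * oh * ow
        k2 = module.kernel_size**2
        macs = out_elems * k2 * (module.in_channels // module.groups)
        elems = out_elems if module.bias is not None else 0
        return macs, elems, (module.out_channels, oh, ow)
    if isinstance(module, nn.BatchNorm2d):
        return 0, 2 * c * h * w, shape
    if isinstance(module, nn.ReLU):
        return 0, c * h * w, shape
    if isinstance(module, nn.MaxPool2d):
        return 0, 3 * c * (h // 2) * (w // 2), (c, h // 2, w // 2)
    if isinstance(module, nn.GlobalAvgPool):
        return 0, c * h * w, (c, 1, 1)
    if isinstance(module, (nn.Flatten, nn.Dropout, nn.Identity)):
        return 0, 0, shape
    if isinstance(module, nn.SqueezeExcite):
        sq = module.fc1.out_channels
        macs = c * sq + sq * c  # two 1x1 convs on 1x1 maps
        elems = 2 * sq + sq + c + _SIGMOID_OPS * c + c * h * w  # biases, relu, sigmoid, scale
        return macs, elems, shape
    if isinstance(module, Bottleneck):
        macs = elems = 0
        sh = shape
        if module.expand is not None:
            for sub in (module.expand, module.expand_bn, nn.ReLU()):
                m, e, sh = _count_module(sub, sh)
                macs, elems = macs + m, elems + e
        for sub in (module.depthwise, module.dw_bn, nn.ReLU()):
            m, e, sh = _count_module(sub, sh)
            macs, elems = macs + m, elems + e
        if module.se is not None:
            m, e, sh = _count_module(module.se, sh)
            macs, elems = macs + m, elems + e
        for sub in (module.project, module.project_bn):
            m, e, sh = _count_module(sub, sh)
            macs, elems = macs + m, elems + e
        if module.use_residual:
            elems += sh[0] * sh[1] * sh[2]
        return macs, elems, sh
    raise InvalidArgumentError(f"cannot count operations for {type(module).__name__}")


def count_macs(model: nn.Module, input_shape: tuple[int, int, int] = INPUT_SHAPE):
    """(macs, elemwise_ops) for a single input under the documented convention.

    ``macs`` counts conv / fully connected multiply-accumulates only
    (conv: out_elements x k^2 x in_ch / groups; FC: in x out).  The
    elementwise tally adds bias, batch-norm, activation, pooling and
    residual costs at the per-element rates documented above.  The
    table-style FLOP figure is ``macs + elemwise_ops`` and the
    multiplications figure is exactly half of it.
    """
    if isinstance(model, Teacher):
        macs, elems, shape = _count_module(model.features, input_shape)
        feat = shape[0] * shape[1] * shape[2]
        for lin, act in ((model.fc1, True), (model.fc2, True), (model.fc3, False)):
            macs += lin.in_features * lin.out_features
            elems += lin.out_features  # bias
            if act:
                elems += lin.out_features  # relu
        return macs, elems
    if isinstance(model, Student):
        macs, elems, shape = _count_module(model.stem, input_shape)
        for block in model.blocks:
            m, e, shape = _count_module(block, shape)
            macs, elems = macs + m, elems + e
        m, e, shape = _count_module(model.pool, shape)
        elems += e
        for conv, act in ((model.head1, True), (model.head2, False)):
            m, e, shape = _count_module(conv, shape)
            macs, elems = macs + m, elems + e
            if act:
                elems += shape[0]
        return macs, elems
    raise InvalidArgumentError("count_macs supports Teacher and Student models")


@dataclass
class EfficiencyProfile:
    name: str
    params: int
    macs: int
    flops_table: int
    mults_table: float
    memory_mib: float
    avg_inference_s: float
    n_trials: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def profile(model: nn.Module, n_trials: int = 100, name: str | None = None) -> EfficiencyProfile:
    """Resource profile: params, MACs, table FLOPs/mults, memory, timing.

    Inference time is the mean over ``n_trials`` single-input forward passes
    in eval mode (reported, never asserted).
    """
    params = count_parameters(model)
    macs, elems = count_macs(model)
    flops_table = macs + elems
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1,) + INPUT_SHAPE, dtype=np.float32))
    with no_grad():
        model(x)  # warm-up
        start = time.perf_counter()
        for _ in range(n_trials):
            model(x)
        avg = (time.perf_counter() - start) / n_trials
    model.train(was_training)
    return EfficiencyProfile(
        name=name or getattr(model, "name", type(model).__name__.lower()),
        params=params,
        macs=macs,
        flops_table=flops_table,
        mults_table=flops_table / 2,
        memory_mib=params * 4 / 2**20,
        avg_inference_s=avg,
        n_trials=n_trials,
    )
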