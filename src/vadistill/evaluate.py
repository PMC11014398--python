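"""Evaluation harness: F1/AUC, bootstrap CIs, Mann-Whitney U, playback reports.

AUC uses the rank-based (Mann-Whitney) formulation with ties counted one
half.  The U test enumerates all labelings exactly when both samples have at
most 8 observations and falls back to the tie-corrected normal approximation
otherwise.  Bootstrap intervals are percentile intervals of the resampled
median.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidArgumentError
from .nn.tensor import Tensor, no_grad

__all__ = [
    "EvalReport",
    "ComparisonReport",
    "DistanceReport",
    "predict_scores",
    "f1_score",
    "auc_score",
    "evaluate_model",
    "bootstrap_median_ci",
    "mann_whitney_u",
    "playback_report",
    "compare_methods",
]


@dataclass
class EvalReport:
    f1: float
    auc: float
    threshold: float
    n: int


@dataclass
class DistanceReport:
    per_distance_f1: dict[float, float]
    overall_f1: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"distance_m": d, "mean_f1": f} for d, f in sorted(self.per_distance_f1.items())]
        rows.append({"distance_m": "overall", "mean_f1": self.overall_f1})
        return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    scores: dict[str, dict[str, list[float]]]  # metric -> method -> run scores
    medians: dict[str, dict[str, float]]
    cis: dict[str, dict[str, tuple[float, float]]]
    pvalues: dict[str, dict[tuple[str, str], float]]

    def to_frame(self, metric: str = "auc") -> pd.DataFrame:
        rows = []
        for method, med in self.medians[metric].items():
            lo, hi = self.cis[metric][method]
            rows.append({"method": method, "median": med, "ci_lower": lo, "ci_upper": hi})
        return pd.DataFrame(rows)


def predict_scores(model, data: dict, split: str, batch_size: int = 32):
    """Sigmoid scores and labels for one split, in manifest order."""
    idx = np.flatnonzero(data["split"] == split)
    if idx.size == 0:
        raise InvalidArgumentError(f"split {split!r} is absent from the archive")
    model.eval()
    scores = np.empty(idx.size, dtype=np.float64)
    with no_grad():
        for lo in range(0, idx.size, batch_size):
            sel = idx[lo : lo + batch_size]
            logits = model(Tensor(data["features"][sel]))
            scores[lo : lo + sel.size] = logits.sigmoid().data
    return scores, data["labels"][idx].astype(int)


def f1_score(labels, predictions) -> float:
    """2PR / (P + R) on binarized predictions; 0 when precision + recall = 0."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def auc_score(labels, scores) -> float:
    """Rank-based AUC (ties counted 1/2); requires both classes present."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise InvalidArgumentError("auc_score requires both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def evaluate_model(model, data: dict, split: str, threshold: float = 0.5) -> EvalReport:
    scores, labels = predict_scores(model, data, split)
    return EvalReport(
        f1=f1_score(labels, scores >= threshold),
        auc=auc_score(labels, scores),
        threshold=threshold,
        n=labels.size,
    )


def bootstrap_median_ci(
    values, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the sample median."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise InvalidArgumentError("bootstrap_median_ci requires non-empty values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2
    return (
        float(np.quantile(medians, alpha)),
        float(np.quantile(medians, 1 - alpha)),
    )


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, u_a: float) -> float:
    """Two-sided exact p by full enumeration of C(n_a + n_b, n_a) labelings."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    n_a = a.size
    ranks = rankdata(pooled)
    mu = n_a * (n - n_a) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        r = ranks[list(combo)].sum()
        u = r - n_a * (n_a + 1) / 2
        if abs(u - mu) >= abs(u_a - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """U statistic for sample_a and a two-sided p-value.

    Exact enumeration when both sample sizes are <= 8; otherwise a
    tie-corrected normal approximation (with continuity correction).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("mann_whitney_u requires non-empty samples")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    if n_a <= 8 and n_b <= 8:
        return u_a, _exact_mwu_p(a, b, u_a)
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if sigma2 == 0:
        return u_a, 1.0
    z = (abs(u_a - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(z / math.sqrt(2))))
    return u_a, min(p, 1.0)


def playback_report(model, playback_records, data_loader=None, threshold: float = 0.5):
    """Mean F1 per playback distance plus the overall mean across distances.

    ``playback_records`` is the list produced by the dataset builder;
    features are computed on the fly from the recorded WAV paths unless a
    pre-featurized ``data_loader(path) -> (1,128,128) grid`` is supplied.
    """
    from .features import featurize_clip
    from .fixtures import read_wav

    records = list(playback_records)
    if not records:
        raise InvalidArgumentError("playback record list is empty")
    by_distance: dict[float, list] = {}
    for r in records:
        by_distance.setdefault(float(r.distance_m), []).append(r)
    expected = {1.0, 5.0, 10.0, 20.0}
    if set(by_distance) != expected:
        raise InvalidArgumentError(
            f"playback set must cover distances {sorted(expected)}, got {sorted(by_distance)}"
        )
    model.eval()
    per_distance: dict[float, float] = {}
    for distance, recs in sorted(by_distance.items()):
        if data_loader is not None:
            grids = np.stack([data_loader(r.path) for r in recs])
        else:
            grids = np.stack([featurize_clip(read_wav(r.path)).grid[None] for r in recs])
        labels = np.array([r.label for r in recs])
        scores = np.empty(len(recs))
        with no_grad():
            for lo in range(0, len(recs), 32):
                scores[lo : lo + 32] = model(Tensor(grids[lo : lo + 32])).sigmoid().data
        per_distance[distance] = f1_score(labels, scores >= threshold)
    overall = float(np.mean(list(per_distance.values())))
    return DistanceReport(per_distance, overall)


def compare_methods(
    runs_per_method: dict[str, dict[str, list[float]]],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> ComparisonReport:
    """Medians, bootstrap CIs and pairwise U tests across distillation methods.

    ``runs_per_method`` maps metric name ("auc", "f1") to method name to the
    per-run score list; every method needs at least 2 runs.
    """
    medians: dict[str, dict[str, float]] = {}
    cis: dict[str, dict[str, tuple[float, float]]] = {}
    pvalues: dict[str, dict[tuple[str, str], float]] = {}
    for metric, by_method in runs_per_method.items():
        for method, vals in by_method.items():
            if len(vals) < 2:
                raise InvalidArgumentError(
                    f"method {method!r} has fewer than 2 runs for metric {metric!r}"
                )
        medians[metric] = {m: float(np.median(v)) for m, v in by_method.items()}
        cis[metric] = {
            m: bootstrap_median_ci(v, n_boot, level, seed) for m, v in by_method.items()
        }
        pvalues[metric] = {}
        for m1, m2 in itertools.combinations(sorted(by_method), 2):
            _, p = mann_whitney_u(by_method[m1], by_method[m2])
            pvalues[metric][(m1, m2)] = p
    return ComparisonReport(runs_per_method, medians, cis, pvalues)
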