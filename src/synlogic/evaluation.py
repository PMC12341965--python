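"""Benchmarking of ranked synergy predictions against gold-standard labels.

Normalized synergy scores rank ascending (lower = more synergistic), so
curves are computed on the negated score.  ROC AUC uses the tie-averaged
trapezoid (equivalent to the Mann-Whitney probability of correct
ranking).  PR AUC is a step-wise integral with no linear interpolation,
using the conservative (lower-recall-endpoint) precision per step: unlike
average precision, its expectation under a uniformly random ranking
equals the positive prevalence n_pos/(n_pos+n_neg) — the uninformative
random-classifier baseline — while a perfect ranking still scores 1.
AUC differences between two score sets are compared by a stratified
paired bootstrap over the labeled pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .attractors import fixed_points
from .logic import BooleanModel, LinkOperator

Pair = tuple[str, str]


def _canonical(pair) -> Pair:
    a, b = sorted(pair)
    return (a, b)


@dataclass(frozen=True)
class GoldStandard:
    """Observed synergy (positive) / non-synergy (negative) labels per pair."""

    labels: Mapping[Pair, bool]

    def __post_init__(self) -> None:
        vals = list(self.labels.values())
        if not any(vals) or all(vals):
            raise ValueError("gold standard needs >= 1 positive and >= 1 negative")

    @property
    def n_pos(self) -> int:
        return sum(self.labels.values())

    @property
    def n_neg(self) -> int:
        return len(self.labels) - self.n_pos


@dataclass(frozen=True)
class BenchmarkResult:
    roc_points: tuple[tuple[float, float], ...]  # (fpr, tpr)
    pr_points: tuple[tuple[float, float], ...]   # (recall, precision)
    roc_auc: float
    pr_auc: float
    n_pos: int
    n_neg: int


def _aligned(scores: Mapping[Pair, float], gold: GoldStandard
             ) -> tuple[np.ndarray, np.ndarray]:
    scores = {_canonical(p): s for p, s in scores.items()}
    pairs = sorted(p for p in scores if _canonical(p) in
                   {_canonical(q) for q in gold.labels})
    labels = {_canonical(p): v for p, v in gold.labels.items()}
    y, s = [], []
    for p in pairs:
        y.append(bool(labels[p]))
        s.append(scores[p])
    y_arr = np.asarray(y, dtype=bool)
    if not y_arr.any() or y_arr.all():
        raise ValueError("scored pairs cover only one gold-standard class")
    return y_arr, np.asarray(s, dtype=float)


def pr_auc_score(y: np.ndarray, decision: np.ndarray) -> float:
    """Step-wise PR AUC, conservative endpoint, no linear interpolation."""
    prec, rec, _ = precision_recall_curve(y, decision)
    r = rec[::-1]   # ascending recall, starting at 0
    p = prec[::-1]
    return float(np.sum(np.diff(r) * p[:-1]))


def benchmark(scores: Mapping[Pair, float], gold: GoldStandard) -> BenchmarkResult:
    """ROC and PR curves/AUCs of a ranking where lower score = more synergistic."""
    y, s = _aligned(scores, gold)
    ranking = -s  # ascending synergy score -> descending decision function
    fpr, tpr, _ = roc_curve(y, ranking)
    prec, rec, _ = precision_recall_curve(y, ranking)
    return BenchmarkResult(
        roc_points=tuple(zip(fpr.tolist(), tpr.tolist())),
        pr_points=tuple(zip(rec.tolist()[::-1], prec.tolist()[::-1])),
        roc_auc=float(roc_auc_score(y, ranking)),
        pr_auc=pr_auc_score(y, ranking),
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def bootstrap_auc_compare(
    scores_a: Mapping[Pair, float],
    scores_b: Mapping[Pair, float],
    gold: GoldStandard,
    n_resamples: int = 10000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """One-sided paired bootstrap p-values for AUC(A) > AUC(B).

    Resampling is stratified (positives and negatives drawn separately,
    with replacement) so no resample is single-class.  The reported
    p-value per metric is the fraction of resamples in which AUC(A) <=
    AUC(B); small values support A ranking better than B.
    """
    rng = np.random.default_rng() if rng is None else rng
    y, sa = _aligned(scores_a, gold)
    y2, sb = _aligned(scores_b, gold)
    if not np.array_equal(y, y2):
        raise ValueError("score sets must cover the same labeled pairs")
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    worse = {"roc": 0, "pr": 0}
    for _ in range(n_resamples):
        idx = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        yy = y[idx]
        ra, rb = -sa[idx], -sb[idx]
        if roc_auc_score(yy, ra) <= roc_auc_score(yy, rb):
            worse["roc"] += 1
        if pr_auc_score(yy, ra) <= pr_auc_score(yy, rb):
            worse["pr"] += 1
    return {metric: count / n_resamples for metric, count in worse.items()}


def agreement_statistic(models: Sequence[BooleanModel]) -> dict[str, float]:
    """Percent agreement between link-operator choice and stable-state value.

    For each node that carries a link operator, an observation is one
    (model, fixed point) combination; it agrees when the permissive OR-NOT
    co-occurs with state 1 or the restrictive AND-NOT with state 0.  Nodes
    with no link-operator observation are excluded from the report.
    """
    agree: dict[str, int] = {}
    total: dict[str, int] = {}
    for model in models:
        attrs = fixed_points(model)
        if attrs.n == 0:
            raise ValueError("agreement statistic requires models with >= 1 fixed point")
        index = model.node_index
        for eq in model.equations:
            if eq.link_operator is LinkOperator.NONE:
                continue
            i = index[eq.target]
            for fp in attrs.fixed_points:
                total[eq.target] = total.get(eq.target, 0) + 1
                hit = (
                    (eq.link_operator is LinkOperator.OR_NOT and fp[i] == 1)
                    or (eq.link_operator is LinkOperator.AND_NOT and fp[i] == 0)
                )
                if hit:
                    agree[eq.target] = agree.get(eq.target, 0) + 1
    return {
        node: 100.0 * agree.get(node, 0) / count
        for node, count in total.items()
    }
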