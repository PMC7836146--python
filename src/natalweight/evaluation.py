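"""Clinical evaluation: error metrics, birthweight categories, splits, subgroups.

Metrics follow the clinical conventions for birthweight prediction:

* MRE — mean relative error, mean(|yhat - y| / y).
* +/-250 g accuracy — fraction of predictions whose absolute error is
  strictly below 250 g, the clinically accepted tolerance.
* Category accuracy — agreement of the SGA/AGA/LGA class of prediction and
  truth, with SGA < 2500 g and LGA > 4000 g (the boundaries themselves are
  AGA, since both published definitions are strict inequalities).

Subgroup reports break the test set down by parity (first vs multiple
deliveries) and completed delivery week (<39, 39, 40, >40).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "BirthweightCategory",
    "EvaluationReport",
    "mre",
    "accuracy_250",
    "categorize",
    "category_accuracy",
    "split_train_test",
    "kfold",
    "subgroup_report",
    "evaluate",
]

SGA_THRESHOLD_G = 2500.0
LGA_THRESHOLD_G = 4000.0
ACCURACY_TOLERANCE_G = 250.0

PARITY_GROUPS = ("first delivery", "multiple deliveries")
WEEK_GROUPS = ("<39", "39", "40", ">40")


class BirthweightCategory(str, Enum):
    SGA = "SGA"
    AGA = "AGA"
    LGA = "LGA"


def _paired(truth, pred):
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape or truth.ndim != 1 or len(truth) < 1:
        raise ValueError("truth and pred must be equal-length 1-D with n >= 1")
    return truth, pred


def mre(truth, pred) -> float:
    """Mean relative error: mean(|yhat - y| / y); truths must be positive."""
    truth, pred = _paired(truth, pred)
    if np.any(truth <= 0):
        raise ValueError("true birthweights must be positive for MRE")
    return float(np.mean(np.abs((pred - truth) / truth)))


def accuracy_250(truth, pred) -> float:
    """Fraction of predictions with |error| strictly below 250 g."""
    truth, pred = _paired(truth, pred)
    return float(np.mean(np.abs(pred - truth) < ACCURACY_TOLERANCE_G))


def categorize(weight: float) -> BirthweightCategory:
    """SGA below 2500 g, LGA above 4000 g, AGA between (bounds inclusive)."""
    if weight <= 0:
        raise ValueError("birthweight must be positive")
    if weight < SGA_THRESHOLD_G:
        return BirthweightCategory.SGA
    if weight > LGA_THRESHOLD_G:
        return BirthweightCategory.LGA
    return BirthweightCategory.AGA


def category_accuracy(truth, pred) -> float:
    """Fraction of cases whose predicted and true SGA/AGA/LGA classes agree."""
    truth, pred = _paired(truth, pred)
    t = [categorize(v) for v in truth]
    p = [categorize(v) for v in pred]
    return float(np.mean([a == b for a, b in zip(t, p)]))


def split_train_test(items, fraction: float = 0.8, seed: int = 0):
    """Seeded random disjoint/exhaustive split; train size = round(f * n).

    ``items`` may be a Cohort, a sequence, or an integer n (index split).
    """
    idx_train, idx_test = _split_indices(_length(items), fraction, seed)
    return _take(items, idx_train), _take(items, idx_test)


def _length(items):
    return items if isinstance(items, int) else len(items)


def _take(items, idx):
    if isinstance(items, int):
        return idx
    from .records import Cohort

    if isinstance(items, Cohort):
        return items.subset([items.records[i] for i in idx])
    if isinstance(items, np.ndarray):
        return items[idx]
    return [items[i] for i in idx]


def _split_indices(n: int, fraction: float, seed: int):
    if n < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def kfold(items, k: int = 5, seed: int = 0):
    """Seeded k-fold partition; every item validated exactly once."""
    n = _length(items)
    if n < k:
        raise ValueError(f"need at least k={k} items, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        val = np.sort(folds[i])
        tr = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((_take(items, tr), _take(items, val)))
    return out


@dataclass
class SubgroupMetrics:
    n: int
    mre: float | None = None
    accuracy_250: float | None = None


@dataclass
class EvaluationReport:
    n: int
    mre: float
    accuracy_250: float
    category_accuracy: float
    subgroups: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mre": self.mre,
            "accuracy_250": self.accuracy_250,
            "category_accuracy": self.category_accuracy,
            "subgroups": {
                f"{p} | {w}": vars(m) for (p, w), m in self.subgroups.items()
            },
        }

    def format_table(self) -> str:
        """Percentage-formatted subgroup table (one decimal)."""
        lines = [f"{'delivery':<22}{'weeks':<6}{'n':>6}{'MRE %':>9}{'Acc %':>9}"]
        for (p, w), m in self.subgroups.items():
            if m.n == 0:
                lines.append(f"{p:<22}{w:<6}{0:>6}{'-':>9}{'-':>9}")
            else:
                lines.append(f"{p:<22}{w:<6}{m.n:>6}"
                             f"{100 * m.mre:>9.1f}{100 * m.accuracy_250:>9.1f}")
        return "\n".join(lines)


def week_group(delivery_week: float) -> str:
    """Bin by completed week (floor): <39, 39, 40, >40."""
    wk = math.floor(delivery_week)
    if wk < 39:
        return "<39"
    if wk == 39:
        return "39"
    if wk == 40:
        return "40"
    return ">40"


def parity_group(parity: int) -> str:
    return PARITY_GROUPS[0] if parity == 0 else PARITY_GROUPS[1]


def subgroup_report(truth, pred, parity, delivery_week) -> EvaluationReport:
    """Full report: pooled metrics plus parity x delivery-week subgroups."""
    truth, pred = _paired(truth, pred)
    parity = np.asarray(parity)
    delivery_week = np.asarray(delivery_week, dtype=float)
    if not (len(parity) == len(delivery_week) == len(truth)):
        raise ValueError("metadata lists must align with truth/pred")
    subgroups = {}
    for pg in PARITY_GROUPS:
        for wg in WEEK_GROUPS:
            mask = np.array([
                parity_group(int(p)) == pg and week_group(w) == wg
                for p, w in zip(parity, delivery_week)
            ])
            n = int(mask.sum())
            if n == 0:
                subgroups[(pg, wg)] = SubgroupMetrics(n=0)
            else:
                subgroups[(pg, wg)] = SubgroupMetrics(
                    n=n,
                    mre=mre(truth[mask], pred[mask]),
                    accuracy_250=accuracy_250(truth[mask], pred[mask]),
                )
    return EvaluationReport(
        n=len(truth),
        mre=mre(truth, pred),
        accuracy_250=accuracy_250(truth, pred),
        category_accuracy=category_accuracy(truth, pred),
        subgroups=subgroups,
    )


def evaluate(truth, pred) -> dict:
    """Pooled metrics only, as a plain dict."""
    return {
        "n": len(np.asarray(truth)),
        "mre": mre(truth, pred),
        "accuracy_250": accuracy_250(truth, pred),
        "category_accuracy": category_accuracy(truth, pred),
    }
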