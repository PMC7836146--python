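"""Visit-series imputation and feature normalization.

Irregular antenatal visit series are reduced to a fixed 6-point weight-change
vector by least-squares quadratic fitting: the maternal weight curve is fit
with P(t) = a2*t^2 + a1*t + a0 minimising sum_i (P(t_i) - y_i)^2, evaluated
at gestational weeks 20, 25, 30, 35, 37 and 38, and differenced against the
pre-pregnancy weight.  All 16 predictors (and the label, during training)
are then min-max scaled to [-1, 1]:

    y = 2*(x - x_min)/(x_max - x_min) - 1

with the per-feature extrema learned on the training rows only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .records import Cohort, PregnancyRecord, STATIC_PREDICTORS

__all__ = [
    "SERIES_WEEKS",
    "FEATURE_NAMES",
    "QuadraticFit",
    "NormalizationSpec",
    "InsufficientDataError",
    "eligibility_filter",
    "fit_quadratic",
    "impute_weight_series",
    "build_feature_table",
    "fit_normalizer",
    "normalize",
    "denormalize",
]

#: Imputation weeks of the temporal input branch.
SERIES_WEEKS = (20.0, 25.0, 30.0, 35.0, 37.0, 38.0)

#: The 16 model-input feature names: 10 statics + 6 weight-change steps.
FEATURE_NAMES = tuple(STATIC_PREDICTORS) + tuple(
    f"weight_change{int(t)}w" for t in SERIES_WEEKS
)
LABEL_NAME = "birthweight"


class InsufficientDataError(ValueError):
    """Fewer than 3 distinct visit weeks: the quadratic fit is singular."""


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic P(t) = a2*t^2 + a1*t + a0 through a visit series."""

    a2: float
    a1: float
    a0: float
    sse: float
    n_points: int

    def __call__(self, week):
        t = np.asarray(week, dtype=float)
        return self.a2 * t * t + self.a1 * t + self.a0

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a2, self.a1, self.a0)


def fit_quadratic(visits) -> QuadraticFit:
    """Fit the quadratic minimising the sum of squared residuals.

    Closed-form least squares on a centred/scaled week variable (for
    conditioning), converted back to raw-week coefficients.
    """
    weeks = np.array([v.week for v in visits], dtype=float)
    weights = np.array([v.weight for v in visits], dtype=float)
    if len(np.unique(weeks)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct visit weeks, got {len(np.unique(weeks))}"
        )
    # numpy's Polynomial.fit maps weeks into [-1, 1] before solving
    poly = np.polynomial.Polynomial.fit(weeks, weights, deg=2).convert()
    a0, a1, a2 = (list(poly.coef) + [0.0, 0.0])[:3]
    resid = a2 * weeks ** 2 + a1 * weeks + a0 - weights
    return QuadraticFit(a2=float(a2), a1=float(a1), a0=float(a0),
                        sse=float(np.dot(resid, resid)), n_points=len(weeks))


def impute_weight_series(record: PregnancyRecord, fit: QuadraticFit) -> tuple[float, ...]:
    """Weight change at the 6 canonical weeks: P(week) - pre-pregnancy weight."""
    return tuple(float(fit(t) - record.w) for t in SERIES_WEEKS)


def eligibility_filter(cohort: Cohort, scheduled_visits: int = 8,
                       min_visits: int = 5):
    """Exclude records with sparse or heavily missing visit series.

    A record is dropped when more than 20% of its scheduled visits are
    missing, or when it has fewer than ``min_visits`` observed visits (also
    the practical minimum for a stable quadratic fit).  Returns the eligible
    sub-cohort and an exclusion log of (id, reason) pairs.
    """
    eligible = []
    log: list[tuple[str, str]] = []
    for r in cohort:
        n_obs = len(r.visits)
        missing_frac = 1.0 - n_obs / scheduled_visits if scheduled_visits > 0 else 0.0
        if n_obs < min_visits:
            log.append((r.id, f"fewer than {min_visits} observed visits ({n_obs})"))
        elif missing_frac > 0.20:
            log.append((r.id, f"{missing_frac:.0%} of scheduled visits missing"))
        else:
            eligible.append(r)
    return cohort.subset(eligible, note="eligibility_filter"), log


def build_feature_table(cohort: Cohort):
    """Raw (unnormalized) 16-feature table for a cohort.

    Returns (X, y, meta): X an (n, 16) array in FEATURE_NAMES order, y an
    (n,) array of birthweights (NaN where absent), meta a pandas DataFrame
    with id, parity and delivery_week for subgroup reporting.
    """
    import pandas as pd

    rows, labels, meta = [], [], []
    for r in cohort:
        fit = fit_quadratic(r.visits)
        series = impute_weight_series(r, fit)
        rows.append(list(r.static_values()) + list(series))
        labels.append(np.nan if r.birthweight is None else r.birthweight)
        meta.append({"id": r.id, "parity": r.parity, "delivery_week": r.delivery_week})
    X = np.asarray(rows, dtype=float).reshape(len(rows), len(FEATURE_NAMES))
    y = np.asarray(labels, dtype=float)
    return X, y, pd.DataFrame(meta, columns=["id", "parity", "delivery_week"])


@dataclass
class NormalizationSpec:
    """Per-feature (min, max) learned on training rows; constants flagged."""

    names: tuple[str, ...]
    x_min: np.ndarray
    x_max: np.ndarray

    @property
    def constant(self) -> np.ndarray:
        return self.x_max <= self.x_min

    def entry(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.x_min[i]), float(self.x_max[i])

    def to_json(self, path) -> None:
        payload = {
            "names": list(self.names),
            "x_min": [float(v) for v in self.x_min],
            "x_max": [float(v) for v in self.x_max],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "NormalizationSpec":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(names=tuple(d["names"]),
                   x_min=np.asarray(d["x_min"], dtype=float),
                   x_max=np.asarray(d["x_max"], dtype=float))


def fit_normalizer(X: np.ndarray, names=None) -> NormalizationSpec:
    """Column-wise min/max over the training rows only."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with >= 2 training rows")
    if names is None:
        names = tuple(f"f{i}" for i in range(X.shape[1]))
    return NormalizationSpec(names=tuple(names),
                             x_min=X.min(axis=0), x_max=X.max(axis=0))


def normalize(X, spec: NormalizationSpec, clamp: bool = True):
    """Map raw values to [-1, 1]; constant features map to 0 by convention.

    Out-of-range values (test rows beyond the training extrema) are clamped
    to [-1, 1] after the transform.
    """
    X = np.asarray(X, dtype=float)
    span = spec.x_max - spec.x_min
    safe = np.where(spec.constant, 1.0, span)
    Y = 2.0 * (X - spec.x_min) / safe - 1.0
    Y = np.where(spec.constant, 0.0, Y)
    if clamp:
        Y = np.clip(Y, -1.0, 1.0)
    return Y


def denormalize(Y, spec: NormalizationSpec):
    """Inverse transform: x = (y + 1)/2 * (x_max - x_min) + x_min."""
    Y = np.asarray(Y, dtype=float)
    span = spec.x_max - spec.x_min
    X = (Y + 1.0) / 2.0 * span + spec.x_min
    return np.where(spec.constant, spec.x_min, X)


def normalize_scalar(x: float, entry: tuple[float, float], clamp: bool = True) -> float:
    """Single-feature convenience form of :func:`normalize`."""
    lo, hi = entry
    if hi <= lo:
        return 0.0
    y = 2.0 * (x - lo) / (hi - lo) - 1.0
    return float(min(max(y, -1.0), 1.0)) if clamp else float(y)


def denormalize_scalar(y: float, entry: tuple[float, float]) -> float:
    lo, hi = entry
    if hi <= lo:
        return lo
    return float((y + 1.0) / 2.0 * (hi - lo) + lo)
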