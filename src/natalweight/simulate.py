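"""Synthetic antenatal cohort generator.

Emulates the marginal statistics of the study population this package was
built around: 10 static maternal/fetal predictors drawn from truncated
normals, a per-woman quadratic gestational weight curve observed at jittered
irregular visit weeks with measurement noise and missing-completely-at-random
visit loss, and a planted linear ground-truth birthweight model whose
marginal mean/sd match the published cohort (3399.1 +/- 385.8 g).

Correlation structure: the published summary gives only marginals, so a
single latent "fetal size" factor with loadings on the size-related
predictors (w, uh, acp, bpd, acf, fl, hc) and on the weight-gain rate is
planted.  Without it uterine height would carry no information about
birthweight and the fundal-height empirical formula would be meaninglessly
bad as a baseline.

Outcome coefficients are frozen constants derived once by moment-matching
simulation (see scripts/calibrate_outcome.py in the repository).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .records import AntenatalVisit, Cohort, PregnancyRecord, STATIC_PREDICTORS

__all__ = [
    "GeneratorConfig",
    "sample_static",
    "sample_trajectory",
    "sample_birthweight",
    "inject_missingness",
    "generate_cohort",
]

#: Per-predictor (mean, sd, min, max) of the reference population.
DEFAULT_STATIC_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "h": (160.4, 4.8, 144.0, 184.0),
    "w": (54.7, 8.1, 35.0, 163.0),
    "a": (29.3, 4.2, 18.0, 46.0),
    "uh": (34.4, 1.9, 26.0, 73.0),
    "acp": (100.2, 6.0, 73.0, 145.0),
    "fl": (7.2, 0.2, 5.9, 8.2),
    "acf": (34.1, 1.5, 28.9, 41.7),
    "bpd": (9.3, 0.3, 7.9, 10.5),
    "hc": (33.2, 1.0, 29.3, 39.2),
    "afi": (10.6, 3.6, 2.0, 29.6),
}

#: Latent fetal-size factor loading per static predictor (0 = independent).
LATENT_LOADINGS: dict[str, float] = {
    "h": 0.0, "w": 0.5, "a": 0.0, "uh": 0.5, "acp": 0.5,
    "fl": 0.5, "acf": 0.5, "bpd": 0.5, "hc": 0.5, "afi": 0.0,
}

# Quadratic weight-curve rates solving the published week-20 and week-38 mean
# gains (3.5 kg and 13.9 kg over pre-pregnancy weight, with week offset t-4):
#   16 g + 256 c = 3.5 ;  34 g + 1156 c = 13.9
GAIN_RATE_MEAN = 0.049795751633986926   # kg/week
CURVATURE_MEAN = 0.010559640522875817   # kg/week^2

#: Moments of the true total gain at week 38 implied by the trajectory
#: defaults; used to standardize the gain term of the outcome model.
GAIN38_MEAN = 13.90
GAIN38_SD = 2.5270

# Ground-truth outcome model: grams per standard deviation of each predictor
# plus the standardized week-38 gain, intercept 3399.1 g, Gaussian residual.
# Frozen from scripts/calibrate_outcome.py so the marginal birthweight matches
# mean 3399.1 g / sd 385.8 g with planted signal R^2 ~= 0.6.
OUTCOME_BETA: dict[str, float] = {
    "h": 16.8132, "w": 33.6264, "a": 0.0, "uh": 117.6924, "acp": 33.6264,
    "fl": 33.6264, "acf": 84.0660, "bpd": 67.2528, "hc": 50.4396,
    "afi": 16.8132, "gain": 117.6924,
}
OUTCOME_INTERCEPT = 3398.0558
OUTCOME_RESIDUAL_SD = 244.0013
BIRTHWEIGHT_CLIP = (1520.0, 4950.0)


@dataclass
class TrajectoryConfig:
    gain_rate_mean: float = GAIN_RATE_MEAN
    gain_rate_sd: float = 0.03
    curvature_mean: float = CURVATURE_MEAN
    curvature_sd: float = 0.002
    visit_noise_sd: float = 0.4
    gain_latent_loading: float = 0.4


@dataclass
class VisitScheduleConfig:
    visits_per_pregnancy: int = 8
    first_week: float = 8.0
    week_jitter_sd: float = 0.7


@dataclass
class OutcomeConfig:
    coefficients: dict = field(default_factory=lambda: dict(OUTCOME_BETA))
    intercept: float = OUTCOME_INTERCEPT
    residual_sd: float = OUTCOME_RESIDUAL_SD
    clip: tuple[float, float] = BIRTHWEIGHT_CLIP


@dataclass
class GeneratorConfig:
    n: int = 1000
    seed: int = 0
    static_params: dict = field(default_factory=lambda: dict(DEFAULT_STATIC_PARAMS))
    latent_loadings: dict = field(default_factory=lambda: dict(LATENT_LOADINGS))
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    visit_schedule: VisitScheduleConfig = field(default_factory=VisitScheduleConfig)
    missing_rate: float = 0.10
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    parity_prob: float = 0.4
    delivery_week_dist: tuple[float, float, float, float] = (39.4, 0.9, 37.0, 44.0)

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for name, (_, sd, lo, hi) in self.static_params.items():
            if sd < 0:
                raise ValueError(f"sd for {name} must be >= 0")
            if hi < lo:
                raise ValueError(f"max < min for {name}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delivery_week_dist"] = list(self.delivery_week_dist)
        d["outcome"]["clip"] = list(self.outcome.clip)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "trajectory" in d and isinstance(d["trajectory"], dict):
            d["trajectory"] = TrajectoryConfig(**d["trajectory"])
        if "visit_schedule" in d and isinstance(d["visit_schedule"], dict):
            d["visit_schedule"] = VisitScheduleConfig(**d["visit_schedule"])
        if "outcome" in d and isinstance(d["outcome"], dict):
            oc = dict(d["outcome"])
            if "clip" in oc:
                oc["clip"] = tuple(oc["clip"])
            d["outcome"] = OutcomeConfig(**oc)
        if "delivery_week_dist" in d:
            d["delivery_week_dist"] = tuple(d["delivery_week_dist"])
        if "static_params" in d:
            d["static_params"] = {k: tuple(v) for k, v in d["static_params"].items()}
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _truncated_draw(rng, mean, sd, lo, hi, shared=0.0, loading=0.0, max_tries=200):
    """One draw of mean + sd*(loading*shared + sqrt(1-loading^2)*eps) in [lo, hi].

    Rejection on the idiosyncratic part preserves the latent component; falls
    back to clamping if the window is unreachable (degenerate configs).
    """
    if hi <= lo:
        return lo
    resid_scale = math.sqrt(max(0.0, 1.0 - loading * loading))
    base = mean + sd * loading * shared
    if sd == 0.0:
        return min(max(base, lo), hi)
    for _ in range(max_tries):
        x = base + sd * resid_scale * rng.standard_normal()
        if lo <= x <= hi:
            return x
    return min(max(base, lo), hi)


def sample_static(config: GeneratorConfig, rng: np.random.Generator):
    """Draw the 10 static predictors; returns (values dict, latent factor z).

    Size-related predictors share the latent factor z so that e.g. uterine
    height is genuinely informative about the planted birthweight.
    """
    z = rng.standard_normal()
    values = {}
    for name in STATIC_PREDICTORS:
        mean, sd, lo, hi = config.static_params[name]
        lam = config.latent_loadings.get(name, 0.0)
        values[name] = _truncated_draw(rng, mean, sd, lo, hi, shared=z, loading=lam)
    return values, z


def true_weight_curve(w: float, g: float, c: float, week):
    """True maternal weight at gestational week t: w + g*(t-4) + c*(t-4)^2."""
    t = np.asarray(week, dtype=float) - 4.0
    return w + g * t + c * t * t


def sample_trajectory(static: dict, config: GeneratorConfig, rng: np.random.Generator,
                      delivery_week: float, z: float = 0.0):
    """Sample a woman's visit series; returns (visits, (g, c)).

    The gain rate g loads on the latent factor z; visits are scheduled
    evenly from first_week to just before delivery, jittered, observed with
    Gaussian noise, then thinned by MCAR missingness.
    """
    tr = config.trajectory
    lam = tr.gain_latent_loading
    g = tr.gain_rate_mean + tr.gain_rate_sd * (
        lam * z + math.sqrt(max(0.0, 1.0 - lam * lam)) * rng.standard_normal()
    )
    c = tr.curvature_mean + tr.curvature_sd * rng.standard_normal()

    vs = config.visit_schedule
    n_sched = int(vs.visits_per_pregnancy)
    last = max(vs.first_week + 1.0, delivery_week - 0.3)
    weeks = np.linspace(vs.first_week, last, n_sched)
    weeks = weeks + vs.week_jitter_sd * rng.standard_normal(n_sched)
    weeks = np.clip(weeks, 4.5, min(delivery_week, 44.5))
    weeks = np.sort(weeks)
    # enforce strictly increasing weeks (jitter can cause collisions)
    for i in range(1, n_sched):
        if weeks[i] <= weeks[i - 1]:
            weeks[i] = weeks[i - 1] + 0.05

    truth = true_weight_curve(static["w"], g, c, weeks)
    observed = truth + tr.visit_noise_sd * rng.standard_normal(n_sched)
    observed = np.clip(observed, 30.0, 200.0)
    visits = tuple(AntenatalVisit(float(t), float(x)) for t, x in zip(weeks, observed))
    visits = inject_missingness(visits, config.missing_rate, rng)
    return visits, (g, c)


def sample_birthweight(static: dict, trajectory_truth: tuple[float, float],
                       config: GeneratorConfig, rng: np.random.Generator) -> float:
    """Planted-outcome draw in grams: linear in standardized predictors + gain."""
    oc = config.outcome
    g, c = trajectory_truth
    gain38 = g * 34.0 + c * 34.0 ** 2
    lin = oc.intercept
    for name in STATIC_PREDICTORS:
        mean, sd, _, _ = config.static_params[name]
        if sd > 0:
            lin += oc.coefficients.get(name, 0.0) * (static[name] - mean) / sd
    lin += oc.coefficients.get("gain", 0.0) * (gain38 - GAIN38_MEAN) / GAIN38_SD
    bw = lin + oc.residual_sd * rng.standard_normal()
    lo, hi = oc.clip
    return float(min(max(bw, lo), hi))


def inject_missingness(visits: tuple[AntenatalVisit, ...], missing_rate: float,
                       rng: np.random.Generator) -> tuple[AntenatalVisit, ...]:
    """Drop each visit independently with probability missing_rate (MCAR)."""
    if missing_rate <= 0.0:
        return tuple(visits)
    keep = rng.random(len(visits)) >= missing_rate
    return tuple(v for v, k in zip(visits, keep) if k)


def sample_delivery_week(config: GeneratorConfig, rng: np.random.Generator) -> float:
    mean, sd, lo, hi = config.delivery_week_dist
    return _truncated_draw(rng, mean, sd, lo, hi)


def generate_cohort(config: GeneratorConfig, return_truth: bool = False):
    """Generate a full cohort; bit-reproducible for equal (config, seed).

    With ``return_truth`` also returns a pandas DataFrame of the per-record
    latent truth (latent factor, gain rate, curvature, true week-38 gain) for
    calibration and learnability checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records = []
    truth_rows = []
    for i in range(config.n):
        static, z = sample_static(config, rng)
        delivery_week = sample_delivery_week(config, rng)
        visits, (g, c) = sample_trajectory(static, config, rng, delivery_week, z=z)
        bw = sample_birthweight(static, (g, c), config, rng)
        parity = int(rng.random() < config.parity_prob)
        records.append(PregnancyRecord(
            id=f"syn{i:06d}",
            **{k: float(v) for k, v in static.items()},
            visits=visits,
            parity=parity,
            delivery_week=float(delivery_week),
            birthweight=bw,
        ))
        if return_truth:
            truth_rows.append({
                "id": f"syn{i:06d}", "z": z, "g": g, "c": c,
                "gain38": g * 34.0 + c * 34.0 ** 2,
                "weight38": true_weight_curve(static["w"], g, c, 38.0),
            })
    cohort = Cohort(records=records, provenance={
        "source": "natalweight.simulate",
        "seed": config.seed,
        "config_hash": config.config_hash(),
    })
    if return_truth:
        import pandas as pd

        return cohort, pd.DataFrame(truth_rows)
    return cohort
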