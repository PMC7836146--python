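"""One-off moment-matching derivation of the planted outcome coefficients.

Scales a fixed set of relative predictor weights so that the simulated
birthweight marginal hits mean 3399.1 g / sd 385.8 g with planted signal
R^2 ~= 0.6 (systematic sd = sqrt(0.6)*385.8, residual sd = sqrt(0.4)*385.8).
The printed constants are frozen into natalweight.simulate.OUTCOME_BETA.

Run from the repository root:  python scripts/calibrate_outcome.py
"""

import numpy as np

from natalweight import simulate
from natalweight.records import STATIC_PREDICTORS

TARGET_MEAN = 3399.1
TARGET_SD = 385.8
TARGET_R2 = 0.6

# Relative weights (unitless): size-related predictors and the gain carry
# most of the signal, age none.
BASE_WEIGHTS = {
    "h": 0.05, "w": 0.10, "a": 0.00, "uh": 0.35, "acp": 0.10,
    "fl": 0.10, "acf": 0.25, "bpd": 0.20, "hc": 0.15, "afi": 0.05,
    "gain": 0.35,
}


def main(n: int = 200_000, seed: int = 12345) -> None:
    cfg = simulate.GeneratorConfig(n=n, seed=seed)
    cfg.outcome.coefficients = dict(BASE_WEIGHTS)
    cfg.outcome.intercept = 0.0
    cfg.outcome.residual_sd = 0.0
    cfg.outcome.clip = (-1e9, 1e9)
    cohort, truth = simulate.generate_cohort(cfg, return_truth=True)
    lin = np.array([r.birthweight for r in cohort])  # pure systematic part

    sys_sd_target = np.sqrt(TARGET_R2) * TARGET_SD
    resid_sd = np.sqrt(1.0 - TARGET_R2) * TARGET_SD
    scale = sys_sd_target / lin.std()
    intercept = TARGET_MEAN - scale * lin.mean()

    print(f"base systematic sd  : {lin.std():.4f}")
    print(f"scale factor        : {scale:.6f}")
    print(f"OUTCOME_INTERCEPT   = {intercept:.4f}")
    print(f"OUTCOME_RESIDUAL_SD = {resid_sd:.4f}")
    print("OUTCOME_BETA = {")
    for k, v in BASE_WEIGHTS.items():
        print(f'    "{k}": {v * scale:.4f},')
    print("}")

    # verification pass with the scaled model
    cfg2 = simulate.GeneratorConfig(n=n, seed=seed + 1)
    cfg2.outcome.coefficients = {k: v * scale for k, v in BASE_WEIGHTS.items()}
    cfg2.outcome.intercept = intercept
    cfg2.outcome.residual_sd = resid_sd
    cohort2 = simulate.generate_cohort(cfg2)
    bw = np.array([r.birthweight for r in cohort2])
    print(f"realized mean {bw.mean():.2f}  sd {bw.std():.2f}  "
          f"min {bw.min():.0f} max {bw.max():.0f}")


if __name__ == "__main__":
    main()
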