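"""Agreement metrics between predicted and reference vitals.

All formulas use the population (divide-by-n) convention:

* MAE   = (1/n) sum |e_i|
* RMSE  = sqrt((1/n) sum e_i^2)
* R     = 1 - MSE(model) / MSE(baseline), the skill of the model against the
  constant mean-of-truth predictor (a coefficient-of-determination form);
  Pearson r is reported alongside since the two are often conflated.
* 2SD   = 2 * population SD of the error
* LOA   = bias +/- 1.96 * SD(error), the Bland-Altman 95 % limits of
  agreement, with the (mean, difference) point cloud for plotting.

where e_i = pred_i - truth_i.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvalReport",
    "mae",
    "rmse",
    "r_skill",
    "pearson_r",
    "two_sd",
    "limits_of_agreement",
    "evaluate",
]

LOA_MULTIPLIER = 1.96   # 95 % limits of agreement


def _check(pred, truth, min_n: int = 1):
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.size != truth.size:
        raise ValueError(f"length mismatch: {pred.size} vs {truth.size}")
    if pred.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {pred.size}")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("non-finite values in pred/truth")
    return pred, truth


def mae(pred, truth) -> float:
    pred, truth = _check(pred, truth)
    return float(np.mean(np.abs(pred - truth)))


def rmse(pred, truth) -> float:
    pred, truth = _check(pred, truth)
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def r_skill(pred, truth) -> float:
    """1 - MSE(model)/MSE(baseline); baseline predicts mean(truth)."""
    pred, truth = _check(pred, truth)
    base = np.mean((truth - np.mean(truth)) ** 2)
    if base == 0.0:
        raise ValueError("constant truth: baseline MSE is zero, R undefined")
    return float(1.0 - np.mean((pred - truth) ** 2) / base)


def pearson_r(pred, truth) -> float:
    pred, truth = _check(pred, truth, min_n=2)
    sp, st = np.std(pred), np.std(truth)
    if sp == 0.0 or st == 0.0:
        return float("nan")
    return float(np.mean((pred - pred.mean()) * (truth - truth.mean())) / (sp * st))


def two_sd(pred, truth, *, sample: bool = False) -> float:
    """Twice the SD of the error (population by default; ddof=1 if sample)."""
    pred, truth = _check(pred, truth, min_n=2)
    err = pred - truth
    return float(2.0 * np.std(err, ddof=1 if sample else 0))


def limits_of_agreement(pred, truth, *, sample: bool = False):
    """95 % Bland-Altman limits: (loa_low, loa_high, points DataFrame).

    Points pair the mean of (pred, truth) with the error, one row per case.
    """
    pred, truth = _check(pred, truth, min_n=3)
    err = pred - truth
    bias = float(np.mean(err))
    sd = float(np.std(err, ddof=1 if sample else 0))
    lo = bias - LOA_MULTIPLIER * sd
    hi = bias + LOA_MULTIPLIER * sd
    points = pd.DataFrame({"mean": (pred + truth) / 2.0, "diff": err})
    return lo, hi, points


@dataclass
class EvalReport:
    """The full metric suite for one prediction/truth pairing."""

    mae: float
    rmse: float
    r_skill: float
    pearson_r: float
    bias: float
    sd_error: float
    two_sd: float
    loa_low: float
    loa_high: float
    n: int
    units: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def evaluate(pred, truth, units: str = "") -> EvalReport:
    """Compute every metric at once (population SD convention)."""
    pred, truth = _check(pred, truth, min_n=3)
    err = pred - truth
    lo, hi, _ = limits_of_agreement(pred, truth)
    return EvalReport(
        mae=mae(pred, truth),
        rmse=rmse(pred, truth),
        r_skill=r_skill(pred, truth),
        pearson_r=pearson_r(pred, truth),
        bias=float(np.mean(err)),
        sd_error=float(np.std(err)),
        two_sd=two_sd(pred, truth),
        loa_low=lo,
        loa_high=hi,
        n=int(pred.size),
        units=units,
    )
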