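"""Five-metric validation of a fitted kinetic law.

An (observed, predicted) concentration pairing is scored with the
metrics conventional in predictive modelling of food and microbial
kinetics:

* R² — coefficient of determination on the original concentration scale,
  ``1 − SSres/SStot``;
* accuracy factor ``Af = 10^(Σ|log10(pred_i/obs_i)|/n)`` — the average
  factor by which predictions differ from observations (1 = perfect,
  always ≥ 1);
* bias factor ``Bf = 10^(Σ log10(pred_i/obs_i)/n)`` — the systematic
  over- (>1) or under- (<1) prediction factor;
* SS — sum of squared differences of the *natural* logarithms of
  observed and predicted values;
* RMSE — root mean squared error, ``sqrt(Σ(obs_i − pred_i)²/n)``,
  in concentration units (µg/ml).

Af, Bf and SS are ratio/log metrics and are undefined as soon as any
observed or predicted value is non-positive; in that case they are
reported as not-computable markers (``None``) while R² and RMSE are
still returned.  This mirrors summary tables in the field that print
"/" for exactly those cells where a fitted line crosses zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GofReport:
    """The five validation metrics for one (observed, predicted) pairing.

    ``r_squared`` is NaN when the observations have zero variance (R²
    undefined).  ``af``, ``bf`` and ``ss`` are ``None`` when
    ``log_metrics_defined`` is False.
    """

    r_squared: float
    rmse: float
    af: float | None
    bf: float | None
    ss: float | None
    log_metrics_defined: bool

    def __post_init__(self) -> None:
        if self.log_metrics_defined:
            if self.af is None or self.bf is None or self.ss is None:
                raise ValueError("log metrics flagged defined but missing")
            # Af >= max(Bf, 1/Bf) is an algebraic identity of the definitions
            # (mean of |x| >= |mean of x|); tolerate only rounding noise.
            if self.af < max(self.bf, 1.0 / self.bf) - 1e-9:
                raise ValueError("Af must be >= max(Bf, 1/Bf)")
        elif not (self.af is None and self.bf is None and self.ss is None):
            raise ValueError("log metrics must all be None when not computable")
        if self.rmse < 0:
            raise ValueError("RMSE must be non-negative")


def compute_gof(observed, predicted) -> GofReport:
    """Score predictions against observations with the five metrics.

    Parameters
    ----------
    observed, predicted
        Equal-length sequences of concentrations (µg/ml), n ≥ 2.

    Returns
    -------
    GofReport
        R² and RMSE always; Af/Bf/SS only when every observed and
        predicted value is strictly positive.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.size} observed vs {pred.size} predicted")
    n = obs.size
    if n < 2:
        raise ValueError("at least 2 points required")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("observed and predicted must be finite")

    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        r_squared = float("nan")
    else:
        r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot

    if np.all(obs > 0) and np.all(pred > 0):
        log10_ratio = np.log10(pred / obs)
        af = float(10.0 ** np.mean(np.abs(log10_ratio)))
        bf = float(10.0 ** np.mean(log10_ratio))
        ss = float(np.sum((np.log(obs) - np.log(pred)) ** 2))
        return GofReport(r_squared, rmse, af, bf, ss, log_metrics_defined=True)
    return GofReport(r_squared, rmse, None, None, None, log_metrics_defined=False)


def r_squared_of(observed, predicted) -> float:
    """Plain coefficient of determination (NaN for zero-variance observed)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return math.nan
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
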