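"""Candidate kinetic laws for product formation in heated sugar systems.

After the induction period of non-enzymatic browning, the concentration
of a degradation product typically grows (or the reactant decays)
following one of three empirical laws in the heating time ``t``:

* zero order:           ``C(t) = C0 + k0·t``
* first order (exp.):   ``C(t) = C0·exp(k1·t)``
* logarithmic:          ``C(t) = C0 + k2·ln t``

``C0`` is the initial content (µg/ml); the rate constants carry units
µg·ml⁻¹·h⁻¹ (k0), h⁻¹ (k1) and µg/ml per ln-hour (k2).  The induction
period itself is handled by restricting the fitting window's start time
rather than by an explicit lag term.

Fits are ordinary least squares on the linearising transform of each
law (C vs t; ln C vs t; C vs ln t), which makes them closed-form and
exactly reproducible; goodness of fit is always evaluated back on the
original concentration scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import stats

from .goodness_of_fit import GofReport, compute_gof, r_squared_of
from .panel import TimeSeries


class ModelForm(str, enum.Enum):
    """The three admitted kinetic laws."""

    ZERO_ORDER = "zero_order"
    FIRST_ORDER_EXP = "first_order_exp"
    LOGARITHMIC = "logarithmic"


#: Simplicity order used as the final tie-break in model selection.
FORM_ORDER = (ModelForm.ZERO_ORDER, ModelForm.FIRST_ORDER_EXP, ModelForm.LOGARITHMIC)

AGGREGATIONS = ("replicate_means", "pooled")


class KineticDomainError(ValueError):
    """A kinetic law was evaluated or fitted outside its domain."""


class NonPositiveConcentrationError(ValueError):
    """Exponential-law fitting requires strictly positive concentrations."""


@dataclass(frozen=True)
class KineticParams:
    """Parameters of one kinetic law: the form, C0 (µg/ml) and rate constant k."""

    form: ModelForm
    c0: float
    k: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c0) and math.isfinite(self.k)):
            raise ValueError("c0 and k must be finite")
        if self.form is ModelForm.FIRST_ORDER_EXP and self.c0 <= 0:
            raise ValueError("first_order_exp requires c0 > 0")


@dataclass(frozen=True)
class FitWindow:
    """Closed time window [t_start, t_end] (hours) over which a law is fitted."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_start < self.t_end <= 6.0):
            raise ValueError("window must satisfy 0 <= t_start < t_end <= 6")

    def contains(self, times: np.ndarray) -> np.ndarray:
        return (times >= self.t_start) & (times <= self.t_end)

    def __str__(self) -> str:
        return f"{self.t_start:g}-{self.t_end:g} h"


@dataclass
class KineticFit:
    """A fitted kinetic law over a window, with its goodness-of-fit report.

    ``window`` is the *effective* window — the span of the points the
    fit actually used, which may be narrower than the requested window
    when grid times or censoring leave gaps at its edges.  ``fittable``
    is False (with a ``reason``) when the window leaves fewer than 3
    usable points or a degenerate time grid; ``params`` and ``gof`` are
    then None and ``window`` is the requested window.
    """

    params: KineticParams | None
    window: FitWindow
    n_points: int
    gof: GofReport | None
    fittable: bool
    reason: str | None = None
    aggregation: str = "replicate_means"
    condition: tuple[str, str, float] | None = None

    def __post_init__(self) -> None:
        if self.fittable:
            if self.n_points < 3:
                raise ValueError("fittable fits require n_points >= 3")
            if self.params is None or self.gof is None:
                raise ValueError("fittable fits must carry params and gof")
        elif self.gof is not None:
            raise ValueError("unfittable results carry no gof")

    @property
    def form(self) -> ModelForm | None:
        return None if self.params is None else self.params.form


def predict(params: KineticParams, times) -> np.ndarray:
    """Evaluate the kinetic law at ``times`` (hours) → concentrations (µg/ml)."""
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if params.form is ModelForm.ZERO_ORDER:
        return params.c0 + params.k * t
    if params.form is ModelForm.FIRST_ORDER_EXP:
        return params.c0 * np.exp(params.k * t)
    # logarithmic
    bad = t[t <= 0]
    if bad.size:
        raise KineticDomainError(
            f"logarithmic law undefined at t <= 0 (offending times: {bad.tolist()})"
        )
    return params.c0 + params.k * np.log(t)


def _window_points(
    series: TimeSeries, window: FitWindow, aggregation: str
) -> tuple[np.ndarray, np.ndarray]:
    """Usable (t, C) pairs inside the window, aggregated as requested."""
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    mask = series.usable_mask() & window.contains(series.time_h)
    t = series.time_h[mask]
    c = series.concentration[mask]
    if aggregation == "pooled":
        order = np.lexsort((series.replicate[mask], t))
        return t[order], c[order]
    times = np.unique(t)
    means = np.array([c[t == ti].mean() for ti in times])
    return times, means


def fit_kinetic(
    series: TimeSeries,
    form: ModelForm,
    window: FitWindow,
    aggregation: str = "replicate_means",
    r2_space: str = "original",
) -> KineticFit:
    """Fit one kinetic law to one series over a window by transform-space OLS.

    Censored (below-LOD) points are dropped, never imputed.  With fewer
    than 3 usable points the result is returned with ``fittable=False``
    rather than raising, mirroring conditions that cannot be analysed.

    Parameters
    ----------
    aggregation
        ``"replicate_means"`` (default) fits the per-time replicate means;
        ``"pooled"`` fits all replicate points individually.
    r2_space
        ``"original"`` (default) computes R² between observed and
        back-transformed predicted concentrations; ``"transformed"``
        computes it in the linearised fitting space instead.

    Raises
    ------
    KineticDomainError
        Logarithmic form with any usable time ≤ 0 in the window.
    NonPositiveConcentrationError
        Exponential form with any non-positive usable concentration.
    """
    if r2_space not in ("original", "transformed"):
        raise ValueError("r2_space must be 'original' or 'transformed'")
    t, c = _window_points(series, window, aggregation)
    common = dict(window=window, aggregation=aggregation, condition=series.condition)
    if t.size == 0:
        return KineticFit(None, n_points=0, gof=None, fittable=False,
                          reason="window excludes all usable data", **common)
    if t.size < 3:
        return KineticFit(None, n_points=int(t.size), gof=None, fittable=False,
                          reason="fewer than 3 usable points", **common)
    if np.unique(t).size < 2:
        return KineticFit(None, n_points=int(t.size), gof=None, fittable=False,
                          reason="degenerate time grid (single time point)", **common)

    if form is ModelForm.LOGARITHMIC and np.any(t <= 0):
        bad = t[t <= 0]
        raise KineticDomainError(
            f"logarithmic law cannot be fitted with t <= 0 in window "
            f"(offending times: {bad.tolist()})"
        )
    if form is ModelForm.FIRST_ORDER_EXP and np.any(c <= 0):
        bad = [(float(ti), float(ci)) for ti, ci in zip(t, c) if ci <= 0]
        raise NonPositiveConcentrationError(
            f"first_order_exp requires positive concentrations; offending (t, C): {bad}"
        )

    if form is ModelForm.ZERO_ORDER:
        x, y = t, c
    elif form is ModelForm.FIRST_ORDER_EXP:
        x, y = t, np.log(c)
    else:
        x, y = np.log(t), c

    res = stats.linregress(x, y)
    if form is ModelForm.FIRST_ORDER_EXP:
        params = KineticParams(form, c0=float(np.exp(res.intercept)), k=float(res.slope))
    else:
        params = KineticParams(form, c0=float(res.intercept), k=float(res.slope))

    pred = predict(params, t)
    gof = compute_gof(c, pred)
    if r2_space == "transformed":
        gof = _dc_replace(gof, r_squared=r_squared_of(y, res.intercept + res.slope * x))
    common["window"] = FitWindow(float(t.min()), float(t.max()))
    return KineticFit(params, n_points=int(t.size), gof=gof, fittable=True, **common)
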