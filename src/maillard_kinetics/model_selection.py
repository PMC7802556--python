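"""Candidate enumeration and best-model selection per heating condition.

For each (system, compound, temperature) condition the three candidate
laws are fitted over a set of candidate induction windows, and the best
(form, window) pair is chosen by ordered criteria: Af, Bf and R² closer
to 1 together with lower SS and RMSE indicate the better-fitting model.
The default ordering puts R² first because it is the one metric defined
for every fit, including those whose ratio metrics are not computable;
ties fall through to SS, RMSE, |Af−1|, |Bf−1|, then to the simpler law.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .kinetic_models import (
    FORM_ORDER,
    FitWindow,
    KineticDomainError,
    KineticFit,
    ModelForm,
    NonPositiveConcentrationError,
    fit_kinetic,
)
from .panel import TimeSeries

logger = logging.getLogger(__name__)

#: Candidate induction windows (hours) observed across the study grid.
DEFAULT_WINDOWS = (
    FitWindow(0, 6),
    FitWindow(1, 6),
    FitWindow(2, 6),
    FitWindow(3, 6),
    FitWindow(1, 4),
    FitWindow(1, 5),
)

#: Criteria in lexicographic order of application.
DEFAULT_CRITERIA = ("r_squared", "ss", "rmse", "af", "bf")

#: Relative tolerance under which two criterion values count as tied.
_TIE_RTOL = 1e-9


@dataclass
class SelectionResult:
    """Outcome of best-model selection for one condition."""

    condition: tuple[str, str, float] | None
    candidates: list[KineticFit]
    best: KineticFit
    criteria_trace: list[tuple[str, list[float | None]]]

    def __post_init__(self) -> None:
        if self.best not in self.candidates:
            raise ValueError("best must be a member of candidates")


def enumerate_fits(
    series: TimeSeries,
    forms=FORM_ORDER,
    windows=DEFAULT_WINDOWS,
    aggregation: str = "replicate_means",
    r2_space: str = "original",
    exclusions: list[tuple[ModelForm, FitWindow, str]] | None = None,
) -> list[KineticFit]:
    """Fit every valid (form, window) candidate pair for one series.

    Invalid pairs — the logarithmic law on a window reaching t = 0, the
    exponential law on non-positive data, windows leaving fewer than 3
    usable points — are excluded with a logged reason (also appended to
    ``exclusions`` when a list is supplied) instead of raising.
    """
    if not forms or not windows:
        return []
    fits: list[KineticFit] = []
    for form in forms:
        for window in windows:
            try:
                fit = fit_kinetic(series, form, window, aggregation, r2_space)
            except (KineticDomainError, NonPositiveConcentrationError) as exc:
                logger.debug("%s: excluded %s on %s: %s",
                             series.condition, form.value, window, exc)
                if exclusions is not None:
                    exclusions.append((form, window, str(exc)))
                continue
            if not fit.fittable:
                logger.debug("%s: unfittable %s on %s: %s",
                             series.condition, form.value, window, fit.reason)
                if exclusions is not None:
                    exclusions.append((form, window, fit.reason or "unfittable"))
                continue
            fits.append(fit)
    return fits


def _badness(fit: KineticFit, criterion: str) -> float | None:
    """Map a criterion to a 'lower is better' value, or None if not computable."""
    gof = fit.gof
    assert gof is not None
    if criterion == "r_squared":
        return None if gof.r_squared != gof.r_squared else -gof.r_squared  # NaN check
    if criterion == "ss":
        return gof.ss
    if criterion == "rmse":
        return gof.rmse
    if criterion == "af":
        return None if gof.af is None else abs(gof.af - 1.0)
    if criterion == "bf":
        return None if gof.bf is None else abs(gof.bf - 1.0)
    raise ValueError(f"unknown criterion {criterion!r}")


def _tied(a: float, b: float) -> bool:
    return abs(a - b) <= _TIE_RTOL * max(1.0, abs(a), abs(b))


def _sort_key(fit: KineticFit) -> tuple:
    """Deterministic final tie-break: simpler form, then the fit using
    more points, then the earlier-starting, wider effective window."""
    return (FORM_ORDER.index(fit.params.form), -fit.n_points,
            fit.window.t_start, -fit.window.t_end)


def select_best(
    fits: list[KineticFit],
    criteria_order=DEFAULT_CRITERIA,
    condition: tuple[str, str, float] | None = None,
) -> SelectionResult:
    """Select the best fit lexicographically under ``criteria_order``.

    Criteria on which either competitor is not computable (ratio metrics
    with non-positive values, R² on constant data) are skipped for that
    comparison rather than disqualifying a candidate.  Remaining ties go
    to the simpler law (zero order < exponential < logarithmic), then to
    the fit using more points, then to the earlier-starting, wider
    effective window, making selection deterministic and independent of
    candidate order.
    """
    if not fits:
        raise ValueError("no candidate fits to select from")
    if any(not f.fittable for f in fits):
        raise ValueError("select_best requires all candidates to be fittable")

    def beats(a: KineticFit, b: KineticFit) -> bool:
        for criterion in criteria_order:
            va, vb = _badness(a, criterion), _badness(b, criterion)
            if va is None or vb is None:
                continue
            if not _tied(va, vb):
                return va < vb
        return _sort_key(a) < _sort_key(b)

    # Candidate order must not matter: scan in the canonical tie-break order.
    best = None
    for fit in sorted(fits, key=_sort_key):
        if best is None or beats(fit, best):
            best = fit
    assert best is not None

    trace = [
        (criterion, [_badness(f, criterion) for f in fits])
        for criterion in criteria_order
    ]
    if condition is None:
        condition = best.condition
    return SelectionResult(condition=condition, candidates=list(fits),
                           best=best, criteria_trace=trace)


def select_for_series(
    series: TimeSeries,
    forms=FORM_ORDER,
    windows=DEFAULT_WINDOWS,
    criteria_order=DEFAULT_CRITERIA,
    aggregation: str = "replicate_means",
    r2_space: str = "original",
) -> SelectionResult | None:
    """Enumerate candidates for a series and pick the best; None if unfittable."""
    fits = enumerate_fits(series, forms, windows, aggregation, r2_space)
    if not fits:
        return None
    return select_best(fits, criteria_order, condition=series.condition)
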