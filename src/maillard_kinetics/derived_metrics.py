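"""Summary statistics over a compound panel.

These are the headline numbers of a heated model-system study: how much
of the starting sugar was consumed, how the major dicarbonyls compare
with one another, how much an added amino acid amplifies each product,
where on the (temperature, time) grid each product peaks, and whether
between-system differences are statistically significant.  All metrics
operate on replicate means; significance uses classical one-way ANOVA.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .panel import CompoundPanel, MissingDataError, TimeSeries


def percent_consumption(series: TimeSeries, t_ref: float) -> float:
    """Percent decrease from the initial content: 100·(C(0) − C(t_ref))/C(0).

    Requires usable replicate means at both t=0 and t=t_ref, and C(0) > 0.
    Negative results indicate net accumulation.
    """
    c0 = series.mean_at(0.0)
    ct = series.mean_at(t_ref)
    if math.isnan(c0) or math.isnan(ct):
        raise MissingDataError(
            f"endpoint censored for {series.condition}: C(0)={c0}, C({t_ref})={ct}"
        )
    if c0 <= 0:
        raise ValueError("C(0) must be positive")
    return 100.0 * (c0 - ct) / c0


def compound_ratio(
    panel: CompoundPanel,
    a: str,
    b: str,
    system: str,
    temperature: float,
    time: float,
) -> float:
    """Mean concentration of analyte ``a`` over analyte ``b`` at one condition.

    Missing conditions raise; a censored or non-positive denominator (or a
    censored numerator) yields NaN as an undefined-ratio marker.
    """
    ca = panel.get(system, a, temperature).mean_at(time)
    cb = panel.get(system, b, temperature).mean_at(time)
    if math.isnan(ca) or math.isnan(cb) or cb <= 0:
        return math.nan
    return ca / cb


def system_fold_change(
    panel_glu: CompoundPanel,
    panel_only: CompoundPanel,
    compound: str,
    temperature: float,
    time: float,
) -> float:
    """Glucose-Glu over glucose-only mean concentration for one compound.

    Quantifies the amplification (or suppression) of a product by the
    added amino acid.  Same missing/censored semantics as
    :func:`compound_ratio`.
    """
    num = panel_glu.get("glucose_glu", compound, temperature).mean_at(time)
    den = panel_only.get("glucose_only", compound, temperature).mean_at(time)
    if math.isnan(num) or math.isnan(den) or den <= 0:
        return math.nan
    return num / den


def peak_condition(
    panel: CompoundPanel, compound: str, system: str
) -> tuple[float, float, float]:
    """(temperature ℃, time h, value µg/ml) of the maximum replicate mean.

    Searches the full (temperature, time) grid present in the panel for
    the compound/system; ties go to the lower temperature, then the
    earlier time.  Raises if every observation is censored.
    """
    cells: list[tuple[float, float, float]] = []
    for (sys_, comp, temp), series in panel:
        if sys_ != system or comp != compound:
            continue
        times, means = series.replicate_means()
        cells.extend((temp, float(t), float(m)) for t, m in zip(times, means))
    if not cells:
        raise MissingDataError(
            f"no usable observations for {compound!r} in {system!r}"
        )
    # max by value; ties by lower temperature then earlier time
    best = min(cells, key=lambda c: (-c[2], c[0], c[1]))
    return best


def anova_significance(
    groups, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Classical one-way ANOVA across replicate groups.

    Returns ``(F, p, significant)`` with ``significant = (p < alpha)``.
    Requires ≥ 2 groups of ≥ 2 values each and nonzero pooled
    within-group variance.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if ssw == 0.0:
        raise ValueError("zero within-group variance: F undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p), bool(p < alpha)
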