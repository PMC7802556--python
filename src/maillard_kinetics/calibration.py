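"""External-calibration quantitation rules.

Each analyte is quantified against a linear external calibration curve
(instrument response vs standard concentration) valid over a declared
concentration range.  Three of the quinoxaline-derivatised dicarbonyls
(glucosone, 1-deoxyglucosone, 3,4-dideoxyglucosone) have no authentic
standard and are semi-quantified on the curve of the structurally
analogous 2-(2,3,4-trihydroxybutyl)-quinoxaline, which shares the same
proton-accepting groups; this surrogate reuse is expressed through
``surrogate_for``.  Sample dilution before measurement is undone by a
multiplicative dilution factor at inverse prediction.

The limit of detection defaults to the lowest calibration standard of
the applicable curve; panel values below it are treated as censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Declared calibration ranges (µg/ml) of the study's methods, per analyte.
#: The trihydroxybutyl-quinoxaline curve doubles as the semi-quantitation
#: surrogate for the three dicarbonyls without authentic standards.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "glucose": (28.0, 7000.0),
    "fructose": (28.0, 7000.0),
    "5-hydroxymethylfurfural": (0.007, 58.0),
    "glyoxal": (3.2e-3, 2.0),            # quinoxaline
    "methylglyoxal": (3.2e-3, 2.0),      # 2-methylquinoxaline
    "diacetyl": (6.4e-4, 2.0),           # 2,3-dimethylquinoxaline
    "3-deoxyglucosone": (8.2e-3, 2.1),   # 2-(2,3,4-trihydroxybutyl)-quinoxaline
}

SURROGATE_ANALYTES = ("glucosone", "1-deoxyglucosone", "3,4-dideoxyglucosone")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear external-calibration line with its validity range."""

    analyte: str
    slope: float
    intercept: float
    range_low: float
    range_high: float
    surrogate_for: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be < range_high")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    def response_at(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(
    standards,
    conc_range: tuple[float, float],
    analyte: str = "",
    surrogate_for: tuple[str, ...] = (),
) -> CalibrationCurve:
    """OLS line through (concentration, response) standards.

    Requires at least 3 standards with non-constant concentrations, all
    inside the declared range; the range is stored verbatim on the curve.
    """
    pts = [(float(c), float(r)) for c, r in standards]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 calibration standards, got {len(pts)}")
    conc = np.array([c for c, _ in pts])
    resp = np.array([r for _, r in pts])
    low, high = float(conc_range[0]), float(conc_range[1])
    if np.ptp(conc) == 0:
        raise ValueError("calibration standards have zero concentration variance")
    outside = conc[(conc < low) | (conc > high)]
    if outside.size:
        raise ValueError(
            f"standard concentrations outside declared range: {outside.tolist()}"
        )
    res = stats.linregress(conc, resp)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        range_low=low,
        range_high=high,
        surrogate_for=tuple(surrogate_for),
    )


def inverse_predict(
    curve: CalibrationCurve, response: float, dilution_factor: float = 1.0
) -> tuple[float, bool]:
    """Concentration in the undiluted sample from an instrument response.

    Returns ``(concentration, in_range)``; ``in_range`` flags whether the
    pre-dilution estimate lies within the curve's declared range.  An
    out-of-range estimate is flagged, never an error.
    """
    if dilution_factor < 1.0:
        raise ValueError("dilution_factor must be >= 1")
    measured = (response - curve.intercept) / curve.slope
    in_range = curve.range_low <= measured <= curve.range_high
    return dilution_factor * measured, in_range


def lod_for(curve: CalibrationCurve, override: float | None = None) -> float:
    """Limit of detection: the lowest calibration standard unless overridden."""
    return curve.range_low if override is None else float(override)
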