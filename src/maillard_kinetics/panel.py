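"""Core containers for replicate concentration–time measurements.

The study design behind this package is a grid of heated model systems:
two reaction mixtures (glucose-only and glucose + glutamic acid), five
temperatures (90–110 ℃ in 5 ℃ steps) and seven sampling times (0–6 h,
hourly), each measured in triplicate for ten analytes.  A
:class:`TimeSeries` holds one analyte's replicate measurements at one
(system, temperature) condition; a :class:`CompoundPanel` holds the full
grid keyed by (system, compound, temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

SYSTEMS = ("glucose_only", "glucose_glu")

COMPOUNDS = (
    "glucose",
    "fructose",
    "1-deoxyglucosone",
    "3-deoxyglucosone",
    "3,4-dideoxyglucosone",
    "glucosone",
    "glyoxal",
    "methylglyoxal",
    "diacetyl",
    "5-hydroxymethylfurfural",
)

TEMPERATURES_C = (90.0, 95.0, 100.0, 105.0, 110.0)

#: Hourly sampling grid of the heating experiments.
TIME_GRID_H = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)

T_MIN_H, T_MAX_H = 0.0, 6.0


class MissingDataError(KeyError):
    """A requested condition or time point is absent from the data."""


@dataclass
class TimeSeries:
    """Replicate concentration–time measurements for one condition.

    Parameters
    ----------
    system, compound, temperature
        Condition key: model system, analyte id and heating temperature (℃).
    time_h, replicate, concentration, censored
        Parallel arrays, one entry per measurement.  Censored entries are
        below the detection limit: their concentration is not usable and is
        stored as NaN.
    lod
        Limit of detection (µg/ml) applied to this series, if any.
    """

    system: str
    compound: str
    temperature: float
    time_h: np.ndarray
    replicate: np.ndarray
    concentration: np.ndarray
    censored: np.ndarray
    lod: float | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.replicate = np.asarray(self.replicate)
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        n = self.time_h.size
        if not (self.replicate.size == self.concentration.size == self.censored.size == n):
            raise ValueError("time_h, replicate, concentration, censored must be equal length")
        if n and (self.time_h.min() < T_MIN_H or self.time_h.max() > T_MAX_H):
            raise ValueError(f"times must lie within [{T_MIN_H}, {T_MAX_H}] h")
        usable = ~self.censored
        if np.any(self.concentration[usable] < 0):
            raise ValueError("uncensored concentrations must be non-negative")
        keys = list(zip(self.time_h.tolist(), self.replicate.tolist()))
        if len(set(keys)) != len(keys):
            raise ValueError("replicate ids must be unique per time point")

    # -- accessors ---------------------------------------------------------

    @property
    def condition(self) -> tuple[str, str, float]:
        return (self.system, self.compound, self.temperature)

    @property
    def n_points(self) -> int:
        return int(self.time_h.size)

    def usable_mask(self) -> np.ndarray:
        """Uncensored points with a finite concentration."""
        return (~self.censored) & np.isfinite(self.concentration)

    def replicate_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean concentration of uncensored replicates per time point.

        Times with no usable replicate are omitted.  Returns ``(times,
        means)`` sorted by time.
        """
        mask = self.usable_mask()
        times = np.unique(self.time_h[mask])
        means = np.array(
            [self.concentration[mask & (self.time_h == t)].mean() for t in times]
        )
        return times, means

    def mean_at(self, time: float) -> float:
        """Replicate-mean concentration at ``time``.

        Raises :class:`MissingDataError` if the time point was never
        measured; returns NaN if it was measured but every replicate is
        censored.
        """
        at_t = np.isclose(self.time_h, time)
        if not at_t.any():
            raise MissingDataError(
                f"time {time} h not measured for {self.condition}"
            )
        mask = at_t & self.usable_mask()
        if not mask.any():
            return float("nan")
        return float(self.concentration[mask].mean())

    def with_censoring(self, censored: np.ndarray, lod: float | None) -> "TimeSeries":
        conc = self.concentration.copy()
        conc[censored] = np.nan
        return replace(self, concentration=conc, censored=censored, lod=lod)


@dataclass
class CompoundPanel:
    """The full study grid: TimeSeries keyed by (system, compound, temperature ℃)."""

    series: dict[tuple[str, str, float], TimeSeries] = field(default_factory=dict)

    def add(self, ts: TimeSeries) -> None:
        key = ts.condition
        if key in self.series:
            raise ValueError(f"duplicate condition {key}")
        self.series[key] = ts

    def get(self, system: str, compound: str, temperature: float) -> TimeSeries:
        key = (system, compound, float(temperature))
        try:
            return self.series[key]
        except KeyError:
            raise MissingDataError(f"condition {key} not in panel") from None

    def __contains__(self, key: tuple[str, str, float]) -> bool:
        return key in self.series

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[tuple[tuple[str, str, float], TimeSeries]]:
        return iter(sorted(self.series.items()))

    def conditions(self) -> list[tuple[str, str, float]]:
        return sorted(self.series)

    def subset(self, system: str | None = None, compound: str | None = None) -> "CompoundPanel":
        out = CompoundPanel()
        for key, ts in self:
            if system is not None and key[0] != system:
                continue
            if compound is not None and key[1] != compound:
                continue
            out.add(ts)
        return out
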