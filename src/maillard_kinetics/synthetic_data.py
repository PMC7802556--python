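"""Synthetic replicate concentration–time panels with the study's structure.

Raw chromatographic measurements for heated-sugar model systems are
rarely deposited; what the literature preserves is the fitted kinetic
law per condition.  This module turns a registry of such laws — one
(form, C0, k, window) entry per (system, compound, temperature) — back
into replicate-level panels so that every downstream stage (fitting,
selection, derived summaries, the CLI) is testable end to end.

The bundled default registry transcribes the study's full summary grid:
2 systems × 10 analytes × 5 temperatures, minus the two conditions the
study could not fit because multiple measurements fell below the
detection limit (1-deoxyglucosone and HMF at 90 ℃ in the glucose-only
system), i.e. 98 entries.

Noise model
-----------
Concentrations in the grid span roughly nine orders of magnitude
(10⁻⁵ µg/ml dicarbonyls to 5×10⁴ µg/ml glucose), so replicate scatter
is modelled as multiplicative Gaussian noise with a single coefficient
of variation: ``C = predict(t) · (1 + ε)``, ``ε ~ N(0, cv²)``.  Any
value that is non-positive — either because the empirical line itself
crosses zero inside its window or because a noise draw pushed it there
— is truncated at zero and emitted as a *censored* point, i.e. treated
as below the detection limit rather than as a usable concentration.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .kinetic_models import FitWindow, KineticParams, ModelForm, predict
from .panel import CompoundPanel, TimeSeries

_DEFAULT_REGISTRY = importlib.resources.files("maillard_kinetics") / "data" / "table_registry.csv"

_REGISTRY_COLUMNS = (
    "system", "compound", "temperature_C", "form",
    "c0", "k", "window_start_h", "window_end_h",
)


@dataclass(frozen=True)
class RegistryEntry:
    """One condition's generating law: who, at what temperature, which law."""

    system: str
    compound: str
    temperature: float
    params: KineticParams
    window: FitWindow

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.system, self.compound, self.temperature)


def _parse_number(text: str) -> float:
    """Parse a coefficient, tolerating Unicode minus signs and digit-group commas."""
    return float(text.strip().replace("−", "-").replace("–", "-").replace(",", ""))


def load_registry(path: str | Path | None = None) -> list[RegistryEntry]:
    """Load a kinetic-law registry from delimited text.

    ``path=None`` loads the bundled study grid.  Duplicate
    (system, compound, temperature) keys are an error.
    """
    if path is None:
        source = _DEFAULT_REGISTRY.open("r", encoding="utf-8")
    else:
        source = open(path, "r", encoding="utf-8")
    entries: list[RegistryEntry] = []
    with source:
        reader = csv.DictReader(source)
        missing = set(_REGISTRY_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"registry missing columns: {sorted(missing)}")
        for row in reader:
            entries.append(
                RegistryEntry(
                    system=row["system"].strip(),
                    compound=row["compound"].strip(),
                    temperature=_parse_number(row["temperature_C"]),
                    params=KineticParams(
                        form=ModelForm(row["form"].strip()),
                        c0=_parse_number(row["c0"]),
                        k=_parse_number(row["k"]),
                    ),
                    window=FitWindow(
                        _parse_number(row["window_start_h"]),
                        _parse_number(row["window_end_h"]),
                    ),
                )
            )
    keys = [e.key for e in entries]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate registry keys: {dupes}")
    return entries


def generate_series(
    entry: RegistryEntry,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int | np.random.SeedSequence | None = 0,
    lod: float | None = None,
) -> TimeSeries:
    """Simulate one condition's replicate series from its registry law.

    The hourly grid points inside the entry's window are evaluated with
    the generating law; each replicate is perturbed by multiplicative
    Gaussian noise with coefficient of variation ``noise_cv`` (0 means
    noiseless).  Non-positive values are truncated at zero and marked
    censored; an explicit ``lod`` additionally censors values below it.
    Deterministic for a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.arange(np.ceil(entry.window.t_start), np.floor(entry.window.t_end) + 1.0)
    truth = predict(entry.params, grid)

    times, reps, concs = [], [], []
    for t, mu in zip(grid, truth):
        eps = rng.normal(0.0, noise_cv, size=n_replicates) if noise_cv > 0 else np.zeros(n_replicates)
        vals = mu * (1.0 + eps)
        for r in range(n_replicates):
            times.append(t)
            reps.append(r)
            concs.append(max(float(vals[r]), 0.0))
    conc = np.array(concs)
    censored = conc <= 0.0
    if lod is not None:
        if lod < 0:
            raise ValueError("lod must be >= 0")
        censored |= conc < lod
    conc = conc.copy()
    conc[censored] = np.nan
    return TimeSeries(
        system=entry.system,
        compound=entry.compound,
        temperature=entry.temperature,
        time_h=np.array(times),
        replicate=np.array(reps),
        concentration=conc,
        censored=censored,
        lod=lod,
    )


def generate_panel(
    registry: list[RegistryEntry] | None = None,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    lod_map: dict[str, float] | None = None,
) -> CompoundPanel:
    """Simulate the full panel: one TimeSeries per registry entry.

    Per-entry seeds are spawned deterministically from the master seed in
    registry order, so the panel is reproducible as a whole and each
    series is independent of how many other entries exist before it only
    through its position.
    """
    if registry is None:
        registry = load_registry()
    panel = CompoundPanel()
    children = np.random.SeedSequence(seed).spawn(len(registry))
    for entry, child in zip(registry, children):
        lod = None if lod_map is None else lod_map.get(entry.compound)
        panel.add(generate_series(entry, noise_cv, n_replicates, seed=child, lod=lod))
    return panel


def apply_lod_censoring(series: TimeSeries, lod: float) -> TimeSeries:
    """Mark points with concentration < lod as censored; record the lod."""
    if lod < 0:
        raise ValueError("lod must be >= 0")
    with np.errstate(invalid="ignore"):
        below = series.concentration < lod
    censored = series.censored | below
    return series.with_censoring(censored, lod)
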