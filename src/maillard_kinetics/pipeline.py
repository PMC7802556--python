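"""End-to-end orchestration: panel I/O, per-condition fitting and summaries.

``load_panel`` reads a tidy CSV of replicate measurements,
``run_pipeline`` fits and selects a kinetic law per condition and
computes the derived summary tables, and ``write_summary`` emits one
CSV per table family plus a JSON run log.  Everything is deterministic
for fixed inputs; not-computable metrics are rendered as an explicit
"/" marker, never as a number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import derived_metrics as dm
from .kinetic_models import FORM_ORDER, FitWindow, ModelForm
from .model_selection import DEFAULT_CRITERIA, DEFAULT_WINDOWS, SelectionResult, select_for_series
from .panel import CompoundPanel, MissingDataError, TimeSeries

logger = logging.getLogger(__name__)

#: Marker written for metrics that cannot be computed (ratio metrics on
#: non-positive values, R² on constant data).
NOT_COMPUTABLE = "/"

PANEL_COLUMNS = (
    "system", "compound", "temperature_C", "time_h",
    "replicate", "concentration_ug_per_ml",
)

#: Ratio pairs tracked by default: the dominant dicarbonyl against its
#: isomer and oxidised sibling, and the two short-chain dicarbonyls.
DEFAULT_RATIO_PAIRS = (
    ("3-deoxyglucosone", "1-deoxyglucosone"),
    ("3-deoxyglucosone", "glucosone"),
    ("glyoxal", "methylglyoxal"),
)


@dataclass
class PipelineConfig:
    """Tunable knobs of the analysis; every default mirrors the study design."""

    forms: tuple[ModelForm, ...] = FORM_ORDER
    windows: tuple[FitWindow, ...] = DEFAULT_WINDOWS
    criteria_order: tuple[str, ...] = DEFAULT_CRITERIA
    aggregation: str = "replicate_means"
    r2_space: str = "original"
    alpha: float = 0.05
    t_ref_h: float = 6.0
    ratio_pairs: tuple[tuple[str, str], ...] = DEFAULT_RATIO_PAIRS
    #: Optional per-condition pinned windows: (system, compound, temperature) -> window
    pinned_windows: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["forms"] = [f.value for f in self.forms]
        d["windows"] = [[w.t_start, w.t_end] for w in self.windows]
        d["pinned_windows"] = {
            "|".join(map(str, k)): [w.t_start, w.t_end]
            for k, w in self.pinned_windows.items()
        }
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "forms" in raw:
            kwargs["forms"] = tuple(ModelForm(f) for f in raw["forms"])
        if "windows" in raw:
            kwargs["windows"] = tuple(FitWindow(lo, hi) for lo, hi in raw["windows"])
        if "pinned_windows" in raw:
            pinned = {}
            for key, (lo, hi) in raw["pinned_windows"].items():
                system, compound, temp = key.split("|")
                pinned[(system, compound, float(temp))] = FitWindow(lo, hi)
            kwargs["pinned_windows"] = pinned
        if "ratio_pairs" in raw:
            kwargs["ratio_pairs"] = tuple((a, b) for a, b in raw["ratio_pairs"])
        for name in ("criteria_order", "aggregation", "r2_space", "alpha", "t_ref_h"):
            if name in raw:
                value = raw[name]
                kwargs[name] = tuple(value) if name == "criteria_order" else value
        return cls(**kwargs)


@dataclass
class DerivedSummary:
    """The derived summary tables computed over one panel."""

    consumption: pd.DataFrame
    ratios: pd.DataFrame
    fold_changes: pd.DataFrame
    peaks: pd.DataFrame
    anova: pd.DataFrame


@dataclass
class SummaryReport:
    """Per-condition selected fits plus derived summaries and provenance."""

    fits: pd.DataFrame
    selections: dict[tuple[str, str, float], SelectionResult | None]
    derived: DerivedSummary
    provenance: dict


# ---------------------------------------------------------------------------
# Panel I/O


def load_panel(path: str | Path) -> CompoundPanel:
    """Read a tidy panel CSV into a CompoundPanel.

    Required columns: system, compound, temperature_C, time_h, replicate,
    concentration_ug_per_ml (an optional ``censored`` 0/1 column is also
    honoured).  A concentration written as ``<LOD`` marks a censored
    point.  Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path, dtype={"concentration_ug_per_ml": str},
                     float_precision="round_trip")
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} missing columns: {sorted(missing)}")

    conc_text = df["concentration_ug_per_ml"].astype(str).str.strip()
    censored = conc_text.str.upper().isin({"<LOD", "LOD", "ND"})
    if "censored" in df.columns:
        censored |= df["censored"].fillna(0).astype(bool)
    def _to_float(s):
        try:
            return float(s)
        except (TypeError, ValueError):
            return float("nan")

    # python float() is round-trip exact for repr output; pd.to_numeric is not
    conc = conc_text.where(~censored).map(_to_float).astype(float)
    bad = (~censored) & conc.isna()
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ValueError(f"non-numeric concentration in {path} at line(s) {rows}")

    for col in ("temperature_C", "time_h"):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            rows = [int(i) + 2 for i in df.index[values.isna()][:10]]
            raise ValueError(f"non-numeric {col} in {path} at line(s) {rows}")
        df[col] = values

    keys = df[["system", "compound", "temperature_C", "time_h", "replicate"]]
    dup = keys.duplicated(keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValueError(f"duplicate (condition, time, replicate) keys at line(s) {rows}")

    panel = CompoundPanel()
    grouped = df.assign(_conc=conc, _cens=censored).groupby(
        ["system", "compound", "temperature_C"], sort=True
    )
    for (system, compound, temp), g in grouped:
        panel.add(
            TimeSeries(
                system=str(system),
                compound=str(compound),
                temperature=float(temp),
                time_h=g["time_h"].to_numpy(float),
                replicate=g["replicate"].to_numpy(),
                concentration=g["_conc"].to_numpy(float),
                censored=g["_cens"].to_numpy(bool),
            )
        )
    return panel


def write_panel(panel: CompoundPanel, path: str | Path) -> None:
    """Write a CompoundPanel as tidy CSV; censored points become ``<LOD``."""
    rows = []
    for (system, compound, temp), series in panel:
        for t, rep, c, cens in zip(
            series.time_h, series.replicate, series.concentration, series.censored
        ):
            rows.append(
                {
                    "system": system,
                    "compound": compound,
                    "temperature_C": temp,
                    "time_h": float(t),
                    "replicate": rep,
                    "concentration_ug_per_ml": "<LOD" if cens else repr(float(c)),
                    "censored": int(bool(cens)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline


def _fit_row(condition, sel: SelectionResult | None, reason: str | None = None) -> dict:
    system, compound, temp = condition
    row = {
        "system": system,
        "compound": compound,
        "temperature_C": temp,
        "fittable": sel is not None,
        "form": NOT_COMPUTABLE,
        "c0": np.nan,
        "k": np.nan,
        "window_start_h": np.nan,
        "window_end_h": np.nan,
        "n_points": 0,
        "r_squared": np.nan,
        "af": np.nan,
        "bf": np.nan,
        "ss": np.nan,
        "rmse": np.nan,
        "note": reason or "",
    }
    if sel is not None:
        best = sel.best
        assert best.params is not None and best.gof is not None
        row.update(
            form=best.params.form.value,
            c0=best.params.c0,
            k=best.params.k,
            window_start_h=best.window.t_start,
            window_end_h=best.window.t_end,
            n_points=best.n_points,
            r_squared=best.gof.r_squared,
            af=np.nan if best.gof.af is None else best.gof.af,
            bf=np.nan if best.gof.bf is None else best.gof.bf,
            ss=np.nan if best.gof.ss is None else best.gof.ss,
            rmse=best.gof.rmse,
            note="" if best.gof.log_metrics_defined else "ratio metrics not computable",
        )
    return row


def run_pipeline(panel: CompoundPanel, config: PipelineConfig | None = None) -> SummaryReport:
    """Fit, select and summarise every condition in the panel.

    Conditions with fewer than 3 usable points are reported as
    unfittable rather than failing the run.  Deterministic for fixed
    (panel, config).
    """
    config = config or PipelineConfig()
    selections: dict[tuple[str, str, float], SelectionResult | None] = {}
    rows = []
    for condition, series in panel:
        windows = config.windows
        if condition in config.pinned_windows:
            windows = (config.pinned_windows[condition],)
        sel = select_for_series(
            series,
            forms=config.forms,
            windows=windows,
            criteria_order=config.criteria_order,
            aggregation=config.aggregation,
            r2_space=config.r2_space,
        )
        selections[condition] = sel
        rows.append(_fit_row(condition, sel, reason=None if sel else "unfittable"))
    fits = pd.DataFrame(rows)

    derived = _derived_summary(panel, config)
    provenance = {
        "config_hash": config.hash(),
        "config": config.to_jsonable(),
        "n_conditions": len(panel),
        "n_fitted": int(fits["fittable"].sum()) if len(fits) else 0,
    }
    return SummaryReport(fits=fits, selections=selections, derived=derived,
                         provenance=provenance)


def _derived_summary(panel: CompoundPanel, config: PipelineConfig) -> DerivedSummary:
    t_ref = config.t_ref_h

    consumption_rows = []
    for (system, compound, temp), series in panel:
        if compound != "glucose":
            continue
        try:
            pct = dm.percent_consumption(series, t_ref)
        except (MissingDataError, ValueError):
            continue
        consumption_rows.append(
            {"system": system, "temperature_C": temp, "t_ref_h": t_ref,
             "percent_consumed": pct}
        )

    systems = sorted({key[0] for key in panel.conditions()})
    temps = sorted({key[2] for key in panel.conditions()})
    compounds = sorted({key[1] for key in panel.conditions()})

    ratio_rows = []
    for a, b in config.ratio_pairs:
        for system in systems:
            for temp in temps:
                try:
                    r = dm.compound_ratio(panel, a, b, system, temp, t_ref)
                except MissingDataError:
                    continue
                ratio_rows.append(
                    {"numerator": a, "denominator": b, "system": system,
                     "temperature_C": temp, "time_h": t_ref, "ratio": r}
                )

    fold_rows = []
    for compound in compounds:
        for temp in temps:
            try:
                fc = dm.system_fold_change(panel, panel, compound, temp, t_ref)
            except MissingDataError:
                continue
            fold_rows.append(
                {"compound": compound, "temperature_C": temp, "time_h": t_ref,
                 "fold_glu_over_only": fc}
            )

    peak_rows = []
    for system in systems:
        for compound in compounds:
            try:
                temp, t, value = dm.peak_condition(panel, compound, system)
            except MissingDataError:
                continue
            peak_rows.append(
                {"system": system, "compound": compound, "temperature_C": temp,
                 "time_h": t, "peak_ug_per_ml": value}
            )

    anova_rows = []
    if len(systems) == 2:
        for compound in compounds:
            for temp in temps:
                keys = [(s, compound, temp) for s in systems]
                if not all(k in panel for k in keys):
                    continue
                series_pair = [panel.get(*k) for k in keys]
                shared = sorted(
                    set(series_pair[0].time_h) & set(series_pair[1].time_h)
                )
                for t in shared:
                    groups = []
                    for s in series_pair:
                        mask = (s.time_h == t) & s.usable_mask()
                        groups.append(s.concentration[mask])
                    if any(g.size < 2 for g in groups):
                        continue
                    try:
                        f, p, sig = dm.anova_significance(groups, config.alpha)
                    except ValueError:
                        continue
                    anova_rows.append(
                        {"compound": compound, "temperature_C": temp, "time_h": t,
                         "F": f, "p": p, "significant": sig}
                    )

    return DerivedSummary(
        consumption=pd.DataFrame(consumption_rows),
        ratios=pd.DataFrame(ratio_rows),
        fold_changes=pd.DataFrame(fold_rows),
        peaks=pd.DataFrame(peak_rows),
        anova=pd.DataFrame(anova_rows),
    )


# ---------------------------------------------------------------------------
# Output


def write_summary(report: SummaryReport, out_dir: str | Path) -> list[Path]:
    """Write one CSV per table family plus a JSON run log; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fits = report.fits.copy()
    for col in ("r_squared", "af", "bf", "ss", "rmse", "c0", "k",
                "window_start_h", "window_end_h"):
        if col in fits.columns:
            fits[col] = fits[col].map(
                lambda v: NOT_COMPUTABLE if (isinstance(v, float) and np.isnan(v)) else repr(v)
                if isinstance(v, float) else v
            )
    path = out / "fits.csv"
    fits.to_csv(path, index=False)
    written.append(path)

    for name in ("consumption", "ratios", "fold_changes", "peaks", "anova"):
        path = out / f"{name}.csv"
        getattr(report.derived, name).to_csv(path, index=False)
        written.append(path)

    log_path = out / "run.json"
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(log_path)
    return written
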