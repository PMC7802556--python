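# maillard-kinetics

Kinetic analysis of α-dicarbonyl compound, sugar and
5-hydroxymethylfurfural (HMF) concentration–time data from heated
glucose model systems — the workhorse experiment behind process-
contaminant studies of the Maillard reaction. It is written for food
chemists and kinetic modellers who have replicate concentration
measurements over a heating time course (here: glucose-only and
glucose + glutamic acid systems, 90–110 ℃, 0–6 h, triplicates, ten
analytes) and want reproducible law fitting, model selection and
summary statistics instead of spreadsheet regressions.

## What it computes

After the induction period, each analyte's concentration C(t) (µg/ml)
is modelled by one of three empirical laws:

* zero order: C(t) = C₀ + k₀·t
* first order: C(t) = C₀·exp(k₁·t)
* logarithmic: C(t) = C₀ + k₂·ln t

Each law is fitted by OLS on its linearising transform over candidate
induction windows, and every fit is scored with five validation
metrics: R², accuracy factor Af = 10^(Σ|log₁₀(predᵢ/obsᵢ)|/n), bias
factor Bf = 10^(Σ log₁₀(predᵢ/obsᵢ)/n), log-residual sum of squares
SS = Σ(ln obsᵢ − ln predᵢ)², and RMSE. Af, Bf and R² closer to 1 with
lower SS and RMSE indicate the better-fitting model; selection is
lexicographic (R² first) with documented tie-breaks. On top of the
fits, the package derives percent sugar consumption, compound ratios,
between-system fold changes, grid peak conditions and one-way ANOVA
significance, and handles external-calibration quantitation (including
surrogate semi-quantitation and below-LOD censoring).

Because raw measurements for such studies are rarely deposited, a
synthetic-data generator rebuilds replicate panels from a bundled
registry of 98 published per-condition kinetic laws (multiplicative
noise, LOD censoring), making the entire pipeline testable end to end.
See `docs/methods.md` for the full model description and assumptions.

## Worked example

Fit one condition from noiseless registry-generated data:

```python
import maillard_kinetics as mk

registry = {e.key: e for e in mk.load_registry()}
entry = registry[("glucose_only", "1-deoxyglucosone", 105.0)]
series = mk.generate_series(entry, noise_cv=0.0, seed=0)
best = mk.select_for_series(series, windows=(entry.window,)).best
print(best.params.form.value, best.params.c0, best.params.k,
      str(best.window), best.gof.r_squared)
```

prints

```
logarithmic 9.999999999999999e-05 0.0002 1-6 h 1.0
```

i.e. among the three candidate laws the logarithmic one is selected
(R² = 1), recovering the generating parameters C₀ = 1×10⁻⁴ µg/ml and
k₂ = 2×10⁻⁴ µg/ml per ln-hour: 1-deoxyglucosone accumulates quickly in
the first hours at 105 ℃ and then nearly plateaus.

The same works from the shell, over the whole study grid:

```sh
maillard-kinetics simulate --noise-cv 0.05 --seed 7 --out panel.csv
# wrote 98 series to panel.csv
maillard-kinetics fit --panel panel.csv --out out
# fitted 98/98 conditions; wrote 7 files under out
```

`out/fits.csv` then holds one row per condition with the selected form,
coefficients, effective window and all five metrics, e.g. the diacetyl
row for the glucose–glutamic-acid system at 90 ℃:

```
form=first_order_exp  c0=7.74e-06  k=0.402  window=1-5 h
R²=0.9978  Af=1.028  Bf=1.000  SS=0.0050  RMSE=8.0e-07
```

— an exponential accumulation with rate constant ≈ 0.40 h⁻¹, recovered
to within a few percent of the generating value 0.3968 h⁻¹ despite 5 %
replicate noise. `out/consumption.csv`, `ratios.csv`,
`fold_changes.csv`, `peaks.csv` and `anova.csv` carry the derived
summaries; for a noiseless panel, glucose consumption in the
glucose-only system at 90 ℃ after 6 h evaluates to 3.911 %.

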