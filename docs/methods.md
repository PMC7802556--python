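# Methods

## Scope and model

`maillard_kinetics` analyses the formation (or consumption) kinetics of
glucose, fructose, 5-hydroxymethylfurfural (HMF) and seven α-dicarbonyl
compounds in heated model systems: aqueous glucose alone
(`glucose_only`) and equimolar glucose + glutamic acid (`glucose_glu`),
heated at 90–110 ℃ for 0–6 h with triplicate sampling every hour.

After the induction period of non-enzymatic browning, each analyte's
concentration is assumed to follow one of three empirical laws in time:

| form              | law                    | rate-constant units  |
|-------------------|------------------------|----------------------|
| `zero_order`      | C(t) = C₀ + k₀·t       | µg·ml⁻¹·h⁻¹          |
| `first_order_exp` | C(t) = C₀·exp(k₁·t)    | h⁻¹                  |
| `logarithmic`     | C(t) = C₀ + k₂·ln t    | µg/ml per ln-hour    |

These are empirical descriptions, not a mechanistic Maillard reaction
network; the induction period is handled by restricting the fit window's
start time (windows observed across the study grid: 0–6, 1–6, 2–6, 3–6,
1–4, 1–5 h), not by a lag parameter. Temperature is condition metadata
only — no Arrhenius analysis is attempted.

## Fitting

Each law is fitted by ordinary least squares on its linearising
transform: C vs t (zero order), ln C vs t (exponential; slope = k₁,
intercept = ln C₀), C vs ln t (logarithmic). Transform-space OLS was
chosen over nonlinear least squares because published summary tables in
this field print the ln-form equations, and because it makes every fit
closed-form, deterministic and exactly testable; a numerical
SSE-minimisation oracle in the test suite confirms the equivalence.

Rules around the fit:

* Censored (below-LOD) points are dropped, never imputed.
* Default aggregation fits per-time replicate means (matching the
  convention of reporting triplicate means ± SD); pooled per-replicate
  fitting is available by configuration.
* Fewer than 3 usable points, or fewer than 2 distinct times, yields an
  `unfittable` result with a reason code, never an exception — mirroring
  conditions that cannot be analysed because multiple measurements fell
  below the detection limit.
* The exponential law refuses non-positive concentrations (named
  error); the logarithmic law refuses windows reaching t = 0.
* A fit records its *effective* window — the span of the points actually
  used — which can be narrower than the requested window when censoring
  removes edge points.

## Goodness of fit

Five metrics per (observed, predicted) pairing, all evaluated on the
original concentration scale against the back-transformed predictions:

* R² = 1 − SSres/SStot (NaN marker when the observations are constant);
* accuracy factor Af = 10^(Σ|log₁₀(predᵢ/obsᵢ)|/n);
* bias factor Bf = 10^(Σ log₁₀(predᵢ/obsᵢ)/n);
* SS = Σ(ln obsᵢ − ln predᵢ)², with natural logs;
* RMSE = √(Σ(obsᵢ−predᵢ)²/n).

Af/Bf use base-10 logarithms, the predictive-microbiology convention
from which these factors originate; SS uses natural logarithms by its
definition. The RMSE denominator is n, not n − p: no
degrees-of-freedom correction is applied, which keeps the metric
defined on 3-point windows. Af ≥ max(Bf, 1/Bf) ≥ 1 is an algebraic
identity of the definitions and is enforced; a consequence of ln-space
OLS worth knowing is that exponential fits evaluated at their own
fitting points have Bf = 1 exactly (ln-residuals sum to zero).

If any observed or predicted value is ≤ 0, Af, Bf and SS are reported
as a not-computable marker (`None` in memory, `/` in CSV output) while
R² and RMSE are still returned. Published tables show `/` in exactly
the cells where a fitted line crosses zero inside its window; one
published row (1-deoxyglucosone, 110 ℃, glucose-only: Af = 0 with
Bf ≈ 2.5×10⁴) violates the Af identity and is treated as a typesetting
artifact, not behaviour to reproduce. Whether the source analysis
computed R² in transformed or original space is not stated; both are
implemented (`r2_space="original" | "transformed"`), default original.

## Model selection

Per condition, all (form, window) candidates are fitted and the best is
chosen lexicographically: highest R², then lowest SS, then lowest RMSE,
then |Af−1|, then |Bf−1|. R² leads because it is the only metric
defined for every fit, including `/` rows. Two values within a relative
tolerance of 1e-9 count as tied; criteria where either competitor is
not computable are skipped rather than disqualifying a candidate.
Residual ties resolve to the simpler law (zero order < exponential <
logarithmic), then to the fit using more points, then to the
earlier-starting, wider effective window — so on noiseless data the
generating window beats its own sub-windows, which fit equally well.
Selection is deterministic and independent of candidate order.

The window-selection rule of the source analysis is unknown; automatic
selection over the default window set documents, but cannot guarantee,
agreement with any given published per-condition window. Windows can be
pinned per condition in the configuration.

## Calibration

Quantitation uses unweighted linear external-calibration curves with the
declared ranges (µg/ml): glucose and fructose 28–7 000; HMF 0.007–58;
quinoxaline 3.2×10⁻³–2 (glyoxal); 2-methylquinoxaline 3.2×10⁻³–2
(methylglyoxal); 2,3-dimethylquinoxaline 6.4×10⁻⁴–2 (diacetyl);
2-(2,3,4-trihydroxybutyl)-quinoxaline 8.2×10⁻³–2.1 (3-deoxyglucosone,
and the semi-quantitation surrogate for glucosone, 1-deoxyglucosone and
3,4-dideoxyglucosone, expressed via `surrogate_for`). Inverse
prediction divides out the slope, subtracts the intercept and applies
the dilution factor; out-of-range estimates are flagged, not rejected.
Detection limits are not published, so the LOD defaults to the lowest
calibration standard, overridable per analyte.

## Synthetic panels

No raw concentration data are deposited for this study design, so the
generator rebuilds replicate panels from a registry transcribing the
fitted law of every condition (98 entries: 2 systems × 10 analytes × 5
temperatures, minus the two 90 ℃ glucose-only conditions that could
not be fitted). Unicode minus signs and digit-group commas in
transcribed coefficients are normalised at parse time.

Replicate scatter is multiplicative Gaussian: C = predict(t)·(1 + ε),
ε ~ N(0, cv²), with a single default cv of 0.05 — concentrations span
~nine orders of magnitude, so a constant coefficient of variation is
the only sensible one-parameter error model; the true replicate
variability is unpublished and 5 % is a convention chosen once.
Triplicates on the hourly grid restricted to each entry's published
window are the default, matching the study design. Generation is
deterministic given a seed; panel generation spawns per-entry
subseeds from the master seed.

Non-positive values — noise draws truncated at zero, and the four
registry lines that are non-positive at their window start
(zero-order rows with negative intercepts: HMF 95 ℃ glucose-only at
2 h; methylglyoxal 105/110 ℃ and diacetyl 110 ℃ glucose-Glu at 1 h) —
are emitted as censored (below-LOD) points. This preserves the
non-negativity invariant, reproduces the `/` pattern of the published
tables, and keeps ≥ 4 usable points in every affected condition, so
noiseless refits still recover every registry law exactly (the
effective window simply starts one hour later in those four rows).

What the generator does **not** emulate: inter-compound correlation
(each series is perturbed independently, whereas real Maillard
intermediates are mechanistically coupled), instrument drift and
heteroscedastic detector noise, the true magnitude of replicate
variability, and deviations of real trajectories from the idealised
laws outside their windows. Tests passing on synthetic panels therefore
validate the *analysis machinery* — not the chemistry — and
observed-data-dependent published summaries (e.g. a 4.21 % glucose
decrease, ratio 10.80, 920.83-fold HMF amplification) are approximated
but not reproduced: the pipeline reports its own values from whatever
panel it is given (the noiseless-panel analogues are 3.91 %, 10.83 and
so on).

## Derived summaries

All derived metrics operate on replicate means: percent consumption
100·(C(0) − C(t_ref))/C(0); compound ratios and glucose-Glu over
glucose-only fold changes at a reference time (default 6 h, zero or
censored denominators yield NaN markers); peak conditions as the argmax
over the (temperature, time) grid with ties to the cooler temperature
then the earlier time; and classical one-way ANOVA. The grouping
factor of the source analysis is unstated, so ANOVA is applied pairwise
per (compound, temperature, time) across the two systems, at α = 0.05.

## Numerical choices and problem sizes

* Selection tie tolerance 1e-9 (relative); noiseless generating fits
  reach R² = 1 to ~1e-12 while wrong-form fits stay below 1 − 3×10⁻⁵
  across the whole registry, so the tolerance is far from both sides.
* Panel CSVs store concentrations via `repr` and are re-parsed with
  Python's round-trip float parser, so write → read is bit-exact and
  the pipeline is byte-deterministic end to end.
* The stochastic parameter-recovery check uses cv = 0.05, triplicates
  and 100 master seeds over all 98 conditions (9 800 fits, a few
  seconds); the measured median relative error of the rate constant is
  ≈ 3 %, against an acceptance bound of 10 %.

## Known limitations

Empirical laws only — no mechanistic ODE network, no global
multi-temperature fitting, no weighted regression, no AIC/BIC or
bootstrap model confidence, no post-hoc multiple-comparison correction.
The package quantifies how well the three candidate laws describe a
panel; it does not decide whether any of them is chemically "true".
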