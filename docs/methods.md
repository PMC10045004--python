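# Methods

This note documents the models, algorithms and design choices behind
`drykin`, in the spirit of a statsmodels/scanpy methods appendix.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Moisture accounting

A drying run is a record of total wet mass `m(t)` (g) with a known
dry-solid mass `m_s`.  Dry-basis moisture is `M_t = (m − m_s)/m_s`
(kg water / kg dry matter); readings that fall below `m_s` from balance
noise are clamped to zero moisture and counted, not rejected.  The
moisture ratio is `MR = (M_t − M_e)/(M_0 − M_e)`; the equilibrium
moisture `M_e` of fresh high-moisture produce is small against `M_0`
and defaults to 0, giving `MR = M_t/M_0` and `MR(0) = 1`.  An 87 %
wet-basis initial moisture — the default of the synthetic designs —
corresponds to `M_0 = 0.87/0.13 = 6.6923` kg/kg db.  Time is minutes
everywhere in model space; the diffusivity estimator alone converts to
seconds.

## The 22-model catalog

The catalog holds the closed forms listed in the thin-layer drying
literature, with constants drawn from `{a, b, c, k, k1, k2, n, L1,
L2}`.  Four entries need interpretation, resolved as follows:

* **Chavez-Mendez et al.** is implemented as
  `MR = (1 − (1−L₂)·L₁·t)^(1/(1−L₂))`, the standard form of this model
  (as `L₂ → 1` it tends to `exp(−L₁t)`).  The expression is undefined
  for a negative base under a non-integer exponent; the public
  evaluator raises a `DomainError` there, while the fitter maps such
  points to a large residual penalty so that batch fitting never
  aborts.
* **Taghian Dinani et al.** reuses `a` as both Gaussian height and
  width, `MR = a·exp(−((t−b)/a)²)`; it is implemented literally with
  the single shared constant.  Whether the source form dropped a third
  constant in typesetting is unknowable from the printed equation.
* **Verma et al.** is implemented as
  `a·exp(−kt) + (1−a)·exp(−k₁t)` — the model's standard form —
  treating the printed first term without `t` as a typo.  In this form
  the model is anchored at `MR(0) = 1` and is flagged accordingly.
* **Sledz et al.** is `MR = b·e^(−kt)/(1 + a·e^(k₁t))` with the
  denominator sign literal, so the negative fitted `k₁` values of the
  reference tables are admissible as printed.
* **Modified Page 2**, `exp(−kt)^n = exp(−knt)`, is algebraically
  degenerate (`k·n` not separately identifiable) but is kept as listed
  and fitted literally.

Documented algebraic nestings (`Sledz a=0 → Henderson–Pabis`,
`Sledz k=0 → Logistic`, `Page n=1 → Newton`,
`Henderson–Pabis a=1 → Newton`) are exposed by `nested_reduction` and
verified to 1e−12 on a 100-point grid.

## Fitting

`ThinLayerModel.fit` minimises the unweighted SSE of MR with
`scipy.optimize.least_squares` (TRF, bounds, `x_scale='jac'`,
tolerances 1e−14).  Goodness of fit is reported as
`RMSE = sqrt(SSE/N)`, `χ² = SSE/(N−z)` with `z` the number of fitted
constants, and `R² = 1 − SSE/SS_tot` with `SS_tot` about the observed
mean — the coefficient of determination conventional in this
literature.  The three are linked by `χ² = N·RMSE²/(N−z)`, an identity
asserted for every fit the package produces.

Initialisation is deterministic and documented: decay rates start at
the |slope| of a log-linear regression of `ln(MR)` on `t` over the
points with MR > 0.01 (clipped to [1e−4, 5] min⁻¹); amplitudes start
from endpoint values; shape exponents at 1; the logistic-type
denominators at `a = 1` with `k₁ = −k`; and the three models linear in
their constants (Parabolic, Wang–Singh, Fernando–Amarasinghe) start
from an exact linear least-squares solve.  An optional seeded
multistart (log-normal perturbations of the start, count chosen by the
caller) is available for ill-conditioned cases but is off by default,
so a fit is a pure function of the data.  Bounds keep rates and
exponents positive and amplitudes wide ([0, 10⁷] for the logistic
pair), so degenerate-but-printed optima such as a logistic
`b ≈ 7.6×10⁵` remain representable.  The simplified Fickian form
`a·exp(−kt/L²)` is optimised in `k/L²` internally because its rate
constant is ~10⁷ smaller than every other constant.

A failed fit (optimizer breakdown, undefined statistics) is data, not
an exception: it is recorded with `converged=False` and infinite-SSE
sentinel statistics and simply ranks last.

**Selection rule.**  `SelectionTable` ranks by highest R², breaking
exact ties by lower RMSE, then fewer constants, then name.  A known
statistical limitation, demonstrated by the closure test: on noisy data
whose truth is a nested model, ranking by raw R² (equivalently raw SSE)
systematically prefers any supermodel with spare constants, because
each spare constant soaks up noise worth ~σ² of SSE.  Concretely, the
6-constant Modified Henderson–Pabis contains Henderson–Pabis, hence
also every pure-exponential Sledz truth (`a = 0`), and generically
out-ranks the 4-constant Sledz form on such data even though both fit
the truth exactly.  Of the three reported statistics only χ² carries a
degrees-of-freedom penalty, and in expectation it merely ties the
competitors.  Consistent selection of a nested truth requires an
information criterion, which is deliberately out of scope here; the
ranking implements the field's customary rule as stated.

## Effective moisture diffusivity

For an infinite slab of half-thickness `L` drying in the falling-rate
period, the Fickian series solution one-term linearisation gives
`F0 = D_eff·t/(4L²) = −0.101·ln(MR) − 0.0213`; the printed coefficients
equal `1/π² = 0.10132` and `ln(8/π²)/π² = −0.02128` at their printed
precision and are used literally.  `estimate_deff` regresses
`F0(MR_i)` on `t_i` in seconds over the interior points with
`0 < MR < 1` and returns `slope·4L²`; `L` is the **half** thickness
(0.25 mm for the default 0.5 mm slabs).  The regression-slope method is
the default because it uses all usable points and is robust to the
early multi-term transient; a per-point variant is exposed for
comparison.  On exact Fickian curves spanning MR ≈ 0.84 → 0.004 the
slope method recovers the generating diffusivity well within 1 % across
10⁻¹¹–10⁻⁹ m²/s (the residual bias is the 0.101/0.10132 rounding,
≈ 0.3 %).

Drying rate is reported as the absolute per-interval moisture loss
`DR = |ΔM_t|/Δt`; the raw finite difference is negative during drying,
but the field tabulates positive rates.  Its sum against Δt telescopes
to `M_0 − M_end`, a conservation identity the tests assert.

## Energy metrics

`SECe = 3600·E/(M_s·(X_i−X_f))` and
`EE = M_s·(X_i−X_f)·Δh_v/(3600·E)·100` with `E` in kWh, masses in kg
and `Δh_v = 2257` kJ/kg (water, 100 °C) by default.  `3600·E` is
dimensionally kJ, so SECe is returned in kJ per kg of evaporated water;
on that consistent basis `SECe·EE/100 = Δh_v` holds exactly and is
asserted to 1e−10 relative over randomized inputs.  Some published
tables print SECe magnitudes (e.g. ×10⁷ MJ/kg) that are not consistent
with this identity or with any unit system we could reconstruct; the
package makes no attempt to reproduce such values and reports the
literal formulas only.

## Assay statistics

Pigments use the linear acetone-extract equations
(`chl_a = 12.25·A₆₆₃.₆ − 2.25·A₆₄₆.₆`, etc.); the map is linear, so
negative outputs are optically possible and are flagged rather than
raised.  DPPH inhibition is `(1 − A_test/A_control)·100`, allowing
negative (pro-oxidant) values.  Standard-curve quantification fits an
OLS line to ≥ 3 calibration points, requires a positive slope, and
flags extrapolation outside the calibrated range.

Group comparison is one-way ANOVA with Fisher's **protected** LSD:
pairwise tests `|x̄_i − x̄_j| > t_{1−α/2,df_e}·sqrt(MSE·(1/n_i+1/n_j))`
are run only when the omnibus F is significant at α (default 0.05),
matching common statistical-package behaviour; an unprotected mode is a
documented option.  With zero pooled error and distinct means
(degenerate MSE) every distinct-mean pair is declared different.
Letters come from the insert-and-absorb compact-letter-display
algorithm, assigned in descending-mean order so that `a` marks the
highest-mean grouping; the display is order-invariant and its sharing
relation is tested against a brute-force all-pairs oracle.  Letters are
intended to be computed within one drying method at a time, mirroring
how such tables are annotated per method.

## Synthetic experiments

The generator emulates: truth MR curve on the protocol sampling grid
(10 min for CD, 0.5 min for MD), additive homoscedastic normal noise on
the MR scale (default sd 0.003, the magnitude of typical convective fit
RMSEs; multiplicative or hierarchical run-level noise is deliberately
not modelled), conversion to mass via
`m = m_s·(1 + M_0·MR)` with `m_s = 10 g × (1−0.87)`, quantisation to
the 0.01 g balance resolution (floored at `m_s − 2` resolutions, the
physical allowance), and truncation at the first window of
`stop_rule = 3` consecutive identical quantised readings — the
operationalisation of "dried to constant weight".

A consequence worth knowing: at the default noise, the MR-scale sd maps
to ≈ 0.026 g on the mass scale, 2.6 balance bins, so three independent
readings coincide with probability ~1 % per step and the stopping rule
fires late or not at all for many seeds.  A run that reaches the
documented horizon (1500 min CD, 120 min MD) without firing is
truncated there and flagged `stopped=False` rather than raised, so
batch pipelines never abort; at low noise (≲ half a bin) the rule fires
deterministically just after the curve flattens.  Real balances average
internally and real operators judge "constant weight" on a trend, so
the generator's stop times are noisier than bench stop times; the
generator is for exercising the analysis, not for calibrating stopping
behaviour.

What passing tests on synthetic data do **not** show: robustness to
shrinkage, case-hardening, non-Gaussian or heteroscedastic noise,
replicate-level variability between runs, or temperature-dependent
diffusivity (no Arrhenius analysis is included).  Truth curves are
empirical catalog forms or the exact Fickian series, not a
heat/mass-transfer simulation.

Energy for synthetic runs is `E = P·t` with the set microwave power, or
the nominal oven power (1.5 kW) times an arbitrary 0.4 thermostat duty
factor for CD — enough to exercise the energy module, not a metering
model.

## Numerical choices and degenerate inputs

* Optimizer tolerances 1e−14 (ftol/xtol/gtol), max 5000 evaluations;
  undefined model values inside the optimizer become a fixed 1e3
  residual penalty.
* `goodness_of_fit` raises on `N ≤ z` and on constant observations
  (R² undefined); `fit_catalog` converts those into failed-fit rows.
* Deff estimation requires ≥ 3 interior points and flags a non-positive
  slope instead of silently returning a negative diffusivity.
* Letter assignment with k groups uses at most k letters; columns are
  sorted by their best-ranked member before lettering, making the
  output deterministic.
* All randomness is `numpy.random.default_rng` seeded explicitly; a
  fixed seed reproduces runs byte-for-byte, including the CSV files.

## Problem sizes used by the test suite

Curve fits use the protocol grids (≈ 45–130 observations).  The
full-closure check fits the complete 22-model catalog on 20 seeded
replicates of each of the nine reference conditions; the Monte-Carlo
RMSE check uses 200 replicates of a 46-point exponential run; the
letter-display oracle uses 50 random tables of 3–7 groups × 3–5
replicates.  These sizes were chosen to make the statistical assertions
stable at desk scale.

## Known limitations

* Model selection by raw R²/RMSE cannot consistently prefer a nested
  truth over a supermodel (see *Selection rule* above); rankings on
  noisy data should be read jointly with χ² and parameter counts.
* The Sledz parametrisation is only locally identifiable: `b` and `a`
  trade off along a `b/(1+a)` ridge whenever the denominator decays
  slowly, and `k₁` is dead once its term decays before the second
  sample.  Fitted constants should be interpreted through the nested
  reductions when `a ≈ 0` or `|k₁|` is large.
* Printed-table diffusivities and energy magnitudes from bench studies
  are often not recoverable from printed quantities alone; this package
  computes the literal formulas and documents, rather than resolves,
  such inconsistencies.
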