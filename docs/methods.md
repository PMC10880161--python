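# Methods

## Problem

A published logistic regression model

p = σ(β₀ + Σᵢ₌₁..d βᵢ xᵢ),  σ(x) = 1/(1+e⁻ˣ),

optionally with a decision threshold θ ∈ (0,1) (high risk iff p > θ),
is to be converted into a nomogram using only the coefficient vector,
the intercept, and each predictor's admissible range [minᵢ, maxᵢ].
No training data are available, so nothing may be refit; the chart must
be an exact re-encoding of the given model.

## Point assignment

Each predictor's *absolute maximum beta value* is

sᵢ = |βᵢ| · (maxᵢ − minᵢ),

its largest attainable absolute contribution to the log-odds. The
predictor maximising sᵢ is the **initializer** and is assigned the full
point scale P^max; ties break to the lowest file index so construction
is deterministic. Every predictor j receives

Pⱼ^max = P^max · sⱼ / sᵢ,

and values map affinely onto its point axis:

Pⱼ(v) = (v − minⱼ)/(maxⱼ − minⱼ) · Pⱼ^max   if βⱼ ≥ 0,
Pⱼ(v) = (maxⱼ − v)/(maxⱼ − minⱼ) · Pⱼ^max   if βⱼ < 0.

The orientation flip for negative coefficients makes every axis
"rightward = more risk". Because Pⱼ^max is a ratio of scores,
multiplying all coefficients by a common positive constant leaves every
point value unchanged (tested).

P^max defaults to 100 — the conventional full scale of clinical point
charts — and is user-configurable (`p_max` in `build_point_scales`,
`--pmax` on the CLI).

## Probability assignment

With each axis oriented as above, the total P_total = Σⱼ Pⱼ(xⱼ) is an
affine image of the linear predictor: writing

min_value = Σ_{βᵢ≥0} βᵢ minᵢ + Σ_{βᵢ<0} βᵢ maxᵢ + β₀,
max_value = Σ_{βᵢ≥0} βᵢ maxᵢ + Σ_{βᵢ<0} βᵢ minᵢ + β₀,
P_total^max = Σⱼ Pⱼ^max,

one has identically

β₀ + Σ βᵢxᵢ = min_value + (P_total / P_total^max)(max_value − min_value),

so mapping the total ruler proportionally onto
[min_value, max_value] and applying the sigmoid reproduces the model
probability exactly. This *master round-trip identity* is the
package's core correctness property and is enforced to 1e−9 absolute
over ≥1000 random (model, patient) pairs in the test suite. A useful
algebraic corollary, also tested: P_total^max = (max_value −
min_value) · P^max / sᵢ.

The probability panel draws this sigmoid over the total-points scale
with a *uniformly spaced* probability axis, rather than projecting
probability onto an unevenly stretched ruler as traditional nomograms
do; the threshold θ, when attainable, is marked at its exact preimage
on the total ruler.

## Nominal variables

One-hot levels are declared in the template as rows named
`parent::level` with range [0,1] (enforced at validation). The score,
point and range formulas treat every level as an independent [0,1]
predictor — faithful to the construction above — even though levels are
mutually exclusive, so min_value/max_value cover a superset of the
totals actually attainable. The round-trip identity still holds at
every *feasible* one-hot assignment (at most one active level), which
is all the chart is ever used for; the only cost is that the outer ends
of the total ruler and probability axis may be unreachable. At layout
time the levels of a group are merged onto a single dashed axis, each
level labelled at the point value it contributes when active, with an
implicit baseline at 0 points (a `(ref)` tick when no level sits
there).

## Evaluation modes and the reading-error bound

*Exact* mode keeps all points as reals. *Graphical* mode emulates
reading the printed chart: each per-predictor point and the total
lookup are rounded to the nearest multiple of a tick granularity g
(default 10 points — chart rulers are typically labelled every 10
points and read to the nearest label). Each of the d predictor axes and
the total ruler contributes at most g/2 points of rounding error; the
affine bridge to the sigmoid input has slope
(max_value−min_value)/P_total^max, and the sigmoid is 1/4-Lipschitz, so

|p_graphical − p_exact| ≤ ¼ · (max_value−min_value)/P_total^max · (d+1) · g/2.

This bound is asserted over random models, and with zero reading noise
a risk label can only flip for cases whose exact probability lies
within the bound of θ — misreads concentrate on near-threshold cases.
Rounding can push a point marginally past its axis maximum (e.g. 14
points at granularity 15); totals are clamped to [0, P_total^max]
before the lookup. The boundary case p = θ is labelled *low*: the
classification rule is a strict inequality for high risk, and strictness
resolves the otherwise-undefined boundary deterministically.

## Simulated-reader study

Human questionnaire studies of chart readability report discrimination
(confusion matrix, accuracy of read labels against model labels) and
calibration (binned read vs. model probability with 95% confidence
intervals). The simulator reproduces those summaries computationally:
each axis reading is the exact point value plus independent Gaussian
noise (SD in points, default 0), rounded to the granularity and clamped
to the axis; the total is rounded and clamped likewise. Calibration
uses equal-width bins on the read probability over [0,1] (default 10)
with a normal-approximation half-width z·sd/√n at 95% by default; empty
bins are reported with count 0 and no interval. The additive-Gaussian
noise model is the simplest plausible model of eye-positioning error;
real reader behaviour (fatigue, digit preference, transcription slips)
is not modelled, so simulator accuracy should be read as an upper bound
on what a careful human reader can achieve, not a prediction of any
particular study population.

## Template format

CSV (comma-separated, UTF-8, header row) or XLSX (first worksheet),
columns `feature, coef, min, max, type, position`; the header `family
coef` is accepted as a synonym for `coef`. Data row 1 carries the
intercept, row 2 the threshold (blank = no threshold; 0 and 1 are
rejected as non-informative). `type` ∈ {continuous, discrete, nominal,
ordinal}; `position` ∈ {up, down} selects the tick-label side.
Validation is total — every rejection carries a row/column locus — and
CSV writing uses the shortest round-tripping decimal form, making
write→read→write byte-stable. Degenerate rows: max < min is an error;
max = min is an error unless coef = 0 (dropped with a warning, since
the value→points map divides by the range); coef = 0 with a proper
range is kept with a warning (a flat axis).

## Axis layout and ticks

Vertical order: points ruler, predictors in file order, total ruler,
probability panel. Tick values come from a nice-step policy
({1, 2, 2.5, 5}×10^k, endpoints always included, count within a factor
of two of the target, default target 11); discrete and ordinal axes
enumerate every integer level up to 25 levels, then fall back to the
nice-step policy. Spans below 0.1% of the endpoint magnitude get
endpoint-only ticks. Predictor tick *positions* are computed through
the same value→points map used for evaluation, so axis geometry and
numerical evaluation cannot drift apart (asserted to 1e−9 in
normalized units). Rendering is matplotlib-based (SVG/PNG/PDF); SVG
output carries stable element ids per axis and pinned hash salt, and
timestamps are stripped, so output is deterministic for a fixed
geometry and library version.

## Synthetic data

`random_model` draws models from configurable range styles (unit-span
and wide continuous predictors, binary indicators, k-level one-hot
groups) with N(0, coef_scale) coefficients bounded away from zero and a
uniform threshold in (0.05, 0.95); `random_patients` draws values
uniformly within each range, integers for discrete/ordinal axes and at
most one active level per one-hot group. Everything is
`numpy.random.default_rng(seed)`-deterministic. These fixtures probe
the construction's algebra, not clinical realism: predictors are
independent and uniform, which real cohorts are not, so passing tests
demonstrate chart/model fidelity, not model quality on any population.

The bundled CMV-infection model carries its published coefficients,
intercept and threshold; its predictor *ranges* (age [0,100], gender
[0,1], underlying disease [0,1], prednisone dose [0,50], CD34⁺ count
[0,20]) are package defaults chosen to enclose plausible clinical
values, because only the coefficients were printed. Exact-mode
probabilities are provably invariant to the range choice (tested);
per-axis point values and printed axis extents are not.

## Problem sizes

The test suite exercises ~110 random models × 10 patients for the
round-trip identity, 30 models for the equation-transcription oracle,
25 models × 2 granularities for the reading-error bound, 200 models for
template round-trips, and simulated-reader studies of 120–200 cases;
the whole suite runs in a few seconds on one CPU. These sizes were
chosen as comfortably past the point where failures of the tested
algebraic identities would appear, since the identities are exact
rather than statistical.

## Known limitations

- Strictly linear logistic models only: no splines, interactions or
  per-predictor transformations.
- The nominal-group superset effect above slightly stretches the total
  ruler for models with one-hot groups.
- Byte-identical vector output across matplotlib versions is not
  promised; structural SVG properties are.
- The simulator's noise model is additive Gaussian per axis; it does
  not emulate human digit preference or fatigue.
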