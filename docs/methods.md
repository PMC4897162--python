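# Methods

## Model

The package forecasts a short, strictly positive annual count series
x⁰(k), k = 1..n (n ≥ 4) under the assumption that its *smoothed* level
decays or grows exponentially while the year-to-year fluctuation is
multiplicative. Three stages:

**Grey trend.** The mean-generated sequence
x̄⁽⁰⁾(k) = (x⁰(k)+x⁰(k−1))/2 (k = 2..n) damps single-year spikes; its
accumulation x̄⁽¹⁾(k) = Σₘ₌₂ᵏ x̄⁽⁰⁾(m) is fitted by the nonhomogeneous
exponential b·e^{a(k−1)} − c. The development coefficient

  a = ln( Σₖ₌₃ⁿ x̄⁽⁰⁾(k−1)·x̄⁽⁰⁾(k) / Σₖ₌₃ⁿ x̄⁽⁰⁾(k−1)² )

is a weighted log-ratio: on a geometric sequence every term of the
quotient equals the common ratio, so recovery is exact (this is a
tested invariant, to 1e−10 across random (a, M, n)). The amplitude b
is the simple-regression slope of x̄⁽¹⁾(k) on e^{a(k−1)} with sample
count n−1; the offset c = (1/(n−1))(b·Σ e^{a·k} − Σ x̄⁽¹⁾(k)) uses the
regressor one step ahead of b's — an asymmetry of the estimator family
we keep as defined and flag in the JSON fit report. c (and U = a·c)
enter only the accumulated-level response; the restored prediction
uses a and b alone through M = (1−e^{−a})·b/(1+e^{−a}):

  x̂⁰(k) = 2M·e^{a(k−1)},  k ≥ 2.

k = 1 has no restored value (the estimators are anchored at k = 2);
the table-compatibility display prints 0 there.

**Exponent conventions.** The case study this package reproduces
evaluates restored values one step ahead of the formula above:
its published fitted column equals 2M·e^{a·k} for the parameters
refit from the raw data (agreement within 0.04% for 1991–2009, and
the convention predicts ≈3972 for 2010 where the published 3987 is a
suspected digit transposition of ≈3973). `restored_fit` therefore
takes an explicit `shift` argument: 0 is the model's own anchoring,
1 the published-table convention. `PipelineConfig.exponent_shift`
defaults to 1 so the tool reproduces the published tables; the two
conventions differ by the constant factor e^a (−3.4% on the case
study). The residual layer uses the matching convention: a layer's
modelled magnitude at original index k is 2M₁·e^{a₁·k}, which is the
reading under which the published residual parameters
(a₁ = −0.0632, b₁ = −21827.6) reproduce the published amended column
to ±1 count. The published development pair (a = −0.039436,
b = −236878) is *not* reproducible from the raw series under any
convention and is kept only as a reference constant.

**Residual correction.** Residuals ε(k) = x̂⁰(k) − x⁰(k) generally
change sign, so one grey model is fitted to the magnitudes |ε(k)| and
applied with the per-index training signs: the correction is
subtracted where ε(k) > 0 and added where ε(k) < 0 (zero residuals
get no correction). Beyond the training window the sign of the latest
nonzero training residual is used. Rounds iterate on the residuals of
the current corrected fit until max|Δ(k)| ≤ tol or `max_rounds` is
reached; defaults tol = 0.10, max_rounds = 3 (the source procedure
iterates "until accuracy suffices" without naming a number; 10%
maximum relative deviation is a common grey-model acceptance level,
and three rounds bound the work on series this short). The layer
fitter re-indexes the magnitude sequence from 1 and folds the
resulting index offset into its stored amplitude, so that a fitted
layer and an externally supplied (a₁, b₁) layer evaluate identically;
exact exponential residual magnitudes are recovered to 1e−10 and one
round cancels them to machine precision (tested). Corrections that
would drive a fitted value to zero or below raise an error naming the
index. All-zero residuals yield a no-op layer; constant magnitudes a
degenerate constant-correction layer.

**Markov state adjustment.** The ratio Y(k) = actual/amended is
discretised into m contiguous interval states. Division methods:
`fixed` (explicit boundaries — the case study's four bands
60–75 / 75–90 / 90–105 / 105–120%), `equal_width`, and `cluster`
(1-D agglomerative clustering, complete linkage, contiguity
constrained via a chain connectivity graph, boundaries at midpoints
between adjacent clusters; outer bounds padded to whole percents).
Membership is half-open [lo, hi) with the top interval closed, so
boundary ratios assign deterministically; out-of-range ratios clip to
the extreme states with a warning. Transition probabilities are
Pᵢⱼ(r) = Mᵢⱼ(r)/Mᵢ counted over all pairs r steps apart; rows never
visited are undefined and fall back to a uniform distribution with a
warning (with ~20 observations empty rows are routine, and failing
hard would break horizon forecasting). State prediction takes the
argmax of the current row of P(1), consulting P(2), P(3), … on ties,
then the nearest state to the current one, then the lower index —
a fully deterministic rule. The adjusted forecast replaces the point
ratio by the predicted band's midpoint:
x′⁰(k) = x̂′⁰(k)·½(⊗₁ᵢ+⊗₂ᵢ), which always lies inside the band times
the base (tested invariant).

**Pipeline.** `run_pipeline` chains the stages and reports, per year:
grey fit, amended fit, ratio, observed state, one-step-ahead
state-adjusted value (each year's state predicted from the previous
year's observed state, matrices frozen from the full path), and
absolute relative errors to 3 display decimals. Horizon rows freeze
everything — grey parameters, residual layers (extrapolation signs),
transition matrices — and propagate the state chain by repeated
one-step prediction; nothing is refit, since the source material is
silent on refitting and freezing keeps the forecast a pure function
of the training window. The decline summary reports the arithmetic
mean of year-over-year percent declines 100·(1 − v(t)/v(t−1)) to one
decimal and a one-step projection at that rate (the case study's
2004–2013 window gives 16.8% and 1067·(1−0.168) = 887.7 → 888; the
source prose says "about 889", an unexplained rounding difference).
JSON reports carry full precision; CSV/text views apply the
table-style rounding (integer counts, whole-percent ratios, 3-decimal
errors), and every displayed number regenerates from the JSON values.

## Synthetic data

The generator emulates the model's own data-generating assumption:
x⁰(k) = 2M·e^{a(k−1)}·η(k) with multiplicative ratio noise η — none,
uniform on a band, or driven by a hidden Markov chain whose state
selects the band. Defaults mirror the case-study regime: a negative
development coefficient of a few percent per year (case study:
−0.0349), series lengths ~20, and a noise band of ±5% around unity.
Additive noise is deliberately absent: the accuracy indicator is a
ratio, so only ratio-scale noise keeps the process inside the model
family. One integer seed drives a single numpy Generator stream;
the fitting path itself contains no randomness.

What passing tests show — and do not. Parameter and state recovery on
these series demonstrate the estimators' correctness under the
model's assumptions; real accident series have level shifts, policy
interventions and reporting changes that are *not* multiplicative
band noise, and the case study's own 2008–2010 rows (errors up to
0.48 for the amended model) show what happens when the regime breaks.

## Known inconsistencies of the published case-study tables

Recorded here because the reproduction tests must exclude them:

* the published development pair (a, b) cannot regenerate the
  published fitted column; refitting the raw series can (above);
* the published 2010 fitted value 3987 breaks the otherwise constant
  fitted ratio (≈3973 expected);
* the amended value for 1996 (5565) does not follow from any published
  numbers (arithmetic gives ≈7365), and the 2010 amended value
  inherits the misprinted base;
* the printed whole-percent ratios for 1996, 1998–2002 and 2008
  disagree with their own actual/amended quotients (e.g. 1998:
  6304/6823 = 92.4% printed as 93%);
* the 2011 Markov-model relative error prints 0.147 where its own
  columns give |2265−1973|/1973 = 0.148;
* the one-step transition matrix is printed garbled in the source;
  it is re-derived from the state path here, and its decisive entry
  (the row-4 maximum) agrees.

## Numerical choices and degenerate inputs

* |a| < 1e−12 is "no trend": the fit degenerates to the series mean,
  and horizon forecasting refuses with a dedicated error (the
  restored exponential and M collapse).
* Residual magnitudes of exactly zero are nudged to a negligible
  positive floor (10⁻⁹ × smallest positive magnitude) for the
  multiplicative fit; their correction sign is 0, so no correction is
  ever applied at those indices.
* Ties in the state-prediction argmax are resolved at 1e−12 absolute
  tolerance to make floating-point-equal probabilities compare equal.
* Series validation rejects zeros and gaps outright rather than
  imputing: the model is multiplicative and the Markov layer assumes
  a uniform annual step.

## Limitations

Single-variable, annual-step series only; no confidence intervals
(the grey formalism is deterministic); the Markov layer is first-order
with interval states — no higher-order or fuzzy-membership chains; and
with ~20 observations the transition matrix rests on very few counts
per row, so predicted states beyond one or two steps carry little
information.
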