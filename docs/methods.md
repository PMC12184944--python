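# Methods

## Model

normcard evaluates, but never fits, GAMLSS-type norms models.  A model is
the family identifier plus, for each distribution parameter
(`mu`, `sigma`, `nu`, `tau` as the family requires), a link function, an
intercept, linear coefficients and P-spline smooth terms.  Evaluation at a
predictor combination `x` proceeds per parameter block as

```
eta = intercept + sum_j beta_j x_j + sum_l B_l(x) c_l
theta = g^{-1}(eta)
```

with `B_l(x)` the B-spline basis row of smooth `l` and `c_l` its penalized
coefficients, then the conditional CDF or quantile function of the family
is applied.  The smoothing penalty, smoothing parameters and information
criteria belong to fitting and are deliberately not represented: they are
irrelevant for prediction and the schema stores nothing that is not needed
for exact evaluation (this is also what keeps the document free of
individual-level data).

## Distributions

* `NO(mu, sigma)` — Gaussian via scipy.
* Box-Cox families (`BCCG`, `BCPE`, `BCT`) standardize `y > 0` by
  `z = ((y/mu)^nu - 1)/(nu sigma)`; `z` follows a standard normal, a
  unit-variance power exponential with kurtosis parameter `tau`, or a t
  distribution with `tau` degrees of freedom.  Positivity of `y` bounds
  `z`, and the base law is renormalized over that interval.  The
  truncation adjustment is always applied exactly; `truncation_mass`
  reports the removed mass (interesting when it exceeds 1e-12, e.g. at
  `sigma*|nu|` approaching 1).
* The power exponential CDF uses the regularized incomplete gamma
  `P(1/tau, (|z|/c)^tau / 2)` with `c = sqrt(2^{-2/tau} Γ(1/tau)/Γ(3/tau))`;
  its quantile inverts that chain through `gammaincinv`.  The whole
  quantile path (truncation unmapping, base quantile, inverse Box-Cox) is
  closed form — there is no root-finding anywhere, which is why a
  centile/score round trip holds to ~1e-13 relative.

Numerical choices:

* The Box-Cox transform switches to its log-limit form at `|nu| < 1e-5`;
  the seam is continuity-tested (adjacent values agree to ~1e-5 relative,
  the size of the first-order term dropped).
* `sigma <= 0`, `tau <= 0`, `mu <= 0` (Box-Cox) are errors, never clamped.
* `exp(eta)` overflow (`eta > 709`) raises instead of returning `inf`: a
  model producing such a linear predictor is broken, and an infinite
  parameter would poison every downstream quantity silently.
* The logit link saturates in double precision: forming `theta` near 1
  loses the information needed to recover `eta` beyond `|eta| ≈ 25`; round
  trips are exact to 1e-12 only inside roughly `|eta| <= 8`.  This is a
  property of the float representation, not of the implementation.

## P-spline basis reconstruction

A smooth is stored as `(range, ndx, degree, coefficients)`.  The knot
vector is implied: spacing `h = (xmax - xmin)/ndx`, `degree` extra knots on
each side, `ndx + 2*degree + 1` knots in total and a basis of dimension
`ndx + degree`.  This is the standard equidistant construction of the
penalized-spline literature and the only one consistent with printed
coefficient counts such as "20 intervals, degree 3, 23 coefficients".
Printed norm reports sometimes list a knot *subset* (e.g. "23 knots")
whose convention is ambiguous; the schema therefore never stores knots as
the primary encoding — an explicit equidistant knot vector is accepted on
input and converted.

Production evaluation uses `scipy.interpolate.BSpline.design_matrix`; the
Cox–de Boor recursion exists only as an independent oracle in the test
suite, so the two routes never share code.  Evaluation at the right
boundary treats the last interval as closed (rows still sum to 1 at
`xmax`).  Points outside `[xmin, xmax]` are an error in the basis layer;
the evaluator offers opt-in clamping to the range boundary, recording a
note in the result, because published norms define nothing outside the
modelled range.  Knot equidistance is checked at relative tolerance 1e-8.

## Schema and validation

Documents are UTF-8 JSON with `schema_version` "1.0"; readers reject other
major versions and, in strict mode (default), unknown fields.  Floats are
serialized with shortest round-trip repr, so write→read reproduces every
numeric field bit-for-bit.  `validate_model` collects *all* violations
rather than failing fast — an author fixing an export wants the complete
list — and is total (it reports, never raises).  The report renderer is a
deterministic layout (family and parameter list, then one block per
parameter in the order mu, sigma, nu, tau) rounded to 2 decimals by
default; the document always keeps full precision, the report is for
humans.

## Queries

Raw-scale predictor names (e.g. `age`) are converted through the declared
power transform `((raw + shift)/scale)^power`, so querying with `age = a`
is exactly querying with `nage = a^(1/2)`; supplying both forms at once is
an error.  Centiles are externally on the 0–100 scale; display rounding (1
decimal for centiles and scores) happens only at the CLI/service surface.
A linear term and a spline term on the same predictor contribute
additively, mirroring reports that print both.  Batch evaluation completes
the rows it can and annotates failed rows with the reason instead of
aborting the table.

## Synthetic data generator

`make_model` draws models whose inverse-linked parameters are
well-conditioned over the declared predictor range: `sigma` in roughly
[0.05, 0.5] (coefficient of variation typical of fitness and growth
outcomes), `tau` in [2, 20] (from near-Gaussian to heavy-tailed), `mu`
positive.  Spline coefficients are a mean-centred random walk of small
normal steps: fitted P-spline coefficients vary slowly along the basis,
and white noise would produce oscillating centile curves no real fit
exhibits.  The SLJ-shaped fixture carries the values a published
standing-long-jump report prints for its mu block (log link, intercept
3.60, linear transformed-age coefficient 0.42, cubic spline on 20
intervals over [2.24, 4.47]) and the age transform; its spline
coefficients and the sigma/nu/tau blocks are synthetic placeholders,
listed as such in the document's provenance.  A real published document is
a drop-in replacement.

What the generator does not emulate: sampling noise in coefficient
estimates, correlations between blocks that joint fitting induces,
heteroscedastic measurement error, or secular/cohort structure.  Passing
tests therefore demonstrate that evaluation of a *given* model is exact
and self-consistent — not that any particular published model is well
fitted.

## Verification strategy and problem sizes

* B-spline basis vs an independently written Cox–de Boor recursion:
  degrees 0–4, 1–10 intervals, 20 points, 50 random instances, agreement
  to 1e-12.
* Distribution CDFs vs quadrature of independently written densities on
  the outcome scale (normalization included), agreement to ~5e-7 (the
  quadrature budget).
* Family nesting: BCPE(`tau`=2) ≡ BCCG to 1e-10; BCT(`tau`=1e6) vs BCCG to
  1e-6; Gaussian vs the error function to 1e-12.
* Quantile∘CDF round trips across 50 random parameter sets per family to
  1e-8; score/centile inversion on 100 random query cases to 1e-8
  relative.
* Probability integral transform: scores simulated from a model's own
  conditional law at 10 synthetic models × 3 query points, n = 10^4 each,
  Kolmogorov–Smirnov uniformity at the 1% level.  With 30 independent
  tests at that level, an occasional single rejection is the expected
  false-positive rate of the check itself, not an evaluator defect; the
  test suite uses fixed seeds, and the acceptance script reports the
  pass count and minimum p-value for whatever seed it is given.
* The web service is exercised over a real socket (threaded stdlib server)
  and must agree with library calls to display precision.

## Design choices on genuinely open points

* Out-of-range queries reject by default; clamping is opt-in and noted.
* The service loads models at startup only (no upload endpoint): the
  publishing workflow is an author deploying a fixed model, and accepting
  uploads would turn an evaluation service into a storage service.
* The service is built on the standard library's threaded HTTP server:
  four JSON endpoints and one page do not justify a framework dependency.
* Per-request logging can be disabled (`--quiet`): query inputs are
  personal data (age, test scores).

## Limitations

* No fitting, model selection, diagnostics or smoothing-parameter logic.
* Only equidistant-knot P-splines; no fractional polynomials or cubic
  smoothing splines.
* Families limited to NO, BCCG, BCPE, BCT; links to identity, log, logit,
  inverse.
* Point evaluation only: no confidence intervals for centiles, no z-score
  output.
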