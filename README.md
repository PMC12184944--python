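# normcard

Portable, privacy-preserving norm models — publish a fitted GAMLSS-type
norms model as a small JSON document and evaluate it exactly: the centile
for any raw score, the score at any centile, full centile curves, batch
tables, a CLI, and a minimal web service.

## The problem

Norm-referenced tests (fitness batteries, growth charts, cognitive scales)
compare an individual's score with a reference population whose
distribution depends on norm-predictors such as age.  Regression-based
("continuous") norming models the full conditional distribution of the
score, typically with GAMLSS: up to four distribution parameters

- `mu` (location), `sigma` (scale), `nu` (skewness), `tau` (kurtosis),

each linked to the predictors through a monotone link function `g`:

```
g_k(theta_k) = beta_k0 + sum_j beta_kj * x_j + sum_l s_kl(x_l)
```

where each smooth `s_kl` is a P-spline: a B-spline basis of degree `d` on
`ndx` equidistant intervals over `[xmin, xmax]`, with `ndx + d` fitted
(penalized) coefficients.  Supported families: `NO` (Gaussian), `BCCG`
(Box-Cox Cole-Green, the LMS method), `BCPE` (Box-Cox power exponential)
and `BCT` (Box-Cox t).  For the Box-Cox families the score `y > 0` is
standardized by

```
z = ((y/mu)^nu - 1) / (nu * sigma)      (nu != 0;  log(y/mu)/sigma at nu = 0)
```

and `z` follows a standard normal, power exponential or t distribution,
renormalized for the positivity constraint (`z` is bounded by
`±1/(sigma*|nu|)`).  The centile of a score is `100 * F(y)`; the score at a
centile is the quantile `F^{-1}(p)` — both closed-form here, with no
root-finding.

Published papers usually print only selected centiles for selected ages,
which cannot answer exact queries; sharing the fitted model object may leak
the individual training data.  The schema in this package carries exactly
the model-level quantities needed for exact evaluation — family, links,
linear coefficients, spline geometry and penalized coefficients — and
nothing about any individual, so it can be published freely.  It is aimed
at authors of norms (who export their fit once) and at practitioners and
tool builders (who evaluate it anywhere).

## Worked example

The repository ships a synthetic fixture shaped exactly like a published
standing-long-jump (SLJ) norms model for boys: Box-Cox t family, all four
parameters modelled on transformed age `nage = age^(1/2)` with cubic
P-splines (20 intervals over `nage` in `[2.24, 4.47]`, i.e. 23 penalized
coefficients per block), `mu` with log link, intercept 3.60 and linear
`nage` coefficient 0.42.  Its spline coefficients are synthetic
placeholders, so the numbers below are fixture-specific demonstrations,
not published norms.

```python
>>> import normcard as nc
>>> m = nc.slj_like_model()
>>> round(nc.centile(m, 140, {"age": 10}), 1)   # raw age accepted
54.3
>>> round(nc.score(m, 90, {"age": 10}), 1)      # 90th-centile SLJ in cm
168.1
```

A 10-year-old jumping 140 cm sits at the 54.3rd centile of this fixture's
reference distribution, and the 90th centile at age 10 is 168.1 cm.  The
same via the CLI:

```sh
$ normcard centile --model tests/data/slj_like_synthetic.json --score 140 --at age=10
54.3
$ normcard report --model tests/data/slj_like_synthetic.json | head -3
Family: BCT (parameters: mu, sigma, nu, tau)
Outcome: Standing Long Jump (cm)
Predictor: nage = age^0.5, range [2.24, 4.47]
$ normcard curves --model tests/data/slj_like_synthetic.json --xname nage --out curves.csv
$ normcard serve --model tests/data/slj_like_synthetic.json --port 8080
```

`curves` writes the classical nine centile curves (P10…P90) on the raw age
scale; `serve` starts a dependency-free web page and JSON API
(`POST /centile`, `POST /score`, `GET /curves`, `GET /models`) so
non-programmers can evaluate scores.  To evaluate a real published model,
point `--model` at its schema document instead of the fixture.

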