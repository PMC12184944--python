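"""Independent test oracles, deliberately written against the textbook
definitions rather than the production code paths.

* Cox-de Boor recursion for B-spline bases, evaluated term by term.
* Conditional densities of the supported families, with the CDF obtained by
  numeric quadrature of the density on the outcome scale — sharing no code
  with the closed-form CDF/quantile chain under test.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special


# ---------------------------------------------------------------------------
# Cox-de Boor recursion

def coxdeboor(x: float, j: int, degree: int, knots: np.ndarray,
              closed_right: float | None = None) -> float:
    """Value of the j-th B-spline basis function by the plain recursion.

    ``closed_right`` (the interior right boundary) makes the interval ending
    there closed, matching evaluation on a closed range.
    """
    if degree == 0:
        if closed_right is not None and x == closed_right:
            # only the interval ending at the boundary counts there
            return 1.0 if (knots[j] < x
                           and abs(knots[j + 1] - x) <= 1e-12 * max(1.0, abs(x))
                           ) else 0.0
        return 1.0 if knots[j] <= x < knots[j + 1] else 0.0
    left = 0.0
    den = knots[j + degree] - knots[j]
    if den > 0:
        left = (x - knots[j]) / den * coxdeboor(x, j, degree - 1, knots, closed_right)
    right = 0.0
    den = knots[j + degree + 1] - knots[j + 1]
    if den > 0:
        right = ((knots[j + degree + 1] - x) / den
                 * coxdeboor(x, j + 1, degree - 1, knots, closed_right))
    return left + right


def basis_matrix_oracle(x, knots: np.ndarray, degree: int,
                        interior_hi: float) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n_basis = len(knots) - degree - 1
    out = np.empty((len(x), n_basis))
    for i, xi in enumerate(x):
        for j in range(n_basis):
            out[i, j] = coxdeboor(float(xi), j, degree, knots, closed_right=interior_hi)
    return out


# ---------------------------------------------------------------------------
# density-based distribution oracle

def _pe_const(tau: float) -> float:
    return float(np.sqrt(np.exp(-2.0 / tau * np.log(2.0)
                                + special.gammaln(1.0 / tau)
                                - special.gammaln(3.0 / tau))))


def _base_pdf(family_id: str, z: float, tau: float | None) -> float:
    if family_id in ("NO", "BCCG"):
        return float(np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi))
    if family_id == "BCT":
        return float(np.exp(special.gammaln((tau + 1) / 2)
                            - special.gammaln(tau / 2))
                     / np.sqrt(np.pi * tau)
                     * (1 + z * z / tau) ** (-(tau + 1) / 2))
    c = _pe_const(tau)  # BCPE: standardized power exponential
    return float(tau * np.exp(-0.5 * np.abs(z / c) ** tau)
                 / (c * 2 ** (1 + 1 / tau) * np.exp(special.gammaln(1 / tau))))


def density(family_id: str, y: float, mu: float, sigma: float,
            nu: float | None, tau: float | None) -> float:
    """Unnormalized conditional density on the outcome scale (the positivity
    renormalization is handled by the quadrature caller)."""
    if family_id == "NO":
        z = (y - mu) / sigma
        return _base_pdf("NO", z, None) / sigma
    if y <= 0:
        return 0.0
    if abs(nu) >= 1e-5:
        z = ((y / mu) ** nu - 1.0) / (nu * sigma)
        jac = y ** (nu - 1.0) / (mu ** nu * sigma)
    else:
        z = np.log(y / mu) / sigma
        jac = 1.0 / (y * sigma)
    return _base_pdf(family_id, z, tau) * jac


def cdf_by_quadrature(family_id: str, y: float, mu: float, sigma: float,
                      nu: float | None = None, tau: float | None = None) -> float:
    """P(Y <= y) by numeric integration of the density, renormalized to the
    (possibly truncated) support."""
    f = lambda t: density(family_id, t, mu, sigma, nu, tau)
    if family_id == "NO":
        lo = mu - 12 * sigma
        total = 1.0
        part, _ = integrate.quad(f, lo, y, limit=200)
        return part / total
    lo = 0.0
    # normalize over the full positive axis: bulk on a finite interval
    # anchored at the density peak, plus the (possibly heavy) upper tail
    anchor = mu * (1.0 + 10.0 * sigma) ** 2
    bulk = [mu * (1 - 2 * sigma), mu, mu * (1 + 2 * sigma)]
    body, _ = integrate.quad(f, lo, anchor, limit=400,
                             points=[b for b in bulk if lo < b < anchor],
                             epsabs=1e-11, epsrel=1e-11)
    tail, _ = integrate.quad(f, anchor, np.inf, limit=400,
                             epsabs=1e-12, epsrel=1e-11)
    total = body + tail
    part, _ = integrate.quad(f, lo, min(y, anchor), limit=400,
                             points=[b for b in bulk if lo < b < min(y, anchor)],
                             epsabs=1e-11, epsrel=1e-11)
    if y > anchor:
        extra, _ = integrate.quad(f, anchor, y, limit=400,
                                  epsabs=1e-12, epsrel=1e-11)
        part += extra
    return part / total
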