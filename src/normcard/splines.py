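"""Equidistant-knot B-spline bases for P-spline smooth terms.

A P-spline smooth is fully determined, for prediction, by its degree d, its
range [xmin, xmax], the number ndx of equidistant interior intervals, and
the ndx + d fitted (penalized) coefficients.  The knot vector is implied:
spacing h = (xmax - xmin)/ndx with d extra knots on each side, giving
ndx + 2d + 1 knots and a basis of dimension ndx + d.  This is the standard
construction of the penalized-spline literature and the only one consistent
with coefficient counts such as 20 intervals + degree 3 = 23 coefficients.

Evaluation at the right boundary xmax is defined by treating the last
interval as closed, so basis rows sum to 1 there too.  Points outside
[xmin, xmax] are an error at this layer; any clamping policy belongs to the
evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import DomainError, RangeError

#: relative tolerance for knot-equidistance checks
KNOT_RTOL = 1e-8


@dataclass(frozen=True)
class KnotVector:
    """A strictly increasing, equidistant knot sequence for one B-spline basis."""

    knots: np.ndarray
    degree: int
    interior_range: tuple[float, float]

    def __post_init__(self):
        object.__setattr__(self, "knots", np.asarray(self.knots, dtype=float))
        k, d = self.knots, self.degree
        if k.ndim != 1 or len(k) < d + 2:
            raise DomainError("knot vector too short for the stated degree")
        diffs = np.diff(k)
        if np.any(diffs <= 0):
            raise DomainError("knot vector must be strictly increasing")
        h = diffs.mean()
        if np.any(np.abs(diffs - h) > KNOT_RTOL * max(abs(h), 1.0)):
            raise DomainError("knot vector must be equidistant")
        lo, hi = self.interior_range
        scale = max(abs(hi - lo), 1.0)
        if abs(k[d] - lo) > KNOT_RTOL * scale or abs(k[len(k) - d - 1] - hi) > KNOT_RTOL * scale:
            raise DomainError("interior range does not match knots[degree], knots[-degree-1]")

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def n_intervals(self) -> int:
        return len(self.knots) - 2 * self.degree - 1


@dataclass(frozen=True)
class SplineTerm:
    """One P-spline smooth: predictor, basis geometry, penalized coefficients."""

    predictor_name: str
    degree: int
    range: tuple[float, float]
    n_intervals: int
    coefficients: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )


def build_knots(range_: tuple[float, float], n_intervals: int, degree: int) -> KnotVector:
    """Construct the implied equidistant knot vector of a P-spline term.

    Spacing h = (xmax - xmin)/n_intervals; knots run from xmin - degree*h to
    xmax + degree*h inclusive, step h (n_intervals + 2*degree + 1 knots).
    """
    xmin, xmax = float(range_[0]), float(range_[1])
    if not xmin < xmax:
        raise DomainError(f"degenerate spline range [{xmin}, {xmax}]: need xmin < xmax")
    if n_intervals < 1:
        raise DomainError(f"n_intervals must be >= 1, got {n_intervals}")
    if degree < 0:
        raise DomainError(f"degree must be >= 0, got {degree}")
    h = (xmax - xmin) / n_intervals
    idx = np.arange(-degree, n_intervals + degree + 1)
    # anchor arithmetic at xmin so knots[degree] == xmin exactly
    knots = xmin + idx * h
    return KnotVector(knots=knots, degree=int(degree), interior_range=(xmin, xmax))


def basis_matrix(x, knots: KnotVector) -> np.ndarray:
    """Evaluate all B-spline basis functions at the points x.

    Returns a dense (len(x), n_basis) matrix whose rows sum to 1 for every x
    in the closed interior range; at most degree+1 entries per row are
    non-zero.  Out-of-range x raises :class:`RangeError` naming the point.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = knots.interior_range
    bad = (x < lo) | (x > hi) | ~np.isfinite(x)
    if np.any(bad):
        raise RangeError(
            f"point(s) {x[bad].tolist()} outside the spline range [{lo}, {hi}]"
        )
    mat = BSpline.design_matrix(x, knots.knots, knots.degree, extrapolate=False)
    return np.asarray(mat.todense())


def spline_value(term: SplineTerm, x) -> np.ndarray:
    """Contribution of one P-spline term at x: basis(x) @ coefficients."""
    kv = build_knots(term.range, term.n_intervals, term.degree)
    if len(term.coefficients) != kv.n_basis:
        raise DomainError(
            f"spline term on {term.predictor_name!r}: {len(term.coefficients)} "
            f"coefficients but basis dimension is {kv.n_basis} "
            f"(n_intervals + degree = {term.n_intervals} + {term.degree})"
        )
    return basis_matrix(x, kv) @ term.coefficients
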