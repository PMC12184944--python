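"""Link functions relating linear predictors to distribution parameters.

GAMLSS models each distribution parameter theta on an unrestricted linear
scale eta through a strictly monotone link g, theta = g^{-1}(eta).  The four
links here (identity, log, logit, inverse) cover the defaults of every
family in the schema vocabulary: identity for unrestricted parameters, log
for positive ones (sigma, tau, and mu under positive support), logit for
parameters in (0, 1), and inverse (reciprocal) as the classical alternative
for positive parameters.

Unknown link names are a hard error, never a silent identity fallback.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError, LinkOverflowError

LINKS = ("identity", "log", "logit", "inverse")

# exp(eta) overflows float64 just above this; a model producing such eta is
# meaningless for evaluation, so it is reported instead of returning inf.
_EXP_OVERFLOW = 709.0


def _check_link(link_id: str) -> None:
    if link_id not in LINKS:
        raise DomainError(f"unknown link function {link_id!r}; expected one of {LINKS}")


def apply_inverse_link(link_id: str, eta):
    """Map linear predictor(s) eta to the parameter scale, g^{-1}(eta).

    Accepts scalars or arrays; returns the same shape.
    """
    _check_link(link_id)
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise DomainError("linear predictor eta must be finite")
    if link_id == "identity":
        out = eta.copy()
    elif link_id == "log":
        if np.any(eta > _EXP_OVERFLOW):
            raise LinkOverflowError(
                f"log link: eta exceeds {_EXP_OVERFLOW}, exp(eta) would overflow"
            )
        out = np.exp(eta)
    elif link_id == "logit":
        # numerically stable on both tails
        out = np.where(eta >= 0, 1.0 / (1.0 + np.exp(-eta)),
                       np.exp(eta) / (1.0 + np.exp(eta)))
    else:  # inverse
        if np.any(eta == 0.0):
            raise DomainError("inverse link: eta = 0 has no finite parameter value")
        out = 1.0 / eta
    return out if out.ndim else float(out)


def apply_link(link_id: str, theta):
    """Map parameter value(s) theta to the linear scale, g(theta).

    Exact functional inverse of :func:`apply_inverse_link` on the
    parameter's domain.
    """
    _check_link(link_id)
    theta = np.asarray(theta, dtype=float)
    if link_id == "identity":
        out = theta.copy()
    elif link_id == "log":
        if np.any(theta <= 0):
            raise DomainError("log link: parameter must be positive")
        out = np.log(theta)
    elif link_id == "logit":
        if np.any((theta <= 0) | (theta >= 1)):
            raise DomainError("logit link: parameter must lie in (0, 1)")
        out = np.log(theta) - np.log1p(-theta)
    else:  # inverse
        if np.any(theta == 0.0):
            raise DomainError("inverse link: parameter must be non-zero")
        out = 1.0 / theta
    return out if out.ndim else float(out)
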