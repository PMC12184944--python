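"""Synthetic norm models and simulated scores.

Real published norm models are external artifacts; everything in this
package is testable without one.  :func:`make_model` generates fully-known,
well-conditioned models for any supported family, and
:func:`slj_like_model` builds a model with the exact structure of a
published standing-long-jump norms report (Box-Cox t, all four parameters
smooth functions of transformed age) whose known coefficients are carried
verbatim and whose unknown ones are clearly-labelled synthetic placeholders.

Synthetic spline coefficients are drawn as a smooth random walk (cumulative
sum of small normal steps): fitted P-spline coefficients vary slowly along
the basis, and a white-noise draw would produce oscillating centile curves
no real fit exhibits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .distributions import family_sample
from .evaluate import predict_parameters
from .model import (BOX_COX_FAMILIES, FAMILY_PARAMS, NormModel, OutcomeSpec,
                    ParameterBlock, PowerTransform, PredictorSpec)
from .splines import SplineTerm

#: default link per parameter for Box-Cox families (mu positive => log)
_BC_LINKS = {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"}
_NO_LINKS = {"mu": "identity", "sigma": "log"}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic model.

    ``splines`` maps a parameter name to (degree, ndx) for blocks that get a
    P-spline on the first predictor; other blocks stay linear.  Magnitudes
    keep the inverse-linked parameters well-conditioned: sigma lands in
    [0.05, 0.5], tau in [2, 20], mu positive over the declared range.
    """

    family_id: str
    seed: int
    n_predictors: int = 1
    splines: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    with_linear: bool = True
    spline_amplitude: float = 0.08
    linear_scale: float = 0.25


def _walk(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    steps = rng.normal(0.0, amplitude / max(np.sqrt(n), 1.0), size=n)
    walk = np.cumsum(steps)
    return walk - walk.mean()


def make_model(spec: FixtureSpec) -> NormModel:
    """Deterministically generate a valid synthetic norm model."""
    if spec.family_id not in FAMILY_PARAMS:
        raise ValueError(f"unknown family {spec.family_id!r}")
    rng = np.random.default_rng(spec.seed)
    boxcox = spec.family_id in BOX_COX_FAMILIES
    links = _BC_LINKS if boxcox else _NO_LINKS

    predictors = tuple(
        PredictorSpec(name=f"x{i + 1}", valid_range=(0.0, 1.0))
        for i in range(spec.n_predictors)
    )
    # intercepts on the link scale, chosen for well-conditioned parameters
    intercepts = {
        "mu": (float(np.log(rng.uniform(50.0, 150.0))) if boxcox
               else float(rng.uniform(50.0, 150.0))),
        "sigma": float(np.log(rng.uniform(0.08, 0.35))),
        "nu": float(rng.uniform(-0.5, 1.5)),
        "tau": float(np.log(rng.uniform(4.0, 12.0))),
    }
    blocks = {}
    for pname in FAMILY_PARAMS[spec.family_id]:
        linear = ()
        if spec.with_linear:
            scale = spec.linear_scale if pname == "mu" else spec.linear_scale / 4.0
            linear = tuple(
                (p.name, float(rng.uniform(-scale, scale))) for p in predictors
            )
        spl = ()
        if pname in spec.splines:
            degree, ndx = spec.splines[pname]
            amp = spec.spline_amplitude if pname == "mu" else spec.spline_amplitude / 2.0
            spl = (SplineTerm(predictor_name=predictors[0].name, degree=degree,
                              range=(0.0, 1.0), n_intervals=ndx,
                              coefficients=_walk(rng, ndx + degree, amp)),)
        blocks[pname] = ParameterBlock(link_id=links[pname],
                                       intercept=intercepts[pname],
                                       linear_terms=linear, spline_terms=spl)
    outcome = OutcomeSpec(name="synthetic score", units="",
                          support="positive-real" if boxcox else "real")
    return NormModel(family_id=spec.family_id, outcome=outcome,
                     predictors=predictors, blocks=blocks,
                     provenance={"source": "synthetic fixture",
                                 "seed": spec.seed})


#: the values a published SLJ-boys norms report prints for its mu block
_SLJ_MU_INTERCEPT = 3.60
_SLJ_MU_NAGE_COEF = 0.42
_SLJ_NAGE_RANGE = (2.24, 4.47)
_SLJ_DEGREE = 3
_SLJ_NDX = 20
_SLJ_SEED = 20250623  # fixed: the synthetic placeholders are part of the fixture


def slj_like_model() -> NormModel:
    """A norms model structurally identical to the published SLJ-boys report.

    Box-Cox t family; all four parameters modelled on nage = age^(1/2) with
    a cubic P-spline (20 equidistant intervals, hence 23 penalized
    coefficients) over nage in [2.24, 4.47] (ages 5-20); mu uses the log
    link with intercept 3.60 and linear nage coefficient 0.42.  Those mu
    values, the spline geometry and the age transform are the published
    ones; every other coefficient is a synthetic placeholder (listed in the
    provenance), so centiles computed from this fixture are *not* the
    published norms.  Load the authors' published model document instead to
    reproduce them.
    """
    rng = np.random.default_rng(_SLJ_SEED)
    n_coef = _SLJ_NDX + _SLJ_DEGREE

    def spline(amplitude: float) -> SplineTerm:
        return SplineTerm(predictor_name="nage", degree=_SLJ_DEGREE,
                          range=_SLJ_NAGE_RANGE, n_intervals=_SLJ_NDX,
                          coefficients=_walk(rng, n_coef, amplitude))

    blocks = {
        "mu": ParameterBlock("log", _SLJ_MU_INTERCEPT,
                             (("nage", _SLJ_MU_NAGE_COEF),), (spline(0.10),)),
        "sigma": ParameterBlock("log", float(np.log(0.17)),
                                (("nage", float(rng.uniform(-0.05, 0.05))),),
                                (spline(0.05),)),
        "nu": ParameterBlock("identity", 1.0,
                             (("nage", float(rng.uniform(-0.1, 0.1))),),
                             (spline(0.05),)),
        "tau": ParameterBlock("log", float(np.log(10.0)),
                              (("nage", float(rng.uniform(-0.05, 0.05))),),
                              (spline(0.05),)),
    }
    return NormModel(
        family_id="BCT",
        outcome=OutcomeSpec(name="Standing Long Jump", units="cm",
                            support="positive-real"),
        predictors=(PredictorSpec(name="nage", raw_name="age",
                                  transform=PowerTransform(power=0.5),
                                  valid_range=_SLJ_NAGE_RANGE),),
        blocks=blocks,
        provenance={
            "source": "synthetic stand-in shaped like the published "
                      "SLJ-boys GAMLSS norms report",
            "published_fields": [
                "family", "predictor transform nage = age^(1/2)",
                "mu link/intercept/linear coefficient",
                "spline range, degree, ndx (all blocks)",
            ],
            "synthetic_fields": [
                "all spline coefficients",
                "sigma/nu/tau intercepts and linear coefficients",
            ],
        },
    )


def simulate_scores(model: NormModel, q: Mapping[str, float], n: int,
                    seed: int) -> np.ndarray:
    """Sample n scores from the model's conditional distribution at q."""
    params = predict_parameters(model, q)
    return family_sample(model.family_id, params, n, seed)
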