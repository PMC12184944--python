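"""Portable norm-model schema: types, JSON (de)serialization, validation, report.

A norm model is the complete, privacy-preserving description of one fitted
GAMLSS-type norms model: the distribution family, per-parameter link
functions, linear coefficients, and P-spline smooth terms.  It contains no
individual-level observation — only model-level quantities — so it can be
published freely while still supporting exact centile evaluation.

Serialized form (UTF-8 JSON, schema_version "1.0")::

    {"schema_version": "1.0",
     "family": "BCT",
     "outcome": {"name": "...", "units": "...", "support": "positive-real"},
     "predictors": [{"name": "nage", "raw_name": "age",
                     "transform": {"power": 0.5, "shift": 0, "scale": 1},
                     "range": [lo, hi]}],
     "parameters": {"mu": {"link": "log", "intercept": 3.6,
                           "linear": [{"name": "nage", "coef": 0.42}],
                           "splines": [{"name": "nage", "degree": 3,
                                        "range": [lo, hi], "ndx": 20,
                                        "coefficients": [...]}]},
                    ...},
     "provenance": {...}}

Numeric fields round-trip bit-for-bit (shortest-repr decimal serialization).
A spline may alternatively supply an explicit equidistant ``knots`` list,
which is converted to the canonical (range, ndx, degree) encoding on read.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ModelValidationError
from .links import LINKS
from .splines import SplineTerm, build_knots

SCHEMA_VERSION = "1.0"

#: required parameter set per family, in canonical order
FAMILY_PARAMS: dict[str, tuple[str, ...]] = {
    "NO": ("mu", "sigma"),
    "BCCG": ("mu", "sigma", "nu"),
    "BCPE": ("mu", "sigma", "nu", "tau"),
    "BCT": ("mu", "sigma", "nu", "tau"),
}

BOX_COX_FAMILIES = ("BCCG", "BCPE", "BCT")

_PARAM_ORDER = ("mu", "sigma", "nu", "tau")


@dataclass(frozen=True)
class PowerTransform:
    """Maps a raw predictor to the model scale: ((raw + shift)/scale)^power."""

    power: float
    shift: float = 0.0
    scale: float = 1.0

    def apply(self, raw: float) -> float:
        base = (raw + self.shift) / self.scale
        return base ** self.power


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    units: str = ""
    support: str = "real"  # "real" or "positive-real"


@dataclass(frozen=True)
class PredictorSpec:
    """One norm-predictor on the scale the model was fitted on.

    ``name`` is the transformed-scale name (e.g. nage); when a transform is
    declared, ``raw_name`` names the original-scale variable (e.g. age) and
    queries may supply either.
    """

    name: str
    valid_range: tuple[float, float]
    raw_name: str | None = None
    transform: PowerTransform | None = None


@dataclass(frozen=True)
class ParameterBlock:
    """Link + linear + smooth structure for one distribution parameter."""

    link_id: str
    intercept: float
    linear_terms: tuple[tuple[str, float], ...] = ()
    spline_terms: tuple[SplineTerm, ...] = ()


@dataclass(frozen=True)
class NormModel:
    """The complete portable description of one fitted norms model."""

    family_id: str
    outcome: OutcomeSpec
    predictors: tuple[PredictorSpec, ...]
    blocks: dict[str, ParameterBlock]
    provenance: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def predictor(self, name: str) -> PredictorSpec | None:
        for p in self.predictors:
            if p.name == name:
                return p
        return None

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return FAMILY_PARAMS[self.family_id]


# ---------------------------------------------------------------------------
# validation

def validate_model(model: NormModel) -> list[str]:
    """Check every schema invariant; return all violations (empty iff valid).

    Total: reports problems, never raises, for any structurally well-typed
    input.
    """
    v: list[str] = []
    if model.family_id not in FAMILY_PARAMS:
        v.append(f"family: unknown family {model.family_id!r}; "
                 f"expected one of {sorted(FAMILY_PARAMS)}")
        return v  # nothing else is checkable without a family

    required = set(FAMILY_PARAMS[model.family_id])
    present = set(model.blocks)
    for missing in sorted(required - present):
        v.append(f"parameters: missing parameter block {missing!r} "
                 f"required by family {model.family_id}")
    for extra in sorted(present - required):
        v.append(f"parameters.{extra}: family {model.family_id} does not "
                 f"use parameter {extra!r}")

    if model.family_id in BOX_COX_FAMILIES and model.outcome.support != "positive-real":
        v.append(f"outcome.support: must be 'positive-real' for Box-Cox "
                 f"family {model.family_id}, got {model.outcome.support!r}")

    names = [p.name for p in model.predictors]
    for n in sorted({n for n in names if names.count(n) > 1}):
        v.append(f"predictors: predictor {n!r} declared more than once")
    declared = set(names)

    for p in model.predictors:
        if p.transform is not None:
            if p.raw_name is None:
                v.append(f"predictors.{p.name}: transform declared without raw_name")
            if p.transform.power == 0:
                v.append(f"predictors.{p.name}.transform: power must be non-zero")
        lo, hi = p.valid_range
        if not lo < hi:
            v.append(f"predictors.{p.name}.range: need lo < hi, got [{lo}, {hi}]")

    for pname, block in model.blocks.items():
        path = f"parameters.{pname}"
        if block.link_id not in LINKS:
            v.append(f"{path}.link: unknown link {block.link_id!r}")
        if not math.isfinite(block.intercept):
            v.append(f"{path}.intercept: must be finite")
        lin_names = [n for n, _ in block.linear_terms]
        for n in sorted({n for n in lin_names if lin_names.count(n) > 1}):
            v.append(f"{path}.linear: predictor {n!r} appears more than once")
        spl_names = [t.predictor_name for t in block.spline_terms]
        for n in sorted({n for n in spl_names if spl_names.count(n) > 1}):
            v.append(f"{path}.splines: predictor {n!r} appears more than once")
        for n in lin_names + spl_names:
            if n not in declared:
                v.append(f"{path}: references undeclared predictor {n!r}")
        for t in block.spline_terms:
            tp = f"{path}.splines[{t.predictor_name}]"
            lo, hi = t.range
            if not lo < hi:
                v.append(f"{tp}.range: need xmin < xmax, got [{lo}, {hi}]")
                continue
            if t.n_intervals < 1:
                v.append(f"{tp}.ndx: must be >= 1, got {t.n_intervals}")
                continue
            if t.degree < 0:
                v.append(f"{tp}.degree: must be >= 0, got {t.degree}")
                continue
            want = t.n_intervals + t.degree
            if len(t.coefficients) != want:
                v.append(f"{tp}.coefficients: length {len(t.coefficients)} != "
                         f"ndx + degree = {t.n_intervals} + {t.degree} = {want}")
            if not np.all(np.isfinite(t.coefficients)):
                v.append(f"{tp}.coefficients: non-finite value present")
    return v


def _require_valid(model: NormModel) -> NormModel:
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    return model


# ---------------------------------------------------------------------------
# JSON reading

def _expect_keys(obj: dict, path: str, required: set[str], optional: set[str],
                 strict: bool) -> None:
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: expected a JSON object, got {type(obj).__name__}")
    for k in required:
        if k not in obj:
            raise FormatError(f"{path}: missing required field {k!r}")
    unknown = set(obj) - required - optional
    if unknown:
        msg = f"{path}: unknown field(s) {sorted(unknown)}"
        if strict:
            raise FormatError(msg)
        warnings.warn(msg, stacklevel=3)


def _num(obj, path: str) -> float:
    if isinstance(obj, bool) or not isinstance(obj, (int, float)):
        raise FormatError(f"{path}: expected a number, got {type(obj).__name__}")
    return float(obj)


def _interval(obj, path: str) -> tuple[float, float]:
    if not isinstance(obj, (list, tuple)) or len(obj) != 2:
        raise FormatError(f"{path}: expected [lo, hi]")
    return (_num(obj[0], f"{path}[0]"), _num(obj[1], f"{path}[1]"))


def _spline_from_json(obj: dict, path: str, strict: bool) -> SplineTerm:
    _expect_keys(obj, path, {"name", "degree", "coefficients"},
                 {"range", "ndx", "knots"}, strict)
    degree = obj["degree"]
    if not isinstance(degree, int) or degree < 0:
        raise FormatError(f"{path}.degree: expected a non-negative integer")
    coefs = obj["coefficients"]
    if not isinstance(coefs, list) or not coefs:
        raise FormatError(f"{path}.coefficients: expected a non-empty array")
    coefs = np.array([_num(c, f"{path}.coefficients[{i}]") for i, c in enumerate(coefs)])

    if "knots" in obj:
        # explicit equidistant knot vector: convert to (range, ndx, degree)
        knots = np.array([_num(k, f"{path}.knots[{i}]") for i, k in enumerate(obj["knots"])])
        ndx = len(knots) - 2 * degree - 1
        if ndx < 1:
            raise FormatError(f"{path}.knots: too few knots for degree {degree}")
        rng = (float(knots[degree]), float(knots[len(knots) - degree - 1]))
        try:
            implied = build_knots(rng, ndx, degree)
        except Exception as exc:
            raise FormatError(f"{path}.knots: {exc}") from exc
        if not np.allclose(implied.knots, knots, rtol=1e-8, atol=0):
            raise FormatError(f"{path}.knots: knot vector is not equidistant")
    else:
        if "range" not in obj or "ndx" not in obj:
            raise FormatError(f"{path}: need either 'knots' or both 'range' and 'ndx'")
        rng = _interval(obj["range"], f"{path}.range")
        ndx = obj["ndx"]
        if not isinstance(ndx, int) or ndx < 1:
            raise FormatError(f"{path}.ndx: expected a positive integer")
    return SplineTerm(predictor_name=str(obj["name"]), degree=degree,
                      range=rng, n_intervals=ndx, coefficients=coefs)


def _block_from_json(obj: dict, path: str, strict: bool) -> ParameterBlock:
    _expect_keys(obj, path, {"link", "intercept"}, {"linear", "splines"}, strict)
    linear = []
    for i, t in enumerate(obj.get("linear", [])):
        tp = f"{path}.linear[{i}]"
        _expect_keys(t, tp, {"name", "coef"}, set(), strict)
        linear.append((str(t["name"]), _num(t["coef"], f"{tp}.coef")))
    splines = tuple(
        _spline_from_json(s, f"{path}.splines[{i}]", strict)
        for i, s in enumerate(obj.get("splines", []))
    )
    return ParameterBlock(link_id=str(obj["link"]),
                          intercept=_num(obj["intercept"], f"{path}.intercept"),
                          linear_terms=tuple(linear), spline_terms=splines)


def read_model(document: str, strict: bool = True) -> NormModel:
    """Parse and validate a serialized norm-model document.

    Raises :class:`FormatError` on malformed JSON or wrong structure (naming
    the offending path) and :class:`ModelValidationError` listing *every*
    violated schema rule otherwise.
    """
    try:
        top = json.loads(document)
    except json.JSONDecodeError as exc:
        raise FormatError(f"document is not valid JSON: {exc}") from exc
    _expect_keys(top, "$", {"schema_version", "family", "outcome", "parameters"},
                 {"predictors", "provenance"}, strict)

    version = str(top["schema_version"])
    major = version.split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise FormatError(
            f"$.schema_version: unsupported major version {version!r} "
            f"(this reader supports {SCHEMA_VERSION})")

    oc = top["outcome"]
    _expect_keys(oc, "$.outcome", {"name"}, {"units", "support"}, strict)
    support = str(oc.get("support", "real"))
    if support not in ("real", "positive-real"):
        raise FormatError("$.outcome.support: expected 'real' or 'positive-real'")
    outcome = OutcomeSpec(name=str(oc["name"]), units=str(oc.get("units", "")),
                          support=support)

    predictors = []
    for i, p in enumerate(top.get("predictors", [])):
        pp = f"$.predictors[{i}]"
        _expect_keys(p, pp, {"name", "range"}, {"raw_name", "transform"}, strict)
        transform = None
        if p.get("transform") is not None:
            tj = p["transform"]
            _expect_keys(tj, f"{pp}.transform", {"power"}, {"shift", "scale"}, strict)
            transform = PowerTransform(power=_num(tj["power"], f"{pp}.transform.power"),
                                       shift=_num(tj.get("shift", 0.0), f"{pp}.transform.shift"),
                                       scale=_num(tj.get("scale", 1.0), f"{pp}.transform.scale"))
        predictors.append(PredictorSpec(
            name=str(p["name"]), valid_range=_interval(p["range"], f"{pp}.range"),
            raw_name=(str(p["raw_name"]) if p.get("raw_name") is not None else None),
            transform=transform))

    params = top["parameters"]
    if not isinstance(params, dict):
        raise FormatError("$.parameters: expected a JSON object")
    blocks = {
        str(name): _block_from_json(block, f"$.parameters.{name}", strict)
        for name, block in params.items()
    }

    model = NormModel(family_id=str(top["family"]), outcome=outcome,
                      predictors=tuple(predictors), blocks=blocks,
                      provenance=dict(top.get("provenance", {})),
                      schema_version=version)
    return _require_valid(model)


# ---------------------------------------------------------------------------
# JSON writing

def write_model(model: NormModel) -> str:
    """Serialize a valid model to its canonical JSON document.

    Floats are written with shortest round-trip repr, so
    ``read_model(write_model(m))`` reproduces every numeric field bit-for-bit.
    """
    _require_valid(model)
    doc = {
        "schema_version": model.schema_version,
        "family": model.family_id,
        "outcome": {"name": model.outcome.name, "units": model.outcome.units,
                    "support": model.outcome.support},
        "predictors": [
            {"name": p.name,
             **({"raw_name": p.raw_name} if p.raw_name is not None else {}),
             **({"transform": {"power": p.transform.power,
                               "shift": p.transform.shift,
                               "scale": p.transform.scale}}
                if p.transform is not None else {}),
             "range": list(p.valid_range)}
            for p in model.predictors
        ],
        "parameters": {
            name: {
                "link": b.link_id,
                "intercept": b.intercept,
                "linear": [{"name": n, "coef": c} for n, c in b.linear_terms],
                "splines": [
                    {"name": t.predictor_name, "degree": t.degree,
                     "range": list(t.range), "ndx": t.n_intervals,
                     "coefficients": t.coefficients.tolist()}
                    for t in b.spline_terms
                ],
            }
            for name, b in sorted(model.blocks.items(),
                                  key=lambda kv: _PARAM_ORDER.index(kv[0]))
        },
        "provenance": model.provenance,
    }
    return json.dumps(doc, indent=2, ensure_ascii=False)


# ---------------------------------------------------------------------------
# human-readable report

def _fmt(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}"


def render_report(model: NormModel, decimals: int = 2) -> str:
    """Render the model as the human-readable table a norms paper would print.

    Layout: the assumed distribution and its parameter list first, then one
    block per parameter (order mu, sigma, nu, tau) showing the link, the
    intercept and linear coefficients, and for every smooth term its range,
    degree, knots, and penalized coefficients, all rounded to ``decimals``.
    """
    _require_valid(model)
    lines: list[str] = []
    pnames = model.parameter_names
    lines.append(f"Family: {model.family_id} (parameters: {', '.join(pnames)})")
    if model.outcome.name:
        unit = f" ({model.outcome.units})" if model.outcome.units else ""
        lines.append(f"Outcome: {model.outcome.name}{unit}")
    for p in model.predictors:
        if p.transform is not None:
            t = p.transform
            inner = p.raw_name
            if t.shift != 0 or t.scale != 1:
                inner = f"(({p.raw_name} + {_fmt(t.shift, decimals)})/{_fmt(t.scale, decimals)})"
            lines.append(f"Predictor: {p.name} = {inner}^{t.power:g}, "
                         f"range [{_fmt(p.valid_range[0], decimals)}, "
                         f"{_fmt(p.valid_range[1], decimals)}]")
        else:
            lines.append(f"Predictor: {p.name}, range "
                         f"[{_fmt(p.valid_range[0], decimals)}, "
                         f"{_fmt(p.valid_range[1], decimals)}]")
    for name in pnames:
        b = model.blocks[name]
        lines.append("")
        lines.append(f"Parameter {name}:")
        lines.append(f"  link: {b.link_id}")
        coef_bits = [f"intercept = {_fmt(b.intercept, decimals)}"] + [
            f"{n} = {_fmt(c, decimals)}" for n, c in b.linear_terms
        ]
        lines.append(f"  linear coefficients: {', '.join(coef_bits)}")
        for t in b.spline_terms:
            kv = build_knots(t.range, t.n_intervals, t.degree)
            lines.append(f"  P-spline on {t.predictor_name}: "
                         f"range [{_fmt(t.range[0], decimals)}, {_fmt(t.range[1], decimals)}], "
                         f"degree {t.degree}, intervals {t.n_intervals}")
            lines.append("    knots: "
                         + ", ".join(_fmt(k, decimals) for k in kv.knots))
            lines.append("    penalized coefficients: "
                         + ", ".join(_fmt(c, decimals) for c in t.coefficients))
    return "\n".join(lines) + "\n"
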