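"""Exact evaluation of a portable norm model.

This layer answers the queries continuous norms exist for: the distribution
parameters at a predictor combination, the centile of a raw score, the
score at a centile, centile curves over a predictor grid, and batch
evaluation of delimited tables.

Queries may supply predictor values on the transformed scale the model was
fitted on (e.g. nage) or, when the model declares a power transform, on the
raw scale (e.g. age); raw values are converted exactly, so querying with
age a is identical to querying with nage = a^(1/2).

Out-of-range predictor values are a hard error by default.  Clamping to the
boundary of the valid range is an explicit opt-in and every clamped value
is recorded in the result notes — published norms do not define behaviour
outside the modelled range, so extrapolation is never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .distributions import DistributionParams, family_cdf, family_quantile
from .errors import QueryError, RangeError
from .links import apply_inverse_link
from .model import NormModel, PredictorSpec, validate_model
from .errors import ModelValidationError
from .splines import spline_value


def _require_valid(model: NormModel) -> None:
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)


def effective_range(model: NormModel, name: str) -> tuple[float, float]:
    """Valid interval for one predictor: its declared range intersected with
    the range of every spline term that uses it."""
    spec = model.predictor(name)
    if spec is None:
        raise QueryError(f"unknown predictor {name!r}")
    lo, hi = spec.valid_range
    for block in model.blocks.values():
        for t in block.spline_terms:
            if t.predictor_name == name:
                lo, hi = max(lo, t.range[0]), min(hi, t.range[1])
    return lo, hi


def _raw_to_transformed(spec: PredictorSpec, raw: float) -> float:
    if spec.transform is None:
        raise QueryError(
            f"predictor {spec.name!r} has no declared transform; "
            f"supply it by its model-scale name")
    return spec.transform.apply(float(raw))


def resolve_query(model: NormModel, values: Mapping[str, float],
                  clamp: bool = False) -> tuple[dict[str, float], list[str]]:
    """Normalize a query to transformed-scale values, one per model predictor.

    Accepts transformed names and raw names (converted via the declared
    transform).  Returns the resolved mapping and a list of notes (one per
    clamped value).  Raises :class:`QueryError` for unknown, duplicate, or
    missing predictors and :class:`RangeError` for out-of-range values when
    clamping is off.
    """
    by_raw = {p.raw_name: p for p in model.predictors if p.raw_name is not None}
    resolved: dict[str, float] = {}
    notes: list[str] = []
    for key, val in values.items():
        if model.predictor(key) is not None:
            name, tval = key, float(val)
        elif key in by_raw:
            spec = by_raw[key]
            name, tval = spec.name, _raw_to_transformed(spec, val)
        else:
            raise QueryError(f"unknown predictor {key!r}")
        if name in resolved:
            raise QueryError(f"predictor {name!r} supplied more than once "
                             f"(raw and transformed forms?)")
        resolved[name] = tval
    missing = [p.name for p in model.predictors if p.name not in resolved]
    if missing:
        raise QueryError(f"missing value(s) for predictor(s): {', '.join(missing)}")
    for name, tval in list(resolved.items()):
        lo, hi = effective_range(model, name)
        if not np.isfinite(tval):
            raise QueryError(f"predictor {name!r}: non-finite value")
        if tval < lo or tval > hi:
            if not clamp:
                raise RangeError(
                    f"predictor {name!r} = {tval:g} outside valid range [{lo:g}, {hi:g}]")
            clamped = min(max(tval, lo), hi)
            notes.append(f"{name} clamped from {tval:g} to {clamped:g}")
            resolved[name] = clamped
    return resolved, notes


def _block_eta(block, values: Mapping[str, np.ndarray]) -> np.ndarray:
    """Linear predictor of one parameter block over vectorized query values."""
    n = len(next(iter(values.values()))) if values else 1
    eta = np.full(n, block.intercept, dtype=float)
    for name, coef in block.linear_terms:
        eta += coef * values[name]
    for term in block.spline_terms:
        eta += spline_value(term, values[name_ := term.predictor_name])
    return eta


def _predict_arrays(model: NormModel,
                    values: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {
        pname: np.atleast_1d(apply_inverse_link(block.link_id,
                                                _block_eta(block, values)))
        for pname, block in model.blocks.items()
    }


def predict_parameters(model: NormModel, q: Mapping[str, float],
                       clamp: bool = False) -> DistributionParams:
    """Evaluate the distribution parameters at one predictor combination.

    For each parameter block: eta = intercept + sum of linear contributions
    + sum of spline contributions, then the inverse link maps eta to the
    parameter scale.
    """
    _require_valid(model)
    resolved, _ = resolve_query(model, q, clamp=clamp)
    arrays = {k: np.array([v]) for k, v in resolved.items()}
    out = _predict_arrays(model, arrays)
    return DistributionParams(**{k: float(v[0]) for k, v in out.items()})


def centile(model: NormModel, score: float, q: Mapping[str, float],
            clamp: bool = False) -> float:
    """Centile (0-100 scale) of a raw score at the given predictor values."""
    params = predict_parameters(model, q, clamp=clamp)
    return 100.0 * family_cdf(model.family_id, float(score), params)


def score(model: NormModel, centile_pct: float, q: Mapping[str, float],
          clamp: bool = False) -> float:
    """Raw score at a centile (0-100 scale); exact inverse of :func:`centile`."""
    if not 0.0 < centile_pct < 100.0:
        raise QueryError(f"centile must lie in (0, 100), got {centile_pct}")
    params = predict_parameters(model, q, clamp=clamp)
    return float(family_quantile(model.family_id, centile_pct / 100.0, params))


DEFAULT_LEVELS = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)


@dataclass
class CentileCurveTable:
    """Centile curves of one predictor: scores[i, j] is the levels[j]-th
    centile at grid point x[i] (transformed scale; x_raw when a raw-scale
    display transform exists)."""

    xname: str
    x: np.ndarray
    levels: tuple[float, ...]
    scores: np.ndarray
    x_raw: np.ndarray | None = None
    raw_name: str | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {}
        if self.x_raw is not None:
            data[self.raw_name or "x_raw"] = self.x_raw
        data[self.xname] = self.x
        for j, lev in enumerate(self.levels):
            data[f"P{lev:g}"] = self.scores[:, j]
        return pd.DataFrame(data)

    def plot(self, ax=None, **kwargs):
        """Draw the curves (raw scale on the x axis when available)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = self.x_raw if self.x_raw is not None else self.x
        for j, lev in enumerate(self.levels):
            ax.plot(xs, self.scores[:, j], label=f"P{lev:g}", **kwargs)
        ax.set_xlabel(self.raw_name if self.x_raw is not None else self.xname)
        ax.legend(fontsize="small")
        return ax


def centile_curves(model: NormModel, xname: str,
                   levels: tuple[float, ...] = DEFAULT_LEVELS,
                   grid_size: int = 100,
                   fixed: Mapping[str, float] | None = None,
                   x_display_transform: Callable[[np.ndarray], np.ndarray] | None = None,
                   clamp: bool = False) -> CentileCurveTable:
    """Centile curves over a grid of one predictor, others held fixed.

    The grid spans the predictor's effective range on the transformed scale.
    When the predictor declares a power transform (or an explicit display
    transform is given), the table carries the raw scale too, so curves plot
    against e.g. age rather than age^(1/2).
    """
    _require_valid(model)
    if grid_size < 1:
        raise QueryError(f"grid_size must be >= 1, got {grid_size}")
    levels = tuple(float(l) for l in levels)
    if not levels or any(not 0.0 < l < 100.0 for l in levels):
        raise QueryError("centile levels must lie in (0, 100)")
    spec = model.predictor(xname)
    if spec is None:
        by_raw = {p.raw_name: p for p in model.predictors if p.raw_name}
        if xname in by_raw:
            spec = by_raw[xname]
        else:
            raise QueryError(f"unknown predictor {xname!r}")
    lo, hi = effective_range(model, spec.name)
    x = np.linspace(lo, hi, grid_size) if grid_size > 1 else np.array([(lo + hi) / 2])

    fixed_resolved: dict[str, float] = {}
    if fixed:
        by_raw = {p.raw_name: p for p in model.predictors if p.raw_name}
        for key, val in fixed.items():
            p = model.predictor(key) or by_raw.get(key)
            if p is None:
                raise QueryError(f"unknown fixed predictor {key!r}")
            fixed_resolved[p.name] = (float(val) if model.predictor(key)
                                      else _raw_to_transformed(p, val))
    missing = [p.name for p in model.predictors
               if p.name != spec.name and p.name not in fixed_resolved]
    if missing:
        raise QueryError(f"fix the remaining predictor(s): {', '.join(missing)}")

    values = {spec.name: x}
    for name, val in fixed_resolved.items():
        rlo, rhi = effective_range(model, name)
        if (val < rlo or val > rhi) and not clamp:
            raise RangeError(f"fixed predictor {name!r} = {val:g} outside "
                             f"[{rlo:g}, {rhi:g}]")
        values[name] = np.full_like(x, min(max(val, rlo), rhi))

    params = _predict_arrays(model, values)
    nu = params.get("nu")
    tau = params.get("tau")
    scores = np.empty((len(x), len(levels)))
    for i in range(len(x)):
        pt = DistributionParams(
            mu=float(params["mu"][i]), sigma=float(params["sigma"][i]),
            nu=(float(nu[i]) if nu is not None else None),
            tau=(float(tau[i]) if tau is not None else None))
        scores[i, :] = family_quantile(model.family_id,
                                       np.array(levels) / 100.0, pt)
    order = np.argsort(levels)
    if np.any(np.diff(scores[:, order], axis=1) <= 0):
        raise RangeError("centile curves cross: quantiles not strictly "
                         "increasing across levels")  # defensive; quantile is monotone

    x_raw = None
    raw_name = None
    if x_display_transform is not None:
        x_raw = np.asarray(x_display_transform(x), dtype=float)
        raw_name = spec.raw_name or f"{spec.name}_display"
    elif spec.transform is not None and spec.raw_name is not None:
        t = spec.transform
        x_raw = t.scale * np.power(x, 1.0 / t.power) - t.shift
        raw_name = spec.raw_name
    return CentileCurveTable(xname=spec.name, x=x, levels=levels,
                             scores=scores, x_raw=x_raw, raw_name=raw_name)


def batch_evaluate(model: NormModel, table: pd.DataFrame, mode: str,
                   clamp: bool = False) -> pd.DataFrame:
    """Row-wise centile or score evaluation of a query table.

    ``mode`` is "centile" (table carries a ``score`` column) or "score"
    (table carries a ``centile`` column).  Row order is preserved; rows that
    fail evaluate to NaN with the reason in the ``note`` column, the others
    complete (partial-failure policy).
    """
    _require_valid(model)
    if mode not in ("centile", "score"):
        raise QueryError(f"mode must be 'centile' or 'score', got {mode!r}")
    input_col = "score" if mode == "centile" else "centile"
    if input_col not in table.columns:
        raise QueryError(f"mode {mode!r} requires a {input_col!r} column")
    pred_cols = [c for c in table.columns if c != input_col]
    if not pred_cols:
        raise QueryError("table has no predictor columns")

    out = table.copy()
    results: list[float] = []
    notes: list[str] = []
    fn = centile if mode == "centile" else score
    for _, row in table.iterrows():
        q = {c: row[c] for c in pred_cols}
        try:
            resolved, row_notes = resolve_query(model, q, clamp=clamp)
            results.append(fn(model, float(row[input_col]), resolved))
            notes.append("; ".join(row_notes))
        except Exception as exc:  # per-row failure policy
            results.append(float("nan"))
            notes.append(f"error: {exc}")
    out[mode] = results
    if any(notes):
        out["note"] = notes
    return out
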