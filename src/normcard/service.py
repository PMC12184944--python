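"""Minimal web service for norm evaluation, on the standard library only.

Models are loaded from documents at startup (no upload endpoint); the
service is stateless per request, so identical requests give identical
responses.  Endpoints:

* ``GET  /models``  — list of served model ids with family and predictors
* ``POST /centile`` — body {"model", "values": {name: number}, "score", ["clamp"]}
* ``POST /score``   — body {"model", "values": {...}, "centile", ["clamp"]}
* ``GET  /curves``  — query params model, xname, [levels, grid, name=value...]
* ``GET  /``        — one functional page: enter predictor values plus a
  score (returns the centile) or a centile (returns the score)

Malformed requests get 400/404; evaluation failures (missing predictor,
out-of-range value, domain errors) get 422 with a machine-readable reason.
Results are rounded to the display precision (1 decimal).
"""

from __future__ import annotations

import json
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Mapping
from urllib.parse import parse_qsl, urlparse

from . import evaluate
from .errors import NormcardError
from .model import NormModel

_PAGE = """<!doctype html>
<html><head><meta charset="utf-8"><title>Norm evaluation</title></head>
<body>
<h2>Norm evaluation</h2>
<form id="f">
  <label>Model <select id="model">{options}</select></label><br>
  <div id="preds"></div>
  <label>Score <input id="score" type="number" step="any"></input></label><br>
  <label>Centile <input id="centile" type="number" step="any"></input></label><br>
  <button type="submit">Evaluate</button>
</form>
<p id="result"></p>
<script>
const MODELS = {models_json};
function renderPreds() {{
  const m = MODELS[document.getElementById('model').value];
  document.getElementById('preds').innerHTML = m.inputs.map(p =>
    `<label>${{p}} <input data-pred="${{p}}" type="number" step="any"></input></label><br>`).join('');
}}
document.getElementById('model').addEventListener('change', renderPreds);
renderPreds();
document.getElementById('f').addEventListener('submit', async ev => {{
  ev.preventDefault();
  const values = {{}};
  document.querySelectorAll('[data-pred]').forEach(el => {{
    if (el.value !== '') values[el.dataset.pred] = parseFloat(el.value);
  }});
  const score = document.getElementById('score').value;
  const centile = document.getElementById('centile').value;
  const body = {{model: document.getElementById('model').value, values: values}};
  let path;
  if (score !== '') {{ path = '/centile'; body.score = parseFloat(score); }}
  else if (centile !== '') {{ path = '/score'; body.centile = parseFloat(centile); }}
  else {{ document.getElementById('result').textContent = 'enter a score or a centile'; return; }}
  const r = await fetch(path, {{method: 'POST', body: JSON.stringify(body)}});
  const j = await r.json();
  document.getElementById('result').textContent = JSON.stringify(j);
}});
</script>
</body></html>
"""


def _model_inputs(model: NormModel) -> list[str]:
    # prefer raw names on the page: users know "age", not "nage"
    return [p.raw_name or p.name for p in model.predictors]


class _Handler(BaseHTTPRequestHandler):
    models: Mapping[str, NormModel] = {}
    enable_log = True

    # -- plumbing ----------------------------------------------------------
    def log_message(self, fmt, *args):
        if self.enable_log:
            super().log_message(fmt, *args)

    def _send(self, status: int, payload, content_type="application/json"):
        body = (payload if isinstance(payload, bytes)
                else json.dumps(payload).encode("utf-8"))
        self.send_response(status)
        self.send_header("Content-Type", content_type)
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def _error(self, status: int, reason: str):
        self._send(status, {"error": reason})

    def _json_body(self):
        length = int(self.headers.get("Content-Length") or 0)
        raw = self.rfile.read(length) if length else b""
        try:
            body = json.loads(raw.decode("utf-8") or "{}")
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise ValueError(f"request body is not valid JSON: {exc}")
        if not isinstance(body, dict):
            raise ValueError("request body must be a JSON object")
        return body

    def _get_model(self, model_id) -> NormModel:
        if not model_id:
            raise LookupError("missing 'model'")
        if model_id not in self.models:
            raise LookupError(f"unknown model {model_id!r}; "
                              f"available: {sorted(self.models)}")
        return self.models[model_id]

    # -- endpoints ---------------------------------------------------------
    def do_GET(self):
        url = urlparse(self.path)
        if url.path == "/":
            meta = {mid: {"inputs": _model_inputs(m)}
                    for mid, m in self.models.items()}
            options = "".join(f'<option value="{mid}">{mid}</option>'
                              for mid in sorted(self.models))
            page = _PAGE.format(options=options, models_json=json.dumps(meta))
            self._send(200, page.encode("utf-8"), content_type="text/html")
        elif url.path == "/models":
            self._send(200, {"models": [
                {"id": mid, "family": m.family_id,
                 "outcome": m.outcome.name, "inputs": _model_inputs(m)}
                for mid, m in sorted(self.models.items())]})
        elif url.path == "/curves":
            self._curves(dict(parse_qsl(url.query)))
        else:
            self._error(404, f"no such path: {url.path}")

    def do_POST(self):
        if self.path not in ("/centile", "/score"):
            self._error(404, f"no such path: {self.path}")
            return
        try:
            body = self._json_body()
        except ValueError as exc:
            self._error(400, str(exc))
            return
        try:
            model = self._get_model(body.get("model"))
        except LookupError as exc:
            self._error(404, str(exc))
            return
        values = body.get("values")
        if not isinstance(values, dict):
            self._error(400, "missing or non-object 'values'")
            return
        clamp = bool(body.get("clamp", False))
        mode = self.path.lstrip("/")
        # /centile takes a raw score; /score takes a centile
        field = "score" if mode == "centile" else "centile"
        if field not in body:
            self._error(400, f"missing {field!r} field")
            return
        try:
            arg = float(body[field])
            resolved, notes = evaluate.resolve_query(model, values, clamp=clamp)
            if mode == "centile":
                result = evaluate.centile(model, arg, resolved)
                payload = {"centile": round(result, 1)}
            else:
                result = evaluate.score(model, arg, resolved)
                payload = {"score": round(result, 1)}
        except (NormcardError, ValueError, TypeError) as exc:
            self._error(422, str(exc))
            return
        if notes:
            payload["note"] = "; ".join(notes)
        self._send(200, payload)

    def _curves(self, params: dict[str, str]):
        try:
            model = self._get_model(params.pop("model", None))
        except LookupError as exc:
            self._error(404, str(exc))
            return
        xname = params.pop("xname", None)
        if not xname:
            self._error(400, "missing 'xname'")
            return
        try:
            levels = tuple(float(v) for v in
                           params.pop("levels", "10,20,30,40,50,60,70,80,90").split(","))
            grid = int(params.pop("grid", "100"))
            clamp = params.pop("clamp", "0") in ("1", "true", "yes")
            fixed = {k: float(v) for k, v in params.items()}
            table = evaluate.centile_curves(model, xname, levels=levels,
                                            grid_size=grid, fixed=fixed,
                                            clamp=clamp)
        except (NormcardError, ValueError) as exc:
            self._error(422, str(exc))
            return
        frame = table.to_frame()
        self._send(200, {"columns": list(frame.columns),
                         "data": frame.to_numpy().tolist()})


def make_server(models: Mapping[str, NormModel], host: str = "127.0.0.1",
                port: int = 8080, log: bool = True) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server; useful for tests."""
    handler = type("NormHandler", (_Handler,),
                   {"models": dict(models), "enable_log": log})
    return ThreadingHTTPServer((host, port), handler)


def run_server(models: Mapping[str, NormModel], host: str = "127.0.0.1",
               port: int = 8080, log: bool = True) -> None:
    server = make_server(models, host=host, port=port, log=log)
    try:
        server.serve_forever()
    except KeyboardInterrupt:
        pass
    finally:
        server.server_close()
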