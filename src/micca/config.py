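"""Declarative model/experiment configs (YAML or JSON).

Schema ``micca-model/1``::

    schema: micca-model/1
    model:
      states: [r, p]
      parameters: {k_r: 2.0, k_p: 3.0, g_r: 1.0, g_p: 2.0}
      rhs:                      # one expression per state; symbols: states,
        r: "k_r - g_r * r"      # parameters, t and the input u
        p: "k_p * r - g_p * p"
      initial_condition: [0, 0]   # numbers or expressions in the parameters
    experiments:
      - name: steady_state
        observe: [r, p]
        times: [40.0]               # or {start: ..., stop: ..., num: ...,
                                    #     spacing: linear|log}
        error_sd: 1.0
        overrides: {g_r: 0.0}       # optional parameter overrides
        initial_state: [30.0, 4.5]  # optional
        input:                      # optional piecewise-linear input u(t)
          times: [0, 5, 20, 25]
          values: [0, 1, 1, 0]

RHS expressions are parsed with sympy, and the state/parameter Jacobians of
the variational system are derived symbolically, so config-driven models get
analytic sensitivities for free.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import sympy as sp
import yaml

from .model import Experiment, OdeModel

__all__ = ["ConfigError", "load_config", "load_model_config"]

SCHEMA = "micca-model/1"


class ConfigError(ValueError):
    """Raised for schema violations, with the offending field named."""


def _require(mapping, key, where):
    if key not in mapping:
        raise ConfigError(f"missing required field {key!r} in {where}")
    return mapping[key]


def _parse_times(spec, where):
    if isinstance(spec, dict):
        start = float(_require(spec, "start", where))
        stop = float(_require(spec, "stop", where))
        num = int(_require(spec, "num", where))
        spacing = spec.get("spacing", "linear")
        if spacing == "linear":
            return np.linspace(start, stop, num)
        if spacing == "log":
            if start <= 0:
                raise ConfigError(f"log spacing needs start > 0 in {where}")
            return np.geomspace(start, stop, num)
        raise ConfigError(f"unknown spacing {spacing!r} in {where}")
    return np.asarray(spec, dtype=float)


def _piecewise_linear(times, values):
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 2:
        raise ConfigError("input profile needs equal-length times/values, >= 2 points")

    def profile(x, t=t, v=v):
        return float(np.interp(x, t, v))

    profile.breakpoints = tuple(t)  # type: ignore[attr-defined]
    return profile


def load_model_config(doc: dict, where: str = "config") -> tuple[OdeModel, list[Experiment]]:
    """Build an :class:`OdeModel` and its experiments from a parsed config."""
    if doc.get("schema") != SCHEMA:
        raise ConfigError(
            f"unsupported or missing schema in {where}: expected {SCHEMA!r}, "
            f"got {doc.get('schema')!r}"
        )
    mdoc = _require(doc, "model", where)
    states = list(_require(mdoc, "states", "model"))
    params = _require(mdoc, "parameters", "model")
    if not isinstance(params, dict) or not params:
        raise ConfigError("model.parameters must be a non-empty mapping")
    param_names = list(params)
    theta_star = np.array([float(params[p]) for p in param_names])

    t_sym = sp.Symbol("t")
    u_sym = sp.Symbol("u")
    state_syms = sp.symbols(states)
    param_syms = sp.symbols(param_names)
    if len(states) == 1:
        state_syms = (state_syms,)
    if len(param_names) == 1:
        param_syms = (param_syms,)
    ns = {s: sym for s, sym in zip(states, state_syms)}
    ns.update({p: sym for p, sym in zip(param_names, param_syms)})
    ns["t"] = t_sym
    ns["u"] = u_sym

    rhs_doc = _require(mdoc, "rhs", "model")
    exprs = []
    for s in states:
        raw = _require(rhs_doc, s, "model.rhs")
        try:
            exprs.append(sp.sympify(raw, locals=ns))
        except (sp.SympifyError, TypeError) as exc:
            raise ConfigError(f"cannot parse model.rhs[{s!r}] = {raw!r}: {exc}") from None
    free = set().union(*(e.free_symbols for e in exprs)) if exprs else set()
    known = set(state_syms) | set(param_syms) | {t_sym, u_sym}
    if free - known:
        raise ConfigError(f"unknown symbols in rhs: {sorted(map(str, free - known))}")

    F = sp.Matrix(exprs)
    Jy = F.jacobian(sp.Matrix(state_syms))
    Jt = F.jacobian(sp.Matrix(param_syms))
    args = (t_sym, list(state_syms), list(param_syms), u_sym)
    f_fun = sp.lambdify(args, F, "numpy")
    jy_fun = sp.lambdify(args, Jy, "numpy")
    jt_fun = sp.lambdify(args, Jt, "numpy")

    ic_doc = _require(mdoc, "initial_condition", "model")
    ic_exprs = []
    raw_list = ic_doc if isinstance(ic_doc, list) else [
        _require(ic_doc, s, "model.initial_condition") for s in states
    ]
    if len(raw_list) != len(states):
        raise ConfigError("initial_condition length does not match states")
    for raw in raw_list:
        expr = sp.sympify(raw, locals=ns)
        if expr.free_symbols - set(param_syms):
            raise ConfigError("initial_condition may depend on parameters only")
        ic_exprs.append(expr)
    ic_mat = sp.Matrix(ic_exprs)
    ic_fun = sp.lambdify((list(param_syms),), ic_mat, "numpy")
    ic_jac = sp.lambdify((list(param_syms),), ic_mat.jacobian(sp.Matrix(param_syms)), "numpy")

    def rhs(t, y, th, u):
        return np.asarray(f_fun(t, list(y), list(th), u), dtype=float).ravel()

    def jac_y(t, y, th, u):
        return np.asarray(jy_fun(t, list(y), list(th), u), dtype=float)

    def jac_theta(t, y, th, u):
        return np.asarray(jt_fun(t, list(y), list(th), u), dtype=float)

    model = OdeModel(
        state_names=states,
        param_names=param_names,
        reference_params=theta_star,
        rhs=rhs,
        initial_condition=lambda th: np.asarray(ic_fun(list(th)), dtype=float).ravel(),
        init_jac_theta=lambda th: np.asarray(ic_jac(list(th)), dtype=float),
        name=str(mdoc.get("name", "config_model")),
    )

    experiments = []
    for i, edoc in enumerate(doc.get("experiments", [])):
        where_e = f"experiments[{i}]"
        name = str(edoc.get("name", f"experiment_{i}"))
        observed = list(_require(edoc, "observe", where_e))
        times = _parse_times(_require(edoc, "times", where_e), where_e)
        overrides = {str(k): float(v) for k, v in (edoc.get("overrides") or {}).items()}
        for p in overrides:
            if p not in param_names:
                raise ConfigError(f"{where_e}.overrides: unknown parameter {p!r}")
        input_profile = None
        breakpoints: tuple[float, ...] = ()
        if "input" in edoc and edoc["input"] is not None:
            idoc = edoc["input"]
            input_profile = _piecewise_linear(
                _require(idoc, "times", f"{where_e}.input"),
                _require(idoc, "values", f"{where_e}.input"),
            )
            breakpoints = input_profile.breakpoints
        initial_state = edoc.get("initial_state")
        experiments.append(
            Experiment(
                observed=observed,
                times=times,
                input_profile=input_profile,
                param_overrides=overrides,
                error_sd=float(edoc.get("error_sd", 1.0)),
                initial_state=None if initial_state is None else np.asarray(initial_state, float),
                breakpoints=breakpoints,
                name=name,
            )
        )
    return model, experiments


def load_config(path) -> tuple[OdeModel, list[Experiment]]:
    """Load a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".json",):
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    return load_model_config(doc, where=str(path))
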