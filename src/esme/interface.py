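"""Model schema, result serialization and parameter sweeps.

Models are declared in YAML or JSON with a ``species`` list, a
``reactions`` list and an ``environment`` section.  Reaction rates may be
numbers, expressions in the environment state (``z`` for scalar labels,
``z1, z2, ...`` for product labels) and named constants, or — for affine
non-mass-action propensities such as linearized repression — a mapping
``{const: ..., coeff: {species: ...}}`` giving the propensity
``const(z) + sum_i coeff_i(z) x_i`` directly.

:func:`dump_model` writes a fully tabulated document (explicit per-state
coefficient tables and an explicit generator) so that load → dump → load
reproduces the matrices bit for bit.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import environment as envmod
from . import esme_core, model_zoo
from .crn_model import LinearSubsystem, ModulatedCRN, RateStructure

FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """Schema violation; the message names the offending field path."""


_EVAL_GLOBALS = {
    "__builtins__": {},
    "exp": math.exp, "log": math.log, "sqrt": math.sqrt,
    "min": min, "max": max, "abs": abs,
}


def _eval_rate(expr, z, constants: dict) -> float:
    if isinstance(expr, (int, float)):
        return float(expr)
    ns = dict(constants)
    if np.isscalar(z):
        ns["z"] = z
    else:
        ns["z"] = tuple(z)
        for k, comp in enumerate(z):
            ns[f"z{k + 1}"] = comp
    try:
        return float(eval(expr, _EVAL_GLOBALS, ns))  # noqa: S307
    except Exception as exc:
        raise SchemaError(f"cannot evaluate rate expression {expr!r}: {exc}")


def load_environment(section: dict) -> envmod.MarkovEnvironment:
    if not isinstance(section, dict) or "type" not in section:
        raise SchemaError("environment: missing 'type'")
    kind = section["type"]
    if kind == "explicit":
        for key in ("states", "generator"):
            if key not in section:
                raise SchemaError(f"environment.{key}: required for explicit")
        return envmod.explicit_environment(
            section["states"], section["generator"],
            orientation=section.get("orientation", "column"))
    if kind == "telegraph":
        return envmod.telegraph(section["rate_on"], section["rate_off"])
    if kind == "birth_death":
        return envmod.birth_death(
            section["birth"], section["death"],
            tail_mass=section.get("tail_mass", 1e-12),
            z_max=section.get("z_max"))
    if kind == "modulated_birth_death":
        return envmod.modulated_birth_death(
            section["birth"], section["death"],
            section["switch_on"], section["switch_off"],
            tail_mass=section.get("tail_mass", 1e-12),
            z_max=section.get("z_max"))
    if kind == "product":
        comps = section.get("components")
        if not comps or len(comps) < 2:
            raise SchemaError("environment.components: need >= 2 components")
        return envmod.product_environment(*[load_environment(c) for c in comps])
    raise SchemaError(f"environment.type: unknown type {kind!r}")


def load_model(source) -> ModulatedCRN:
    """Build a :class:`ModulatedCRN` from a schema document.

    ``source`` may be a dict, a YAML/JSON string, or a path.
    """
    doc = _coerce_document(source)
    for key in ("species", "environment"):
        if key not in doc:
            raise SchemaError(f"{key}: required top-level key missing")
    env = load_environment(doc["environment"])
    species = list(doc["species"])
    if "rates" in doc and "stoichiometry" in doc:
        return _load_tabulated(doc, species, env)
    if "reactions" not in doc:
        raise SchemaError("reactions: required top-level key missing")
    constants = doc.get("constants", {})
    sidx = {name: i for i, name in enumerate(species)}
    d = len(species)
    M = len(doc["reactions"])
    S = np.zeros((d, M), dtype=int)
    P = np.zeros((d, M), dtype=int)
    specs = []
    for j, rxn in enumerate(doc["reactions"]):
        for name, coeff in (rxn.get("substrates") or {}).items():
            if name not in sidx:
                raise SchemaError(f"reactions[{j}].substrates: unknown "
                                  f"species {name!r}")
            S[sidx[name], j] = coeff
        for name, coeff in (rxn.get("products") or {}).items():
            if name not in sidx:
                raise SchemaError(f"reactions[{j}].products: unknown "
                                  f"species {name!r}")
            P[sidx[name], j] = coeff
        if "rate" not in rxn:
            raise SchemaError(f"reactions[{j}].rate: missing")
        specs.append(rxn["rate"])
    sub = LinearSubsystem(species, S=S, P=P)

    def Gamma(z):
        G = np.zeros((M, d))
        for j, spec in enumerate(specs):
            if isinstance(spec, dict):
                for name, expr in (spec.get("coeff") or {}).items():
                    if name not in sidx:
                        raise SchemaError(
                            f"reactions[{j}].rate.coeff: unknown species "
                            f"{name!r}")
                    G[j, sidx[name]] = _eval_rate(expr, z, constants)
            else:
                subs = np.nonzero(S[:, j])[0]
                if len(subs):  # first-order mass action
                    G[j, subs[0]] = _eval_rate(spec, z, constants)
        return G

    def gamma(z):
        g = np.zeros(M)
        for j, spec in enumerate(specs):
            if isinstance(spec, dict):
                g[j] = _eval_rate(spec.get("const", 0.0), z, constants)
            elif not np.any(S[:, j]):  # zeroth order
                g[j] = _eval_rate(spec, z, constants)
        return g

    rates = RateStructure(Gamma=Gamma, gamma=gamma, states=env.states)
    return ModulatedCRN(sub, rates, env, meta=doc.get("meta", {}))


def _load_tabulated(doc, species, env) -> ModulatedCRN:
    sto = doc["stoichiometry"]
    sub = LinearSubsystem(species, S=sto["substrates"], P=sto["products"])
    tab = doc["rates"]
    keys = [tuple(s) if isinstance(s, list) else s for s in tab["states"]]
    Gmap = {k: np.asarray(G, dtype=float)
            for k, G in zip(keys, tab["Gamma"])}
    gmap = {k: np.asarray(g, dtype=float)
            for k, g in zip(keys, tab["gamma"])}
    rates = RateStructure(Gamma=Gmap, gamma=gmap, states=env.states)
    return ModulatedCRN(sub, rates, env, meta=doc.get("meta", {}))


def dump_model(crn: ModulatedCRN) -> dict:
    """Fully tabulated schema document for exact round-tripping."""
    env = crn.environment
    return {
        "species": list(crn.subsystem.species_names),
        "stoichiometry": {
            "substrates": crn.subsystem.S.tolist(),
            "products": crn.subsystem.P.tolist(),
        },
        "rates": {
            "states": [list(s) if isinstance(s, tuple) else s
                       for s in env.states],
            "Gamma": [crn.rates.Gamma(z).tolist() for z in env.states],
            "gamma": [crn.rates.gamma(z).tolist() for z in env.states],
        },
        "environment": {
            "type": "explicit",
            "orientation": "column",
            "states": [list(s) if isinstance(s, tuple) else s
                       for s in env.states],
            "generator": env.Lambda.tolist(),
        },
        "meta": _jsonable(crn.meta),
    }


def _coerce_document(source) -> dict:
    if isinstance(source, dict):
        return source
    try:
        is_file = Path(str(source)).exists()
    except OSError:
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError("document is not a mapping")
    return doc


def save_model(crn: ModulatedCRN, path) -> None:
    path = Path(path)
    doc = dump_model(crn)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Result serialization


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def result_to_dict(result: esme_core.ESMEResult) -> dict:
    shares = {
        name: {str(z): float(result.shares[k, i])
               for k, z in enumerate(result.states)}
        for i, name in enumerate(result.species_names)
    }
    return _jsonable({
        "species": result.species_names,
        "mean": result.mean,
        "qss_mean": result.qss_mean,
        "deviation": result.deviation,
        "shares": shares,
        "validity": {
            "passed": result.validity.passed,
            "min_share": result.validity.min_share,
            "negative_share_states":
                [str(z) for z in result.validity.negative_shares],
            "flagged_states": [str(z) for z in result.validity.flagged_states],
            "flagged_share_mass": result.validity.flagged_share_mass,
        },
        "condition_estimate": result.condition_estimate,
        "meta": result.meta,
    })


def result_table(result: esme_core.ESMEResult) -> pd.DataFrame:
    """One row per environment state: label, pi, x_i, y_i, alpha_i."""
    rows = {"state": [str(z) for z in result.states], "pi": result.pi}
    for i, name in enumerate(result.species_names):
        rows[f"x_{name}"] = result.x[:, i]
        rows[f"y_{name}"] = result.y[:, i]
        rows[f"alpha_{name}"] = result.shares[:, i]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sweeps


def run_sweep(spec: dict) -> pd.DataFrame:
    """Solve a zoo model over a grid of one parameter.

    ``spec``: ``{zoo: name, fixed: {...}, parameter: name, values: [...],
    outputs: [...]}``.  ``outputs`` may include ``asymmetry`` (adds r, r0,
    R columns for two-species models).  Failed solves become rows with
    ``status != "ok"``; the sweep continues.
    """
    name = spec.get("zoo")
    if name not in model_zoo.ZOO:
        raise SchemaError(f"zoo: unknown model {name!r}")
    param = spec.get("parameter")
    values = spec.get("values")
    if not param:
        raise SchemaError("parameter: required")
    if not values:
        raise SchemaError("values: empty sweep")
    values = [float(v) for v in values]
    if not all(np.isfinite(values)):
        raise SchemaError("values: must be finite")
    fixed = dict(spec.get("fixed", {}))
    outputs = spec.get("outputs", [])
    rows = []
    for v in values:
        row = {param: v, "status": "ok"}
        try:
            crn = model_zoo.ZOO[name](**fixed, **{param: v})
            res = esme_core.solve(crn, check_condition=False)
            for i, sp in enumerate(res.species_names):
                row[f"mean_{sp}"] = res.mean[i]
                row[f"qss_{sp}"] = res.qss_mean[i]
                row[f"deviation_{sp}"] = res.deviation[i]
            row["validity"] = "pass" if res.validity.passed else "fail"
            if "asymmetry" in outputs and len(res.mean) == 2:
                r, r0, R = model_zoo.asymmetry_ratios(res.mean, res.qss_mean)
                row.update({"r": r, "r0": r0, "R": R})
        except Exception as exc:
            row["status"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
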