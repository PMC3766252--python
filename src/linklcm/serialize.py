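"""YAML/JSON round-tripping for model specs, scenarios, fits, and traces."""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import yaml

from .model import ClassicalSE, FitResult, InteractionTerm, ModelSpec, n_free_params
from .stepwise import StepwiseTrace
from .synthetic import SimulationScenario

__all__ = [
    "spec_to_dict",
    "spec_from_dict",
    "load_spec_yaml",
    "save_spec_yaml",
    "load_scenario_yaml",
    "fit_to_dict",
    "trace_to_dict",
    "write_json",
]


def _resolve_pair(pair, field_names: tuple[str, ...] | None, K: int) -> tuple[int, int]:
    """A pair may be given as two field names or two 1-based positions."""
    out = []
    for item in pair:
        if isinstance(item, str) and field_names and item in field_names:
            out.append(field_names.index(item))
        else:
            idx = int(item) - 1
            if not (0 <= idx < K):
                raise ValueError(f"field position {item} out of range 1..{K}")
            out.append(idx)
    j, l = sorted(out)
    return j, l


def spec_to_dict(spec: ModelSpec) -> dict:
    names = spec.field_names or tuple(f"field_{k + 1}" for k in range(spec.K))
    return {
        "fields": list(names),
        "interactions": [
            {"pair": [names[t.j], names[t.l]], "structure": t.structure}
            for t in spec.interactions
        ],
    }


def spec_from_dict(d: Mapping) -> ModelSpec:
    if "fields" not in d:
        raise ValueError("model spec requires a 'fields' list")
    names = tuple(str(f) for f in d["fields"])
    K = len(names)
    terms = []
    for entry in d.get("interactions") or []:
        j, l = _resolve_pair(entry["pair"], names, K)
        terms.append(InteractionTerm(j, l, entry["structure"]))
    return ModelSpec(K, tuple(terms), names)


def load_spec_yaml(path) -> ModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def save_spec_yaml(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_scenario_yaml(path) -> SimulationScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    names = tuple(str(f) for f in d["fields"]) if "fields" in d else None
    K = len(names) if names else int(d["K"])
    injected = []
    for entry in d.get("injected") or []:
        j, l = _resolve_pair(entry["pair"], names, K)
        injected.append(
            (
                InteractionTerm(j, l, "both_distinct"),
                float(entry.get("gamma_nonmatch", 0.0)),
                float(entry.get("gamma_match", 0.0)),
            )
        )
    return SimulationScenario(
        K=K,
        pi=float(d["pi"]),
        m=np.asarray(d["m"], dtype=float),
        u=np.asarray(d["u"], dtype=float),
        N=int(d["N"]),
        seed=int(d.get("seed", 0)),
        injected=tuple(injected),
        field_names=names,
    )


def _se_to_dict(se: ClassicalSE | None) -> dict | None:
    if se is None:
        return None
    return {"pi": se.pi, "m": se.m.tolist(), "u": se.u.tolist()}


def fit_to_dict(fit: FitResult) -> dict:
    names = fit.spec.field_names or tuple(f"field_{k + 1}" for k in range(fit.spec.K))
    lam = fit.lam
    return {
        "spec": spec_to_dict(fit.spec),
        "lambda": {
            "lam0": lam.lam0,
            "lamM": lam.lamM,
            "lam_k": lam.lam_k.tolist(),
            "lamM_k": lam.lamM_k.tolist(),
            "lam_jl": lam.lam_jl.tolist(),
            "lamM_jl": lam.lamM_jl.tolist(),
        },
        "classical": {
            "pi": fit.classical.pi,
            "m": dict(zip(names, fit.classical.m.tolist())),
            "u": dict(zip(names, fit.classical.u.tolist())),
        },
        "se_classical": _se_to_dict(fit.se_classical),
        "loglik": fit.loglik,
        "deviance": fit.deviance,
        "bic": fit.bic,
        "n_free_params": n_free_params(fit.spec),
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "N": fit.N,
        "optima_log": fit.optima_log,
    }


def fit_from_dict(d: Mapping) -> FitResult:
    from .model import ClassicalParams, LambdaParams, lambda_to_natural, natural_to_classical

    spec = spec_from_dict(d["spec"])
    lamd = d["lambda"]
    lam = LambdaParams(
        lam0=float(lamd["lam0"]),
        lamM=float(lamd["lamM"]),
        lam_k=np.asarray(lamd["lam_k"], dtype=float),
        lamM_k=np.asarray(lamd["lamM_k"], dtype=float),
        lam_jl=np.asarray(lamd["lam_jl"], dtype=float),
        lamM_jl=np.asarray(lamd["lamM_jl"], dtype=float),
    )
    nat = lambda_to_natural(lam, spec)
    sed = d.get("se_classical")
    se = (
        ClassicalSE(float(sed["pi"]), np.asarray(sed["m"]), np.asarray(sed["u"]))
        if sed
        else None
    )
    return FitResult(
        spec=spec,
        lam=lam,
        natural=nat,
        classical=natural_to_classical(nat, spec),
        se_classical=se,
        loglik=float(d["loglik"]),
        deviance=float(d["deviance"]),
        bic=float(d["bic"]),
        converged=bool(d["converged"]),
        n_iter=int(d["n_iter"]),
        N=int(d["N"]),
        optima_log=list(d.get("optima_log", [])),
    )


def load_fit_json(path) -> FitResult:
    with open(path) as fh:
        return fit_from_dict(json.load(fh))


def trace_to_dict(trace: StepwiseTrace) -> dict:
    return {
        "models": [fit_to_dict(m) for m in trace.models],
        "decisions": [
            {
                "pair": list(d.pair),
                "residual": d.residual,
                "candidate_bics": d.candidate_bics,
                "winner_structure": d.winner_structure,
                "accepted": d.accepted,
                "model_index": d.model_index,
            }
            for d in trace.decisions
        ],
        "stop_reason": trace.stop_reason,
    }


def write_json(obj: dict, path) -> None:
    """Deterministic JSON with round-trip-exact floats."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")
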