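"""Synthetic agreement-pattern data from a fully specified two-class model.

Scenarios describe the generative mixture directly: prevalence, per-field
m/u probabilities, and optional within-class pairwise loglinear coefficients
that inject conditional dependence.  Used for parameter-recovery studies and
as the test bed for everything that cannot rely on external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AgreementPatternTable
from .estimation import FitOptions, fit_ml
from scipy.special import logit

from .model import (
    InteractionTerm,
    ModelSpec,
    NaturalParams,
    class_pattern_probs,
)

__all__ = ["SimulationScenario", "scenario_probabilities", "sample_table", "recovery_experiment"]


@dataclass(frozen=True)
class SimulationScenario:
    """Generator settings: K, prevalence, m/u, injected dependence, N, seed.

    ``injected`` holds ``(InteractionTerm, gamma0, gamma1)`` triples; the
    within-class log-probability is proportional to
    ``sum_k y_k logit(p_ck) + sum gamma_c y_j y_l``, so with no injected
    terms each class factorizes exactly into its m/u Bernoulli products.
    """

    K: int
    pi: float
    m: np.ndarray
    u: np.ndarray
    N: int
    seed: int = 0
    injected: tuple[tuple[InteractionTerm, float, float], ...] = ()
    field_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        if self.m.shape != (self.K,) or self.u.shape != (self.K,):
            raise ValueError("m and u must have length K")
        if not (0.0 < self.pi < 1.0):
            raise ValueError("pi must lie strictly in (0, 1)")
        for name, arr in (("m", self.m), ("u", self.u)):
            if np.any(arr <= 0.0) or np.any(arr >= 1.0):
                raise ValueError(f"{name}-probabilities must lie strictly in (0, 1)")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        object.__setattr__(self, "injected", tuple(self.injected))
        for term, _, _ in self.injected:
            if term.l >= self.K:
                raise ValueError(f"injected term {term.pair} out of range for K={self.K}")

    @property
    def spec(self) -> ModelSpec:
        """The (true) model spec implied by the injected terms, all both_distinct."""
        terms = tuple(
            InteractionTerm(t.j, t.l, "both_distinct") for t, _, _ in self.injected
        )
        return ModelSpec(self.K, terms, self.field_names)

    @property
    def natural(self) -> NaturalParams:
        g0 = np.array([g0 for _, g0, _ in self.injected])
        g1 = np.array([g1 for _, _, g1 in self.injected])
        return NaturalParams(self.pi, logit(self.u), logit(self.m), g0, g1)


def scenario_probabilities(scenario: SimulationScenario) -> np.ndarray:
    """Joint probabilities ``P(Y_d, M)`` as a D x 2 array (columns: M=0, M=1); sums to 1."""
    q0, q1 = class_pattern_probs(scenario.natural, scenario.spec)
    return np.column_stack([(1.0 - scenario.pi) * q0, scenario.pi * q1])


def sample_table(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """One multinomial draw of size N over the joint cells, marginalized over M.

    With ``return_truth`` the per-class pattern counts are returned alongside
    the table for validation purposes.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    joint = scenario_probabilities(scenario)
    D = joint.shape[0]
    draw = rng.multinomial(scenario.N, joint.ravel()).reshape(D, 2)
    counts = draw.sum(axis=1)
    table = AgreementPatternTable(scenario.K, counts, scenario.field_names)
    if return_truth:
        return table, draw
    return table


def recovery_experiment(
    scenario: SimulationScenario,
    n_reps: int,
    seed: int = 0,
    fit_spec: ModelSpec | None = None,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Bias/RMSE of the fitted (pi, m, u) across replicates under a given spec.

    Each replicate draws a fresh table and fits ``fit_spec`` (the true spec
    by default).  Failed fits are counted in the ``n_failed`` dataframe
    attribute rather than aborting the study.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    spec = fit_spec if fit_spec is not None else scenario.spec
    rng = np.random.default_rng(seed)
    truth = np.concatenate([[scenario.pi], scenario.m, scenario.u])
    names = (
        ["pi"]
        + [f"m_{k + 1}" for k in range(scenario.K)]
        + [f"u_{k + 1}" for k in range(scenario.K)]
    )
    estimates = []
    n_failed = 0
    for rep in range(n_reps):
        table = sample_table(scenario, rng=rng)
        opts = options or FitOptions(seed=seed + rep, n_starts=1, compute_se=False)
        try:
            fit = fit_ml(table, spec, opts)
        except Exception:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        cp = fit.classical
        estimates.append(np.concatenate([[cp.pi], cp.m, cp.u]))
    if not estimates:
        raise RuntimeError("every replicate fit failed")
    est = np.array(estimates)
    bias = est.mean(axis=0) - truth
    rmse = np.sqrt(((est - truth) ** 2).mean(axis=0))
    df = pd.DataFrame({"parameter": names, "truth": truth, "bias": bias, "rmse": rmse})
    df.attrs["n_failed"] = n_failed
    df.attrs["n_used"] = len(estimates)
    return df
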