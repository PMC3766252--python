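"""Stepwise model building: fit, diagnose residuals, compare structures, repeat.

Starting from the conditional-independence fit, each iteration flags the
field pair with the largest residual above the guideline threshold, fits the
four candidate interaction structures for that pair, keeps the BIC winner,
and stops once no residual exceeds the threshold (with BIC non-improvement
and an iteration cap as secondary guards).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import AgreementPatternTable
from .diagnostics import correlation_residuals, flag_candidates
from .estimation import FitOptions, fit_ml
from .model import STRUCTURES, FitResult, InteractionTerm, ModelSpec, n_free_params

__all__ = ["StepwiseDecision", "StepwiseTrace", "compare_structures", "run_stepwise"]

#: Fixed order used for tie-breaking between equally scored structures.
_STRUCTURE_ORDER = ("match_only", "nonmatch_only", "both_shared", "both_distinct")


@dataclass(frozen=True)
class StepwiseDecision:
    """One iteration's record: the flagged pair, the four candidate fits, the winner."""

    pair: tuple[int, int]
    residual: float
    candidate_bics: dict[str, float]
    winner_structure: str
    accepted: bool
    model_index: int | None = None  # index into trace.models, None if not appended


@dataclass
class StepwiseTrace:
    """Ordered model sequence (Model 0, I, II, ...) plus per-iteration decisions."""

    models: list[FitResult] = field(default_factory=list)
    decisions: list[StepwiseDecision] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def final(self) -> FitResult:
        return self.models[-1]

    @property
    def chosen(self) -> FitResult:
        """Last model adopted under the threshold rule (explored-only fits excluded)."""
        idx = 0
        for d in self.decisions:
            if d.accepted and d.model_index is not None:
                idx = d.model_index
        return self.models[idx]


def compare_structures(
    table: AgreementPatternTable,
    base_spec: ModelSpec,
    pair: tuple[int, int],
    options: FitOptions = FitOptions(),
    warm_start: FitResult | None = None,
) -> tuple[FitResult, list[FitResult]]:
    """Fit the four interaction structures for ``pair``; the lowest BIC wins.

    Ties are broken toward fewer parameters, then by the fixed structure
    order.  Non-converged candidates are excluded; if all four fail a
    RuntimeError is raised.
    """
    j, l = pair
    if any(t.pair == (j, l) for t in base_spec.interactions):
        raise ValueError(f"pair {pair} is already in the base spec")

    fits: list[FitResult] = []
    for structure in STRUCTURES:
        spec = base_spec.with_interaction(InteractionTerm(j, l, structure))
        opts = options
        if warm_start is not None:
            init = _warm_init(warm_start, spec)
            opts = replace(options, init="user", init_params=init)
        fits.append(fit_ml(table, spec, opts))

    usable = [f for f in fits if f.converged]
    if not usable:
        raise RuntimeError(f"all four candidate structures failed to converge for pair {pair}")

    def sort_key(f: FitResult):
        structure = f.spec.interactions[-1].structure
        return (f.bic, n_free_params(f.spec), _STRUCTURE_ORDER.index(structure))

    winner = min(usable, key=sort_key)
    return winner, fits


def _warm_init(previous: FitResult, spec: ModelSpec):
    """Carry shared parameters from the previous winner; new coefficients start at 0."""
    from .model import NaturalParams

    prev = previous.natural
    n_terms = len(spec.interactions)
    gamma0 = np.zeros(n_terms)
    gamma1 = np.zeros(n_terms)
    prev_terms = {t.pair: i for i, t in enumerate(previous.spec.interactions)}
    for i, term in enumerate(spec.interactions):
        if term.pair in prev_terms:
            gamma0[i] = prev.gamma0[prev_terms[term.pair]]
            gamma1[i] = prev.gamma1[prev_terms[term.pair]]
    return NaturalParams(prev.pi, prev.alpha0.copy(), prev.alpha1.copy(), gamma0, gamma1)


def run_stepwise(
    table: AgreementPatternTable,
    options: FitOptions = FitOptions(),
    threshold: float = 0.05,
    max_terms: int = 5,
    explore_below_threshold: bool = False,
) -> StepwiseTrace:
    """Run the full iterative procedure from the CI model.

    The residual-threshold rule governs stopping; with
    ``explore_below_threshold`` the largest remaining residual is pursued one
    more round even when it sits below the guideline (the accepted model is
    still chosen by the threshold rule, so the extra fit is recorded but not
    adopted unless above threshold).
    """
    spec = ModelSpec(table.K, (), table.field_names)
    trace = StepwiseTrace()
    current = fit_ml(table, spec, options)
    trace.models.append(current)

    for _ in range(max_terms):
        residuals = correlation_residuals(table, current)
        in_model = {t.pair for t in current.spec.interactions}
        candidates = [
            (pair, r) for pair, r in flag_candidates(residuals, threshold) if pair not in in_model
        ]
        explored = False
        if not candidates and explore_below_threshold:
            below = [
                (pair, r)
                for pair, r in flag_candidates(residuals, threshold=0.0)
                if pair not in in_model
            ]
            if below:
                candidates = below[:1]
                explored = True
        if not candidates:
            trace.stop_reason = "no_candidates"
            return trace

        pair, residual = candidates[0]
        winner, all4 = compare_structures(table, current.spec, pair, options, warm_start=current)
        bics = {f.spec.interactions[-1].structure: f.bic for f in all4}
        if winner.bic >= current.bic:
            trace.decisions.append(
                StepwiseDecision(
                    pair, residual, bics, winner.spec.interactions[-1].structure, False, None
                )
            )
            trace.stop_reason = "bic_no_improvement"
            return trace

        accepted = not explored  # below-threshold exploration is recorded, not adopted
        trace.models.append(winner)
        trace.decisions.append(
            StepwiseDecision(
                pair,
                residual,
                bics,
                winner.spec.interactions[-1].structure,
                accepted,
                len(trace.models) - 1,
            )
        )
        if explored:
            trace.stop_reason = "no_candidates"
            return trace
        current = winner

    trace.stop_reason = "max_iterations"
    return trace
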