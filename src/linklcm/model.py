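"""Loglinear two-class latent model over binary agreement patterns.

The model describes the expected number of record pairs ``m(Y, M)`` with
agreement pattern ``Y`` and latent match status ``M`` as a loglinear function
of the pattern bits, the class indicator, and optional pairwise interactions
within each class.  With an empty interaction list it is exactly the classical
Fellegi-Sunter conditional-independence mixture; pairwise terms relax that
assumption field pair by field pair.

Two equivalent parameterizations are used throughout:

* ``LambdaParams`` -- the loglinear coefficients (intercept, class effect,
  per-field main and class-interaction effects, pairwise terms).  This is the
  reporting surface.
* ``NaturalParams`` -- the minimal free set (mixing proportion plus
  class-conditional field coefficients and interaction coefficients), which
  removes the flat direction of the cell-mean scale and is what the
  optimizer works on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import logit, logsumexp

__all__ = [
    "STRUCTURES",
    "InteractionTerm",
    "ModelSpec",
    "LambdaParams",
    "NaturalParams",
    "ClassicalParams",
    "FitResult",
    "pattern_matrix",
    "n_free_params",
    "class_pattern_probs",
    "expected_cell_means",
    "pattern_probabilities",
    "lambda_to_natural",
    "natural_to_lambda",
    "lambda_to_classical",
    "natural_to_classical",
    "classical_to_lambda",
    "log_likelihood",
    "deviance_from_probs",
    "deviance",
    "bic",
    "match_score",
]

#: The four admissible class structures for a pairwise interaction term.
STRUCTURES = ("match_only", "nonmatch_only", "both_distinct", "both_shared")

#: Free coefficients contributed by each structure.
_STRUCTURE_NPARAMS = {
    "match_only": 1,
    "nonmatch_only": 1,
    "both_distinct": 2,
    "both_shared": 1,
}


@dataclass(frozen=True)
class InteractionTerm:
    """A within-class dependence term between fields ``j`` and ``l`` (0-based, j < l)."""

    j: int
    l: int
    structure: str

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown interaction structure {self.structure!r}; "
                f"expected one of {STRUCTURES}"
            )
        if not (0 <= self.j < self.l):
            raise ValueError(f"interaction requires 0 <= j < l, got ({self.j}, {self.l})")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.j, self.l)


@dataclass(frozen=True)
class ModelSpec:
    """Field count plus the list of pairwise interaction terms.

    An empty interaction list is the conditional-independence (classical
    Fellegi-Sunter) model.
    """

    K: int
    interactions: tuple[InteractionTerm, ...] = ()
    field_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        object.__setattr__(self, "interactions", tuple(self.interactions))
        seen: set[tuple[int, int]] = set()
        for term in self.interactions:
            if term.l >= self.K:
                raise ValueError(f"interaction field index {term.l} out of range for K={self.K}")
            if term.pair in seen:
                raise ValueError(f"duplicate interaction pair {term.pair}")
            seen.add(term.pair)
        if self.field_names is not None:
            names = tuple(self.field_names)
            if len(names) != self.K:
                raise ValueError("field_names length must equal K")
            object.__setattr__(self, "field_names", names)

    @property
    def is_ci(self) -> bool:
        return not self.interactions

    def with_interaction(self, term: InteractionTerm) -> "ModelSpec":
        """Return a new spec extended by one interaction term."""
        return ModelSpec(self.K, self.interactions + (term,), self.field_names)

    def name_of(self, k: int) -> str:
        return self.field_names[k] if self.field_names else f"field_{k + 1}"


@dataclass(frozen=True)
class LambdaParams:
    """Loglinear coefficients for a :class:`ModelSpec`.

    ``lam_jl`` / ``lamM_jl`` are aligned with ``spec.interactions``; entries
    constrained to zero by the term's structure are stored as exact zeros.
    """

    lam0: float
    lamM: float
    lam_k: np.ndarray
    lamM_k: np.ndarray
    lam_jl: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lamM_jl: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "lam_k", np.asarray(self.lam_k, dtype=float))
        object.__setattr__(self, "lamM_k", np.asarray(self.lamM_k, dtype=float))
        object.__setattr__(self, "lam_jl", np.asarray(self.lam_jl, dtype=float))
        object.__setattr__(self, "lamM_jl", np.asarray(self.lamM_jl, dtype=float))
        vals = np.concatenate(
            [[self.lam0, self.lamM], self.lam_k, self.lamM_k, self.lam_jl, self.lamM_jl]
        )
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite loglinear coefficient")

    def translated(self, c: float) -> "LambdaParams":
        """Shift the intercept by ``c`` (a likelihood-invariant rescaling)."""
        return LambdaParams(
            self.lam0 + c, self.lamM, self.lam_k, self.lamM_k, self.lam_jl, self.lamM_jl
        )


@dataclass(frozen=True)
class NaturalParams:
    """Minimal free parameterization: (pi; per-class field and interaction coefficients)."""

    pi: float
    alpha0: np.ndarray  # nonmatch-class field coefficients, length K
    alpha1: np.ndarray  # match-class field coefficients, length K
    gamma0: np.ndarray  # nonmatch-class interaction coefficients, length n_terms
    gamma1: np.ndarray  # match-class interaction coefficients, length n_terms

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha1", "gamma0", "gamma1"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (0.0 < self.pi < 1.0):
            raise ValueError(f"pi must lie strictly in (0, 1), got {self.pi}")


@dataclass(frozen=True)
class ClassicalParams:
    """Match prevalence and per-field m/u agreement probabilities."""

    pi: float
    m: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        if not (0.0 < self.pi < 1.0):
            raise ValueError(f"pi must lie strictly in (0, 1), got {self.pi}")
        for name, arr in (("m", self.m), ("u", self.u)):
            if np.any(arr <= 0.0) or np.any(arr >= 1.0):
                raise ValueError(f"all {name}-probabilities must lie strictly in (0, 1)")
        if self.m.shape != self.u.shape:
            raise ValueError("m and u must have the same length")


@dataclass(frozen=True)
class ClassicalSE:
    """Standard errors on the (pi, m, u) scale; no range validation beyond non-negativity."""

    pi: float
    m: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        if self.pi < 0 or np.any(self.m < 0) or np.any(self.u < 0):
            raise ValueError("standard errors must be non-negative")


@dataclass
class FitResult:
    """A fitted model: parameters on both scales plus fit statistics."""

    spec: ModelSpec
    lam: LambdaParams
    natural: NaturalParams
    classical: ClassicalParams
    se_classical: ClassicalSE | None
    loglik: float
    deviance: float
    bic: float
    converged: bool
    n_iter: int
    N: int
    optima_log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pattern enumeration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def pattern_matrix(K: int) -> np.ndarray:
    """All ``D = 2**K`` binary agreement patterns, one row per pattern.

    Pattern index ``d`` encodes the bits of ``(y_1, ..., y_K)`` with field 1
    as the most significant bit, so the ordering is fixed across runs.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    d = np.arange(2**K, dtype=np.int64)
    shifts = np.arange(K - 1, -1, -1)
    out = (d[:, None] >> shifts[None, :]) & 1
    out.setflags(write=False)
    return out


def pattern_index(pattern: Sequence[int]) -> int:
    """Index of a single binary pattern under the fixed enumeration."""
    idx = 0
    for bit in pattern:
        idx = (idx << 1) | int(bit)
    return idx


def n_free_params(spec: ModelSpec) -> int:
    """Number of free parameters: ``2K + 1`` for CI plus the structure-dependent extras."""
    return 2 * spec.K + 1 + sum(_STRUCTURE_NPARAMS[t.structure] for t in spec.interactions)


# ---------------------------------------------------------------------------
# cell means and probabilities
# ---------------------------------------------------------------------------


def _interaction_columns(spec: ModelSpec) -> np.ndarray:
    """D x n_terms matrix of products ``y_j * y_l`` for each interaction term."""
    Y = pattern_matrix(spec.K)
    if not spec.interactions:
        return np.zeros((Y.shape[0], 0))
    cols = [Y[:, t.j] * Y[:, t.l] for t in spec.interactions]
    return np.column_stack(cols).astype(float)


def _class_scores(nat: NaturalParams, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized within-class log-weights, one array of length D per class."""
    Y = pattern_matrix(spec.K).astype(float)
    X = _interaction_columns(spec)
    s0 = Y @ nat.alpha0 + X @ nat.gamma0
    s1 = Y @ nat.alpha1 + X @ nat.gamma1
    return s0, s1


def class_pattern_probs(nat: NaturalParams, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional pattern distributions ``P(Y_d | M=0)`` and ``P(Y_d | M=1)``."""
    s0, s1 = _class_scores(nat, spec)
    q0 = np.exp(s0 - logsumexp(s0))
    q1 = np.exp(s1 - logsumexp(s1))
    return q0, q1


def expected_cell_means(lam: LambdaParams, spec: ModelSpec) -> np.ndarray:
    """Cell means ``m(Y_d, M)`` as a D x 2 array (column 0: M=0, column 1: M=1)."""
    _check_dims(lam, spec)
    Y = pattern_matrix(spec.K).astype(float)
    X = _interaction_columns(spec)
    log_m0 = lam.lam0 + Y @ lam.lam_k + X @ lam.lam_jl
    log_m1 = log_m0 + lam.lamM + Y @ lam.lamM_k + X @ lam.lamM_jl
    return np.exp(np.column_stack([log_m0, log_m1]))


def pattern_probabilities(lam: LambdaParams, spec: ModelSpec) -> np.ndarray:
    """Marginal pattern probabilities ``P(Y_d)``: row sums of the cell means, normalized."""
    cells = expected_cell_means(lam, spec)
    totals = cells.sum(axis=1)
    return totals / totals.sum()


def pattern_probabilities_natural(nat: NaturalParams, spec: ModelSpec) -> np.ndarray:
    """``P(Y_d)`` straight from the free parameterization (no intercept needed)."""
    q0, q1 = class_pattern_probs(nat, spec)
    return nat.pi * q1 + (1.0 - nat.pi) * q0


# ---------------------------------------------------------------------------
# parameter mappings
# ---------------------------------------------------------------------------


def _check_dims(lam: LambdaParams, spec: ModelSpec) -> None:
    n_terms = len(spec.interactions)
    if lam.lam_k.shape != (spec.K,) or lam.lamM_k.shape != (spec.K,):
        raise ValueError("lambda main-effect vectors must have length K")
    if lam.lam_jl.shape != (n_terms,) or lam.lamM_jl.shape != (n_terms,):
        raise ValueError("lambda interaction vectors must match the spec's term list")


def lambda_to_natural(lam: LambdaParams, spec: ModelSpec) -> NaturalParams:
    _check_dims(lam, spec)
    cells = expected_cell_means(lam, spec)
    pi = cells[:, 1].sum() / cells.sum()
    return NaturalParams(
        pi=pi,
        alpha0=lam.lam_k.copy(),
        alpha1=lam.lam_k + lam.lamM_k,
        gamma0=lam.lam_jl.copy(),
        gamma1=lam.lam_jl + lam.lamM_jl,
    )


def natural_to_lambda(nat: NaturalParams, spec: ModelSpec, total: float = 1.0) -> LambdaParams:
    """Identified loglinear coefficients with the scale fixed so cell means sum to ``total``.

    The cell-mean scale is a flat direction of the likelihood; following the
    convention that the fitted means reproduce the observed pair count, the
    intercept is chosen so ``sum m(Y, M) = total``.
    """
    s0, s1 = _class_scores(nat, spec)
    logZ0 = logsumexp(s0)
    logZ1 = logsumexp(s1)
    lam0 = math.log(total * (1.0 - nat.pi)) - logZ0
    lamM = math.log(total * nat.pi) - logZ1 - lam0
    return LambdaParams(
        lam0=lam0,
        lamM=lamM,
        lam_k=nat.alpha0.copy(),
        lamM_k=nat.alpha1 - nat.alpha0,
        lam_jl=nat.gamma0.copy(),
        lamM_jl=nat.gamma1 - nat.gamma0,
    )


def natural_to_classical(nat: NaturalParams, spec: ModelSpec) -> ClassicalParams:
    """Match prevalence and class-conditional marginal agreement probabilities.

    For a field that appears in no interaction term this reduces exactly to
    the logistic identities ``u_k = expit(lam_k)``, ``m_k = expit(lam_k +
    lamM_k)``; for interacting fields the marginal is a cell-sum ratio.
    """
    Y = pattern_matrix(spec.K).astype(float)
    q0, q1 = class_pattern_probs(nat, spec)
    u = q0 @ Y
    m = q1 @ Y
    return ClassicalParams(pi=nat.pi, m=m, u=u)


def lambda_to_classical(lam: LambdaParams, spec: ModelSpec) -> ClassicalParams:
    return natural_to_classical(lambda_to_natural(lam, spec), spec)


def classical_to_lambda(classical: ClassicalParams, K: int, total: float = 1.0) -> LambdaParams:
    """Loglinear coefficients of the CI model matching ``(pi, m, u)`` exactly.

    Only defined for the conditional-independence spec, where the logistic
    identities are invertible.  Probabilities at 0 or 1 have no finite logit
    and are rejected.
    """
    if classical.m.shape != (K,):
        raise ValueError("classical params dimensioned for a different K")
    nat = NaturalParams(
        pi=classical.pi,
        alpha0=logit(classical.u),
        alpha1=logit(classical.m),
        gamma0=np.zeros(0),
        gamma1=np.zeros(0),
    )
    if not (np.all(np.isfinite(nat.alpha0)) and np.all(np.isfinite(nat.alpha1))):
        raise ValueError("m/u probabilities at the boundary have no loglinear image")
    return natural_to_lambda(nat, ModelSpec(K), total=total)


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def log_likelihood(lam: LambdaParams, spec: ModelSpec, table) -> float:
    """Multinomial log-likelihood ``sum_d f_d log P(Y_d)``."""
    if table.K != spec.K:
        raise ValueError(f"table has K={table.K} fields but spec expects K={spec.K}")
    P = pattern_probabilities(lam, spec)
    mask = table.counts > 0
    return float(table.counts[mask] @ np.log(P[mask]))


def deviance_from_probs(P: np.ndarray, table) -> float:
    """G^2 against the saturated multinomial; empty cells contribute zero."""
    f = table.counts.astype(float)
    mask = f > 0
    expected = table.N * P[mask]
    return float(2.0 * (f[mask] @ np.log(f[mask] / expected)))


def deviance(fit: FitResult, table) -> float:
    return deviance_from_probs(pattern_probabilities_natural(fit.natural, fit.spec), table)


def bic(loglik: float, spec: ModelSpec, N: int) -> float:
    """``-2 loglik + p log N`` with N the number of record pairs."""
    return -2.0 * loglik + n_free_params(spec) * math.log(N)


def match_score(lam: LambdaParams, spec: ModelSpec, pattern: Sequence[int]) -> float:
    """Base-2 log likelihood ratio of a pattern under the match vs. nonmatch class."""
    if len(pattern) != spec.K:
        raise ValueError(f"pattern length {len(pattern)} does not match K={spec.K}")
    nat = lambda_to_natural(lam, spec)
    q0, q1 = class_pattern_probs(nat, spec)
    d = pattern_index(pattern)
    return float(np.log2(q1[d]) - np.log2(q0[d]))


def match_scores_all(nat: NaturalParams, spec: ModelSpec) -> np.ndarray:
    """Match scores for every pattern at once (length D)."""
    q0, q1 = class_pattern_probs(nat, spec)
    return np.log2(q1) - np.log2(q0)
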