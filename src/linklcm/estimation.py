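"""Maximum-likelihood fitting of the latent-class loglinear model.

Two independent estimation routes are provided:

* :func:`fit_ml` -- quasi-Newton maximization of the multinomial likelihood
  in an unconstrained free parameterization, with seeded multi-start.
* :func:`fit_em` -- a classical EM algorithm (closed-form M-step under
  conditional independence, inner concave maximization when interaction
  terms are present), kept deliberately separate so the two routes can
  cross-check each other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import AgreementPatternTable
from .model import (
    ClassicalSE,
    FitResult,
    ModelSpec,
    NaturalParams,
    bic,
    class_pattern_probs,
    deviance_from_probs,
    n_free_params,
    natural_to_classical,
    natural_to_lambda,
    pattern_matrix,
    pattern_probabilities_natural,
)

__all__ = ["FitOptions", "fit_ml", "fit_em", "standard_errors", "SingularInformationError"]

_EPS_P = 1e-300  # floor for pattern probabilities inside logs


class SingularInformationError(np.linalg.LinAlgError):
    """The observed information matrix is numerically singular."""


@dataclass(frozen=True)
class FitOptions:
    """Knobs for the optimizer: iteration cap, tolerance, multi-start, seeding."""

    max_iter: int = 1000
    tol: float = 1e-10
    n_starts: int = 5
    seed: int = 0
    init: str = "heuristic"
    init_params: NaturalParams | None = None
    compute_se: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.init not in ("heuristic", "user", "random"):
            raise ValueError(f"unknown init mode {self.init!r}")
        if self.init == "user" and self.init_params is None:
            raise ValueError("init='user' requires init_params")


# ---------------------------------------------------------------------------
# free-vector packing
# ---------------------------------------------------------------------------
# theta = [logit(pi), alpha0 (K), alpha1 (K), per-term free gammas]
# both_distinct contributes (gamma0, gamma1); single-coefficient structures
# contribute their one free coefficient.


def _pack(nat: NaturalParams, spec: ModelSpec) -> np.ndarray:
    parts = [np.array([logit(nat.pi)]), nat.alpha0, nat.alpha1]
    for t, term in enumerate(spec.interactions):
        if term.structure == "match_only":
            parts.append([nat.gamma1[t]])
        elif term.structure == "nonmatch_only":
            parts.append([nat.gamma0[t]])
        elif term.structure == "both_shared":
            parts.append([nat.gamma0[t]])
        else:  # both_distinct
            parts.append([nat.gamma0[t], nat.gamma1[t]])
    return np.concatenate([np.asarray(p, dtype=float) for p in parts])


def _unpack(theta: np.ndarray, spec: ModelSpec) -> NaturalParams:
    K = spec.K
    n_terms = len(spec.interactions)
    pi = float(expit(theta[0]))
    pi = min(max(pi, 1e-15), 1 - 1e-15)
    alpha0 = theta[1 : 1 + K]
    alpha1 = theta[1 + K : 1 + 2 * K]
    gamma0 = np.zeros(n_terms)
    gamma1 = np.zeros(n_terms)
    pos = 1 + 2 * K
    for t, term in enumerate(spec.interactions):
        if term.structure == "match_only":
            gamma1[t] = theta[pos]
            pos += 1
        elif term.structure == "nonmatch_only":
            gamma0[t] = theta[pos]
            pos += 1
        elif term.structure == "both_shared":
            gamma0[t] = gamma1[t] = theta[pos]
            pos += 1
        else:
            gamma0[t] = theta[pos]
            gamma1[t] = theta[pos + 1]
            pos += 2
    return NaturalParams(pi, alpha0.copy(), alpha1.copy(), gamma0, gamma1)


def _interaction_design(spec: ModelSpec) -> np.ndarray:
    Y = pattern_matrix(spec.K)
    if not spec.interactions:
        return np.zeros((Y.shape[0], 0))
    return np.column_stack([Y[:, t.j] * Y[:, t.l] for t in spec.interactions]).astype(float)


def _negloglik_grad(theta: np.ndarray, spec: ModelSpec, counts: np.ndarray, N: int):
    """Mean negative log-likelihood and its gradient in the free parameterization."""
    nat = _unpack(theta, spec)
    Y = pattern_matrix(spec.K).astype(float)
    X = _interaction_design(spec)
    q0, q1 = class_pattern_probs(nat, spec)
    P = nat.pi * q1 + (1.0 - nat.pi) * q0
    P = np.maximum(P, _EPS_P)
    nll = -float(counts @ np.log(P)) / N

    # class responsibilities weighted by counts
    r1 = nat.pi * q1 / P
    F1 = counts * r1
    F0 = counts - F1
    W0, W1 = F0.sum(), F1.sum()

    g = np.empty_like(theta)
    g[0] = -(F1.sum() - N * nat.pi) / N  # d(-l)/d logit(pi)
    K = spec.K
    g[1 : 1 + K] = -(F0 @ Y - W0 * (q0 @ Y)) / N
    g[1 + K : 1 + 2 * K] = -(F1 @ Y - W1 * (q1 @ Y)) / N
    pos = 1 + 2 * K
    for t, term in enumerate(spec.interactions):
        x = X[:, t]
        d0 = -(F0 @ x - W0 * (q0 @ x)) / N
        d1 = -(F1 @ x - W1 * (q1 @ x)) / N
        if term.structure == "match_only":
            g[pos] = d1
            pos += 1
        elif term.structure == "nonmatch_only":
            g[pos] = d0
            pos += 1
        elif term.structure == "both_shared":
            g[pos] = d0 + d1
            pos += 1
        else:
            g[pos] = d0
            g[pos + 1] = d1
            pos += 2
    return nll, g


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------


def _check_table(table: AgreementPatternTable, spec: ModelSpec) -> None:
    if table.K != spec.K:
        raise ValueError(f"table has K={table.K} fields but spec expects K={spec.K}")
    if table.N == 0:
        raise ValueError("cannot fit an empty pattern table")
    props = table.agreement_proportions()
    bad = [table.field_names[k] for k in range(table.K) if props[k] in (0.0, 1.0)]
    if bad:
        raise ValueError(
            f"degenerate field(s) with agreement proportion 0 or 1: {bad}; "
            "remove them before fitting"
        )


def _heuristic_start(table: AgreementPatternTable, spec: ModelSpec) -> NaturalParams:
    """Non-matches dominate blocked pairs, so margins approximate u."""
    u = np.clip(table.agreement_proportions(), 1e-4, 1 - 1e-4)
    m = np.minimum(0.95, u + 0.3)
    n_terms = len(spec.interactions)
    return NaturalParams(0.01, logit(u), logit(m), np.zeros(n_terms), np.zeros(n_terms))


def _random_start(rng: np.random.Generator, table: AgreementPatternTable, spec: ModelSpec) -> NaturalParams:
    base = _heuristic_start(table, spec)
    K = spec.K
    n_terms = len(spec.interactions)
    return NaturalParams(
        pi=float(expit(logit(base.pi) + rng.normal(0, 1.0))),
        alpha0=base.alpha0 + rng.normal(0, 0.5, K),
        alpha1=base.alpha1 + rng.normal(0, 1.0, K),
        gamma0=rng.normal(0, 0.2, n_terms),
        gamma1=rng.normal(0, 0.2, n_terms),
    )


def _project_to_structure(nat: NaturalParams, spec: ModelSpec) -> NaturalParams:
    """Zero out interaction coefficients a structure constrains (after relabeling)."""
    gamma0 = nat.gamma0.copy()
    gamma1 = nat.gamma1.copy()
    for t, term in enumerate(spec.interactions):
        if term.structure == "match_only":
            gamma0[t] = 0.0
        elif term.structure == "nonmatch_only":
            gamma1[t] = 0.0
        elif term.structure == "both_shared":
            shared = 0.5 * (gamma0[t] + gamma1[t])
            gamma0[t] = gamma1[t] = shared
    return replace(nat, gamma0=gamma0, gamma1=gamma1)


def _swap_classes(nat: NaturalParams) -> NaturalParams:
    return NaturalParams(1.0 - nat.pi, nat.alpha1, nat.alpha0, nat.gamma1, nat.gamma0)


# ---------------------------------------------------------------------------
# quasi-Newton fit
# ---------------------------------------------------------------------------


def _run_optimizer(theta0, spec, counts, N, options):
    res = minimize(
        _negloglik_grad,
        theta0,
        args=(spec, counts, N),
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": options.max_iter,
            "ftol": 1e-14,
            "gtol": 1e-8,
            "maxcor": 30,
        },
    )
    gnorm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or gnorm < 1e-6)
    return res.x, -res.fun * N, converged, int(res.nit), gnorm


def _build_result(
    nat: NaturalParams,
    spec: ModelSpec,
    table: AgreementPatternTable,
    loglik: float,
    converged: bool,
    n_iter: int,
    options: FitOptions,
    optima_log: list[dict],
) -> FitResult:
    lam = natural_to_lambda(nat, spec, total=table.N)
    classical = natural_to_classical(nat, spec)
    P = pattern_probabilities_natural(nat, spec)
    dev = deviance_from_probs(P, table)
    se = None
    if options.compute_se and converged:
        try:
            se = standard_errors_natural(nat, spec, table)
        except SingularInformationError:
            se = None
    return FitResult(
        spec=spec,
        lam=lam,
        natural=nat,
        classical=classical,
        se_classical=se,
        loglik=loglik,
        deviance=dev,
        bic=bic(loglik, spec, table.N),
        converged=converged,
        n_iter=n_iter,
        N=table.N,
        optima_log=optima_log,
    )


def fit_ml(
    table: AgreementPatternTable,
    spec: ModelSpec,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Best local maximum of the multinomial likelihood over seeded multi-starts.

    The reported solution is oriented so that ``sum(m) > sum(u)``; if the
    optimizer lands in the label-swapped mode the classes are relabeled
    (re-optimizing when the interaction structure is class-asymmetric).
    """
    _check_table(table, spec)
    counts = table.counts.astype(float)
    N = table.N
    rng = np.random.default_rng(options.seed)

    starts: list[NaturalParams] = []
    if options.init == "user":
        starts.append(options.init_params)
    elif options.init == "heuristic":
        starts.append(_heuristic_start(table, spec))
    else:
        starts.append(_random_start(rng, table, spec))
    while len(starts) < options.n_starts:
        starts.append(_random_start(rng, table, spec))

    best = None
    optima_log: list[dict] = []
    for s_idx, start in enumerate(starts):
        theta0 = _pack(start, spec)
        theta, loglik, conv, nit, gnorm = _run_optimizer(theta0, spec, counts, N, options)
        optima_log.append(
            {"start": s_idx, "loglik": loglik, "converged": conv, "n_iter": nit, "gnorm": gnorm}
        )
        if best is None or loglik > best[1] + 1e-9 or (loglik > best[1] - 1e-9 and conv and not best[2]):
            best = (theta, loglik, conv, nit)

    theta, loglik, conv, nit = best
    nat = _unpack(theta, spec)

    classical = natural_to_classical(nat, spec)
    if classical.m.sum() < classical.u.sum():
        relabeled = _project_to_structure(_swap_classes(nat), spec)
        theta2, loglik2, conv2, nit2, gnorm2 = _run_optimizer(
            _pack(relabeled, spec), spec, counts, N, options
        )
        optima_log.append(
            {"start": "relabel", "loglik": loglik2, "converged": conv2, "n_iter": nit2, "gnorm": gnorm2}
        )
        nat2 = _unpack(theta2, spec)
        if natural_to_classical(nat2, spec).m.sum() >= natural_to_classical(nat2, spec).u.sum():
            nat, loglik, conv, nit = nat2, loglik2, conv2, nit2

    return _build_result(nat, spec, table, loglik, conv, nit, options, optima_log)


# ---------------------------------------------------------------------------
# EM (independent cross-checking route)
# ---------------------------------------------------------------------------


def _em_mstep_ci(F0, F1, Y):
    """Closed-form weighted-proportion updates for the CI model."""
    W0, W1 = F0.sum(), F1.sum()
    u = np.clip((F0 @ Y) / W0, 1e-12, 1 - 1e-12)
    m = np.clip((F1 @ Y) / W1, 1e-12, 1 - 1e-12)
    return logit(u), logit(m)


def _em_mstep_loglinear(nat, spec, F0, F1, Y, X):
    """Inner maximization of the expected complete-data class terms (concave)."""
    W0, W1 = F0.sum(), F1.sum()

    def negQ(theta_s):
        full = np.concatenate([[0.0], theta_s])  # dummy logit(pi), unused below
        cand = _unpack(full, spec)
        q0, q1 = class_pattern_probs(cand, spec)
        val = -(F0 @ np.log(np.maximum(q0, _EPS_P)) + F1 @ np.log(np.maximum(q1, _EPS_P)))
        K = spec.K
        g = np.empty_like(theta_s)
        g[:K] = -(F0 @ Y - W0 * (q0 @ Y))
        g[K : 2 * K] = -(F1 @ Y - W1 * (q1 @ Y))
        pos = 2 * K
        for t, term in enumerate(spec.interactions):
            x = X[:, t]
            d0 = -(F0 @ x - W0 * (q0 @ x))
            d1 = -(F1 @ x - W1 * (q1 @ x))
            if term.structure == "match_only":
                g[pos] = d1
                pos += 1
            elif term.structure == "nonmatch_only":
                g[pos] = d0
                pos += 1
            elif term.structure == "both_shared":
                g[pos] = d0 + d1
                pos += 1
            else:
                g[pos] = d0
                g[pos + 1] = d1
                pos += 2
        return val, g

    theta_s0 = _pack(nat, spec)[1:]
    res = minimize(negQ, theta_s0, jac=True, method="L-BFGS-B", options={"maxiter": 200, "ftol": 1e-13})
    full = np.concatenate([[logit(nat.pi)], res.x])
    return _unpack(full, spec)


def fit_em(
    table: AgreementPatternTable,
    spec: ModelSpec,
    options: FitOptions = FitOptions(),
    max_em_iter: int = 20000,
) -> FitResult:
    """EM fit; observed-data log-likelihood is non-decreasing across iterations."""
    _check_table(table, spec)
    counts = table.counts.astype(float)
    N = table.N
    Y = pattern_matrix(spec.K).astype(float)
    X = _interaction_design(spec)
    rng = np.random.default_rng(options.seed)

    starts: list[NaturalParams] = []
    if options.init == "user":
        starts.append(options.init_params)
    elif options.init == "heuristic":
        starts.append(_heuristic_start(table, spec))
    else:
        starts.append(_random_start(rng, table, spec))
    while len(starts) < options.n_starts:
        starts.append(_random_start(rng, table, spec))

    best = None
    optima_log: list[dict] = []
    for s_idx, start in enumerate(starts):
        nat = start
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, max_em_iter + 1):
            q0, q1 = class_pattern_probs(nat, spec)
            P = np.maximum(nat.pi * q1 + (1.0 - nat.pi) * q0, _EPS_P)
            ll = float(counts @ np.log(P))
            if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):  # EM must be monotone
                raise RuntimeError(f"EM log-likelihood decreased at iteration {it}")
            if it > 1 and (ll - prev_ll) <= options.tol * max(1.0, abs(ll)):
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
            # E-step
            F1 = counts * (nat.pi * q1 / P)
            F0 = counts - F1
            pi_new = min(max(F1.sum() / N, 1e-15), 1 - 1e-15)
            # M-step
            if spec.is_ci:
                a0, a1 = _em_mstep_ci(F0, F1, Y)
                nat = NaturalParams(pi_new, a0, a1, nat.gamma0, nat.gamma1)
            else:
                nat = replace(
                    _em_mstep_loglinear(nat, spec, F0, F1, Y, X), pi=pi_new
                )
        optima_log.append({"start": s_idx, "loglik": prev_ll, "converged": converged, "n_iter": it})
        if best is None or prev_ll > best[1]:
            best = (nat, prev_ll, converged, it)

    nat, loglik, conv, nit = best
    classical = natural_to_classical(nat, spec)
    if classical.m.sum() < classical.u.sum():
        nat = _project_to_structure(_swap_classes(nat), spec)
        q0, q1 = class_pattern_probs(nat, spec)
        P = np.maximum(nat.pi * q1 + (1.0 - nat.pi) * q0, _EPS_P)
        loglik = float(counts @ np.log(P))
    return _build_result(nat, spec, table, loglik, conv, nit, options, optima_log)


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------


def _numeric_hessian(func, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    p = theta.size
    H = np.zeros((p, p))
    for i in range(p):
        step = h * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += step
        tm[i] -= step
        _, gp = func(tp)
        _, gm = func(tm)
        H[:, i] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def standard_errors_natural(
    nat: NaturalParams, spec: ModelSpec, table: AgreementPatternTable
) -> ClassicalSE:
    """Delta-method SEs for (pi, m, u) from the inverse observed information."""
    counts = table.counts.astype(float)
    N = table.N
    theta = _pack(nat, spec)

    H = _numeric_hessian(lambda t: _negloglik_grad(t, spec, counts, N), theta) * N
    try:
        cov_theta = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError(str(exc)) from exc
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        worst = int(np.argmin(np.abs(np.diag(H))))
        raise SingularInformationError(
            f"observed information is numerically singular (cond={cond:.2e}, "
            f"flattest free parameter index {worst})"
        )

    def psi(t: np.ndarray) -> np.ndarray:
        cp = natural_to_classical(_unpack(t, spec), spec)
        return np.concatenate([[cp.pi], cp.m, cp.u])

    p = theta.size
    base = psi(theta)
    J = np.zeros((base.size, p))
    for i in range(p):
        step = 1e-6 * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += step
        tm[i] -= step
        J[:, i] = (psi(tp) - psi(tm)) / (2 * step)

    var = np.einsum("ij,jk,ik->i", J, cov_theta, J)
    var = np.maximum(var, 0.0)
    se = np.sqrt(var)
    K = spec.K
    return ClassicalSE(pi=float(se[0]), m=se[1 : 1 + K], u=se[1 + K : 1 + 2 * K])


def standard_errors(fit: FitResult, table: AgreementPatternTable) -> ClassicalSE:
    """Public wrapper on the fitted result."""
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    return standard_errors_natural(fit.natural, fit.spec, table)
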