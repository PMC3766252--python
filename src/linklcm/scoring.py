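"""Match scores, posterior match probabilities, and record-pair classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AgreementPatternTable
from .model import FitResult, class_pattern_probs, match_scores_all

__all__ = [
    "ClassificationRule",
    "posterior_probabilities",
    "classify",
    "Classification",
    "score_frame",
]


@dataclass(frozen=True)
class ClassificationRule:
    """How pattern-level scores become match / nonmatch / uncertain labels.

    Modes:

    * ``posterior_threshold`` -- match iff the posterior match probability
      exceeds ``posterior_cut`` (the canonical Bayes rule; default).
    * ``score_thresholds`` -- three-way Fellegi-Sunter split on the log2
      match score with an uncertain zone between the bounds.
    * ``prevalence_rank`` -- declare the highest-scoring patterns as matches
      until the cumulative pair count first reaches ``N * target``; the
      target defaults to the fitted prevalence.
    """

    mode: str = "posterior_threshold"
    posterior_cut: float = 0.5
    score_lower: float = 0.0
    score_upper: float = 0.0
    target_prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("posterior_threshold", "score_thresholds", "prevalence_rank"):
            raise ValueError(f"unknown classification mode {self.mode!r}")
        if not (0.0 <= self.posterior_cut <= 1.0):
            raise ValueError("posterior_cut must lie in [0, 1]")
        if self.score_lower > self.score_upper:
            raise ValueError("score_lower must not exceed score_upper")
        if self.target_prevalence is not None and not (0.0 <= self.target_prevalence <= 1.0):
            raise ValueError("target_prevalence must lie in [0, 1]")


def posterior_probabilities(fit: FitResult) -> np.ndarray:
    """``P(M=1 | Y_d)`` for every pattern: the Bayes inversion of the mixture."""
    q0, q1 = class_pattern_probs(fit.natural, fit.spec)
    pi = fit.natural.pi
    num = pi * q1
    return num / (num + (1.0 - pi) * q0)


@dataclass(frozen=True)
class Classification:
    """Per-pattern labels plus the total declared-match pair count."""

    labels: tuple[str, ...]  # one of "match", "nonmatch", "uncertain" per pattern
    n_matches: int


def classify(
    fit: FitResult,
    table: AgreementPatternTable,
    rule: ClassificationRule = ClassificationRule(),
) -> Classification:
    """Label every agreement pattern and count the declared-match pairs.

    Classification is a function of the pattern only; counts come from the
    table's frequencies.
    """
    if table.K != fit.spec.K:
        raise ValueError("table and fit disagree on the number of fields")
    D = 2**fit.spec.K
    posterior = posterior_probabilities(fit)
    scores = match_scores_all(fit.natural, fit.spec)
    labels = np.full(D, "nonmatch", dtype=object)

    if rule.mode == "posterior_threshold":
        labels[posterior > rule.posterior_cut] = "match"
    elif rule.mode == "score_thresholds":
        labels[scores > rule.score_upper] = "match"
        labels[(scores >= rule.score_lower) & (scores <= rule.score_upper)] = "uncertain"
        if rule.score_lower == rule.score_upper:
            # degenerate zone: two-way split at the common bound
            labels = np.where(scores > rule.score_upper, "match", "nonmatch").astype(object)
    else:  # prevalence_rank
        target = rule.target_prevalence if rule.target_prevalence is not None else fit.natural.pi
        goal = table.N * target
        order = np.argsort(-scores, kind="stable")
        cum = 0
        for d in order:
            if cum >= goal:
                break
            labels[d] = "match"
            cum += int(table.counts[d])

    n_matches = int(table.counts[labels == "match"].sum())
    return Classification(tuple(labels), n_matches)


def score_frame(
    fit: FitResult,
    table: AgreementPatternTable,
    rule: ClassificationRule = ClassificationRule(),
) -> pd.DataFrame:
    """Scored pattern table: bits, count, log2 match score, posterior, label."""
    cls = classify(fit, table, rule)
    df = table.to_frame()
    df["match_score_log2"] = match_scores_all(fit.natural, fit.spec)
    df["posterior"] = posterior_probabilities(fit)
    df["label"] = list(cls.labels)
    return df
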