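"""Pairwise correlation residuals: the conditional-dependence diagnostic.

For each of the K(K-1)/2 field pairs the observed agreement correlation is
compared with the correlation implied by a fitted model's expected pattern
counts.  A residual far from zero flags a pair whose within-class dependence
the model fails to capture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AgreementPatternTable
from .model import FitResult, pattern_matrix, pattern_probabilities_natural

__all__ = [
    "ResidualSet",
    "observed_correlations",
    "expected_correlations",
    "correlation_residuals",
    "flag_candidates",
    "plot_residuals",
]


@dataclass(frozen=True)
class ResidualSet:
    """Observed, expected, and residual correlations for every field pair.

    Pairs are in lexicographic (j, l) order by field position.  Entries for
    pairs with a degenerate margin are NaN and are excluded from flagging.
    """

    pairs: tuple[tuple[int, int], ...]
    observed: np.ndarray
    expected: np.ndarray
    field_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed", np.asarray(self.observed, dtype=float))
        object.__setattr__(self, "expected", np.asarray(self.expected, dtype=float))
        n = len(self.pairs)
        if self.observed.shape != (n,) or self.expected.shape != (n,):
            raise ValueError("observed/expected must align with the pair list")

    @property
    def residual(self) -> np.ndarray:
        return self.observed - self.expected

    def labels(self) -> list[str]:
        return [f"{self.field_names[j]}:{self.field_names[l]}" for j, l in self.pairs]

    def residual_of(self, j: int, l: int) -> float:
        if j > l:
            j, l = l, j
        idx = self.pairs.index((j, l))
        return float(self.residual[idx])

    def to_frame(self, threshold: float = 0.05) -> pd.DataFrame:
        res = self.residual
        return pd.DataFrame(
            {
                "field_j": [self.field_names[j] for j, _ in self.pairs],
                "field_l": [self.field_names[l] for _, l in self.pairs],
                "observed": self.observed,
                "expected": self.expected,
                "residual": res,
                "flagged": np.abs(res) > threshold,
            }
        )


def _pair_list(K: int) -> list[tuple[int, int]]:
    return [(j, l) for j in range(K) for l in range(j + 1, K)]


def _correlations_from_weights(weights: np.ndarray, K: int) -> np.ndarray:
    """Phi correlations per pair from (possibly fractional) pattern weights."""
    Y = pattern_matrix(K).astype(float)
    total = weights.sum()
    p = (weights @ Y) / total
    out = np.empty(K * (K - 1) // 2)
    for idx, (j, l) in enumerate(_pair_list(K)):
        pjl = float(weights @ (Y[:, j] * Y[:, l])) / total
        denom = p[j] * (1 - p[j]) * p[l] * (1 - p[l])
        if denom <= 0:
            out[idx] = np.nan
        else:
            out[idx] = (pjl - p[j] * p[l]) / math.sqrt(denom)
    return out


def observed_correlations(table: AgreementPatternTable) -> ResidualSet:
    """Observed pairwise agreement correlations; expected entries are NaN placeholders."""
    if table.N == 0:
        raise ValueError("empty table has no correlations")
    obs = _correlations_from_weights(table.counts.astype(float), table.K)
    n = len(obs)
    return ResidualSet(
        tuple(_pair_list(table.K)), obs, np.full(n, np.nan), table.field_names
    )


def expected_correlations(fit: FitResult) -> np.ndarray:
    """Correlations implied by the model-expected counts ``N * P(Y_d)`` over all patterns."""
    P = pattern_probabilities_natural(fit.natural, fit.spec)
    return _correlations_from_weights(fit.N * P, fit.spec.K)


def correlation_residuals(table: AgreementPatternTable, fit: FitResult) -> ResidualSet:
    """Observed minus model-expected correlation for every field pair."""
    if table.K != fit.spec.K:
        raise ValueError("table and fit disagree on the number of fields")
    obs = _correlations_from_weights(table.counts.astype(float), table.K)
    exp = expected_correlations(fit)
    names = fit.spec.field_names or table.field_names
    return ResidualSet(tuple(_pair_list(table.K)), obs, exp, tuple(names))


def flag_candidates(
    residuals: ResidualSet, threshold: float = 0.05
) -> list[tuple[tuple[int, int], float]]:
    """Pairs with |residual| above the guideline, sorted by descending magnitude.

    NaN residuals (degenerate margins) are never flagged.
    """
    res = residuals.residual
    flagged = [
        (pair, float(res[i]))
        for i, pair in enumerate(residuals.pairs)
        if np.isfinite(res[i]) and abs(res[i]) > threshold
    ]
    flagged.sort(key=lambda item: -abs(item[1]))
    return flagged


def plot_residuals(
    residuals: ResidualSet | list[ResidualSet],
    output_path,
    threshold: float = 0.05,
    titles: list[str] | None = None,
) -> None:
    """Scatter of residual vs. pair index with +-threshold guides; multi-panel for a model sequence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = residuals if isinstance(residuals, list) else [residuals]
    fig, axes = plt.subplots(
        len(panels), 1, figsize=(8, 3 * len(panels)), squeeze=False, sharex=True
    )
    for p_idx, (ax, rset) in enumerate(zip(axes[:, 0], panels)):
        res = rset.residual
        x = np.arange(len(res))
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.axhline(threshold, color="red", lw=0.8, ls="--")
        ax.axhline(-threshold, color="red", lw=0.8, ls="--")
        ok = np.isfinite(res)
        ax.scatter(x[ok], res[ok], color="black", s=18)
        ax.set_ylabel("correlation residual")
        if titles and p_idx < len(titles):
            ax.set_title(titles[p_idx])
        if len(res):
            ax.set_xticks(x)
            ax.set_xticklabels(rset.labels(), rotation=90, fontsize=7)
    axes[-1, 0].set_xlabel("field pair")
    fig.tight_layout()
    fig.savefig(output_path, dpi=150)
    plt.close(fig)
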