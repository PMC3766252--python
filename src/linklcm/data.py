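"""Agreement-pattern data: record comparison, blocking, and frequency tables.

Everything downstream of this module consumes an :class:`AgreementPatternTable`
-- the frequency counts ``f_d`` over all ``2**K`` binary agreement patterns,
which is the sufficient statistic for the latent-class model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import pattern_matrix

__all__ = [
    "DEFAULT_NA_TOKENS",
    "FieldConfig",
    "AgreementPatternTable",
    "canonicalize",
    "compare_records",
    "block_pairs",
    "build_pattern_table",
    "table_from_records",
    "read_table_csv",
    "write_table_csv",
    "read_agreement_csv",
]

#: Values treated as missing after canonicalization (besides actual NaN/None).
DEFAULT_NA_TOKENS = ("", "na", "null")


@dataclass(frozen=True)
class FieldConfig:
    """One compared field: exact equality after canonicalization; missing counts as disagreement."""

    field_name: str
    comparator: str = "exact"
    missing_policy: str = "disagree"

    def __post_init__(self) -> None:
        if self.comparator != "exact":
            raise ValueError(f"unsupported comparator {self.comparator!r}")
        if self.missing_policy != "disagree":
            raise ValueError(f"unsupported missing policy {self.missing_policy!r}")


def validate_field_configs(configs: Sequence[FieldConfig]) -> None:
    if not configs:
        raise ValueError("field configuration list is empty")
    names = [c.field_name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate field names in configuration: {names}")


def canonicalize(value, na_tokens: Sequence[str] = DEFAULT_NA_TOKENS):
    """Trim + casefold a value; return ``None`` when it is missing.

    ``None`` and float NaN are missing, as is any value whose canonical string
    form appears in ``na_tokens`` (token comparison is case-insensitive).
    """
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip().casefold()
    if text in {t.strip().casefold() for t in na_tokens}:
        return None
    return text


class FieldMissingError(KeyError):
    """A configured field is absent from a record."""


def _get_field(record: Mapping, name: str):
    if name not in record:
        raise FieldMissingError(f"record is missing configured field {name!r}")
    return record[name]


def compare_records(
    record_a: Mapping,
    record_b: Mapping,
    config: Sequence[FieldConfig],
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
) -> np.ndarray:
    """Binary agreement vector over the configured fields.

    Component ``k`` is 1 iff both values are non-missing and canonically
    equal; missing on either side is coded as disagreement.
    """
    validate_field_configs(config)
    out = np.zeros(len(config), dtype=np.int8)
    for k, cfg in enumerate(config):
        a = canonicalize(_get_field(record_a, cfg.field_name), na_tokens)
        b = canonicalize(_get_field(record_b, cfg.field_name), na_tokens)
        out[k] = 1 if (a is not None and b is not None and a == b) else 0
    return out


def block_pairs(
    records: Sequence[Mapping],
    blocking_fields: Sequence[str],
    records2: Sequence[Mapping] | None = None,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
) -> Iterator[tuple[int, int]]:
    """Yield index pairs agreeing (non-missing, canonically equal) on every blocking field.

    De-duplication mode (``records2`` is None) yields ``i < j`` pairs within
    one file; two-file mode yields the cross product within blocks.  Records
    with a missing blocking key appear in no pair.
    """
    if not blocking_fields:
        raise ValueError("at least one blocking field is required")

    def key_of(record: Mapping):
        parts = []
        for name in blocking_fields:
            v = canonicalize(_get_field(record, name), na_tokens)
            if v is None:
                return None
            parts.append(v)
        return tuple(parts)

    blocks: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        key = key_of(rec)
        if key is not None:
            blocks.setdefault(key, []).append(i)

    if records2 is None:
        for members in blocks.values():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    yield members[a], members[b]
    else:
        blocks2: dict[tuple, list[int]] = {}
        for j, rec in enumerate(records2):
            key = key_of(rec)
            if key is not None:
                blocks2.setdefault(key, []).append(j)
        for key, members in blocks.items():
            for i in members:
                for j in blocks2.get(key, ()):
                    yield i, j


@dataclass(frozen=True)
class AgreementPatternTable:
    """Frequency counts over all ``D = 2**K`` agreement patterns.

    Pattern ``d`` encodes the bits of ``(y_1, ..., y_K)`` with field 1 as the
    most significant bit; unobserved patterns carry count 0.
    """

    K: int
    counts: np.ndarray
    field_names: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2**self.K,):
            raise ValueError(f"counts must have length 2**K = {2 ** self.K}, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("pattern counts must be non-negative")
        counts = counts.copy()
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        names = self.field_names
        if names is None:
            names = tuple(f"field_{k + 1}" for k in range(self.K))
        names = tuple(names)
        if len(names) != self.K:
            raise ValueError("field_names length must equal K")
        object.__setattr__(self, "field_names", names)

    @property
    def N(self) -> int:
        """Total number of compared record pairs."""
        return int(self.counts.sum())

    @property
    def patterns(self) -> np.ndarray:
        return pattern_matrix(self.K)

    def agreement_proportions(self) -> np.ndarray:
        """Observed marginal agreement proportion per field."""
        if self.N == 0:
            raise ValueError("empty table has no agreement proportions")
        return (self.counts @ self.patterns) / self.N

    def expand(self) -> np.ndarray:
        """Vector multiset as an N x K matrix (inverse of tabulation)."""
        return np.repeat(self.patterns, self.counts, axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.patterns, columns=list(self.field_names))
        df["count"] = self.counts
        return df


def build_pattern_table(
    vectors: Iterable[Sequence[int]],
    K: int,
    field_names: Sequence[str] | None = None,
) -> AgreementPatternTable:
    """Tabulate a stream of binary agreement vectors into pattern counts."""
    counts = np.zeros(2**K, dtype=np.int64)
    shifts = np.arange(K - 1, -1, -1)
    for vec in vectors:
        v = np.asarray(vec)
        if v.shape != (K,):
            raise ValueError(f"agreement vector of length {v.size} does not match K={K}")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("agreement vectors must be binary")
        counts[int((v.astype(np.int64) << shifts).sum())] += 1
    return AgreementPatternTable(K, counts, tuple(field_names) if field_names else None)


def table_from_records(
    records: Sequence[Mapping],
    blocking_fields: Sequence[str],
    compare_fields: Sequence[str],
    records2: Sequence[Mapping] | None = None,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
) -> AgreementPatternTable:
    """Block, compare, and tabulate raw records in one pass.

    Blocking fields are excluded from the agreement vector.
    """
    overlap = set(blocking_fields) & set(compare_fields)
    if overlap:
        raise ValueError(f"blocking fields cannot also be compared: {sorted(overlap)}")
    config = [FieldConfig(name) for name in compare_fields]
    validate_field_configs(config)
    other = records if records2 is None else records2

    def vectors():
        for i, j in block_pairs(records, blocking_fields, records2, na_tokens):
            yield compare_records(records[i], other[j], config, na_tokens)

    return build_pattern_table(vectors(), len(compare_fields), compare_fields)


# ---------------------------------------------------------------------------
# CSV round-tripping
# ---------------------------------------------------------------------------


def write_table_csv(table: AgreementPatternTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_table_csv(path, field_names: Sequence[str] | None = None) -> AgreementPatternTable:
    """Read a pattern-frequency CSV: K binary pattern columns plus a ``count`` column."""
    df = pd.read_csv(path)
    if "count" not in df.columns:
        raise ValueError(f"{path}: pattern-table CSV requires a 'count' column")
    names = [c for c in df.columns if c != "count"]
    if field_names is not None:
        missing = set(field_names) - set(names)
        if missing:
            raise ValueError(f"{path}: requested fields not present: {sorted(missing)}")
        names = list(field_names)
    K = len(names)
    if K == 0:
        raise ValueError(f"{path}: no pattern columns found")
    bits = df[names].to_numpy()
    if not np.isin(bits, (0, 1)).all():
        raise ValueError(f"{path}: pattern columns must be binary")
    shifts = np.arange(K - 1, -1, -1)
    idx = (bits.astype(np.int64) << shifts).sum(axis=1)
    counts = np.zeros(2**K, dtype=np.int64)
    np.add.at(counts, idx, df["count"].to_numpy(dtype=np.int64))
    return AgreementPatternTable(K, counts, tuple(names))


def read_agreement_csv(path, field_names: Sequence[str] | None = None) -> AgreementPatternTable:
    """Read pair-level binary agreement data (one row per record pair, 0/1 per field).

    Accepts an optional ``count``/``freq`` column of row weights, so both
    fully expanded pair files and pre-aggregated files load through this path.
    """
    df = pd.read_csv(path)
    weight_col = next((c for c in ("count", "freq", "frequency") if c in df.columns), None)
    names = [c for c in df.columns if c != weight_col]
    if field_names is not None:
        missing = set(field_names) - set(names)
        if missing:
            raise ValueError(f"{path}: requested fields not present: {sorted(missing)}")
        names = list(field_names)
    K = len(names)
    if K == 0:
        raise ValueError(f"{path}: no agreement columns found")
    bits = df[names].to_numpy()
    if not np.isin(bits, (0, 1)).all():
        raise ValueError(f"{path}: agreement columns must be binary (0/1)")
    weights = (
        df[weight_col].to_numpy(dtype=np.int64) if weight_col else np.ones(len(df), dtype=np.int64)
    )
    shifts = np.arange(K - 1, -1, -1)
    idx = (bits.astype(np.int64) << shifts).sum(axis=1)
    counts = np.zeros(2**K, dtype=np.int64)
    np.add.at(counts, idx, weights)
    return AgreementPatternTable(K, counts, tuple(names))
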