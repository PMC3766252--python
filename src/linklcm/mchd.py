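"""Loader for the MCHD client-registry supplementary dataset ("MCHD data.csv").

The file is distributed as de-identified blocked record pairs over seven
comparison fields (618,213 pairs blocked on last and first name).  It is not
shipped with this package; point ``LINKLCM_MCHD_DATA`` at a local copy or
drop the file under ``data/``.
"""

from __future__ import annotations

import os
from pathlib import Path

from .data import AgreementPatternTable, read_agreement_csv

__all__ = ["MCHD_FIELDS", "MCHD_EXPECTED_N", "find_mchd_file", "load_mchd_table"]

#: Canonical field order used for reporting (field 1 .. field 7).
MCHD_FIELDS = (
    "year_of_birth",
    "ssn",
    "day_of_birth",
    "telephone",
    "zip",
    "sex",
    "month_of_birth",
)

MCHD_EXPECTED_N = 618_213

#: Substrings used to recognize each canonical field in the file's own header.
_FIELD_HINTS = {
    "year_of_birth": ("year", "yob", "birth_year", "yr"),
    "ssn": ("ssn", "social"),
    "day_of_birth": ("day", "dob_day", "birth_day"),
    "telephone": ("tel", "phone"),
    "zip": ("zip", "postal"),
    "sex": ("sex", "gender"),
    "month_of_birth": ("month", "mob", "birth_month", "mo"),
}

_SEARCH_PATHS = (
    "data/MCHD data.csv",
    "data/MCHD_data.csv",
    "data/mchd.csv",
    "MCHD data.csv",
)


def find_mchd_file(root: str | os.PathLike = ".") -> Path | None:
    """Locate the supplementary CSV: env var first, then conventional paths."""
    env = os.environ.get("LINKLCM_MCHD_DATA")
    if env:
        p = Path(env)
        if p.exists():
            return p
    for rel in _SEARCH_PATHS:
        p = Path(root) / rel
        if p.exists():
            return p
    return None


def _canonical_names(raw_names: tuple[str, ...]) -> tuple[str, ...]:
    """Map the file's column names onto the canonical seven, by hint then by position."""
    if len(raw_names) != len(MCHD_FIELDS):
        raise ValueError(
            f"expected {len(MCHD_FIELDS)} comparison fields, found {len(raw_names)}: {raw_names}"
        )
    mapping: dict[int, str] = {}
    used: set[str] = set()
    for i, raw in enumerate(raw_names):
        low = raw.strip().lower()
        for canon, hints in _FIELD_HINTS.items():
            if canon in used:
                continue
            if any(h in low for h in hints):
                mapping[i] = canon
                used.add(canon)
                break
    if len(mapping) == len(MCHD_FIELDS):
        return tuple(mapping[i] for i in range(len(raw_names)))
    # fall back to documented field order
    return MCHD_FIELDS


def load_mchd_table(path: str | os.PathLike) -> AgreementPatternTable:
    """Read the supplementary file as an agreement-pattern table.

    Accepts either pair-level binary rows (optionally weighted by a
    ``count``/``freq`` column) or an aggregated pattern-frequency CSV.
    Non-binary columns other than the weight (e.g. pair identifiers) are
    dropped; the seven agreement columns are renamed to the canonical field
    labels so reports are comparable.
    """
    import numpy as np
    import pandas as pd

    df = pd.read_csv(path)
    weight_col = next((c for c in df.columns if c.strip().lower() in ("count", "freq", "frequency")), None)
    binary_cols = [
        c
        for c in df.columns
        if c != weight_col and np.isin(df[c].dropna().unique(), (0, 1)).all()
    ]
    if len(binary_cols) != len(MCHD_FIELDS):
        raise ValueError(
            f"{path}: expected {len(MCHD_FIELDS)} binary agreement columns, "
            f"found {len(binary_cols)}: {binary_cols}"
        )
    import io

    sub = df[binary_cols + ([weight_col] if weight_col else [])]
    buf = io.StringIO()
    sub.to_csv(buf, index=False)
    buf.seek(0)
    table = read_agreement_csv(buf)
    names = _canonical_names(tuple(binary_cols))
    return AgreementPatternTable(table.K, table.counts.copy(), names)
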