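"""Long-format trial-table reading, validation and writing.

The native schema is one row per trial per participant:

    participant, experiment, trial, phase, block, role, stimulus, size_mm,
    us, k, size_estimate_mm, expectancy

``size_estimate_mm`` (perceived size, 0-200 mm VAS) and ``expectancy``
(US-expectancy rating) are nullable; empty cells encode missingness.
External files with different column names are adapted through a
column-mapping dialect rather than guessed at.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .designs import ROLE_CS_MINUS, ROLE_CS_PLUS, ROLE_TS

REQUIRED_COLUMNS = (
    "participant",
    "trial",
    "phase",
    "block",
    "role",
    "stimulus",
    "size_mm",
    "us",
    "k",
)
OPTIONAL_COLUMNS = ("experiment", "size_estimate_mm", "expectancy")

#: built-in column-name dialects for external long-format exports
DIALECTS: Dict[str, Dict[str, str]] = {
    "genmix": {},
    # generic deposited-data layout: subject/stim/shock naming
    "osf": {
        "subject": "participant",
        "stim": "stimulus",
        "size": "size_mm",
        "shock": "us",
        "perceived_size": "size_estimate_mm",
        "us_expectancy": "expectancy",
    },
}


class TrialTableError(ValueError):
    """Schema violation in a long-format trial table."""


def validate_trials(table: pd.DataFrame, strict_scale: bool = True) -> None:
    """Raise ``TrialTableError`` with row-level messages on schema violations.

    ``strict_scale`` additionally enforces the native measurement ranges
    (expectancy in [1, 10], percepts in [0, 200]); synthetic ratings are
    deliberately unclipped, so simulated tables are validated with
    ``strict_scale=False``.
    """
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise TrialTableError(f"missing required columns: {sorted(missing)}")

    bad_role = ~table["role"].isin([ROLE_CS_PLUS, ROLE_CS_MINUS, ROLE_TS])
    if bad_role.any():
        rows = table.index[bad_role].tolist()[:5]
        raise TrialTableError(f"unknown cue role at rows {rows}")

    bad_us = (table["role"] != ROLE_CS_PLUS) & (table["us"] != 0)
    if bad_us.any():
        rows = table.index[bad_us].tolist()[:5]
        raise TrialTableError(f"US delivered on non-CS+ rows {rows}")

    k_expect = table["role"].isin([ROLE_CS_PLUS, ROLE_CS_MINUS]).astype(int)
    bad_k = table["k"] != k_expect
    if bad_k.any():
        rows = table.index[bad_k].tolist()[:5]
        raise TrialTableError(f"update flag k inconsistent with role at rows {rows}")

    for pid, grp in table.groupby("participant", sort=False):
        trials = grp["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, len(trials) + 1)):
            raise TrialTableError(
                f"participant {pid}: trial indices not contiguous from 1"
            )

    if strict_scale:
        if "expectancy" in table.columns:
            y = pd.to_numeric(table["expectancy"], errors="coerce")
            bad = y.notna() & ((y < 1) | (y > 10))
            if bad.any():
                rows = table.index[bad].tolist()[:5]
                raise TrialTableError(
                    f"expectancy outside [1, 10] at rows {rows}"
                )
        if "size_estimate_mm" in table.columns:
            x = pd.to_numeric(table["size_estimate_mm"], errors="coerce")
            bad = x.notna() & ((x < 0) | (x > 200))
            if bad.any():
                rows = table.index[bad].tolist()[:5]
                raise TrialTableError(
                    f"size estimate outside [0, 200] at rows {rows}"
                )


def read_trials(
    path,
    dialect: str = "genmix",
    column_map: Optional[Dict[str, str]] = None,
    strict_scale: Optional[bool] = None,
) -> pd.DataFrame:
    """Read and validate a long-format trial CSV.

    ``dialect`` selects a built-in column mapping; ``column_map`` overrides
    or extends it. Native files (which may contain unclipped synthetic
    ratings) are range-checked leniently, external dialects strictly.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; know {sorted(DIALECTS)}")
    mapping = dict(DIALECTS[dialect])
    if column_map:
        mapping.update(column_map)
    table = pd.read_csv(path)
    if mapping:
        table = table.rename(columns=mapping)
    if strict_scale is None:
        strict_scale = dialect != "genmix"
    validate_trials(table, strict_scale=strict_scale)
    return table


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with empty cells for missing values."""
    table.to_csv(path, index=False, na_rep="")
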