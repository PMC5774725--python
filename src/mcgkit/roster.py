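"""Study roster and eligibility filtering.

Mirrors a CONSORT-style participant flow: every enrolled subject carries a
candidate group and boolean exclusion flags (scans lost to device
malfunction, low signal-to-noise ratio, missing/corrupted data, prior
ischemic-heart-disease history in a volunteer).  Filtering removes any
subject with a set flag and pools the remainder into analysis groups
A (patients), B (controls) and C (young healthy volunteers).

The packaged fixture roster encodes the combined study flow: a technical
performance study (63 patients enrolled / 55 analyzed; 60 volunteers / 51
analyzed), a pilot clinical study (21 + 21 enrolled / 15 + 18 analyzed)
and a young healthy reference set (37), yielding analysis groups of
70 / 69 / 37.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO
from pathlib import Path

import pandas as pd

FLAG_COLUMNS = ("device_malfunction", "low_snr", "missing_data", "prior_ihd")
ROSTER_COLUMNS = ("subject_id", "study", "candidate_group") + FLAG_COLUMNS


@dataclass(frozen=True)
class EligibilityResult:
    """Filtered roster plus per-group analysis counts."""

    included: pd.DataFrame
    excluded: pd.DataFrame
    counts: dict[str, int]


def _validate_roster(roster: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ROSTER_COLUMNS if c not in roster.columns]
    if missing:
        raise ValueError(f"roster missing columns: {missing}")
    bad_groups = set(roster["candidate_group"]) - {"A", "B", "C"}
    if bad_groups:
        raise ValueError(f"unknown candidate groups: {sorted(bad_groups)}")
    out = roster.copy()
    for col in FLAG_COLUMNS:
        vals = out[col]
        if vals.dtype == object:
            mapped = vals.astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
            if mapped.isna().any():
                bad = vals[mapped.isna()].unique()
                raise ValueError(f"unknown flag value(s) in {col}: {list(bad)}")
            out[col] = mapped
        elif vals.dtype in ("int64", "float64"):
            if not set(vals.unique()) <= {0, 1}:
                raise ValueError(f"flag column {col} must be boolean-like")
            out[col] = vals.astype(bool)
        else:
            out[col] = vals.astype(bool)
    return out


def load_roster(path: str | Path) -> pd.DataFrame:
    return _validate_roster(pd.read_csv(path))


def packaged_roster() -> pd.DataFrame:
    """The fixture roster encoding the combined study's participant flow."""
    raw = resources.files("mcgkit.data").joinpath("consort_roster.csv").read_text()
    return _validate_roster(pd.read_csv(StringIO(raw)))


def apply_eligibility_filters(roster: pd.DataFrame) -> EligibilityResult:
    """Drop flagged subjects and count the pooled analysis groups.

    A subject is excluded when any exclusion flag is set; the operation is
    a pure row filter (order-independent).  Returns the included roster
    with a ``group`` column, the excluded rows, and counts per group.
    """
    roster = _validate_roster(roster)
    flagged = roster[list(FLAG_COLUMNS)].any(axis=1)
    included = roster.loc[~flagged].copy()
    included["group"] = included["candidate_group"]
    excluded = roster.loc[flagged].copy()
    counts = {g: int((included["group"] == g).sum()) for g in ("A", "B", "C")}
    return EligibilityResult(included=included, excluded=excluded, counts=counts)
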