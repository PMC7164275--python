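"""Long-format CSV dialect and result serialisation.

One dialect only: UTF-8 CSV with header, decimal point ".", required
columns ``subject_id, group, day, parameter, phase, side, replicate,
value`` and optional per-subject columns (``symptoms, t5ss, age, sex,
weight, height, bmi``, repeated on each record row or supplied in a
separate subjects file).  The key (subject_id, day, parameter, phase,
side, replicate) must be unique.  Validation failures raise errors with a
machine-readable ``code`` and the offending rows/columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import DuplicateKeyError, SchemaError, ValueParseError
from .study import StudyDataset

logger = logging.getLogger("rhinostat")

REQUIRED_COLUMNS = [
    "subject_id", "group", "day", "parameter", "phase", "side",
    "replicate", "value",
]
SUBJECT_COLUMNS = ["symptoms", "t5ss", "age", "sex", "weight", "height", "bmi"]
KEY = ["subject_id", "day", "parameter", "phase", "side", "replicate"]
VALID_PARAMETERS = {"R2", "R75", "R100", "R150"}

__all__ = ["read_study_csv", "write_study_csv", "write_json", "config_hash"]


def read_study_csv(path) -> StudyDataset:
    """Read and validate a long-format study CSV.

    Raises :class:`SchemaError` (code ``schema``) for missing columns,
    :class:`ValueParseError` (``nonnumeric_value``) for unparseable
    values, and :class:`DuplicateKeyError` (``duplicate_key``) for
    repeated measurement keys; each error names the offending rows
    (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required columns {missing}", columns=missing
        )
    for col in ("day", "replicate", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 1
        if len(bad):
            raise ValueParseError(
                f"{path.name}: non-numeric {col!r} at rows {list(bad[:10])}",
                rows=list(bad),
            )
        if coerced.isna().any():
            rows = list(df.index[coerced.isna()] + 1)
            raise ValueParseError(
                f"{path.name}: missing {col!r} at rows {rows[:10]}", rows=rows
            )
        df[col] = coerced
    if (df["day"] < 0).any():
        raise SchemaError(f"{path.name}: negative day values")
    unknown = set(df["parameter"].unique()) - VALID_PARAMETERS
    if unknown:
        raise SchemaError(f"{path.name}: unknown parameters {sorted(unknown)}")
    dupes = df.index[df.duplicated(KEY, keep=False)] + 1
    if len(dupes):
        raise DuplicateKeyError(
            f"{path.name}: duplicated measurement keys at rows "
            f"{list(dupes[:10])}", rows=list(dupes)
        )
    df["day"] = df["day"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    subj_cols = [c for c in SUBJECT_COLUMNS if c in df.columns]
    subjects = (
        df.groupby(["subject_id", "group"], sort=False)[subj_cols]
        .first()
        .reset_index()
        if subj_cols
        else df[["subject_id", "group"]].drop_duplicates().reset_index(drop=True)
    )
    if "symptoms" in subjects:
        subjects["symptoms"] = subjects["symptoms"].astype(bool)
    records = df[REQUIRED_COLUMNS].copy()
    return StudyDataset(records=records, subjects=subjects)


def write_study_csv(data: StudyDataset, path) -> None:
    """Write a dataset in the dialect read_study_csv accepts (subject-level
    columns repeated on each record row)."""
    merged = data.records.merge(
        data.subjects.drop(columns=["group"]), on="subject_id", how="left"
    )
    cols = REQUIRED_COLUMNS + [c for c in SUBJECT_COLUMNS if c in merged.columns]
    merged[cols].to_csv(path, index=False)


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def config_hash(obj) -> str:
    """Stable short hash of a configuration (non-string mapping keys are
    stringified first)."""
    payload = json.dumps(_stringify_keys(obj), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_json(obj, path, *, seed=None, config=None) -> None:
    """Write a result bundle with provenance metadata (package version,
    seed, config hash)."""
    bundle = {
        "meta": {
            "package": "rhinostat",
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(config) if config is not None else None,
        },
        "results": obj,
    }
    Path(path).write_text(json.dumps(bundle, indent=2, default=str) + "\n")
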