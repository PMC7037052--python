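"""CSV readers/writers and the packaged study tables.

Three fixtures ship with the package (UTF-8, comma-separated, "." decimal):

* ``retention_params.csv`` — extrapolated (log k_w, s) pairs for 65 test
  compounds on the ODS, IAM and Cholester stationary phases;
* ``training_set.csv`` — Abraham descriptors (E, S, A, B, V) and
  experimental rat log BB for the 23-compound calibration set;
* ``test_compounds.csv`` — Abraham + bulk descriptors (TPSA, alpha, MW)
  for the 65 test compounds, plus the published 2-dp predicted log BB
  columns used as reproduction references (never as training input).

``load_compound_table`` validates a user-supplied CSV against one of the
three schemas and reports row-level problems with line numbers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = [
    "COLUMNS",
    "fixture_path",
    "load_retention_params",
    "load_training_set",
    "load_test_compounds",
    "load_compound_table",
    "load_raw_retention",
    "round_half_away",
]

#: Stationary-phase labels of the packaged retention table.
COLUMNS = ("ODS", "IAM", "Cholester")

_SCHEMAS = {
    "retention": {
        "required": (
            "compound_id",
            "log_kw_ODS",
            "s_ODS",
            "log_kw_IAM",
            "s_IAM",
            "log_kw_Cholester",
            "s_Cholester",
        ),
        "positive": (),
        "nonnegative": ("s_ODS", "s_IAM", "s_Cholester"),
    },
    "training": {
        "required": ("compound_id", "A", "B", "S", "E", "V", "log_bb_exp"),
        "positive": ("V",),
        "nonnegative": ("A", "B"),
    },
    "prediction": {
        "required": ("compound_id", "A", "B", "S", "E", "V", "TPSA", "alpha", "MW"),
        "positive": ("V", "alpha", "MW"),
        "nonnegative": ("A", "B", "TPSA"),
    },
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("bbbperm.data") / name)


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot read {path}: {exc}") from exc


def load_compound_table(path, schema: str) -> pd.DataFrame:
    """Load and validate a compound table.

    ``schema`` is one of ``retention``, ``training``, ``prediction``.
    All problems found are collected and raised together, each tagged
    with its CSV line number (header = line 1).
    """
    if schema not in _SCHEMAS:
        raise ValueError(
            f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}"
        )
    spec = _SCHEMAS[schema]
    df = _read_csv(path)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) for schema {schema!r}: "
            + ", ".join(missing)
        )
    problems = []
    numeric_cols = [c for c in spec["required"] if c != "compound_id"]
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[parsed.isna() & df[col].notna()]:
            problems.append(
                f"line {idx + 2}: non-numeric value {df.at[idx, col]!r} "
                f"in column {col}"
            )
        for idx in df.index[df[col].isna()]:
            problems.append(f"line {idx + 2}: missing value in column {col}")
        df[col] = parsed
    for col in spec["positive"]:
        for idx in df.index[df[col] <= 0]:
            problems.append(
                f"line {idx + 2}: {col} must be > 0, got {df.at[idx, col]}"
            )
    for col in spec["nonnegative"]:
        for idx in df.index[df[col] < 0]:
            problems.append(
                f"line {idx + 2}: {col} must be >= 0, got {df.at[idx, col]}"
            )
    if df["compound_id"].duplicated().any():
        dupes = df["compound_id"][df["compound_id"].duplicated()].tolist()
        problems.append(f"duplicated compound_id(s): {dupes}")
    if problems:
        raise SchemaError(
            f"{path}: {len(problems)} invalid value(s):\n  "
            + "\n  ".join(problems)
        )
    df["compound_id"] = df["compound_id"].astype(str)
    return df


def load_retention_params(path=None) -> pd.DataFrame:
    """The 65-compound (log k_w, s) table; packaged fixture by default."""
    return load_compound_table(
        fixture_path("retention_params.csv") if path is None else path,
        "retention",
    )


def load_training_set(path=None) -> pd.DataFrame:
    """The 23-compound LFER calibration table; fixture by default."""
    return load_compound_table(
        fixture_path("training_set.csv") if path is None else path,
        "training",
    )


def load_test_compounds(path=None) -> pd.DataFrame:
    """The 65-compound descriptor table (plus, in the fixture, the
    published 2-dp prediction columns); fixture by default."""
    return load_compound_table(
        fixture_path("test_compounds.csv") if path is None else path,
        "prediction",
    )


def load_raw_retention(path) -> pd.DataFrame:
    """Long-format raw isocratic measurements:
    (compound_id, column_id, phi, t_r, t_0)."""
    df = _read_csv(path)
    required = ("compound_id", "column_id", "phi", "t_r", "t_0")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s): " + ", ".join(missing)
        )
    problems = []
    for col in ("phi", "t_r", "t_0"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[parsed.isna()]:
            problems.append(
                f"line {idx + 2}: non-numeric or missing {col}"
            )
        df[col] = parsed
    bad_phi = df.index[(df["phi"] <= 0) | (df["phi"] >= 1)]
    problems += [f"line {i + 2}: phi outside (0, 1)" for i in bad_phi]
    bad_t = df.index[(df["t_0"] <= 0) | (df["t_r"] <= df["t_0"])]
    problems += [
        f"line {i + 2}: requires t_r > t_0 > 0" for i in bad_t
    ]
    if problems:
        raise SchemaError(
            f"{path}: {len(problems)} invalid value(s):\n  "
            + "\n  ".join(problems)
        )
    df["compound_id"] = df["compound_id"].astype(str)
    df["column_id"] = df["column_id"].astype(str)
    return df


def round_half_away(x, decimals: int = 2):
    """Round half away from zero — the convention of printed report
    tables (numpy's ``round`` rounds half to even)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.ndim else float(out)
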