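"""CSV readers/writers for trial data tables.

Two tabular formats, both plain CSV with case-sensitive headers copied from
the reference printouts: the longitudinal toxicity table
(``uniqueID, cohort, subj, dose, cycle, nTTP, DLT`` — the ``subID`` variant
with the id column renamed is also accepted) and the one-row-per-patient
efficacy table (``subID, dose, Efficacy``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

TOX_REQUIRED = ("dose", "cycle", "nTTP", "DLT")
EFF_REQUIRED = ("dose", "Efficacy")


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"could not parse {path}: {exc}") from exc


def _id_column(df: pd.DataFrame, table: str) -> str:
    for c in ("uniqueID", "subID"):
        if c in df.columns:
            return c
    raise ValidationError(f"{table} table needs a 'uniqueID' or 'subID' column")


def _require_numeric(df: pd.DataFrame, col: str, table: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any() or df[col].isna().any():
        row = int(np.flatnonzero(bad | df[col].isna())[0]) + 2  # +2: header + 1-based
        raise ValidationError(f"{table} table: non-numeric or missing {col!r} near line {row}")
    return vals.to_numpy()


def read_tox_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a longitudinal toxicity table.

    Enforces: required columns present, integer cycles >= 1, nTTP in [0, 1],
    DLT in {0, 1}, and no duplicate patient-cycle records.
    """
    df = _read_csv(path)
    idcol = _id_column(df, "toxicity")
    missing = [c for c in TOX_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"toxicity table is missing columns {missing}")
    if len(df) == 0:
        return df
    for col in TOX_REQUIRED:
        vals = _require_numeric(df, col, "toxicity")
        df[col] = vals
    for col, ok, msg in (
        ("cycle", (df["cycle"] >= 1) & (df["cycle"] == df["cycle"].astype(int)), "cycles must be integers >= 1"),
        ("dose", df["dose"] >= 1, "dose levels must be >= 1"),
        ("nTTP", (df["nTTP"] >= 0) & (df["nTTP"] <= 1), "nTTP must lie in [0, 1]"),
        ("DLT", df["DLT"].isin([0, 1]), "DLT must be 0 or 1"),
    ):
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0]) + 2
            raise ValidationError(f"toxicity table: {msg} (line {row})")
    df["cycle"] = df["cycle"].astype(int)
    df["DLT"] = df["DLT"].astype(int)
    dup = df.duplicated(subset=[idcol, "cycle"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValidationError(f"toxicity table: duplicate patient-cycle record (line {row})")
    return df


def read_eff_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-patient efficacy table (Efficacy strictly in (0, 1))."""
    df = _read_csv(path)
    idcol = _id_column(df, "efficacy")
    missing = [c for c in EFF_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"efficacy table is missing columns {missing}")
    if len(df) == 0:
        return df
    for col in EFF_REQUIRED:
        df[col] = _require_numeric(df, col, "efficacy")
    ok = (df["Efficacy"] > 0) & (df["Efficacy"] < 1)
    if not ok.all():
        row = int(np.flatnonzero(~ok.to_numpy())[0]) + 2
        raise ValidationError(f"efficacy table: Efficacy must lie strictly in (0, 1) (line {row})")
    dup = df.duplicated(subset=[idcol])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValidationError(f"efficacy table: duplicate patient record (line {row})")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def surface_to_csv(surface, path: str | Path) -> None:
    """Posterior surface as CSV: statistic rows by dose columns, one block per cycle."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    surface.table.to_csv(path)
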