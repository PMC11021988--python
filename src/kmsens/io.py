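"""CSV readers/writers for IPD tables and digitized curve inputs.

All files are UTF-8, comma-separated, decimal point, LF line endings.
Malformed files raise ``ValueError`` rather than being silently coerced.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .survival_core import IPD_COLUMNS, validate_ipd


def read_ipd_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in IPD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[list(IPD_COLUMNS)]
    validate_ipd(df)
    return df


def write_ipd_csv(df: pd.DataFrame, path: str | Path) -> None:
    validate_ipd(df)
    df.to_csv(path, index=False, lineterminator="\n")


def read_curve_csv(path: str | Path) -> np.ndarray:
    """Read digitized KM coordinates (columns time_days, survival) -> (N,2)."""
    df = pd.read_csv(path)
    for col in ("time_days", "survival"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df[["time_days", "survival"]].to_numpy(dtype=float)


def write_curve_csv(coords: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(coords, float), columns=["time_days", "survival"]).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_risk_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a number-at-risk table (columns time_days, n_at_risk)."""
    df = pd.read_csv(path)
    for col in ("time_days", "n_at_risk"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df["time_days"].to_numpy(dtype=float), df["n_at_risk"].to_numpy(dtype=int)


def write_risk_csv(times: np.ndarray, n_at_risk: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"time_days": times, "n_at_risk": n_at_risk}).to_csv(
        path, index=False, lineterminator="\n"
    )
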