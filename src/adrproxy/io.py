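"""CSV input readers with schema validation, and cohort writers.

Three comma-separated, UTF-8, headered dialects:

* ``dispensing.csv``: patient_id, atc_code, dispense_date (ISO 8601),
  units_dispensed, daily_number
* ``followup.csv``: patient_id, entry_date, exit_date, exit_reason
  (END_OF_STUDY | MOVED_OUT | DEATH)
* ``gp_events.csv``: patient_id, event_date, adjudication_code, adr_term
  (optional column)

Load errors name the file and the offending data row (1-based, excluding the
header).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import pandas as pd

from .adjudication import AdjudicationCode
from .episodes import ExitReason
from .errors import DataIntegrityError, LoadError

__all__ = [
    "read_dispensing",
    "read_follow_up",
    "read_gp_events",
    "read_inputs",
    "write_cohort",
]

_DISPENSING_COLS = ["patient_id", "atc_code", "dispense_date", "units_dispensed", "daily_number"]
_FOLLOWUP_COLS = ["patient_id", "entry_date", "exit_date", "exit_reason"]
_EVENT_COLS = ["patient_id", "event_date", "adjudication_code"]


def _load(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LoadError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    return df


def _parse_dates(df: pd.DataFrame, col: str, path: Path) -> None:
    parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df[col].notna()
    if bad.any() or df[col].isna().any():
        row = int((bad | df[col].isna()).idxmax()) + 1
        raise LoadError(f"{path}: row {row}: unparseable {col} {df[col].iloc[row - 1]!r}")
    df[col] = parsed


def read_dispensing(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _load(path, _DISPENSING_COLS)
    _parse_dates(df, "dispense_date", path)
    for col in ("units_dispensed", "daily_number"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise LoadError(
                f"{path}: row {row}: {col} must be a positive number, got {df[col].iloc[row - 1]!r}"
            )
        df[col] = vals.astype(float)
    empty = df["atc_code"].isna() | (df["atc_code"].astype(str).str.len() == 0)
    if empty.any():
        raise LoadError(f"{path}: row {int(empty.idxmax()) + 1}: empty atc_code")
    return df[_DISPENSING_COLS]


def read_follow_up(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _load(path, _FOLLOWUP_COLS)
    _parse_dates(df, "entry_date", path)
    _parse_dates(df, "exit_date", path)
    valid = {r.value for r in ExitReason}
    bad = ~df["exit_reason"].astype(str).isin(valid)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise LoadError(
            f"{path}: row {row}: exit_reason must be one of {sorted(valid)}, "
            f"got {df['exit_reason'].iloc[row - 1]!r}"
        )
    bad = df["entry_date"] >= df["exit_date"]
    if bad.any():
        raise LoadError(f"{path}: row {int(bad.idxmax()) + 1}: entry_date >= exit_date")
    return df[_FOLLOWUP_COLS]


def read_gp_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _load(path, _EVENT_COLS)
    _parse_dates(df, "event_date", path)
    valid = {c.value for c in AdjudicationCode}
    bad = ~df["adjudication_code"].astype(str).isin(valid)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise LoadError(
            f"{path}: row {row}: adjudication_code must be one of {sorted(valid)}, "
            f"got {df['adjudication_code'].iloc[row - 1]!r}"
        )
    if "adr_term" not in df.columns:
        df["adr_term"] = None
    return df[_EVENT_COLS + ["adr_term"]]


def read_inputs(
    dispensing_path: str | Path,
    followup_path: str | Path,
    events_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the three inputs.

    Every dispensing and GP-event patient must have a follow-up record, and
    all dates must fall inside the patient's follow-up interval.
    """
    disp = read_dispensing(dispensing_path)
    fu = read_follow_up(followup_path)
    events = (
        read_gp_events(events_path)
        if events_path is not None
        else pd.DataFrame(columns=_EVENT_COLS + ["adr_term"])
    )
    known = set(fu["patient_id"])
    for name, df, datecol in (
        ("dispensing", disp, "dispense_date"),
        ("gp_events", events, "event_date"),
    ):
        if df.empty:
            continue
        orphans = set(df["patient_id"]) - known
        if orphans:
            raise DataIntegrityError(
                f"{name}: patients with no follow-up record: {sorted(orphans)[:5]}"
            )
        merged = df.merge(fu, on="patient_id", how="left")
        out = (merged[datecol] < merged["entry_date"]) | (
            merged[datecol] > merged["exit_date"]
        )
        if out.any():
            pid = merged.loc[out.idxmax(), "patient_id"]
            raise DataIntegrityError(
                f"{name}: {datecol} outside follow-up for patient {pid!r}"
            )
    return disp, fu, events


def _iso_dates(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    return out


def write_cohort(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a :class:`~adrproxy.simulate.SyntheticCohort` as the three input
    CSVs plus ``ground_truth.csv``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("dispensing", cohort.dispensing),
        ("followup", cohort.follow_up),
        ("gp_events", cohort.gp_events),
        ("ground_truth", cohort.ground_truth),
    ):
        p = out / f"{name}.csv"
        _iso_dates(df).to_csv(p, index=False)
        paths[name] = p
    return paths
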