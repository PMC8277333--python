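"""Reading, writing and validation of weight-record streams and derived tables.

The interchange format is CSV (no standard exists for consumer smart-scale
exports).  A record stream has columns ``user_id, timestamp, weight_kg`` with
ISO-8601 timestamps carrying a UTC offset; a profile table has
``user_id, age, height_m, sex, timezone`` with an IANA timezone name per user.

Internally timestamps are held timezone-aware in UTC; "day" always means the
calendar date in the user's own timezone (the morning/evening split and the
day-difference rules are only meaningful in local time), and
:func:`attach_local_time` materialises that local view.
"""

from __future__ import annotations

import logging
from pathlib import Path
from zoneinfo import ZoneInfo

import pandas as pd

logger = logging.getLogger("selfweigh")

RECORD_COLUMNS = ["user_id", "timestamp", "weight_kg"]
PROFILE_COLUMNS = ["user_id", "age", "height_m", "sex", "timezone"]
CLEANED_COLUMNS = ["user_id", "local_date", "weight_kg", "timestamp"]
LEDGER_COLUMNS = ["record_id", "user_id", "timestamp", "weight_kg", "reason"]
STATUS_COLUMNS = ["user_id", "status", "reason"]

#: reason codes a removed record may carry (exactly one each)
REMOVAL_REASONS = ("below_floor", "mad_outlier", "vote_outlier", "intraday_duplicate")


class RecordParseError(ValueError):
    """A row in an input CSV could not be parsed; carries the 1-based line number."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordParseError(f"{path}: missing required column(s) {missing}")


def read_profiles(path) -> pd.DataFrame:
    """Read and validate a user-profile table."""
    profiles = pd.read_csv(path, dtype={"user_id": str})
    _require_columns(profiles, PROFILE_COLUMNS, path)
    dup = profiles["user_id"][profiles["user_id"].duplicated()]
    if len(dup):
        raise RecordParseError(f"{path}: duplicate profile rows for user_id(s) {sorted(set(dup))}")
    for tz in profiles["timezone"].dropna().unique():
        try:
            ZoneInfo(tz)
        except Exception as exc:  # noqa: BLE001 - any resolution failure is fatal
            raise RecordParseError(f"{path}: unresolvable timezone {tz!r}") from exc
    return profiles[PROFILE_COLUMNS].reset_index(drop=True)


def read_records(path, profiles_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a measurement stream plus its profile table.

    Returns ``(records, profiles)`` with records sorted by (user_id, timestamp)
    and byte-identical duplicate rows collapsed to one (logged).  Timestamps are
    converted to UTC; ``record_id`` is assigned after sorting.

    Raises :class:`RecordParseError` with a line number for unparseable rows and
    for users appearing in the stream without a profile row.
    """
    profiles = read_profiles(profiles_path)
    raw = pd.read_csv(path, dtype={"user_id": str, "timestamp": str})
    _require_columns(raw, RECORD_COLUMNS, path)
    n_raw = len(raw)

    ts = pd.to_datetime(raw["timestamp"], utc=True, format="ISO8601", errors="coerce")
    bad = ts.isna() & raw["timestamp"].notna() | raw["timestamp"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in raw.index[bad][:10]]  # +2: header + 1-based
        raise RecordParseError(f"{path}: unparseable timestamp at line(s) {lines}")
    weight = pd.to_numeric(raw["weight_kg"], errors="coerce")
    bad = weight.isna() | (weight <= 0)
    if bad.any():
        lines = [int(i) + 2 for i in raw.index[bad][:10]]
        raise RecordParseError(f"{path}: missing/non-positive weight at line(s) {lines}")

    records = pd.DataFrame({"user_id": raw["user_id"], "timestamp": ts, "weight_kg": weight})
    unknown = sorted(set(records["user_id"]) - set(profiles["user_id"]))
    if unknown:
        raise RecordParseError(f"{path}: stream contains user_id(s) with no profile: {unknown}")

    records = records.drop_duplicates(subset=RECORD_COLUMNS, keep="first")
    n_dupes = n_raw - len(records)
    if n_dupes:
        logger.info("read_records: collapsed %d exact-duplicate row(s)", n_dupes)
    records = records.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    records.insert(0, "record_id", records.index.to_numpy())
    logger.info("read_records: %d records for %d users", len(records), records["user_id"].nunique())
    return records, profiles


def attach_local_time(records: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Add ``local_dt`` (naive, user-local) and ``local_date`` columns."""
    out = records.copy()
    tz_of = profiles.set_index("user_id")["timezone"].to_dict()
    local = pd.Series(pd.NaT, index=out.index, dtype="datetime64[ns]")
    for uid, idx in out.groupby("user_id", sort=False).groups.items():
        tz = tz_of.get(uid)
        local.loc[idx] = out.loc[idx, "timestamp"].dt.tz_convert(ZoneInfo(tz)).dt.tz_localize(None)
    out["local_dt"] = local
    out["local_date"] = local.dt.normalize()
    return out


def _format_local_iso(records: pd.DataFrame, profiles: pd.DataFrame) -> pd.Series:
    tz_of = profiles.set_index("user_id")["timezone"].to_dict()
    out = pd.Series("", index=records.index, dtype=object)
    for uid, idx in records.groupby("user_id", sort=False).groups.items():
        conv = records.loc[idx, "timestamp"].dt.tz_convert(ZoneInfo(tz_of[uid]))
        out.loc[idx] = conv.map(lambda t: t.isoformat())
    return out


def write_records(path, records: pd.DataFrame, profiles: pd.DataFrame) -> None:
    """Write a record stream as CSV, timestamps in each user's local time with offset."""
    out = pd.DataFrame(
        {
            "user_id": records["user_id"],
            "timestamp": _format_local_iso(records, profiles),
            "weight_kg": records["weight_kg"].map(lambda w: f"{w:.3f}"),
        }
    )
    out.to_csv(path, index=False)


def write_profiles(path, profiles: pd.DataFrame) -> None:
    profiles[PROFILE_COLUMNS].to_csv(path, index=False)


def write_clean(out_dir, result, profiles: pd.DataFrame) -> None:
    """Write cleaned.csv, ledger.csv and exclusions.csv for a CleaningResult."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cleaned = result.cleaned.copy()
    cleaned["timestamp"] = _format_local_iso(cleaned, profiles)
    cleaned["local_date"] = cleaned["local_date"].dt.strftime("%Y-%m-%d")
    cleaned[CLEANED_COLUMNS].to_csv(out_dir / "cleaned.csv", index=False)
    ledger = result.ledger.copy()
    if len(ledger):
        ledger["timestamp"] = _format_local_iso(ledger, profiles)
    ledger[LEDGER_COLUMNS].to_csv(out_dir / "ledger.csv", index=False)
    result.status[STATUS_COLUMNS].to_csv(out_dir / "exclusions.csv", index=False)
    logger.info(
        "write_clean: %d retained, %d removed, %d eligible users",
        len(cleaned),
        len(ledger),
        int((result.status["status"] == "eligible").sum()),
    )


def read_clean(path, profiles: pd.DataFrame) -> pd.DataFrame:
    """Read a cleaned daily-minimum series written by :func:`write_clean`."""
    df = pd.read_csv(path, dtype={"user_id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    df["local_date"] = pd.to_datetime(df["local_date"])
    return attach_local_time(df, profiles)


def write_metrics(path, metrics: pd.DataFrame) -> None:
    metrics.to_csv(path, index=False)


def write_pairs(path, pairs: pd.DataFrame) -> None:
    pairs.to_csv(path, index=False)


def write_breaks(path, breaks: pd.DataFrame) -> None:
    breaks.to_csv(path, index=False)
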