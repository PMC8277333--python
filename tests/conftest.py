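"""Shared builders for hand-crafted measurement streams and daily series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from selfweigh.io import attach_local_time


def profiles_for(user_ids, tz="UTC", age=40.0, height=1.75, sex="male"):
    return pd.DataFrame(
        {
            "user_id": list(user_ids),
            "age": age,
            "height_m": height,
            "sex": sex,
            "timezone": tz,
        }
    )


def stream(entries, user_id="u1", tz="UTC", profiles=None):
    """Build (records, profiles) from [(local iso timestamp, weight), ...].

    Entries may also be (user_id, ts, weight) triples for multi-user streams.
    Records come back sorted with record_id and local time attached.
    """
    rows = []
    for e in entries:
        if len(e) == 3:
            uid, ts, w = e
        else:
            uid, (ts, w) = user_id, e
        rows.append({"user_id": uid, "timestamp": ts, "weight_kg": float(w)})
    df = pd.DataFrame(rows)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.tz_localize(tz).dt.tz_convert("UTC")
    df = df.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "record_id", df.index.to_numpy())
    if profiles is None:
        profiles = profiles_for(sorted(df["user_id"].unique()), tz=tz)
    return attach_local_time(df, profiles), profiles


def daily_series(day_weight_pairs, user_id="u1", start="2020-01-01", hour=8):
    """Cleaned-style daily-minimum series from [(day_offset, weight), ...].

    ``hour`` may be a constant or a list per entry (to control morning/evening).
    """
    start = pd.Timestamp(start)
    hours = hour if isinstance(hour, (list, tuple)) else [hour] * len(day_weight_pairs)
    rows = []
    for (d, w), h in zip(day_weight_pairs, hours):
        dt = start + pd.Timedelta(days=int(d), hours=h)
        rows.append(
            {
                "user_id": user_id,
                "timestamp": dt.tz_localize("UTC"),
                "local_dt": dt,
                "local_date": dt.normalize(),
                "weight_kg": float(w),
            }
        )
    df = pd.DataFrame(rows)
    df.insert(0, "record_id", np.arange(len(df)))
    return df


@pytest.fixture
def small_cohort():
    """A deterministic 40-user synthetic cohort with contamination, for pipeline tests."""
    import dataclasses

    from selfweigh.synthetic import emulate_cohort_profile, generate_cohort

    cfg = dataclasses.replace(emulate_cohort_profile(1234), n_users=40)
    return generate_cohort(cfg)
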