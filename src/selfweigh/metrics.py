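"""Derived self-weighing and weight-change variables.

From each user's cleaned daily-minimum series the module derives the
study variables:

* follow-up time (days between first and last retained measurement);
* initial / final weight: mean retained daily minimum over the first /
  last 7 calendar days of follow-up; weight change in kg and in % of
  initial weight (negative = loss); the most negative running change
  from initial weight;
* BMI from initial weight and profile height, grouped as normal
  [18.5, 25), overweight [25, 30), obese [30, inf);
* self-weighing frequency: percentage of follow-up days with a
  measurement, and measurements per week.  Both use the *inclusive* day
  count (span + 1) as denominator so that a daily series scores 100%
  and exactly 7 per week;
* breaks: gaps of >=30 days between consecutive measurements, with the
  across-break weight change, and user-level means over all breaks;
* consecutive-measurement pairs: day gap, weight change per day (kg and
  as a fraction of the earlier weight), a frequency category from the
  intervening-day count, the morning/evening combination of the two
  timestamps (morning = local time in [05:00, 13:00)), and the weekday
  of the later measurement.  Pairs whose per-day fractional change
  exceeds 20% are flagged as excluded (kept in the table, dropped from
  models).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BMI_GROUPS",
    "FREQ_CATEGORIES",
    "bmi_group",
    "classify_time_of_day",
    "freq_category",
    "detect_breaks",
    "compute_pairs",
    "compute_user_metrics",
    "compute_metrics",
]

BMI_GROUPS = ("normal", "overweight", "obese")

#: frequency categories from the number of intervening days between two
#: consecutive measurements (0 intervening days = measured on consecutive dates)
FREQ_CATEGORIES = (
    "daily",            # 0 intervening days
    "every_other_day",  # 1
    "2-4_per_week",     # 2
    "1-2_per_week",     # 3-7
    "every_other_week", # 8-14
    "monthly",          # 15-29
    "less_than_monthly" # >= 30
)

BREAK_MIN_DAYS = 30
PAIR_EXCLUSION_FRAC = 0.20  # |change per day| as fraction of the earlier weight
_WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def bmi_group(bmi: float) -> str:
    """BMI category with half-open boundaries [18.5,25), [25,30), [30,inf)."""
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def classify_time_of_day(local_dt) -> str:
    """'morning' iff the local wall-clock time is in [05:00, 13:00)."""
    h = local_dt.hour
    return "morning" if 5 <= h < 13 else "evening"


def freq_category(intervening_days: int) -> str:
    if intervening_days < 0:
        raise ValueError("intervening_days must be >= 0")
    if intervening_days == 0:
        return "daily"
    if intervening_days == 1:
        return "every_other_day"
    if intervening_days == 2:
        return "2-4_per_week"
    if intervening_days <= 7:
        return "1-2_per_week"
    if intervening_days <= 14:
        return "every_other_week"
    if intervening_days <= 29:
        return "monthly"
    return "less_than_monthly"


def _user_sorted(series: pd.DataFrame) -> pd.DataFrame:
    return series.sort_values("local_date", kind="mergesort")


def detect_breaks(series: pd.DataFrame) -> pd.DataFrame:
    """Breaks (gaps >= 30 days) in one or many users' daily-minimum series.

    Returns one row per break: start/end dates (the measurements flanking the
    gap), duration in days, and the across-break weight change in kg and %.
    """
    rows = []
    for uid, sub in series.groupby("user_id", sort=False):
        sub = _user_sorted(sub)
        dates = sub["local_date"].to_numpy()
        w = sub["weight_kg"].to_numpy()
        gaps = (dates[1:] - dates[:-1]).astype("timedelta64[D]").astype(int)
        for j in np.flatnonzero(gaps >= BREAK_MIN_DAYS):
            rows.append(
                {
                    "user_id": uid,
                    "start_date": dates[j],
                    "end_date": dates[j + 1],
                    "duration_days": int(gaps[j]),
                    "weight_before_kg": w[j],
                    "weight_after_kg": w[j + 1],
                    "weight_change_kg": w[j + 1] - w[j],
                    "weight_change_pct": 100.0 * (w[j + 1] - w[j]) / w[j],
                }
            )
    cols = ["user_id", "start_date", "end_date", "duration_days", "weight_before_kg",
            "weight_after_kg", "weight_change_kg", "weight_change_pct"]
    return pd.DataFrame(rows, columns=cols)


def compute_pairs(series: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-measurement pair observations for one or many users.

    ``series`` must carry ``local_dt`` timestamps of the retained daily
    minima (used for the morning/evening combination).  The ``excluded``
    flag marks pairs whose fractional change per day exceeds 20%; they are
    retained in the table but skipped by the temporal models.
    """
    df = series.sort_values(["user_id", "local_date"], kind="mergesort")
    same_user = df["user_id"].to_numpy()[1:] == df["user_id"].to_numpy()[:-1]

    dates = df["local_date"].to_numpy()
    w = df["weight_kg"].to_numpy()
    hours = df["local_dt"].dt.hour.to_numpy()
    tod = np.where((hours >= 5) & (hours < 13), "morning", "evening")

    gap = (dates[1:] - dates[:-1]).astype("timedelta64[D]").astype(np.int64)[same_user]
    delta = (w[1:] - w[:-1])[same_user]
    per_day = delta / gap
    frac = delta / (gap * w[:-1][same_user])
    iv = gap - 1
    cats = np.select(
        [iv == 0, iv == 1, iv == 2, iv <= 7, iv <= 14, iv <= 29],
        FREQ_CATEGORIES[:-1],
        FREQ_CATEGORIES[-1],
    )
    later = dates[1:][same_user]
    weekday_idx = (later.astype("datetime64[D]").astype(np.int64) + 3) % 7  # epoch day 0 = Thu
    out = pd.DataFrame(
        {
            "user_id": df["user_id"].to_numpy()[1:][same_user],
            "date_prev": dates[:-1][same_user],
            "date": later,
            "gap_days": gap,
            "intervening_days": iv,
            "delta_kg": delta,
            "change_per_day_kg": per_day,
            "change_per_day_frac": frac,
            "freq_category": cats,
            "tod_combo": np.char.add(np.char.add(tod[:-1][same_user], "-"), tod[1:][same_user]),
            "weekday": np.array(_WEEKDAYS)[weekday_idx],
            "excluded": np.abs(frac) > PAIR_EXCLUSION_FRAC,
        }
    )
    return out.reset_index(drop=True)


def compute_user_metrics(series: pd.DataFrame, profile: pd.Series) -> dict:
    """All user-level derived variables for one user's daily-minimum series."""
    if len(series) == 0:
        raise ValueError("empty series: metrics are undefined")
    sub = _user_sorted(series)
    dates = sub["local_date"]
    w = sub["weight_kg"].to_numpy()
    first, last = dates.iloc[0], dates.iloc[-1]
    follow_up_days = int((last - first).days)
    incl_days = follow_up_days + 1

    initial = sub.loc[dates <= first + pd.Timedelta(days=6), "weight_kg"].mean()
    final = sub.loc[dates >= last - pd.Timedelta(days=6), "weight_kg"].mean()
    change = final - initial

    height = float(profile["height_m"])
    bmi = initial / height**2

    breaks = detect_breaks(sub.assign(user_id=sub["user_id"]))
    n_breaks = len(breaks)

    return {
        "user_id": sub["user_id"].iloc[0],
        "follow_up_days": follow_up_days,
        "n_measurements": int(len(sub)),
        "measuring_days": int(dates.nunique()),
        "pct_days_measured": 100.0 * dates.nunique() / incl_days,
        "per_week": len(sub) / (incl_days / 7.0),
        "initial_weight_kg": initial,
        "final_weight_kg": final,
        "weight_change_kg": change,
        "weight_change_pct": 100.0 * change / initial,
        "max_weight_change_kg": float(np.min(w) - initial),
        "bmi": bmi,
        "bmi_group": bmi_group(bmi),
        "n_breaks": n_breaks,
        "mean_break_days": breaks["duration_days"].mean() if n_breaks else np.nan,
        "mean_break_gain_kg": breaks["weight_change_kg"].mean() if n_breaks else np.nan,
        "mean_break_gain_pct": breaks["weight_change_pct"].mean() if n_breaks else np.nan,
        "sex": profile.get("sex", "unknown"),
        "age": float(profile["age"]),
        "height_m": height,
    }


def compute_metrics(cleaned: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """User-level metrics table, one row per user present in ``cleaned``."""
    prof = profiles.set_index("user_id")
    rows = [
        compute_user_metrics(sub, prof.loc[uid])
        for uid, sub in cleaned.groupby("user_id", sort=False)
    ]
    return pd.DataFrame(rows)
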