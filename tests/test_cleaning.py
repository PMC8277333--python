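"""Cleaning-stage contracts, checked against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from selfweigh.cleaning import (
    CleaningConfig,
    EligibilityConfig,
    _vote_screen_user,
    apply_exclusions,
    apply_floor,
    clean_cohort,
    daily_minimum,
    mad_screen,
    vote_screen,
    vote_threshold,
)
from selfweigh.io import attach_local_time

from conftest import daily_series, profiles_for, stream

# ---------------------------------------------------------------- oracles


def mad_oracle(weights, window=30, threshold=4.0):
    """Brute-force robust-z flags: centred window truncated at the edges."""
    n = len(weights)
    if n < 2:
        return [False] * n
    win = min(window, n)
    flags = []
    for i in range(n):
        lo = min(max(0, i - win // 2), n - win)
        view = [weights[j] for j in range(lo, lo + win)]
        med = float(np.median(view))
        mad = float(np.median([abs(v - med) for v in view]))
        dev = abs(weights[i] - med)
        if mad > 0:
            flags.append(dev / (1.4826 * mad) > threshold)
        elif dev > 0 and len(set(view)) >= 3:
            sd = float(np.std(view))
            flags.append(sd > 0 and dev / sd > threshold)
        else:
            flags.append(False)
    return flags


def vote_oracle(weights, days, base=0.03, per_day=0.001, req=3, span=2):
    """Re-evaluating reference for the vote screen; returns removal positions in order."""
    alive = list(range(len(weights)))
    removed = []
    while True:
        scored = []
        for pos, i in enumerate(alive):
            nbrs = alive[max(0, pos - span):pos] + alive[pos + 1:pos + 1 + span]
            votes, s = 0, []
            for j in nbrs:
                diff = abs(weights[i] - weights[j])
                if diff / weights[j] > base + per_day * abs(days[i] - days[j]):
                    votes += 1
                s.append(diff)
            if votes >= req:
                scored.append((votes, round(math.fsum(s), 9), i))
        if not scored:
            return removed
        scored.sort()
        best = scored[-1][2]
        removed.append(best)
        alive.remove(best)


# ---------------------------------------------------------------- floor


def test_floor_removes_only_sub30():
    records, _ = stream([("2020-01-01T08:00", 80), ("2020-01-02T08:00", 25), ("2020-01-03T08:00", 81)])
    kept, led = apply_floor(records)
    assert list(kept["weight_kg"]) == [80, 81]
    assert list(led["weight_kg"]) == [25]
    assert set(led["reason"]) == {"below_floor"}


def test_floor_boundary_thirty_retained():
    records, _ = stream([("2020-01-01T08:00", 30.0), ("2020-01-02T08:00", 80.0)])
    kept, led = apply_floor(records)
    assert len(led) == 0 and len(kept) == 2


# ---------------------------------------------------------------- MAD screen


def test_constant_series_survives_mad():
    records, _ = stream([(f"2020-01-{d:02d}T08:00", 80.0) for d in range(1, 21)])
    kept, led = mad_screen(records)
    assert len(led) == 0 and len(kept) == 20


def test_mad_removes_single_gross_outlier():
    rng = np.random.default_rng(0)
    weights = list(80 + rng.uniform(-0.3, 0.3, 40))
    weights[17] = 120.0
    records, _ = stream(
        [(str(pd.Timestamp("2020-01-01T08:00") + pd.Timedelta(days=i)), w) for i, w in enumerate(weights)]
    )
    kept, led = mad_screen(records)
    assert list(led["weight_kg"]) == [120.0]
    assert mad_oracle(weights)[17] and sum(mad_oracle(weights)) == 1


@pytest.mark.parametrize("n", [5, 10, 25])
def test_mad_truncated_window_matches_oracle(n):
    rng = np.random.default_rng(n)
    weights = list(np.round(80 + rng.normal(0, 0.5, n), 2))
    weights[n // 2] += 15.0
    records, _ = stream(
        [(str(pd.Timestamp("2020-01-01T08:00") + pd.Timedelta(days=i)), w) for i, w in enumerate(weights)]
    )
    kept, led = mad_screen(records)
    expected = [w for w, f in zip(weights, mad_oracle(weights)) if f]
    assert sorted(led["weight_kg"]) == sorted(expected)


def test_mad_zero_spread_falls_back_to_sd():
    weights = [80.0] * 20 + [81.0, 120.0]
    records, _ = stream(
        [(str(pd.Timestamp("2020-01-01T08:00") + pd.Timedelta(days=i)), w) for i, w in enumerate(weights)]
    )
    kept, led = mad_screen(records)
    assert list(led["weight_kg"]) == [120.0]


# ---------------------------------------------------------------- vote screen


@pytest.mark.parametrize("gap,expected", [(0, 0.030), (1, 0.031), (10, 0.040)])
def test_vote_threshold_formula(gap, expected):
    assert vote_threshold(gap) == pytest.approx(expected)


def test_vote_threshold_rejects_negative_gap():
    with pytest.raises(ValueError):
        vote_threshold(-1)


def test_monotone_drift_survives_vote_screen():
    """0.1 kg/day drift never exceeds 3% + 0.1%/day between near neighbours."""
    entries = [
        (str(pd.Timestamp("2020-01-01T08:00") + pd.Timedelta(days=i)), 80 + 0.1 * i) for i in range(30)
    ]
    records, _ = stream(entries)
    kept, led = vote_screen(records)
    assert len(led) == 0


def test_vote_screen_hand_example():
    """80, 80.1, 95, 80.2, 80.1 on consecutive days: the 95 gets 4 votes and goes."""
    weights = [80.0, 80.1, 95.0, 80.2, 80.1]
    entries = [
        (str(pd.Timestamp("2020-01-01T08:00") + pd.Timedelta(days=i)), w) for i, w in enumerate(weights)
    ]
    records, _ = stream(entries)
    kept, led = vote_screen(records)
    assert list(led["weight_kg"]) == [95.0]
    assert vote_oracle(weights, list(range(5))) == [2]


@given(
    weights=st.lists(st.integers(3000, 15000).map(lambda v: v / 100.0), min_size=1, max_size=12),
    gaps=st.lists(st.integers(0, 4), min_size=11, max_size=11),
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_vote_screen_matches_reevaluating_oracle(weights, gaps):
    """Removal set AND order match a brute-force oracle for any short series."""
    days = np.concatenate([[0], np.cumsum(gaps)])[: len(weights)]
    got = _vote_screen_user(np.array(weights), days.astype(np.int64), CleaningConfig())
    assert got == vote_oracle(weights, list(days))


# ---------------------------------------------------------------- daily minimum


def test_daily_minimum_keeps_lowest_of_day():
    records, _ = stream([("2020-01-01T07:30", 81.2), ("2020-01-01T22:10", 80.4)])
    kept, led = daily_minimum(records)
    assert list(kept["weight_kg"]) == [80.4]
    assert kept["local_dt"].iloc[0].hour == 22
    assert set(led["reason"]) == {"intraday_duplicate"}


def test_daily_minimum_single_measurement_untouched():
    records, _ = stream([("2020-01-01T08:00", 80.0), ("2020-01-02T08:00", 80.5)])
    kept, led = daily_minimum(records)
    assert len(kept) == 2 and len(led) == 0


def test_daily_minimum_tie_keeps_earlier_timestamp():
    records, _ = stream([("2020-01-01T07:00", 80.0), ("2020-01-01T21:00", 80.0)])
    kept, _ = daily_minimum(records)
    assert kept["local_dt"].iloc[0].hour == 7


# ---------------------------------------------------------------- exclusions


def _daily_entries(n_days, weight=80.0, start="2020-01-01", step=1):
    t0 = pd.Timestamp(start + "T08:00")
    return [(str(t0 + pd.Timedelta(days=i * step)), weight) for i in range(n_days)]


def _status_for(entries, **profile_kw):
    records, prof = stream(entries)
    if profile_kw:
        prof = profiles_for(["u1"], **profile_kw)
    result = clean_cohort(records[["record_id", "user_id", "timestamp", "weight_kg"]], prof)
    return result.status.iloc[0]


def test_too_few_clean_observations_excluded():
    # 37 raw measurements but only 29 distinct days, spanning > 1 year
    entries = _daily_entries(29, step=14)
    extra = [(str(pd.Timestamp("2020-01-01T21:00") + pd.Timedelta(days=14 * i)), 80.6) for i in range(8)]
    status = _status_for(entries + extra)
    assert status["status"] == "excluded" and status["reason"] == "too_few_clean"


def test_short_height_excluded():
    status = _status_for(_daily_entries(40, step=10), height=1.39)
    assert status["reason"] == "height"


def test_age_out_of_range_excluded():
    status = _status_for(_daily_entries(40, step=10), age=101)
    assert status["reason"] == "age"


def test_low_first_week_bmi_excluded():
    status = _status_for(_daily_entries(40, weight=50.0, step=10), height=1.75)
    assert status["reason"] == "low_bmi"


def test_short_span_excluded():
    status = _status_for(_daily_entries(40, step=5))  # 195-day span
    assert status["reason"] == "too_short_span"


def test_removed_daily_minima_exclusion():
    """11 days whose original daily minimum is a sub-30 artifact: user excluded."""
    good = _daily_entries(40, step=10)
    artifacts = [(str(pd.Timestamp("2020-01-01T06:00") + pd.Timedelta(days=10 * i)), 20.0) for i in range(11)]
    status = _status_for(good + artifacts)
    assert status["reason"] == "minima_removed"
    # with one fewer tainted day the user stays in
    status = _status_for(good + artifacts[:10])
    assert status["status"] == "eligible"


def test_eligible_user_passes_all_gates():
    status = _status_for(_daily_entries(40, step=10))
    assert status["status"] == "eligible" and status["reason"] == ""


# ---------------------------------------------------------------- pipeline invariants


def test_pipeline_conservation_and_idempotence(small_cohort):
    records, profiles, _ = small_cohort
    result = clean_cohort(records, profiles)
    assert len(result.cleaned) + len(result.ledger) == len(records)
    ids = pd.concat([result.cleaned["record_id"], result.ledger["record_id"]])
    assert ids.is_unique and len(ids) == len(records)

    again = clean_cohort(result.cleaned[["record_id", "user_id", "timestamp", "weight_kg"]], profiles)
    assert len(again.ledger) == 0


def test_pipeline_order_insensitive(small_cohort):
    records, profiles, _ = small_cohort
    base = clean_cohort(records, profiles)
    shuffled = records.sample(frac=1, random_state=5).reset_index(drop=True).drop(columns=["record_id"])
    redo = clean_cohort(shuffled, profiles)
    a = base.cleaned.sort_values(["user_id", "timestamp"]).reset_index(drop=True)
    b = redo.cleaned.sort_values(["user_id", "timestamp"]).reset_index(drop=True)
    assert (a["timestamp"].to_numpy() == b["timestamp"].to_numpy()).all()
    assert a["weight_kg"].tolist() == b["weight_kg"].tolist()
    pd.testing.assert_frame_equal(base.status, redo.status)
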