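"""Outlier cleaning and eligibility filtering for self-weighing streams.

Free-living smart-scale data are contaminated by impossible readings, other
household members using the scale, and carried objects.  The pipeline removes
them in a fixed order:

1. **Floor** — every measurement strictly below 30 kg is removed.
2. **Rolling-MAD screen** — a measurement is removed when its robust z-score,
   |w - rolling median| / (1.4826 x rolling MAD) over a centred 30-sample
   window (truncated at the series edges), exceeds 4.
3. **Vote screen** — an iterative unrealistic-change filter: each of up to 4
   temporal neighbours (2 preceding, 2 succeeding) votes against a
   measurement when the relative difference from that neighbour exceeds
   3% + 0.1% per day of calendar-date gap; measurements with >=3 votes are
   removed one at a time (most votes first, ties by largest summed absolute
   difference, then by later timestamp) and votes are recomputed after every
   removal until none remain.
4. **Daily minima** — one record per local calendar day, the day's minimum
   surviving weight, to suppress diurnal variation and clothing effects.
5. **Eligibility** — users are excluded for implausible profile data, short
   span, too few measurements, first-week BMI < 18.5, more than 10 of their
   original daily minima removed by the outlier screens, or fewer than 30
   clean observations.

The four record-level stages are cycled in that order until a full cycle
removes nothing, so cleaning is idempotent: re-running the pipeline on its
own output removes nothing further.  Every removed record lands in a ledger
with exactly one reason code, so retained + ledger always reconstructs the
input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import attach_local_time, logger

__all__ = [
    "CleaningConfig",
    "EligibilityConfig",
    "CleaningResult",
    "apply_floor",
    "mad_screen",
    "vote_threshold",
    "vote_screen",
    "daily_minimum",
    "apply_exclusions",
    "clean_cohort",
]

_MAD_SCALE = 1.4826  # consistency constant for normally distributed data

#: user-level exclusion reason codes, in precedence order
EXCLUSION_REASONS = (
    "missing_profile",
    "too_short_span",
    "too_few_raw",
    "age",
    "height",
    "low_bmi",
    "minima_removed",
    "too_few_clean",
)


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds of the record-level screens (defaults are the published rules)."""

    floor_kg: float = 30.0
    mad_window: int = 30          # samples, centred
    mad_threshold: float = 4.0    # robust-z units
    vote_base: float = 0.03       # relative change allowed at zero day gap
    vote_per_day: float = 0.001   # extra allowance per day of gap
    votes_required: int = 3
    neighbor_span: int = 2        # preceding and succeeding neighbours each

    def validate(self) -> None:
        if min(self.floor_kg, self.mad_window, self.mad_threshold, self.vote_base,
               self.vote_per_day, self.votes_required, self.neighbor_span) <= 0:
            raise ValueError("all cleaning thresholds must be > 0")
        if self.votes_required > 2 * self.neighbor_span:
            raise ValueError("votes_required exceeds the number of available neighbours")


@dataclass(frozen=True)
class EligibilityConfig:
    """User-level inclusion rules (defaults are the published criteria)."""

    age_range: tuple[float, float] = (18.0, 100.0)
    height_range: tuple[float, float] = (1.40, 2.10)
    min_bmi: float = 18.5                 # kg/m^2, from first-week mean weight
    min_raw_measurements: int = 30
    min_clean_observations: int = 30
    max_removed_daily_minima: int = 10    # exclusion when *more than* this many
    min_span_days: int = 365

    def validate(self) -> None:
        if self.age_range[0] >= self.age_range[1] or self.height_range[0] >= self.height_range[1]:
            raise ValueError("eligibility ranges must be increasing pairs")
        if min(self.min_raw_measurements, self.min_clean_observations, self.min_span_days) <= 0:
            raise ValueError("eligibility counts must be positive")


@dataclass
class CleaningResult:
    """Cleaned daily-minimum series, removal ledger and per-user status."""

    cleaned: pd.DataFrame  # record_id, user_id, timestamp, local_dt, local_date, weight_kg
    ledger: pd.DataFrame   # record_id, user_id, timestamp, weight_kg, reason
    status: pd.DataFrame   # user_id, status {eligible, excluded}, reason

    def eligible_users(self) -> pd.Index:
        return pd.Index(self.status.loc[self.status["status"] == "eligible", "user_id"])

    def eligible_cleaned(self) -> pd.DataFrame:
        return self.cleaned[self.cleaned["user_id"].isin(self.eligible_users())].reset_index(drop=True)


def _split(records: pd.DataFrame, remove_mask: np.ndarray, reason: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    removed = records.loc[remove_mask, ["record_id", "user_id", "timestamp", "weight_kg"]].copy()
    removed["reason"] = reason
    return records.loc[~remove_mask].copy(), removed


def apply_floor(records: pd.DataFrame, config: CleaningConfig = CleaningConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove measurements strictly below the floor (default 30 kg)."""
    mask = records["weight_kg"].to_numpy() < config.floor_kg
    return _split(records, mask, "below_floor")


def _mad_flags(w: np.ndarray, window: int, threshold: float) -> np.ndarray:
    """Robust-z outlier flags for one time-sorted weight series."""
    n = len(w)
    if n < 2:
        return np.zeros(n, dtype=bool)
    win = min(window, n)
    views = sliding_window_view(w, win)                      # (n - win + 1, win)
    med = np.median(views, axis=1)
    mad = np.median(np.abs(views - med[:, None]), axis=1)
    idx = np.clip(np.arange(n) - win // 2, 0, n - win)       # centred, truncated at edges
    dev = np.abs(w - med[idx])
    flags = np.zeros(n, dtype=bool)
    pos = mad[idx] > 0
    flags[pos] = dev[pos] / (_MAD_SCALE * mad[idx][pos]) > threshold
    # zero-MAD fallback: only meaningful when the window is not essentially constant
    for i in np.flatnonzero(~pos & (dev > 0)):
        view = views[idx[i]]
        if len(np.unique(view)) >= 3:
            sd = view.std()
            if sd > 0 and dev[i] / sd > threshold:
                flags[i] = True
    return flags


def mad_screen(records: pd.DataFrame, config: CleaningConfig = CleaningConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass rolling-MAD screen, per user, over time-sorted measurements."""
    mask = np.zeros(len(records), dtype=bool)
    pos_of = {lbl: i for i, lbl in enumerate(records.index)}
    for _, idx in records.groupby("user_id", sort=False).groups.items():
        w = records.loc[idx, "weight_kg"].to_numpy()
        flags = _mad_flags(w, config.mad_window, config.mad_threshold)
        mask[[pos_of[l] for l in idx]] = flags
    return _split(records, mask, "mad_outlier")


def vote_threshold(gap_days: int, config: CleaningConfig = CleaningConfig()) -> float:
    """Allowed relative weight change for a pair of measurements ``gap_days`` apart."""
    if gap_days < 0:
        raise ValueError(f"gap_days must be >= 0, got {gap_days}")
    return config.vote_base + config.vote_per_day * gap_days


def _vote_screen_user(w: np.ndarray, day: np.ndarray, config: CleaningConfig) -> list[int]:
    """Positions removed by the iterative vote screen, in removal order.

    ``w``: weights in chronological order; ``day``: local calendar-date ordinals.
    Each surviving measurement i is compared with up to ``neighbor_span``
    preceding and succeeding survivors j; j votes against i iff
    |w_i - w_j| / w_j > vote_threshold(|day_i - day_j|).
    """
    alive = np.arange(len(w))
    removed: list[int] = []
    span, req = config.neighbor_span, config.votes_required
    while True:
        m = len(alive)
        if m < req + 1:
            break
        wa, da = w[alive], day[alive]
        votes = np.zeros(m, dtype=np.int64)
        sabs = np.zeros(m)
        for k in range(1, span + 1):
            diff = np.abs(wa[k:] - wa[:-k])
            thr = config.vote_base + config.vote_per_day * (da[k:] - da[:-k])
            votes[k:] += diff / wa[:-k] > thr   # earlier neighbour votes against later point
            votes[:-k] += diff / wa[k:] > thr   # later neighbour votes against earlier point
            sabs[k:] += diff
            sabs[:-k] += diff
        cand = np.flatnonzero(votes >= req)
        if len(cand) == 0:
            break
        # most votes, then largest summed |diff| (rounded so the tie-break does
        # not depend on float summation order), then the later timestamp
        best = cand[np.lexsort((cand, np.round(sabs[cand], 9), votes[cand]))[-1]]
        removed.append(int(alive[best]))
        alive = np.delete(alive, best)
    return removed


def vote_screen(records: pd.DataFrame, config: CleaningConfig = CleaningConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iterative neighbour-vote screen for unrealistic weight changes."""
    mask = np.zeros(len(records), dtype=bool)
    pos_of = {lbl: i for i, lbl in enumerate(records.index)}
    for _, idx in records.groupby("user_id", sort=False).groups.items():
        sub = records.loc[idx]
        w = sub["weight_kg"].to_numpy()
        day = sub["local_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
        for p in _vote_screen_user(w, day, config):
            mask[pos_of[idx[p]]] = True
    return _split(records, mask, "vote_outlier")


def daily_minimum(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep one record per user and local calendar day: the day's minimum weight.

    Equal minima on the same day keep the earlier timestamp; the retained
    record keeps the timestamp of the minimum measurement.
    """
    order = records.sort_values(["user_id", "local_date", "weight_kg", "timestamp"], kind="mergesort")
    keep_labels = order.drop_duplicates(subset=["user_id", "local_date"], keep="first").index
    mask = ~records.index.isin(keep_labels)
    kept, removed = _split(records, mask.to_numpy() if hasattr(mask, "to_numpy") else mask, "intraday_duplicate")
    return kept, removed


def _original_daily_min_ids(raw: pd.DataFrame) -> pd.Series:
    """record_id of each user-day's minimum weight before any processing."""
    order = raw.sort_values(["user_id", "local_date", "weight_kg", "timestamp"], kind="mergesort")
    firsts = order.drop_duplicates(subset=["user_id", "local_date"], keep="first")
    return firsts.set_index("record_id")["user_id"]


def apply_exclusions(
    daily: pd.DataFrame,
    raw: pd.DataFrame,
    profiles: pd.DataFrame,
    outlier_removed_ids: set[int],
    config: EligibilityConfig = EligibilityConfig(),
) -> pd.DataFrame:
    """Per-user eligibility status with exactly one exclusion reason.

    ``daily`` is the cleaned daily-minimum series, ``raw`` the exact-duplicate
    collapsed input (both with local dates attached), ``outlier_removed_ids``
    the record_ids removed by the floor/MAD/vote screens.  First-week BMI uses
    the mean of the retained daily minima over the user's first 7 calendar
    days and the profile height.  Reasons are assigned in a fixed precedence
    order so the status is deterministic.
    """
    config.validate()
    prof = profiles.set_index("user_id")
    origin_min = _original_daily_min_ids(raw)
    removed_min_counts = origin_min[origin_min.index.isin(outlier_removed_ids)].value_counts()

    raw_counts = raw.groupby("user_id").size()
    raw_span = raw.groupby("user_id")["local_date"].agg(lambda d: (d.max() - d.min()).days)

    rows = []
    for uid in raw_counts.index:
        sub = daily[daily["user_id"] == uid]
        reason = None
        if uid not in prof.index or pd.isna(prof.loc[uid, "age"]) or pd.isna(prof.loc[uid, "height_m"]):
            reason = "missing_profile"
        elif raw_span[uid] < config.min_span_days:
            reason = "too_short_span"
        elif raw_counts[uid] < config.min_raw_measurements:
            reason = "too_few_raw"
        elif not config.age_range[0] <= prof.loc[uid, "age"] <= config.age_range[1]:
            reason = "age"
        elif not config.height_range[0] <= prof.loc[uid, "height_m"] <= config.height_range[1]:
            reason = "height"
        elif len(sub) == 0:
            reason = "too_few_clean"
        else:
            first = sub["local_date"].min()
            week = sub[sub["local_date"] <= first + pd.Timedelta(days=6)]
            bmi = week["weight_kg"].mean() / float(prof.loc[uid, "height_m"]) ** 2
            if bmi < config.min_bmi:
                reason = "low_bmi"
            elif int(removed_min_counts.get(uid, 0)) > config.max_removed_daily_minima:
                reason = "minima_removed"
            elif len(sub) < config.min_clean_observations:
                reason = "too_few_clean"
        rows.append(
            {"user_id": uid, "status": "eligible" if reason is None else "excluded", "reason": reason or ""}
        )
    return pd.DataFrame(rows, columns=["user_id", "status", "reason"])


def clean_cohort(
    records: pd.DataFrame,
    profiles: pd.DataFrame,
    cleaning: CleaningConfig = CleaningConfig(),
    eligibility: EligibilityConfig = EligibilityConfig(),
) -> CleaningResult:
    """Run the full pipeline: floor -> MAD -> vote -> daily minima -> exclusions.

    The four record-level stages are cycled, in that fixed order, until a full
    cycle removes nothing.  Dropping intraday duplicates tightens the local
    dispersion the screens see, so a screen that passed on the raw stream can
    flag again on the daily-minimum series; iterating to the fixed point makes
    the pipeline idempotent — re-cleaning its own output removes nothing.

    Input rows are re-sorted internally, so shuffled input yields identical
    output; retained + ledger rows always equal the input rows.
    """
    cleaning.validate()
    eligibility.validate()
    recs = records.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    if "record_id" not in recs.columns:
        recs.insert(0, "record_id", recs.index.to_numpy())
    recs = attach_local_time(recs, profiles)

    kept = recs
    ledgers = []
    cycle = 0
    while True:
        cycle += 1
        n_before = len(kept)
        kept, led_floor = apply_floor(kept, cleaning)
        kept, led_mad = mad_screen(kept, cleaning)
        kept, led_vote = vote_screen(kept, cleaning)
        kept, led_daily = daily_minimum(kept)
        ledgers.extend([led_floor, led_mad, led_vote, led_daily])
        logger.info(
            "cleaning cycle %d: floor %d, MAD %d, vote %d, intraday %d (retained %d)",
            cycle, len(led_floor), len(led_mad), len(led_vote), len(led_daily), len(kept),
        )
        if len(kept) == n_before:
            break

    ledger = pd.concat(ledgers, ignore_index=True)
    outlier_ids = set(ledger.loc[ledger["reason"] != "intraday_duplicate", "record_id"])
    status = apply_exclusions(kept, recs, profiles, outlier_ids, eligibility)
    logger.info(
        "cleaning: %d of %d users eligible",
        int((status["status"] == "eligible").sum()),
        len(status),
    )
    cleaned = kept[["record_id", "user_id", "timestamp", "local_dt", "local_date", "weight_kg"]].reset_index(drop=True)
    assert len(cleaned) + len(ledger) == len(recs), "conservation violated"
    return CleaningResult(cleaned=cleaned, ledger=ledger, status=status)
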