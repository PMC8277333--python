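"""End-to-end convenience: records -> cleaning -> metrics -> pairs/breaks."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cleaning import CleaningConfig, CleaningResult, EligibilityConfig, clean_cohort
from .metrics import compute_metrics, compute_pairs, detect_breaks


@dataclass
class PipelineResult:
    cleaning: CleaningResult
    metrics: pd.DataFrame   # one row per eligible user
    pairs: pd.DataFrame     # consecutive-pair observations, eligible users
    breaks: pd.DataFrame    # one row per break, eligible users


def run_pipeline(
    records: pd.DataFrame,
    profiles: pd.DataFrame,
    cleaning: CleaningConfig = CleaningConfig(),
    eligibility: EligibilityConfig = EligibilityConfig(),
) -> PipelineResult:
    """Clean a cohort and derive all user-level and pair-level variables."""
    result = clean_cohort(records, profiles, cleaning, eligibility)
    eligible = result.eligible_cleaned()
    metrics = compute_metrics(eligible, profiles)
    pairs = compute_pairs(eligible)
    breaks = detect_breaks(eligible)
    return PipelineResult(cleaning=result, metrics=metrics, pairs=pairs, breaks=breaks)
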