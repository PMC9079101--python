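"""Post-stroke cognitive impairment (PSCI) classification and transitions.

PSCI is defined per assessment from norm-referenced percentiles: impairment
is performance below the 5th percentile in at least one cognitive domain.
Six domains are recognised (attention/executive, processing speed, language,
verbal memory, visuospatial perception/construction, visuospatial memory).
With a full neuropsychological battery, at least three assessed domains are
needed to *exclude* PSCI — fewer than three unimpaired domains yields an
indeterminate status. Cohorts with only a MoCA screen classify directly on
the MoCA percentile.

Transitions compare the sub-acute baseline (the earliest determinate
assessment before 90 days post-stroke) with later follow-up: recovery is
PSCI at baseline followed by no-PSCI later; decline is the reverse.
Indeterminate assessments never serve as transition endpoints.

Time strata use left-closed day bins: [0, 90) "<3 months", [90, 365)
"3-12 months", [365, 730) "12-24 months", [730, inf) ">24 months".

Prevalence percentages are integer percents truncated toward zero — the
convention fixed by the printed cohort fractions this package reproduces
(208/522 = 39.85% is reported as 39%).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DOMAIN_COLUMNS",
    "PSCI",
    "NO_PSCI",
    "INDETERMINATE",
    "INTERVAL_LABELS",
    "classify_psci",
    "classify_cohort",
    "classify_transition",
    "classify_transitions",
    "interval_stratify",
    "prevalence",
]

#: The six cognitive domains of the full neuropsychological battery.
DOMAIN_COLUMNS = [
    "attention_executive",
    "processing_speed",
    "language",
    "verbal_memory",
    "visuospatial_perception",
    "visuospatial_memory",
]

PSCI = "PSCI"
NO_PSCI = "no_PSCI"
INDETERMINATE = "indeterminate"

RECOVERY = "recovery"
DECLINE = "decline"
STABLE_PSCI = "stable_PSCI"
STABLE_NO_PSCI = "stable_no_PSCI"
NOT_EVALUABLE = "not_evaluable"

IMPAIRMENT_PERCENTILE = 5.0  # strict: percentile < 5 is impaired
MIN_DOMAINS_TO_EXCLUDE = 3
BASELINE_WINDOW_DAYS = 90

INTERVAL_LABELS = ["<3 months", "3-12 months", "12-24 months", ">24 months"]
_INTERVAL_EDGES = [0, 90, 365, 730]


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def classify_psci(assessment) -> str:
    """Classify one assessment as PSCI / no_PSCI / indeterminate.

    ``assessment`` is a mapping (or pandas row) with an ``instrument`` field
    of ``"full_battery"`` or ``"moca"``, the six domain percentile columns
    (nullable) and/or ``moca_percentile``.

    Full battery: any domain percentile < 5 -> PSCI; otherwise no_PSCI when
    >= 3 domains were assessed, else indeterminate. MoCA-only: the MoCA
    percentile alone decides (< 5 -> PSCI).
    """
    instrument = assessment.get("instrument", "full_battery")
    if instrument == "moca":
        moca = assessment.get("moca_percentile")
        if _is_missing(moca):
            raise ValidationError("MoCA-only assessment without moca_percentile")
        _check_percentile(moca)
        return PSCI if moca < IMPAIRMENT_PERCENTILE else NO_PSCI
    if instrument != "full_battery":
        raise ValidationError(f"unknown instrument {instrument!r}")
    values = [assessment.get(col) for col in DOMAIN_COLUMNS]
    assessed = [v for v in values if not _is_missing(v)]
    if not assessed:
        raise ValidationError("assessment has no non-missing domain measure")
    for v in assessed:
        _check_percentile(v)
    if any(v < IMPAIRMENT_PERCENTILE for v in assessed):
        return PSCI
    if len(assessed) >= MIN_DOMAINS_TO_EXCLUDE:
        return NO_PSCI
    return INDETERMINATE


def _check_percentile(value) -> None:
    if not (0.0 <= float(value) <= 100.0):
        raise ValidationError(f"percentile {value!r} outside [0, 100]")


def interval_stratify(days_post_stroke) -> str:
    """Map days post-stroke to the four reporting intervals.

    Bins are left-closed, right-open in days: day 89 is "<3 months", day 90
    is "3-12 months", day 365 is "12-24 months", day 730 is ">24 months".
    """
    days = float(days_post_stroke)
    if not np.isfinite(days) or days < 0:
        raise ValidationError(f"days_post_stroke must be >= 0, got {days_post_stroke!r}")
    idx = int(np.searchsorted(_INTERVAL_EDGES, days, side="right")) - 1
    return INTERVAL_LABELS[idx]


def classify_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Annotate a long cohort table with per-assessment status and interval.

    Adds ``psci_status``, ``psci`` (1/0, NA when indeterminate) and
    ``interval`` columns; the input frame is not modified.
    """
    out = cohort.copy()
    statuses = [classify_psci(row) for row in out.to_dict("records")]
    out["psci_status"] = statuses
    out["psci"] = [
        1 if s == PSCI else (0 if s == NO_PSCI else np.nan) for s in statuses
    ]
    out["interval"] = [interval_stratify(d) for d in out["days_post_stroke"]]
    return out


def classify_transition(assessments: Iterable[tuple]) -> str:
    """Transition status for one patient.

    ``assessments`` is an iterable of ``(days_post_stroke, status)`` pairs,
    statuses as returned by :func:`classify_psci`. The baseline is the
    earliest *determinate* assessment before 90 days. Recovery and decline
    are triggered by ANY qualifying later determinate assessment and take
    precedence over the stable statuses.
    """
    records = sorted(
        ((float(d), s) for d, s in assessments), key=lambda pair: pair[0]
    )
    baseline = None
    for day, status in records:
        if day < BASELINE_WINDOW_DAYS and status in (PSCI, NO_PSCI):
            baseline = (day, status)
            break
    if baseline is None:
        return NOT_EVALUABLE
    later = [s for d, s in records if d > baseline[0] and s in (PSCI, NO_PSCI)]
    if not later:
        return NOT_EVALUABLE
    if baseline[1] == PSCI:
        return RECOVERY if NO_PSCI in later else STABLE_PSCI
    return DECLINE if PSCI in later else STABLE_NO_PSCI


def classify_transitions(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-patient transition table from a :func:`classify_cohort` frame.

    Returns one row per patient: transition status, baseline day and status.
    """
    rows = []
    for patient_id, grp in classified.groupby("patient_id", sort=True):
        pairs = list(zip(grp["days_post_stroke"], grp["psci_status"]))
        status = classify_transition(pairs)
        det = sorted(
            (float(d), s)
            for d, s in pairs
            if float(d) < BASELINE_WINDOW_DAYS and s in (PSCI, NO_PSCI)
        )
        rows.append(
            (
                patient_id,
                status,
                det[0][0] if det else np.nan,
                det[0][1] if det else pd.NA,
            )
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "transition", "baseline_day", "baseline_status"]
    )


def prevalence(n_psci: int, n_assessed: int) -> int:
    """Integer prevalence percent, truncated toward zero.

    ``100 * n_psci / n_assessed`` with the fractional part discarded:
    397/844 -> 47, 208/522 -> 39 (39.85 truncates, it does not round).
    """
    n_psci, n_assessed = int(n_psci), int(n_assessed)
    if n_assessed <= 0:
        raise ValidationError("n_assessed must be positive")
    if not (0 <= n_psci <= n_assessed):
        raise ValidationError(f"need 0 <= n_psci <= n_assessed, got {n_psci}/{n_assessed}")
    # exact integer arithmetic; floor == truncation for non-negative counts
    return (100 * n_psci) // n_assessed
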