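"""NEDA-style responder stratification.

A subject is a non-responder if any component of disease activity occurred
over the study window: MRI activity (new/enlarging T2 or gadolinium-
enhancing lesions), a clinical relapse, or confirmed EDSS disability
progression. EDSS progression uses baseline-dependent thresholds; the
published middle band is ambiguous (it names only a baseline of exactly 1.5),
so the conventional reading 0 < baseline <= 5.0 is the default, with the
literal reading selectable.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ValidationError
from .types import ActivityRecord


def edss_progression(
    baseline: float, followup: float, middle_band: str = "conventional"
) -> bool:
    """Disability progression from baseline-dependent EDSS increase.

    Thresholds: ≥1.5 points from baseline 0; ≥1.0 point from the middle
    band; ≥0.5 points from baseline > 5.0. ``middle_band='conventional'``
    applies the 1.0-point rule to 0 < baseline ≤ 5.0; ``'literal'`` applies
    it only at baseline exactly 1.5 (other mid-range baselines can then
    never progress).
    """
    if middle_band not in ("conventional", "literal"):
        raise ValidationError(f"unknown middle_band {middle_band!r}")
    delta = followup - baseline
    if baseline == 0.0:
        return delta >= 1.5
    if baseline > 5.0:
        return delta >= 0.5
    if middle_band == "conventional":
        return delta >= 1.0
    return baseline == 1.5 and delta >= 1.0


@dataclass
class StratificationResult:
    """Responder labels plus the contingency breakdown of activity evidence."""

    labels: dict[str, str]  # subject id -> "responder" | "non_responder"
    n_responders: int
    n_non_responders: int
    breakdown: dict[str, int]  # mri_only / relapse_only / mri_and_relapse / ...


def classify_responders(
    records: list[ActivityRecord], middle_band: str = "conventional"
) -> StratificationResult:
    """Label each subject and tabulate which activity criteria fired.

    Non-responder iff MRI activity, relapse, or EDSS progression; the
    breakdown separates MRI-only, relapse-only, their overlap, and
    progression-only cases. Order-invariant; duplicate ids are rejected.
    """
    ids = [r.subject_id for r in records]
    dup = sorted(k for k, v in Counter(ids).items() if v > 1)
    if dup:
        raise ValidationError(f"duplicate subject ids: {dup}")
    labels: dict[str, str] = {}
    breakdown = Counter(
        {"mri_only": 0, "relapse_only": 0, "mri_and_relapse": 0, "progression_only": 0}
    )
    for rec in records:
        prog = edss_progression(rec.edss_baseline, rec.edss_followup, middle_band)
        active = rec.mri_activity or rec.relapse or prog
        labels[rec.subject_id] = "non_responder" if active else "responder"
        if rec.mri_activity and rec.relapse:
            breakdown["mri_and_relapse"] += 1
        elif rec.mri_activity:
            breakdown["mri_only"] += 1
        elif rec.relapse:
            breakdown["relapse_only"] += 1
        elif prog:
            breakdown["progression_only"] += 1
    n_nr = sum(1 for v in labels.values() if v == "non_responder")
    return StratificationResult(
        labels=labels,
        n_responders=len(labels) - n_nr,
        n_non_responders=n_nr,
        breakdown=dict(breakdown),
    )


def records_from_cohort(cohort) -> list[ActivityRecord]:
    """Activity records from a cohort table (MRI activity as one flag)."""
    return [
        ActivityRecord(
            subject_id=s.id,
            new_or_enlarging_t2=s.mri_activity_flag,
            gd_enhancing=False,
            relapse=s.relapse_flag,
            edss_baseline=s.edss_baseline,
            edss_followup=s.edss_followup,
        )
        for s in cohort
    ]
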