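"""Annualized regional cortical atrophy rates and group comparisons.

The longitudinal measure is the symmetrized annualized percent change

    rate = 100 * (t1 - t0) / (interval_years * (t0 + t1) / 2)   [% / year]

computed region-wise per subject. The denominator averages the two
timepoints, which makes the measure exactly antisymmetric under swapping
baseline and follow-up and invariant to thickness unit rescaling.
Group differences are assessed per region by a linear model
``rate ~ group + age + sex`` with family-wise correction by max-|t|
permutation of the group labels.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .glm import PermutationGLMResult, permutation_glm
from .types import AtrophyMap, Cohort, ThicknessTable


def annualized_percent_change(t0, t1, interval_years) -> np.ndarray | float:
    """Symmetrized annualized percent thickness change, elementwise.

    Parameters are baseline and follow-up thickness (any positive unit, same
    for both) and the scan interval in years.
    """
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    interval = np.asarray(interval_years, dtype=float)
    if np.any(t0 <= 0) or np.any(t1 <= 0):
        raise ValidationError("thickness values must be positive")
    if np.any(interval <= 0):
        raise ValidationError("scan interval must be positive")
    rate = 100.0 * (t1 - t0) / (interval * (t0 + t1) / 2.0)
    return rate if rate.ndim else float(rate)


def build_atrophy_map(thickness: ThicknessTable, cohort: Cohort) -> AtrophyMap:
    """Per-subject, per-region annualized rates from a two-timepoint table."""
    by_id = {s.id: s for s in cohort}
    missing = [i for i in thickness.subject_ids if i not in by_id]
    if missing:
        raise ValidationError(f"subjects missing from cohort: {missing}")
    intervals = np.array(
        [by_id[i].followup_interval / 12.0 for i in thickness.subject_ids]
    )
    rates = annualized_percent_change(
        thickness.timepoint("baseline"),
        thickness.timepoint("followup"),
        intervals[:, None],
    )
    cov = pd.DataFrame(
        {
            "age": [by_id[i].age for i in thickness.subject_ids],
            "sex": [1.0 if by_id[i].sex == "M" else 0.0 for i in thickness.subject_ids],
        },
        index=thickness.subject_ids,
    )
    return AtrophyMap(
        subject_ids=list(thickness.subject_ids),
        region_labels=list(thickness.region_labels),
        values=rates,
        covariates=cov,
    )


def mean_cortical_atrophy(amap: AtrophyMap, subject_subset=None) -> float:
    """Mean over subjects of each subject's mean regional rate (% / year)."""
    if subject_subset is None:
        values = amap.values
    else:
        wanted = list(subject_subset)
        if not wanted:
            raise ValidationError("subject subset is empty")
        pos = [amap.subject_ids.index(i) for i in wanted]
        values = amap.values[pos]
    if values.shape[0] == 0:
        raise ValidationError("subject subset is empty")
    return float(values.mean(axis=1).mean())


def regional_group_comparison(
    amap: AtrophyMap,
    group_labels,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> PermutationGLMResult:
    """Per-region GLM ``rate ~ group + age + sex`` with max-|t| permutation.

    ``group_labels`` is a binary coding (or two-level label sequence) aligned
    with the map's subjects; adjusted p-values control the family-wise error
    over regions and are floored at 1/(n_perm+1).
    """
    labels = pd.Series(list(group_labels))
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    x = (labels == levels[1]).to_numpy(dtype=float)
    if x.sum() < 2 or (1 - x).sum() < 2:
        raise ValidationError("need at least 2 subjects per group")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100 for a usable adjustment")
    return permutation_glm(
        amap.values,
        x,
        amap.covariates,
        amap.region_labels,
        n_perm=n_perm,
        rng=rng,
    )
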