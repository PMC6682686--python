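"""Lymphocyte-subset statistics and the atrophy-lymphocyte association.

Between-group comparisons of follow-up counts use the Mann-Whitney U test
(exact enumeration for small samples without ties), within-group baseline
vs follow-up changes the Wilcoxon signed-rank test, and the association of
regional atrophy rates with T-cell count changes a per-region linear model
``rate ~ Δcount + age + sex`` with max-|t| permutation correction across
regions. Δ is follow-up minus baseline throughout.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .glm import PermutationGLMResult, permutation_glm
from .types import AtrophyMap, LymphocytePanel, SubsetComparison

_EXACT_MAX_N = 8


def _followup_counts(panels: list[LymphocytePanel], subset: str) -> np.ndarray:
    vals = [getattr(p, subset) for p in panels if p.timepoint == "followup"]
    return np.asarray(vals, dtype=float)


def panel_deltas(panels: list[LymphocytePanel], subset: str) -> pd.Series:
    """Follow-up minus baseline counts per subject for one subset."""
    by_tp: dict[str, dict[str, float]] = {"baseline": {}, "followup": {}}
    for p in panels:
        by_tp[p.timepoint][p.subject_id] = getattr(p, subset)
    ids = sorted(set(by_tp["baseline"]) & set(by_tp["followup"]))
    missing = sorted(set(by_tp["baseline"]) ^ set(by_tp["followup"]))
    if missing:
        raise ValidationError(f"subjects missing a timepoint: {missing}")
    return pd.Series(
        {i: by_tp["followup"][i] - by_tp["baseline"][i] for i in ids}, name=subset
    )


def between_group_subset_test(
    panels_a: list[LymphocytePanel],
    panels_b: list[LymphocytePanel],
    subset: str,
    label: str = "A vs B",
) -> SubsetComparison:
    """Mann-Whitney U rank-sum test on follow-up counts of two groups.

    Exact null enumeration when both groups have at most 8 subjects and no
    ties; normal approximation with tie correction otherwise. Fully tied
    data degenerates to p = 1 with a warning.
    """
    a = _followup_counts(panels_a, subset)
    b = _followup_counts(panels_b, subset)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("need at least 3 subjects per group")
    note = ""
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn(f"{subset}: all values tied; p set to 1", stacklevel=2)
        u, p, note = len(a) * len(b) / 2.0, 1.0, "degenerate: all tied"
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = (
            "exact"
            if (len(a) <= _EXACT_MAX_N and len(b) <= _EXACT_MAX_N and not has_ties)
            else "asymptotic"
        )
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return SubsetComparison(
        subset=subset,
        comparison=label,
        statistic=float(u),
        p_value=float(p),
        direction=int(np.sign(np.median(a) - np.median(b))),
        n=(len(a), len(b)),
        note=note,
    )


def within_group_paired_test(
    panels: list[LymphocytePanel], subset: str, label: str = "followup vs baseline"
) -> SubsetComparison:
    """Wilcoxon signed-rank test on follow-up − baseline paired differences.

    Zero differences are dropped (the standard convention); if every
    difference is zero the test degenerates to p = 1 with a warning.
    """
    deltas = panel_deltas(panels, subset).to_numpy()
    if len(deltas) < 3:
        raise ValidationError("need at least 3 paired subjects")
    nonzero = deltas[deltas != 0]
    note = ""
    if len(nonzero) == 0:
        warnings.warn(f"{subset}: all paired differences zero; p set to 1", stacklevel=2)
        w, p, note = 0.0, 1.0, "degenerate: all differences zero"
    else:
        w, p = stats.wilcoxon(
            deltas, zero_method="wilcox", alternative="two-sided", method="auto"
        )
    return SubsetComparison(
        subset=subset,
        comparison=label,
        statistic=float(w),
        p_value=float(p),
        direction=int(np.sign(np.median(deltas))),
        n=(len(deltas),),
        note=note,
    )


def atrophy_lymphocyte_association(
    amap: AtrophyMap,
    deltas: pd.Series,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> PermutationGLMResult:
    """Per-region GLM ``rate ~ Δcount + age + sex`` with max-|t| correction.

    ``deltas`` is indexed by subject id (per-subject ΔCD4 or ΔCD8 — or
    absolute counts, both entry points are the same call). The result table
    carries slope, t, partial R² of the count term, raw and family-wise
    adjusted p per region; ``result.peak_region`` is the region with the
    largest partial R².
    """
    try:
        x = deltas.loc[amap.subject_ids].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValidationError(f"deltas missing subjects: {exc}") from exc
    if len(amap.subject_ids) < 10:
        raise ValidationError("need at least 10 subjects for the association GLM")
    if not np.all(np.isfinite(x)):
        raise ValidationError("deltas contain non-finite values")
    if np.ptp(x) == 0:
        raise ValidationError("count change is constant across subjects")
    return permutation_glm(
        amap.values,
        x,
        amap.covariates,
        amap.region_labels,
        n_perm=n_perm,
        rng=rng,
    )
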