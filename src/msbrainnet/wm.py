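"""Per-subject white-matter streamline networks and their modularity.

Streamline counts are converted to connection probabilities (counts divided
by the number of samples drawn per seed), spurious connections are removed
by a retention filter (keep edges carrying at least a fixed fraction of the
samples — "at least" means the boundary value is retained), and the weighted
retained matrix is partitioned with the Newman spectral algorithm. Subjects
are compared longitudinally by a paired t-test on Q.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .modularity import AdjacencyMatrix, newman_spectral_partition
from .types import StreamlineMatrix, WMNetworkResult


def retention_filter(
    mat: StreamlineMatrix, threshold_fraction: float = 0.10
) -> AdjacencyMatrix:
    """Weighted adjacency of connection probabilities above the retention cut.

    Edge weight = counts / samples_per_seed; weights strictly below
    ``threshold_fraction`` are zeroed, weights equal to it are kept.
    """
    if not (0 <= threshold_fraction < 1):
        raise ValidationError(
            f"retention threshold {threshold_fraction} outside [0, 1)"
        )
    weights = mat.counts.astype(float) / mat.samples_per_seed
    weights[weights < threshold_fraction] = 0.0
    return AdjacencyMatrix(
        weights=weights, node_labels=list(mat.node_labels), is_binary=False
    )


def subject_modularity(
    mat: StreamlineMatrix,
    threshold_fraction: float = 0.10,
    binarize: bool = False,
) -> WMNetworkResult:
    """Weighted spectral modularity of one subject's retained network.

    An empty retained graph yields a flagged result with missing Q rather
    than an exception, so cohort sweeps can log and skip such subjects.
    ``binarize`` switches the retained matrix to unweighted edges.
    """
    adj = retention_filter(mat, threshold_fraction)
    n_possible = np.count_nonzero(mat.counts) or 1
    retained = np.count_nonzero(adj.weights)
    fraction = retained / n_possible
    if adj.total_weight <= 0:
        return WMNetworkResult(
            subject_id=mat.subject_id,
            timepoint=mat.timepoint,
            q=None,
            n_modules=None,
            retained_edge_fraction=fraction,
        )
    if binarize:
        adj = AdjacencyMatrix(
            weights=(adj.weights > 0).astype(float),
            node_labels=adj.node_labels,
            is_binary=True,
        )
    part = newman_spectral_partition(adj)
    return WMNetworkResult(
        subject_id=mat.subject_id,
        timepoint=mat.timepoint,
        q=part.q,
        n_modules=part.n_modules,
        retained_edge_fraction=fraction,
    )


@dataclass
class PairedSubjectComparison:
    """Paired t-test on subject-level Q between two timepoints."""

    t: float
    p_value: float
    mean_delta_q: float
    n_pairs: int
    excluded: list[str]  # subjects dropped for missing Q at either timepoint


def compare_subjects_longitudinal(
    results_t0: list[WMNetworkResult],
    results_t1: list[WMNetworkResult],
    alternative: str = "two-sided",
) -> PairedSubjectComparison:
    """Paired t-test across subjects on Q(follow-up) − Q(baseline)."""
    by0 = {r.subject_id: r for r in results_t0}
    by1 = {r.subject_id: r for r in results_t1}
    unmatched = sorted(set(by0) ^ set(by1))
    if unmatched:
        raise ValidationError(f"unmatched subject ids across timepoints: {unmatched}")
    excluded = sorted(
        sid for sid in by0 if by0[sid].q is None or by1[sid].q is None
    )
    if excluded:
        warnings.warn(
            f"excluding subjects with empty retained graphs: {excluded}",
            stacklevel=2,
        )
    ids = sorted(set(by0) - set(excluded))
    if len(ids) < 2:
        raise ValidationError("need at least 2 matched subjects with defined Q")
    q0 = np.array([by0[s].q for s in ids])
    q1 = np.array([by1[s].q for s in ids])
    delta = q1 - q0
    if np.ptp(delta) == 0:
        mean = float(delta.mean())
        t = 0.0 if mean == 0 else float(np.sign(mean) * np.inf)
        p = 1.0 if mean == 0 else 0.0
    else:
        t, p = stats.ttest_rel(q1, q0, alternative=alternative)
        t, p = float(t), float(p)
    return PairedSubjectComparison(
        t=t,
        p_value=p,
        mean_delta_q=float(delta.mean()),
        n_pairs=len(ids),
        excluded=excluded,
    )
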