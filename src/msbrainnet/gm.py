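"""Group-level gray-matter structural covariance networks.

A structural covariance network has cortical regions as nodes and, as edge
weights, Pearson correlations of regional thickness *across the subjects of
a group*. Networks are binarized over a proportional-density grid and the
Newman spectral partition gives modularity Q and module count per density;
baseline and follow-up curves are compared by a paired t-test across the
density grid (the repeated measure available for one network per timepoint).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .modularity import newman_spectral_partition, threshold_at_density
from .types import DensityCurve, ThicknessTable

DEFAULT_DENSITY_GRID = np.round(np.arange(0.10, 0.501, 0.05), 2)
REFERENCE_DENSITY = 0.15


@dataclass
class CovarianceNetwork:
    """Region × region Pearson correlation matrix for one group/timepoint."""

    r_matrix: np.ndarray
    region_labels: list[str]
    group_label: str
    timepoint: str
    n_subjects: int

    def __post_init__(self) -> None:
        self.r_matrix = np.asarray(self.r_matrix, dtype=float)
        n = len(self.region_labels)
        if self.r_matrix.shape != (n, n):
            raise ValidationError("correlation matrix shape mismatch")
        if not np.allclose(self.r_matrix, self.r_matrix.T, atol=1e-10):
            raise ValidationError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r_matrix), 1.0, atol=1e-10):
            raise ValidationError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.r_matrix) > 1 + 1e-10):
            raise ValidationError("correlations outside [-1, 1]")


def build_covariance_network(
    thickness: ThicknessTable,
    subject_subset,
    timepoint: str,
    group_label: str = "",
    adjust_covariates: bool = False,
    covariates: pd.DataFrame | None = None,
) -> CovarianceNetwork:
    """Pearson correlations between region columns across a subject subset.

    With ``adjust_covariates`` the correlations are computed on residuals of
    thickness ~ age + sex (``covariates`` indexed by subject id).
    """
    ids = list(subject_subset)
    if len(ids) < 4:
        raise ValidationError(
            f"need at least 4 subjects for a covariance network, got {len(ids)}"
        )
    sub = thickness.subset(ids)
    data = sub.timepoint(timepoint)
    variances = data.var(axis=0)
    dead = [sub.region_labels[i] for i in np.where(variances <= 1e-24)[0]]
    if dead:
        raise ValidationError(f"zero-variance regions: {dead}")
    if adjust_covariates:
        if covariates is None:
            raise ValidationError("adjust_covariates requires a covariate table")
        z = covariates.loc[ids].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(ids)), z - z.mean(axis=0)])
        beta, *_ = np.linalg.lstsq(design, data, rcond=None)
        data = data - design @ beta
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CovarianceNetwork(
        r_matrix=r,
        region_labels=list(sub.region_labels),
        group_label=group_label,
        timepoint=timepoint,
        n_subjects=len(ids),
    )


def modularity_density_curve(
    net: CovarianceNetwork, densities=DEFAULT_DENSITY_GRID
) -> DensityCurve:
    """Q and module count from the spectral partition at each density."""
    densities = np.asarray(densities, dtype=float)
    qs, counts = [], []
    for d in densities:
        adj = threshold_at_density(net.r_matrix, d, net.region_labels)
        part = newman_spectral_partition(adj)
        qs.append(part.q)
        counts.append(part.n_modules)
    return DensityCurve(densities=densities, q_values=qs, module_counts=counts)


@dataclass
class PairedCurveComparison:
    """Paired t-test of Q across the density grid, baseline vs follow-up."""

    t: float
    p_value: float
    mean_delta_q: float
    auc_delta_q: float  # trapezoidal area of ΔQ over the density grid
    n_densities: int

    @property
    def direction(self) -> int:
        return int(np.sign(self.mean_delta_q))


def compare_curves_longitudinal(
    curve_t0: DensityCurve, curve_t1: DensityCurve
) -> PairedCurveComparison:
    """Paired t-test across densities on Q(follow-up) − Q(baseline)."""
    if not np.array_equal(curve_t0.densities, curve_t1.densities):
        raise ValidationError("density grids differ between timepoints")
    delta = curve_t1.q_values - curve_t0.q_values
    mean = float(delta.mean())
    auc = float(np.trapezoid(delta, curve_t0.densities))
    if np.ptp(delta) == 0:
        # degenerate: constant shift (or identical curves)
        t = 0.0 if mean == 0 else float(np.sign(mean) * np.inf)
        p = 1.0 if mean == 0 else 0.0
    else:
        t, p = stats.ttest_rel(curve_t1.q_values, curve_t0.q_values)
        t, p = float(t), float(p)
    return PairedCurveComparison(
        t=t,
        p_value=p,
        mean_delta_q=mean,
        auc_delta_q=auc,
        n_densities=len(delta),
    )
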