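"""Core domain containers for the cohort, imaging-derived tables and networks.

Everything here is plain tabular/array data: per-subject clinical records,
regional cortical thickness (mm) at two timepoints, streamline-count
connectivity matrices, lymphocyte subset panels (cells/μl), and the
network-analysis products (partitions, modularity-vs-density curves).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ARMS = ("DMF", "NAT")
SEXES = ("M", "F")
TIMEPOINTS = ("baseline", "followup")
LYMPHOCYTE_SUBSETS = ("cd3", "cd4", "cd8", "cd56", "cd19", "alc")


def _check_edss(value: float, name: str) -> None:
    if not (0.0 <= value <= 10.0) or abs(value * 2 - round(value * 2)) > 1e-9:
        raise ValidationError(
            f"{name}={value!r} is not on the EDSS 0-10 half-point grid"
        )


@dataclass
class Subject:
    """One study participant with clinical timeline and lesion volumes."""

    id: str
    arm: str
    age: float
    sex: str
    disease_duration: float  # months
    followup_interval: float  # months
    edss_baseline: float
    edss_followup: float
    relapse_flag: bool
    mri_activity_flag: bool
    lesion_volume_baseline: float  # mL
    lesion_volume_followup: float  # mL

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"unknown treatment arm {self.arm!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex code {self.sex!r}")
        if not (18.0 <= self.age <= 60.0):
            raise ValidationError(
                f"subject {self.id}: age {self.age} outside the 18-60 year "
                "inclusion window"
            )
        if self.followup_interval <= 0:
            raise ValidationError(
                f"subject {self.id}: follow-up interval must be positive"
            )
        _check_edss(self.edss_baseline, "edss_baseline")
        _check_edss(self.edss_followup, "edss_followup")
        for fld in ("lesion_volume_baseline", "lesion_volume_followup"):
            if getattr(self, fld) < 0:
                raise ValidationError(f"subject {self.id}: {fld} negative")

    @property
    def has_activity(self) -> bool:
        return self.relapse_flag or self.mri_activity_flag


@dataclass
class Cohort:
    """Ordered collection of subjects plus pass-through annotation columns."""

    subjects: list[Subject]
    annotations: pd.DataFrame | None = None  # indexed by subject id

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dup}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def arm(self, arm: str) -> "Cohort":
        sel = [s for s in self.subjects if s.arm == arm]
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[[s.id for s in sel]]
        return Cohort(sel, ann)

    def select(self, ids: Iterable[str]) -> "Cohort":
        wanted = set(ids)
        sel = [s for s in self.subjects if s.id in wanted]
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[[s.id for s in sel]]
        return Cohort(sel, ann)

    def frame(self) -> pd.DataFrame:
        rows = [vars(s).copy() for s in self.subjects]
        df = pd.DataFrame(rows).set_index("id", drop=False)
        if self.annotations is not None and len(self.annotations.columns):
            df = df.join(self.annotations)
        return df


@dataclass
class LymphocytePanel:
    """Lymphocyte subset counts (cells/μl) for one subject at one timepoint."""

    subject_id: str
    timepoint: str
    cd3: float = 0.0
    cd4: float = 0.0
    cd8: float = 0.0
    cd56: float = 0.0
    cd19: float = 0.0
    alc: float = 0.0
    cd4_cd8_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        for subset in LYMPHOCYTE_SUBSETS:
            if getattr(self, subset) < 0:
                raise ValidationError(
                    f"{self.subject_id}/{self.timepoint}: {subset} count negative"
                )
        if self.cd4_cd8_ratio is None:
            self.cd4_cd8_ratio = self.cd4 / self.cd8 if self.cd8 > 0 else float("nan")


@dataclass
class ThicknessTable:
    """Regional cortical thickness, subjects × regions × (baseline, followup), mm."""

    subject_ids: list[str]
    region_labels: list[str]
    values: np.ndarray  # (n_subjects, n_regions, 2)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, r = len(self.subject_ids), len(self.region_labels)
        if self.values.shape != (n, r, 2):
            raise ValidationError(
                f"thickness values shape {self.values.shape} != ({n}, {r}, 2)"
            )
        if not np.all((self.values > 0) & (self.values < 7)):
            raise ValidationError("thickness values must lie in (0, 7) mm")

    def timepoint(self, tp: str) -> np.ndarray:
        return self.values[:, :, TIMEPOINTS.index(tp)]

    def subset(self, ids: Sequence[str]) -> "ThicknessTable":
        pos = [self.subject_ids.index(i) for i in ids]
        return ThicknessTable(list(ids), list(self.region_labels), self.values[pos])


@dataclass
class StreamlineMatrix:
    """Symmetric streamline-sample count matrix for one subject/timepoint."""

    subject_id: str
    timepoint: str
    node_labels: list[str]
    counts: np.ndarray
    samples_per_seed: int = 5000

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.node_labels)
        if self.counts.shape != (n, n):
            raise ValidationError("streamline count matrix is not square")
        if np.any(self.counts < 0):
            raise ValidationError("streamline counts must be non-negative")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValidationError("streamline count matrix is not symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValidationError("streamline count matrix diagonal must be zero")
        if self.samples_per_seed <= 0:
            raise ValidationError("samples_per_seed must be positive")


@dataclass
class Partition:
    """Node → module assignment with its modularity value Q."""

    assignment: dict[str, int]
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[n] for n in nodes], dtype=int)


@dataclass
class DensityCurve:
    """Modularity Q and module count along a proportional-density grid."""

    densities: np.ndarray
    q_values: np.ndarray
    module_counts: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.module_counts = np.asarray(self.module_counts, dtype=int)
        if not (
            len(self.densities) == len(self.q_values) == len(self.module_counts)
        ):
            raise ValidationError("density-curve fields have unequal lengths")
        if np.any(np.diff(self.densities) <= 0):
            raise ValidationError("densities must be strictly increasing")

    def q_at(self, density: float) -> float:
        idx = int(np.argmin(np.abs(self.densities - density)))
        return float(self.q_values[idx])

    def modules_at(self, density: float) -> int:
        idx = int(np.argmin(np.abs(self.densities - density)))
        return int(self.module_counts[idx])


@dataclass
class AtrophyMap:
    """Annualized percent thickness change, subjects × regions (% per year)."""

    subject_ids: list[str]
    region_labels: list[str]
    values: np.ndarray  # (n_subjects, n_regions)
    covariates: pd.DataFrame | None = None  # age, sex per subject

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, r = len(self.subject_ids), len(self.region_labels)
        if self.values.shape != (n, r):
            raise ValidationError(
                f"atrophy map shape {self.values.shape} != ({n}, {r})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("atrophy map contains non-finite values")


@dataclass
class WMNetworkResult:
    """Per-subject white-matter network modularity summary."""

    subject_id: str
    timepoint: str
    q: float | None
    n_modules: int | None
    retained_edge_fraction: float


@dataclass
class ActivityRecord:
    """Disease-activity evidence for one subject over the study window."""

    subject_id: str
    new_or_enlarging_t2: bool
    gd_enhancing: bool
    relapse: bool
    edss_baseline: float
    edss_followup: float

    def __post_init__(self) -> None:
        _check_edss(self.edss_baseline, "edss_baseline")
        _check_edss(self.edss_followup, "edss_followup")

    @property
    def mri_activity(self) -> bool:
        return self.new_or_enlarging_t2 or self.gd_enhancing


@dataclass
class SubsetComparison:
    """Result of one lymphocyte-subset hypothesis test."""

    subset: str
    comparison: str
    statistic: float
    p_value: float
    direction: int  # sign of the (A−B or followup−baseline) location shift
    n: tuple[int, ...]
    note: str = ""
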