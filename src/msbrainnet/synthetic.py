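"""Synthetic MS therapy-cohort generator with planted statistical structure.

Emulates the derived data of a two-arm observational MS study: a dimethyl
fumarate (DMF) arm and a natalizumab (NAT) reference arm, matched on
demographics; responder/non-responder subgroups defined by disease activity;
responder-dependent CD8+ T-cell depletion; group- and subgroup-specific
annualized cortical atrophy rates; modular cross-subject covariance structure
in regional cortical thickness; and modular weighted block structure in
streamline-count connectomes.

Every planted first and second moment is recoverable by the downstream
analysis code, which gives the whole pipeline a parameter-recovery testing
surface. One master seed drives deterministic per-stage child seeds, so an
identical spec yields a bit-identical dataset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import SpecError
from .types import (
    Cohort,
    LymphocytePanel,
    StreamlineMatrix,
    Subject,
    ThicknessTable,
)

# Desikan-Killiany cortical parcellation: 34 regions per hemisphere.
_DK34 = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
]
DK68_REGIONS = [f"lh_{r}" for r in _DK34] + [f"rh_{r}" for r in _DK34]
AAL116_NODES = [f"aal_{i:03d}" for i in range(1, 117)]

SUBGROUPS = ("DMF_R", "DMF_NR", "NAT_active", "NAT_inactive")

_STAGES = {"cohort": 0, "thickness": 1, "streamlines": 2, "lymphocytes": 3}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage child generator from the master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES[stage]])


@lru_cache(maxsize=512)
def _matched_loc(mean: float, sd: float, lower: float) -> float:
    """Location of a lower-truncated normal whose truncated mean equals ``mean``."""

    def excess(loc: float) -> float:
        a = (lower - loc) / sd
        return loc + sd * stats.norm.pdf(a) / stats.norm.sf(a) - mean

    return float(optimize.brentq(excess, mean - 30.0 * sd, mean))


def truncated_normal(
    mean: float,
    sd: float,
    size: int,
    rng: np.random.Generator,
    lower: float = 0.0,
) -> np.ndarray:
    """Lower-truncated normal draws whose *truncated* mean is exactly ``mean``.

    The underlying location is solved so the distribution's mean after
    truncation matches the planted value (naive truncation would bias the
    mean upward). ``sd`` is the pre-truncation scale; ``sd == 0`` degenerates
    to the constant ``mean``.
    """
    if sd < 0:
        raise SpecError("sd must be non-negative")
    if mean <= lower:
        raise SpecError(f"planted mean {mean} must exceed the lower bound {lower}")
    if sd == 0:
        return np.full(size, float(mean))
    loc = _matched_loc(float(mean), float(sd), float(lower))
    a = (lower - loc) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=size, random_state=rng)


def planted_partition(n_items: int, n_modules: int) -> np.ndarray:
    """Contiguous, nearly equal-sized module assignment of n_items."""
    if not (1 <= n_modules <= n_items):
        raise SpecError(f"cannot split {n_items} items into {n_modules} modules")
    return np.sort(np.arange(n_items) % n_modules)


@dataclass
class ArmDemographics:
    age_mean: float
    age_sd: float
    n_male: int
    duration_mean: float  # months
    duration_sd: float
    interval_mean: float  # months
    interval_sd: float
    edss_mean: float
    edss_sd: float


@dataclass
class LymphSubsetSpec:
    followup_mean: float  # cells/μl
    followup_sd: float
    delta_mean: float  # follow-up minus baseline, cells/μl
    delta_sd: float


def _default_lymph_spec() -> dict[str, dict[str, LymphSubsetSpec]]:
    # CD8 follow-up/Δ means are the study's printed per-subgroup values; the
    # remaining subsets use realistic DMF-lymphopenia levels (shared between
    # subgroups, follow-up below baseline in distribution).
    shared = {
        "cd3": LymphSubsetSpec(900.0, 300.0, -500.0, 200.0),
        "cd4": LymphSubsetSpec(600.0, 200.0, -300.0, 150.0),
        "cd56": LymphSubsetSpec(150.0, 60.0, -50.0, 40.0),
        "cd19": LymphSubsetSpec(220.0, 90.0, -40.0, 50.0),
        "alc": LymphSubsetSpec(1250.0, 350.0, -650.0, 250.0),
    }
    return {
        "DMF_R": {"cd8": LymphSubsetSpec(197.7, 97.1, -206.0, 80.0), **shared},
        "DMF_NR": {"cd8": LymphSubsetSpec(298.4, 190.6, -158.0, 80.0), **shared},
    }


def _default_lesion_spec() -> dict[str, tuple[float, float, float, float]]:
    # (baseline mean, baseline sd, follow-up mean, follow-up sd) in mL.
    # Active-DMF values are the printed subgroup means; inactive-DMF values
    # are derived so the whole arm reproduces the arm-level table
    # (42*11.1 = 25*11.2 + 17*x etc.); NAT subgroups share the arm values.
    return {
        "DMF_NR": (11.2, 8.0, 12.3, 8.2),
        "DMF_R": (10.953, 7.5, 10.571, 8.0),
        "NAT_active": (12.8, 3.0, 12.0, 2.5),
        "NAT_inactive": (12.8, 3.0, 12.0, 2.5),
    }


@dataclass
class ScenarioSpec:
    """Full calibration of one synthetic study scenario.

    Defaults reproduce the study conditions: arm sizes 42 (DMF) / 36 (NAT),
    responder split 17/25 with activity breakdown 15 MRI-active, 17 relapsing,
    7 both in the DMF arm (7/10/4 in NAT), subgroup CD8 depletion, and
    group-mode atrophy calibration (-2.4 / -2.1 %/yr). ``calibration_mode``
    switches the atrophy means between the whole-group and subgroup printed
    values, which are not mutually consistent arithmetically and therefore
    form two distinct scenarios.
    """

    seed: int = 0
    arm_sizes: dict[str, int] = field(
        default_factory=lambda: {"DMF": 42, "NAT": 36}
    )
    responder_split: dict[str, int] = field(
        default_factory=lambda: {"DMF_R": 17, "DMF_NR": 25, "NAT_active": 13}
    )
    # (n MRI-active, n relapsing, n both) among the active subjects of each arm
    activity_breakdown: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {"DMF": (15, 17, 7), "NAT": (7, 10, 4)}
    )
    demographics: dict[str, ArmDemographics] = field(
        default_factory=lambda: {
            "DMF": ArmDemographics(34.5, 9.0, 14, 54.2, 67.8, 15.8, 7.2, 1.8, 1.2),
            "NAT": ArmDemographics(30.6, 8.1, 14, 47.4, 43.9, 16.1, 4.3, 2.1, 1.2),
        }
    )
    lesion_spec: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_lesion_spec
    )
    lymph_spec: dict[str, dict[str, LymphSubsetSpec]] = field(
        default_factory=_default_lymph_spec
    )

    # --- atrophy calibration ---
    calibration_mode: str = "group"  # "group" | "subgroup"
    atrophy_means_group: dict[str, float] = field(
        default_factory=lambda: {"DMF": -2.4, "NAT": -2.1}
    )
    atrophy_means_subgroup: dict[str, float] = field(
        default_factory=lambda: {
            "DMF_R": -1.7,
            "DMF_NR": -3.2,
            "NAT_active": -2.1,
            "NAT_inactive": -2.1,
        }
    )
    atrophy_sd: float = 1.0  # %/yr between subjects
    region_rate_sd: float = 0.3  # %/yr region-level noise (rate mode)

    # --- gray-matter thickness field ---
    longitudinal_mode: str = "field"  # "field" | "rate"
    thickness_mean_mm: float = 2.5
    thickness_log_sd: float = 0.1  # ~0.25 mm at 2.5 mm
    region_labels: list[str] = field(default_factory=lambda: list(DK68_REGIONS))
    gm_modules: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "DMF": {"baseline": 2, "followup": 5},
            "NAT": {"baseline": 3, "followup": 2},
        }
    )
    r_within: float = 0.9
    r_between: float = 0.0

    # --- ΔCD8 / atrophy coupling (region level; active in rate mode) ---
    coupling_rho: float = 0.7
    coupling_regions: list[str] = field(
        default_factory=lambda: [
            "lh_superiorparietal",
            "lh_cuneus",
            "lh_rostralmiddlefrontal",
            "rh_rostralanteriorcingulate",
            "rh_lateraloccipital",
        ]
    )

    # --- white-matter streamline block model ---
    wm_node_labels: list[str] = field(default_factory=lambda: list(AAL116_NODES))
    wm_n_modules: int = 4
    wm_p_within: float = 0.4
    wm_p_between: float = 0.01
    wm_followup_within_scale: float = 1.0
    wm_followup_between_scale: float = 1.0
    samples_per_seed: int = 5000

    def __post_init__(self) -> None:
        for arm, n in self.arm_sizes.items():
            if n < 2:
                raise SpecError(f"arm {arm} needs at least 2 subjects")
        n_dmf_r = self.responder_split.get("DMF_R", 0)
        n_dmf_nr = self.responder_split.get("DMF_NR", 0)
        if n_dmf_r + n_dmf_nr != self.arm_sizes.get("DMF", 0):
            raise SpecError(
                "responder_split DMF_R + DMF_NR must equal the DMF arm size"
            )
        if self.responder_split.get("NAT_active", 0) > self.arm_sizes.get("NAT", 0):
            raise SpecError("NAT_active exceeds the NAT arm size")
        for arm, (mri, relapse, both) in self.activity_breakdown.items():
            n_active = (
                n_dmf_nr if arm == "DMF" else self.responder_split.get("NAT_active", 0)
            )
            if both > min(mri, relapse):
                raise SpecError(f"{arm}: overlap exceeds the marginal counts")
            if mri + relapse - both != n_active:
                raise SpecError(
                    f"{arm}: MRI {mri} + relapse {relapse} - both {both} != "
                    f"active count {n_active}"
                )
        if not (-1 < self.r_between < self.r_within < 1):
            raise SpecError("need -1 < r_between < r_within < 1")
        if not (-1 < self.coupling_rho < 1):
            raise SpecError("coupling_rho must lie in (-1, 1)")
        if self.atrophy_sd < 0 or self.region_rate_sd < 0:
            raise SpecError("atrophy noise SDs must be non-negative")
        for p in (self.wm_p_within, self.wm_p_between):
            if not (0 <= p <= 1):
                raise SpecError(f"block probability {p} outside [0, 1]")
        if not (0 <= self.wm_p_within * self.wm_followup_within_scale <= 1):
            raise SpecError("scaled follow-up within-block probability outside [0, 1]")
        if not (0 <= self.wm_p_between * self.wm_followup_between_scale <= 1):
            raise SpecError("scaled follow-up between-block probability outside [0, 1]")
        if self.calibration_mode not in ("group", "subgroup"):
            raise SpecError(f"unknown calibration_mode {self.calibration_mode!r}")
        if self.longitudinal_mode not in ("field", "rate"):
            raise SpecError(f"unknown longitudinal_mode {self.longitudinal_mode!r}")
        unknown = set(self.coupling_regions) - set(self.region_labels)
        if unknown:
            raise SpecError(f"coupling regions not in region_labels: {sorted(unknown)}")

    def subgroup_atrophy_mean(self, subgroup: str) -> float:
        if self.calibration_mode == "group":
            return self.atrophy_means_group[subgroup.split("_")[0]]
        return self.atrophy_means_subgroup[subgroup]


def _round_edss(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values * 2.0) / 2.0, 0.0, 6.0)


def generate_cohort(spec: ScenarioSpec) -> Cohort:
    """Draw demographics, activity flags, lesion volumes and latent factors.

    Activity flags are assigned so the planted MRI/relapse/overlap breakdown
    holds exactly; EDSS follow-up changes are capped below every progression
    threshold, so disease activity is carried entirely by the MRI and relapse
    flags (matching a cohort with no isolated disability progression).
    """
    rng = _stage_rng(spec.seed, "cohort")
    subjects: list[Subject] = []
    ann_rows: list[dict] = []
    for arm in sorted(spec.arm_sizes):
        n = spec.arm_sizes[arm]
        demo = spec.demographics[arm]
        if arm == "DMF":
            n_active = spec.responder_split["DMF_NR"]
        else:
            n_active = spec.responder_split.get("NAT_active", 0)
        mri, relapse, both = spec.activity_breakdown[arm]
        # role per subject: both / mri-only / relapse-only / inactive
        roles = (
            ["both"] * both
            + ["mri"] * (mri - both)
            + ["relapse"] * (relapse - both)
            + ["inactive"] * (n - n_active)
        )
        rng.shuffle(roles)
        ages = np.clip(rng.normal(demo.age_mean, demo.age_sd, n), 18.0, 60.0)
        sexes = np.array(["M"] * demo.n_male + ["F"] * (n - demo.n_male))
        rng.shuffle(sexes)
        durations = truncated_normal(demo.duration_mean, demo.duration_sd, n, rng, 1.0)
        intervals = truncated_normal(demo.interval_mean, demo.interval_sd, n, rng, 3.0)
        edss0 = _round_edss(rng.normal(demo.edss_mean, demo.edss_sd, n))
        steps = rng.choice([-0.5, 0.0, 0.5], size=n, p=[0.25, 0.5, 0.25])
        steps = np.where(edss0 > 5.0, np.minimum(steps, 0.0), steps)
        edss1 = np.clip(edss0 + steps, 0.0, 10.0)
        z_cd8 = rng.standard_normal(n)
        for i in range(n):
            active = roles[i] != "inactive"
            if arm == "DMF":
                subgroup = "DMF_NR" if active else "DMF_R"
            else:
                subgroup = "NAT_active" if active else "NAT_inactive"
            lb_m, lb_s, lf_m, lf_s = spec.lesion_spec[subgroup]
            lv0 = float(truncated_normal(lb_m, lb_s, 1, rng)[0])
            lv1 = float(truncated_normal(lf_m, lf_s, 1, rng)[0])
            subjects.append(
                Subject(
                    id=f"{arm}{i + 1:03d}",
                    arm=arm,
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    disease_duration=float(durations[i]),
                    followup_interval=float(intervals[i]),
                    edss_baseline=float(edss0[i]),
                    edss_followup=float(edss1[i]),
                    relapse_flag=roles[i] in ("relapse", "both"),
                    mri_activity_flag=roles[i] in ("mri", "both"),
                    lesion_volume_baseline=lv0,
                    lesion_volume_followup=lv1,
                )
            )
            ann_rows.append(
                {"id": subjects[-1].id, "subgroup": subgroup, "_z_cd8": float(z_cd8[i])}
            )
    annotations = pd.DataFrame(ann_rows).set_index("id")
    return Cohort(subjects=subjects, annotations=annotations)


def _subgroup_of(cohort: Cohort, subject: Subject) -> str:
    if cohort.annotations is not None and "subgroup" in cohort.annotations.columns:
        return str(cohort.annotations.loc[subject.id, "subgroup"])
    if subject.arm == "DMF":
        return "DMF_NR" if subject.has_activity else "DMF_R"
    return "NAT_active" if subject.has_activity else "NAT_inactive"


def _z_cd8_of(cohort: Cohort, rng: np.random.Generator) -> pd.Series:
    if cohort.annotations is not None and "_z_cd8" in cohort.annotations.columns:
        return cohort.annotations["_z_cd8"].astype(float)
    return pd.Series(rng.standard_normal(len(cohort)), index=cohort.ids)


def _module_field(
    rng: np.random.Generator,
    n_subjects: int,
    assignment: np.ndarray,
    r_within: float,
    r_between: float,
) -> np.ndarray:
    """Standard-normal field with planted cross-subject region correlations."""
    n_regions = len(assignment)
    shared = rng.standard_normal((n_subjects, 1))
    factors = rng.standard_normal((n_subjects, assignment.max() + 1))
    noise = rng.standard_normal((n_subjects, n_regions))
    rb = max(r_between, 0.0)
    return (
        np.sqrt(rb) * shared
        + np.sqrt(r_within - rb) * factors[:, assignment]
        + np.sqrt(1.0 - r_within) * noise
    )


def _calibrate_scale(
    t0: np.ndarray, raw1: np.ndarray, rates: np.ndarray, dt_years: np.ndarray
) -> np.ndarray:
    """Per-subject scale g so mean regional annualized change equals ``rates``.

    Solves mean_r[ (200/dt) (g c_r - 1)/(g c_r + 1) ] = rate by vectorized
    Newton iteration (the target is smooth and strictly increasing in g).
    """
    c = raw1 / t0
    g = np.ones(t0.shape[0])
    coef = 200.0 / dt_years
    for _ in range(100):
        gc = g[:, None] * c
        h = coef * np.mean((gc - 1.0) / (gc + 1.0), axis=1)
        resid = h - rates
        if np.all(np.abs(resid) < 1e-11):
            break
        dh = coef * np.mean(2.0 * c / (gc + 1.0) ** 2, axis=1)
        step = resid / dh
        g_new = g - step
        g = np.where(g_new > 1e-6, g_new, g / 2.0)
    return g


def generate_thickness(cohort: Cohort, spec: ScenarioSpec) -> ThicknessTable:
    """Cortical thickness with planted covariance modules and atrophy rates.

    Baseline (and, in field mode, follow-up) log-thickness fields carry the
    planted per-arm, per-timepoint module correlation structure. In field
    mode each subject's follow-up field is rescaled so the subject's mean
    regional annualized percent change equals the planted subgroup rate
    exactly. In rate mode the follow-up is derived region-wise from baseline
    through the exact inverse of the annualized-change formula, with
    region-level noise and ΔCD8 coupling in the designated regions.
    """
    rng = _stage_rng(spec.seed, "thickness")
    regions = spec.region_labels
    n_regions = len(regions)
    log_mu = np.log(spec.thickness_mean_mm)
    sigma = spec.thickness_log_sd
    z_cd8 = _z_cd8_of(cohort, rng)
    coupling_idx = [regions.index(r) for r in spec.coupling_regions]

    values = np.empty((len(cohort), n_regions, 2))
    row_of = {sid: i for i, sid in enumerate(cohort.ids)}
    for arm in sorted({s.arm for s in cohort}):
        members = [s for s in cohort if s.arm == arm]
        idx = np.array([row_of[s.id] for s in members])
        n = len(members)
        part0 = planted_partition(n_regions, spec.gm_modules[arm]["baseline"])
        f0 = _module_field(rng, n, part0, spec.r_within, spec.r_between)
        t0 = np.exp(log_mu + sigma * f0)
        dt = np.array([s.followup_interval / 12.0 for s in members])
        means = np.array(
            [spec.subgroup_atrophy_mean(_subgroup_of(cohort, s)) for s in members]
        )
        rates_subj = means + spec.atrophy_sd * rng.standard_normal(n)
        if spec.longitudinal_mode == "field":
            part1 = planted_partition(n_regions, spec.gm_modules[arm]["followup"])
            f1 = _module_field(rng, n, part1, spec.r_within, spec.r_between)
            raw1 = np.exp(log_mu + sigma * f1)
            g = _calibrate_scale(t0, raw1, rates_subj, dt)
            t1 = g[:, None] * raw1
        else:
            region_rates = (
                rates_subj[:, None]
                + spec.region_rate_sd * rng.standard_normal((n, n_regions))
            )
            if coupling_idx and abs(spec.coupling_rho) > 0:
                z = z_cd8.loc[[s.id for s in members]].to_numpy()
                eta = rng.standard_normal((n, len(coupling_idx)))
                coupled = means[:, None] + spec.atrophy_sd * (
                    spec.coupling_rho * z[:, None]
                    + np.sqrt(1.0 - spec.coupling_rho**2) * eta
                )
                region_rates[:, coupling_idx] = coupled
            k = region_rates * dt[:, None] / 200.0
            if np.any(np.abs(k) >= 1.0):
                raise SpecError("planted rates too extreme for the interval")
            t1 = t0 * (1.0 + k) / (1.0 - k)
        values[idx, :, 0] = t0
        values[idx, :, 1] = t1
    return ThicknessTable(
        subject_ids=list(cohort.ids), region_labels=list(regions), values=values
    )


def generate_streamlines(
    cohort: Cohort,
    spec: ScenarioSpec,
    timepoints: Sequence[str] = ("baseline", "followup"),
) -> list[StreamlineMatrix]:
    """Poisson streamline-count matrices from a weighted planted block model.

    Edge counts are Poisson with mean samples_per_seed × block probability
    (high within planted modules, low between); matrices are symmetric with
    zero diagonal. The follow-up within-module probability can be scaled to
    plant a longitudinal contrast change.
    """
    rng = _stage_rng(spec.seed, "streamlines")
    labels = spec.wm_node_labels
    n_nodes = len(labels)
    assignment = planted_partition(n_nodes, spec.wm_n_modules)
    same = assignment[:, None] == assignment[None, :]
    iu, ju = np.triu_indices(n_nodes, k=1)
    out: list[StreamlineMatrix] = []
    for subject in cohort:
        for tp in timepoints:
            p_within = spec.wm_p_within
            p_between = spec.wm_p_between
            if tp == "followup":
                p_within *= spec.wm_followup_within_scale
                p_between *= spec.wm_followup_between_scale
            probs = np.where(same, p_within, p_between)
            lam = spec.samples_per_seed * probs[iu, ju]
            draws = rng.poisson(lam)
            counts = np.zeros((n_nodes, n_nodes), dtype=np.int64)
            counts[iu, ju] = draws
            counts += counts.T
            out.append(
                StreamlineMatrix(
                    subject_id=subject.id,
                    timepoint=tp,
                    node_labels=list(labels),
                    counts=counts,
                    samples_per_seed=spec.samples_per_seed,
                )
            )
    return out


def generate_lymphocytes(cohort: Cohort, spec: ScenarioSpec) -> list[LymphocytePanel]:
    """Baseline and follow-up lymphocyte panels for the DMF arm.

    Follow-up counts are mean-matched zero-truncated normal draws at the
    planted subgroup levels; baseline = follow-up − Δ with Δ drawn at the
    planted per-subgroup change (CD8's Δ is driven by the subject's shared
    latent factor, which also couples to atrophy in rate-mode scenarios).
    The study design has flow-cytometry panels only for DMF-treated subjects.
    """
    rng = _stage_rng(spec.seed, "lymphocytes")
    z_cd8 = _z_cd8_of(cohort, rng)
    panels: list[LymphocytePanel] = []
    for subject in cohort:
        subgroup = _subgroup_of(cohort, subject)
        if subgroup not in spec.lymph_spec:
            continue
        subset_specs = spec.lymph_spec[subgroup]
        followup: dict[str, float] = {}
        baseline: dict[str, float] = {}
        for subset, sub in subset_specs.items():
            fu = float(truncated_normal(sub.followup_mean, sub.followup_sd, 1, rng)[0])
            if subset == "cd8":
                delta = sub.delta_mean + sub.delta_sd * float(z_cd8.loc[subject.id])
            else:
                delta = sub.delta_mean + sub.delta_sd * float(rng.standard_normal())
            followup[subset] = fu
            baseline[subset] = max(fu - delta, 0.0)
        for tp, counts in (("baseline", baseline), ("followup", followup)):
            panels.append(
                LymphocytePanel(subject_id=subject.id, timepoint=tp, **counts)
            )
    return panels


@dataclass
class SyntheticDataset:
    """Bundle of all generated products plus run metadata."""

    cohort: Cohort
    thickness: ThicknessTable | None
    streamlines: list[StreamlineMatrix] | None
    lymphocytes: list[LymphocytePanel] | None
    metadata: dict


def generate_dataset(
    spec: ScenarioSpec,
    include: Sequence[str] = ("thickness", "streamlines", "lymphocytes"),
) -> SyntheticDataset:
    """Generate the full dataset (or a subset of stages) for one scenario."""
    cohort = generate_cohort(spec)
    thickness = generate_thickness(cohort, spec) if "thickness" in include else None
    streamlines = (
        generate_streamlines(cohort, spec) if "streamlines" in include else None
    )
    lymphocytes = (
        generate_lymphocytes(cohort, spec) if "lymphocytes" in include else None
    )
    metadata = {
        "seed": spec.seed,
        "seed_splitting": "SeedSequence(master).spawn per stage "
        + str(_STAGES),
        "calibration_mode": spec.calibration_mode,
        "longitudinal_mode": spec.longitudinal_mode,
        "arm_sizes": dict(spec.arm_sizes),
        "responder_split": dict(spec.responder_split),
        "note": "baseline lymphocyte means derived as follow-up minus planted delta; "
        "symmetrization rule for streamline IO: max(i,j),(j,i)",
    }
    return SyntheticDataset(cohort, thickness, streamlines, lymphocytes, metadata)
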