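# Methods

This note documents the models and procedures implemented in `msbrainnet`,
the calibration of the synthetic cohort generator, the numerical choices,
and what the test suite does and does not establish about real data.

## Annualized cortical atrophy

Regional thickness change between two scans is summarized as the
symmetrized annualized percent change

    rate = 100 · (t1 − t0) / (Δt · (t0 + t1) / 2)        [% / year]

with Δt the scan interval in years. The pair-average denominator was chosen
over a baseline-only denominator because it makes the measure exactly
antisymmetric under swapping the timepoints and invariant to thickness unit
rescaling; for realistic changes (a few percent) the two conventions differ
only in the second decimal. Rates are reported in percent (a −2.4 value
means 2.4% thickness loss per year), and a subject's summary value is the
mean over regions.

Group differences are assessed per region by ordinary least squares
`rate ~ group + age + sex` (age mean-centered, sex a single indicator).
Family-wise error across regions is controlled by max-|t| permutation: the
group labels are permuted (covariates fixed), the maximum |t| across
regions is recorded per permutation, and each region's adjusted p is the
fraction of permutations (plus one) whose maximum reaches its observed |t|.
Adjusted p-values are therefore floored at 1/(n_perm + 1), monotone in the
raw p, and calibrated by construction (verified empirically in the suite:
family-wise error ≤ 5% under the null). The t statistics are computed via
Frisch–Waugh residualization — covariates are projected out of the rates
once and out of each permuted predictor — which is algebraically identical
to refitting the full model and fast enough for 10⁴ permutations. This
region-level permutation scheme is the package's analog of vertex-wise
cluster-based Monte Carlo correction, which requires surface geometry that
tabular regional data does not carry.

## Modularity core

Community structure is quantified by Newman–Girvan modularity with weighted
degrees,

    Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j),

and optimized by the leading-eigenvector method: recursive bisection along
the dominant eigenvector of the generalized modularity matrix
`B(g)_ij = B_ij − δ_ij Σ_{l∈g} B_il` (the degree-preserving correction that
makes the Q change of a subdivision exact and prevents spurious splits).
Each candidate bisection is refined by a Kernighan–Lin pass (every node
flipped once, best gain first, best intermediate state kept, repeated to
convergence) and accepted only if it strictly increases Q. Connected
components are taken as the initial modules and subdivided independently.

Recursive bisection alone can miss optima whose modules straddle the first
cut, so after the recursion a global refinement alternates with renewed
subdivision attempts until a fixed point: a multiway Kernighan–Lin pass
over the full partition in which the candidate moves are single-node
relocations *and joint relocations of both endpoints of an edge* (one spare
empty module is always on offer, so passes can carve out new modules). The
pair moves matter because splitting off a connected pair is invisible to
single-node search — each lone endpoint move loses Q. All steps are
deterministic: the eigensolver is `numpy.linalg.eigh` on a symmetric
matrix, eigenvector entries within 1e-10 of zero are assigned to the
positive side, and argmax ties resolve to the first index. On exhaustive
comparisons against the brute-force optimizer (all set partitions,
restricted-growth-string enumeration) over hundreds of random graphs of up
to 8 nodes the heuristic attains the optimum or stays within a few percent
of it; the suite asserts Q_spectral ≥ 0.95 · Q_optimal on its sweeps and
exact equality on clique families. Fine-tuning can be disabled
(`fine_tune=False`) for comparability with bare leading-eigenvector
implementations.

Proportional density thresholding keeps exactly `floor(d · N(N−1)/2)`
strongest off-diagonal entries as unweighted edges (227 of 2278 at d = 0.10
for N = 68). Edges are ranked by signed value, so negative correlations are
effectively excluded at the studied densities — the dominant convention for
structural covariance networks — with a config switch for absolute-value
ranking. Ties break by (row, column) order, making the graph deterministic.

## Gray-matter covariance networks

A covariance network for a group and timepoint is the 68×68 Pearson
correlation matrix of regional thickness across the group's subjects
(minimum 4). Optional covariate adjustment (residuals of thickness ~ age +
sex) is off by default. The modularity-vs-density curve applies the
threshold-then-partition pipeline over a grid, by default 0.10 to 0.50 in
steps of 0.05; module counts are read at the reference density 0.15, the
sparsest grid point at which the planted follow-up modules stay internally
dense enough to be indivisible. Baseline and follow-up curves are compared
by a paired t-test across the density grid — the grid is the only repeated
measure available when there is one network per timepoint — with the
trapezoidal area under the ΔQ curve emitted as a secondary summary.

A geometric caveat documented here because it is easy to trip over: a
module count read at density d can only reflect planted modules whose
within-module pair count exceeds d · N(N−1)/2. Two planted modules of 34
regions (1122 within pairs) cannot survive a 0.15 threshold (341 edges)
intact; their subgraphs fragment, and the planted pair is visible only near
density 0.5. The five-module follow-up structure (429 within pairs) is the
configuration the reference density is matched to.

## White-matter streamline networks

Streamline counts are divided by the number of samples drawn per seed
(default 5000) to give connection probabilities; the retention filter zeros
weights below 10% and keeps the boundary value ("at least 10 percent").
The filter maps a voxel-level spurious-connection rule onto matrix-level
data — the granularity this package models — and is idempotent and
invariant to proportional rescaling of counts and samples. Modularity is
computed on the retained *weighted* matrix by default (binarization is a
switch); a subject whose retained graph is empty yields a flagged result
with missing Q that longitudinal comparisons exclude with a warning.
Baseline/follow-up comparisons are paired t-tests across subjects on Q.
Raw probability weights are used as-is: no log transform or hemispheric
normalization, since no convention for them is established for this data
type.

## Responder stratification

Non-responder = MRI activity (new/enlarging T2 or Gd-enhancing lesions) OR
clinical relapse OR EDSS disability progression; responder otherwise. EDSS
progression uses baseline-dependent thresholds: ≥1.5 points from baseline
0, ≥1.0 point from the middle band, ≥0.5 points from baseline > 5.0. The
conventional middle band 0 < baseline ≤ 5.0 is the default; the literal
reading of the published rule (a 1.0-point threshold only at baseline
exactly 1.5, leaving other mid-range baselines without a progression rule)
is selectable, because the published sentence is ambiguous and most
plausibly a typo for the conventional band. Progression confirmation
("sustained" over a confirmation visit) is not modeled: the data model has
a single follow-up assessment.

## Immune statistics

Between-group subset comparisons are Mann–Whitney U tests on follow-up
counts, exact enumeration when both groups have ≤8 subjects and no ties,
normal approximation with tie correction otherwise; fully tied data
degenerates to p = 1 with a warning rather than an error. Within-group
changes are Wilcoxon signed-rank tests on follow-up − baseline differences
with zero differences dropped. Tests are two-sided at α = 0.05.

The atrophy–lymphocyte association fits, per region, `rate ~ Δcount + age +
sex` and reports the slope, the partial R² of the count term, and max-|t|
permutation-adjusted p-values; the peak region is the largest partial R².
A peak-*region* R² is the tabular analog of a peak-vertex R². The same
entry point accepts absolute counts in place of Δ counts.

## Synthetic cohort generator

The generator is the package's test bed: it plants the statistical
structure of a two-arm observational cohort and every downstream stage is
validated by recovering the planted parameters.

**Cohort.** Default arm sizes 42 (DMF) and 36 (NAT). Disease-activity flags
are assigned to match an exact breakdown — DMF: 15 MRI-active, 17
relapsing, 7 both (hence 25 active by inclusion–exclusion, 17 quiet); NAT:
7/10/4 (13 active). Demographics are normal draws at the planted arm means
(ages clipped to the 18–60 inclusion window; durations and intervals
truncated at 1 and 3 months). EDSS follow-up changes are capped at +0.5
(and ≤0 above EDSS 5), below every progression threshold, so activity is
carried entirely by the MRI/relapse flags — a cohort with no isolated
disability progression. Lesion volumes are planted per subgroup; the
active-DMF subgroup uses the published subgroup means (11.2 → 12.3 mL) and
the quiet-DMF means are derived so the whole arm matches its published
arm-level values.

**Positive-support draws.** Cell counts and lesion volumes use a
zero-truncated normal whose *truncated* mean is solved to equal the planted
mean (a naive truncated normal at, e.g., mean 12.3 and SD 8.2 would be
biased upward by ~9%). The printed SDs are used as the pre-truncation
scale. SD = 0 degenerates to the constant.

**Lymphocytes.** Follow-up CD8 is planted per subgroup (responders 197.7 ±
97.1, non-responders 298.4 ± 190.6 cells/μl); baseline = follow-up − Δ with
Δ planted at −206 (responders) and −158 (non-responders), SD 80 (the SD of
Δ is not published; 80 is a realistic repeat-measurement spread). Baselines
are therefore derived quantities — their per-subgroup means are not
published. Each subject's CD8 Δ is driven by a shared latent factor that
the thickness generator can couple to. Other subsets (CD3, CD4, CD56,
CD19, ALC) have no published subgroup means; the defaults are one-time
choices at realistic DMF-lymphopenia levels, identical across subgroups,
with follow-up below baseline in distribution. Panels exist only for the
DMF arm, matching the study design.

**Thickness.** Baseline log-thickness is `log 2.5 mm + 0.1 · field`, where
the field gives cross-subject correlation r_w = 0.9 within planted modules
and r_b = 0.0 between (via shared, module-level and region-level standard
normal factors); 0.1 on the log scale ≈ 0.25 mm at 2.5 mm. Gray-matter
module layouts are planted per arm and timepoint (DMF: 2 modules at
baseline, 5 at follow-up; NAT: 3 → 2) as contiguous equal blocks.

Two *longitudinal modes* exist because two desiderata are mutually
exclusive. In **field mode** (default) each timepoint's field carries its
own planted module structure, and each subject's follow-up is rescaled by a
Newton-solved factor so that the subject's mean regional annualized change
equals their planted rate exactly; this is the mode for covariance-network
scenarios, since a follow-up defined as a ~3% perturbation of baseline
would inherit the baseline's covariance structure and could never show a
different module layout. In **rate mode** the follow-up is derived
region-wise from baseline through the exact inverse of the
annualized-change formula, `t1 = t0 (1 + k)/(1 − k)` with `k = rate ·
Δt/200`, plus region-level rate noise (SD 0.3 %/yr); this is the mode for
atrophy-coupling scenarios, where five designated regions get rates
correlated at ρ = 0.7 with the subject's latent CD8 factor (so their
partial R² recovers ρ² ≈ 0.49). The exact-inverse construction was chosen
over the naive `t0 (1 + rate · Δt/100)` so the analysis formula recovers
planted rates without a second-order bias. Per-subject rates are drawn at
the planted subgroup mean with SD 1.0 %/yr (not published; a field-typical
between-subject spread).

**Atrophy calibration modes.** The published whole-arm means (−2.4 DMF,
−2.1 NAT) and the published DMF subgroup means (−1.7 at n = 17, −3.2 at
n = 25) are arithmetically inconsistent (the subgroup means average to
−2.59, not −2.4), so the generator has two calibration modes — "group"
plants the arm-level values, "subgroup" the subgroup values — and each
recovery check uses the matching mode.

**Streamlines.** Counts are Poisson with mean `samples_per_seed × block
probability` on a 116-node planted block model (4 modules, within 0.4,
between 0.01), symmetrized with zero diagonal. Follow-up within- and
between-block probabilities can be scaled to plant longitudinal contrast
changes; the default plants none.

**Determinism.** One master seed; per-stage child generators derive from
`SeedSequence(master).spawn` (cohort/thickness/streamlines/lymphocytes),
recorded in run metadata. Identical spec ⇒ bit-identical dataset.

## What the synthetic tests do and do not show

The generator emulates first and second moments and block/modular
structure, not real cortical geometry: no spatial autocorrelation along the
cortex, no hemispheric symmetry beyond the label layout, Gaussian
log-thickness rather than real morphometric distributions, Poisson counts
rather than tractography's distance and curvature biases, activity flags
as exact planted sets rather than stochastic clinical events. Passing the
recovery suite therefore shows that the *pipeline* is correct and
calibrated — that it recovers what was planted at the stated sample sizes —
not that the scientific findings would replicate on new patients. Power
findings transfer only in order of magnitude; for instance the planted
responder/non-responder CD8 gap at n = 17/25 is detected in roughly half
of generated cohorts, which is consistent with the marginal significance
reported for the real cohort.

## Problem sizes in the shipped checks

The acceptance script averages 200 replicate cohorts for moment-recovery
quantities (SE of the recovered CD8 mean ≈ 1.7 cells/μl, of the atrophy
means ≈ 0.011 %/yr) and 20 seeds for the modal module count; the test
suite uses 10⁴–10⁵ draws for law-of-large-numbers checks and a few hundred
replicates for error-rate calibration. These sizes put Monte-Carlo error
well inside each stated tolerance while keeping the full run in minutes on
one CPU.

## Known limitations

- Vertex-level inference (cluster extent, surface smoothing) is out of
  scope; region-level max-statistic permutation is the implemented analog.
- The paired t-test across a density grid treats grid points as exchangeable
  repeated measures; neighboring densities are correlated, so its p-value
  is an approximation (the AUC summary is provided as an alternative).
- The spectral partitioner is a deterministic heuristic; on rare small
  graphs it can stop a few percent short of the global optimum.
- Mann–Whitney exact enumeration is used only for ≤8 per group without
  ties; with ties it falls back to the tie-corrected normal approximation
  even at small n.
- Single follow-up assessment: no confirmed/sustained progression, no
  time-to-event modeling.
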