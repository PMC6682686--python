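# msbrainnet

Structural brain-network and immune-cell response analysis for longitudinal
multiple-sclerosis (MS) therapy cohorts.

The package addresses a question from MS treatment monitoring: when patients
start a disease-modifying drug (here dimethyl fumarate, DMF, with natalizumab,
NAT, as a reference arm), which of them show a favorable *structural* brain
response, and how does that response track their peripheral immune-cell
dynamics? It works entirely on derived tabular data — regional cortical
thickness, streamline-count connectomes, lymphocyte panels, clinical
timelines — and provides:

- **Annualized cortical atrophy rates.** Per region and subject,
  `rate = 100 (t1 − t0) / (Δt · (t0 + t1)/2)` in % per year (Δt in years),
  with group comparisons by a per-region GLM `rate ~ group + age + sex` and
  family-wise max-|t| permutation correction.
- **Gray-matter structural covariance networks.** 68-region Pearson
  correlation matrices of thickness across a group, proportionally
  thresholded over a density grid (0.10–0.50) and summarized by modularity.
- **White-matter streamline networks.** Per-subject 116-node
  connection-probability matrices (counts / samples per seed), a ≥10%
  retention filter, and weighted modularity per subject.
- **Newman spectral modularity.** A from-scratch leading-eigenvector
  partitioner maximizing
  `Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j)`
  by recursive bisection on the generalized modularity matrix, with
  Kernighan–Lin fine-tuning, a global multiway refinement, and an exhaustive
  brute-force oracle for small graphs.
- **NEDA-style responder stratification.** Non-responder = any of MRI
  activity, relapse, or baseline-dependent EDSS progression.
- **Lymphocyte statistics.** Mann–Whitney / Wilcoxon subset comparisons and
  a per-region GLM associating atrophy with ΔCD8/ΔCD4 (Δ = follow-up −
  baseline), max-|t| corrected.
- **A synthetic cohort generator** that plants all of the above structure
  (arm sizes, activity breakdowns, subgroup CD8 depletion, atrophy rates,
  covariance modules, weighted connectome blocks) so every analysis stage
  has a parameter-recovery test surface.

## Worked example

```python
import msbrainnet as mb

spec = mb.ScenarioSpec(seed=1)            # default study calibration
cohort = mb.generate_cohort(spec)

result = mb.classify_responders(mb.records_from_cohort(cohort.arm("DMF")))
print(result.n_non_responders, result.n_responders)   # -> 25 17
print(result.breakdown)
# -> {'mri_only': 8, 'relapse_only': 10, 'mri_and_relapse': 7, 'progression_only': 0}

thickness = mb.generate_thickness(cohort, spec)
amap = mb.build_atrophy_map(thickness, cohort)
dmf = [s.id for s in cohort if s.arm == "DMF"]
print(round(mb.mean_cortical_atrophy(amap, dmf), 2))  # -> -2.23  (%/yr)
```

The stratification recovers 25 DMF non-responders and 17 responders exactly
from the planted activity breakdown (15 MRI-active + 17 relapsing − 7
overlapping = 25 by inclusion–exclusion). The mean DMF atrophy for one
42-subject cohort (−2.23 %/yr here) scatters around the planted −2.4 %/yr
with an SE of about 0.15; averaging replicate cohorts converges on the
planted value. The `examples/` directory has one narrative script per
capability (simulation, stratification, atrophy, GM networks, WM networks,
immune statistics); each prints the numbers it computes and what they mean.

A thin CLI mirrors the pipeline stages:

```bash
msbrainnet simulate --seed 1 --out data/
msbrainnet stratify --cohort data/cohort.tsv --out results/
msbrainnet atrophy --cohort data/cohort.tsv --thickness data/thickness.tsv --out results/
```

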