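"""Per-subject white-matter networks from streamline counts.

Counts come from a planted weighted block model (Poisson around
samples-per-seed x block probability, 116 nodes, 4 modules). The retention
filter keeps connections carrying at least 10% of the streamline samples;
modularity is computed on the retained weighted matrix per subject and
compared between timepoints with a paired t-test.
"""
import msbrainnet as mb

spec = mb.ScenarioSpec(
    seed=1,
    arm_sizes={"DMF": 6, "NAT": 2},
    responder_split={"DMF_R": 3, "DMF_NR": 3, "NAT_active": 1},
    activity_breakdown={"DMF": (2, 2, 1), "NAT": (1, 0, 0)},
)
cohort = mb.generate_cohort(spec).arm("DMF")
matrices = mb.generate_streamlines(cohort, spec)

results = {"baseline": [], "followup": []}
for mat in matrices:
    res = mb.subject_modularity(mat, threshold_fraction=0.10)
    results[mat.timepoint].append(res)
    if mat.timepoint == "baseline":
        print(f"{mat.subject_id} baseline: Q = {res.q:.3f}, "
              f"{res.n_modules} modules, retained {res.retained_edge_fraction:.0%} of edges")

comp = mb.compare_subjects_longitudinal(results["baseline"], results["followup"])
print(f"\nfollow-up minus baseline: mean dQ = {comp.mean_delta_q:+.4f}, "
      f"t = {comp.t:.2f}, p = {comp.p_value:.3f} (n = {comp.n_pairs})")
# Default scenario plants no longitudinal change, so dQ hovers at zero;
# Q ~ 0.75 is the signature of 4 equal modules with between-module edges
# removed by the filter.
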