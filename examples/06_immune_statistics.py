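"""Lymphocyte-subset statistics and the CD8-atrophy association.

Responders show a deeper CD8+ depletion than non-responders (planted
follow-up means 197.7 vs 298.4 cells/ul, deltas -206 vs -158). The
association analysis regresses regional atrophy on each subject's CD8
change, adjusting for age and sex, with max-|t| permutation correction;
the rate-mode generator plants correlation 0.7 in five designated regions,
so their partial R^2 recovers about 0.49.
"""
import numpy as np

import msbrainnet as mb

spec = mb.ScenarioSpec(seed=3, longitudinal_mode="rate")
cohort = mb.generate_cohort(spec)
panels = mb.generate_lymphocytes(cohort, spec)
sub = cohort.annotations["subgroup"]

p_r = [p for p in panels if sub.loc[p.subject_id] == "DMF_R"]
p_nr = [p for p in panels if sub.loc[p.subject_id] == "DMF_NR"]
test = mb.between_group_subset_test(p_r, p_nr, "cd8", label="DMF_R vs DMF_NR")
fu = [p.cd8 for p in p_r if p.timepoint == "followup"]
fu_nr = [p.cd8 for p in p_nr if p.timepoint == "followup"]
print(f"follow-up CD8: responders {np.mean(fu):.0f}, "
      f"non-responders {np.mean(fu_nr):.0f} cells/ul; "
      f"Mann-Whitney U = {test.statistic:.0f}, p = {test.p_value:.3f}")

paired = mb.within_group_paired_test(panels, "cd8")
print(f"CD8 follow-up vs baseline (all DMF): Wilcoxon p = {paired.p_value:.2g}")

thickness = mb.generate_thickness(cohort, spec)
ids = [s.id for s in cohort.arm("DMF")]
amap = mb.build_atrophy_map(thickness.subset(ids), cohort)
deltas = mb.panel_deltas(panels, "cd8")
assoc = mb.atrophy_lymphocyte_association(
    amap, deltas, n_perm=999, rng=np.random.default_rng(0)
)
peak = assoc.table.set_index("region").loc[assoc.peak_region]
print(f"peak association region: {assoc.peak_region} "
      f"(partial R^2 = {peak['partial_r2']:.2f}, adjusted p = {peak['p_adj']:.3g})")
# Positive slope: a smaller CD8 decline goes with less atrophy reduction —
# i.e. stronger depletion accompanies lower atrophy rates.
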