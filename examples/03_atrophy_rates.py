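"""Annualized cortical atrophy rates and the DMF-vs-NAT group comparison.

The longitudinal measure per region is the symmetrized annualized percent
change, 100 (t1 - t0) / (years * mean(t0, t1)), in % per year. Negative
values are thinning. The group comparison fits rate ~ group + age + sex per
region and corrects across the 68 regions with a max-|t| permutation test.
"""
import numpy as np

import msbrainnet as mb

spec = mb.ScenarioSpec(seed=1, calibration_mode="group")
cohort = mb.generate_cohort(spec)
thickness = mb.generate_thickness(cohort, spec)
amap = mb.build_atrophy_map(thickness, cohort)

for arm in ("DMF", "NAT"):
    ids = [s.id for s in cohort if s.arm == arm]
    print(f"{arm} mean cortical atrophy: {mb.mean_cortical_atrophy(amap, ids):+.2f} %/yr")
# The generator plants -2.4 (DMF) and -2.1 (NAT); one cohort of 42/36
# subjects scatters around those by ~0.15 %/yr.

arms = [s.arm for s in cohort]
res = mb.regional_group_comparison(amap, arms, n_perm=999, rng=np.random.default_rng(1))
n_sig = int((res.table["p_adj"] < 0.05).sum())
print(f"regions with adjusted p < 0.05: {n_sig} of 68 "
      f"(planted arm gap 0.3 %/yr is small relative to SD 1 %/yr)")
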