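"""Synthetic cohort generator: planted structure and determinism."""
import numpy as np
import pytest

from msbrainnet import (
    ScenarioSpec,
    SpecError,
    generate_cohort,
    generate_dataset,
    generate_lymphocytes,
    generate_streamlines,
    generate_thickness,
    planted_partition,
    truncated_normal,
)
from msbrainnet.immune import panel_deltas


class TestCohort:
    def test_default_arm_sizes(self, default_spec):
        cohort = generate_cohort(default_spec)
        assert len(cohort.arm("DMF")) == 42
        assert len(cohort.arm("NAT")) == 36

    def test_activity_flag_breakdown(self, default_spec):
        cohort = generate_cohort(default_spec)
        dmf = cohort.arm("DMF").subjects
        assert sum(s.mri_activity_flag for s in dmf) == 15
        assert sum(s.relapse_flag for s in dmf) == 17
        assert sum(s.mri_activity_flag and s.relapse_flag for s in dmf) == 7
        assert sum(s.has_activity for s in dmf) == 25  # inclusion-exclusion
        nat = cohort.arm("NAT").subjects
        assert sum(s.has_activity for s in nat) == 7 + 10 - 4

    def test_micro_cohort(self, micro_spec):
        cohort = generate_cohort(micro_spec)
        assert len(cohort) == 4

    def test_inconsistent_split_rejected(self):
        with pytest.raises(SpecError, match="responder_split"):
            ScenarioSpec(responder_split={"DMF_R": 10, "DMF_NR": 25, "NAT_active": 13})

    def test_inconsistent_breakdown_rejected(self):
        with pytest.raises(SpecError):
            ScenarioSpec(activity_breakdown={"DMF": (15, 17, 3), "NAT": (7, 10, 4)})

    def test_demographics_within_bounds(self, default_spec):
        for s in generate_cohort(default_spec):
            assert 18 <= s.age <= 60
            assert s.followup_interval > 0
            assert s.edss_baseline * 2 == int(s.edss_baseline * 2)


class TestDeterminism:
    def test_identical_seed_gives_bit_identical_dataset(self, micro_spec):
        ds1 = generate_dataset(micro_spec)
        ds2 = generate_dataset(micro_spec)
        assert ds1.cohort.frame().equals(ds2.cohort.frame())
        assert np.array_equal(ds1.thickness.values, ds2.thickness.values)
        for m1, m2 in zip(ds1.streamlines, ds2.streamlines):
            assert np.array_equal(m1.counts, m2.counts)
        for p1, p2 in zip(ds1.lymphocytes, ds2.lymphocytes):
            assert vars(p1) == vars(p2)

    def test_different_seed_changes_data(self, micro_spec):
        other = ScenarioSpec(**{**vars(micro_spec), "seed": micro_spec.seed + 1})
        assert not np.array_equal(
            generate_thickness(generate_cohort(micro_spec), micro_spec).values,
            generate_thickness(generate_cohort(other), other).values,
        )


class TestTruncatedNormal:
    def test_matched_mean_large_sample(self):
        rng = np.random.default_rng(0)
        draws = truncated_normal(12.3, 8.2, 200_000, rng)
        assert draws.min() >= 0
        assert draws.mean() == pytest.approx(12.3, abs=0.06)

    def test_zero_sd_degenerates_to_constant(self):
        rng = np.random.default_rng(0)
        assert np.all(truncated_normal(5.0, 0.0, 10, rng) == 5.0)


class TestThickness:
    def test_within_module_correlation_recovered(self):
        """r_w = 0.9, r_b = 0 planted -> empirical within-module r ~ 0.9."""
        n = 200
        spec = ScenarioSpec(
            seed=21,
            arm_sizes={"DMF": n, "NAT": 2},
            responder_split={"DMF_R": n // 2, "DMF_NR": n - n // 2, "NAT_active": 1},
            activity_breakdown={"DMF": (60, 60, 20), "NAT": (1, 0, 0)},
        )
        cohort = generate_cohort(spec)
        table = generate_thickness(cohort, spec)
        dmf_rows = [table.subject_ids.index(s.id) for s in cohort.arm("DMF")]
        base = table.values[dmf_rows, :, 0]
        r = np.corrcoef(base, rowvar=False)
        part = planted_partition(68, spec.gm_modules["DMF"]["baseline"])
        same = part[:, None] == part[None, :]
        iu = np.triu_indices(68, 1)
        within = r[iu][same[iu]]
        between = r[iu][~same[iu]]
        assert within.mean() == pytest.approx(0.9, abs=0.05)
        assert abs(between.mean()) < 0.05

    def test_zero_rate_in_rate_mode_keeps_followup_equal_to_baseline(self, micro_spec):
        spec = ScenarioSpec(
            **{
                **vars(micro_spec),
                "longitudinal_mode": "rate",
                "atrophy_means_group": {"DMF": 0.0, "NAT": 0.0},
                "atrophy_sd": 0.0,
                "region_rate_sd": 0.0,
                "coupling_rho": 0.0,
            }
        )
        cohort = generate_cohort(spec)
        table = generate_thickness(cohort, spec)
        assert np.array_equal(table.values[:, :, 0], table.values[:, :, 1])

    @pytest.mark.parametrize("mode", ["field", "rate"])
    def test_subgroup_mean_rate_recovered_at_large_n(self, mode):
        """Planted subgroup atrophy means recovered by the analysis formula."""
        from msbrainnet import build_atrophy_map, mean_cortical_atrophy

        n = 2000
        spec = ScenarioSpec(
            seed=22,
            calibration_mode="subgroup",
            longitudinal_mode=mode,
            arm_sizes={"DMF": n, "NAT": 2},
            responder_split={"DMF_R": n // 2, "DMF_NR": n // 2, "NAT_active": 1},
            activity_breakdown={"DMF": (n // 2, n // 2, n // 2), "NAT": (1, 0, 0)},
        )
        cohort = generate_cohort(spec)
        table = generate_thickness(cohort, spec)
        amap = build_atrophy_map(table, cohort)
        sub = cohort.annotations["subgroup"]
        for group, planted in [("DMF_R", -1.7), ("DMF_NR", -3.2)]:
            ids = [i for i in cohort.ids if sub.loc[i] == group]
            assert mean_cortical_atrophy(amap, ids) == pytest.approx(
                planted, abs=0.05
            )


class TestStreamlines:
    def test_strong_contrast_retention_keeps_only_within_module_edges(self, micro_spec):
        spec = ScenarioSpec(**{**vars(micro_spec), "seed": 31})
        cohort = generate_cohort(spec)
        mat = generate_streamlines(cohort, spec, timepoints=("baseline",))[0]
        from msbrainnet import retention_filter

        adj = retention_filter(mat, 0.10)
        part = planted_partition(116, spec.wm_n_modules)
        same = part[:, None] == part[None, :]
        assert np.all(adj.weights[~same] == 0)  # between-module edges all dropped
        within_mask = same & ~np.eye(116, dtype=bool)
        assert np.all(adj.weights[within_mask] > 0)  # Poisson(2000) never below 500

    def test_zero_probabilities_give_zero_matrix(self, micro_spec):
        spec = ScenarioSpec(
            **{**vars(micro_spec), "wm_p_within": 0.0, "wm_p_between": 0.0}
        )
        mats = generate_streamlines(generate_cohort(spec), spec)
        assert all(np.all(m.counts == 0) for m in mats)

    def test_bad_block_probability_rejected(self, micro_spec):
        with pytest.raises(SpecError):
            ScenarioSpec(**{**vars(micro_spec), "wm_p_within": 1.4})

    def test_counts_symmetric_zero_diagonal(self, micro_spec):
        mat = generate_streamlines(generate_cohort(micro_spec), micro_spec)[0]
        assert np.array_equal(mat.counts, mat.counts.T)
        assert np.all(np.diag(mat.counts) == 0)


class TestLymphocytes:
    def test_planted_followup_mean_recovered_large_n(self):
        n = 20_000
        spec = ScenarioSpec(
            seed=41,
            arm_sizes={"DMF": n, "NAT": 2},
            responder_split={"DMF_R": n, "DMF_NR": 0, "NAT_active": 1},
            activity_breakdown={"DMF": (0, 0, 0), "NAT": (1, 0, 0)},
        )
        cohort = generate_cohort(spec)
        panels = generate_lymphocytes(cohort, spec)
        fu = np.array([p.cd8 for p in panels if p.timepoint == "followup"])
        assert len(fu) == n
        assert fu.mean() == pytest.approx(197.7, abs=2.0)

    def test_planted_delta_recovered(self):
        n = 20_000
        spec = ScenarioSpec(
            seed=42,
            arm_sizes={"DMF": n, "NAT": 2},
            responder_split={"DMF_R": n, "DMF_NR": 0, "NAT_active": 1},
            activity_breakdown={"DMF": (0, 0, 0), "NAT": (1, 0, 0)},
        )
        cohort = generate_cohort(spec)
        deltas = panel_deltas(generate_lymphocytes(cohort, spec), "cd8")
        assert deltas.mean() == pytest.approx(-206.0, abs=2.0)

    def test_zero_sd_spec_gives_constant_draws(self, micro_spec):
        from msbrainnet import LymphSubsetSpec

        lymph = {
            "DMF_R": {"cd8": LymphSubsetSpec(200.0, 0.0, -100.0, 0.0)},
            "DMF_NR": {"cd8": LymphSubsetSpec(300.0, 0.0, -100.0, 0.0)},
        }
        spec = ScenarioSpec(**{**vars(micro_spec), "lymph_spec": lymph})
        cohort = generate_cohort(spec)
        panels = generate_lymphocytes(cohort, spec)
        sub = cohort.annotations["subgroup"]
        for p in panels:
            expected = 200.0 if sub.loc[p.subject_id] == "DMF_R" else 300.0
            if p.timepoint == "baseline":
                expected += 100.0
            assert p.cd8 == pytest.approx(expected)

    def test_followup_below_baseline_in_distribution(self, default_spec):
        cohort = generate_cohort(default_spec)
        panels = generate_lymphocytes(cohort, default_spec)
        for subset in ("cd3", "cd4", "cd8", "alc"):
            assert panel_deltas(panels, subset).mean() < 0
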