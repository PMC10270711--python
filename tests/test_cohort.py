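"""Synthetic cohort generator: determinism, covariate medians, planted effects."""

import numpy as np
import pandas as pd
import pytest

from netclass.cohort import (
    CohortSpec,
    CohortSpecError,
    PlantedEffect,
    generate_cohort,
    resolve_effects,
    simulate_covariates,
    simulate_roi_timeseries,
    base_roi_correlation,
)
from netclass.functional import roi_connectivity

from conftest import tiny_spec


class TestSpecValidation:
    def test_default_spec_counts_total_cohort(self):
        spec = CohortSpec()
        assert spec.n_subjects == 99 + 47 + 38 + 34 + 42 + 38 == 298
        assert spec.tr_seconds == 2.0
        assert spec.n_roi == 116

    @pytest.mark.parametrize(
        "overrides, field",
        [
            (dict(group_sizes=(0, 0)), "group_sizes"),
            (dict(group_names=("A", "A")), "group_names"),
            (dict(n_timepoints=5), "n_timepoints"),
            (dict(grid_dims=(0, 6, 6)), "grid_dims"),
            (
                dict(effect_plan=(PlantedEffect("functional", ("edge", 0, 99), ("HC",), 1.0),)),
                "target",
            ),
            (
                dict(effect_plan=(PlantedEffect("voxelmap", ("voxel", (99, 0, 0), 1), ("HC",), 1.0),)),
                "outside grid",
            ),
            (
                dict(effect_plan=(PlantedEffect("functional", ("edge", 0, 1), (), 1.0),)),
                "affected_groups",
            ),
        ],
    )
    def test_invalid_specs_name_the_offending_field(self, overrides, field):
        with pytest.raises(CohortSpecError, match=field):
            tiny_spec(**overrides)


class TestDeterminism:
    def test_same_seed_bit_identical_different_seed_differs(self):
        a, _ = generate_cohort(tiny_spec(seed=7))
        b, _ = generate_cohort(tiny_spec(seed=7))
        c, _ = generate_cohort(tiny_spec(seed=8))
        sid = a.subject_ids[0]
        assert np.array_equal(a.roi_timeseries[sid], b.roi_timeseries[sid])
        assert np.array_equal(a.fa_matrices[sid], b.fa_matrices[sid])
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        assert not np.array_equal(a.roi_timeseries[sid], c.roi_timeseries[sid])

    def test_ground_truth_records_every_planted_effect(self):
        plan = (
            PlantedEffect("functional", ("edge", 0, 1), ("bvFTD",), -1.0),
            PlantedEffect("voxelmap", ("voxel", (3, 3, 3), 1), ("bvFTD",), 2.0),
        )
        _, truth = generate_cohort(tiny_spec(effect_plan=plan))
        assert len(truth.entries) == len(plan)


class TestCovariates:
    def test_hc_and_bvftd_medians_converge_to_plan(self, rng):
        spec = tiny_spec()
        hc = simulate_covariates(spec, "HC", 4000, rng)
        assert hc["mmse"].median() == pytest.approx(30.0, abs=0.5)
        assert hc["cdr"].median() == pytest.approx(0.0, abs=0.01)
        bv = simulate_covariates(spec, "bvFTD", 4000, rng)
        assert bv["cdr"].median() == pytest.approx(1.0, abs=0.01)
        assert bv["mmse"].median() == pytest.approx(25.0, abs=0.5)
        assert set(bv["cdr"]).issubset({0.0, 0.5, 1.0, 2.0, 3.0})
        assert bv["mmse"].between(0, 30).all()

    def test_zero_scale_plan_is_degenerate(self, rng):
        spec = tiny_spec()
        nf = simulate_covariates(
            CohortSpec(
                group_names=("nfvPPA",),
                group_sizes=(5,),
                covariate_plan={"nfvPPA": spec.covariate_plan["nfvPPA"]},
                n_roi=4,
                seed=0,
            ),
            "nfvPPA",
            200,
            rng,
        )
        # CDR MAD is 0 for this group: every subject sits exactly at the median
        assert (nf["cdr"] == 0.5).all()

    def test_unknown_group_rejected(self, rng):
        with pytest.raises(CohortSpecError, match="group"):
            simulate_covariates(tiny_spec(), "nope", 5, rng)


class TestRoiTimeseries:
    def test_empirical_correlation_converges_to_base(self):
        spec = tiny_spec(n_timepoints=20000, sigma_subject_z=0.0)
        base = base_roi_correlation(spec)
        ts = simulate_roi_timeseries(spec, "HC", np.random.default_rng(0), base)
        emp = np.corrcoef(ts.T)
        assert np.abs(emp - base).max() < 0.06

    def test_planted_edge_lowers_group_mean_fisher_z(self):
        plan = (PlantedEffect("functional", ("edge", 0, 1), ("bvFTD",), -1.5),)
        cohort, _ = generate_cohort(tiny_spec(group_sizes=(30, 30), effect_plan=plan))
        z01 = {
            g: [
                roi_connectivity(cohort.roi_timeseries[s])[0, 1]
                for s in cohort.subjects.loc[cohort.subjects.group == g, "subject_id"]
            ]
            for g in ("HC", "bvFTD")
        }
        assert np.mean(z01["bvFTD"]) < np.mean(z01["HC"])

    def test_single_roi_gives_single_column(self):
        spec = tiny_spec(n_roi=1)
        ts = simulate_roi_timeseries(spec, "HC", np.random.default_rng(0))
        assert ts.shape == (spec.n_timepoints, 1)

    def test_effect_monotonicity_on_planted_edge(self):
        """Realized group-mean z differences grow with |effect size|."""
        gaps = []
        for d in (0.5, 1.0, 2.0):
            plan = (PlantedEffect("functional", ("edge", 0, 1), ("bvFTD",), -d),)
            cohort, _ = generate_cohort(
                tiny_spec(group_sizes=(40, 40), effect_plan=plan, seed=11)
            )
            z = {
                g: np.mean(
                    [
                        roi_connectivity(cohort.roi_timeseries[s])[0, 1]
                        for s in cohort.subjects.loc[
                            cohort.subjects.group == g, "subject_id"
                        ]
                    ]
                )
                for g in ("HC", "bvFTD")
            }
            gaps.append(z["HC"] - z["bvFTD"])
        assert gaps[0] < gaps[1] < gaps[2]


class TestVoxelAndStructural:
    def test_background_is_standard_normal(self):
        cohort, _ = generate_cohort(tiny_spec(grid_dims=(10, 10, 10)))
        vol = cohort.voxel_maps[cohort.subject_ids[0]]["gcor"]
        assert vol.shape == (10, 10, 10)
        assert abs(vol.mean()) < 0.1
        assert abs(vol.std() - 1.0) < 0.1

    def test_planted_cluster_shifts_group_mean_by_d(self):
        plan = (PlantedEffect("voxelmap", ("voxel", (3, 3, 3), 2), ("bvFTD",), 2.0, "gcor"),)
        spec = tiny_spec(group_sizes=(40, 40), effect_plan=plan)
        cohort, truth = generate_cohort(spec)
        idx = np.asarray(truth.entries[0]["voxel_indices"])
        means = {
            g: np.mean(
                [
                    cohort.voxel_maps[s]["gcor"].ravel()[idx].mean()
                    for s in cohort.subjects.loc[cohort.subjects.group == g, "subject_id"]
                ]
            )
            for g in ("HC", "bvFTD")
        }
        assert means["bvFTD"] - means["HC"] == pytest.approx(2.0, abs=0.35)

    def test_radius_zero_shifts_exactly_one_voxel(self):
        plan = (PlantedEffect("voxelmap", ("voxel", (2, 2, 2), 0), ("HC",), 1.0),)
        effects, truth = resolve_effects(tiny_spec(effect_plan=plan))
        assert len(truth.entries[0]["voxel_indices"]) == 1
        shift = effects.voxel["HC"]["gcor"]
        assert (shift != 0).sum() == 1

    def test_structural_matrix_invariants(self):
        cohort, _ = generate_cohort(tiny_spec())
        for sid in cohort.subject_ids[:5]:
            fa = cohort.fa_matrices[sid]
            assert np.allclose(fa, fa.T)
            assert np.all(np.diag(fa) == 0)
            assert fa.min() >= 0 and fa.max() <= 1
            assert list(cohort.tract_metrics[sid].columns) == [
                "fa", "ad", "rd", "md", "nqa", "iso", "rdi",
            ]

    def test_planted_tract_lowers_affected_group_fa(self):
        plan = (PlantedEffect("structural", ("tract", 2), ("bvFTD",), -1.0, "fa"),)
        cohort, _ = generate_cohort(tiny_spec(group_sizes=(40, 40), effect_plan=plan))
        means = {
            g: np.mean(
                [
                    cohort.tract_metrics[s].loc[2, "fa"]
                    for s in cohort.subjects.loc[cohort.subjects.group == g, "subject_id"]
                ]
            )
            for g in ("HC", "bvFTD")
        }
        assert means["bvFTD"] < means["HC"]
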