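"""Synthetic cohort generator: geometry, lesion growth, intensities, outcomes."""

import numpy as np
import pandas as pd
import pytest

from fivmap import outcome_models as om
from fivmap.parcellation import RelevanceTable, decompose_volumes
from fivmap.segmentation import segment_mirror_difference
from fivmap.synthetic import (
    CohortConfig,
    InfeasibleTargetError,
    InvalidConfigError,
    draw_covariates,
    generate_cohort,
    generate_lesion,
    generate_parcellation,
    render_intensity,
    simulate_outcomes,
)

from conftest import TEST_GRID


class TestParcellation:
    def test_default_has_66_symmetric_regions(self, parc):
        assert len(parc.regions) == 66
        assert set(np.unique(parc.labels)) - {0} == set(range(1, 67))
        counts = np.bincount(parc.labels.ravel(), minlength=67)
        for left_id in range(1, 34):
            assert counts[left_id] == counts[left_id + 33]

    def test_label_grid_mirror_symmetric_up_to_identity(self, parc):
        # reflecting a left-region voxel lands on its right homologue (id + 33)
        flipped = np.flip(parc.labels, axis=0)
        left_mask = (parc.labels >= 1) & (parc.labels <= 33)
        np.testing.assert_array_equal(flipped[left_mask], parc.labels[left_mask] + 33)

    def test_same_seed_is_bit_identical(self, small_config):
        a = generate_parcellation(small_config)
        b = generate_parcellation(small_config)
        np.testing.assert_array_equal(a.labels, b.labels)
        pd.testing.assert_frame_equal(a.regions, b.regions)

    def test_relevance_override_forces_class(self, small_config):
        cfg = CohortConfig(
            n_patients=1,
            seed=small_config.seed,
            relevance_override={i: "high" for i in range(1, 67)},
            **TEST_GRID,
        )
        p = generate_parcellation(cfg)
        lesion = generate_lesion(p, 80.0, seed=2)
        r = decompose_volumes(lesion, p, RelevanceTable.from_parcellation(p))
        assert r.fiv_mod == r.fiv_low == 0.0
        assert r.fiv_high == r.fiv_total

    def test_too_many_regions_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_parcellation(
                CohortConfig(n_patients=1, n_regions=200000, **TEST_GRID)
            )


class TestLesionGrowth:
    def test_zero_target_gives_empty_mask(self, parc):
        assert generate_lesion(parc, 0.0, seed=1).n_voxels == 0

    def test_small_lesion_is_pure_high(self, parc, relevance_table):
        r = decompose_volumes(generate_lesion(parc, 3.0, seed=4), parc, relevance_table)
        assert r.fiv_high == r.fiv_total > 0
        assert r.fiv_mod == r.fiv_low == 0.0

    def test_achieved_volume_within_one_voxel(self, parc):
        vox_mL = parc.spacing[0] * parc.spacing[1] * parc.spacing[2] / 1000
        for target in (1.0, 17.3, 60.0):
            les = generate_lesion(parc, target, seed=9)
            assert abs(les.volume_mL - target) <= vox_mL

    def test_confined_to_one_hemisphere(self, parc):
        half = parc.labels.shape[0] // 2
        for seed in range(5):
            les = generate_lesion(parc, 50.0, seed=seed)
            left, right = les.values[:half].sum(), les.values[half:].sum()
            assert left == 0 or right == 0

    def test_occupancy_ordering_monotone(self, parc, relevance_table, rng):
        """Low-relevance occupancy implies moderate implies high (growth order)."""
        targets = np.exp(rng.normal(3.9, 1.1, 30))
        targets = np.minimum(targets, 350.0)
        for t in targets:
            r = decompose_volumes(generate_lesion(parc, float(t), seed=rng), parc, relevance_table)
            if r.n_low > 0:
                assert r.n_mod > 0
            if r.n_mod > 0:
                assert r.n_high > 0

    def test_infeasible_target_rejected(self, parc):
        with pytest.raises(InfeasibleTargetError):
            generate_lesion(parc, 5000.0, seed=1)

    def test_connected_6_neighbourhood(self, parc):
        from scipy import ndimage

        les = generate_lesion(parc, 45.0, seed=11)
        _, n = ndimage.label(les.values, structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1


class TestIntensity:
    def test_empty_lesion_gives_symmetric_volume(self, parc, small_config):
        from fivmap.volumes import LesionMask

        empty = LesionMask(np.zeros(parc.labels.shape, dtype=bool), parc.spacing)
        vol = render_intensity(parc, empty, small_config)
        np.testing.assert_array_equal(vol.values, np.flip(vol.values, axis=0))

    def test_lesion_exceeds_mirror_by_exact_contrast(self, parc):
        cfg = CohortConfig(n_patients=1, contrast=0.30, noise_sd=0.0, **TEST_GRID)
        les = generate_lesion(parc, 20.0, seed=3)
        vol = render_intensity(parc, les, cfg)
        mirrored = np.flip(vol.values, axis=0)
        ratio = vol.values[les.values] / mirrored[les.values]
        np.testing.assert_allclose(ratio, 1.30, rtol=1e-12)

    def test_subthreshold_contrast_segments_empty(self, parc):
        cfg = CohortConfig(n_patients=1, contrast=0.19, noise_sd=0.0, **TEST_GRID)
        les = generate_lesion(parc, 20.0, seed=3)
        vol = render_intensity(parc, les, cfg)
        assert segment_mirror_difference(vol, 0.20).n_voxels == 0

    def test_lesion_outside_brain_rejected(self, parc, small_config):
        from fivmap.volumes import LesionMask

        bad = np.zeros(parc.labels.shape, dtype=bool)
        bad[0, 0, 0] = True  # far outside the ellipsoid
        with pytest.raises(ValueError, match="outside"):
            render_intensity(parc, LesionMask(bad, parc.spacing), small_config)


class TestOutcomes:
    def _null_cohort(self, n, cfg, rng):
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "fiv_high": np.exp(rng.normal(3, 1, n)),
                "fiv_mod": np.zeros(n),
                "fiv_low": np.zeros(n),
            }
        )
        df["fiv_total"] = df["fiv_high"]
        return pd.concat([df, draw_covariates(n, cfg, rng)], axis=1)

    def test_null_model_marginal_matches_cutpoints(self, rng):
        cfg = CohortConfig(beta_high=0.0, gamma={}, cutpoints=(-2.0, -1.0, 0.0, 1.0, 2.0, 3.0))
        n = 2000
        df = simulate_outcomes(self._null_cohort(n, cfg, rng), cfg, rng=rng)
        from scipy.special import expit

        implied = np.diff(np.concatenate([[0], expit(np.array(cfg.cutpoints)), [1]]))
        observed = np.bincount(df["mrs_90d"], minlength=7) / n
        # three binomial SDs per category
        tol = 3 * np.sqrt(implied * (1 - implied) / n)
        assert np.all(np.abs(observed - implied) <= tol + 1e-9)

    def test_null_c_statistic_near_half(self, rng):
        cfg = CohortConfig(beta_high=0.0, gamma={})
        df = simulate_outcomes(self._null_cohort(2000, cfg, rng), cfg, rng=rng)
        c = om.c_statistic_ordinal(df["fiv_high"].to_numpy(), df["mrs_90d"].to_numpy())
        assert c == pytest.approx(0.5, abs=0.03)

    def test_overwhelming_harm_forces_death(self, rng):
        cfg = CohortConfig(beta_high=-1e6, gamma={})
        df = simulate_outcomes(self._null_cohort(200, cfg, rng), cfg, rng=rng)
        assert (df.loc[df.fiv_high > 0, "mrs_90d"] == 6).all()

    def test_same_seed_reproduces_outcomes(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(0)
        df = self._null_cohort(100, cfg, rng)
        a = simulate_outcomes(df, cfg, rng=42)
        b = simulate_outcomes(df, cfg, rng=42)
        assert (a["mrs_90d"] == b["mrs_90d"]).all()

    def test_nonincreasing_cutpoints_rejected(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(cutpoints=(0.0, 1.0, 1.0, 2.0, 3.0, 4.0))


class TestGenerateCohort:
    def test_smoke_run_writes_manifest_and_files(self, tmp_path):
        cfg = CohortConfig(n_patients=5, seed=77, **TEST_GRID)
        out = generate_cohort(cfg, out_dir=tmp_path)
        manifest = out["manifest"]
        assert len(manifest["files"]["intensity"]) == 5
        assert len(manifest["files"]["truth_mask"]) == 5
        assert (tmp_path / "parcellation.nii.gz").exists()
        cohort = pd.read_csv(tmp_path / "cohort.csv")
        assert len(cohort) == 5

    def test_cohort_contains_full_adjustment_set(self, tmp_path):
        cfg = CohortConfig(n_patients=4, seed=78, **TEST_GRID)
        out = generate_cohort(cfg, out_dir=None, write_volumes=False)
        cols = set(out["cohort"].columns)
        expected = {
            "age",
            "sex",
            "diabetes",
            "atrial_fibrillation",
            "prior_stroke_or_prestroke_mrs_gt0",
            "treatment_allocation",
            "occlusion_site",
            "onset_to_treatment_min",
            "collateral_score",
            "mrs_90d",
        }
        assert expected <= cols
        assert not out["cohort"].isna().any().any()

    def test_seed_changes_lesions(self):
        a = generate_cohort(CohortConfig(n_patients=2, seed=1, **TEST_GRID), write_volumes=False)
        b = generate_cohort(CohortConfig(n_patients=2, seed=2, **TEST_GRID), write_volumes=False)
        assert not np.array_equal(a["lesions"][0].values, b["lesions"][0].values)

    def test_same_config_bit_identical(self):
        cfg = CohortConfig(n_patients=3, seed=9, **TEST_GRID)
        a = generate_cohort(cfg, write_volumes=False)
        b = generate_cohort(cfg, write_volumes=False)
        pd.testing.assert_frame_equal(a["cohort"], b["cohort"])
        np.testing.assert_array_equal(a["lesions"][2].values, b["lesions"][2].values)
        np.testing.assert_array_equal(a["intensities"][1].values, b["intensities"][1].values)
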