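"""Generator calibration, determinism and on-disk round-trips."""

import dataclasses

import numpy as np
import pytest

from mciprog.errors import ConfigurationError
from mciprog.synthetic import (GeneratorConfig, atrophy_mask, cohort_to_frame,
                               generate_cohort, generate_volume_pair,
                               generate_volumes, read_cohort, write_cohort)


def test_cohort_composition_matches_prevalence():
    config = GeneratorConfig(n_subjects=332, prevalence_early_ad=0.328,
                             seed=3)
    cohort = generate_cohort(config)
    n_early = sum(s.group == "early_ad" for s in cohort)
    # binomial(332, 0.328): mean 108.9, SD 8.6 -> 4 SD band
    assert abs(n_early - 108.9) < 4 * 8.6
    exact = dataclasses.replace(config, exact_counts=True)
    n_exact = sum(s.group == "early_ad"
                  for s in generate_cohort(exact))
    assert n_exact == 109


def test_group_marginals_calibrated_at_large_n():
    """Large-sample group means match the configured Gaussians within 3 SE.

    Checked for the hippocampal volume (the planted imaging signal) and for
    baseline MMSE (truncation to [24, 30] shifts the mean, so a wider,
    truncation-aware band applies there).
    """
    config = GeneratorConfig(n_subjects=10_000, prevalence_early_ad=0.5,
                             seed=9)
    cohort = generate_cohort(config)
    hv = {g: np.array([s.hippocampal_volume_mm3 for s in cohort
                       if s.group == g]) for g in ("non_ad", "early_ad")}
    for g, (mu, sd) in (("non_ad", (3339.0, 480.0)),
                        ("early_ad", (2927.0, 415.0))):
        n = hv[g].size
        assert abs(hv[g].mean() - mu) < 3 * sd / np.sqrt(n)
        assert abs(hv[g].std() - sd) < 0.05 * sd
    apoe = {g: np.mean([s.apoe_e4_count for s in cohort if s.group == g])
            for g in ("non_ad", "early_ad")}
    assert abs(apoe["non_ad"] - 0.4) < 0.03
    assert abs(apoe["early_ad"] - 1.0) < 0.04


def test_inclusion_bounds_enforced():
    cohort = generate_cohort(GeneratorConfig(n_subjects=2000, seed=5))
    for s in cohort:
        assert 60.0 <= s.age <= 80.0
        assert 24.0 <= s.baseline_mmse <= 30.0
        assert s.adas_delayed_recall >= 0.0
        assert s.apoe_e4_count in (0, 1, 2)
        assert s.hippocampal_volume_mm3 > 0 and s.icv_cm3 > 0
        assert len(s.regional_volumes) == 68
        assert s.followups[0][0] == 0.0
        assert [t for t, _ in s.followups] == sorted(
            t for t, _ in s.followups)
        assert all(0.0 <= y <= 30.0 for _, y in s.followups)


def test_determinism_same_seed_identical_cohorts():
    config = GeneratorConfig(n_subjects=50, seed=11)
    a = cohort_to_frame(generate_cohort(config))
    b = cohort_to_frame(generate_cohort(config))
    assert a.equals(b)
    c = cohort_to_frame(generate_cohort(
        dataclasses.replace(config, seed=12)))
    assert not a.equals(c)


def test_noiseless_followups_lie_on_the_true_line():
    config = GeneratorConfig(n_subjects=30, seed=2, visit_noise_sd=0.0)
    for s in generate_cohort(config):
        expected = [min(30.0, max(0.0, s.baseline_mmse + s.true_slope * t))
                    for t, _ in s.followups]
        observed = [y for _, y in s.followups]
        assert observed == pytest.approx(expected, abs=1e-12)


def test_mmse_clipping_floor():
    grp = GeneratorConfig().group_params
    steep = {g: dataclasses.replace(p, mmse_slope=(-10.0, 0.01))
             for g, p in grp.items()}
    cohort = generate_cohort(GeneratorConfig(
        n_subjects=40, seed=4, group_params=steep))
    lows = [y for s in cohort for _, y in s.followups]
    assert min(lows) >= 0.0


class TestVolumePairs:
    def test_jd_identity_at_group_mean_and_contraction_below(self):
        config = GeneratorConfig(seed=0)
        cohort = generate_cohort(GeneratorConfig(n_subjects=5, seed=0))
        s = cohort[0]
        mask = atrophy_mask(config)

        s.hippocampal_volume_mm3 = 3339.0   # exactly the non-AD mean
        pair = generate_volume_pair(s, config)
        assert np.allclose(pair.jd[mask], 1.0)   # no atrophy -> identity
        # background carries only registration-scale noise around 1.0
        noise_band = 6 * config.jd_background_noise_sd
        assert np.abs(pair.jd[~mask] - 1.0).max() <= noise_band

        s.hippocampal_volume_mm3 = 0.8 * 3339.0
        pair = generate_volume_pair(s, config)
        inside = pair.jd[mask]
        outside = pair.jd[~mask]
        assert np.allclose(inside, 0.8, atol=1e-6)
        assert np.abs(outside - 1.0).max() <= noise_band
        assert inside.mean() < outside.mean()
        assert (pair.jd > 0).all() and (pair.mri >= 0).all()

    def test_mean_jd_in_region_perfectly_tracks_hippocampal_volume(self):
        config = GeneratorConfig(n_subjects=40, seed=6)
        cohort = generate_cohort(config)
        volumes = generate_volumes(cohort, config)
        mask = atrophy_mask(config)
        hv = np.array([s.hippocampal_volume_mm3 for s in cohort])
        mean_jd = np.array([volumes[s.subject_id].jd[mask].mean()
                            for s in cohort])
        r = np.corrcoef(hv, mean_jd)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-5)

    def test_mri_structure_size_scales_with_hippocampus(self):
        config = GeneratorConfig(seed=0)
        cohort = generate_cohort(GeneratorConfig(n_subjects=2, seed=1))
        s = cohort[0]
        s.hippocampal_volume_mm3 = 3339.0
        big = (generate_volume_pair(s, config).mri > 80.0).sum()
        s.hippocampal_volume_mm3 = 0.5 * 3339.0
        small = (generate_volume_pair(s, config).mri > 80.0).sum()
        assert big > small > 0

    def test_volume_determinism_per_subject(self):
        config = GeneratorConfig(seed=8)
        cohort = generate_cohort(GeneratorConfig(n_subjects=3, seed=8))
        a = generate_volume_pair(cohort[1], config)
        b = generate_volume_pair(cohort[1], config)
        assert np.array_equal(a.mri, b.mri) and np.array_equal(a.jd, b.jd)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(prevalence_early_ad=0.0),
        dict(prevalence_early_ad=1.5),
        dict(followup_schedule=(1.0, 2.0)),          # no baseline visit
        dict(followup_schedule=(0.0, 5.0)),          # beyond the window
        dict(atrophy_center=(30, 16, 16)),           # sphere leaves the grid
        dict(atrophy_radius=0),
        dict(n_subjects=0),
        dict(voxel_size_mm=0.0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(**bad).validate()


def test_write_read_round_trip(tmp_path):
    config = GeneratorConfig(n_subjects=6, seed=13,
                             mri_shape=(12, 12, 12), jd_shape=(10, 10, 10),
                             atrophy_center=(5, 5, 5), atrophy_radius=3)
    cohort = generate_cohort(config)
    volumes = generate_volumes(cohort, config)
    write_cohort(cohort, volumes, tmp_path, config)
    back, vols = read_cohort(tmp_path)
    assert cohort_to_frame(back).equals(cohort_to_frame(cohort))
    for s in cohort:
        np.testing.assert_allclose(vols[s.subject_id].mri,
                                   volumes[s.subject_id].mri, rtol=1e-6)
        np.testing.assert_allclose(vols[s.subject_id].jd,
                                   volumes[s.subject_id].jd, rtol=1e-6)


def test_nifti_affine_encodes_voxel_spacing(tmp_path):
    import nibabel as nib
    config = GeneratorConfig(n_subjects=1, seed=1, voxel_size_mm=4.0,
                             mri_shape=(12, 12, 12), jd_shape=(10, 10, 10),
                             atrophy_center=(5, 5, 5), atrophy_radius=3)
    cohort = generate_cohort(config)
    write_cohort(cohort, generate_volumes(cohort, config), tmp_path, config)
    img = nib.load(tmp_path / "volumes" / "sub-0001_mri.nii.gz")
    assert np.allclose(img.affine[:3, :3], np.diag([4.0, 4.0, 4.0]))


def test_missing_volume_raises_with_subject_id(tmp_path):
    config = GeneratorConfig(n_subjects=2, seed=1, mri_shape=(12, 12, 12),
                             jd_shape=(10, 10, 10), atrophy_center=(5, 5, 5),
                             atrophy_radius=3)
    cohort = generate_cohort(config)
    volumes = generate_volumes(cohort, config)
    del volumes[cohort[1].subject_id]
    with pytest.raises(KeyError, match=cohort[1].subject_id):
        write_cohort(cohort, volumes, tmp_path, config)
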