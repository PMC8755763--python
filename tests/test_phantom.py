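"""Synthetic phantom generator: targets, spectra, scenes, determinism."""

import hashlib

import numpy as np
import pytest

from chondrohsi import (
    AbsorbanceCube,
    GeneratorConfig,
    IndexModel,
    RegionAnnotation,
    SpectralTargets,
    TWIParams,
    WavelengthGrid,
    band_value,
    build_absorbance_spectrum,
    calibrate_generator,
    calibrate_reflectance,
    generate_cohort,
    realize_scene,
    sample_cohort_targets,
    sample_region_table,
    to_absorbance,
    window_mean,
)
from chondrohsi.exceptions import InfeasibleTargetError, LayoutError
from chondrohsi.phantom import HEALTHY_A540_MIXTURE, sample_target_arrays


def extract_targets(cube: AbsorbanceCube, mask=None) -> SpectralTargets:
    """Pipeline-side re-extraction of the three index targets."""
    def reduce(img):
        return float(img.values[mask].mean() if mask is not None
                     else img.values.mean())

    ratio = reduce(window_mean(cube, 955, 980)) / reduce(
        window_mean(cube, 880, 900)
    )
    return SpectralTargets(
        a540=reduce(band_value(cube, 540)),
        a960=reduce(band_value(cube, 960)),
        twi_ratio=ratio,
    )


class TestTargetSampling:
    def test_zero_variance_gives_identical_class_means(self):
        cfg = GeneratorConfig(
            index_model=IndexModel.degenerate(), patient_effect_rho=0.0, seed=5
        )
        pairs = sample_cohort_targets(cfg)
        tp = cfg.twi_params
        for healthy, damaged in pairs:
            assert healthy.a540 == pytest.approx(0.59)
            assert damaged.a540 == pytest.approx(1.18)
            assert healthy.a960 == pytest.approx(0.47)
            assert damaged.a960 == pytest.approx(0.49)
            assert healthy.twi_ratio == pytest.approx(tp.twi_to_ratio(75.0))
            assert damaged.twi_ratio == pytest.approx(tp.twi_to_ratio(67.0))

    def test_marginals_recover_cohort_moments(self):
        # one large draw instead of many replicate cohorts
        arr = sample_target_arrays(GeneratorConfig(n_patients=20000, seed=2))
        assert arr["a540_damaged"].mean() == pytest.approx(1.18, abs=0.02)
        assert arr["a540_healthy"].mean() == pytest.approx(0.59, abs=0.012)
        assert arr["a540_healthy"].std() == pytest.approx(0.27, abs=0.027)
        assert arr["a960_healthy"].mean() == pytest.approx(0.47, abs=0.01)
        assert arr["a960_damaged"].mean() == pytest.approx(0.49, abs=0.01)
        assert arr["twi_healthy"].mean() == pytest.approx(75.0, abs=0.5)
        assert arr["twi_damaged"].mean() == pytest.approx(67.0, abs=0.5)

    def test_within_patient_correlation_tracks_rho(self):
        arr = sample_target_arrays(
            GeneratorConfig(n_patients=10500, patient_effect_rho=0.3, seed=3)
        )
        corr = np.corrcoef(arr["a540_healthy"], arr["a540_damaged"])[0, 1]
        assert corr == pytest.approx(0.3, abs=0.1)

    def test_rho_zero_gives_uncorrelated_draws(self):
        arr = sample_target_arrays(
            GeneratorConfig(n_patients=10500, patient_effect_rho=0.0, seed=3)
        )
        corr = np.corrcoef(arr["twi_healthy"], arr["twi_damaged"])[0, 1]
        assert abs(corr) < 0.05

    @pytest.mark.parametrize(
        "kwargs", [dict(n_patients=1), dict(patient_effect_rho=1.0),
                   dict(noise_cv=-0.1), dict(roi_radius=0)]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)


class TestCalibrateGenerator:
    def test_solved_mixture_satisfies_all_three_constraints(self):
        mix = calibrate_generator()
        mean, sd = mix.moments()
        assert mean == pytest.approx(0.59, abs=1e-6)
        assert sd == pytest.approx(0.27, abs=1e-6)
        assert float(mix.cdf(np.asarray(0.74))) == pytest.approx(0.81, abs=1e-6)

    def test_frozen_default_satisfies_the_same_constraints(self):
        # the solve is underdetermined (4 parameters, 3 constraints), so the
        # frozen parameters are checked against the constraints themselves
        mean, sd = HEALTHY_A540_MIXTURE.moments()
        assert mean == pytest.approx(0.59, abs=1e-6)
        assert sd == pytest.approx(0.27, abs=1e-6)
        p = float(HEALTHY_A540_MIXTURE.cdf(np.asarray(0.74)))
        assert p == pytest.approx(0.81, abs=1e-6)

    def test_damaged_tail_mass_from_gaussian_tail(self):
        from chondrohsi import TruncNormSpec

        damaged = TruncNormSpec(1.18, 0.48)
        p = 1.0 - float(damaged.cdf(np.asarray(0.74)))
        # untruncated tail is Phi(0.9167) = 0.820; zero-truncation lifts it slightly
        assert p == pytest.approx(0.8261, abs=1e-3)


class TestSpectrumConstruction:
    def test_roundtrip_identity_for_random_valid_targets(self, rng):
        grid = WavelengthGrid.default()
        for _ in range(30):
            targets = SpectralTargets(
                a540=rng.uniform(0.3, 2.0),
                a960=rng.uniform(0.3, 0.7),
                twi_ratio=rng.uniform(0.8, 1.7),
            )
            spectrum = build_absorbance_spectrum(targets, grid)
            cube = AbsorbanceCube(
                np.broadcast_to(spectrum, (1, 1, grid.n_bands)).copy(), grid
            )
            got = extract_targets(cube)
            assert got.a540 == pytest.approx(targets.a540, abs=1e-9)
            assert got.a960 == pytest.approx(targets.a960, abs=1e-9)
            assert got.twi_ratio == pytest.approx(targets.twi_ratio, abs=1e-9)

    def test_hemoglobin_free_targets_recover_flat_spectrum(self):
        # a spectrum built without any hemoglobin amplitude must round-trip
        # through its own index targets with aHb solved back to ~0
        from chondrohsi.phantom import _basis

        grid = WavelengthGrid.default()
        slope, _, water = _basis(grid.band_centers)
        flat = 0.5 + 0.05 * slope + 0.3 * water
        cube = AbsorbanceCube(
            np.broadcast_to(flat, (1, 1, grid.n_bands)).copy(), grid
        )
        rebuilt = build_absorbance_spectrum(extract_targets(cube), grid)
        np.testing.assert_allclose(rebuilt, flat, atol=1e-9)

    def test_damaged_mean_targets_show_oxyhemoglobin_peak(self):
        grid = WavelengthGrid.default()
        tp = TWIParams()
        spectrum = build_absorbance_spectrum(
            SpectralTargets(a540=1.18, a960=0.49,
                            twi_ratio=float(tp.twi_to_ratio(67.0))),
            grid,
        )
        sel = (grid.band_centers >= 535) & (grid.band_centers <= 550)
        inner_max = spectrum[sel].max()
        # a genuine local maximum: higher than the flanking bands
        left = spectrum[grid.index_of(530)]
        right = spectrum[grid.index_of(560)]
        assert inner_max > left and inner_max > right

    def test_infeasible_targets_raise(self):
        with pytest.raises(InfeasibleTargetError):
            build_absorbance_spectrum(
                SpectralTargets(a540=0.01, a960=2.0, twi_ratio=0.5)
            )


class TestSceneRealization:
    def _region_defs(self, cfg, targets):
        spectrum = build_absorbance_spectrum(targets, cfg.grid)
        ann = RegionAnnotation("P001", 1, 0)
        return [(ann, targets, spectrum)]

    def test_noise_free_scene_inverts_exactly(self):
        cfg = GeneratorConfig(noise_cv=0.0, dark_noise_sd=0.0,
                              cube_shape=(16, 16), roi_radius=3)
        targets = SpectralTargets(a540=0.8, a960=0.5, twi_ratio=1.2)
        scene = realize_scene("P001", self._region_defs(cfg, targets), cfg,
                              cfg.rng())
        cube = to_absorbance(calibrate_reflectance(scene.raw, scene.references))
        spectrum = build_absorbance_spectrum(targets, cfg.grid)
        mask = scene.labels == 1
        assert np.abs(cube.values[mask] - spectrum[None, :]).max() < 1e-6

    def test_zero_absorbance_region_equals_white_reference(self):
        cfg = GeneratorConfig(noise_cv=0.0, dark_noise_sd=0.0,
                              cube_shape=(16, 16), roi_radius=3)
        targets = SpectralTargets(a540=0.8, a960=0.5, twi_ratio=1.2)
        ann = RegionAnnotation("P001", 1, 0)
        zero_spectrum = np.zeros(cfg.grid.n_bands)
        scene = realize_scene("P001", [(ann, targets, zero_spectrum)], cfg,
                              cfg.rng())
        mask = scene.labels == 1
        np.testing.assert_allclose(
            scene.raw.intensities[mask], cfg.white_level, rtol=1e-12
        )

    def test_default_noise_region_mean_close_to_truth(self):
        cfg = GeneratorConfig(cube_shape=(32, 32), roi_radius=6, seed=17)
        targets = SpectralTargets(a540=0.9, a960=0.5, twi_ratio=1.2)
        scene = realize_scene("P001", self._region_defs(cfg, targets), cfg,
                              cfg.rng())
        cube = to_absorbance(calibrate_reflectance(scene.raw, scene.references))
        mask = scene.labels == 1
        assert mask.sum() >= 100
        got = band_value(cube, 540).values[mask].mean()
        assert got == pytest.approx(targets.a540, abs=0.005)

    def test_layout_that_does_not_fit_raises(self):
        cfg = GeneratorConfig(cube_shape=(16, 16), roi_radius=7,
                              noise_cv=0.0, dark_noise_sd=0.0)
        targets = SpectralTargets(a540=0.8, a960=0.5, twi_ratio=1.2)
        spectrum = build_absorbance_spectrum(targets, cfg.grid)
        regions = [
            (RegionAnnotation("P001", i + 1, 0), targets, spectrum)
            for i in range(4)
        ]
        with pytest.raises(LayoutError):
            realize_scene("P001", regions, cfg, cfg.rng())


class TestCohort:
    def test_default_cohort_shape(self):
        scenes, manifest = generate_cohort(GeneratorConfig(seed=1))
        assert len(scenes) == 21
        assert sum(len(s.annotations) for s in scenes) == 42
        assert len(manifest["scene_sha256"]) == 21
        classes = {a.tissue_class for s in scenes for a in s.annotations}
        assert classes == {"healthy", "damaged"}

    def test_equal_seeds_bitwise_identical(self):
        m1 = generate_cohort(GeneratorConfig(seed=9, n_patients=3,
                                             cube_shape=(32, 32)))[1]
        m2 = generate_cohort(GeneratorConfig(seed=9, n_patients=3,
                                             cube_shape=(32, 32)))[1]
        assert m1["scene_sha256"] == m2["scene_sha256"]

    def test_different_seeds_differ(self):
        m1 = generate_cohort(GeneratorConfig(seed=1, n_patients=3,
                                             cube_shape=(32, 32)))[1]
        m2 = generate_cohort(GeneratorConfig(seed=2, n_patients=3,
                                             cube_shape=(32, 32)))[1]
        assert m1["scene_sha256"] != m2["scene_sha256"]

    def test_raw_nonnegative_and_white_above_dark(self):
        scenes, _ = generate_cohort(GeneratorConfig(seed=4, n_patients=2,
                                                    cube_shape=(32, 32)))
        for s in scenes:
            assert np.all(s.raw.intensities >= 0)
            assert np.all(s.references.white > s.references.dark)

    def test_fast_path_table_matches_truth_targets(self):
        cfg = GeneratorConfig(seed=6, n_patients=3)
        table = sample_region_table(cfg)
        pairs = sample_cohort_targets(cfg)
        tp = cfg.twi_params
        for p, (healthy, damaged) in enumerate(pairs):
            rows = table[table.patient_id == f"P{p + 1:03d}"]
            h = rows[rows.tissue_class == "healthy"].iloc[0]
            d = rows[rows.tissue_class == "damaged"].iloc[0]
            assert h.mean_a540 == pytest.approx(healthy.a540)
            assert d.mean_a540 == pytest.approx(damaged.a540)
            assert h.mean_twi == pytest.approx(
                min(100.0, max(0.0, float(tp.ratio_to_twi(healthy.twi_ratio))))
            )

    def test_region_pixel_sums_bounded_by_nonbackground(self):
        scenes, _ = generate_cohort(GeneratorConfig(seed=4, n_patients=2,
                                                    cube_shape=(32, 32),
                                                    roi_radius=4))
        for s in scenes:
            n_nonbg = int((s.labels > 0).sum())
            per_region = [int((s.labels == a.region_id).sum())
                          for a in s.annotations]
            assert all(n >= 1 for n in per_region)
            assert sum(per_region) <= n_nonbg
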