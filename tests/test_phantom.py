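"""Phantom geometry, forward model and study generation."""

import numpy as np
import pytest

from msi3d.errors import ConfigError, InputError
from msi3d.phantom import (
    LESION_BY_DAY,
    PhantomConfig,
    REGIONS,
    generate_study,
    lesion_profile,
    make_section_geometry,
    synthesize_spectrum,
)

SMALL = dict(grid_size=24, mz_range=(380.0, 880.0), mz_bin_width=1.0, peak_sigma=(0.5, 4e-4))


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"grid_size": 8},
            {"mz_bin_width": 0.0},
            {"sections_per_segment": 0},
            {"noise_sd": -1.0},
            {"segments": ("R1", "XX")},
            {"timepoints": (3, 5)},
            {"mz_range": (900.0, 300.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            PhantomConfig(**kwargs)

    def test_axis_and_planted_peaks_within_range(self):
        cfg = PhantomConfig(**SMALL)
        axis = cfg.mz_axis
        assert axis[0] == 380.0 and axis[-1] <= 880.0
        for tp in cfg.timepoints:
            for mz, regions in cfg.planted_peaks(tp):
                assert 380.0 <= mz <= 880.0
                assert all(a >= 0 for a in regions.values())


class TestGeometry:
    @pytest.mark.parametrize("z,tp,seg", [(0.5, 3, "L"), (0.1, 7, "L"), (0.9, 10, "C1"), (0.5, 3, "R1")])
    def test_masks_partition_grid(self, z, tp, seg):
        cfg = PhantomConfig(**SMALL)
        masks, _ = make_section_geometry(z, tp, seg, cfg)
        assert set(masks) == set(REGIONS)
        total = np.zeros(masks["gray"].shape, dtype=int)
        for m in masks.values():
            total += m.astype(int)
        np.testing.assert_array_equal(total, 1)  # exclusive and covering

    def test_unlesioned_section(self):
        cfg = PhantomConfig(**SMALL)
        masks, (r_in, r_out) = make_section_geometry(0.02, 3, "R1", cfg)
        assert r_out == 0.0
        assert masks["lesion_core"].sum() == 0 and masks["lesion_margin"].sum() == 0
        assert masks["gray"].sum() > 0

    def test_lesion_confined_to_L_at_later_timepoints(self):
        cfg = PhantomConfig(**SMALL)
        for seg in ("R1", "C1"):
            for z in np.linspace(0, 1, 11):
                masks, _ = make_section_geometry(z, 7, seg, cfg)
                assert masks["lesion_margin"].sum() == 0
                assert masks["lesion_core"].sum() == 0

    def test_day3_margin_thicker_at_center_than_entry(self):
        cfg = PhantomConfig(grid_size=64, **{k: v for k, v in SMALL.items() if k != "grid_size"})
        # global lesion entry is inside R1 at day 3; lesion center is mid-L
        entry, _ = make_section_geometry(0.93, 3, "R1", cfg)
        center, _ = make_section_geometry(0.5, 3, "L", cfg)
        assert center["lesion_margin"].sum() > entry["lesion_margin"].sum() > 0

    def test_profile_spot_ring_collapse(self):
        r_cord = 0.42 * 64
        a, b = LESION_BY_DAY[3]["extent"]
        us = np.linspace(1e-4, 1 - 1e-4, 400)
        prof = np.array([lesion_profile(a + u * (b - a), 3, r_cord) for u in us])
        r_in, r_out = prof[:, 0], prof[:, 1]
        assert np.all(r_out >= r_in)
        # closed spots at both ends, open ring in the middle
        assert r_in[0] == 0.0 and r_in[-1] == 0.0
        assert r_in.max() > 1.0
        # past the rostral cap transition, ring thickness grows monotonically
        # to its caudal maximum and then collapses
        from msi3d.phantom import _CAP_R

        sel = (r_in > 0) & (us >= _CAP_R)
        thick = (r_out - r_in)[sel]
        peak = thick.argmax()
        assert np.all(np.diff(thick[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(thick[peak:]) <= 1e-9)
        # outside the axial extent there is no lesion
        assert lesion_profile(a - 0.01, 3, r_cord) == (0.0, 0.0)

    def test_input_validation(self):
        cfg = PhantomConfig(**SMALL)
        with pytest.raises(InputError):
            make_section_geometry(0.5, 3, "XX", cfg)
        with pytest.raises(InputError):
            make_section_geometry(1.5, 3, "L", cfg)
        with pytest.raises(InputError):
            make_section_geometry(0.5, 5, "L", cfg)


class TestSpectrum:
    def test_silent_config_gives_zero_vector(self):
        cfg = PhantomConfig(noise_sd=0.0, baseline_amplitude=0.0, tic_variation_cv=0.0, **SMALL)
        rng = np.random.default_rng(0)
        spec = synthesize_spectrum({"background": 1.0}, 3, cfg, rng)
        np.testing.assert_array_equal(spec, 0.0)

    def test_pure_gray_support(self):
        from msi3d.phantom import GRAY_PEAKS

        cfg = PhantomConfig(noise_sd=0.0, baseline_amplitude=0.0, tic_variation_cv=0.0, **SMALL)
        spec = synthesize_spectrum({"gray": 1.0}, 3, cfg, np.random.default_rng(0))
        axis = cfg.mz_axis
        support = np.zeros(axis.size, dtype=bool)
        for mz in GRAY_PEAKS:
            sigma = float(cfg.sigma_at(mz))
            support |= np.abs(axis - mz) <= 4 * sigma
        assert spec[support].sum() > 0
        # outside +/-4 sigma only far Gaussian tails remain (< 1e-3 of max)
        assert np.abs(spec[~support]).max() < 1e-3 * spec.max()

    def test_determinism_and_weight_validation(self):
        cfg = PhantomConfig(**SMALL)
        s1 = synthesize_spectrum({"gray": 0.5, "white": 0.5}, 3, cfg, np.random.default_rng(9))
        s2 = synthesize_spectrum({"gray": 0.5, "white": 0.5}, 3, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(s1, s2)
        with pytest.raises(InputError):
            synthesize_spectrum({"gray": 0.7}, 3, cfg, np.random.default_rng(0))
        with pytest.raises(InputError):
            synthesize_spectrum({"blob": 1.0}, 3, cfg, np.random.default_rng(0))

    def test_heme_marker_decays_with_timepoint(self):
        cfg = PhantomConfig(noise_sd=0.0, baseline_amplitude=0.0, tic_variation_cv=0.0,
                            timepoints=(3, 7, 10), **SMALL)
        axis = cfg.mz_axis
        window = np.abs(axis - 616.2) <= 2.0
        heights = []
        for tp in (3, 7, 10):
            spec = synthesize_spectrum({"lesion_core": 1.0}, tp, cfg, np.random.default_rng(0))
            heights.append(spec[window].max())
        assert heights[0] > heights[1] > heights[2]
        assert heights[2] < 0.05 * heights[0]


class TestGenerateStudy:
    def test_section_count_formula(self):
        cfg = PhantomConfig(sections_per_segment=2, timepoints=(3, 7), **SMALL)
        study, truth = generate_study(cfg)
        assert len(study) == 2 * 3 * 2
        assert len(truth.true_transforms) == len(study)

        solo = PhantomConfig(sections_per_segment=1, segments=("L",), timepoints=(3,), **SMALL)
        study, truth = generate_study(solo)
        assert len(study) == 1
        (t,) = truth.true_transforms.values()
        t_max, rot_max = solo.misalignment_max
        assert abs(t.dx) <= t_max and abs(t.dy) <= t_max and abs(t.rotation_deg) <= rot_max

    def test_seed_determinism_and_sidecar(self, tmp_path):
        cfg = PhantomConfig(sections_per_segment=1, timepoints=(3,), seed=5, **SMALL)
        s1, t1 = generate_study(cfg, out_dir=tmp_path / "a")
        s2, t2 = generate_study(cfg, out_dir=tmp_path / "b")
        a = (tmp_path / "a" / "ground_truth.json").read_bytes()
        b = (tmp_path / "b" / "ground_truth.json").read_bytes()
        assert a == b
        for x, y in zip(s1, s2):
            np.testing.assert_array_equal(x.intensities, y.intensities)
        # different seed changes the study
        s3, _ = generate_study(
            PhantomConfig(sections_per_segment=1, timepoints=(3,), seed=6, **SMALL)
        )
        assert not np.array_equal(s1.sections[0].intensities, s3.sections[0].intensities)

    def test_output_files(self, tmp_path):
        cfg = PhantomConfig(sections_per_segment=1, timepoints=(3,), **SMALL)
        generate_study(cfg, out_dir=tmp_path)
        assert sorted(p.name for p in tmp_path.glob("*.imzML")) == [
            "3d_C1.imzML", "3d_L.imzML", "3d_R1.imzML"
        ]
        assert (tmp_path / "ground_truth.json").exists()
        assert len(list((tmp_path / "masks").glob("*.tif"))) == 3

    def test_ground_truth_labels_match_sections(self, day7):
        sec = day7.study.sections[0]
        labels = day7.truth.labels_for(sec)
        assert labels.shape == (sec.n_pixels,)
        assert set(labels) <= set(REGIONS)
        # emitted pixels are tissue: background labels are rare (warp edges)
        assert np.mean(labels == "background") < 0.1
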