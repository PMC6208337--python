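"""Shared phantom fixtures.

The study fixtures keep the generator's spectral/noise/geometry defaults (the
study conditions) and scale down only the computational size: grid edge,
m/z range/binning (with a proportionally wider peak-width model so peaks stay
resolved on the coarser axis) and sections per segment.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from msi3d.peakpick import FeatureMatrix, PeakList, align_to_mean, detect_peaks_omp, section_key
from msi3d.phantom import PhantomConfig, GroundTruth, generate_study
from msi3d.preprocess import mean_spectrum, preprocess_study
from msi3d.io import MSIStudy

# coarse-axis settings shared by the study fixtures
COARSE = dict(mz_range=(380.0, 880.0), mz_bin_width=0.5, peak_sigma=(0.3, 2.5e-4))
#: OMP stop used for phantom analyses (lesion-core peaks carry <1% of
#: mean-spectrum energy after TIC normalization; 5e-4 captures them)
PHANTOM_RESIDUAL_FRACTION = 5e-4


@dataclass
class PhantomRun:
    config: PhantomConfig
    study: MSIStudy
    truth: GroundTruth
    processed: MSIStudy
    mean: np.ndarray
    peaks: PeakList
    features: FeatureMatrix

    @property
    def section_keys(self):
        return [section_key(s) for s in self.processed]


def _run(config: PhantomConfig) -> PhantomRun:
    study, truth = generate_study(config)
    processed = preprocess_study(study)
    mean = mean_spectrum(processed)
    peaks = detect_peaks_omp(
        mean,
        processed.mz_axis,
        width_model=config.peak_sigma,
        residual_fraction=PHANTOM_RESIDUAL_FRACTION,
    )
    features = align_to_mean(processed, peaks)
    return PhantomRun(config, study, truth, processed, mean, peaks, features)


@pytest.fixture(scope="session")
def day3() -> PhantomRun:
    """Acute-timepoint study: full lesion across R1/L/C1, all three segments."""
    return _run(
        PhantomConfig(grid_size=48, sections_per_segment=8, timepoints=(3,), seed=7, **COARSE)
    )


@pytest.fixture(scope="session")
def day7() -> PhantomRun:
    """Subacute study: lesion confined to L; used for segmentation checks."""
    return _run(
        PhantomConfig(grid_size=32, sections_per_segment=4, timepoints=(7,), seed=11, **COARSE)
    )


@pytest.fixture(scope="session")
def multi_tp() -> PhantomRun:
    """Small study covering all three timepoints and segments."""
    return _run(
        PhantomConfig(
            grid_size=24,
            sections_per_segment=2,
            timepoints=(3, 7, 10),
            seed=23,
            mz_range=(380.0, 880.0),
            mz_bin_width=1.0,
            peak_sigma=(0.5, 4e-4),
        )
    )


@pytest.fixture(scope="session")
def reg_stack_study():
    """Unlesioned R1 stack at native grid resolution for registration tests."""
    config = PhantomConfig(
        grid_size=64,
        sections_per_segment=8,
        segments=("R1",),
        timepoints=(7,),
        seed=3,
        mz_range=(380.0, 880.0),
        mz_bin_width=2.0,
        peak_sigma=(0.3, 2.5e-4),
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def day3_volumes(day3):
    """Registered margin- and core-ion volumes of the day-3 study."""
    from msi3d.volume3d import apply_transform, build_volume, register_stack

    keys = day3.section_keys
    transforms = register_stack([s.tic_image() for s in day3.processed])
    volumes = {}
    for mz in (400.3, 518.3):
        j = day3.features.interval_index(mz)
        images = [
            apply_transform(day3.features.ion_image(k, j), t)
            for k, t in zip(keys, transforms)
        ]
        volumes[mz] = build_volume(
            images, z_spacing_um=day3.config.z_spacing,
            pixel_size_um=day3.config.pixel_size, center_mz=mz, transforms=transforms,
        )
    return volumes
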