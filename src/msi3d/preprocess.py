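"""Spectral preprocessing: iterative-convolution baseline removal and total
ion count (TIC) normalization, plus the study mean spectrum.

Baseline model
--------------
The baseline estimator is the minimum-of-smoothed recursion

    b_0 = s,    b_{k+1}(i) = min( b_k(i), (b_k * G_sigma)(i) )

with a Gaussian kernel of width ``kernel_sigma`` (Da) and reflective
boundaries. Each iteration can only lower the estimate, so the sequence is
pointwise non-increasing and always stays below the input; narrow peaks are
eroded while broad, smooth structure (chemical noise / matrix background)
survives. The kernel width, iteration count and the recursion itself are
implementation-defined here — they are stated parameters with defaults, not
claims about any vendor software.

TIC normalization rescales every pixel spectrum to a common total intensity
(default 1), which removes per-pixel acquisition variability; only relative
intensities matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import InputError, NormalizationError
from .io import MSISection, MSIStudy

__all__ = [
    "PreprocessParams",
    "estimate_baseline",
    "remove_baseline",
    "normalize_tic",
    "preprocess_section",
    "preprocess_study",
    "mean_spectrum",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Baseline and normalization parameters.

    kernel_sigma : Gaussian smoothing width of the baseline recursion, in Da.
    iterations : number of min-of-smoothed iterations.
    tic_target : total intensity each pixel is scaled to.
    """

    kernel_sigma: float = 5.0
    iterations: int = 30
    tic_target: float = 1.0

    def __post_init__(self):
        if self.kernel_sigma <= 0:
            raise InputError("kernel_sigma must be > 0")
        if self.iterations < 1:
            raise InputError("iterations must be >= 1")
        if self.tic_target <= 0:
            raise InputError("tic_target must be > 0")


def _axis_spacing(mz_axis: np.ndarray) -> float:
    diffs = np.diff(np.asarray(mz_axis, float))
    if diffs.size == 0:
        raise InputError("m/z axis needs at least two bins")
    if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
        raise InputError("baseline estimation requires a uniform m/z axis")
    return float(diffs[0])


def estimate_baseline(
    spectrum: np.ndarray, mz_axis: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Estimate the baseline of one spectrum (or a stack of spectra).

    ``spectrum`` may be 1-D (n_bins,) or 2-D (n_pixels, n_bins); the recursion
    runs along the last axis.
    """
    spacing = _axis_spacing(mz_axis)
    sigma_bins = params.kernel_sigma / spacing
    b = np.asarray(spectrum, dtype=np.float64).copy()
    if b.shape[-1] != np.asarray(mz_axis).size:
        raise InputError("spectrum length must match the m/z axis")
    # pad with a linear continuation of the local edge slope: reflective or
    # constant padding systematically undershoots a monotone baseline at the
    # axis ends, which leaves a spurious residual ramp after subtraction
    pad = int(np.ceil(4 * sigma_bins)) + 1
    n = b.shape[-1]
    k = max(4, min(pad, n // 2))
    for _ in range(params.iterations):
        slope_l = _edge_slope(b[..., :k], b[..., k:2 * k], k)
        slope_r = _edge_slope(b[..., -2 * k:-k], b[..., -k:], k)
        anchor_l = np.median(b[..., :k], axis=-1)
        anchor_r = np.median(b[..., -k:], axis=-1)
        left = anchor_l[..., None] + slope_l[..., None] * (np.arange(-pad, 0) - (k - 1) / 2)
        right = anchor_r[..., None] + slope_r[..., None] * (np.arange(1, pad + 1) + (k - 1) / 2)
        padded = np.concatenate([left, b, right], axis=-1)
        smoothed = gaussian_filter1d(padded, sigma_bins, axis=-1, mode="nearest")
        np.minimum(b, smoothed[..., pad:pad + n], out=b)
    return b


def _edge_slope(near: np.ndarray, far: np.ndarray, k: int) -> np.ndarray:
    """Robust per-bin slope from the medians of two adjacent edge windows;
    narrow peaks inside a window barely move its median."""
    return (np.median(far, axis=-1) - np.median(near, axis=-1)) / k


def remove_baseline(
    spectrum: np.ndarray, mz_axis: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Baseline-corrected spectrum, clipped at zero."""
    baseline = estimate_baseline(spectrum, mz_axis, params)
    return np.maximum(np.asarray(spectrum, np.float64) - baseline, 0.0)


def normalize_tic(spectrum: np.ndarray, tic_target: float = 1.0) -> np.ndarray:
    """Scale a spectrum so its total intensity equals ``tic_target``.

    Raises :class:`NormalizationError` for an all-zero spectrum; study-level
    wrappers catch this and flag the pixel instead of aborting.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    total = float(spectrum.sum())
    if total <= 0:
        raise NormalizationError("cannot TIC-normalize an all-zero spectrum")
    return spectrum * (tic_target / total)


def preprocess_section(
    section: MSISection, params: PreprocessParams = PreprocessParams()
) -> MSISection:
    """Baseline-remove and TIC-normalize every pixel of a section.

    Pixels whose spectrum is all-zero after baseline removal cannot be
    normalized; they are kept at zero and their row indices are recorded in
    ``metadata['excluded_pixels']`` so downstream stages can skip them.
    """
    corrected = remove_baseline(section.intensities, section.mz_axis, params)
    totals = corrected.sum(axis=1)
    ok = totals > 0
    out = np.zeros_like(corrected)
    out[ok] = corrected[ok] * (params.tic_target / totals[ok, None])
    meta = dict(section.metadata)
    meta["excluded_pixels"] = np.nonzero(~ok)[0].tolist()
    return MSISection(
        mz_axis=section.mz_axis,
        coords=section.coords,
        intensities=out.astype(np.float32),
        grid_shape=section.grid_shape,
        pixel_size=section.pixel_size,
        metadata=meta,
    )


def preprocess_study(
    study: MSIStudy, params: PreprocessParams = PreprocessParams()
) -> MSIStudy:
    return MSIStudy([preprocess_section(s, params) for s in study])


def mean_spectrum(study: MSIStudy | MSISection) -> np.ndarray:
    """Arithmetic mean spectrum over all non-flagged pixels of a study."""
    sections = [study] if isinstance(study, MSISection) else list(study)
    total = np.zeros(sections[0].mz_axis.size, dtype=np.float64)
    n = 0
    for sec in sections:
        excluded = set(sec.metadata.get("excluded_pixels", []))
        if excluded:
            keep = np.array([i for i in range(sec.n_pixels) if i not in excluded])
            if keep.size == 0:
                continue
            total += sec.intensities[keep].sum(axis=0)
            n += keep.size
        else:
            total += sec.intensities.sum(axis=0, dtype=np.float64)
            n += sec.n_pixels
    if n == 0:
        raise InputError("no usable pixels for the mean spectrum")
    return total / n
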