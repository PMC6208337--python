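"""Peak detection by orthogonal matching pursuit (OMP) and alignment of every
pixel spectrum to the mean-spectrum peaks ("datacube" construction).

OMP treats the baseline-removed mean spectrum as a sparse combination of
unit-norm Gaussian atoms, one centered at every axis bin, with a linear
resolution model sigma(m/z) = a + b * m/z. Each iteration selects the atom
best correlated with the residual, re-fits all selected amplitudes jointly by
least squares, and updates the residual; the pursuit stops when the residual
energy falls below ``residual_fraction`` of the input energy or ``max_peaks``
atoms are selected. Detected centers are refined to the intensity-weighted
centroid within +/-2 sigma; refined centers closer than half a sigma are
merged so the peak list stays strictly increasing.

Alignment follows the mean-spectrum peak set: for every pixel and peak, the
local-maximum centroid within the match tolerance is located and intensity is
integrated (trapezoidal) over centroid +/- 2 sigma; when no interior local
maximum exists the integral is taken at the nominal peak center, so absent
peaks yield the local residual level rather than an imputed zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigError, InputError
from .io import MSIStudy

__all__ = ["PeakList", "FeatureMatrix", "detect_peaks_omp", "align_to_mean"]

DEFAULT_WIDTH_MODEL = (0.05, 1e-4)  # sigma = a + b * m/z, in Da


@dataclass
class PeakList:
    """Detected peaks: centers (Da), Gaussian sigmas (Da), amplitudes (a.u.),
    sorted by center."""

    centers: np.ndarray
    sigmas: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, float)
        self.sigmas = np.asarray(self.sigmas, float)
        self.amplitudes = np.asarray(self.amplitudes, float)
        if not (self.centers.shape == self.sigmas.shape == self.amplitudes.shape):
            raise InputError("centers, sigmas, amplitudes must have equal length")
        if self.centers.size:
            order = np.argsort(self.centers)
            self.centers = self.centers[order]
            self.sigmas = self.sigmas[order]
            self.amplitudes = self.amplitudes[order]
            if np.any(np.diff(self.centers) <= 0):
                raise InputError("peak centers must be strictly increasing")
            if np.any(self.sigmas <= 0):
                raise InputError("peak widths must be positive")

    def __len__(self) -> int:
        return self.centers.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"center_mz": self.centers, "sigma": self.sigmas, "amplitude": self.amplitudes}
        )


@dataclass
class FeatureMatrix:
    """Pixels x m/z-interval intensity table.

    ``values[i, j]`` is the integrated, TIC-normalized intensity of pixel
    ``i`` in interval ``j`` (center +/- 2 sigma). ``keys`` holds one row per
    pixel with columns (section, timepoint_days, segment, z_index, x, y);
    ``section_slices`` maps section key -> (slice into rows, grid_shape).
    """

    values: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    keys: pd.DataFrame
    section_slices: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.keys), np.asarray(self.centers).size):
            raise InputError("values shape must be (n_pixels, n_intervals)")
        if float(self.values.min(initial=0.0)) < 0:
            raise InputError("feature values must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    def interval_index(self, mz: float, tol: float = 0.51) -> int:
        """Index of the interval whose center is nearest to ``mz``."""
        i = int(np.argmin(np.abs(self.centers - mz)))
        if abs(self.centers[i] - mz) > tol:
            raise InputError(f"no interval within {tol} Da of m/z {mz}")
        return i

    def ion_image(self, section_key: str, interval: int) -> np.ndarray:
        """Ion image of one interval on one section's grid (0 off-tissue)."""
        sl, grid_shape = self.section_slices[section_key]
        img = np.zeros(grid_shape)
        sub = self.keys.iloc[sl]
        img[sub["y"].to_numpy(), sub["x"].to_numpy()] = self.values[sl, interval]
        return img

    def to_frame(self) -> pd.DataFrame:
        frame = self.keys.copy().reset_index(drop=True)
        for j, c in enumerate(np.asarray(self.centers)):
            frame[f"{c:.4f}"] = self.values[:, j]
        return frame


def _gaussian_dictionary(mz_axis: np.ndarray, width_model) -> tuple[sparse.csc_matrix, np.ndarray, np.ndarray]:
    """Sparse dictionary of unit-norm Gaussian atoms at every axis bin.

    Returns (dictionary, sigmas per atom, raw norms per atom); the raw norm
    converts a unit-atom coefficient back to a peak height.
    """
    a, b = width_model
    mz_axis = np.asarray(mz_axis, float)
    n = mz_axis.size
    spacing = float(mz_axis[1] - mz_axis[0])
    sigmas = a + b * mz_axis
    if np.any(sigmas <= 0):
        raise ConfigError("width model must give positive sigma over the axis")
    half = np.maximum(1, np.ceil(4 * sigmas / spacing).astype(int))
    rows, cols, vals, norms = [], [], [], np.empty(n)
    for j in range(n):
        lo, hi = max(0, j - half[j]), min(n, j + half[j] + 1)
        g = np.exp(-0.5 * ((mz_axis[lo:hi] - mz_axis[j]) / sigmas[j]) ** 2)
        nrm = np.linalg.norm(g)
        norms[j] = nrm
        rows.append(np.arange(lo, hi))
        cols.append(np.full(hi - lo, j))
        vals.append(g / nrm)
    D = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return D, sigmas, norms


def detect_peaks_omp(
    mean_spectrum: np.ndarray,
    mz_axis: np.ndarray,
    max_peaks: int = 200,
    residual_fraction: float = 0.01,
    width_model: tuple[float, float] = DEFAULT_WIDTH_MODEL,
) -> PeakList:
    """Detect peaks in a baseline-removed mean spectrum by OMP."""
    if not (0 < residual_fraction < 1):
        raise ConfigError("residual_fraction must lie in (0, 1)")
    if max_peaks < 1:
        raise ConfigError("max_peaks must be >= 1")
    s = np.asarray(mean_spectrum, float)
    mz_axis = np.asarray(mz_axis, float)
    if s.size == 0 or float(np.abs(s).max(initial=0.0)) == 0.0:
        return PeakList(np.empty(0), np.empty(0), np.empty(0))
    if s.shape != mz_axis.shape:
        raise InputError("spectrum and axis must have equal length")

    D, sigmas, norms = _gaussian_dictionary(mz_axis, width_model)
    energy = float(s @ s)
    residual = s.copy()
    selected: list[int] = []
    banned = np.zeros(s.size, dtype=bool)
    coeffs = np.empty(0)

    while len(selected) < max_peaks:
        corr = D.T @ residual
        corr[banned] = 0.0
        j = int(np.argmax(np.abs(corr)))
        if abs(corr[j]) < 1e-12 * np.sqrt(energy):
            break
        selected.append(j)
        banned[j] = True
        sub = D[:, selected].toarray()
        coeffs, *_ = np.linalg.lstsq(sub, s, rcond=None)
        residual = s - sub @ coeffs
        if float(residual @ residual) / energy < residual_fraction:
            break

    # discard atoms whose jointly re-fit amplitude is non-positive
    while selected and np.any(coeffs <= 0):
        keep = [sel for sel, c in zip(selected, coeffs) if c > 0]
        if not keep:
            return PeakList(np.empty(0), np.empty(0), np.empty(0))
        selected = keep
        sub = D[:, selected].toarray()
        coeffs, *_ = np.linalg.lstsq(sub, s, rcond=None)

    if not selected:
        return PeakList(np.empty(0), np.empty(0), np.empty(0))

    # refine centers to the intensity-weighted centroid within +/-2 sigma
    spacing = float(mz_axis[1] - mz_axis[0])
    refined = []
    for j, c in zip(selected, coeffs):
        k = max(1, int(round(2 * sigmas[j] / spacing)))
        lo, hi = max(0, j - k), min(s.size, j + k + 1)
        w = np.maximum(s[lo:hi], 0.0)
        center = mz_axis[j] if w.sum() == 0 else float(np.sum(mz_axis[lo:hi] * w) / w.sum())
        refined.append((center, sigmas[j], c / norms[j]))
    refined.sort()

    # merge refined centers closer than half a sigma (off-grid peaks can
    # select a correction atom next to the main one)
    merged: list[list[float]] = []
    for center, sig, amp in refined:
        if merged and center - merged[-1][0] < 0.5 * sig:
            c0, s0, a0 = merged[-1]
            tot = a0 + amp
            merged[-1] = [(c0 * a0 + center * amp) / tot, s0, tot]
        else:
            merged.append([center, sig, amp])
    arr = np.array(merged)
    return PeakList(arr[:, 0], arr[:, 1], arr[:, 2])


def section_key(section) -> str:
    m = section.metadata
    return f"{m.get('timepoint_days', 0)}d_{m.get('segment', 'S')}_z{m.get('z_index', 0):03d}"


def align_to_mean(
    study: MSIStudy,
    peaks: PeakList,
    match_tolerance_da: float | None = None,
) -> FeatureMatrix:
    """Align every pixel to the mean-spectrum peaks by centroid matching."""
    if match_tolerance_da is not None and match_tolerance_da <= 0:
        raise ConfigError("match_tolerance_da must be positive")
    if len(peaks) == 0:
        raise InputError("empty peak list")
    axis = study.mz_axis
    spacing = float(axis[1] - axis[0])
    n_peaks = len(peaks)

    blocks, key_rows, section_slices = [], [], {}
    row0 = 0
    for sec in study:
        excluded = set(sec.metadata.get("excluded_pixels", []))
        keep = np.array([i for i in range(sec.n_pixels) if i not in excluded], dtype=int)
        inten = np.asarray(sec.intensities, float)[keep]
        npix = keep.size
        values = np.empty((npix, n_peaks))
        for p in range(n_peaks):
            center, sig = peaks.centers[p], peaks.sigmas[p]
            tol = match_tolerance_da if match_tolerance_da is not None else max(0.2, 2 * sig)
            c_idx = int(round((center - axis[0]) / spacing))
            c_idx = min(max(c_idx, 0), axis.size - 1)
            t = max(1, int(round(tol / spacing)))
            lo, hi = max(0, c_idx - t), min(axis.size, c_idx + t + 1)
            window = inten[:, lo:hi]
            arg = np.argmax(window, axis=1)
            # an argmax on the window edge means no interior local maximum
            interior = (arg > 0) & (arg < hi - lo - 1)
            max_idx = np.where(interior, lo + arg, c_idx)
            k = max(1, int(round(2 * sig / spacing)))
            offsets = np.arange(-k, k + 1)
            gather = np.clip(max_idx[:, None] + offsets[None, :], 0, axis.size - 1)
            seg = np.take_along_axis(inten, gather, axis=1)
            # trapezoid on a uniform axis
            values[:, p] = (seg.sum(axis=1) - 0.5 * (seg[:, 0] + seg[:, -1])) * spacing
        blocks.append(values)
        key = section_key(sec)
        m = sec.metadata
        for i in keep:
            key_rows.append(
                (key, m.get("timepoint_days"), m.get("segment"), m.get("z_index"),
                 int(sec.coords[i, 0]), int(sec.coords[i, 1]))
            )
        section_slices[key] = (slice(row0, row0 + npix), sec.grid_shape)
        row0 += npix

    keys = pd.DataFrame(
        key_rows, columns=["section", "timepoint_days", "segment", "z_index", "x", "y"]
    )
    return FeatureMatrix(
        values=np.maximum(np.vstack(blocks), 0.0),
        centers=peaks.centers.copy(),
        sigmas=peaks.sigmas.copy(),
        keys=keys,
        section_slices=section_slices,
    )
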