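"""Containers and standard-format I/O for MSI studies.

An :class:`MSISection` is one imaged tissue section: a dense pixel grid where
each measured pixel carries an intensity vector on a shared m/z axis. An
:class:`MSIStudy` is an ordered collection of sections grouped by
(timepoint, segment) with one common axis.

On disk, studies live as continuous-mode imzML/ibd pairs (one file per
timepoint × segment) via pyimzml, with per-section grid metadata in a small
JSON sidecar next to the imzML (imzML itself has no slot for section-level
metadata). Coordinates follow the image convention: 0-based, x rightward,
y downward; imzML's 1-based indices are converted on read/write. Intensities
are encoded as 32-bit floats by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, InputError

__all__ = [
    "MSISection",
    "MSIStudy",
    "read_imzml",
    "write_imzml",
    "export_feature_matrix",
    "write_mask_tiff",
    "write_volume_tiff",
]


@dataclass
class MSISection:
    """Gridded spectra of one tissue section on a shared m/z axis.

    Parameters
    ----------
    mz_axis : strictly increasing m/z values (Da), shared across pixels.
    coords : (n_pixels, 2) int array of 0-based (x, y) grid coordinates.
    intensities : (n_pixels, n_bins) non-negative intensity array (a.u.).
    grid_shape : (ny, nx) of the full acquisition raster.
    pixel_size : lateral pixel edge in µm.
    metadata : free-form dict; the pipeline uses keys ``segment``,
        ``timepoint_days``, ``z_index`` and ``z_position_um``.
    """

    mz_axis: np.ndarray
    coords: np.ndarray
    intensities: np.ndarray
    grid_shape: tuple[int, int]
    pixel_size: float = 40.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.intensities = np.asarray(self.intensities)
        if self.mz_axis.ndim != 1 or np.any(np.diff(self.mz_axis) <= 0):
            raise InputError("mz_axis must be 1-D and strictly increasing")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise InputError("coords must be (n_pixels, 2)")
        if self.intensities.shape != (self.coords.shape[0], self.mz_axis.size):
            raise InputError(
                "intensities must be (n_pixels, n_bins) matching coords and mz_axis"
            )
        if self.intensities.size and float(self.intensities.min()) < 0:
            raise InputError("intensities must be non-negative")
        keys = {tuple(c) for c in self.coords.tolist()}
        if len(keys) != self.coords.shape[0]:
            raise InputError("duplicate pixel coordinates in section")

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    def image(self, values, fill: float = 0.0) -> np.ndarray:
        """Place a per-pixel value vector onto the (ny, nx) grid."""
        values = np.asarray(values)
        if values.shape[0] != self.n_pixels:
            raise InputError("values length must equal n_pixels")
        out = np.full(self.grid_shape, fill, dtype=np.float64)
        out[self.coords[:, 1], self.coords[:, 0]] = values
        return out

    def tic(self) -> np.ndarray:
        """Per-pixel total ion count."""
        return self.intensities.sum(axis=1)

    def tic_image(self) -> np.ndarray:
        return self.image(self.tic())


#: rostro-caudal order of the standard spinal-cord segments; unknown labels
#: sort alphabetically after them
_ANATOMICAL_ORDER = {"R2": 0, "R1": 1, "L": 2, "C1": 3, "C2": 4, "C3": 5}


def _segment_rank(segment) -> tuple:
    seg = str(segment)
    return (0, _ANATOMICAL_ORDER[seg], "") if seg in _ANATOMICAL_ORDER else (1, 0, seg)


class MSIStudy:
    """Ordered collection of sections sharing one m/z axis (sections sorted
    by timepoint, rostro-caudal segment position, then z index)."""

    def __init__(self, sections: list[MSISection]):
        if not sections:
            raise InputError("study needs at least one section")
        axis = sections[0].mz_axis
        for s in sections:
            if s.mz_axis.shape != axis.shape or not np.allclose(s.mz_axis, axis):
                raise InputError("all sections of a study must share one m/z axis")
        seen = set()
        for s in sections:
            key = (
                s.metadata.get("timepoint_days"),
                s.metadata.get("segment"),
                s.metadata.get("z_index"),
            )
            if key in seen:
                raise InputError(f"duplicate section key {key}")
            seen.add(key)
        self.sections = sorted(
            sections,
            key=lambda s: (
                s.metadata.get("timepoint_days", 0),
                _segment_rank(s.metadata.get("segment", "")),
                s.metadata.get("z_index", 0),
            ),
        )

    @property
    def mz_axis(self) -> np.ndarray:
        return self.sections[0].mz_axis

    def __len__(self) -> int:
        return len(self.sections)

    def __iter__(self):
        return iter(self.sections)

    @property
    def n_pixels(self) -> int:
        return sum(s.n_pixels for s in self.sections)

    def select(self, timepoint=None, segment=None) -> "MSIStudy":
        """Sub-study restricted to one timepoint and/or segment."""
        keep = [
            s
            for s in self.sections
            if (timepoint is None or s.metadata.get("timepoint_days") == timepoint)
            and (segment is None or s.metadata.get("segment") == segment)
        ]
        if not keep:
            raise InputError(f"no sections match timepoint={timepoint} segment={segment}")
        return MSIStudy(keep)

    def groups(self):
        """Iterate (timepoint, segment) -> MSIStudy sub-groups in order."""
        keys = []
        for s in self.sections:
            k = (s.metadata.get("timepoint_days"), s.metadata.get("segment"))
            if k not in keys:
                keys.append(k)
        for tp, seg in keys:
            yield (tp, seg), self.select(timepoint=tp, segment=seg)


# ---------------------------------------------------------------------------
# imzML read / write
# ---------------------------------------------------------------------------

def write_imzml(sections, path, intensity_dtype=np.float32) -> None:
    """Write one or more sections to a continuous-mode imzML/ibd pair.

    Several sections may share one file; each section's pixels are stored with
    a 1-based z coordinate (= z_index + 1). Grid shape, pixel size and section
    metadata go to ``<path>.meta.json``.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if isinstance(sections, MSISection):
        sections = [sections]
    elif isinstance(sections, MSIStudy):
        sections = list(sections.sections)
    if not sections:
        raise InputError("nothing to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    axis = sections[0].mz_axis
    meta = {"sections": [], "pixel_size": sections[0].pixel_size}
    try:
        with ImzMLWriter(
            str(path),
            mode="continuous",
            intensity_dtype=intensity_dtype,
            polarity="positive",
        ) as writer:
            for si, sec in enumerate(sections):
                if not np.allclose(sec.mz_axis, axis):
                    raise InputError("sections written together must share an axis")
                z = int(sec.metadata.get("z_index", si)) + 1
                for p in range(sec.n_pixels):
                    x, y = sec.coords[p]
                    writer.addSpectrum(
                        sec.mz_axis,
                        np.ascontiguousarray(sec.intensities[p], dtype=np.float64),
                        (int(x) + 1, int(y) + 1, z),
                    )
                meta["sections"].append(
                    {
                        "z": z,
                        "grid_shape": list(sec.grid_shape),
                        "metadata": _jsonable(sec.metadata),
                    }
                )
    except OSError as exc:
        raise FormatError(f"cannot write imzML to {path}: {exc}") from exc
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_imzml(path, bin_width: float | None = None) -> list[MSISection]:
    """Read an imzML file into one section per z plane.

    Continuous-mode files keep their native axis. Processed-mode files (one
    centroid axis per pixel) are resampled by linear interpolation onto a
    common uniform axis whose bin width defaults to the median spacing of the
    observed m/z values.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such imzML file: {path}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML or missing ibd
        raise FormatError(f"malformed imzML {path}: {exc}") from exc
    if not parser.coordinates:
        raise FormatError(f"imzML {path} contains no pixels")

    continuous = "continuous" in parser.metadata.file_description.param_by_name
    spectra = []
    for i in range(len(parser.coordinates)):
        mzs, ints = parser.getspectrum(i)
        spectra.append((np.asarray(mzs, float), np.asarray(ints, float)))

    if continuous and bin_width is None:
        axis = spectra[0][0]
        if np.any(np.diff(axis) <= 0):
            raise FormatError(f"non-monotone m/z axis in {path}")
        resampled = [ints for _, ints in spectra]
    else:
        lo = min(s[0][0] for s in spectra if s[0].size)
        hi = max(s[0][-1] for s in spectra if s[0].size)
        if bin_width is None:
            spacings = np.concatenate(
                [np.diff(s[0]) for s in spectra if s[0].size > 1]
            )
            bin_width = float(np.median(spacings)) if spacings.size else 1.0
        n = max(2, int(math.floor((hi - lo) / bin_width)) + 1)
        axis = lo + bin_width * np.arange(n)
        resampled = [
            np.interp(axis, mzs, ints, left=0.0, right=0.0) for mzs, ints in spectra
        ]

    meta_path = Path(str(path) + ".meta.json")
    sidecar = None
    if meta_path.exists():
        with open(meta_path) as fh:
            sidecar = json.load(fh)

    by_z: dict[int, list[int]] = {}
    for i, c in enumerate(parser.coordinates):
        z = int(c[2]) if len(c) > 2 else 1
        by_z.setdefault(z, []).append(i)

    sections = []
    for z in sorted(by_z):
        idx = by_z[z]
        coords = np.array(
            [(int(parser.coordinates[i][0]) - 1, int(parser.coordinates[i][1]) - 1) for i in idx]
        )
        inten = np.stack([resampled[i] for i in idx]).astype(np.float32)
        grid_shape = (int(coords[:, 1].max()) + 1, int(coords[:, 0].max()) + 1)
        pixel_size, metadata = 40.0, {"z_index": z - 1}
        if sidecar is not None:
            pixel_size = sidecar.get("pixel_size", pixel_size)
            for entry in sidecar["sections"]:
                if entry["z"] == z:
                    grid_shape = tuple(entry["grid_shape"])
                    metadata = dict(entry["metadata"])
        sections.append(
            MSISection(
                mz_axis=axis,
                coords=coords,
                intensities=np.maximum(inten, 0.0),
                grid_shape=grid_shape,
                pixel_size=pixel_size,
                metadata=metadata,
            )
        )
    return sections


def export_feature_matrix(feature_matrix, path) -> None:
    """Write a FeatureMatrix to CSV: (section, x, y) keys + one column per
    m/z interval center."""
    frame = feature_matrix.to_frame()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def write_mask_tiff(mask: np.ndarray, path) -> None:
    """Export a boolean/region mask as single-channel 8-bit TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(mask).astype(np.uint8))


def write_volume_tiff(volume: np.ndarray, path) -> None:
    """Export a (z, y, x) volume as multi-page 32-bit float TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(volume, dtype=np.float32))


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out
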