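"""Synthetic 3D spinal-cord MSI phantom with full ground truth.

The phantom emulates a serial-section MALDI-MSI study of a contused rat
spinal cord: three consecutive segments (R1 rostral, L lesion, C1 caudal)
each cut into equally spaced sections, imaged at three post-injury
timepoints. Every section is a pixel grid holding one spectrum per tissue
pixel on a shared m/z axis.

Geometry per section
--------------------
A circular cord cross-section contains a butterfly-shaped gray-matter region
(mirrored dorsal/ventral horn ellipses plus a central commissure) surrounded
by white matter. Inside the lesion's axial extent a "turnip"-shaped shell is
carved out: a thin margin ring at the rostral entry that widens and thickens
toward the caudal side of the lesion center, then collapses; the ring is the
lesion margin, its interior the lesion core. At 3 days the lesion extends
axially into the facing ends of R1 and C1; at 7 and 10 days it is confined
to L and axially smaller (scar formation).

Spectral forward model
----------------------
Each tissue class carries its own Gaussian peaks (width from a linear
resolution model in m/z): gray and white matter distinct high-MW lipid
peaks, the lesion margin acylcarnitine-class low-MW peaks, the lesion core
lysoPC-class peaks plus a heme marker whose amplitude decays with timepoint
(hemorrhage resolution). A smooth exponentially decaying baseline,
truncated-Gaussian noise and a lognormal per-pixel TIC factor complete the
model. Pixels are emitted only where cord occupancy is at least 0.3 — MSI
measurement regions are drawn around the tissue — and every section is
resampled through a small random rigid transform (the recorded per-section
misalignment that registration must recover).

All amplitudes and radii are free parameters with documented defaults; they
are stylized study conditions, not claims about tissue chemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError, InputError
from .io import MSISection, MSIStudy, write_imzml, write_mask_tiff
from .volume3d import RigidTransform, apply_transform

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "make_section_geometry",
    "synthesize_spectrum",
    "generate_study",
    "REGIONS",
]

#: region labels; order fixes label-map encoding (background = 0)
REGIONS = ("background", "gray", "white", "lesion_margin", "lesion_core")
TISSUE_REGIONS = ("gray", "white", "lesion_margin", "lesion_core")

#: canonical rostro-caudal span of each segment on the global 0-1 axis
SEGMENT_SPAN = {"R1": (0.0, 1 / 3), "L": (1 / 3, 2 / 3), "C1": (2 / 3, 1.0)}

#: lesion axial extent (global fraction) and maximum shell radius (fraction
#: of the cord radius) per timepoint; day 3 crosses into R1 and C1, later
#: timepoints are confined to L and smaller
LESION_BY_DAY = {
    3: {"extent": (0.30, 0.70), "r_frac": 0.95},
    7: {"extent": (0.36, 0.64), "r_frac": 0.85},
    10: {"extent": (0.38, 0.62), "r_frac": 0.75},
}
_RISE_W = 0.08   # fraction of lesion length over which the shell radius opens
_FALL_W = 0.10   # ... and collapses at the caudal end
_THICK0, _THICK1 = 0.55, 0.40  # ring thickness fraction: 0.55 + 0.40 u
_CAP_R, _CAP_C = 0.12, 0.15    # end caps: the ring closes into a solid spot

#: class marker peaks (m/z -> amplitude, a.u.); heme is timepoint-dependent
GRAY_PEAKS = {844.5: 2000.0, 830.5: 1100.0}
WHITE_PEAKS = {768.5: 700.0, 822.6: 420.0}
MARGIN_PEAKS = {398.3: 600.0, 400.3: 700.0, 426.4: 500.0}
CORE_PEAKS = {518.3: 600.0, 544.3: 500.0, 546.3: 350.0}
HEME_MZ = 616.2
HEME_AMPLITUDE_BY_DAY = {3: 400.0, 7: 80.0, 10: 10.0}
#: lesion tissue keeps part of the myelin lipid signal — the injury disrupts
#: the high-MW content without erasing it (penumbra), so lesion spectra stay
#: molecularly closer to white matter than to gray matter
MARGIN_WHITE_RETENTION = 0.5
CORE_WHITE_RETENTION = 0.35


@dataclass(frozen=True)
class PhantomConfig:
    """Acquisition design and forward-model parameters of the phantom."""

    grid_size: int = 64
    pixel_size: float = 40.0  # µm
    mz_range: tuple[float, float] = (300.0, 1100.0)
    mz_bin_width: float = 0.1  # Da
    sections_per_segment: int = 36
    segments: tuple[str, ...] = ("R1", "L", "C1")
    timepoints: tuple[int, ...] = (3, 7, 10)
    z_spacing: float = 204.0  # µm: 12 µm section + 16 skipped x 12 µm
    noise_sd: float = 0.5  # a.u., truncated-Gaussian detector noise
    baseline_amplitude: float = 20.0  # a.u. at the low-m/z end
    tic_variation_cv: float = 0.15  # lognormal per-pixel scale CV
    misalignment_max: tuple[float, float] = (3.0, 5.0)  # (px, deg)
    peak_sigma: tuple[float, float] = (0.05, 1e-4)  # sigma = a + b*m/z (Da)
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 16:
            raise ConfigError("grid_size must be >= 16")
        if self.mz_bin_width <= 0:
            raise ConfigError("mz_bin_width must be > 0")
        if self.sections_per_segment < 1:
            raise ConfigError("sections_per_segment must be >= 1")
        if self.mz_range[1] <= self.mz_range[0]:
            raise ConfigError("mz_range must be increasing")
        for name in ("noise_sd", "baseline_amplitude", "tic_variation_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for seg in self.segments:
            if seg not in SEGMENT_SPAN:
                raise ConfigError(f"unknown segment label {seg!r}")
        for tp in self.timepoints:
            if tp not in LESION_BY_DAY:
                raise ConfigError(f"no lesion model for timepoint {tp}")

    @property
    def mz_axis(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(np.floor((hi - lo) / self.mz_bin_width)) + 1
        return lo + self.mz_bin_width * np.arange(n)

    def sigma_at(self, mz) -> np.ndarray:
        a, b = self.peak_sigma
        return a + b * np.asarray(mz, float)

    def planted_peaks(self, timepoint: int) -> list[tuple[float, dict[str, float]]]:
        """(m/z, per-region amplitude) list for one timepoint."""
        peaks: dict[float, dict[str, float]] = {}
        for mz, amp in GRAY_PEAKS.items():
            peaks.setdefault(mz, {})["gray"] = amp
        for mz, amp in WHITE_PEAKS.items():
            entry = peaks.setdefault(mz, {})
            entry["white"] = amp
            entry["lesion_margin"] = amp * MARGIN_WHITE_RETENTION
            entry["lesion_core"] = amp * CORE_WHITE_RETENTION
        for mz, amp in MARGIN_PEAKS.items():
            peaks.setdefault(mz, {})["lesion_margin"] = amp
        for mz, amp in CORE_PEAKS.items():
            peaks.setdefault(mz, {})["lesion_core"] = amp
        peaks.setdefault(HEME_MZ, {})["lesion_core"] = HEME_AMPLITUDE_BY_DAY[timepoint]
        lo, hi = self.mz_range
        for mz in peaks:
            if not (lo <= mz <= hi):
                raise ConfigError(f"planted m/z {mz} outside mz_range {self.mz_range}")
        return sorted((mz, regions) for mz, regions in peaks.items())


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipse_mask(xx, yy, cx, cy, ax, ay, rot_deg):
    th = np.deg2rad(rot_deg)
    dx, dy = xx - cx, yy - cy
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def _butterfly(xx, yy, cx, cy, r_cord):
    """Gray-matter butterfly: mirrored dorsal/ventral horns + commissure."""
    gray = np.zeros_like(xx, dtype=bool)
    for s in (-1.0, 1.0):
        gray |= _ellipse_mask(
            xx, yy, cx + s * 0.26 * r_cord, cy - 0.30 * r_cord,
            0.14 * r_cord, 0.40 * r_cord, -s * 25.0,
        )
        gray |= _ellipse_mask(
            xx, yy, cx + s * 0.30 * r_cord, cy + 0.28 * r_cord,
            0.22 * r_cord, 0.31 * r_cord, s * 15.0,
        )
    gray |= _ellipse_mask(xx, yy, cx, cy, 0.11 * r_cord, 0.30 * r_cord, 0.0)
    return gray


def lesion_profile(z_global: float, timepoint: int, r_cord: float) -> tuple[float, float]:
    """(inner, outer) shell radius in pixels at a global axial position."""
    model = LESION_BY_DAY[timepoint]
    a, b = model["extent"]
    if not (a <= z_global <= b):
        return (0.0, 0.0)
    u = (z_global - a) / (b - a)
    rise = np.sin(0.5 * np.pi * min(1.0, u / _RISE_W))
    fall = np.sin(0.5 * np.pi * min(1.0, (1.0 - u) / _FALL_W))
    r_out = model["r_frac"] * r_cord * rise * fall
    thick = _THICK0 + _THICK1 * u
    thick += max(0.0, 1.0 - u / _CAP_R) + max(0.0, 1.0 - (1.0 - u) / _CAP_C)
    thick = min(thick, 0.98)
    r_in = r_out * (1.0 - thick)
    if r_in < 1.0:  # sub-pixel hole: the shell is effectively closed here
        r_in = 0.0
    return (float(r_in), float(r_out))


def make_section_geometry(
    z_fraction: float,
    timepoint: int,
    segment: str,
    config: PhantomConfig,
) -> tuple[dict[str, np.ndarray], tuple[float, float]]:
    """Region masks of one section plus its lesion shell radii.

    ``z_fraction`` runs 0-1 within the segment (rostral to caudal); masks are
    mutually exclusive and jointly cover the grid.
    """
    if not (0.0 <= z_fraction <= 1.0):
        raise InputError("z_fraction must lie in [0, 1]")
    if segment not in SEGMENT_SPAN:
        raise InputError(f"unknown segment label {segment!r}")
    if timepoint not in config.timepoints or timepoint not in LESION_BY_DAY:
        raise InputError(f"timepoint {timepoint} not in study design")

    n = config.grid_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    r_cord = 0.42 * n
    dist = np.hypot(xx - c, yy - c)
    cord = dist <= r_cord

    lo, hi = SEGMENT_SPAN[segment]
    z_global = lo + z_fraction * (hi - lo)
    r_in, r_out = lesion_profile(z_global, timepoint, r_cord)

    core = cord & (dist <= r_in)
    margin = cord & (dist <= r_out) & ~core
    gray = _butterfly(xx, yy, c, c, r_cord) & cord & ~core & ~margin
    white = cord & ~gray & ~core & ~margin
    background = ~cord
    masks = {
        "background": background,
        "gray": gray,
        "white": white,
        "lesion_margin": margin,
        "lesion_core": core,
    }
    return masks, (r_in, r_out)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _class_templates(config: PhantomConfig, timepoint: int) -> np.ndarray:
    """(len(TISSUE_REGIONS), n_bins) noise/baseline-free class spectra."""
    axis = config.mz_axis
    templates = np.zeros((len(TISSUE_REGIONS), axis.size))
    for mz, regions in config.planted_peaks(timepoint):
        sigma = float(config.sigma_at(mz))
        profile = np.exp(-0.5 * ((axis - mz) / sigma) ** 2)
        for region, amp in regions.items():
            if amp < 0:
                raise ConfigError(f"negative amplitude for {region} at m/z {mz}")
            templates[TISSUE_REGIONS.index(region)] += amp * profile
    return templates


def _baseline(config: PhantomConfig) -> np.ndarray:
    axis = config.mz_axis
    return config.baseline_amplitude * np.exp(-(axis - axis[0]) / 300.0)


def synthesize_spectrum(
    weights: dict[str, float],
    timepoint: int,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One pixel spectrum from its per-region occupancy weights.

    spectrum = tic_factor * (sum of region peaks + baseline + noise), with
    truncated-Gaussian (optionally Poisson) non-negative noise.
    """
    total = float(sum(weights.values()))
    if not np.isclose(total, 1.0, atol=1e-6):
        raise InputError("region weights must sum to 1")
    for region in weights:
        if region not in REGIONS:
            raise InputError(f"unknown region {region!r}")
    templates = _class_templates(config, timepoint)
    w = np.array([weights.get(r, 0.0) for r in TISSUE_REGIONS])
    signal = w @ templates + _baseline(config)
    if config.poisson_noise:
        noise = rng.poisson(max(config.noise_sd, 0.0), signal.size).astype(float)
    else:
        noise = np.maximum(rng.normal(0.0, config.noise_sd, signal.size), 0.0) \
            if config.noise_sd > 0 else 0.0
    factor = _tic_factors(config, rng, 1)[0]
    return factor * (signal + noise)


def _tic_factors(config: PhantomConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    cv = config.tic_variation_cv
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


# ---------------------------------------------------------------------------
# ground truth + study generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the analysis is later asked to recover."""

    config: PhantomConfig
    region_masks: dict = field(default_factory=dict)  # key -> {region: bool image}
    true_transforms: dict = field(default_factory=dict)  # key -> RigidTransform
    lesion_profile: dict = field(default_factory=dict)  # key -> (r_in, r_out) px
    planted_peaks: dict = field(default_factory=dict)  # timepoint -> [(mz, {region: amp})]

    @staticmethod
    def section_id(timepoint: int, segment: str, z_index: int) -> str:
        return f"{timepoint}d_{segment}_z{z_index:03d}"

    def labels_for(self, section: MSISection) -> np.ndarray:
        """Region label (string) of every emitted pixel of a section."""
        key = self.section_id(
            section.metadata["timepoint_days"],
            section.metadata["segment"],
            section.metadata["z_index"],
        )
        masks = self.region_masks[key]
        label_img = np.zeros(section.grid_shape, dtype=int)
        for i, region in enumerate(REGIONS):
            label_img[masks[region]] = i
        idx = label_img[section.coords[:, 1], section.coords[:, 0]]
        return np.array([REGIONS[i] for i in idx])

    def region_vector(self, features, region: str) -> np.ndarray:
        """0/1 vector over FeatureMatrix rows marking one true region."""
        out = np.zeros(len(features.keys), dtype=float)
        for key, (sl, _) in features.section_slices.items():
            masks = self.region_masks[key]
            sub = features.keys.iloc[sl]
            out[np.arange(sl.start, sl.stop)] = masks[region][
                sub["y"].to_numpy(), sub["x"].to_numpy()
            ]
        return out

    def to_json(self) -> str:
        payload = {
            "config": _config_dict(self.config),
            "true_transforms": {
                k: {"rotation_deg": t.rotation_deg, "dx": t.dx, "dy": t.dy}
                for k, t in sorted(self.true_transforms.items())
            },
            "lesion_profile": {k: list(v) for k, v in sorted(self.lesion_profile.items())},
            "planted_peaks": {
                str(tp): [[mz, regions] for mz, regions in peaks]
                for tp, peaks in sorted(self.planted_peaks.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _config_dict(config: PhantomConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def generate_study(
    config: PhantomConfig, out_dir=None
) -> tuple[MSIStudy, GroundTruth]:
    """Generate the full phantom study (and optionally write it to disk).

    Emits ``sections_per_segment x len(segments) x len(timepoints)`` sections,
    each resampled through a small random rigid misalignment recorded in the
    ground truth. With ``out_dir`` set, writes one continuous-mode imzML per
    (timepoint, segment), one label-map TIFF per section, and a
    ``ground_truth.json`` sidecar; everything is reproducible from the seed.
    """
    axis = config.mz_axis
    truth = GroundTruth(config=config)
    for tp in config.timepoints:
        truth.planted_peaks[tp] = config.planted_peaks(tp)

    n = config.grid_size
    t_max, rot_max = config.misalignment_max
    root = np.random.SeedSequence(config.seed)
    n_total = len(config.timepoints) * len(config.segments) * config.sections_per_segment
    children = root.spawn(n_total)

    sections = []
    counter = 0
    baseline = _baseline(config)
    for tp in config.timepoints:
        templates = _class_templates(config, tp)
        for seg in config.segments:
            for k in range(config.sections_per_segment):
                rng = np.random.default_rng(children[counter])
                counter += 1
                z_frac = (k + 0.5) / config.sections_per_segment
                masks, profile = make_section_geometry(z_frac, tp, seg, config)
                transform = RigidTransform(
                    rotation_deg=float(rng.uniform(-rot_max, rot_max)),
                    dx=float(rng.uniform(-t_max, t_max)),
                    dy=float(rng.uniform(-t_max, t_max)),
                )
                warped = {
                    r: np.clip(apply_transform(masks[r].astype(float), transform), 0.0, 1.0)
                    for r in TISSUE_REGIONS
                }
                tissue = sum(warped.values())
                key = GroundTruth.section_id(tp, seg, k)
                obs_masks = _argmax_masks(warped, tissue)
                truth.region_masks[key] = obs_masks
                truth.true_transforms[key] = transform
                truth.lesion_profile[key] = profile

                ys, xs = np.nonzero(tissue >= 0.3)
                order = np.lexsort((xs, ys))
                ys, xs = ys[order], xs[order]
                npix = ys.size
                w = np.stack([warped[r][ys, xs] for r in TISSUE_REGIONS], axis=1)
                signal = w @ templates + baseline[None, :]
                if config.poisson_noise:
                    noise = rng.poisson(
                        max(config.noise_sd, 0.0), signal.shape
                    ).astype(float)
                elif config.noise_sd > 0:
                    noise = np.maximum(rng.normal(0.0, config.noise_sd, signal.shape), 0.0)
                else:
                    noise = 0.0
                factors = _tic_factors(config, rng, npix)
                spectra = (signal + noise) * factors[:, None]
                sections.append(
                    MSISection(
                        mz_axis=axis,
                        coords=np.stack([xs, ys], axis=1),
                        intensities=spectra.astype(np.float32),
                        grid_shape=(n, n),
                        pixel_size=config.pixel_size,
                        metadata={
                            "segment": seg,
                            "timepoint_days": tp,
                            "z_index": k,
                            "z_position_um": k * config.z_spacing,
                        },
                    )
                )

    study = MSIStudy(sections)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (tp, seg), group in study.groups():
            write_imzml(group, out_dir / f"{tp}d_{seg}.imzML")
        for key, masks in truth.region_masks.items():
            label_img = np.zeros((n, n), dtype=np.uint8)
            for i, region in enumerate(REGIONS):
                label_img[masks[region]] = i
            write_mask_tiff(label_img, out_dir / "masks" / f"{key}.tif")
        (out_dir / "ground_truth.json").write_text(truth.to_json())
    return study, truth


def _argmax_masks(warped: dict[str, np.ndarray], tissue: np.ndarray) -> dict[str, np.ndarray]:
    """Exclusive boolean masks in the observed frame (argmax occupancy)."""
    bg = np.clip(1.0 - tissue, 0.0, 1.0)
    stack = np.stack([bg] + [warped[r] for r in TISSUE_REGIONS], axis=0)
    arg = np.argmax(stack, axis=0)
    return {region: arg == i for i, region in enumerate(REGIONS)}
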