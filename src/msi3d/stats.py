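"""Co-localization and discrimination statistics on the feature matrix.

* Pearson co-localization ranks m/z intervals by the correlation of their
  per-pixel intensity vector with a reference — either another ion image or a
  0/1 region mask (point-biserial form).
* ROC analysis scores how well an interval separates two pixel groups; the
  AUC is computed through the Mann-Whitney rank-sum identity with midrank tie
  handling and oriented so AUC >= 0.5, with the higher group recorded.
* Balanced subsampling draws equally from two segments so that a comparison
  against a third segment uses similar numbers of spectra.
* Group summaries report per-group mean, sd and a mean +/- z*sd population
  band; individual spectra outside the band are flagged as outliers (an
  observation interval — a standard-error band would flag nearly everything).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import InputError
from .peakpick import FeatureMatrix

__all__ = [
    "CorrelationResult",
    "ROCResult",
    "GroupSummary",
    "pearson_colocalization",
    "roc_auc",
    "roc_discriminative",
    "balanced_subsample",
    "group_intensity_summary",
]


@dataclass(frozen=True)
class CorrelationResult:
    center_mz: float
    r: float
    rank: int
    zero_variance: bool = False


@dataclass(frozen=True)
class ROCResult:
    center_mz: float
    auc: float
    direction: str  # which group has the higher intensities, "A" or "B"
    n_a: int
    n_b: int


@dataclass(frozen=True)
class GroupSummary:
    group: object
    center_mz: float
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    outlier_rows: tuple = field(default=())


def pearson_colocalization(features: FeatureMatrix, reference) -> list[CorrelationResult]:
    """Rank intervals by Pearson correlation with a reference pixel vector.

    ``reference`` may be a continuous ion-image vector or a boolean/0-1
    region-mask vector of length n_pixels. Zero-variance intervals get r = 0
    with a flag; a zero-variance reference is an error.
    """
    x = features.values
    ref = np.asarray(reference, float).ravel()
    if ref.size != x.shape[0]:
        raise InputError("reference length must equal the number of pixels")
    ref_c = ref - ref.mean()
    ref_ss = float(ref_c @ ref_c)
    if ref_ss == 0:
        raise InputError("reference has zero variance")
    xc = x - x.mean(axis=0, keepdims=True)
    xss = (xc**2).sum(axis=0)
    flagged = xss == 0
    denom = np.sqrt(np.where(flagged, 1.0, xss) * ref_ss)
    r = np.where(flagged, 0.0, xc.T @ ref_c / denom)
    order = np.argsort(-r)
    results = [None] * r.size
    for rank, j in enumerate(order, start=1):
        results[rank - 1] = CorrelationResult(
            center_mz=float(features.centers[j]),
            r=float(r[j]),
            rank=rank,
            zero_variance=bool(flagged[j]),
        )
    return results


def roc_auc(a: np.ndarray, b: np.ndarray) -> float:
    """AUC = P(a > b) + 0.5 P(a = b), by the rank-sum identity with midranks."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([a, b]), method="average")
    r_a = ranks[: a.size].sum()
    return float((r_a - a.size * (a.size + 1) / 2) / (a.size * b.size))


def roc_discriminative(
    features: FeatureMatrix, pixels_a, pixels_b
) -> list[ROCResult]:
    """Per-interval ROC analysis between two disjoint pixel index sets,
    oriented so the reported AUC is >= 0.5, sorted by AUC descending."""
    pa = np.asarray(pixels_a, int)
    pb = np.asarray(pixels_b, int)
    if pa.size == 0 or pb.size == 0:
        raise InputError("both pixel sets must be nonempty")
    if np.intersect1d(pa, pb).size:
        raise InputError("pixel sets must be disjoint")
    results = []
    for j in range(features.values.shape[1]):
        auc = roc_auc(features.values[pa, j], features.values[pb, j])
        direction = "A" if auc >= 0.5 else "B"
        results.append(
            ROCResult(
                center_mz=float(features.centers[j]),
                auc=max(auc, 1.0 - auc),
                direction=direction,
                n_a=pa.size,
                n_b=pb.size,
            )
        )
    results.sort(key=lambda r: -r.auc)
    return results


def balanced_subsample(
    pixels_r1, pixels_c1, n_target: int, seed: int = 0
) -> np.ndarray:
    """Equal-size random draws (without replacement) from two segments.

    The combined subset has ``n_target`` pixels (an odd target puts the extra
    draw in the first segment), mirroring the use of a balanced R1+C1
    reference against the lesion segment.
    """
    r1 = np.asarray(pixels_r1, int)
    c1 = np.asarray(pixels_c1, int)
    n_first = n_target // 2 + n_target % 2
    n_second = n_target // 2
    if n_first > r1.size or n_second > c1.size:
        raise InputError(
            f"n_target={n_target} exceeds available pixels ({r1.size}, {c1.size})"
        )
    rng = np.random.default_rng(seed)
    take_r = rng.choice(r1, size=n_first, replace=False)
    take_c = rng.choice(c1, size=n_second, replace=False)
    return np.sort(np.concatenate([take_r, take_c]))


def group_intensity_summary(
    features: FeatureMatrix,
    grouping: str,
    ci_level: float = 0.95,
) -> list[GroupSummary]:
    """Mean/sd/CI per (group, interval), with per-spectrum outlier flagging.

    ``grouping`` is a column of ``features.keys`` — normally
    ``"timepoint_days"`` or ``"segment"``. The CI is the population band
    mean +/- z(ci_level) * sd; rows whose intensity falls outside it are
    reported as outliers.
    """
    if grouping not in features.keys.columns:
        raise InputError(f"unknown grouping column {grouping!r}")
    if not (0 < ci_level < 1):
        raise InputError("ci_level must lie in (0, 1)")
    z = float(norm.ppf(0.5 + ci_level / 2))
    groups = features.keys[grouping].to_numpy()
    out = []
    for g in pd.unique(groups):
        rows = np.nonzero(groups == g)[0]
        sub = features.values[rows]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        lo, hi = mean - z * sd, mean + z * sd
        for j in range(sub.shape[1]):
            outliers = rows[(sub[:, j] < lo[j]) | (sub[:, j] > hi[j])]
            out.append(
                GroupSummary(
                    group=g,
                    center_mz=float(features.centers[j]),
                    mean=float(mean[j]),
                    sd=float(sd[j]),
                    ci_lower=float(lo[j]),
                    ci_upper=float(hi[j]),
                    outlier_rows=tuple(int(i) for i in outliers),
                )
            )
    return out


def correlation_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "center_mz": [r.center_mz for r in results],
            "pearson_r": [r.r for r in results],
            "rank": [r.rank for r in results],
            "zero_variance": [r.zero_variance for r in results],
        }
    )


def roc_to_frame(results: list[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "center_mz": [r.center_mz for r in results],
            "auc": [r.auc for r in results],
            "direction": [r.direction for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
        }
    )
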