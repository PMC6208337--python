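# msi3d

3D MALDI mass-spectrometry-imaging (MSI) analysis of spinal-cord injury, as a
reusable, tested Python pipeline — with a synthetic spinal-cord phantom that
provides the ground truth real tissue cannot.

## The problem

After a spinal-cord contusion, the injured segment (L) and the adjacent
rostral (R1) and caudal (C1) segments reorganize their lipid content: the
high-MW phospholipid signals (m/z 750–1000) that distinguish gray ("butterfly")
from white matter disappear in affected tissue, while low-MW species
(m/z 300–600) appear. Imaging serial sections at ~40 µm and stacking them into
3D ion volumes shows that long-chain acylcarnitines — AC(16:1) m/z 398.3,
AC(16:0) m/z 400.3, AC(18:1) m/z 426.4 as [M+H]⁺ — outline the lesion as a
hollow, turnip-shaped shell (the lesion margin), while lysoPCs (518.3, 544.3,
546.3 as [M+Na]⁺) and the hemoglobin-derived heme b ion (m/z 616.2, [M]⁺•)
occupy the core. `msi3d` implements the full computational chain needed to
produce and quantify such findings, for anyone analyzing serial-section MSI
studies (imzML in, tables/volumes out).

## What's inside

Each stage is a module; together they form the pipeline:

- **phantom** — synthetic 3-segment × 3-timepoint spinal-cord study with known
  region masks, planted peaks and per-section rigid misalignments.
- **io** — imzML/ibd read–write (continuous and processed mode, via pyimzml),
  CSV/TIFF export, the `MSISection`/`MSIStudy` containers.
- **preprocess** — baseline removal by the iterative min-of-Gaussian-smoothed
  recursion b₀ = s, bₖ₊₁ = min(bₖ, bₖ ∗ G_σ); TIC normalization; mean spectrum.
- **peakpick** — orthogonal matching pursuit over Gaussian atoms
  (σ = a + b·m/z) on the mean spectrum; per-pixel centroid-matching alignment
  into the pixels × intervals feature matrix.
- **segment** — bisecting k-means (Euclidean; split the largest-WCSS leaf by
  2-means) with dendrogram depth cutting.
- **stats** — Pearson co-localization against ion images or region masks,
  Mann–Whitney AUC (midrank ties) with balanced R1∪C1 subsampling, and
  mean ± z·sd group bands with per-spectrum outlier flagging.
- **volume3d** — automated rigid serial-section registration (rotation search
  + phase correlation, NCC-scored), ion volumes D(x, y, z), virtual
  dissection along arbitrary planes, composite/MIP rendering.
- **annotate** — molecular-formula parser, monoisotopic adduct m/z
  calculator, and matching of detected peaks to a bundled lipid table.

A thin CLI (`msi3d simulate|preprocess|peaks|segment|stats|register|volume|
annotate|run-all`) orchestrates the stages with YAML configuration, per-stage
manifests and a single fan-out seed. See `docs/methods.md` for the models,
defaults and design rationale.

## Worked example

Generate a reduced-scale day-3 study (24 sections, 48 px grid, 380–880 Da at
0.5 Da), preprocess it, pick peaks, annotate them and ask which ions mark the
lesion margin:

```python
import numpy as np
from msi3d import (PhantomConfig, generate_study, preprocess_study, mean_spectrum,
                   detect_peaks_omp, align_to_mean, load_candidates, match_peaks,
                   pearson_colocalization, roc_discriminative, balanced_subsample)

config = PhantomConfig(
    grid_size=48, sections_per_segment=8, timepoints=(3,),
    mz_range=(380.0, 880.0), mz_bin_width=0.5, peak_sigma=(0.3, 2.5e-4), seed=7,
)
study, truth = generate_study(config)
processed = preprocess_study(study)
peaks = detect_peaks_omp(mean_spectrum(processed), processed.mz_axis,
                         width_model=config.peak_sigma, residual_fraction=5e-4)
features = align_to_mean(processed, peaks)

for a in match_peaks(peaks.centers, load_candidates()):
    print(f"m/z {a.peak_mz:7.2f} -> {a.candidate.name:32s} "
          f"({a.candidate.adduct}, {a.error_ppm:+.0f} ppm)")

margin = truth.region_vector(features, "lesion_margin")
top = pearson_colocalization(features, margin)[:3]
print("top margin-co-localized intervals:",
      ", ".join(f"{r.center_mz:.1f} (r={r.r:.2f})" for r in top))

seg = features.keys["segment"].to_numpy()
l_pixels = np.nonzero(seg == "L")[0]
ref = balanced_subsample(np.nonzero(seg == "R1")[0], np.nonzero(seg == "C1")[0],
                         n_target=l_pixels.size, seed=1)
best = roc_discriminative(features, l_pixels, ref)[0]
print(f"most lesion-discriminative: m/z {best.center_mz:.1f}  AUC={best.auc:.3f}")
```

Output:

```
m/z  398.35 -> AC(16:1) palmitoleoylcarnitine   ([M+H]+, +66 ppm)
m/z  400.25 -> AC(16:0) palmitoylcarnitine      ([M+H]+, -221 ppm)
m/z  426.40 -> AC(18:1) elaidic carnitine       ([M+H]+, +95 ppm)
m/z  518.32 -> lysoPC(16:0)                     ([M+Na]+, -12 ppm)
m/z  544.38 -> lysoPC(18:1)                     ([M+Na]+, +84 ppm)
m/z  546.31 -> lysoPC(18:0)                     ([M+Na]+, -76 ppm)
m/z  616.18 -> heme b                           ([M]+., +2 ppm)
top margin-co-localized intervals: 398.4 (r=0.99), 400.3 (r=0.99), 426.4 (r=0.99)
most lesion-discriminative: m/z 398.4  AUC=0.938
```

The detected peak set annotates to the acylcarnitine, lysoPC and heme ions
planted in the phantom (centroid errors of tens–hundreds of ppm, as expected
at 0.5 Da binning); the three acylcarnitine intervals are the top-ranked
co-localizers with the true margin mask and near-perfectly separate lesion
from adjacent-segment spectra. Stacking the margin ion's registered images
(`register_stack` + `build_volume`) reproduces the closed turnip shell — the
test suite verifies its connectivity and that it encloses the lysoPC core.

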