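# Methods

`msi3d` re-implements, as a reusable and tested pipeline, the analysis chain
used to localize long-chain acylcarnitines at the margins of spinal-cord
injury (SCI) lesions by 3D MALDI mass-spectrometry imaging: spectral
preprocessing, sparse peak picking, spatial segmentation, co-localization and
ROC statistics, rigid serial-section registration into ion volumes, and
formula-based adduct annotation. Because no public MSI dataset of this design
is available, the package ships a synthetic spinal-cord phantom with complete
ground truth; every claim the test suite makes is a claim about what the
pipeline recovers from that phantom, not about tissue.

## The phantom

**Acquisition design.** Three consecutive cord segments — R1 (rostral to the
injury), L (lesion) and C1 (caudal) — are each represented by
`sections_per_segment` (default 36) cross-sections on a square pixel grid
(default 64 px at 40 µm), imaged at 3, 7 and 10 days post-injury. The default
z spacing is 204 µm: a 12 µm section kept after skipping 16 × 12 µm, which
realizes the "one section per ≈200 µm" design. The defaults give
36 × 3 × 3 = 324 sections. Spectra live on a shared m/z axis, default
300–1100 Da at 0.1 Da bins.

**Cross-section geometry.** A circular cord (radius 0.42 × grid edge)
contains a butterfly-shaped gray-matter region built from two mirrored
dorsal-horn ellipses, two ventral-horn ellipses and a central commissure
ellipse; the remainder of the cord is white matter. The ellipse semi-axes
were fixed once so that the gray:white pixel ratio is ≈0.4.

**Lesion ("turnip") geometry.** Inside the lesion's axial extent the cord
carries a margin shell and a core. The shell's outer radius opens over the
first 8 % of the lesion length, plateaus near 0.95 × cord radius (day 3) and
collapses over the last 10 %; its thickness fraction grows linearly from 0.55
at the rostral entry to 0.95 caudally, so the ring is thin rostrally and
thick caudally. Within 12 % (rostral) / 15 % (caudal) of the lesion ends an
additional cap term closes the ring into a solid spot, so the full shape is
spot → expanding ring → thickening ring → collapse → spot and the shell is
topologically closed. Sub-pixel holes (inner radius < 1 px) are treated as
closed. Axial extents: day 3 covers global fractions 0.30–0.70 of the
R1+L+C1 axis (reaching into the facing ends of R1 and C1); day 7 covers
0.36–0.64 and day 10 0.38–0.62, both confined to L with a smaller radius
(scar formation). All radii and extents are free parameters of the generator
with these documented defaults; they are stylized study conditions chosen to
realize the qualitative anatomy (full-girth shell near the lesion center,
margins thickening caudally), not measurements.

**Spectral forward model.** Each tissue class carries Gaussian marker peaks
with widths from a linear resolution model σ(m/z) = a + b·m/z (default
a = 0.05 Da, b = 1e-4):

| class | peaks (m/z : amplitude, a.u.) |
| --- | --- |
| gray matter | 844.5 : 2000, 830.5 : 1100 |
| white matter | 768.5 : 700, 822.6 : 420 |
| lesion margin | 398.3 : 600, 400.3 : 700, 426.4 : 500 (+50 % of the white-matter peaks) |
| lesion core | 518.3 : 600, 544.3 : 500, 546.3 : 350, heme 616.2 (+35 % of the white-matter peaks) |

The heme amplitude decays with timepoint (400 / 80 / 10 a.u. at days
3 / 7 / 10), modeling hemorrhage resolution. The margin/core retention of
part of the white-matter signal models the penumbra — injured tissue whose
high-MW lipid content is disrupted but not erased. This compositional choice
also determines the clustering topology: after TIC normalization, spectra are
effectively compositions, and the retention places white matter, margin and
core closer to one another in feature space than any of them is to gray
matter, which is exactly the "gray vs everything else" first split the
segmentation is expected to produce. Amplitudes are otherwise arbitrary
units; only ratios matter after normalization.

Each pixel spectrum is `tic_factor × (Σ region-weighted peaks + baseline +
noise)` with a smooth exponential baseline (amplitude 20 a.u. at the low-m/z
end, 300 Da decay constant), truncated-Gaussian noise (σ = 0.5 a.u.; a
Poisson flag exists), and a lognormal per-pixel TIC factor with CV 0.15.
Pixels are emitted only where warped cord occupancy ≥ 0.3 (MSI measurement
regions are drawn around tissue). Every section is resampled (bilinear)
through a random rigid misalignment, uniform within ±3 px and ±5°, recorded
in the ground truth.

**What the phantom does not emulate.** Isotope envelopes, MS/MS
fragmentation, detector saturation, mass-calibration drift, chemical
(matrix-cluster) background off tissue, spectral richness (real tissue has
hundreds of peaks), non-rigid tissue deformation, and histology. Tests
passing on the phantom therefore demonstrate that the pipeline's operations
are correct and recover known structure under realistic noise/misalignment,
not that the pipeline would reach identical conclusions on real tissue.

## Preprocessing

Baseline estimation is the minimum-of-smoothed recursion
b₀ = s, bₖ₊₁ = min(bₖ, bₖ ∗ G_σ) with a Gaussian kernel (default σ = 5 Da,
30 iterations): each iteration can only lower the estimate, so b ≤ s
pointwise and bₖ is monotone in k; narrow peaks are eroded while smooth
background survives. At the axis boundaries the signal is padded with a
robust linear continuation (median slopes of two edge windows) before
smoothing: reflective or constant padding systematically underestimates a
monotone baseline at the edges, which leaves a residual ramp that peak
picking would either have to fit or (worse) that inflates the stopping
criterion. The kernel, iteration count and this recursion are
implementation-defined; no claim is made that they replicate any vendor
software. Corrected spectra are clipped at zero and TIC-normalized to sum 1
(the constant is irrelevant downstream); all-zero pixels are flagged and
excluded from the mean spectrum and feature matrix.

## Peak picking (OMP) and the feature matrix

The baseline-removed mean spectrum is decomposed by orthogonal matching
pursuit over a dictionary of unit-norm Gaussian atoms, one per axis bin, with
σ from the same resolution model. Each iteration selects the atom maximizing
|⟨residual, atom⟩|, re-fits all selected amplitudes jointly by least squares
and recomputes the residual; the pursuit stops at `max_peaks` (default 200)
or when residual energy < `residual_fraction` of the input energy (default
0.01). Atoms whose joint re-fit amplitude is non-positive are discarded (and
re-fit without them). Centers are refined to the intensity-weighted centroid
within ±2σ; refined centers closer than 0.5σ are merged, which absorbs the
correction atom OMP sometimes places next to an off-grid peak. For phantom
analyses the stop is set to 5e-4: after TIC normalization the weakest planted
core lipid carries only ~5e-4 of the mean-spectrum energy, while ~1e-4
already reaches the noise floor.

Alignment to the mean-spectrum peaks: per pixel and peak, the local-maximum
position within ±max(0.2 Da, 2σ) of the peak center is located and intensity
integrated (trapezoid) over that position ±2σ; when the window maximum sits
on the window edge (no interior local maximum) the integral is taken at the
nominal center, so absent peaks report the local residual level rather than
an imputed zero. Rows are pixels, columns are intervals; values are
non-negative normalized intensities.

## Segmentation

Bisecting k-means: starting from one cluster, the leaf with the largest
within-cluster sum of squares (WCSS) is split by 2-means (k-means++, default
10 restarts, best-WCSS solution kept; scikit-learn backend) until `n_leaves`
leaves. Ties in WCSS break toward the older node; leaves with identical rows
are terminal. `cut_tree(depth)` merges nodes below the cut. An optional 3×3
median filter on feature images exists but is off by default. Determinism is
seeded; pixel order does not affect the partition.

## Statistics

Pearson co-localization correlates each interval's pixel vector with a
reference — an ion image or a 0/1 region mask (point-biserial form);
zero-variance intervals get r = 0 with a flag; a constant reference is an
error. ROC analysis uses the Mann–Whitney rank-sum identity with midrank tie
handling; reported AUCs are oriented ≥ 0.5 with the higher group recorded.
For L vs R1∪C1 comparisons a balanced reference is drawn without replacement,
half from each adjacent segment. Group summaries report mean, SD and the
mean ± z·SD population band (default 95 %); individual spectra outside the
band are flagged — a standard-error band would flag nearly every spectrum
and could not reproduce per-spectrum outlier marking. No p-values or
multiple-testing control are computed; the discriminative-AUC report
threshold (0.75) is configurable and carries no inferential weight.

## Registration and volumes

`estimate_rigid` searches rotation coarse-to-fine (±10° at 0.5°, refined at
0.1°, then a second pass at 0.05° around zero residual on the pre-aligned
image, where resampling bias is symmetric); per candidate angle the
translation comes from subpixel phase correlation, and the candidate with the
highest normalized cross-correlation wins. Blank (constant) images are
rejected. `register_stack` proceeds sequentially along z with the first
section as reference; by default each section is registered to the mean of
the last five aligned sections rather than only its immediate predecessor —
per-pair NCC noise from multiplicative pixel speckle otherwise accumulates as
a random walk of ≈0.5°/step, and averaging the reference keeps mean recovery
error below 1 px / 1° on the phantom. Pure chaining remains available
(`reference_policy="previous"`). Registration uses TIC images, since
lesion-specific ions vanish in healthy sections.

Volumes stack one interval's registered images at the section spacing into a
scalar density D(x, y, z) (stored z, y, x; voxel 40 × 40 × 204 µm by
default), with optional linear interpolation to isotropic voxels. Virtual
dissection samples D trilinearly on an arbitrary plane (point + normal, µm);
axis-aligned planes through voxel layers reproduce array slices exactly.
Composite rendering min-max scales each channel, composes additively in RGB
and optionally reduces by maximum-intensity projection; ray-traced emission
rendering is out of scope.

## Annotation

Formulas are parsed from Hill-like notation; monoisotopic masses use
CODATA/AME most-abundant-isotope values; adduct m/z is M + mass(X) − mₑ for
[M+H]+/[M+Na]+/[M+K]+/[M+Li]+ and M − mₑ for the radical cation [M]+•
(the electron mass is irrelevant at 0.1 Da but kept for correctness).
Matching takes the nearest candidate within 0.3 Da (TOF-appropriate);
multiple candidates within tolerance are all reported and flagged ambiguous.
The bundled table covers only the lipids this analysis names: four
acylcarnitines as [M+H]+, three lysoPCs as [M+Na]+ (the only adduct that
reconciles their printed masses), heme b as [M]+•, and PC(16:0/20:4) as
[M+K]+. Two table notes: the species printed as "14:1 tetradecanoylcarnitine
372.3" matches the saturated C21H41NO4 at 372.3 (the 14:1 formula would give
370.3); we encode C21H41NO4 and keep the common name. lysoPC(18:0) as
[M+Na]+ computes to 546.35 (printed 546.3). A PC [16:0/16:0] at m/z 830.5
matches no common adduct of that species and is excluded from the table;
830.5 is still used as a phantom gray-matter marker m/z, which carries no
formula claim.

## Pipeline

Stages (simulate → preprocess → peaks → segment / stats / register → volume →
annotate) exchange artifacts on disk (imzML, CSV, TIFF, JSON) and each writes
a manifest (parameters, derived seed, inputs, version). One global seed fans
out per stage by CRC-32 of the stage name, so stages are independently
reproducible. Missing upstream artifacts raise a dependency error naming the
stage to run first.

## Problem sizes

The test suite exercises the pipeline on reduced realizations of the study
design chosen as sensible desk-scale experiments: grids of 24–64 px, m/z
windows of 380–880 Da at 0.5–2 Da bins with a proportionally wider resolution
model (so peaks stay sampled), and 4–10 sections per segment; noise,
baseline, TIC variation, misalignment ranges and class amplitudes stay at
their defaults. The 324-section design count is verified on a 16 px / 5 Da
realization, since the count is resolution-independent. Full-resolution
default studies are intended to be written section-wise to disk
(`generate_study(..., out_dir=...)`); holding one fully in memory at default
resolution is not practical and not needed by any analysis step, which all
operate per section or on the feature matrix.

## Known limitations

Registration assumes the cord stays rigid and fully inside the grid;
accuracy degrades below ~48 px grids where 1° of rotation moves edge pixels
by < 0.25 px. The OMP dictionary assumes Gaussian peaks on a uniform axis.
The segmentation backend is exact k-means on the full feature matrix — fine
at phantom scales, but a minibatch backend would be needed for
full-resolution studies. The phantom's class templates are low-dimensional;
statistics that depend on rich spectral correlation structure (e.g.,
correlation between many co-varying lipids) cannot be validated against it.
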