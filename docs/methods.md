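# Methods

`filbundle` analyses cross-linker bridges between actin filaments in cryo-EM:
it fabricates synthetic training data of cross-linked filament pairs, picks
two-filament bundle particles from micrographs with small learned networks,
classifies the relative polarity of bundle class averages by projection
matching, builds initial two-filament models, and measures per-particle bundle
geometry (skew, splay, interfilament distance, bridge span) from multibody
poses. This note records the models, conventions and numerical choices, and
what the synthetic benchmarks do and do not demonstrate about real data.

## Conventions

Coordinates are Angstrom in right-handed axes. Images are `(row, col)` with
row 0 at top, 0-based indices, pixel centers on integers. Maps and
micrographs are MRC2014 (micrographs as nz = 1 volumes); models are PDB/mmCIF
(mmCIF preferred when both exist; altlocs resolved to highest occupancy, ties
to first encountered); particle metadata are RELION-dialect STAR tables with
ZYZ intrinsic Euler angles in degrees and translations in Angstrom, rotations
taken about each body's center. Helical symmetry defaults to canonical
F-actin values, rise 27.5 Å and twist −166.7° per protomer; both are
configurable, as no value in the package depends on them being exact.

## Bundle geometry: the common frame

A two-filament bridge is described by polarity, two angles and two spacings.
With filament A as reference (unit plus-end direction **ẑ**, origin at its
body center) and **Δ** the displacement to filament B's body center:

* **x̂** = unit component of **Δ** perpendicular to **ẑ**; **ŷ** = **ẑ** × **x̂**.
* B's direction **d̂** is flipped when **d̂**·**ẑ** < 0 (antiparallel), so both
  polarities measure deviation from their own ideal.
* **splay** = atan2(**d̂**·**x̂**, **d̂**·**ẑ**) — in-plane rotation, positive
  toward +**x̂**;
* **skew** = asin(**d̂**·**ŷ**) — out-of-plane tilt, positive toward +**ŷ**;
* **interfilament distance** = |**Δ** − (**Δ**·**ẑ**)**ẑ**|, the
  origin-referenced axis separation; the minimum distance between the two
  infinite axis lines is reported alongside as `axis_min_distance`.
* **axial offset** = **Δ**·**ẑ**.

The frame is anchored to the body centers rather than the lines' mutual
perpendicular for two reasons. First, a frame built on the mutual
perpendicular cannot decompose the inter-axis angle into two components at
all (the second axis is always orthogonal to that displacement, so the
in-plane component vanishes identically); body centers supply the reference
the decomposition needs, and they are exactly what multibody refinement
reports. Second, it makes the construction an exact inverse of the simulator:
`place_pair` realises any configuration as two poses and `pair_geometry`
recovers every parameter to 1 × 10⁻⁹, which is asserted over 1,000 random
configurations. The price is a documented asymmetry: swapping A and B
re-expresses the decomposition in the other filament's frame, preserving
polarity and the total inter-axis angle exactly but not the individual
skew/splay signs, and changing the origin-referenced distance by at most the
projection factor set by the inter-axis angle (the line-line minimum distance
is exactly swap-symmetric). Filament A is therefore a deliberate, stated
reference choice. Exactly coincident axes are flagged degenerate with
distance and angles zero. Only magnitudes and displacement-from-zero of skew
and splay are treated as comparable across sign conventions.

**Bridge span** is the distance between the Cα centroids of the two actin
protomers anchoring the cross-linker: the protomer contacted by the CH1-side
actin-binding surface and the one contacted by the CH3-side surface, each
identified by a 4.0 Å heavy-atom contact cutoff (most-contacted chain wins).
Protomer-centroid anchoring is this package's declared definition; with
protomer centroids ~25 Å off-axis and axes ~146 Å apart, it yields spans in
the observed ~93–98 Å range.

**Residue annotation.** The T-plastin landmarks used by the measurement
operators (CH1–CH4 domain ranges; the 28-residue CH1–2 linker at 240–269, the
20-residue CH2–3 linker, the 7-residue CH3–4 linker; markers I309, P363,
D332, W390, F191, R594/R595; modeled ABD2 range 388–630) ship as defaults in
`PlastinAnnotation`. Only the linker lengths and stated ranges are pinned by
the structures; the remaining CHD boundaries are reasonable defaults and are
meant to be overridden from configuration when exact boundaries are
available. The CH2–3 linker can also be auto-located as the chain gap nearest
residue 388.

## Structural measurements

Superposition is Kabsch (SVD of the cross-covariance with the reflection
branch disallowed); collinear or under-determined point sets raise rather
than return an arbitrary rotation. Rotation magnitudes are extracted via
quaternions, which stay accurate near 0° and 180° where the trace formula
loses precision. Domain swings superpose two conformations on an alignment
selection (Cα, residue ranges), then report the rotation of the measurement
selection; landmark displacements and orientation-vector angles (e.g. the
I309→P363 CH2 vector) follow the same align-then-measure pattern. Linker
end-to-end distances are measured between the Cα atoms flanking a
residue-numbering gap. Two subtly different end-point definitions exist for
such distances (linker terminus residues vs. resolved flanking residues);
both are expressible through the `gap` argument and neither is canonised.

Filament axes are fitted to ordered protomer centroids by minimising the
variance of point-to-line distances (all helix points share one radius),
initialised from the principal component and refined by trust-region least
squares with the axial-shift null direction removed from the
parameterisation. The direction is signed so it points toward the plus end
given minus→plus input order; rise and twist estimates and an RMS radial
residual are returned as diagnostics, with a warning flag when the residual
is large relative to the fitted radius. With 13 centroids and 1 Å Gaussian
noise the direction is typically recovered within ~1°.

## Synthetic data

The generator's defaults are the package's study conditions.

**Decorated protomer.** A synthetic pseudo-atom protomer (70-atom "actin"
lobe near the axis, 24-atom "ABD" lobe protruding to ~38 Å radius, and a
10-atom arm slanted toward the plus end) stands in for a real decorated
asymmetric unit so that nothing needs downloading. The plus-ward slant makes
filament projections polar — the property the polarity classifier exploits —
mimicking the arrowhead-like asymmetry of genuinely decorated filaments.
Volumes are sums of per-atom isotropic Gaussians (FWHM = nominal resolution,
default 12 Å; integral exactly one weight unit per atom), repeated under the
helical symmetry.

**Bundle configurations** are sampled i.i.d. uniform per parameter:
interfilament distance 120–180 Å (bracketing the measured ~146–149 Å means),
skew and splay ±30°, axial offset ± half a rise, spins and view angles over
their full ranges, polarity 50/50. These wide ranges describe *per-particle*
pose variability. Two derived regimes are narrower by construction:

* **Scenes** (`compose_scene`): relative tilts between bridged filaments stay
  small over micrograph-scale lengths — a pair diverging at 30° would exceed
  any plausible bridge span within one particle length — so scene-level
  skew/splay are sampled at ±8° and splay is applied symmetrically about the
  bundle midline. Views span the full top-to-side range.
* **Class averages** (`make_class_averages`): 2D classification aligns many
  particles, so residual within-class spread is modest; averages are
  generated with skew/splay ±12° and near-top views (roll ≤ 25°), without
  CTF (averages of many CTF-corrected particles), at the stated snr.

**Projection** is an orthographic line integral after rigid scene rotation
(resampled with `scipy.ndimage.affine_transform`; line-integral step carries
Å units so integrated intensity is conserved to <0.1%). View tilt 0 is a top
view (both filaments resolved), 90° a side view (superimposed). **CTF
corruption** applies CTF(s) = −[√(1−A²)·sin χ + A·cos χ] with
χ = πλzs² − (π/2)Csλ³s⁴ (underfocus positive; 300 kV, Cs 2.7 mm, amplitude
contrast 0.07, defocus sampled 0.8–2.5 μm per scene), then white Gaussian
noise scaled so var(signal)/var(noise) equals the requested snr over the
whole frame. No structured noise (ice gradients, carbon edges) is modelled —
a known limitation bounding what the picking benchmarks say about real
micrographs.

**Scenes and labels.** Micrograph-scale scenes place singles, two-filament
bundles and 3–4-filament assemblies by rejection sampling with a minimum
separation. Filament density is rendered analytically in 2D (projected
core + decoration-shoulder transverse profile, 55 Å axial modulation) at
4.4 Å/px — a deliberate fast path; the volumetric projection route is
exercised by the library/polarity stack. Class labels are *object bands*: the
filled region within one half-width of any filament of the object plus the
band between a bundle's filaments, with higher-order > bundle > single
priority on overlap. Band labels (rather than per-filament ribbons) make the
bundle midline — where ground-truth picks are laid every 50 px — part of the
bundle class, and give the segmenter a target whose connected components
correspond to objects. Datasets are emitted with a manifest holding every
seed and parameter; regeneration is bit-identical.

## Picking networks

Two deliberately small scikit-learn MLPs operate at a 2× working binning
(8.8 Å/px effective):

* **Denoiser** — an MLP regressor (17×17 window → 64 hidden → center pixel)
  trained with MSE on standardized (noisy, clean) pairs; ~19k weights.
* **Segmenter** — an MLP classifier over a multiscale window stack (11×11 at
  1×, 2×, 4×, 8× decimation → 484 features → 96 hidden → 4 classes); the 8×
  scale gives a ~775 Å receptive field, wide enough to tell a 3–4-filament
  assembly from a bundle. Class weighting is implemented by resampling
  (background oversampled 3×, suppressing false positives on empty ice);
  training pixels are drawn per class per patch; a held-out patch split
  tracks per-class accuracy. The denoiser's output is the segmenter's input
  by default; raw-input segmentation is a flag.

Per-pixel prediction makes tiled inference exactly equal to untiled inference
(asserted); inference runs on a stride-2 grid with bilinear upsampling of the
probability maps. Training and inference are deterministic under fixed seeds.

**Pick extraction**: smooth the probability maps (σ = 3 px full-scale),
threshold the bundle-class probability at 0.5, drop tiny components, then per
component (i) veto components carrying appreciable single-class (> 0.07 mean)
or higher-class (> 0.05 mean) probability — a genuine two-filament component
is nearly pure; (ii) skeletonize, take the longest path (this prunes
branches), smooth it, extend the ends by the local half-width (skeletons
erode ribbon ends), and emit picks every 50 px of arc length; (iii) drop
components shorter than 60 px and picks whose box overlaps predicted
higher-class pixels beyond 25%. Pick scores are mean bundle-class
probabilities; a pick matches ground truth within half a pick step. The veto
and threshold values are configuration, chosen on development scenes separate
from the held-out benchmark seeds.

At the benchmark conditions (training on 200 patches at snr 0.2, twenty
held-out 1024² scenes) the picker reaches precision and recall ≈ 0.85 with
≈ 6% of picks on single filaments. Because the scenes are rendered with the
analytic 2D path and white noise, these numbers demonstrate the pipeline's
internal consistency and the pickability of the geometry, not performance on
real micrographs.

## Polarity by projection matching

The reference projection library samples a (tilt, psi) grid of the decorated
single-filament map (axis on z): psi spins the filament about its own axis,
tilt rocks it through the image plane. The polarity library uses tilts
74–106° in 8° steps — symmetric about in-plane, since a filament can flex out
of plane either way — and 12° spin steps. Matching is exhaustive normalized
cross-correlation over library entries × in-plane rotations with FFT
translation search; rotated-reference FFTs are cached per rotation grid; ties
break lexicographically toward the smallest (tilt, psi, rotation). Matching a
library entry to itself scores 1 to 10⁻⁶.

`classify_polarity` estimates the bundle axis from the intensity
second-moment tensor — which turns unreliable for short, widely spaced pairs
whose moment tensor is nearly isotropic — so it searches a small fan of
candidate axis angles (estimate ± 0/30/60/90°), rotates the average
axis-horizontal for each, and locates the two filament tracks as the
strongest pair of row-profile peaks separated by a physically plausible
spacing (16–48 px at 4.4 Å/px, i.e. ~70–210 Å). The winning pair must be
genuinely prominent (normalized peak prominence ≥ 0.33): merged side-view
ridges expose only weak axial ripples at any candidate rotation (measured
ceiling ≈ 0.26 at snr 1) while true twin tracks typically score ≥ 0.44, so
the gate rejects side views without guessing. Each track is then cut out as a
cosine-tapered strip and matched over rotations near 0°/180°; polarity is the
sign of the dot product of the two matched in-plane plus-end directions,
confidence the weaker of the two scores. Inseparable averages return
*indeterminate* rather than a guess; a bare (undecorated) filament would
match 0° and 180° nearly equally, surfacing as low confidence. At the
benchmark conditions (200 averages, snr 1.0) accuracy is ≈ 98–100% with zero
indeterminate calls; averages with every geometry parameter simultaneously at
its range extreme can fall in the narrow band between the side-view ceiling
and the prominence gate and come back indeterminate (observed once in 400
across two seeds).

**Initial models** resample two copies of the single-filament map at their
matched orientations into one box; given additional class averages at other
views, the copy-B offset along the unresolved (beam) axis is refined on a
local grid (default ±30 Å in 5 Å steps) by maximising summed normalized
correlation between composite projections and the averages. Half-masked (per
track) matching rather than whole-average matching is this package's own
choice.

## Rigid-body docking

Docking maximizes real-space normalized cross-correlation: a coarse stage
over rotation offsets (±10° default, 5° steps per axis) with the optimal
translation per rotation found by FFT cross-correlation (capped at ±10 Å),
then Powell refinement of all six parameters on a cubic-spline resampling of
the template (spline-filtered once; xtol 2 × 10⁻³). Trilinear interpolation
was found to bias sub-voxel optima by ~1–2 Å/°; cubic interpolation removes
it. Under the benchmark conditions (perturbations ≤ 5°/5 Å, map noise at
snr 2) recovery is within 0.5° and 0.5 Å in 20/20 seeded trials, with median
errors ≈ 0.05°/0.05 Å. A correlation floor (default 0.2) flags low-confidence
docks.

## Distribution summaries

`summarize` reports per-parameter mean, sample SD (n−1), n, histograms and
the Pearson correlation matrix; constant columns get SD 0 and NaN
correlations with an explicit flag, and fewer than two rows is an error.
Outputs are asserted against brute-force loop implementations to 10⁻¹².
Simulated multibody tables with Gaussian skew/splay at the measured
parallel/antiparallel moments, pushed through pose ingestion → geometry →
summary, recover the generating means and SDs to sampling error and show
|skew–splay correlation| < 0.05, the independence signature expected of a
freely flexing cross-linker.

## Problem sizes

Benchmarks run at deliberate desk scale on one CPU: 1,000-configuration
round-trips, 20 docking trials on 45³ templates, 200 training patches and 20
held-out 1024² scenes for the picker, 200 class averages for polarity, and
n = 10,000 summary draws. The per-particle distributions of the deposited
study (tens of thousands of particles per polarity) are not reproducible
without the original particle data; the simulated-table recovery above is the
corresponding desk-scale check of the measurement chain.

## Known limitations

* Scene rendering is analytic 2D (no volumetric scene projection, no
  structural noise or ice gradients); picker metrics are internal-consistency
  results.
* The synthetic protomer is a labelled stand-in, not real coordinates;
  absolute match scores are not transferable to real maps.
* The segmentation networks are windowed MLPs, not encoder–decoder conv
  nets; they have no translation-equivariant inductive bias beyond the
  window structure, traded for minutes-scale CPU training.
* Skew/splay signs are convention-bound (filament-A reference); only
  magnitudes and offsets from zero are comparable across analyses.
* CTF is applied without phase flipping or envelope; defocus is per scene,
  not estimated from data.
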