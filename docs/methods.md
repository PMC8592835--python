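# Methods

This note documents the models, conventions and design choices behind
`histostress`, in the spirit of a methods appendix: what each component
computes, which parameters matter, and what the synthetic data does and
does not emulate.

## Raster and optical-density conventions

All processing operates on 8-bit RGB patches (default 300 × 300 px), stored
row-major with the origin at the top-left; coordinates are `(row, col)`,
0-based, half-open. Optical density uses the base-10 logarithm with
reference white `I₀ = 255` and the transmitted intensity floored at 1
before the log, so OD is finite and bounded by `log10(255) ≈ 2.41`. These
are conventions, not measurements: they match the dominant practice in
stain-deconvolution implementations and make `od_to_rgb ∘ rgb_to_od`
invert to within one intensity unit (8-bit quantization).

## Artifact generators

**Focus.** Level `L ∈ 1..16` blurs with a square Gaussian window of side
`k = 2L − 1` px; the standard deviation follows the common imaging
convention `σ = 0.3·((k−1)/2 − 1) + 0.8`, with reflective borders. Under
this parameterization level 1 (k = 1) is exactly the identity. Because
real scanners can produce sub-pixel defocus even at nominal "level 1", an
alternative `radius` mode (`σ = k/3`, window auto-sized at 4σ) perturbs at
every level; the default remains window mode.

**JPEG.** Encode/decode round trip through the JPEG codec with chroma
subsampling pinned at 4:2:0 so results do not depend on codec build
defaults. The default ladder runs from the scanner-standard quality 80
(the undegraded reference) down to 5 in steps of 5.

**Flips and rotations.** Mirror images and multiples of 90°, so no border
content is ever fabricated. Arbitrary angles are deliberately excluded:
they would require inventing pixels outside the patch.

**Elastic deformation.** Control points on a regular grid (cell side
30–110 px in the default ladder, centred on 70 px) are displaced by i.i.d.
uniform offsets in `[−m, m]` per axis with `m = grid/8` by default — large
enough to visibly wave gland boundaries, small enough to stay in the
visually plausible range. Offsets are interpolated bicubically to a dense
displacement field; the patch is resampled bilinearly with reflective
padding. Bilinear sampling cannot overshoot, so the output range is
contained in the input's, and zero magnitude is the exact identity.

**Brightness / contrast.** Brightness is multiplicative gain
`I' = I·(1+δ)`; contrast scales deviations from the patch's mean Rec. 601
luma `I' = μ + (1+δ)·(I−μ)`. The two are orthogonal (contrast fixes μ,
brightness scales it) and both step in ±0.1 increments, ±0.5 at the ladder
ends.

**Overlays.** Dark spots, threads, squamous clusters and the fingerprint
fat drop are RGBA templates alpha-composited onto the patch:
`out = α·template + (1−α)·patch`, leaving everything outside the footprint
bit-identical. Template inventory: 3 dark-spot sizes (opacity 0.6–0.95),
10 thread paths (opacity 0.85), 20 squame clusters (opacity 0.35 with
faint nuclei), 1 elliptical bright-rimmed drop (opacity ≤ 0.4, mostly
0.2). Threads additionally blur patch content inside their footprint
dilated by a 12 px halo (9 px Gaussian window), emulating the focal focus
distortion threads cause at scan time; the other overlay kinds do not
affect focus. Placements are drawn uniformly over offsets that keep the
template fully inside the patch; multi-object placements are re-drawn
until centers are at least half a template diagonal apart. Template
opacities and the halo extent are package choices — plausible values, not
measured ones.

## Stain normalization and transfer

Estimation is the Macenko procedure: background pixels are removed with an
OD threshold β = 0.15 (a pixel counts as tissue when *any* channel exceeds
β — requiring all channels would discard eosin-dominant stroma, whose
red-channel absorbance is far below β); the remaining OD cloud is
projected onto its two principal directions (eigenvectors of the OD
covariance), oriented so the cloud lies in the positive half-plane
(otherwise the angle distribution wraps at ±π and percentiles are
meaningless); the α = 1 and 99 angle percentiles give the two extreme
directions, mapped back to nonnegative unit 3-vectors. Hematoxylin is the
column with the larger red-channel component — the convention that keeps
scheme-to-scheme assignments consistent. Concentrations are the
pseudo-inverse projection with negatives clipped to 0 (an exact NNLS path
exists behind a flag; it is orders of magnitude slower and visually
indistinguishable on H&E material). `max_concentrations` is the per-stain
99th percentile, the robust "stain strength".

Transfer rescales each stain's concentration map by
`target.max / source.max` and reconstructs through the target matrix.
Degenerate inputs raise typed errors: fewer than 0.5% tissue pixels
(near-white patch) or an effectively rank-1 OD cloud (single stain,
detected by an eigenvalue ratio below 1e−4).

Brightness standardization divides CIELAB lightness by its 95th percentile
(clipping to the valid range), pinning glass background at white. A patch
whose L p95 is already within one 8-bit gray level of white (≥ 99.0) is
returned unchanged, which makes the operation exactly idempotent.

The staining sweep runs on *unnormalized* patches (transferring a
normalized patch to a distorting scheme would cancel the artifact);
all other sweeps can optionally normalize first, matching how a
stain-normalized classifier is deployed.

## Synthetic data

Patches are rendered in stain-concentration space — a hematoxylin field
(nuclei) and an eosin field (cytoplasm/stroma) — and pushed through a
fixed reference stain matrix (columns ∝ (0.65, 0.70, 0.29) and
(0.07, 0.99, 0.11)), with 1.5% multiplicative noise on the fields. Because
the generative stain vectors and concentrations are known exactly, Macenko
recovery is testable by construction. Class geometry: GLAND renders 2–5
large glands (outer radius 45–70 px) with open near-white lumina and a
single nuclear rim; TUMOR renders 8–20 small crowded glands (12–22 px)
with scant lumina, dense rims and 150–300 scattered nuclei; NONGLAND
renders wavy fibrous eosin streaks, optional fat vacuoles and sparse
nuclei. The scheme bank re-renders a fixed glandular geometry under
per-scheme hue jitter and concentration gains 0.4 → 1.6 (S01 weakest, S09
strongest; REF = 1.0), giving a monotone weak-to-strong staining gradient.

What the generator emulates: the color statistics, nuclear blob texture,
lumen geometry and staining variation that stain/texture-based features
respond to. What it does not: real tissue morphology (no pathologist would
be fooled), scanner-specific resolution or color profiles, and the
morphological confounders (HGPIN, inflammation, retraction) that drive
misclassification structure in real material. Passing degradation tests
therefore demonstrates that the *harness* behaves correctly and that the
artifact operators destroy the information they are meant to destroy — not
that any particular clinical model is robust.

## Toy classifier

The bundled classifier exists to exercise the protocol end to end. It
scores four stain-deconvolved features — nucleus-blob count (connected
components of the hematoxylin map above 0.5, area ≥ 4 px), near-white area
fraction, mean squared Laplacian edge energy, and mean eosin concentration
— with a nearest-centroid rule on z-scored features; probabilities are a
softmax over negative squared centroid distances. Centroids are calibrated
on a freshly generated clean batch (16 patches/class, seeded). On clean
synthetic data it is 100% accurate, so baseline filtering retains
(essentially) everything and baseline F1 is exactly 1.0; its features are
genuinely blur-sensitive, so the focus ladder produces a steep, monotone
F1 collapse dominated by false negatives. It is deliberately much more
brittle than a trained CNN — its curves illustrate the harness, and their
absolute values should not be compared with any published model's.

## Problem sizes and numerical choices

Default in-memory experiments use the desk-scale composition 500/500/200
(the full 50,000/50,000/20,000 composition is supported via the manifest
dry-run and on-disk generation). The test suite runs its heaviest check —
focus and JPEG full ladders on the 1,200-patch desk-scale set — in about
five minutes on one CPU. Per-patch artifact randomness derives from
`(global seed, CRC32(patch id), CRC32(level))`, so curves are reproducible
and patch-aligned across artifacts, which the misclassification-overlap
(Venn) analysis requires. Whether randomness should be re-drawn per
severity level or shared across levels is underdetermined; independent
per-level draws are used.

## Known limitations

- Overlay templates and staining schemes are synthetic stand-ins rendered
  by the generator, not extracts from scanned slides.
- The elastic ladder's five grid sizes and the photometric ladder
  endpoints are package choices around the one printed anchor (70 px grid;
  ±10% steps).
- Tissue folds and pen marks are not modeled.
- F1 with a zero denominator is defined as 0; other conventions exist.
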