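# Methods

This note records the model and procedure behind `nucleocarta`, the
choices made where the design was genuinely open, and what the synthetic
tests do and do not establish about real microscopy data.

## Coordinate conventions

All geometry lives in the raster pixel frame: pixel (0,0) at the
top-left, x rightward, y downward, pixel centres at integer coordinates.
The canonical (oriented) pose puts the hook tip at the left end of a
horizontal hook-tip → tail-attachment chord, the boundary centroid at the
origin, and the dorsal side at smaller y (so images display hook-up).
Oriented boundaries are traversed with positive shoelace area, which runs
from the hook tip along the dorsal side first, and are re-indexed to
start at the hook tip. Areas convert to µm² through the square of the
pixel calibration (default 0.05 µm/pixel, a typical 100× epifluorescence
scale; always configurable, never inferred from files).

## Segmentation and landmarks

Nuclei are found in the counterstain channel by Otsu threshold, hole
filling and 8-connected components, filtered by area (default
10–60 µm², bracketing swelled sperm nuclei) and solidity (> 0.7).
Border-touching objects are dropped; clumps are rejected rather than
split, which is safe because all downstream quantities are population
aggregates. Boundaries come from sub-pixel contour tracing, resampled to
uniform ~1 px arc spacing.

Curvature is measured as a sliding-window interior angle: the value at
boundary point *i* is the angle at that point subtended by the points
half a window behind and ahead, with the window a fraction (default 5%)
of the boundary length. This windowed angle is robust to pixel-level
boundary noise; note that on an ideal circle it equals 180° − w·180° for
window fraction w (the inscribed-angle theorem), not 180° exactly.

The hook tip is the global minimum of this profile (the sharpest convex
protrusion); the tail attachment is the most prominent remaining local
minimum at least a quarter perimeter away from the hook, with ties broken
toward the smallest index after the hook for determinism. Outlines whose
profile is too flat (range < 25°) or that lack a qualifying tail minimum
— circles, debris — are flagged unanalysable and excluded.

Auxiliary landmarks are a run parameter, default 0. A 2-anchor
"hook-flank" mode exists for strongly hooked outlines: the bottom of the
hook bay (the most prominent concave maximum of the profile) paired with
the nearest point of the opposite hook–tail arc (the far side of the
hook throat). It anchors the across-hook vertex pairing of the mesh but
is not needed in the default swelled regime (below) and so is off by
default.

**Mirror detection.** Both chord endpoints (hook tip, tail pole) sit
dorsal of the bulk of the nucleus, so in the canonical pose the centre
of mass lies ventral of the horizontal chord. A nucleus whose chord
falls below its centroid after rotation is therefore mirror-imaged and
is flipped (recorded in the `flipped` flag). This chord-versus-centroid
test has a margin of roughly a micron on realistic shapes, where cues
local to the tip (which straddles the chord) proved unstable to noise.

## Consensus and mesh

Each oriented outline is resampled segment-wise: a fixed number of
arc-length-equidistant points per inter-landmark segment ("equidistant"
is read as equidistant in arc length; it is the only reading that is
stable under the rigid orientation step). The consensus shape is the
pointwise arithmetic mean of these resampled boundaries — no Procrustes
scaling, because nuclei are already rigidly aligned and size differences
between strains are biology to be preserved, not nuisance.

The mesh on any boundary with the run's landmark structure: peripheral
vertices are the landmarks plus the requested semi-landmarks per segment
(default 20). Walking pairwise from the hook tip, the *i*-th vertex after
the tip pairs with the *i*-th before it; each pair contributes an
internal vertex at its chord midpoint, tracing a midline skeleton from
tip to base. Faces triangulate the tip cap, the dorsal and ventral band
quads between consecutive pairs (each split along the diagonal toward
the tip-ward internal vertex — any consistent split works where the
quads are simple), and a fan from the last internal vertex over unpaired
basal vertices. The structure signature encodes landmark count,
per-segment counts and face connectivity only, so meshes from
differently shaped nuclei with equal counts are graph-isomorphic and
per-face affine maps between them are always defined.

**Degenerate meshes.** On deeply curled, unswelled hooks the midpoint
skeleton can reverse inside the hook-bay concavity, folding band quads
so that no diagonal split tiles them. Such meshes raise a degenerate-mesh
error and the nucleus is excluded from the run; faces are never silently
re-oriented, since that converts a construction failure into a quiet
tiling violation. In the swelled regime the pipeline actually analyses
(see below) this exclusion is not observed across hundreds of random
outlines. Supporting strongly curled shapes would need landmark-anchored
pairing richer than the midpoint rule — a known limitation.

## Warping and composites

FISH channels are binarised per nucleus before warping (threshold
computed within the nucleus mask only; default: half the in-mask
maximum, with Otsu and fixed thresholds available), so bright and dim
hybridisations contribute equally. Warping is forward: each ON pixel's
centre moves by the affine map of the source face containing it
(pixel-to-face assignment by barycentric test, shared-edge ties to the
lower face index) and lands at the nearest target pixel. Forward mapping
leaves holes where a target face is larger than its source face; the
gap-filling kernel exists precisely for this: in a single pass computed
from a frozen copy of the input, any zero pixel with ≥ 4 non-zero
8-connected neighbours becomes their mean (for binary rasters, 1). The
pass count is configurable (default 1). Results are clipped to the
target polygon. The target raster is the template polygon's bounding box
plus a 2-pixel margin, so all warps onto one template share a pixel grid.

Composites are per-pixel means of the binary warped rasters — values in
[0, 1], with value × n integral. Composites persist as 16-bit TIFF with
a JSON sidecar recording n and the linear scale; renderings use the
cividis palette.

## MS-SSIM*

Similarity of warped/composite images uses multi-scale SSIM with the
canonical 5-scale exponents (0.0448, 0.2856, 0.3001, 0.2363, 0.1333),
an 11×11 Gaussian window (σ = 1.5), contrast/structure at every scale,
luminance at the coarsest, combined as a weighted geometric product and
clamped to [0, 1]. Constants default to K1 = 0.01, K2 = 0.03 with the
dynamic range taken as the maximum of the pair; all are configurable.
The \* modification defines the score on degenerate windows (reachable
when the stabilising constants are zero, and the right semantics for
binarised and composite images that are flat almost everywhere): windows
where both images have zero variance and equal means contribute 1,
windows where only one image is flat contribute 0. Variances are left
unclamped so that identical inputs give bitwise-equal numerator and
denominator — self-similarity is exactly 1, not 1 − ε. Images too small
for the requested scales reduce the scale count with a warning and
renormalised exponents.

## Signals, distances, statistics

Discrete signals are 8-connected components of the thresholded in-mask
raster, filtered at 0.3 µm² minimum area, summarised by
intensity-weighted centre of mass. Distances between co-hybridised
probes are Euclidean, in µm. Distance sets are compared with two-sided
Wilcoxon rank-sum tests (exact null distribution for small untied
samples, normal approximation otherwise — R's policy); groups under 3
are refused. Note the exact test's floor: complete separation at n = 3
per group gives p = 0.1, so no 3-vs-3 comparison can reach p < 0.05.
Cross-population similarity matrices require all composites on one
template; the matrix is symmetric with unit diagonal.

## The synthetic generator

The generator emulates the nuclei the pipeline actually sees: sperm
heads after the DTT swelling required for FISH, whose area roughly
doubles (to ~30–40 µm²), whose swelling is mostly dorso-ventral, and
whose outlines are smoother with a milder hook than unswelled sperm. A
nucleus is a parametric midline (straight body, hook curl over the
apical third, total turn `hook_curl` radians) with a tapered half-width
profile (pointed tip, thinned hook, rounded-pointed base pole whose
wedge is the tail-attachment curvature landmark), plus optional smooth
shape noise applied in shape space (multiplicative on the half-width,
additive on the midline, pinned at tip and base) so outlines stay simple
and the ground truth tracks the noise. Default strains: two similar
elongated shapes (10.0 × 5.6 µm and 10.2 × 5.7 µm, curl 1.3/1.25 rad)
and one shorter, wider shape (8.8 × 6.2 µm, curl 1.15 rad), giving areas
of ~33–35 µm².

Signals are Gaussian blobs (σ = 0.5 µm, a chromosome-paint-like scale)
planted at (u, v) addresses — u the arc fraction along the midline from
hook tip to base, v the signed fractional offset toward dorsal (+) or
ventral (−). Named addresses: `dorsal_subacrosomal` (0.35, +0.50)
emulating the conserved sex-chromosome territory, `ventral_basal`
(0.72, −0.45) emulating the chr11/chr19 territory. Each nucleus draws
its own position from a truncated Gaussian around the address (defaults
σ_u = 0.06, σ_v = 0.12; the autosome-like cohorts use broader scatter
drawn independently per probe), and with probability `placement_noise`
(default 0.05 in the test cohorts — an occasional mis-hybridisation) the
signal is instead uniform inside the nucleus. Fields hold up to 3
non-overlapping nuclei at random rotation and mirror; rendering is 8-bit
with Gaussian read noise and smoothed edges.

**What passing tests show — and not.** The generator gives planted truth
for every quantity, so the tests establish that the chain
segmentation → landmarks → orientation → consensus → mesh → warp →
composite → metric is internally correct and recovers known addresses
through realistic pose, placement and rendering noise. It does not
render chromatin texture, acrosomes, uneven illumination, overlapping
probes, hybridisation-efficiency differences between species, or the
swelling process itself, so performance on real micrographs (especially
segmentation and threshold choices) still needs checking against real
data.

## Problem sizes and numerical choices

Default analyses in the test suite use populations of 24–200 nuclei at
0.05 µm/pixel in 512² fields — large enough for composite frequencies
and rank-sum tests to be meaningful while a full suite run stays within
a few minutes. Determinism throughout: one seeded generator per run;
equal-prominence landmark ties break toward the smallest index after the
hook tip; pixel-face ties toward the lower face index; orientation is
idempotent. Degenerate inputs (blank channels, empty warps, all-zero
rasters) yield empty results rather than errors wherever the quantity is
well-defined as empty.
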