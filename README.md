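# nucleocarta

Automated mapping of FISH signals in asymmetric nuclei — "nuclear
cartography" for the falciform (hooked) mouse sperm head.

## The problem

Where a chromosome territory sits inside a sperm nucleus has traditionally
been scored by hand: divide the nucleus into zones, look at each cell,
tally which zone the fluorescence in-situ hybridisation (FISH) signal
falls in. That is slow, subjective, and caps the number of nuclei anyone
can analyse. Round nuclei can be automated with concentric-shell
erosion, but a sperm head is not round. The mouse sperm nucleus is
falciform — hooked — with distinct anterior–posterior and dorso-ventral
axes, which is bad news for shell analysis but good news for automation:
the shape itself fixes an unambiguous 2D coordinate frame.

`nucleocarta` exploits that. For every segmented nucleus it:

1. detects **curvature landmarks** on the boundary — the apical hook tip
   (sharpest convex protrusion of the interior-angle profile) and the
   tail-attachment point at the base — and uses them to rotate, mirror
   and re-index each nucleus into one canonical pose;
2. builds a **structurally equivalent triangular mesh**: semi-landmarks
   spaced equidistantly (in arc length) between landmarks form the
   peripheral vertices; walking pairwise from the hook tip, each
   dorsal–ventral vertex pair contributes an internal vertex at its chord
   midpoint; peripheral and internal vertices are joined into triangular
   faces. Meshes built with the same counts share one graph structure on
   every nucleus, whatever its geometry;
3. **warps** each nucleus's binarised FISH raster onto the population
   consensus shape by the per-face affine maps between its mesh and the
   consensus mesh (forward mapping, nearest-pixel), then applies a
   gap-filling kernel: an empty pixel with at least 4 non-zero 8-connected
   neighbours becomes their mean;
4. aggregates the warped binary rasters of the population into a
   **composite map** — the per-pixel frequency with which a probe is seen
   at each consensus-frame location, a heat map of the probe's nuclear
   address;
5. **quantifies**: composite and single-nucleus warped images are compared
   with a multi-scale structural similarity index (MS-SSIM\*, in [0, 1],
   exactly 1 for identical images, with the \* rule defining the score on
   zero-variance windows), and co-hybridised probes are compared per
   nucleus by the distance between their intensity-weighted centres of
   mass, with two-sided Wilcoxon rank-sum tests between distance sets.

Because no imaging data accompany the method, the package ships a
first-class synthetic generator: parametric falciform nuclei (midline +
half-width profile, optional smooth boundary noise, strain-like shape
variants) with probe blobs planted at configurable nuclear addresses in
shape-intrinsic (u, v) coordinates. Every stage is tested against this
ground truth.

## Worked example

```python
import nucleocarta as nc
from nucleocarta.cli import (build_template, detect_population,
                             measure_distances, warp_population)

signals = [
    nc.PlantedSignal("chrX", "dorsal_subacrosomal", placement_noise=0.05),
    nc.PlantedSignal("chrY", "dorsal_subacrosomal", placement_noise=0.05),
]
fields, manifest = nc.generate_population(n_per_strain=20, signals=signals, seed=7)
records = detect_population(fields)
consensus, template = build_template(records)
warps = warp_population(fields, records, template)
comp_x = nc.composite(warps["signal_A"], "chrX")
comp_y = nc.composite(warps["signal_B"], "chrY")
print(nc.similarity_matrix([comp_x, comp_y]).round(3))
dist = measure_distances(fields, records,
                         probe_labels={"signal_A": "chrX", "signal_B": "chrY"})
print(dist["value"].median())
```

Output:

```
simulated 60 nuclei across 21 fields (PWK-like, LEWES-like, STF-like)
detected and oriented 60 analysable nuclei
consensus shape from 60 nuclei; mesh has 80 faces
chrX composite: peak frequency 0.78 over n=60
MS-SSIM* matrix:
      chrX  chrY
chrX  1.00  0.97
chrY  0.97  1.00
chrX-chrY centre-of-mass distance: median 0.65 um over 60 nuclei
```

Reading this: all 60 planted nuclei were recovered and oriented; the two
sex-chromosome-style probes, planted in the same dorsal/sub-acrosomal
region of every nucleus, produce composite maps that agree almost
perfectly (MS-SSIM\* 0.97), and within any one nucleus their centres of
mass lie a fraction of a micron apart. Probes planted in disjoint regions
score far lower against these (see the block-structure test in
`tests/test_acceptance.py`).

## Command line

```sh
nucleocarta simulate --out data --seed 9 --config run.toml   # synthetic fields + ground truth
nucleocarta detect   --config run.toml --seed 9 --out out    # outlines, landmarks, manifest
nucleocarta warp     --config run.toml --seed 9 --out out    # composites per probe (TIFF+PNG)
nucleocarta compare  --out out                               # MS-SSIM* matrix, Wilcoxon tests
```

The TOML config names the input glob, the pixel calibration (µm/pixel),
the channel-role order and probe labels, and any parameter overrides;
identical config and seed reproduce byte-identical outputs.

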