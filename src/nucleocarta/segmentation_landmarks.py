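"""Nucleus segmentation, curvature landmarks and orientation.

Falciform sperm nuclei have two axes of asymmetry, so a nucleus seen in a
2D image can be oriented unambiguously: the apical hook marks the anterior
end and the hook curls toward the dorsal side. This module finds nuclei in
the counterstain channel, extracts closed boundary outlines, computes a
sliding-window interior-angle profile along each boundary, names the
curvature landmarks (hook tip = sharpest convex protrusion, tail
attachment = the dominant remaining convexity at the base), and brings
every nucleus into a common pose: hook left, dorsal up, centre of mass at
the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from scipy.ndimage import binary_fill_holes

from .geometry import (
    apply_affine,
    cyclic_arc_distance,
    ensure_positive_orientation,
    resample_closed,
    rigid_transform,
    signed_area,
)
from .imaging_io import Calibration, FieldImage

log = logging.getLogger(__name__)


class UnanalyzableNucleusError(ValueError):
    """The outline has too few distinct curvature extrema to landmark."""


@dataclass
class SegmentationParams:
    """Filters applied to counterstain connected components.

    The default area window brackets swelled sperm nuclei (roughly
    20-40 um^2 after the DTT swelling needed for FISH). Clumped or
    misshapen objects are rejected by the solidity filter rather than
    split; border-touching objects are discarded.
    """

    min_area_um2: float = 10.0
    max_area_um2: float = 60.0
    min_solidity: float = 0.7
    boundary_point_spacing_px: float = 1.0

    def validate(self) -> None:
        if self.min_area_um2 > self.max_area_um2:
            raise ValueError(
                f"min_area_um2 ({self.min_area_um2}) > max_area_um2 ({self.max_area_um2})"
            )
        if not 0 <= self.min_solidity <= 1:
            raise ValueError("min_solidity must be in [0, 1]")


@dataclass
class NucleusOutline:
    """One segmented nucleus.

    ``boundary`` is a closed, simple polygon over pixel coordinates,
    traversed with positive shoelace area; after orientation it starts at
    the hook tip. ``transform`` accumulates the rigid map from the source
    image frame to the current boundary frame (identity at detection).
    """

    boundary: np.ndarray
    area_um2: float
    centre_of_mass: np.ndarray
    calibration: Calibration
    nucleus_id: str = ""
    source: str = ""
    flipped: bool = False
    oriented: bool = False
    mask: np.ndarray | None = None
    mask_origin: tuple[int, int] = (0, 0)
    transform: np.ndarray = field(default_factory=lambda: np.eye(2, 3))
    landmarks: "LandmarkSet | None" = None

    def __post_init__(self) -> None:
        self.boundary = ensure_positive_orientation(np.asarray(self.boundary, dtype=float))
        if len(self.boundary) < 3:
            raise ValueError("boundary needs at least 3 points")

    @property
    def n_points(self) -> int:
        return len(self.boundary)


@dataclass
class AngleProfile:
    """Interior angle (degrees) at every boundary point, measured between
    the points half a window behind and ahead along the boundary."""

    values: np.ndarray
    window_fraction: float
    index_zero: int = 0

    def __post_init__(self) -> None:
        if not np.all((self.values > 0) & (self.values < 360)):
            raise ValueError("interior angles must lie in (0, 360)")


@dataclass
class LandmarkSet:
    """Named structural landmarks as boundary indices.

    ``hook_tip`` and ``tail_attachment`` are required; auxiliary landmarks
    (further curvature extrema) are optional and named ``aux_0``,
    ``aux_1``, ... in rank order.
    """

    indices: dict[str, int]

    REQUIRED = ("hook_tip", "tail_attachment")

    def __post_init__(self) -> None:
        for name in self.REQUIRED:
            if name not in self.indices:
                raise ValueError(f"required landmark {name!r} missing")
        vals = list(self.indices.values())
        if len(set(vals)) != len(vals):
            raise ValueError("landmark indices must be pairwise distinct")

    def __getitem__(self, name: str) -> int:
        return self.indices[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.indices)

    def ordered_indices(self, n: int) -> list[tuple[str, int]]:
        """Landmarks sorted by boundary position starting at hook_tip."""
        start = self.indices["hook_tip"]
        return sorted(self.indices.items(), key=lambda kv: (kv[1] - start) % n)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def detect_nuclei(
    fieldimg: FieldImage, params: SegmentationParams | None = None
) -> list[NucleusOutline]:
    """Find candidate nuclei in the counterstain channel.

    Otsu threshold, hole filling and connected components, followed by
    area/solidity filters; objects touching the image border are dropped.
    Returns one outline per accepted object, boundaries resampled to
    uniform ~1 px arc spacing.
    """
    if params is None:
        params = SegmentationParams()
    params.validate()
    img = fieldimg.counterstain.pixels
    if img.max() == img.min():
        return []
    thr = threshold_otsu(img)
    binary = binary_fill_holes(img > thr)
    binary = remove_small_objects(binary, max_size=15)
    labels = measure.label(binary, connectivity=2)
    mpp = fieldimg.calibration.microns_per_pixel
    outlines: list[NucleusOutline] = []
    h, w = img.shape
    for region in measure.regionprops(labels):
        minr, minc, maxr, maxc = region.bbox
        if minr == 0 or minc == 0 or maxr == h or maxc == w:
            continue
        area_um2 = region.area * mpp**2
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            continue
        if region.solidity < params.min_solidity:
            continue
        crop = np.pad(labels[minr:maxr, minc:maxc] == region.label, 1)
        contours = measure.find_contours(crop.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        # find_contours yields (row, col); convert to (x, y) in field coords
        bnd = np.c_[contour[:, 1] + minc - 1, contour[:, 0] + minr - 1]
        if np.allclose(bnd[0], bnd[-1]):
            bnd = bnd[:-1]
        n = max(32, int(round(_perimeter(bnd) / params.boundary_point_spacing_px)))
        bnd = resample_closed(ensure_positive_orientation(bnd), n)
        cy, cx = region.centroid
        outlines.append(
            NucleusOutline(
                boundary=bnd,
                area_um2=area_um2,
                centre_of_mass=np.array([cx, cy]),
                calibration=fieldimg.calibration,
                nucleus_id=f"{fieldimg.source_path}#{region.label}",
                source=fieldimg.source_path,
                mask=(labels[minr:maxr, minc:maxc] == region.label),
                mask_origin=(minc, minr),
            )
        )
    return outlines


def _perimeter(boundary: np.ndarray) -> float:
    d = np.roll(boundary, -1, axis=0) - boundary
    return float(np.sqrt((d**2).sum(1)).sum())


# ---------------------------------------------------------------------------
# Angle profile and landmarks
# ---------------------------------------------------------------------------


def compute_angle_profile(
    outline: NucleusOutline, window_fraction: float = 0.05
) -> AngleProfile:
    """Sliding-window interior-angle profile of a closed boundary.

    The value at point i is the angle at ``boundary[i]`` subtended by the
    boundary points half a window behind and ahead (window = fraction of
    the total boundary point count, which approximates perimeter fraction
    for uniformly resampled outlines). Convex features give values below
    180 deg, concave (reflex) regions above.
    """
    if not 0 < window_fraction < 0.5:
        raise ValueError(f"window_fraction must lie in (0, 0.5), got {window_fraction}")
    b = outline.boundary
    n = len(b)
    if n < 3 / window_fraction:
        raise ValueError(
            f"boundary has {n} points; needs >= {3 / window_fraction:.0f} "
            f"for window_fraction {window_fraction}"
        )
    k = max(2, int(round(window_fraction * n / 2)))
    back = np.roll(b, k, axis=0) - b
    fwd = np.roll(b, -k, axis=0) - b
    cross = back[:, 0] * fwd[:, 1] - back[:, 1] * fwd[:, 0]
    dot = (back * fwd).sum(axis=1)
    ang = np.degrees(np.arctan2(np.abs(cross), dot))
    # convexity test for a positively-oriented boundary
    turn = (-back[:, 0]) * fwd[:, 1] - (-back[:, 1]) * fwd[:, 0]
    interior = np.where(turn >= 0, ang, 360.0 - ang)
    interior = np.clip(interior, 1e-9, 360 - 1e-9)
    return AngleProfile(values=interior, window_fraction=window_fraction)


def _cyclic_minima(values: np.ndarray, prominence: float) -> tuple[np.ndarray, np.ndarray]:
    """Local minima of a cyclic profile with their prominences."""
    n = len(values)
    ext = np.tile(values, 3)
    peaks, props = find_peaks(-ext, prominence=prominence)
    sel = (peaks >= n) & (peaks < 2 * n)
    return peaks[sel] - n, props["prominences"][sel]


def _hook_flank_anchors(
    values: np.ndarray,
    boundary: np.ndarray,
    hook: int,
    tail: int,
    min_prominence_deg: float,
) -> tuple[int, int]:
    """The two anchors spanning the hook throat.

    The hook bay is the strongest concave feature of a falciform outline:
    the most prominent local maximum of the interior-angle profile, away
    from the hook tip and tail. Its partner is the boundary point of the
    opposite hook-tail arc closest to it in the plane (the far side of
    the throat) — a purely metric criterion, so the pair is invariant to
    rotation and equivariant under mirroring.
    """
    n = len(values)
    ext = np.tile(values, 3)
    peaks, props = find_peaks(ext, prominence=min_prominence_deg)
    sel = (peaks >= n) & (peaks < 2 * n)
    maxima, prom = peaks[sel] - n, props["prominences"][sel]
    guard = max(2, int(0.02 * n))
    ok = np.array(
        [
            values[m] > 185.0
            and cyclic_arc_distance(m, hook, n) > guard
            and cyclic_arc_distance(m, tail, n) > guard
            for m in maxima
        ],
        dtype=bool,
    )
    if not ok.any():
        raise UnanalyzableNucleusError("no concave hook bay found")
    cand, cand_prom = maxima[ok], prom[ok]
    order = np.lexsort(((cand - hook) % n, -cand_prom))
    bay = int(cand[order[0]])
    # the opposite hook-tail arc (the one not containing the bay)
    arc1 = (np.arange((tail - hook) % n + 1) + hook) % n      # hook -> tail
    arc2 = (np.arange((hook - tail) % n + 1) + tail) % n      # tail -> hook
    opp = arc2 if bay in set(arc1.tolist()) else arc1
    opp = np.array(
        [
            i
            for i in opp
            if cyclic_arc_distance(i, hook, n) > guard
            and cyclic_arc_distance(i, tail, n) > guard
        ]
    )
    if len(opp) == 0:
        raise UnanalyzableNucleusError("no opposite-arc candidates for the hook throat")
    d = np.linalg.norm(boundary[opp] - boundary[bay], axis=1)
    throat = int(opp[int(np.argmin(d))])
    return bay, throat


def detect_landmarks(
    profile: AngleProfile,
    outline: NucleusOutline,
    n_auxiliary: int = 0,
    min_prominence_deg: float = 5.0,
    min_angle_range_deg: float = 25.0,
    min_separation_fraction: float = 0.05,
) -> LandmarkSet:
    """Name the curvature landmarks of one outline.

    hook_tip is the global minimum of the interior-angle profile (the
    sharpest convex protrusion). tail_attachment is the most prominent
    remaining local minimum at least a quarter perimeter away from the
    hook. With the default ``n_auxiliary=2`` the two hook-flank anchors
    are added: the bottom of the hook bay (the most prominent concave
    maximum of the profile between hook and tail) and the point of the
    opposite boundary arc nearest to it (the far side of the hook
    throat). These anchor the across-the-hook vertex pairing of the mesh,
    which otherwise skews on strongly curled nuclei. Other values of
    ``n_auxiliary`` select that many further prominence-ranked local
    minima subject to a minimum arc separation. Nuclei whose profile is
    too featureless (e.g. near-circular swelled debris) raise
    :class:`UnanalyzableNucleusError` and are excluded from a run.
    """
    v = profile.values
    n = len(v)
    if n != outline.n_points:
        raise ValueError("profile was not computed from this outline")
    if v.max() - v.min() < min_angle_range_deg:
        raise UnanalyzableNucleusError(
            f"angle profile range {v.max() - v.min():.1f} deg is too flat to landmark"
        )
    hook = int(np.argmin(v))
    minima, prom = _cyclic_minima(v, min_prominence_deg)
    # drop the hook itself and anything within a quarter perimeter of it
    keep = np.array(
        [cyclic_arc_distance(m, hook, n) > 0.25 * n for m in minima], dtype=bool
    )
    cand, cand_prom = minima[keep], prom[keep]
    if len(cand) == 0:
        raise UnanalyzableNucleusError("no tail-attachment candidate minimum found")
    # most prominent wins; ties broken toward the smallest index after hook_tip
    order = np.lexsort(((cand - hook) % n, -cand_prom))
    tail = int(cand[order[0]])
    indices = {"hook_tip": hook, "tail_attachment": tail}
    if n_auxiliary == 2:
        bay, throat = _hook_flank_anchors(
            v, outline.boundary, hook, tail, min_prominence_deg
        )
        indices["aux_0"], indices["aux_1"] = bay, throat
    elif n_auxiliary > 0:
        rest = [
            (int(m), p)
            for m, p in zip(minima, prom)
            if m not in (hook, tail)
        ]
        rest.sort(key=lambda mp: (-mp[1], (mp[0] - hook) % n))
        min_sep = int(min_separation_fraction * n)
        chosen: list[int] = []
        for m, _ in rest:
            if all(
                cyclic_arc_distance(m, o, n) >= min_sep
                for o in [hook, tail, *chosen]
            ):
                chosen.append(m)
            if len(chosen) == n_auxiliary:
                break
        if len(chosen) < n_auxiliary:
            raise UnanalyzableNucleusError(
                f"only {len(chosen)} auxiliary extrema available, {n_auxiliary} requested"
            )
        chosen.sort(key=lambda m: (m - hook) % n)
        for i, m in enumerate(chosen):
            indices[f"aux_{i}"] = m
    return _canonical_aux_names(indices, n)


def _canonical_aux_names(indices: dict[str, int], n: int) -> LandmarkSet:
    """Rename auxiliary landmarks aux_0, aux_1, ... in traversal order from
    the hook tip, so structure comparisons are independent of how each
    nucleus happened to be traversed before orientation."""
    hook = indices["hook_tip"]
    aux = sorted(
        (idx for name, idx in indices.items() if name.startswith("aux_")),
        key=lambda m: (m - hook) % n,
    )
    out = {k: v for k, v in indices.items() if not k.startswith("aux_")}
    for i, m in enumerate(aux):
        out[f"aux_{i}"] = m
    return LandmarkSet(indices=out)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------


def orient_nucleus(outline: NucleusOutline, landmarks: LandmarkSet) -> NucleusOutline:
    """Bring a nucleus into the canonical pose.

    Rotates so the hook_tip -> tail_attachment chord is horizontal with the
    hook on the left, translates the boundary centroid to the origin, and
    mirrors if needed so the hook curls dorsally (toward smaller y, i.e.
    upward as displayed). The boundary is re-indexed to start at hook_tip;
    the applied mirror is recorded in ``flipped``. Orientation is
    idempotent and deterministic.
    """
    b = outline.boundary
    n = len(b)
    hook = landmarks["hook_tip"]
    tail = landmarks["tail_attachment"]
    chord = b[tail] - b[hook]
    angle = -np.arctan2(chord[1], chord[0])
    aff = rigid_transform(angle, np.zeros(2))
    rb = apply_affine(aff, b)
    centroid = rb.mean(axis=0)
    rb = rb - centroid
    aff[:, 2] -= centroid
    # mirror test: both chord endpoints (hook tip, tail pole) sit dorsal of
    # the bulk of the nucleus, so in the canonical pose the centre of mass
    # lies ventral (below, larger y) of the horizontal chord. If the chord
    # is below the centroid instead, the nucleus is seen mirror-imaged.
    flipped = bool(rb[hook, 1] > 0)
    if flipped:
        mir = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0]])
        rb = apply_affine(mir, rb)
        aff = np.c_[mir[:, :2] @ aff[:, :2], mir[:, :2] @ aff[:, 2]]
    # restore positive traversal (a mirror reverses it) and start at hook_tip
    order = np.arange(n)
    if signed_area(rb) < 0:
        rb = rb[::-1]
        order = order[::-1]
    start = int(np.nonzero(order == hook)[0][0])
    rb = np.roll(rb, -start, axis=0)
    order = np.roll(order, -start)
    index_map = {int(orig): i for i, orig in enumerate(order)}
    new_landmarks = _canonical_aux_names(
        {name: index_map[idx] for name, idx in landmarks.indices.items()}, n
    )
    total_transform = np.c_[
        aff[:, :2] @ outline.transform[:, :2],
        aff[:, :2] @ outline.transform[:, 2] + aff[:, 2],
    ]
    return replace(
        outline,
        boundary=rb,
        centre_of_mass=np.zeros(2),
        flipped=outline.flipped ^ flipped,
        oriented=True,
        mask=None,
        transform=total_transform,
        landmarks=new_landmarks,
    )
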