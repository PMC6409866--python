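"""Population consensus shape and structurally equivalent triangular meshes.

Because all nuclei in a run share a landmark structure, every outline can
be resampled to the same number of arc-length-equidistant semi-landmarks
per inter-landmark segment. The pointwise mean of these resampled
boundaries is the population consensus shape. The same construction then
yields a triangular mesh on any boundary with that landmark structure:
peripheral vertices (landmarks + semi-landmarks), internal vertices at
the midpoints of chords pairing the i-th vertex clockwise from the hook
tip with the i-th counter-clockwise, and triangular faces joining them.
Two meshes built with the same counts have identical graph structure, so
per-face affine maps between them are well defined whatever the geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon

from .geometry import signed_area
from .segmentation_landmarks import LandmarkSet, NucleusOutline


class StructuralMismatchError(ValueError):
    """Operands do not share a landmark/mesh graph structure."""


class DegenerateMeshError(ValueError):
    """Mesh construction failed for this nucleus (it should be excluded)."""


@dataclass
class ConsensusShape:
    """Population-average boundary with landmarks at the segment joins."""

    boundary: np.ndarray
    landmarks: LandmarkSet
    n_contributing: int
    points_per_segment: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_contributing < 1:
            raise ValueError("n_contributing must be >= 1")


@dataclass
class NucleusMesh:
    """Triangular mesh over one nucleus (or the consensus).

    ``faces`` index into the concatenation of ``peripheral_vertices`` and
    ``internal_vertices``. ``structure_signature`` encodes only the counts
    and connectivity, never the geometry, so meshes from differently
    shaped nuclei built with the same counts compare equal.
    """

    peripheral_vertices: np.ndarray
    internal_vertices: np.ndarray
    faces: np.ndarray
    structure_signature: str

    @property
    def vertices(self) -> np.ndarray:
        if len(self.internal_vertices) == 0:
            return self.peripheral_vertices
        return np.vstack([self.peripheral_vertices, self.internal_vertices])

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_coords(self) -> np.ndarray:
        """(n_faces, 3, 2) array of face vertex coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        """Signed areas of all faces."""
        tri = self.face_coords()
        a = tri[:, 1] - tri[:, 0]
        b = tri[:, 2] - tri[:, 0]
        return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])

    def polygon(self) -> Polygon:
        return Polygon(self.peripheral_vertices)


def _segment_boundaries(outline: NucleusOutline) -> list[np.ndarray]:
    """Split a closed boundary into open inter-landmark segments, in
    traversal order starting at hook_tip. Each segment includes both of
    its bounding landmarks."""
    lm = outline.landmarks
    if lm is None:
        raise ValueError("outline has no landmarks; run detect_landmarks/orient first")
    b = outline.boundary
    n = len(b)
    ordered = lm.ordered_indices(n)
    segs = []
    for k in range(len(ordered)):
        i0 = ordered[k][1]
        i1 = ordered[(k + 1) % len(ordered)][1]
        idx = np.arange(i0, i0 + ((i1 - i0) % n) + 1) % n
        segs.append(b[idx])
    return segs


def _resample_segment(seg: np.ndarray, n_interior: int) -> np.ndarray:
    """Equidistant-in-arc-length points along an open segment, excluding
    the final endpoint (it begins the next segment)."""
    d = np.diff(seg, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.sqrt((d**2).sum(1)))])
    si = np.linspace(0.0, s[-1], n_interior + 2)[:-1]
    return np.c_[np.interp(si, s, seg[:, 0]), np.interp(si, s, seg[:, 1])]


def resample_by_segments(
    outline: NucleusOutline, points_per_segment: tuple[int, ...] | int
) -> tuple[np.ndarray, LandmarkSet]:
    """Resample an oriented outline segment-wise.

    Returns the resampled boundary (landmarks exactly preserved as join
    points) and the landmark set re-indexed into it.
    """
    segs = _segment_boundaries(outline)
    if isinstance(points_per_segment, int):
        points_per_segment = (points_per_segment,) * len(segs)
    if len(points_per_segment) != len(segs):
        raise StructuralMismatchError(
            f"{len(points_per_segment)} segment counts for {len(segs)} segments"
        )
    parts = [
        _resample_segment(seg, npts) for seg, npts in zip(segs, points_per_segment)
    ]
    boundary = np.vstack(parts)
    names = [name for name, _ in outline.landmarks.ordered_indices(outline.n_points)]
    starts = np.concatenate([[0], np.cumsum([len(p) for p in parts])[:-1]])
    lms = LandmarkSet(indices={name: int(s) for name, s in zip(names, starts)})
    return boundary, lms


def build_consensus(
    outlines: list[NucleusOutline], points_per_segment: int = 100
) -> ConsensusShape:
    """Average oriented outlines into the population consensus shape.

    Each outline is resampled to ``points_per_segment`` equidistant points
    per inter-landmark segment; corresponding points are averaged
    arithmetically. Nuclei are already rigidly aligned by orientation, so
    no Procrustes scaling is applied — size differences are biological and
    preserved in the mean.
    """
    if not outlines:
        raise ValueError("need at least one outline")
    structures = {tuple(o.landmarks.names) if o.landmarks else None for o in outlines}
    if len(structures) != 1 or None in structures:
        raise StructuralMismatchError(f"mixed landmark structures: {structures}")
    if not all(o.oriented for o in outlines):
        raise ValueError("all outlines must be oriented")
    resampled = []
    lms = None
    for o in outlines:
        b, lms = resample_by_segments(o, points_per_segment)
        resampled.append(b)
    mean_boundary = np.mean(resampled, axis=0)
    n_segments = len(lms.indices)
    return ConsensusShape(
        boundary=mean_boundary,
        landmarks=lms,
        n_contributing=len(outlines),
        points_per_segment=(points_per_segment,) * n_segments,
    )


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------


def _structure_signature(
    n_landmarks: int, counts: tuple[int, ...], faces_struct: tuple
) -> str:
    payload = {
        "landmarks": n_landmarks,
        "semilandmarks_per_segment": list(counts),
        "faces": [list(f) for f in faces_struct],
    }
    return json.dumps(payload, separators=(",", ":"))


def build_mesh(
    boundary: np.ndarray,
    landmarks: LandmarkSet,
    semilandmarks_per_segment: tuple[int, ...] | int = 20,
) -> NucleusMesh:
    """Build the triangular mesh for one boundary.

    Peripheral vertices are the landmarks plus the requested equidistant
    semi-landmarks per segment. Walking pairwise from the hook tip, the
    i-th vertex after the tip is paired with the i-th before it; each pair
    contributes an internal vertex at its chord midpoint. Faces
    triangulate the tip cap, the dorsal and ventral bands between
    consecutive pairs (each quad split along the diagonal toward the
    tip-ward internal vertex), and a fan over any excess basal vertices.
    """
    # re-use the segment resampler via a temporary outline
    from .imaging_io import Calibration

    tmp = NucleusOutline(
        boundary=boundary,
        area_um2=abs(signed_area(np.asarray(boundary, dtype=float))),
        centre_of_mass=np.asarray(boundary, dtype=float).mean(axis=0),
        calibration=Calibration(1.0),
        oriented=True,
        landmarks=landmarks,
    )
    n_segments = len(landmarks.indices)
    if isinstance(semilandmarks_per_segment, int):
        counts = (semilandmarks_per_segment,) * n_segments
    else:
        counts = tuple(semilandmarks_per_segment)
    if any(c < 1 for c in counts):
        raise ValueError("each segment needs at least one semi-landmark")
    ring, ring_lms = resample_by_segments(tmp, counts)
    n_ring = len(ring)

    tail_ring = ring_lms["tail_attachment"]
    n_before = tail_ring - 1          # vertices strictly between tip and tail, first side
    n_after = n_ring - tail_ring - 1  # ... second side
    k_pairs = min(n_before, n_after)

    internal = np.empty((k_pairs, 2))
    for i in range(1, k_pairs + 1):
        internal[i - 1] = 0.5 * (ring[i] + ring[n_ring - i])

    poly = Polygon(ring)
    for i, p in enumerate(internal):
        if not poly.contains(Point(p)):
            raise DegenerateMeshError(
                f"internal vertex {i} falls outside the outline; nucleus excluded"
            )

    # faces reference peripheral vertices 0..n_ring-1 then internal n_ring..
    def internal_id(i: int) -> int:
        return n_ring + i - 1  # pair index i (1-based) -> vertex id

    faces: list[tuple[int, int, int]] = []
    # tip cap
    faces.append((0, 1, internal_id(1)))
    faces.append((0, internal_id(1), n_ring - 1))
    # bands between consecutive pairs, both sides; diagonal toward the
    # tip-ward internal vertex
    for i in range(1, k_pairs):
        faces.append((i, i + 1, internal_id(i)))
        faces.append((i + 1, internal_id(i + 1), internal_id(i)))
        faces.append((n_ring - i, internal_id(i), n_ring - i - 1))
        faces.append((n_ring - i - 1, internal_id(i), internal_id(i + 1)))
    # base cap: fan from the last internal vertex over the unpaired basal chain
    basal = list(range(k_pairs, n_ring - k_pairs + 1))
    for a, b in zip(basal[:-1], basal[1:]):
        faces.append((internal_id(k_pairs), a, b))

    faces_arr = np.array(faces, dtype=int)
    mesh = NucleusMesh(
        peripheral_vertices=ring,
        internal_vertices=internal,
        faces=faces_arr,
        structure_signature=_structure_signature(n_segments, counts, tuple(faces)),
    )
    # an inverted face means a band quad folded over itself (the midpoint
    # skeleton crossed the periphery); such a nucleus cannot be tiled by
    # this construction and must be excluded from the run
    if (mesh.face_areas() <= 0).any():
        raise DegenerateMeshError(
            "mesh contains an inverted or zero-area face; nucleus excluded"
        )
    return mesh


def mesh_isomorphic(a: NucleusMesh, b: NucleusMesh) -> bool:
    """True iff two meshes share the same graph structure (vertex counts
    per segment and face connectivity), regardless of geometry."""
    return a.structure_signature == b.structure_signature


def mesh_to_off(mesh: NucleusMesh, path: str | Path) -> None:
    """Write a mesh in OFF format (z = 0) for external inspection."""
    verts = mesh.vertices
    lines = ["OFF", f"{len(verts)} {mesh.n_faces} 0"]
    lines += [f"{x:.4f} {y:.4f} 0.0" for x, y in verts]
    lines += [f"3 {i} {j} {k}" for i, j, k in mesh.faces]
    Path(path).write_text("\n".join(lines) + "\n")


def mesh_to_json(mesh: NucleusMesh, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "peripheral_vertices": mesh.peripheral_vertices.tolist(),
                "internal_vertices": mesh.internal_vertices.tolist(),
                "faces": mesh.faces.tolist(),
                "structure_signature": mesh.structure_signature,
            }
        )
    )
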