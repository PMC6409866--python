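"""Binarisation, per-face affine warping and composite signal maps.

Each FISH channel is binarised inside its nucleus mask (so bright and dim
hybridisations count equally), then every ON pixel is moved by the affine
map of the mesh face containing it into the corresponding face of the
target mesh (forward mapping with nearest-pixel rasterisation). A
gap-filling kernel then sets any empty pixel with at least four non-zero
8-connected neighbours to their mean, countering the holes forward
mapping leaves where a target face is larger than its source face.
Binarised warps from many nuclei average into a composite map: the
per-pixel frequency with which the probe was seen at each consensus-frame
location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .consensus_mesh import NucleusMesh, StructuralMismatchError, mesh_isomorphic
from .imaging_io import ChannelRaster

log = logging.getLogger(__name__)


@dataclass
class WarpedSignal:
    """A binarised FISH raster re-expressed in the target-shape frame.

    ``origin`` is the (x, y) of the raster's top-left pixel in
    target-mesh coordinates; all warps onto the same mesh share it.
    """

    raster: np.ndarray
    source_nucleus: str
    target_signature: str
    origin: tuple[int, int]


@dataclass
class CompositeMap:
    """Per-pixel signal frequency in [0, 1] over a warped population."""

    frequencies: np.ndarray
    n_nuclei: int
    probe_label: str
    target_signature: str
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        f = self.frequencies
        if f.min() < 0 or f.max() > 1:
            raise ValueError("composite frequencies must lie in [0, 1]")


def parse_threshold(spec: str):
    """Parse a threshold spec: ``otsu``, ``fixed:<value>`` or
    ``fraction:<f>`` (fraction of the in-mask maximum)."""
    if spec == "otsu":
        return ("otsu", None)
    kind, _, arg = spec.partition(":")
    if kind in ("fixed", "fraction") and arg:
        return (kind, float(arg))
    raise ValueError(f"unrecognised threshold spec {spec!r}")


def _threshold_value(values: np.ndarray, spec: str) -> float:
    kind, arg = parse_threshold(spec)
    if kind == "fixed":
        return arg
    if kind == "fraction":
        return arg * float(values.max())
    if values.max() == values.min():
        return float(values.max())  # uniform: nothing exceeds the threshold
    return float(threshold_otsu(values))


def binarise_signal(
    channel: ChannelRaster | np.ndarray,
    mask: np.ndarray,
    method: str = "otsu",
) -> np.ndarray:
    """Binarise a FISH channel within one nucleus mask.

    The threshold is computed from in-mask pixels only; pixels outside the
    mask are always 0. An all-zero channel yields an all-zero output.
    """
    pixels = channel.pixels if isinstance(channel, ChannelRaster) else np.asarray(channel)
    mask = np.asarray(mask, dtype=bool)
    if pixels.shape != mask.shape:
        raise ValueError(f"channel {pixels.shape} and mask {mask.shape} dimensions differ")
    out = np.zeros(pixels.shape, dtype=np.uint8)
    inside = pixels[mask]
    if inside.size == 0 or inside.max() == 0:
        return out
    thr = _threshold_value(inside.astype(float), method)
    out[mask] = (pixels[mask] > thr).astype(np.uint8)
    return out


def assign_pixels_to_faces(mesh: NucleusMesh, shape: tuple[int, int]) -> np.ndarray:
    """Map every pixel of a raster to the mesh face containing its centre.

    Returns an int array of face indices, -1 outside the mesh. Pixels on a
    shared edge are assigned to the lower face index (faces are visited in
    order and a pixel is never reassigned).
    """
    h, w = shape
    face_map = np.full(shape, -1, dtype=np.int32)
    tri = mesh.face_coords()
    eps = 1e-9
    for fi in range(len(tri)):
        t = tri[fi]
        x0 = max(0, int(np.floor(t[:, 0].min())))
        x1 = min(w - 1, int(np.ceil(t[:, 0].max())))
        y0 = max(0, int(np.floor(t[:, 1].min())))
        y1 = min(h - 1, int(np.ceil(t[:, 1].max())))
        if x1 < x0 or y1 < y0:
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        p = np.c_[xs.ravel(), ys.ravel()].astype(float)
        def _cross(a, b):
            return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

        d = _cross(t[1] - t[0], t[2] - t[0])
        if abs(d) < 1e-12:
            continue
        w0 = _cross(t[1] - p, t[2] - p) / d
        w1 = _cross(t[2] - p, t[0] - p) / d
        w2 = 1.0 - w0 - w1
        inside = (w0 >= -eps) & (w1 >= -eps) & (w2 >= -eps)
        sub = face_map[y0 : y1 + 1, x0 : x1 + 1]
        sel = inside.reshape(sub.shape) & (sub == -1)
        sub[sel] = fi
    return face_map


def _face_affines(source: NucleusMesh, target: NucleusMesh) -> np.ndarray:
    """(n_faces, 2, 3) affine maps sending each source face onto the
    corresponding target face. Degenerate source faces yield NaN rows."""
    src = source.face_coords()
    tgt = target.face_coords()
    n = len(src)
    out = np.full((n, 2, 3), np.nan)
    for i in range(n):
        s = np.c_[src[i], np.ones(3)]  # 3x3
        try:
            sol = np.linalg.solve(s, tgt[i])  # 3x2
        except np.linalg.LinAlgError:
            log.warning("degenerate source face %d skipped", i)
            continue
        out[i, :, :2] = sol[:2].T
        out[i, :, 2] = sol[2]
    return out


def target_frame(mesh: NucleusMesh, margin: int = 2) -> tuple[tuple[int, int], tuple[int, int]]:
    """Raster geometry for a target mesh: (origin_xy, shape_hw).

    The raster is the bounding box of the mesh polygon plus a fixed
    margin, so every warp onto this mesh shares one pixel grid.
    """
    v = mesh.peripheral_vertices
    x0 = int(np.floor(v[:, 0].min())) - margin
    y0 = int(np.floor(v[:, 1].min())) - margin
    x1 = int(np.ceil(v[:, 0].max())) + margin
    y1 = int(np.ceil(v[:, 1].max())) + margin
    return (x0, y0), (y1 - y0 + 1, x1 - x0 + 1)


def target_polygon_mask(mesh: NucleusMesh, margin: int = 2) -> np.ndarray:
    """Boolean mask of the target polygon interior on the target frame."""
    from skimage.draw import polygon as draw_polygon

    (x0, y0), shape = target_frame(mesh, margin)
    v = mesh.peripheral_vertices
    rr, cc = draw_polygon(v[:, 1] - y0, v[:, 0] - x0, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def fill_gaps(raster: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Gap-filling kernel: one pass sets every zero pixel that has at
    least 4 non-zero 8-connected neighbours (counted in the input, not
    updated in place) to the mean of those non-zero neighbours. For
    binary input this amounts to filling with 1.
    """
    out = np.asarray(raster).copy()
    for _ in range(iterations):
        src = out.astype(float)
        nz = (src != 0).astype(float)
        count = np.zeros_like(src)
        total = np.zeros_like(src)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                shifted_nz = np.zeros_like(src)
                shifted_val = np.zeros_like(src)
                ys = slice(max(0, dy), src.shape[0] + min(0, dy))
                yd = slice(max(0, -dy), src.shape[0] + min(0, -dy))
                xs = slice(max(0, dx), src.shape[1] + min(0, dx))
                xd = slice(max(0, -dx), src.shape[1] + min(0, -dx))
                shifted_nz[yd, xd] = nz[ys, xs]
                shifted_val[yd, xd] = src[ys, xs]
                count += shifted_nz
                total += shifted_val
        fill = (src == 0) & (count >= 4)
        if not fill.any():
            break
        vals = total[fill] / count[fill]
        if out.dtype.kind in "ui":
            vals = np.round(vals)
        filled = out.copy()
        filled[fill] = vals.astype(out.dtype)
        out = filled
    return out


def warp_signal(
    source_mesh: NucleusMesh,
    target_mesh: NucleusMesh,
    binary: np.ndarray,
    source_nucleus: str = "",
    gap_fill_iterations: int = 1,
    margin: int = 2,
) -> WarpedSignal:
    """Warp one nucleus's binarised signal raster onto a target mesh.

    Forward mapping: each ON pixel's centre is moved by the affine map of
    the source face containing it to the matching target face, and set at
    the nearest target pixel. Gap filling is then applied and the result
    clipped to the target polygon.
    """
    if not mesh_isomorphic(source_mesh, target_mesh):
        raise StructuralMismatchError("source and target meshes are not graph-isomorphic")
    binary = np.asarray(binary)
    (ox, oy), shape = target_frame(target_mesh, margin)
    out = np.zeros(shape, dtype=np.uint8)
    ys, xs = np.nonzero(binary)
    if len(ys):
        face_map = assign_pixels_to_faces(source_mesh, binary.shape)
        affines = _face_affines(source_mesh, target_mesh)
        fidx = face_map[ys, xs]
        ok = fidx >= 0
        ok &= ~np.isnan(affines[np.clip(fidx, 0, None), 0, 0])
        pts = np.c_[xs[ok], ys[ok]].astype(float)
        fsel = fidx[ok]
        moved = np.einsum("nij,nj->ni", affines[fsel, :, :2], pts) + affines[fsel, :, 2]
        px = np.round(moved[:, 0]).astype(int) - ox
        py = np.round(moved[:, 1]).astype(int) - oy
        keep = (px >= 0) & (px < shape[1]) & (py >= 0) & (py < shape[0])
        out[py[keep], px[keep]] = 1
        out = fill_gaps(out, iterations=gap_fill_iterations)
        out &= target_polygon_mask(target_mesh, margin)
    return WarpedSignal(
        raster=out,
        source_nucleus=source_nucleus,
        target_signature=target_mesh.structure_signature,
        origin=(ox, oy),
    )


def composite(warps: Sequence[WarpedSignal], probe_label: str = "") -> CompositeMap:
    """Average binarised warps into a per-pixel frequency map."""
    if not warps:
        raise ValueError("cannot composite an empty list of warps")
    sig = {w.target_signature for w in warps}
    if len(sig) != 1:
        raise StructuralMismatchError("warps target different mesh structures")
    shapes = {w.raster.shape for w in warps}
    if len(shapes) != 1:
        raise StructuralMismatchError(f"warps have mixed raster shapes: {shapes}")
    stack = np.stack([w.raster for w in warps]).astype(float)
    return CompositeMap(
        frequencies=stack.mean(axis=0),
        n_nuclei=len(warps),
        probe_label=probe_label,
        target_signature=sig.pop(),
        origin=warps[0].origin,
    )


def render_composite_png(comp: CompositeMap, path, cmap: str = "cividis") -> None:
    """Write a pseudo-colour rendering of a composite map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    im = ax.imshow(comp.frequencies, cmap=cmap, vmin=0, vmax=max(comp.frequencies.max(), 1e-9))
    ax.set_title(f"{comp.probe_label} (n={comp.n_nuclei})")
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8, label="signal frequency")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
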