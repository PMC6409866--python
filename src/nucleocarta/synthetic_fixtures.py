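"""Synthetic falciform (hooked) sperm nuclei with planted FISH signals.

Real mouse sperm heads are sickle-shaped, with an apical hook and a
tail-attachment site at the base; after the swelling needed for FISH the
outline smooths but keeps those landmarks. No microscopy data accompany
the method, so this module builds populations of such nuclei with known
ground truth: a parametric midline with a curling hook, a tapered
half-width profile, optional boundary noise, and punctate probe signals
planted at configurable nuclear addresses. Every downstream stage
(segmentation, landmarking, meshing, warping, metrics) is tested against
the ground truth recorded here.

Addresses use shape-intrinsic (u, v) coordinates: ``u`` is the fractional
arc position along the midline from hook tip (0) to base (1), ``v`` the
signed fractional offset from the midline toward the dorsal (+1) or
ventral (-1) boundary. These transfer across differently shaped strains
exactly as the warping mesh does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from shapely.geometry import Point, Polygon
from skimage.draw import polygon as draw_polygon

from .geometry import (
    apply_affine,
    ensure_positive_orientation,
    is_simple_polygon,
    resample_open,
    rigid_transform,
    signed_area,
)
from .imaging_io import Calibration, ChannelRaster, FieldImage


class GenerationError(RuntimeError):
    """Parameters produced an unusable (e.g. self-intersecting) outline."""


@dataclass(frozen=True)
class FalciformParams:
    """Shape parameters of one synthetic strain.

    ``hook_curl`` is the total turning angle (radians) of the midline over
    the apical hook; zero would be an ellipse-like non-falciform shape and
    is rejected. ``boundary_noise_sd`` is the s.d. (pixels) of smooth
    radial noise added to the rendered outline.
    """

    length_um: float = 10.0
    width_um: float = 5.6
    hook_curl: float = 1.3
    boundary_noise_sd: float = 1.0
    strain_label: str = "PWK-like"

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0:
            raise ValueError("nucleus dimensions must be positive")
        if not self.hook_curl > 0:
            raise ValueError("hook_curl must be > 0: a hook-less outline is not falciform")
        if self.boundary_noise_sd < 0:
            raise ValueError("boundary_noise_sd must be >= 0")


#: Default strain triplet: two similar elongated strains and one shorter,
#: wider one, mimicking the shape contrast between M. musculus subspecies
#: and M. spretus.
DEFAULT_STRAINS: tuple[FalciformParams, ...] = (
    FalciformParams(10.0, 5.6, 1.3, 1.0, "PWK-like"),
    FalciformParams(10.2, 5.7, 1.25, 1.0, "LEWES-like"),
    FalciformParams(8.8, 6.2, 1.15, 1.0, "STF-like"),
)

#: Named nuclear addresses in (u, v) shape coordinates. The
#: dorsal/sub-acrosomal address mimics the conserved X/Y territory; the
#: ventral/basal address mimics the chr11/chr19 territory.
NAMED_ADDRESSES: dict[str, tuple[float, float]] = {
    "dorsal_subacrosomal": (0.35, 0.50),
    "ventral_basal": (0.72, -0.45),
}


@dataclass(frozen=True)
class PlantedSignal:
    """One probe planted at a nuclear address.

    ``address`` is a named region or an explicit (u, v) pair; each nucleus
    draws its own position from a truncated Gaussian centred there with
    s.d. (``u_sd``, ``v_sd``), emulating territory variability. With
    probability ``placement_noise`` the signal is instead planted
    uniformly at random inside the nucleus.
    """

    probe_label: str
    address: str | tuple[float, float]
    spread_um: float = 0.5
    placement_noise: float = 0.0
    u_sd: float = 0.06
    v_sd: float = 0.12

    def __post_init__(self) -> None:
        if self.spread_um <= 0:
            raise ValueError("spread_um must be > 0")
        if not 0 <= self.placement_noise <= 1:
            raise ValueError("placement_noise is a probability")
        u, v = self.address_uv
        if not (0.0 <= u <= 1.0 and -1.0 <= v <= 1.0):
            raise ValueError(f"address (u={u}, v={v}) lies outside the nucleus")

    @property
    def address_uv(self) -> tuple[float, float]:
        if isinstance(self.address, str):
            try:
                return NAMED_ADDRESSES[self.address]
            except KeyError:
                raise ValueError(
                    f"unknown address {self.address!r}; known: {sorted(NAMED_ADDRESSES)}"
                ) from None
        u, v = self.address
        return float(u), float(v)


# ---------------------------------------------------------------------------
# Parametric shape construction (shape frame, microns; hook tip at left,
# dorsal at smaller y, see geometry module for the frame convention)
# ---------------------------------------------------------------------------

_N_MIDLINE = 600
# fixed profile constants; tuned once so the base pole and the hook tip are
# the two dominant curvature landmarks of the outline
_BASE_FRAC = 0.20   # fraction of midline forming the rounded-pointed base cap
_BASE_POW = 1.6     # cap profile exponent (>1 gives a pointed base pole)
_THIN_START = 0.45  # where (tip->base fraction from base) thinning begins
_THIN_END = 0.70
_HOOK_W = 0.42      # hook half-width as a fraction of body half-width
_CURL_START = 0.62  # fraction of midline (from base) where the hook curl begins


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class FalciformTruth:
    """Analytic ground truth of one generated nucleus, in the shape frame
    (microns). ``midline_um`` runs from hook tip to base."""

    params: FalciformParams
    boundary_um: np.ndarray
    midline_um: np.ndarray
    halfwidth_um: np.ndarray
    dorsal_normal: np.ndarray
    hook_tip_um: np.ndarray
    tail_attachment_um: np.ndarray

    def address_to_um(self, u: float, v: float) -> np.ndarray:
        """Map a (u, v) nuclear address to shape-frame coordinates."""
        n = len(self.midline_um)
        fi = np.clip(u, 0.0, 1.0) * (n - 1)
        i0 = int(np.floor(fi))
        i1 = min(i0 + 1, n - 1)
        w = fi - i0
        m = (1 - w) * self.midline_um[i0] + w * self.midline_um[i1]
        h = (1 - w) * self.halfwidth_um[i0] + w * self.halfwidth_um[i1]
        nrm = (1 - w) * self.dorsal_normal[i0] + w * self.dorsal_normal[i1]
        nrm = nrm / max(np.linalg.norm(nrm), 1e-12)
        return m + v * h * nrm

    @property
    def area_um2(self) -> float:
        return abs(signed_area(self.boundary_um))

    @property
    def perimeter_um(self) -> float:
        d = np.roll(self.boundary_um, -1, axis=0) - self.boundary_um
        return float(np.sqrt((d**2).sum(1)).sum())


def _smooth_cyclic_noise(n: int, rng: np.random.Generator, frac: float = 0.08) -> np.ndarray:
    """Unit-s.d. smooth noise over n samples (smoothed open profile)."""
    raw = rng.standard_normal(n)
    sm = gaussian_filter1d(raw, sigma=max(3.0, frac * n), mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 1e-12 else np.zeros(n)


def _build_truth(
    params: FalciformParams,
    rng: np.random.Generator | None = None,
    noise_sd_um: float = 0.0,
) -> FalciformTruth:
    """Construct the analytic outline; optional smooth shape noise.

    Noise is applied in shape space (multiplicative on the half-width
    profile, additive on the midline along its normal, pinned at the tip
    and base) so the outline stays simple and the landmark ground truth
    remains at the analytic midline endpoints.
    """
    L = params.length_um
    w_half = params.width_um / 2.0
    n = _N_MIDLINE
    t = np.linspace(0.0, 1.0, n)  # base (0) -> tip (1), fraction of midline
    g = _smoothstep((t - _CURL_START) / (1 - _CURL_START))
    phi = np.pi + params.hook_curl * g  # heading; curls toward dorsal (-y)
    ds = L / (n - 1)
    cx, sx = np.cos(phi), np.sin(phi)
    x = np.concatenate([[0.0], np.cumsum((cx[1:] + cx[:-1]) / 2 * ds)])
    y = np.concatenate([[0.0], np.cumsum((sx[1:] + sx[:-1]) / 2 * ds)])
    mid = np.c_[x, y]
    n_dorsal = np.c_[-np.sin(phi), np.cos(phi)]  # (0,-1) at the straight body

    h = np.ones_like(t)
    m = t < _BASE_FRAC
    u = (_BASE_FRAC - t[m]) / _BASE_FRAC
    h[m] = (1 - u**2) ** _BASE_POW
    m2 = (t >= _THIN_START) & (t < _THIN_END)
    h[m2] = 1 - (1 - _HOOK_W) * _smoothstep((t[m2] - _THIN_START) / (_THIN_END - _THIN_START))
    m3 = t >= _THIN_END
    h[m3] = _HOOK_W * (1 - (t[m3] - _THIN_END) / (1 - _THIN_END))
    h = h * w_half

    if rng is not None and noise_sd_um > 0:
        rel = np.clip(_smooth_cyclic_noise(n, rng) * noise_sd_um / w_half, -0.4, 0.4)
        h = h * (1.0 + rel)
        wobble = _smooth_cyclic_noise(n, rng) * noise_sd_um
        wobble *= 4.0 * t * (1.0 - t)  # pinned at tip and base
        mid = mid + wobble[:, None] * n_dorsal

    dorsal = mid + h[:, None] * n_dorsal
    ventral = mid - h[:, None] * n_dorsal
    # closed boundary: tip -> dorsal side -> base pole -> ventral side
    boundary = np.vstack([dorsal[::-1], ventral[1:-1]])
    if not is_simple_polygon(boundary):
        raise GenerationError(
            f"parameters {params} yield a self-intersecting outline "
            "(hook too curled for the chosen width?)"
        )
    return FalciformTruth(
        params=params,
        boundary_um=ensure_positive_orientation(boundary),
        midline_um=mid[::-1].copy(),       # tip -> base for the u coordinate
        halfwidth_um=h[::-1].copy(),
        dorsal_normal=n_dorsal[::-1].copy(),
        hook_tip_um=mid[-1].copy(),
        tail_attachment_um=mid[0].copy(),
    )


# ---------------------------------------------------------------------------
# Placement and rendering
# ---------------------------------------------------------------------------


@dataclass
class PlacedNucleus:
    """A ground-truth nucleus placed into a raster frame.

    ``transform`` is the 2x3 affine taking shape-frame microns to pixel
    coordinates (includes the 1/microns_per_pixel scale, any rotation or
    mirror used at placement, and the translation into the field).
    """

    nucleus_id: str
    truth: FalciformTruth
    transform: np.ndarray
    rotation: float = 0.0
    mirrored: bool = False
    signal_centres_px: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def boundary_px(self) -> np.ndarray:
        return apply_affine(self.transform, self.truth.boundary_um)

    @property
    def hook_tip_px(self) -> np.ndarray:
        return apply_affine(self.transform, self.truth.hook_tip_um[None])[0]

    @property
    def tail_attachment_px(self) -> np.ndarray:
        return apply_affine(self.transform, self.truth.tail_attachment_um[None])[0]

    def address_to_px(self, u: float, v: float) -> np.ndarray:
        return apply_affine(self.transform, self.truth.address_to_um(u, v)[None])[0]


def _placement_affine(
    mpp: float, rotation: float, mirrored: bool, shift: np.ndarray
) -> np.ndarray:
    aff = rigid_transform(rotation, shift, mirror_y=mirrored)
    aff[:, :2] /= mpp
    return aff


def _noisy_truth(
    params: FalciformParams, rng: np.random.Generator, mpp: float
) -> FalciformTruth:
    """Build a truth with per-nucleus shape noise, retrying the noise draw
    if it happens to self-intersect."""
    noise_um = params.boundary_noise_sd * mpp
    if noise_um <= 0:
        return _build_truth(params)
    for _ in range(8):
        try:
            return _build_truth(params, rng, noise_um)
        except GenerationError:
            continue
    raise GenerationError("could not draw a simple noisy outline")


def _rasterise(polygon_px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(polygon_px[:, 1], polygon_px[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _render_counterstain(
    masks: Sequence[np.ndarray],
    shape: tuple[int, int],
    rng: np.random.Generator,
    interior: float = 160.0,
    background: float = 6.0,
) -> ChannelRaster:
    img = np.full(shape, background, dtype=float)
    img += rng.normal(0.0, 2.0, shape)
    for mask in masks:
        img[mask] = interior + rng.normal(0.0, 12.0, int(mask.sum()))
    img = gaussian_filter(img, 0.8)
    return ChannelRaster(np.clip(img, 0, 255).astype(np.uint8), "counterstain")


def _render_blob(
    img: np.ndarray, centre_px: np.ndarray, sigma_px: float, amplitude: float
) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma_px))
    x0, y0 = centre_px
    xs = np.arange(max(0, int(x0) - r), min(w, int(x0) + r + 1))
    ys = np.arange(max(0, int(y0) - r), min(h, int(y0) + r + 1))
    if len(xs) == 0 or len(ys) == 0:
        return
    gx = np.exp(-((xs - x0) ** 2) / (2 * sigma_px**2))
    gy = np.exp(-((ys - y0) ** 2) / (2 * sigma_px**2))
    img[np.ix_(ys, xs)] += amplitude * np.outer(gy, gx)


def generate_nucleus(
    params: FalciformParams = FalciformParams(),
    seed: int = 0,
    calibration: Calibration = Calibration(0.05),
    margin_px: int = 12,
) -> tuple[PlacedNucleus, ChannelRaster]:
    """Generate one pre-oriented nucleus and its counterstain raster.

    The nucleus is rendered hook-left, dorsal-up in a raster just large
    enough to hold it; the returned :class:`PlacedNucleus` carries the
    analytic ground truth (boundary, hook apex, tail attachment, address
    map) in the raster's pixel coordinates.
    """
    rng = np.random.default_rng(seed)
    mpp = calibration.microns_per_pixel
    truth = _noisy_truth(params, rng, mpp)
    b_um = truth.boundary_um
    shift = -b_um.min(axis=0) / mpp + margin_px
    aff = _placement_affine(mpp, 0.0, False, shift)
    placed = PlacedNucleus(nucleus_id=f"{params.strain_label}_s{seed}", truth=truth, transform=aff)
    b_px = placed.boundary_px
    extent = b_um.max(axis=0) - b_um.min(axis=0)
    shape = (
        int(np.ceil(extent[1] / mpp)) + 2 * margin_px,
        int(np.ceil(extent[0] / mpp)) + 2 * margin_px,
    )
    mask = _rasterise(b_px, shape)
    raster = _render_counterstain([mask], shape, rng)
    return placed, raster


def plant_signals(
    placed: PlacedNucleus,
    signals: Sequence[PlantedSignal],
    seed: int,
    shape: tuple[int, int],
    calibration: Calibration = Calibration(0.05),
    rng: np.random.Generator | None = None,
    images: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Plant probe blobs for one nucleus into per-probe float images.

    Returns (and updates ``placed.signal_centres_px`` with) the
    ground-truth centre of each planted blob. ``images`` maps probe label
    to a float accumulation image of the field; new images are created as
    needed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if images is None:
        images = {}
    poly = Polygon(placed.boundary_px)
    for sig in signals:
        u0, v0 = sig.address_uv
        if rng.random() < sig.placement_noise:
            # uniform random position inside the nucleus
            minx, miny, maxx, maxy = poly.bounds
            for _ in range(1000):
                p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
                if poly.contains(Point(p)):
                    centre = p
                    break
            else:  # pragma: no cover - bounds always contain interior points
                raise GenerationError("failed to sample a position inside the nucleus")
        else:
            u = float(np.clip(rng.normal(u0, sig.u_sd), 0.03, 0.97))
            v = float(np.clip(rng.normal(v0, sig.v_sd), -0.80, 0.80))
            centre = placed.address_to_px(u, v)
        img = images.setdefault(sig.probe_label, None)
        if img is None:
            img = np.zeros(shape, dtype=float)
            images[sig.probe_label] = img
        _render_blob(img, centre, sig.spread_um / calibration.microns_per_pixel, 180.0)
        placed.signal_centres_px[sig.probe_label] = centre
    return images


def _finalise_signal_channels(
    images: dict[str, np.ndarray], rng: np.random.Generator, roles: dict[str, str]
) -> dict[str, ChannelRaster]:
    out = {}
    for probe, img in images.items():
        img = img + 8.0 + rng.normal(0.0, 3.0, img.shape)
        out[roles[probe]] = ChannelRaster(
            np.clip(img, 0, 255).astype(np.uint8), roles[probe]
        )
    return out


def generate_population(
    strains: Sequence[FalciformParams] = DEFAULT_STRAINS,
    n_per_strain: int = 10,
    signals: Sequence[PlantedSignal] = (),
    seed: int = 0,
    calibration: Calibration = Calibration(0.05),
    field_shape: tuple[int, int] = (512, 512),
    max_per_field: int = 3,
    randomise_pose: bool = True,
    out_dir: str | Path | None = None,
) -> tuple[list[FieldImage], dict]:
    """Generate multi-nucleus fields for each strain plus a ground-truth manifest.

    Each nucleus is placed at a random position (and, if ``randomise_pose``,
    random rotation and mirror) without overlap; up to two probes are
    rendered into signal channels, mirroring a co-hybridisation. Returns the
    list of :class:`FieldImage` and a manifest dict; if ``out_dir`` is given
    the fields are written as multi-plane TIFFs and the manifest as JSON.
    """
    if n_per_strain < 1:
        raise ValueError("n_per_strain must be >= 1")
    if len(signals) > 2:
        raise ValueError("at most two probes can be co-hybridised per field")
    rng = np.random.default_rng(seed)
    roles = {
        sig.probe_label: role
        for sig, role in zip(signals, ("signal_A", "signal_B"))
    }
    fields: list[FieldImage] = []
    manifest_nuclei: list[dict] = []
    mpp = calibration.microns_per_pixel

    for params in strains:
        truth0 = _build_truth(params)
        b_um = truth0.boundary_um
        half_extent = np.abs(b_um - b_um.mean(axis=0)).max() / mpp + 6
        placed_left = n_per_strain
        idx = 0
        while placed_left > 0:
            n_here = min(max_per_field, placed_left)
            placed_nuclei: list[PlacedNucleus] = []
            occupied: list[Polygon] = []
            attempts = 0
            while len(placed_nuclei) < n_here and attempts < 400:
                attempts += 1
                angle = rng.uniform(0, 2 * np.pi) if randomise_pose else 0.0
                mirrored = bool(rng.integers(2)) if randomise_pose else False
                centre = np.array(
                    [
                        rng.uniform(half_extent, field_shape[1] - half_extent),
                        rng.uniform(half_extent, field_shape[0] - half_extent),
                    ]
                )
                truth_i = _noisy_truth(params, rng, mpp)
                bi = truth_i.boundary_um
                aff = _placement_affine(mpp, angle, mirrored, np.zeros(2))
                aff[:, 2] += centre - apply_affine(aff, bi.mean(axis=0)[None])[0]
                b_px = apply_affine(aff, bi)
                poly = Polygon(b_px).buffer(4)
                if any(poly.intersects(o) for o in occupied):
                    continue
                nid = f"{params.strain_label}_{len(manifest_nuclei) + len(placed_nuclei):04d}"
                placed_nuclei.append(
                    PlacedNucleus(nid, truth_i, aff, rotation=angle, mirrored=mirrored)
                )
                occupied.append(poly)
            if len(placed_nuclei) < n_here:
                raise GenerationError(
                    f"could not place {n_here} nuclei in a {field_shape} field without overlap"
                )
            masks = []
            sig_images: dict[str, np.ndarray] = {}
            for pn in placed_nuclei:
                masks.append(_rasterise(pn.boundary_px, field_shape))
                plant_signals(pn, signals, 0, field_shape, calibration, rng=rng, images=sig_images)
            channels = {"counterstain": _render_counterstain(masks, field_shape, rng)}
            for probe in roles:
                sig_images.setdefault(probe, np.zeros(field_shape, dtype=float))
            channels.update(_finalise_signal_channels(sig_images, rng, roles))
            fld = FieldImage(
                channels=channels,
                calibration=calibration,
                source_path=f"synthetic:{params.strain_label}:{idx}",
            )
            fields.append(fld)
            for pn in placed_nuclei:
                manifest_nuclei.append(
                    {
                        "nucleus_id": pn.nucleus_id,
                        "strain": params.strain_label,
                        "field_index": len(fields) - 1,
                        "rotation": pn.rotation,
                        "mirrored": pn.mirrored,
                        "hook_tip_px": pn.hook_tip_px.tolist(),
                        "tail_attachment_px": pn.tail_attachment_px.tolist(),
                        "boundary_px": resample_open(pn.boundary_px, 150).tolist(),
                        "signals_px": {
                            k: v.tolist() for k, v in pn.signal_centres_px.items()
                        },
                    }
                )
            placed_left -= n_here
            idx += 1

    manifest = {
        "seed": seed,
        "microns_per_pixel": mpp,
        "probe_roles": roles,
        "n_nuclei": len(manifest_nuclei),
        "strains": [p.strain_label for p in strains],
        "nuclei": manifest_nuclei,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import tifffile

        for i, fld in enumerate(fields):
            order = ["counterstain"] + fld.signal_roles()
            stack = np.stack([fld.channels[r].pixels for r in order])
            path = out_dir / f"field_{i:03d}.tif"
            tifffile.imwrite(path, stack, photometric="minisblack")
            fld.source_path = str(path)
        manifest["fields"] = [str(out_dir / f"field_{i:03d}.tif") for i in range(len(fields))]
        manifest["channel_order"] = ["counterstain"] + (
            fields[0].signal_roles() if fields else []
        )
        (out_dir / "manifest.json").write_text(json.dumps(manifest))
    return fields, manifest
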