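"""Binarisation, pixel-face assignment, warping and compositing."""

import numpy as np
import pytest

import nucleocarta as nc
from nucleocarta.cli import AnalysisOptions, full_field_mask, source_mesh_for
from nucleocarta.consensus_mesh import StructuralMismatchError
from nucleocarta.warping import fill_gaps, target_frame, target_polygon_mask


# ---------------------------------------------------------------------------
# binarisation
# ---------------------------------------------------------------------------


def test_uniform_channel_above_fixed_threshold():
    img = np.full((20, 20), 100, dtype=np.uint8)
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    binary = nc.binarise_signal(nc.ChannelRaster(img, "signal_A"), mask, "fixed:50")
    assert binary[mask].all()
    assert not binary[~mask].any()


def test_all_zero_channel_gives_all_zero_output():
    img = np.zeros((16, 16), dtype=np.uint8)
    mask = np.ones((16, 16), bool)
    assert nc.binarise_signal(img, mask, "otsu").sum() == 0


def test_signal_outside_mask_contributes_nothing():
    img = np.zeros((30, 30), dtype=np.uint8)
    img[2:5, 2:5] = 250  # bright but outside the mask
    mask = np.zeros((30, 30), bool)
    mask[15:25, 15:25] = True
    binary = nc.binarise_signal(img, mask, "fixed:50")
    assert binary.sum() == 0


def test_otsu_recovers_planted_blob_centroid():
    yy, xx = np.mgrid[0:60, 0:60]
    blob = 10 + 190 * np.exp(-((xx - 33.0) ** 2 + (yy - 21.0) ** 2) / (2 * 9.0))
    img = blob.astype(np.uint8)
    mask = np.ones((60, 60), bool)
    binary = nc.binarise_signal(img, mask, "otsu")
    ys, xs = np.nonzero(binary)
    assert abs(xs.mean() - 33.0) < 1.0 and abs(ys.mean() - 21.0) < 1.0


def test_dimension_mismatch_rejected():
    with pytest.raises(ValueError):
        nc.binarise_signal(np.zeros((4, 4), np.uint8), np.ones((5, 5), bool))


def test_threshold_spec_parsing():
    from nucleocarta.warping import parse_threshold

    assert parse_threshold("otsu") == ("otsu", None)
    assert parse_threshold("fixed:12.5") == ("fixed", 12.5)
    assert parse_threshold("fraction:0.5") == ("fraction", 0.5)
    with pytest.raises(ValueError):
        parse_threshold("quantile:0.9")


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------


def _centre_with_neighbours(k, value=1):
    """3x3 raster, zero centre, first k of the 8 neighbours set."""
    r = np.zeros((3, 3), dtype=np.uint8)
    coords = [(0, 0), (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1), (2, 2)]
    for y, x in coords[:k]:
        r[y, x] = value
    return r


@pytest.mark.parametrize("k", range(9))
def test_gap_fill_threshold_is_four_nonzero_neighbours(k):
    out = fill_gaps(_centre_with_neighbours(k))
    assert bool(out[1, 1]) == (k >= 4)


def test_gap_fill_value_is_mean_of_nonzero_neighbours():
    r = np.zeros((3, 3), dtype=float)
    r[0, 0], r[0, 1], r[0, 2], r[1, 0] = 10, 20, 30, 40
    out = fill_gaps(r)
    assert out[1, 1] == pytest.approx(25.0)


def test_gap_fill_counts_neighbours_in_input_not_in_place():
    # two adjacent holes, each with exactly 3 non-zero neighbours in the
    # input: neither may fill (an in-place pass would cascade)
    r = np.array(
        [
            [1, 0, 0, 1],
            [1, 0, 0, 1],
            [0, 0, 0, 0],
        ],
        dtype=np.uint8,
    )
    out = fill_gaps(r)
    assert out[0, 1] == 0 and out[0, 2] == 0


def test_gap_fill_preserves_existing_pixels():
    rng = np.random.default_rng(3)
    r = (rng.random((20, 20)) < 0.5).astype(np.uint8) * 7
    out = fill_gaps(r)
    np.testing.assert_array_equal(out[r != 0], r[r != 0])


# ---------------------------------------------------------------------------
# pixel-face assignment
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fixture_mesh(detected_outline):
    lm = nc.detect_landmarks(nc.compute_angle_profile(detected_outline), detected_outline)
    o = nc.orient_nucleus(detected_outline, lm)
    return nc.build_mesh(o.boundary, o.landmarks, 20)


def test_every_polygon_pixel_assigned_to_one_face(fixture_mesh):
    (ox, oy), shape = target_frame(fixture_mesh)
    shifted = nc.NucleusMesh(
        peripheral_vertices=fixture_mesh.peripheral_vertices - (ox, oy),
        internal_vertices=fixture_mesh.internal_vertices - (ox, oy),
        faces=fixture_mesh.faces,
        structure_signature=fixture_mesh.structure_signature,
    )
    face_map = nc.assign_pixels_to_faces(shifted, shape)
    # independent membership test: pixel centres inside the peripheral ring
    from matplotlib.path import Path

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    centres = np.c_[xx.ravel(), yy.ravel()]
    inside = Path(shifted.peripheral_vertices).contains_points(centres).reshape(shape)
    assigned = face_map >= 0
    # every interior pixel centre is assigned to exactly one face...
    assert assigned[inside].mean() > 0.999
    # ...and the assigned count matches the interior pixel count within 1%
    assert abs(assigned.sum() - inside.sum()) / inside.sum() < 0.01


def test_pixel_strictly_inside_face_maps_to_it():
    tri = nc.NucleusMesh(
        peripheral_vertices=np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]),
        internal_vertices=np.empty((0, 2)),
        faces=np.array([[0, 1, 2]]),
        structure_signature="t",
    )
    fm = nc.assign_pixels_to_faces(tri, (12, 12))
    assert fm[2, 2] == 0
    assert fm[11, 11] == -1


def test_shared_edge_tie_breaks_to_lower_face_index():
    quad = nc.NucleusMesh(
        peripheral_vertices=np.array(
            [[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]
        ),
        internal_vertices=np.empty((0, 2)),
        faces=np.array([[0, 1, 2], [0, 2, 3]]),
        structure_signature="q",
    )
    fm = nc.assign_pixels_to_faces(quad, (11, 11))
    # pixels on the diagonal y = x belong to both triangles; face 0 wins
    for i in range(1, 10):
        assert fm[i, i] == 0


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def first_record(small_population, small_records):
    fields, _ = small_population
    rec = small_records[0]
    return fields[rec.field_index], rec


def test_identity_warp_preserves_on_pixels(first_record):
    fieldimg, rec = first_record
    opts = AnalysisOptions()
    smesh = source_mesh_for(rec, opts)
    mask = full_field_mask(rec, fieldimg.shape)
    binary = nc.binarise_signal(fieldimg.channels["signal_A"], mask)
    w = nc.warp_signal(smesh, smesh, binary)
    ys, xs = np.nonzero(binary)
    ox, oy = w.origin
    assert w.raster[ys - oy, xs - ox].mean() >= 0.99


def test_empty_raster_warps_to_empty(first_record, small_records):
    fieldimg, rec = first_record
    opts = AnalysisOptions()
    smesh = source_mesh_for(rec, opts)
    tmesh = source_mesh_for(small_records[1], opts)
    w = nc.warp_signal(smesh, tmesh, np.zeros(fieldimg.shape, np.uint8))
    assert w.raster.sum() == 0


def test_non_isomorphic_meshes_rejected(first_record):
    fieldimg, rec = first_record
    opts = AnalysisOptions()
    smesh = source_mesh_for(rec, opts)
    other = nc.build_mesh(rec.oriented.boundary, rec.oriented.landmarks, 7)
    with pytest.raises(StructuralMismatchError):
        nc.warp_signal(smesh, other, np.zeros(fieldimg.shape, np.uint8))


def test_warped_raster_clipped_to_target_polygon(first_record, small_records):
    fieldimg, rec = first_record
    opts = AnalysisOptions()
    smesh = source_mesh_for(rec, opts)
    target = nc.build_mesh(
        small_records[1].oriented.boundary, small_records[1].oriented.landmarks, 20
    )
    mask = full_field_mask(rec, fieldimg.shape)
    binary = nc.binarise_signal(fieldimg.channels["signal_A"], mask)
    w = nc.warp_signal(smesh, target, binary)
    poly = target_polygon_mask(target)
    assert not w.raster[~poly].any()


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------


def _warp(raster, sig="s", nucleus="n", origin=(0, 0)):
    return nc.WarpedSignal(
        raster=raster, source_nucleus=nucleus, target_signature=sig, origin=origin
    )


def test_composite_of_identical_warps_equals_each():
    r = np.zeros((8, 8), np.uint8)
    r[2:4, 2:4] = 1
    comp = nc.composite([_warp(r.copy()) for _ in range(5)], "p")
    np.testing.assert_allclose(comp.frequencies, r.astype(float))
    assert comp.n_nuclei == 5


def test_composite_of_disjoint_single_pixels():
    a = np.zeros((4, 4), np.uint8)
    b = np.zeros((4, 4), np.uint8)
    a[1, 1] = 1
    b[2, 3] = 1
    comp = nc.composite([_warp(a), _warp(b)])
    assert comp.frequencies[1, 1] == 0.5 and comp.frequencies[2, 3] == 0.5
    assert comp.frequencies.sum() == 1.0


def test_composite_is_permutation_invariant():
    rng = np.random.default_rng(1)
    warps = [_warp((rng.random((10, 10)) < 0.3).astype(np.uint8)) for _ in range(6)]
    c1 = nc.composite(warps)
    c2 = nc.composite(warps[::-1])
    np.testing.assert_array_equal(c1.frequencies, c2.frequencies)


def test_composite_frequencies_times_n_are_integral():
    rng = np.random.default_rng(2)
    warps = [_warp((rng.random((9, 9)) < 0.4).astype(np.uint8)) for _ in range(7)]
    comp = nc.composite(warps)
    counts = comp.frequencies * comp.n_nuclei
    np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
    assert comp.frequencies.min() >= 0 and comp.frequencies.max() <= 1


def test_probe_ordering_robust_to_template_choice(cohort_composites):
    """Warping the same populations onto a different consensus template
    changes the raw MS-SSIM* values only slightly: the within-pair versus
    cross-pair ordering of probe similarities is preserved."""
    from nucleocarta.cli import AnalysisOptions, build_template, warp_population

    fields = cohort_composites["fields"]
    records = cohort_composites["records"]
    opts = AnalysisOptions()
    # alternative template: consensus of the X/Y cohort only (a different,
    # structurally equivalent shape)
    _, template2 = build_template(records["xy"], opts)
    assert template2.structure_signature == cohort_composites["template"].structure_signature
    warps_xy = warp_population(fields["xy"], records["xy"], template2, opts)
    warps_auto = warp_population(fields["auto"], records["auto"], template2, opts)
    comps = [
        nc.composite(warps_xy["signal_A"], "chrX"),
        nc.composite(warps_xy["signal_B"], "chrY"),
        nc.composite(warps_auto["signal_A"], "chr11"),
        nc.composite(warps_auto["signal_B"], "chr19"),
    ]
    mat2 = nc.similarity_matrix(comps)
    within = [mat2.loc["chrX", "chrY"], mat2.loc["chr11", "chr19"]]
    cross = [mat2.loc[a, b] for a in ("chrX", "chrY") for b in ("chr11", "chr19")]
    assert min(within) > max(cross)


def test_composite_rejects_empty_and_mixed_inputs():
    with pytest.raises(ValueError):
        nc.composite([])
    a = _warp(np.zeros((4, 4), np.uint8), sig="s1")
    b = _warp(np.zeros((4, 4), np.uint8), sig="s2")
    with pytest.raises(StructuralMismatchError):
        nc.composite([a, b])
    c = _warp(np.zeros((5, 4), np.uint8), sig="s1")
    with pytest.raises(StructuralMismatchError):
        nc.composite([a, c])
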