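"""Volumetric container I/O, warping, rigid alignment and cropping."""

import numpy as np
import pytest

from deformgen.grid import (
    AlignmentError,
    FormatError,
    GeometryError,
    LabelMask,
    ScalarVolume,
    VectorField,
    crop_to_common_space,
    read_mask,
    read_vector_field,
    read_volume,
    rigid_align,
    warp_mask,
    warp_volume,
    write_mask,
    write_vector_field,
    write_volume,
)

from conftest import smooth_random_field


@pytest.mark.parametrize("ext", [".nii", ".nii.gz", ".mha", ".mhd"])
def test_volume_round_trip_preserves_data_and_geometry(tmp_path, rng, ext):
    data = rng.normal(0.0, 100.0, size=(8, 8, 8)).astype(np.float32)
    vol = ScalarVolume(data, spacing=(1.0, 1.0, 2.5), origin=(-4.0, 3.0, 0.5))
    path = str(tmp_path / ("vol" + ext))
    write_volume(vol, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.data, data)
    assert back.spacing == vol.spacing
    assert np.allclose(back.origin, vol.origin)


def test_integer_volume_round_trip_bit_exact(tmp_path, rng):
    data = rng.integers(-1000, 2000, size=(6, 5, 4)).astype(np.int16)
    vol = ScalarVolume(data, spacing=(2.0, 2.0, 3.0))
    path = str(tmp_path / "ct.nii.gz")
    write_volume(vol, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.data, data)
    assert back.data.dtype == np.int16


def test_mask_round_trip_label_histogram_and_names(tmp_path, rng):
    labels = rng.integers(0, 4, size=(8, 8, 8)).astype(np.int32)
    mask = LabelMask(labels, {1: "body", 2: "bone", 3: "gland"}, (2.0, 2.0, 3.0))
    path = str(tmp_path / "mask.mha")
    write_mask(mask, path)
    back = read_mask(path)
    for lab in (0, 1, 2, 3):
        assert (back.data == lab).sum() == (labels == lab).sum()
    assert back.label_names == {1: "body", 2: "bone", 3: "gland"}


@pytest.mark.parametrize("const", [(0.0, 0.0, 0.0), (1.0, -2.0, 3.0)])
def test_vector_field_round_trip_constant(tmp_path, const):
    shape = (6, 6, 6)
    fld = VectorField(
        np.full(shape, const[0]), np.full(shape, const[1]), np.full(shape, const[2]),
        spacing=(1.0, 1.0, 2.5),
    )
    path = str(tmp_path / "dvf.mha")
    write_vector_field(fld, path)
    back = read_vector_field(path)
    np.testing.assert_array_equal(back.as_array(), fld.as_array())
    assert back.spacing == fld.spacing


def test_vector_field_round_trip_smooth_within_float32(tmp_path):
    fld = smooth_random_field((10, 9, 8), (2.0, 2.0, 3.0), 3.0, seed=5)
    path = str(tmp_path / "dvf.nii.gz")
    write_vector_field(fld, path)
    back = read_vector_field(path)
    # storage is 32-bit; quantization only
    assert np.abs(back.as_array() - fld.as_array()).max() <= 1e-6


def test_vector_field_reads_4d_scalar_dialect(tmp_path):
    import SimpleITK as sitk

    comps = np.arange(3 * 4 * 5 * 6, dtype=np.float32).reshape(3, 4, 5, 6)
    # 4D scalar layout: three 3D channel images joined along a 4th axis
    channels = [
        sitk.GetImageFromArray(np.ascontiguousarray(c.transpose(2, 1, 0)))
        for c in comps
    ]
    img = sitk.JoinSeries(channels)
    path = str(tmp_path / "dvf4d.nii")
    sitk.WriteImage(img, path)
    back = read_vector_field(path)
    np.testing.assert_array_equal(back.dx, comps[0])
    np.testing.assert_array_equal(back.dy, comps[1])
    np.testing.assert_array_equal(back.dz, comps[2])


def test_vector_field_wrong_component_count_raises(tmp_path):
    import SimpleITK as sitk

    arr = np.zeros((4, 5, 6, 2), dtype=np.float32)
    img = sitk.GetImageFromArray(arr, isVector=True)
    path = str(tmp_path / "bad.mha")
    sitk.WriteImage(img, path)
    with pytest.raises(FormatError):
        read_vector_field(path)


def test_read_missing_or_unknown_extension_raises(tmp_path):
    with pytest.raises(FormatError):
        read_volume(str(tmp_path / "nope.mha"))
    with pytest.raises(FormatError):
        write_volume(ScalarVolume(np.zeros((2, 2, 2))), str(tmp_path / "x.txt"))


# -- warping ---------------------------------------------------------------

def test_warp_zero_field_is_identity(ramp_volume):
    dvf = VectorField.zeros(ramp_volume.shape, ramp_volume.spacing)
    out = warp_volume(ramp_volume, dvf)
    np.testing.assert_array_equal(out.data, ramp_volume.data)


def test_warp_integer_voxel_shift_matches_index_shift(rng):
    data = rng.normal(size=(10, 10, 10))
    vol = ScalarVolume(data, spacing=(2.0, 2.0, 3.0))
    dvf = VectorField(
        np.full(vol.shape, 2.0), np.zeros(vol.shape), np.zeros(vol.shape),
        vol.spacing,
    )  # +1 voxel along LR
    out = warp_volume(vol, dvf)
    np.testing.assert_allclose(out.data[:-1], data[1:], atol=1e-12)


def test_warp_half_voxel_shift_on_ramp_matches_closed_form(ramp_volume):
    # ramp(x) = 10·x_index; displacement +1 mm = +0.5 voxel along LR
    dvf = VectorField(
        np.full(ramp_volume.shape, 1.0),
        np.zeros(ramp_volume.shape), np.zeros(ramp_volume.shape),
        ramp_volume.spacing,
    )
    out = warp_volume(ramp_volume, dvf)
    interior = out.data[:-1]
    expected = ramp_volume.data[:-1] + 5.0
    np.testing.assert_allclose(interior, expected, atol=1e-9)


def test_warp_fill_value_and_nearest_mode(rng):
    labels = (rng.random((6, 6, 6)) > 0.5).astype(np.int32)
    mask = LabelMask(labels, {1: "s"}, (1.0, 1.0, 1.0))
    dvf = VectorField.zeros((6, 6, 6))
    out = warp_mask(mask, dvf)
    np.testing.assert_array_equal(out.data, labels)

    vol = ScalarVolume(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
    big = VectorField(
        np.full((4, 4, 4), 100.0), np.zeros((4, 4, 4)), np.zeros((4, 4, 4)),
        (1.0, 1.0, 1.0),
    )
    out = warp_volume(vol, big, fill=-1000.0)
    assert (out.data == -1000.0).all()


def test_warp_geometry_mismatch_raises(ramp_volume):
    dvf = VectorField.zeros((4, 4, 4), ramp_volume.spacing)
    with pytest.raises(GeometryError):
        warp_volume(ramp_volume, dvf)


# -- rigid alignment -------------------------------------------------------

def test_rigid_align_identity(rng):
    vol = ScalarVolume(rng.normal(size=(12, 12, 12)))
    assert rigid_align(vol, vol, search_radius=3) == (0, 0, 0)


@pytest.mark.parametrize("noise_sd", [0.0, 0.05])
def test_rigid_align_recovers_constructed_shift(rng, noise_sd):
    base = np.zeros((16, 16, 16))
    base[4:10, 5:12, 6:11] = 1.0
    base += 0.2 * rng.random(base.shape)
    fixed = ScalarVolume(base)
    shift = (3, -2, 1)
    moved = np.roll(base, shift, axis=(0, 1, 2))
    if noise_sd:
        moved = moved + rng.normal(0.0, noise_sd * base.std(), size=base.shape)
    moving = ScalarVolume(moved)
    # moving(i) = fixed(i - s) -> best translation is -s
    assert rigid_align(moving, fixed, search_radius=4) == (-3, 2, -1)


def test_rigid_align_constant_images_raise():
    vol = ScalarVolume(np.ones((6, 6, 6)))
    with pytest.raises(AlignmentError):
        rigid_align(vol, vol, search_radius=2)


def test_rigid_align_spacing_mismatch_raises():
    a = ScalarVolume(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
    b = ScalarVolume(np.zeros((4, 4, 4)), (2.0, 2.0, 2.0))
    with pytest.raises(GeometryError):
        rigid_align(a, b)


# -- common-space cropping -------------------------------------------------

def test_crop_identity_when_aligned(rng):
    vols = [ScalarVolume(rng.normal(size=(8, 8, 8))) for _ in range(3)]
    out = crop_to_common_space(vols, [(0, 0, 0)] * 3)
    for a, b in zip(out, vols):
        np.testing.assert_array_equal(a.data, b.data)


def test_crop_two_voxel_si_offset_shortens_si():
    a = ScalarVolume(np.zeros((8, 8, 8)))
    b = ScalarVolume(np.zeros((8, 8, 8)))
    out = crop_to_common_space([a, b], [(0, 0, 0), (0, 0, 2)])
    assert out[0].shape == (8, 8, 6)
    assert out[1].shape == (8, 8, 6)


def test_crop_matches_interval_intersection_oracle(rng):
    shapes = [(9, 8, 7), (8, 9, 8), (10, 7, 9)]
    trans = [tuple(rng.integers(-2, 3, size=3)) for _ in shapes]
    vols = [ScalarVolume(rng.normal(size=s)) for s in shapes]
    out = crop_to_common_space(vols, trans)
    # brute-force interval intersection per axis
    for ax in range(3):
        lo = max(t[ax] for t in trans)
        hi = min(t[ax] + s[ax] for t, s in zip(trans, shapes))
        assert out[0].shape[ax] == hi - lo
    # contents preserved: each output equals the right slab of its input
    for vol, t, cropped in zip(vols, trans, out):
        lo = [max(tt[ax] for tt in trans) - t[ax] for ax in range(3)]
        sl = tuple(slice(l, l + s) for l, s in zip(lo, cropped.shape))
        np.testing.assert_array_equal(cropped.data, vol.data[sl])
    # all outputs share one geometry
    for c in out[1:]:
        assert out[0].same_geometry(c)


def test_crop_empty_intersection_raises():
    a = ScalarVolume(np.zeros((4, 4, 4)))
    b = ScalarVolume(np.zeros((4, 4, 4)))
    with pytest.raises(GeometryError):
        crop_to_common_space([a, b], [(0, 0, 0), (10, 0, 0)])
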