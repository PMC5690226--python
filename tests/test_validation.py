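"""Validation metrics: error maps, structure stats, DSC/MSD, mode coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deformgen.grid import LabelMask, ScalarVolume, VectorField
from deformgen.shape_model import fit_shape_model
from deformgen.validation import (
    dice,
    error_map,
    mean_deformation_magnitude,
    mean_surface_distance,
    mode_coverage_curve,
    modes_needed_interpolated,
    modes_vs_training_size,
    structure_report,
    structure_stats,
)

from conftest import smooth_random_field

SPACING = (2.0, 2.0, 3.0)


def test_error_map_zero_when_fields_equal():
    d = smooth_random_field((6, 6, 6), SPACING, 2.0, seed=1)
    assert (error_map(d, d).data == 0).all()


def test_error_map_345_triangle():
    shape = (5, 5, 5)
    a = VectorField(np.full(shape, 3.0), np.full(shape, 4.0), np.zeros(shape), SPACING)
    b = VectorField.zeros(shape, SPACING)
    np.testing.assert_allclose(error_map(a, b).data, 5.0)


def test_error_map_matches_sqrt_of_squares_oracle(rng):
    a = smooth_random_field((6, 6, 6), SPACING, 3.0, seed=2)
    b = smooth_random_field((6, 6, 6), SPACING, 3.0, seed=3)
    got = error_map(a, b).data
    want = np.sqrt(
        (a.dx - b.dx) ** 2 + (a.dy - b.dy) ** 2 + (a.dz - b.dz) ** 2
    )
    np.testing.assert_allclose(got, want)


def make_mask(labels):
    return LabelMask(labels, {int(l): f"s{l}" for l in np.unique(labels) if l},
                     SPACING)


def test_structure_stats_constant_and_two_voxel_closed_forms():
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[0, 0, 0] = 1
    labels[1, 0, 0] = 1
    mask = make_mask(labels)
    data = np.zeros((4, 4, 4))
    data[0, 0, 0], data[1, 0, 0] = 1.0, 3.0
    mean, sd, mx, n = structure_stats(ScalarVolume(data, SPACING), mask, 1)
    assert (mean, mx, n) == (2.0, 3.0, 2)
    assert np.isclose(sd, np.sqrt(2.0))

    const = ScalarVolume(np.full((4, 4, 4), 2.0), SPACING)
    mean, sd, mx, n = structure_stats(const, mask, 1)
    assert (mean, sd, mx) == (2.0, 0.0, 2.0)


def test_structure_stats_matches_flat_loop_oracle(rng):
    labels = rng.integers(0, 3, size=(6, 6, 6))
    data = rng.normal(size=(6, 6, 6))
    mask = make_mask(labels)
    mean, sd, mx, n = structure_stats(ScalarVolume(data, SPACING), mask, 2)
    vals = [data[i, j, k] for i in range(6) for j in range(6) for k in range(6)
            if labels[i, j, k] == 2]
    assert np.isclose(mean, np.mean(vals))
    assert np.isclose(sd, np.std(vals, ddof=1))
    assert mx == max(vals) and n == len(vals)


def test_structure_stats_empty_label_raises():
    mask = make_mask(np.ones((3, 3, 3), dtype=int))
    with pytest.raises(ValueError):
        structure_stats(ScalarVolume(np.zeros((3, 3, 3)), SPACING), mask, 7)


def test_mean_deformation_magnitude_cases(rng):
    labels = np.ones((5, 5, 5), dtype=int)
    mask = make_mask(labels)
    z = VectorField.zeros((5, 5, 5), SPACING)
    assert mean_deformation_magnitude(z, mask, 1) == (0.0, 0.0)
    c = VectorField(np.zeros((5, 5, 5)), np.zeros((5, 5, 5)),
                    np.full((5, 5, 5), 2.0), SPACING)
    mean, sd = mean_deformation_magnitude(c, mask, 1)
    assert np.isclose(mean, 2.0) and sd == 0.0


# -- Dice ------------------------------------------------------------------

def test_dice_identical_disjoint_and_half_overlap():
    a = np.zeros((8, 8, 8), dtype=int)
    a[:4] = 1
    b = np.zeros((8, 8, 8), dtype=int)
    b[2:6] = 1
    assert dice(make_mask(a), make_mask(a)) == 100.0
    disjoint = np.zeros((8, 8, 8), dtype=int)
    disjoint[6:] = 1
    assert dice(make_mask(a), make_mask(disjoint)) == 0.0
    # equal-volume slabs overlapping exactly half
    assert dice(make_mask(a), make_mask(b)) == 50.0


def test_dice_symmetric_and_bounded(rng):
    a = (rng.random((6, 6, 6)) > 0.5).astype(int)
    b = (rng.random((6, 6, 6)) > 0.5).astype(int)
    d1 = dice(make_mask(a), make_mask(b))
    d2 = dice(make_mask(b), make_mask(a))
    assert d1 == d2 and 0.0 <= d1 <= 100.0


def test_dice_both_empty_raises():
    z = np.zeros((4, 4, 4), dtype=int)
    with pytest.raises(ValueError):
        dice(LabelMask(z, {}, SPACING), LabelMask(z, {}, SPACING))


# -- mean surface distance -------------------------------------------------

def msd_brute_force(a, b, spacing):
    """All-pairs nearest-neighbour oracle on surface voxels."""
    from scipy import ndimage

    def surf(m):
        er = ndimage.binary_erosion(m, ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
        return np.argwhere(m & ~er) * np.asarray(spacing)

    pa, pb = surf(a), surf(b)
    d_ab = np.mean([np.sqrt(((q - pb) ** 2).sum(axis=1)).min() for q in pa])
    d_ba = np.mean([np.sqrt(((q - pa) ** 2).sum(axis=1)).min() for q in pb])
    return (d_ab + d_ba) / 2


def test_msd_identical_masks_is_zero(rng):
    m = np.zeros((8, 8, 8), dtype=int)
    m[2:6, 2:6, 2:6] = 1
    assert mean_surface_distance(make_mask(m), make_mask(m)) == 0.0


def test_msd_parallel_plates_anisotropic():
    # two 1-voxel plates, 3 voxels apart along LR at 2 mm spacing -> 6 mm
    a = np.zeros((8, 8, 8), dtype=int)
    b = np.zeros((8, 8, 8), dtype=int)
    a[2] = 1
    b[5] = 1
    assert np.isclose(mean_surface_distance(make_mask(a), make_mask(b)), 6.0)


def test_msd_matches_all_pairs_brute_force(rng):
    for seed in (1, 2, 3):
        r = np.random.default_rng(seed)
        a = np.zeros((12, 12, 12), dtype=int)
        b = np.zeros((12, 12, 12), dtype=int)
        ca, cb = r.integers(3, 9, size=3), r.integers(3, 9, size=3)
        idx = np.indices((12, 12, 12))
        a[((idx - ca.reshape(3, 1, 1, 1)) ** 2).sum(axis=0) <= 9] = 1
        b[((idx - cb.reshape(3, 1, 1, 1)) ** 2).sum(axis=0) <= 4] = 1
        got = mean_surface_distance(make_mask(a), make_mask(b))
        want = msd_brute_force(a.astype(bool), b.astype(bool), SPACING)
        assert np.isclose(got, want)


def test_msd_empty_mask_raises():
    a = np.zeros((4, 4, 4), dtype=int)
    b = np.ones((4, 4, 4), dtype=int)
    with pytest.raises(ValueError):
        mean_surface_distance(make_mask(a), make_mask(b))


# -- mode coverage ---------------------------------------------------------

def test_mode_coverage_equal_eigenvalues():
    curve = mode_coverage_curve([1.0, 1.0, 1.0, 1.0])
    assert [p for _, p in curve] == [25.0, 50.0, 75.0, 100.0]


def test_mode_coverage_single_nonzero():
    curve = mode_coverage_curve([2.0, 0.0, 0.0])
    assert [p for _, p in curve] == [100.0, 100.0, 100.0]


@settings(deadline=None, max_examples=40)
@given(lam=st.lists(st.floats(0.001, 50.0), min_size=1, max_size=10))
def test_mode_coverage_matches_cumsum_oracle_and_is_monotone(lam):
    lam = np.sort(np.asarray(lam))[::-1]
    curve = mode_coverage_curve(lam)
    pct = [p for _, p in curve]
    np.testing.assert_allclose(pct, 100 * np.cumsum(lam) / lam.sum(), rtol=1e-12)
    assert all(b >= a - 1e-9 for a, b in zip(pct, pct[1:]))
    assert abs(pct[-1] - 100.0) < 1e-9


def test_modes_interpolation_worked_example_and_exact_point():
    assert round(modes_needed_interpolated([(4, 88.0), (5, 91.0)], 90.0), 1) == 4.7
    curve = [(1, 40.0), (2, 70.0), (3, 100.0)]
    assert modes_needed_interpolated(curve, 70.0) == 2.0
    with pytest.raises(ValueError):
        modes_needed_interpolated(curve, 101.0)


def test_modes_interpolation_matches_fine_grid_oracle(rng):
    pct = np.sort(rng.uniform(5, 100, size=6))
    pct[-1] = 100.0
    curve = [(k + 1, p) for k, p in enumerate(pct)]
    xs = np.concatenate([[0], np.arange(1, 7)])
    ys = np.concatenate([[0], pct])
    for target in rng.uniform(1, 100, size=20):
        want = np.interp(target, ys, xs)  # piecewise-linear inverse
        got = modes_needed_interpolated(curve, target)
        assert abs(got - want) < 1e-9


def test_modes_vs_training_size_full_size_and_reproducibility():
    fields = [smooth_random_field((5, 5, 5), SPACING, 2.0, seed=s) for s in range(8)]
    t1 = modes_vs_training_size(fields, 90.0, [4, 8], seed=3)
    t2 = modes_vs_training_size(fields, 90.0, [4, 8], seed=3)
    assert t1.equals(t2)
    res = fit_shape_model(fields, alpha=90.0)
    full_curve = mode_coverage_curve(res.eigenvalues)
    want = modes_needed_interpolated(full_curve, 90.0)
    got = float(t1.loc[t1.n_training == 8, "modes_interpolated"].iloc[0])
    assert np.isclose(got, want)


def test_modes_vs_training_size_plateaus_at_latent_rank():
    # rank-3 population: all fields are combinations of 3 basis fields
    rng = np.random.default_rng(5)
    basis = [smooth_random_field((5, 5, 5), SPACING, 2.0, seed=100 + s)
             for s in range(3)]
    fields = []
    for _ in range(12):
        w = rng.normal(size=3)
        f = w[0] * basis[0] + w[1] * basis[1] + w[2] * basis[2]
        fields.append(f)
    t = modes_vs_training_size(fields, 99.9, [6, 12], seed=1)
    assert (t.modes_interpolated <= 3.0 + 1e-9).all()


def test_structure_report_layout(rng):
    labels = np.zeros((6, 6, 6), dtype=int)
    labels[1:3] = 1
    labels[4:5] = 2
    mask = LabelMask(labels, {1: "organ_a", 2: "organ_b"}, SPACING)
    a = smooth_random_field((6, 6, 6), SPACING, 2.0, seed=4)
    b = smooth_random_field((6, 6, 6), SPACING, 2.0, seed=5)
    rep = structure_report(a, b, mask, d_max=3.0)
    assert list(rep.columns) == ["structure", "Dmax", "mean_mm", "sd_mm",
                                 "max_mm", "n_voxels"]
    assert set(rep.structure) == {"organ_a", "organ_b"}
    assert (rep.Dmax == 3.0).all()
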