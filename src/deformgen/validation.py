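"""Registration validation: voxel error maps, structure statistics, contour
overlap metrics, and mode-coverage analysis of fitted shape models."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GeometryError, LabelMask, ScalarVolume, VectorField, _check_geometry
from .shape_model import fit_shape_model

__all__ = [
    "error_map",
    "structure_stats",
    "mean_deformation_magnitude",
    "dice",
    "mean_surface_distance",
    "mode_coverage_curve",
    "modes_needed_interpolated",
    "modes_vs_training_size",
    "structure_report",
]


def error_map(computed: VectorField, truth: VectorField) -> ScalarVolume:
    """Per-voxel registration error in mm.

    The computed DVF is subtracted from the ground truth component-wise
    (LR, AP, SI) and the Euclidean magnitude of the difference is the error
    at each voxel.
    """
    _check_geometry(computed, truth)
    diff = computed.as_array() - truth.as_array()
    return ScalarVolume(np.sqrt((diff**2).sum(axis=0)), computed.spacing, computed.origin)


def structure_stats(err: ScalarVolume, mask: LabelMask, label: int):
    """(mean, sd, max, n_voxels) of a scalar map over one labelled structure.

    The standard deviation uses the N−1 denominator.
    """
    _check_geometry(err, mask)
    sel = err.data[mask.binary(label)]
    if sel.size == 0:
        raise ValueError(f"label {label} is empty in the mask")
    sd = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
    return float(sel.mean()), sd, float(sel.max()), int(sel.size)


def mean_deformation_magnitude(dvf: VectorField, mask: LabelMask, label: int):
    """(mean, sd) of the displacement magnitude over one structure, in mm."""
    mag = ScalarVolume(dvf.magnitude(), dvf.spacing, dvf.origin)
    mean, sd, _, _ = structure_stats(mag, mask, label)
    return mean, sd


def _binary(mask, label):
    if isinstance(mask, LabelMask):
        return mask.binary(label), mask.spacing
    return np.asarray(mask, dtype=bool), (1.0, 1.0, 1.0)


def dice(a, b, label_a: int = 1, label_b: int | None = None) -> float:
    """Dice similarity coefficient of two structures, in percent.

    Accepts :class:`LabelMask` objects (with a label each) or boolean
    arrays.  Two empty masks make the metric undefined and raise, rather
    than silently reporting agreement.
    """
    label_b = label_a if label_b is None else label_b
    A, _ = _binary(a, label_a)
    B, _ = _binary(b, label_b)
    if A.shape != B.shape:
        raise GeometryError(f"mask shapes differ: {A.shape} vs {B.shape}")
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        raise ValueError("Dice is undefined: both masks are empty")
    return 100.0 * 2.0 * int((A & B).sum()) / (na + nb)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Labelled voxels with at least one six-connected unlabelled neighbour."""
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def mean_surface_distance(a, b, label_a: int = 1, label_b: int | None = None) -> float:
    """Symmetric mean surface distance between two structures, in mm.

    Surfaces are voxel shells (six-connectivity); the metric averages the
    two directed mean nearest-surface distances A→B and B→A, with distances
    measured in mm under anisotropic spacing.
    """
    label_b = label_a if label_b is None else label_b
    A, spacing = _binary(a, label_a)
    B, spacing_b = _binary(b, label_b)
    if isinstance(a, LabelMask) and isinstance(b, LabelMask):
        _check_geometry(a, b)
    if A.shape != B.shape:
        raise GeometryError(f"mask shapes differ: {A.shape} vs {B.shape}")
    if not A.any() or not B.any():
        raise ValueError("mean surface distance requires two non-empty masks")
    sa, sb = _surface(A), _surface(B)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = dist_to_b[sa].mean()
    d_ba = dist_to_a[sb].mean()
    return float((d_ab + d_ba) / 2.0)


def mode_coverage_curve(eigenvalues) -> list[tuple[int, float]]:
    """Percent of total variation covered by the leading k modes, for each k.

    Point k is 100·(Σ_{j≤k} λ(j))/Σ_j λ(j); the curve is non-decreasing and
    ends at 100.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    total = lam.sum()
    if total <= 0:
        raise ValueError("total variance is zero; coverage curve undefined")
    pct = 100.0 * np.cumsum(lam) / total
    return [(k + 1, float(p)) for k, p in enumerate(pct)]


def modes_needed_interpolated(curve, target_percent: float) -> float:
    """Fractional mode count reaching a target coverage, by linear interpolation.

    The curve is anchored at (0, 0); a target below the first point is
    interpolated on that initial segment, a target hitting a point exactly
    returns that integer, and anything else interpolates between the
    bracketing integer mode counts.
    """
    pts = [(0, 0.0)] + [(int(k), float(p)) for k, p in curve]
    if target_percent > pts[-1][1] + 1e-9:
        raise ValueError(
            f"target {target_percent}% exceeds curve maximum {pts[-1][1]:.6g}%"
        )
    for (k0, p0), (k1, p1) in zip(pts, pts[1:]):
        if target_percent <= p1 + 1e-12:
            if p1 == p0:
                return float(k1)
            return k0 + (target_percent - p0) / (p1 - p0) * (k1 - k0)
    return float(pts[-1][0])


def modes_vs_training_size(dvfs, alpha: float, subset_sizes, seed=None) -> pd.DataFrame:
    """Interpolated modes-at-α as a function of training-set size.

    For each size, a seeded random subset of the DVFs is fitted and the
    fractional mode count reaching ``alpha`` percent coverage is recorded.
    Subsets of size N use every field.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dvfs = list(dvfs)
    rows = []
    for size in subset_sizes:
        size = int(size)
        if size < 2:
            raise ValueError("subset sizes must be at least 2")
        if size > len(dvfs):
            raise ValueError(f"subset size {size} exceeds population {len(dvfs)}")
        idx = rng.choice(len(dvfs), size=size, replace=False) if size < len(dvfs) \
            else np.arange(len(dvfs))
        res = fit_shape_model([dvfs[i] for i in idx], alpha=alpha)
        curve = mode_coverage_curve(res.eigenvalues)
        rows.append({
            "n_training": size,
            "modes_interpolated": modes_needed_interpolated(curve, alpha),
        })
    return pd.DataFrame(rows)


def structure_report(computed: VectorField, truth: VectorField, mask: LabelMask,
                     d_max: float | None = None) -> pd.DataFrame:
    """Per-structure registration-error table (one row per labelled structure).

    Columns: structure, Dmax, mean_mm, sd_mm, max_mm, n_voxels.
    """
    emap = error_map(computed, truth)
    rows = []
    for label in mask.labels():
        mean, sd, mx, n = structure_stats(emap, mask, label)
        rows.append({
            "structure": mask.label_names.get(label, f"label_{label}"),
            "Dmax": d_max,
            "mean_mm": mean,
            "sd_mm": sd,
            "max_mm": mx,
            "n_voxels": n,
        })
    return pd.DataFrame(rows)
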