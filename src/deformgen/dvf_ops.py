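"""Displacement-field algebra: inversion, composition and cross-space transfer.

All operations act on :class:`~deformgen.grid.VectorField` objects under the
pull-back warping convention of :func:`~deformgen.grid.warp_volume`.
Out-of-grid samples during inversion and composition clamp to the nearest
edge value, which avoids introducing spurious boundary vectors.
"""

from __future__ import annotations

import numpy as np

from .grid import GeometryError, ScalarVolume, VectorField, _check_geometry, _sample_at

__all__ = ["invert_dvf", "compose_dvfs", "transfer_dvf"]


def _sample_field(d: VectorField, coords: np.ndarray, fill=None) -> np.ndarray:
    """Trilinear sampling of all three components at voxel coords."""
    return np.stack([
        _sample_at(c, coords, order=1, fill=fill)
        for c in (d.dx, d.dy, d.dz)
    ])


def invert_dvf(d: VectorField, tol: float = 0.01, max_iter: int = 50) -> VectorField:
    """Invert a displacement field by fixed-point iteration.

    Starting from v = 0, each sweep refines v(x) ← −d(x + v(x)) with
    trilinear sampling of d, so that composing d after v is (approximately)
    the identity.  Iteration stops when the largest per-voxel change drops
    below ``tol`` voxels or after ``max_iter`` sweeps.

    The result's ``meta`` carries ``inverse_residual_mm`` (mean and max of
    ‖d(x + v(x)) + v(x)‖) and a ``converged`` flag; non-convergence
    (residual above 10·tol at max_iter) is flagged there rather than raised,
    since a slightly inaccurate inverse is still usable downstream.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not np.all(np.isfinite(d.as_array())):
        raise ValueError("displacement field contains non-finite values")
    sp = np.asarray(d.spacing).reshape(3, 1, 1, 1)
    idx = np.indices(d.shape, dtype=float)
    v = np.zeros((3,) + d.shape)
    converged = False
    for _ in range(int(max_iter)):
        coords = idx + v / sp
        v_new = -_sample_field(d, coords)
        step_vox = np.abs(v_new - v) / sp
        v = v_new
        if step_vox.max() < tol:
            converged = True
            break
    coords = idx + v / sp
    resid = np.sqrt(((_sample_field(d, coords) + v) ** 2).sum(axis=0))
    vox = float(np.min(d.spacing))
    if not converged and resid.max() / vox > 10 * tol:
        converged = False
    out = VectorField(v[0], v[1], v[2], d.spacing, d.origin)
    out.meta["inverse_residual_mm"] = {
        "mean": float(resid.mean()), "max": float(resid.max()),
    }
    out.meta["converged"] = bool(converged)
    return out


def compose_dvfs(a: VectorField, b: VectorField) -> VectorField:
    """Compose two displacement fields: c(x) = b(x) + a(x + b(x)).

    Pull-back warping by c equals warping by b first and then by a, i.e.
    ``warp(vol, c) ≈ warp(warp(vol, a), b)`` up to interpolation error.
    """
    _check_geometry(a, b)
    sp = np.asarray(a.spacing).reshape(3, 1, 1, 1)
    coords = np.indices(a.shape, dtype=float) + b.as_array() / sp
    c = b.as_array() + _sample_field(a, coords)
    return VectorField(c[0], c[1], c[2], a.spacing, a.origin)


def transfer_dvf(intra: VectorField, inter: VectorField) -> VectorField:
    """Carry a within-patient DVF across patients via a between-patient DVF.

    Each component of ``intra`` is treated as a scalar image and resampled
    through ``inter`` exactly as :func:`~deformgen.grid.warp_volume`
    resamples a volume: output_c(y) = intra_c(y + inter(y)).  Vectors are
    deliberately NOT reoriented (no Jacobian applied) — the deformation
    magnitudes along LR/AP/SI are moved as images, which keeps the transfer
    linear in ``intra``.
    """
    _check_geometry(intra, inter)
    sp = np.asarray(inter.spacing).reshape(3, 1, 1, 1)
    coords = np.indices(inter.shape, dtype=float) + inter.as_array() / sp
    moved = np.stack([
        _sample_at(c, coords, order=1, fill=0.0)
        for c in (intra.dx, intra.dy, intra.dz)
    ])
    return VectorField(moved[0], moved[1], moved[2], intra.spacing, intra.origin)
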