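"""Synthetic head-and-neck-like phantom population with known deformations.

A stand-in for a clinical cohort of planning + daily CT scans: geometric
CT-like volumes (body ellipsoid at ~0 HU, a mandible-like bone arc at
~+1000 HU, two parotid-like soft-tissue ellipsoids at ~+40 HU on an air
background) deformed by smooth, low-rank random displacement fields whose
ground truth is stored.  Between-subject ("inter") and per-fraction
("intra") variation each come from a small orthogonal basis of latent
deformation modes with Gaussian weights — the same low-rank statistical
structure the shape-model learner assumes — so that learned models can be
checked against the generating basis.

The phantoms are deliberately geometric rather than anatomically textured:
the learning pipeline depends on smooth intensity structures with distinct
organs, not anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dvf_ops import transfer_dvf
from .grid import LabelMask, ScalarVolume, VectorField, warp_mask, warp_volume
from .shape_model import devectorize_field, vectorize_field

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "PhantomPopulation",
    "make_reference_phantom",
    "make_latent_deformation_basis",
    "make_population",
]

LABELS = {1: "body", 2: "mandible", 3: "parotid_L", 4: "parotid_R"}

# nominal intensities, HU
_HU = {"air": -1000.0, "body": 0.0, "mandible": 1000.0, "parotid": 40.0}


@dataclass
class PhantomSpec:
    """Geometry and noise settings of the reference phantom.

    Defaults: a 64×64×48 grid at (2, 2, 3) mm — large enough for a 3-level
    registration pyramid, small enough for seconds-scale registration —
    with 15 HU additive Gaussian noise, a plausible CT-on-rails level.
    Structure geometry is given in mm as (center offsets from the volume
    center, semi-axes).
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    body_radii: tuple[float, float, float] = (52.0, 48.0, 66.0)
    parotid_radii: tuple[float, float, float] = (12.0, 14.0, 18.0)
    parotid_offset: tuple[float, float, float] = (30.0, 4.0, 6.0)
    mandible_arc_radius: float = 34.0
    mandible_tube_radius: float = 6.0
    mandible_offset: tuple[float, float, float] = (0.0, 14.0, -18.0)
    texture_sd: float = 60.0
    texture_smoothness_mm: float = 5.0
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        for r, e in zip(self.body_radii, extent):
            if 2 * r >= e:
                raise ValueError("body ellipsoid does not fit inside the grid")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def center_mm(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    def foldover_limit_mm(self) -> float:
        """Largest admissible displacement: half the smallest body semi-axis.

        Displacements beyond half the anatomy scale, at the smoothness used
        here, risk non-invertible (folded) deformations.
        """
        return 0.5 * float(min(self.body_radii))


@dataclass
class PhantomSubject:
    """One synthetic patient: planning volume + daily volumes, with truth."""

    planning: ScalarVolume
    planning_mask: LabelMask
    dailies: list[ScalarVolume]
    true_inter: VectorField        # planning = warp(reference, true_inter)
    true_intra: list[VectorField]  # daily j = warp(planning, true_intra[j])


@dataclass
class PhantomPopulation:
    """A cohort of phantom subjects with stored ground-truth deformations."""

    spec: PhantomSpec
    reference: ScalarVolume
    reference_mask: LabelMask
    subjects: list[PhantomSubject]
    inter_basis: list[VectorField] = field(default_factory=list)
    intra_basis: list[VectorField] = field(default_factory=list)
    inter_weights: np.ndarray | None = None   # (n_subjects, K_inter)
    intra_weights: np.ndarray | None = None   # (n_subjects, n_fractions, K_intra)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _world_grid(spec: PhantomSpec):
    idx = np.indices(spec.shape, dtype=float)
    sp = np.asarray(spec.spacing).reshape(3, 1, 1, 1)
    return idx * sp  # origin at 0


def _ellipsoid(world, center, radii) -> np.ndarray:
    q = sum(((world[k] - center[k]) / radii[k]) ** 2 for k in range(3))
    return q <= 1.0


def make_reference_phantom(spec: PhantomSpec | None = None
                           ) -> tuple[ScalarVolume, LabelMask]:
    """Build the reference CT-like phantom and its structure mask.

    Deterministic for a given spec/seed.  With ``noise_sd=0`` and
    ``texture_sd=0`` the volume takes exactly the four nominal intensities
    (air, body, mandible, parotid).
    """
    spec = spec or PhantomSpec()
    world = _world_grid(spec)
    c = spec.center_mm()

    body = _ellipsoid(world, c, spec.body_radii)
    mc = c + np.asarray(spec.mandible_offset)
    rho = np.sqrt((world[0] - mc[0]) ** 2 + (world[1] - mc[1]) ** 2)
    torus = (rho - spec.mandible_arc_radius) ** 2 + (world[2] - mc[2]) ** 2 \
        <= spec.mandible_tube_radius ** 2
    mandible = torus & (world[1] >= mc[1]) & body   # anterior half-arc
    off = np.asarray(spec.parotid_offset)
    par_l = _ellipsoid(world, c + off * np.array([1, 1, 1]), spec.parotid_radii) & body
    par_r = _ellipsoid(world, c + off * np.array([-1, 1, 1]), spec.parotid_radii) & body
    for s in (par_l, par_r):
        if not s.any():
            raise ValueError("parotid structure lies outside the grid")
    par_l &= ~mandible
    par_r &= ~mandible

    data = np.full(spec.shape, _HU["air"])
    data[body] = _HU["body"]
    data[par_l | par_r] = _HU["parotid"]
    data[mandible] = _HU["mandible"]
    if spec.texture_sd > 0:
        # smooth soft-tissue heterogeneity inside the body (bone excluded):
        # part of the anatomy, not noise — it deforms with the subject and
        # gives intensity-driven registration interior signal to work with
        trng = np.random.default_rng((spec.seed, 1))
        tex = ndimage.gaussian_filter(
            trng.standard_normal(spec.shape),
            sigma=spec.texture_smoothness_mm / np.asarray(spec.spacing),
        )
        tex *= spec.texture_sd / max(tex.std(), 1e-12)
        data[body & ~mandible] += tex[body & ~mandible]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[body] = 1
    labels[mandible] = 2
    labels[par_l] = 3
    labels[par_r] = 4
    vol = ScalarVolume(data, spec.spacing, (0.0, 0.0, 0.0))
    mask = LabelMask(labels, dict(LABELS), spec.spacing, (0.0, 0.0, 0.0))
    return vol, mask


def make_latent_deformation_basis(shape, spacing, k: int, magnitude_mm: float = 3.0,
                                  smoothness_mm: float = 20.0, seed=None,
                                  support: np.ndarray | None = None
                                  ) -> list[VectorField]:
    """K smooth, zero-boundary, mutually orthogonal latent deformation modes.

    Each mode starts as seeded white noise per component, is smoothed by a
    Gaussian of ``smoothness_mm``, tapered to zero on the one-voxel boundary
    shell, optionally multiplied by a ``support`` weight in [0, 1] (used to
    confine deformation to the anatomy — air does not deform),
    orthonormalised against the previous modes (vectorized dot products
    < 1e−8 afterwards), and finally scaled so its peak displacement
    magnitude is ``magnitude_mm``.
    """
    if k < 1:
        raise ValueError("need at least one latent mode")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    sp = np.asarray(spacing, dtype=float)
    sig = smoothness_mm / sp

    # smooth taper that is exactly zero on the boundary shell
    win = np.ones(shape)
    for ax, n in enumerate(shape):
        ramp = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
        ramp = np.clip(ramp / max(3.0, 0.05 * n), 0.0, 1.0)
        sl = [None] * 3
        sl[ax] = slice(None)
        win = win * ramp[tuple(sl)]

    basis_vecs = []
    fields = []
    while len(fields) < k:
        comps = np.stack([
            ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sig, mode="constant")
            for _ in range(3)
        ]) * win
        if support is not None:
            comps = comps * support
        f = VectorField(comps[0], comps[1], comps[2], tuple(sp), (0.0, 0.0, 0.0))
        v = vectorize_field(f)
        for u in basis_vecs:
            v = v - (u @ v) * u
        norm = np.linalg.norm(v)
        if norm < 1e-8:  # pragma: no cover - essentially impossible draw
            continue
        v = v / norm
        basis_vecs.append(v)
        unit = devectorize_field(v, shape, tuple(sp), (0.0, 0.0, 0.0))
        peak = float(unit.magnitude().max())
        fields.append(unit * (magnitude_mm / peak))
    return fields


def _combine(basis: list[VectorField], weights: np.ndarray) -> VectorField:
    out = VectorField.zeros(basis[0].shape, basis[0].spacing, basis[0].origin)
    for w, b in zip(weights, basis):
        out = out + b * float(w)
    return out


def make_population(spec: PhantomSpec | None = None, n_subjects: int = 8,
                    n_fractions: int = 5, k_inter: int = 2, k_intra: int = 3,
                    weight_sd_inter: float = 1.0, weight_sd_intra: float = 1.0,
                    magnitude_inter_mm: float = 5.0, magnitude_intra_mm: float = 6.0,
                    smoothness_mm: float = 20.0, seed: int = 0) -> PhantomPopulation:
    """Generate a phantom cohort with known inter/intra deformations.

    Subject i's planning volume is the (noise-free) reference warped by
    d_i = Σ_k w_ik B_k (inter basis).  Fraction j of subject i is the
    planning volume warped by the population-common intra pattern
    Σ_k v_ijk C_k expressed in subject i's anatomy, i.e. resampled through
    d_i — within-patient variation is shared across the population in
    reference coordinates, exactly the structure the intra variation model
    assumes.  The applied fields are stored as ground truth and fresh noise
    is added to every volume.  Latent weights are Gaussian, truncated at ±2.5 sd so that no
    draw can approach the foldover guard (any realized displacement beyond
    half the smallest body semi-axis is rejected as a spec error).
    """
    spec = spec or PhantomSpec()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_fractions < 1:
        raise ValueError("need at least 1 fraction")
    rng = np.random.default_rng(seed)
    noiseless = PhantomSpec(**{**spec.__dict__, "noise_sd": 0.0})
    ref_clean, ref_mask = make_reference_phantom(noiseless)

    # deformation is confined to the anatomy: a feathered body window keeps
    # the latent modes ~1 inside the body and decaying to 0 a few voxels out
    support = ndimage.gaussian_filter(
        (ref_mask.data > 0).astype(float),
        sigma=6.0 / np.asarray(spec.spacing),
    )
    support /= support.max()

    inter_basis = make_latent_deformation_basis(
        spec.shape, spec.spacing, k_inter, magnitude_inter_mm, smoothness_mm, rng,
        support=support,
    )
    intra_basis = make_latent_deformation_basis(
        spec.shape, spec.spacing, k_intra, magnitude_intra_mm, smoothness_mm, rng,
        support=support,
    )

    def draw(sd, size):
        w = rng.normal(0.0, 1.0, size=size)
        return np.clip(w, -2.5, 2.5) * sd

    w_inter = draw(weight_sd_inter, (n_subjects, k_inter))
    w_intra = draw(weight_sd_intra, (n_subjects, n_fractions, k_intra))

    limit = spec.foldover_limit_mm()

    def checked(fld: VectorField) -> VectorField:
        peak = float(fld.magnitude().max())
        if peak > limit:
            raise ValueError(
                f"deformation peak {peak:.2f} mm exceeds foldover guard {limit:.2f} mm"
            )
        return fld

    def add_noise(vol: ScalarVolume) -> ScalarVolume:
        if spec.noise_sd == 0:
            return vol.copy()
        return ScalarVolume(
            vol.data + rng.normal(0.0, spec.noise_sd, size=vol.data.shape),
            vol.spacing, vol.origin,
        )

    subjects = []
    for i in range(n_subjects):
        d_inter = checked(_combine(inter_basis, w_inter[i]))
        plan_clean = warp_volume(ref_clean, d_inter, fill=_HU["air"])
        plan_mask = warp_mask(ref_mask, d_inter)
        dailies, intras = [], []
        for j in range(n_fractions):
            common = _combine(intra_basis, w_intra[i, j])
            d_intra = checked(transfer_dvf(common, d_inter))
            daily_clean = warp_volume(plan_clean, d_intra, fill=_HU["air"])
            dailies.append(add_noise(daily_clean))
            intras.append(d_intra)
        subjects.append(PhantomSubject(
            planning=add_noise(plan_clean),
            planning_mask=plan_mask,
            dailies=dailies,
            true_inter=d_inter,
            true_intra=intras,
        ))

    ref_noisy, _ = make_reference_phantom(spec)
    return PhantomPopulation(
        spec=spec,
        reference=ref_noisy,
        reference_mask=ref_mask,
        subjects=subjects,
        inter_basis=inter_basis,
        intra_basis=intra_basis,
        inter_weights=w_inter,
        intra_weights=w_intra,
    )
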