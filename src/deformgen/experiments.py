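"""Canned end-to-end experiments on phantom populations.

These drive the full workflow — generate a phantom cohort with known
low-rank deformation structure, learn the variation models through
registration, sample artificial image pairs, validate registration against
the stored truth — and reduce the outcome to a few scalar figures of merit
(subspace recovery, scree separation, error-vs-deformation statistics).
They are what the package's own quality checks run; problem sizes default
to the desk-scale study conditions (8 subjects × 5 fractions on a 64×64×48
grid at (2, 2, 3) mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import VectorField
from .phantom import PhantomSpec, make_population
from .pipeline import (
    align_and_crop_population,
    build_interpatient_model,
    build_intrapatient_model,
    generate_artificial_pair,
    run_validation_experiment,
)
from .registration import DemonsParams
from .shape_model import ShapeModelResults, vectorize_field

__all__ = [
    "RecoveryResult",
    "parameter_recovery_experiment",
    "self_consistency_experiment",
    "subspace_alignment",
]


def _crop_like(fld: VectorField, target_shape, target_origin) -> VectorField:
    """Crop a field on the full phantom grid to a model's cropped grid,
    located via the origin offset (axis-aligned grids only)."""
    off = np.round(
        (np.asarray(target_origin) - np.asarray(fld.origin)) / np.asarray(fld.spacing)
    ).astype(int)
    sl = tuple(slice(o, o + s) for o, s in zip(off, target_shape))
    return VectorField(
        fld.dx[sl], fld.dy[sl], fld.dz[sl], fld.spacing, tuple(target_origin)
    )


def subspace_alignment(results: ShapeModelResults, basis: list[VectorField],
                       k: int | None = None) -> np.ndarray:
    """Principal-angle cosines between the fitted top-k mode subspace and a
    generating basis (fields cropped to the model grid if needed)."""
    k = len(basis) if k is None else int(k)
    cropped = [
        b if b.shape == results.grid_shape
        else _crop_like(b, results.grid_shape, results.grid_origin)
        for b in basis
    ]
    B = np.column_stack([vectorize_field(b) for b in cropped])
    B, _ = np.linalg.qr(B)
    M = results.modes[:, :k]
    return np.linalg.svd(B.T @ M, compute_uv=False)


@dataclass
class RecoveryResult:
    """Outcome of the learn-the-generator experiment."""

    inter: ShapeModelResults
    intra: ShapeModelResults
    inter_coverage_k: float        # % variance covered by the top K_inter modes
    intra_scree_drop: float        # λ(K_intra) / λ(K_intra + 1)
    intra_subspace_cosines: np.ndarray
    planning: list
    dailies: list
    masks: list
    reference_index: int


def parameter_recovery_experiment(seed: int = 0, n_subjects: int = 8,
                                  n_fractions: int = 5, k_inter: int = 2,
                                  k_intra: int = 3,
                                  spec: PhantomSpec | None = None,
                                  params: DemonsParams | None = None,
                                  reference_index: int = 0,
                                  alpha_inter: float = 90.0,
                                  alpha_intra: float = 95.0) -> RecoveryResult:
    """Generate a phantom cohort with K latent modes, run the full
    register → transfer → fit workflow, and measure how well the fitted
    models recover the generating low-rank structure."""
    spec = spec or PhantomSpec(seed=seed)
    pop = make_population(
        spec, n_subjects=n_subjects, n_fractions=n_fractions,
        k_inter=k_inter, k_intra=k_intra, seed=seed,
    )
    planning, dailies, masks = align_and_crop_population(
        [s.planning for s in pop.subjects],
        [s.dailies for s in pop.subjects],
        [s.planning_mask for s in pop.subjects],
        reference_index=reference_index,
    )
    inter, efs = build_interpatient_model(
        planning, reference_index, alpha=alpha_inter, params=params,
        preprocess=False,
    )
    intra, _ = build_intrapatient_model(
        planning, dailies, efs, reference_index, alpha=alpha_intra, params=params,
    )
    ev = intra.eigenvalues
    drop = float(ev[k_intra - 1] / ev[k_intra]) if ev.size > k_intra else np.inf
    cos = subspace_alignment(intra, pop.intra_basis, k=k_intra)
    return RecoveryResult(
        inter=inter,
        intra=intra,
        inter_coverage_k=inter.explained_percent(k_inter),
        intra_scree_drop=drop,
        intra_subspace_cosines=cos,
        planning=planning,
        dailies=dailies,
        masks=masks,
        reference_index=reference_index,
    )


def self_consistency_experiment(recovery: RecoveryResult, seed: int = 0,
                                d_max_inter: float = 3.0,
                                d_max_intra: tuple[float, ...] = (2.0, 3.5, 4.5),
                                params: DemonsParams | None = None,
                                ) -> pd.DataFrame:
    """Sample artificial planning/daily pairs from fitted models and score a
    fresh registration of each pair against the stored ground truth.

    Returns the per-structure report: registration error ‖DN − DI‖ next to
    the true deformation magnitude ‖DI‖, for every daily volume and
    structure.  A sound pipeline leaves the former well below the latter.
    """
    ref_idx = recovery.reference_index
    pair = generate_artificial_pair(
        recovery.inter, recovery.intra, recovery.planning[ref_idx],
        d_max_inter=d_max_inter, d_max_intra=d_max_intra,
        seed=seed, reference_mask=recovery.masks[ref_idx],
    )
    return run_validation_experiment([pair], params=params)
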