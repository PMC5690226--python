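"""End-to-end workflows: learn the variation models from a population,
generate artificial planning/daily image pairs with known deformation, and
validate a registration algorithm against that ground truth.

Two variation models are learned.  The between-patient ("inter") model is
fitted to the DVFs EF_k obtained by registering every non-reference planning
volume to the reference planning volume.  The within-patient ("intra") model
is fitted to the per-fraction DVFs IF_(i,j), each computed in its own
planning space and carried to the reference space through that subject's
EF field.  Artificial image pairs are then produced by sampling the models:

    DE  ← sample(inter model, D_max);  planning ← warp(reference, DE⁻¹)
    DT  ← sample(intra model, D_max);  DI ← transfer(DT, DE)
    daily ← warp(planning, DI⁻¹)

so every artificial daily volume carries a voxel-level ground-truth
deformation DI against which a registration result DN can be scored.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dvf_ops import invert_dvf, transfer_dvf
from .grid import (
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
from .phantom import PhantomPopulation, PhantomSpec, make_population
from .registration import DemonsParams, demons_register
from .shape_model import ShapeModelResults, fit_shape_model
from .validation import mean_deformation_magnitude, structure_report

__all__ = [
    "ArtificialDaily",
    "ArtificialPair",
    "align_and_crop_population",
    "build_interpatient_model",
    "build_intrapatient_model",
    "generate_artificial_pair",
    "run_validation_experiment",
    "write_population",
    "load_population_volumes",
]


# ---------------------------------------------------------------------------
# Model building (training workflow)
# ---------------------------------------------------------------------------

def align_and_crop_population(planning: list[ScalarVolume],
                              dailies: list[list[ScalarVolume]] | None = None,
                              masks: list[LabelMask] | None = None,
                              reference_index: int = 0,
                              search_radius: int = 3):
    """Rigidly align every volume to the reference planning volume and crop
    all of them to the common (intersection) space.

    Each planning AND each daily volume gets its own integer-voxel
    translation (maximising cross-correlation with the reference); per-
    subject masks follow their subject's planning translation.  Returns
    ``(planning, dailies, masks)`` with ``dailies``/``masks`` ``None`` when
    not supplied; afterwards everything shares one grid geometry.
    """
    ref = planning[reference_index]
    t_plan = [
        (0, 0, 0) if i == reference_index
        else rigid_align(vol, ref, search_radius=search_radius)
        for i, vol in enumerate(planning)
    ]
    vols = list(planning)
    trans = list(t_plan)
    counts = []
    if dailies is not None:
        for subj in dailies:
            counts.append(len(subj))
            for dvol in subj:
                vols.append(dvol)
                trans.append(rigid_align(dvol, ref, search_radius=search_radius))
    if masks is not None:
        for m, t in zip(masks, t_plan):
            vols.append(ScalarVolume(m.data.astype(float), m.spacing, m.origin))
            trans.append(t)
    cropped = crop_to_common_space(vols, trans)
    n = len(planning)
    out_planning = cropped[:n]
    out_dailies = None
    pos = n
    if dailies is not None:
        out_dailies = []
        for c in counts:
            out_dailies.append(cropped[pos:pos + c])
            pos += c
    out_masks = None
    if masks is not None:
        out_masks = [
            LabelMask(np.round(c.data).astype(m.data.dtype), m.label_names,
                      c.spacing, c.origin)
            for c, m in zip(cropped[pos:], masks)
        ]
    return out_planning, out_dailies, out_masks


def build_interpatient_model(planning_volumes: list[ScalarVolume],
                             reference_index: int, alpha: float = 90.0,
                             params: DemonsParams | None = None,
                             search_radius: int = 3,
                             preprocess: bool = True,
                             ) -> tuple[ShapeModelResults, list[VectorField]]:
    """Fit the between-patient variation model.

    Every non-reference planning volume is rigidly aligned and cropped to
    the reference (unless ``preprocess=False``, for volumes already on one
    grid), then deformably registered to it; the resulting EF fields train
    the shape model at retention level ``alpha`` (default 90).  Returns the
    fitted results and the EF fields, ordered as the input with the
    reference's own (identity) field included, so that ``ef_fields[i]``
    always belongs to ``planning_volumes[i]``.
    """
    if len(planning_volumes) < 3:
        raise ValueError("need at least 3 subjects to model between-patient variation")
    if preprocess:
        cropped, _, _ = align_and_crop_population(
            planning_volumes, reference_index=reference_index,
            search_radius=search_radius,
        )
    else:
        cropped = list(planning_volumes)
    ref = cropped[reference_index]
    ef_fields: list[VectorField] = []
    for i, vol in enumerate(cropped):
        if i == reference_index:
            ef_fields.append(VectorField.zeros(ref.shape, ref.spacing, ref.origin))
            continue
        try:
            ef = demons_register(ref, vol, params)
        except Exception as exc:
            raise RuntimeError(f"registration failed for subject {i}: {exc}") from exc
        ef.meta["subject"] = i
        ef_fields.append(ef)
    training = [f for i, f in enumerate(ef_fields) if i != reference_index]
    results = fit_shape_model(training, alpha=alpha)
    return results, ef_fields


def build_intrapatient_model(planning_volumes: list[ScalarVolume],
                             daily_volumes: list[list[ScalarVolume]],
                             ef_fields: list[VectorField],
                             reference_index: int, alpha: float = 95.0,
                             params: DemonsParams | None = None,
                             ) -> tuple[ShapeModelResults, list[list[VectorField]]]:
    """Fit the within-patient variation model.

    For each subject (the reference included) every daily volume is
    registered to that subject's planning volume; the per-fraction DVFs are
    carried to the reference space through the subject's EF field (the
    reference subject's fields need no transfer) and pooled into one
    training set, fitted at level ``alpha`` (default 95).
    """
    if not (len(planning_volumes) == len(daily_volumes) == len(ef_fields)):
        raise ValueError("planning volumes, daily volumes and EF fields must align")
    if_fields: list[list[VectorField]] = []
    pooled: list[VectorField] = []
    for i, (plan, dailies) in enumerate(zip(planning_volumes, daily_volumes)):
        ef = ef_fields[i]
        if ef is None:
            raise ValueError(f"missing EF field for subject {i}")
        subject_fields = []
        for j, daily in enumerate(dailies):
            intra = demons_register(plan, daily, params)
            moved = intra if i == reference_index else transfer_dvf(intra, ef)
            moved.meta["subject"] = i
            moved.meta["fraction"] = j
            subject_fields.append(moved)
            pooled.append(moved)
        if_fields.append(subject_fields)
    results = fit_shape_model(pooled, alpha=alpha)
    return results, if_fields


# ---------------------------------------------------------------------------
# Artificial image generation (sampling workflow)
# ---------------------------------------------------------------------------

@dataclass
class ArtificialDaily:
    """One artificial daily volume with its voxel-level ground truth DI."""

    volume: ScalarVolume
    truth: VectorField
    d_max: float
    mask: LabelMask | None = None
    inversion_converged: bool = True


@dataclass
class ArtificialPair:
    """An artificial planning volume plus its daily volumes and provenance."""

    planning: ScalarVolume
    de: VectorField
    dailies: list[ArtificialDaily]
    mask: LabelMask | None = None
    provenance: dict = field(default_factory=dict)


def generate_artificial_pair(inter: ShapeModelResults, intra: ShapeModelResults,
                             reference: ScalarVolume,
                             d_max_inter: float = 3.0,
                             d_max_intra: tuple[float, ...] = (2.0, 3.5, 4.5),
                             seed: int | None = None,
                             reference_mask: LabelMask | None = None,
                             ) -> ArtificialPair:
    """Sample the two models into an artificial planning/daily image set.

    Operation order: a random DE from the inter model is inverted and
    applied to the reference to make the artificial planning volume; for
    each intra D_max a random DT is transferred through DE into the
    artificial planning space (giving the ground truth DI), inverted, and
    applied to the planning volume to make a daily volume.  Masks, when
    given, are propagated with the same warps (nearest-neighbour).
    Everything is reproducible from ``seed``; non-converged inversions are
    recorded per daily, not raised.
    """
    if inter.grid_shape != intra.grid_shape:
        raise ValueError("inter and intra models must share the reference grid")
    rng = np.random.default_rng(seed)
    de, w_inter = inter.sample(d_max_inter, seed=rng)
    de_inv = invert_dvf(de)
    planning = warp_volume(reference, de_inv)
    mask = warp_mask(reference_mask, de_inv) if reference_mask is not None else None

    dailies = []
    for dm in d_max_intra:
        dt, w = intra.sample(dm, seed=rng)
        di = transfer_dvf(dt, de)
        di_inv = invert_dvf(di)
        daily = warp_volume(planning, di_inv)
        dmask = warp_mask(mask, di_inv) if mask is not None else None
        dailies.append(ArtificialDaily(
            volume=daily, truth=di, d_max=float(dm), mask=dmask,
            inversion_converged=bool(di_inv.meta.get("converged", True)),
        ))
    prov = {
        "seed": seed,
        "d_max_inter": float(d_max_inter),
        "d_max_intra": [float(d) for d in d_max_intra],
        "inter_weights": [float(x) for x in w_inter.b],
        "de_inversion_converged": bool(de_inv.meta.get("converged", True)),
    }
    return ArtificialPair(planning=planning, de=de, dailies=dailies,
                          mask=mask, provenance=prov)


def run_validation_experiment(pairs: list[ArtificialPair],
                              params: DemonsParams | None = None,
                              structures: tuple[int, ...] = (2, 3, 4),
                              ) -> pd.DataFrame:
    """Register every artificial daily to its planning volume and score it.

    For each pair and each labelled structure the report carries the
    registration error ‖DN − DI‖ (mean ± SD ± max over structure voxels)
    and the ground-truth deformation magnitude ‖DI‖ (mean ± SD) — the
    registration-error table and deformation-magnitude table of a
    validation study, side by side.
    """
    rows = []
    for p_idx, pair in enumerate(pairs):
        if pair.mask is None:
            raise ValueError("validation requires mask-propagated pairs")
        for daily in pair.dailies:
            if daily.truth is None:
                raise ValueError("daily volume is missing its ground-truth DVF")
            dn = demons_register(pair.planning, daily.volume, params)
            rep = structure_report(dn, daily.truth, pair.mask, d_max=daily.d_max)
            for _, r in rep.iterrows():
                label = [k for k, v in pair.mask.label_names.items()
                         if v == r["structure"]]
                if not label or label[0] not in structures:
                    continue
                mag_mean, mag_sd = mean_deformation_magnitude(
                    daily.truth, pair.mask, label[0]
                )
                rows.append({
                    "pair": p_idx,
                    "d_max": daily.d_max,
                    "structure": r["structure"],
                    "error_mean_mm": r["mean_mm"],
                    "error_sd_mm": r["sd_mm"],
                    "error_max_mm": r["max_mm"],
                    "truth_mean_mm": mag_mean,
                    "truth_sd_mm": mag_sd,
                    "n_voxels": r["n_voxels"],
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Population persistence (manifest + volumes on disk, for the CLI stages)
# ---------------------------------------------------------------------------

def write_population(pop: PhantomPopulation, outdir: str, fmt: str = ".mha") -> str:
    """Write a phantom population to disk with a JSON manifest.

    Every file (volumes, masks, ground-truth fields) is listed in the
    manifest with its role; returns the manifest path.
    """
    os.makedirs(outdir, exist_ok=True)
    man = {
        "spec": {
            "shape": list(pop.spec.shape),
            "spacing": list(pop.spec.spacing),
            "noise_sd": pop.spec.noise_sd,
            "seed": pop.spec.seed,
        },
        "reference": {"volume": "reference" + fmt, "mask": "reference_mask" + fmt},
        "subjects": [],
    }
    write_volume(pop.reference, os.path.join(outdir, man["reference"]["volume"]))
    write_mask(pop.reference_mask, os.path.join(outdir, man["reference"]["mask"]))
    for i, subj in enumerate(pop.subjects):
        entry = {
            "id": i,
            "planning": f"s{i:02d}_planning{fmt}",
            "planning_mask": f"s{i:02d}_planning_mask{fmt}",
            "true_inter": f"s{i:02d}_true_inter{fmt}",
            "dailies": [],
            "true_intra": [],
        }
        write_volume(subj.planning, os.path.join(outdir, entry["planning"]))
        write_mask(subj.planning_mask, os.path.join(outdir, entry["planning_mask"]))
        write_vector_field(subj.true_inter, os.path.join(outdir, entry["true_inter"]))
        for j, (daily, tf) in enumerate(zip(subj.dailies, subj.true_intra)):
            dname = f"s{i:02d}_daily{j:02d}{fmt}"
            tname = f"s{i:02d}_true_intra{j:02d}{fmt}"
            write_volume(daily, os.path.join(outdir, dname))
            write_vector_field(tf, os.path.join(outdir, tname))
            entry["dailies"].append(dname)
            entry["true_intra"].append(tname)
        man["subjects"].append(entry)
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(man, fh, indent=1)
    return path


def load_population_volumes(manifest_path: str):
    """Load (planning volumes, daily volumes, reference mask) from a manifest."""
    base = os.path.dirname(manifest_path)
    with open(manifest_path) as fh:
        man = json.load(fh)
    planning = [read_volume(os.path.join(base, s["planning"])) for s in man["subjects"]]
    dailies = [
        [read_volume(os.path.join(base, d)) for d in s["dailies"]]
        for s in man["subjects"]
    ]
    ref_mask = read_mask(os.path.join(base, man["reference"]["mask"]))
    return planning, dailies, ref_mask
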