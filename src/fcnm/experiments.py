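"""End-to-end phantom experiments for validating the mapping pipeline.

These drive the whole chain — phantom simulation, lite preprocessing, seed
construction, subject FC maps, group t-tests, FWE thresholding, probability
overlay — against planted ground truth, and are what the acceptance script
and the heavier integration tests run.

Phantom preprocessing configuration
-----------------------------------
Phantom runs keep the nuisance machinery that is meaningful for the phantom
(linear drift, Friston-24 motion expansion, FD spike regressors, 0.01-0.1 Hz
band-pass) but disable tissue-signal regression and spatial smoothing:

* The phantom plants a small number of latent networks in spatially white
  noise, so its global mean series is essentially a clean copy of the
  planted latents themselves; regressing it out would delete the very
  structure the phantom exists to recover. Real data's global signal is a
  broad mixture of vascular, respiratory and neural sources, which is why
  global-signal regression stays on by default for real runs. There is no
  white matter or CSF compartment in the phantom at all.
* Spatial smoothing exists to suppress registration noise across real
  subjects; the phantom has none, and a 6-mm kernel on a 3-mm grid would
  only blur the sharp planted boundary that recovery is scored against.
  Smoothing correctness is verified by its own convolution oracle tests.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .coords import FocusRecord, SeedSpec, build_contrast_seed
from .fc import FCMap, seed_fc_map
from .grid import BinaryMask, VolumeGrid
from .group import fwe_threshold_mask, one_sample_t, overlay_probability, threshold_probability
from .overlap import dice_coefficient
from .preprocess import NuisanceSpec, preprocess_bold
from .synthetic import (
    Blob,
    NetworkSpec,
    PhantomScene,
    SceneConfig,
    generate_ground_truth,
    simulate_subject_bold,
    simulate_null_bold,
)

__all__ = [
    "phantom_nuisance_spec",
    "recovery_scene_config",
    "scene_foci_records",
    "run_phantom_fcnm",
    "phantom_recovery_experiment",
    "fwe_null_calibration",
    "negative_fc_experiment",
]


def phantom_nuisance_spec(**overrides) -> NuisanceSpec:
    """Preprocessing spec for phantom runs (see module docstring)."""
    kwargs = dict(
        include_global=False,
        include_wm=False,
        include_csf=False,
        smoothing_fwhm_mm=0.0,
    )
    kwargs.update(overrides)
    return NuisanceSpec(**kwargs)


def recovery_scene_config(
    n_contrasts: int = 10,
    foci_per_contrast: int = 3,
    snr: float = 1.0,
    n_timepoints: int = 200,
    grid_n: int = 30,
    network_radius_mm: float = 24.0,
) -> SceneConfig:
    """One planted spherical network at the grid center, all contrasts in it."""
    return SceneConfig(
        networks=(
            NetworkSpec(
                name="planted",
                blobs=(Blob(center_mm=(0.0, 0.0, 0.0), radius_mm=network_radius_mm),),
                n_contrasts=n_contrasts,
                foci_per_contrast=foci_per_contrast,
            ),
        ),
        grid_n=grid_n,
        snr=snr,
        n_timepoints=n_timepoints,
    )


def scene_foci_records(scene: PhantomScene, direction: str = "hyper") -> dict[str, list[FocusRecord]]:
    """Scene foci grouped per contrast, as coordinate records."""
    out: dict[str, list[FocusRecord]] = {}
    for _, row in scene.foci.iterrows():
        rec = FocusRecord(
            study_id=row["study_id"],
            contrast_id=row["contrast_id"],
            xyz_mm=(row["x"], row["y"], row["z"]),
            space="MNI",
            direction=direction,
        )
        out.setdefault(rec.contrast_id, []).append(rec)
    return out


def run_phantom_fcnm(
    scene: PhantomScene,
    n_subjects: int,
    seed: int,
    radii_mm: Sequence[float] = (4.0,),
    thresholds: Sequence[float] = (0.6,),
    alpha: float = 0.05,
    fwe_method: str = "bonferroni",
    tail: str = "positive",
    nuisance: NuisanceSpec | None = None,
    contrast_ids: Sequence[str] | None = None,
) -> dict:
    """Simulate subjects and run the full mapping once per seed radius.

    Subjects are simulated and preprocessed once; FC maps are computed for
    every (radius, contrast) seed. Returns per-radius group maps, FWE masks,
    probability maps, and the thresholded networks keyed (radius, threshold).
    """
    nuisance = nuisance if nuisance is not None else phantom_nuisance_spec()
    foci = scene_foci_records(scene)
    if contrast_ids is None:
        contrast_ids = list(foci)
    seeds = {
        (r, cid): build_contrast_seed(foci[cid], SeedSpec(radius_mm=r), scene.grid)
        for r in radii_mm
        for cid in contrast_ids
    }
    brain = BinaryMask.full(scene.grid)

    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31, size=n_subjects)
    z_maps: dict[tuple[float, str], list[FCMap]] = {key: [] for key in seeds}
    n_qc_failed = 0
    for i, sseed in enumerate(subject_seeds):
        bold, motion = simulate_subject_bold(scene, int(sseed))
        clean, qc = preprocess_bold(bold, motion, nuisance)
        if qc is not None and not qc.passed:
            n_qc_failed += 1
            continue
        for (r, cid), seed_mask in seeds.items():
            fcmap = seed_fc_map(
                clean, seed_mask, brain, subject_id=f"sub-{i:03d}", contrast_id=cid
            )
            fcmap.z = fcmap.z.astype(np.float32)  # bound memory across subjects
            z_maps[(r, cid)].append(fcmap)

    stats = {key: one_sample_t(maps) for key, maps in z_maps.items()}
    fwe_masks = {
        key: fwe_threshold_mask(
            stat, alpha=alpha, method=fwe_method, tail=tail,
            z_maps=z_maps[key] if fwe_method == "permutation" else None,
            seed=int(rng.integers(0, 2**31)),
        )
        for key, stat in stats.items()
    }
    prob_maps = {
        r: overlay_probability([fwe_masks[(r, cid)] for cid in contrast_ids])
        for r in radii_mm
    }
    networks = {
        (r, thr): threshold_probability(prob_maps[r], thr)
        for r in radii_mm
        for thr in thresholds
    }
    return {
        "scene": scene,
        "seeds": seeds,
        "stats": stats,
        "fwe_masks": fwe_masks,
        "prob_maps": prob_maps,
        "networks": networks,
        "n_subjects_used": n_subjects - n_qc_failed,
        "n_qc_failed": n_qc_failed,
        "contrast_ids": list(contrast_ids),
    }


def phantom_recovery_experiment(
    seed: int,
    n_subjects: int = 40,
    n_contrasts: int = 10,
    foci_per_contrast: int = 3,
    snr: float = 1.0,
    n_timepoints: int = 200,
    grid_n: int = 30,
    radii_mm: Sequence[float] = (1.0, 4.0, 7.0),
    thresholds: Sequence[float] = (0.5, 0.6, 0.7),
    alpha: float = 0.05,
    reference_radius_mm: float = 4.0,
) -> dict:
    """Planted-network recovery plus radius/threshold robustness in one run.

    Returns the recovered networks, Dice against the planted ground truth
    (at the reference 4-mm radius and 60% threshold), Dice between the
    reference-radius network and each alternative radius, and the strict
    set-inclusion nesting status across probability thresholds.
    """
    config = recovery_scene_config(
        n_contrasts=n_contrasts,
        foci_per_contrast=foci_per_contrast,
        snr=snr,
        n_timepoints=n_timepoints,
        grid_n=grid_n,
    )
    scene = generate_ground_truth(config, rng_seed=seed)
    run = run_phantom_fcnm(
        scene,
        n_subjects=n_subjects,
        seed=seed + 1,
        radii_mm=radii_mm,
        thresholds=thresholds,
        alpha=alpha,
    )
    truth = scene.networks["planted"]
    networks = run["networks"]
    ref = networks[(reference_radius_mm, 0.6)]
    radius_dice = {
        r: dice_coefficient(ref, networks[(r, 0.6)])
        for r in radii_mm
        if r != reference_radius_mm
    }
    nesting_ok = all(
        networks[(r, hi)].issubset(networks[(r, lo)])
        for r in radii_mm
        for lo, hi in zip(sorted(thresholds), sorted(thresholds)[1:])
    )
    return {
        "run": run,
        "truth": truth,
        "recovery_dice": dice_coefficient(ref, truth),
        "radius_dice": radius_dice,
        "nesting_ok": nesting_ok,
    }


def fwe_null_calibration(
    seed: int,
    n_reps: int = 100,
    n_subjects: int = 20,
    grid_n: int = 15,
    n_timepoints: int = 120,
    alpha: float = 0.05,
    seed_radius_mm: float = 4.0,
    method: str = "bonferroni",
) -> dict:
    """Family-wise error calibration on pure-noise phantoms.

    Each repetition simulates ``n_subjects`` null series, seeds a single
    sphere at the grid center, runs the FC -> one-sample-t -> FWE chain,
    and records whether any voxel *outside the seed itself* survives. Seed
    voxels are excluded from the count: the seed time course is their own
    average, so their connectivity to it is real by construction, not a
    false positive. Returns the fraction of repetitions with any survivor.
    """
    grid = VolumeGrid.isotropic(grid_n, 3.0)
    center = FocusRecord(study_id="null", contrast_id="null", xyz_mm=(0.0, 0.0, 0.0))
    seed_mask = build_contrast_seed([center], SeedSpec(radius_mm=seed_radius_mm), grid)
    brain = BinaryMask.full(grid)
    rng = np.random.default_rng(seed)
    survivors_per_rep = []
    for _ in range(n_reps):
        maps = []
        for s in range(n_subjects):
            bold = simulate_null_bold(grid, n_timepoints, int(rng.integers(0, 2**31)))
            maps.append(seed_fc_map(bold, seed_mask, brain, subject_id=f"s{s}", contrast_id="null"))
        stat = one_sample_t(maps)
        mask = fwe_threshold_mask(stat, alpha=alpha, method=method, tail="positive",
                                  z_maps=maps if method == "permutation" else None,
                                  seed=int(rng.integers(0, 2**31)))
        outside = mask.data & ~seed_mask.data
        survivors_per_rep.append(int(outside.sum()))
    n_with_any = sum(1 for s in survivors_per_rep if s > 0)
    return {
        "rate": n_with_any / n_reps,
        "n_reps": n_reps,
        "survivors_per_rep": survivors_per_rep,
    }


def negative_fc_experiment(
    seed: int,
    n_subjects: int = 12,
    n_timepoints: int = 150,
    grid_n: int = 20,
    alpha: float = 0.05,
) -> dict:
    """Recover an antiphase region through the negative-connectivity tail.

    Two disjoint planted regions share one latent series with opposite
    signs; seeding in the first and thresholding the negative tail should
    recover the second.
    """
    config = SceneConfig(
        networks=(
            NetworkSpec(
                name="source",
                blobs=(Blob(center_mm=(-13.5, 0.0, 0.0), radius_mm=12.0),),
                n_contrasts=1,
                foci_per_contrast=3,
            ),
            NetworkSpec(
                name="antiphase",
                blobs=(Blob(center_mm=(13.5, 0.0, 0.0), radius_mm=12.0),),
                n_contrasts=0,
                sign=-1.0,
                share_latent_with="source",
            ),
        ),
        grid_n=grid_n,
        snr=1.0,
        n_timepoints=n_timepoints,
    )
    scene = generate_ground_truth(config, rng_seed=seed)
    pos = run_phantom_fcnm(scene, n_subjects=n_subjects, seed=seed + 1,
                           radii_mm=(4.0,), thresholds=(0.6,), alpha=alpha,
                           tail="positive")
    neg = run_phantom_fcnm(scene, n_subjects=n_subjects, seed=seed + 1,
                           radii_mm=(4.0,), thresholds=(0.6,), alpha=alpha,
                           tail="negative")
    return {
        "scene": scene,
        "positive_network": pos["networks"][(4.0, 0.6)],
        "negative_network": neg["networks"][(4.0, 0.6)],
        "dice_positive_vs_source": dice_coefficient(
            pos["networks"][(4.0, 0.6)], scene.networks["source"]
        ),
        "dice_negative_vs_antiphase": dice_coefficient(
            neg["networks"][(4.0, 0.6)], scene.networks["antiphase"]
        ),
    }
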