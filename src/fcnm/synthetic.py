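"""Phantom resting-state datasets with planted network structure.

The generator builds the statistical world the connectivity analysis
assumes: a small MNI-like grid carrying one or more pairwise-disjoint
"planted" networks, each driven by its own smooth latent time course that
every member voxel shares (scaled by the signal-to-noise ratio) on top of
unit-variance i.i.d. Gaussian voxel noise. Study foci are sampled inside
the planted networks, and rigid-body motion traces with optional spike
volumes exercise the motion-QC and spike-regressor paths.

Under this model the Pearson correlation between two voxels of the same
network has the closed form r = snr^2 / (1 + snr^2), which the test suite
uses as an analytic oracle.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import BinaryMask, BOLDSeries, VolumeGrid

__all__ = [
    "Blob",
    "NetworkSpec",
    "SceneConfig",
    "PhantomScene",
    "generate_ground_truth",
    "simulate_subject_bold",
    "simulate_null_bold",
    "simulate_motion",
    "write_phantom_dataset",
]

#: latent time courses contain no power above this frequency (Hz), so the
#: 0.01-0.1 Hz band-pass of the preprocessing stage leaves planted signal
#: largely intact
LATENT_LOWPASS_HZ = 0.1


@dataclasses.dataclass(frozen=True)
class Blob:
    """A sphere in world mm defining part of a planted network."""

    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("blob radius must be positive")
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Ground-truth network: blobs, its contrasts, and its latent coupling.

    ``sign`` scales the latent with +1/-1 so a region can fluctuate in
    antiphase; ``share_latent_with`` makes this network reuse another
    network's latent series (e.g. a sign-inverted copy of it), which is how
    phantoms for the negative-connectivity variant are built.
    """

    name: str
    blobs: tuple[Blob, ...]
    n_contrasts: int = 1
    foci_per_contrast: int = 3
    sign: float = 1.0
    share_latent_with: str | None = None

    def __post_init__(self) -> None:
        if len(self.blobs) == 0:
            raise ValueError(f"network {self.name!r} needs at least one blob")
        if self.n_contrasts < 0 or self.foci_per_contrast < 1:
            raise ValueError("invalid contrast/foci counts")
        object.__setattr__(self, "blobs", tuple(self.blobs))


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Parameters of a phantom scene."""

    networks: tuple[NetworkSpec, ...]
    grid_n: int = 30
    voxel_mm: float = 3.0
    snr: float = 1.0
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    n_motion_spikes: int = 2
    motion_step_mm: float = 0.02
    motion_step_rad: float = 0.0002

    def __post_init__(self) -> None:
        if len(self.networks) == 0:
            raise ValueError("a scene needs at least one network")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.n_timepoints < 60:
            raise ValueError("n_timepoints must be >= 60")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "networks", tuple(self.networks))


@dataclasses.dataclass
class PhantomScene:
    """Ground truth of a phantom: grid, planted networks, and sampled foci."""

    grid: VolumeGrid
    networks: dict[str, BinaryMask]
    foci: pd.DataFrame
    snr: float
    n_timepoints: int
    tr_seconds: float
    config: SceneConfig

    def network_labels(self) -> np.ndarray:
        """Integer label volume: 0 background, 1.. in network order."""
        labels = np.zeros(self.grid.shape, dtype=np.int16)
        for i, mask in enumerate(self.networks.values(), start=1):
            labels[mask.data] = i
        return labels


def _blob_mask(grid: VolumeGrid, blobs: Sequence[Blob]) -> np.ndarray:
    centers = grid.voxel_centers()
    mask = np.zeros(grid.n_voxels, dtype=bool)
    for blob in blobs:
        d2 = ((centers - np.asarray(blob.center_mm)) ** 2).sum(axis=1)
        mask |= d2 <= blob.radius_mm**2 + 1e-9
    return mask.reshape(grid.shape)


def generate_ground_truth(config: SceneConfig, rng_seed: int) -> PhantomScene:
    """Build a phantom scene: masks, then foci sampled inside each network.

    Blobs belonging to different networks must not intersect; a colliding
    pair is rejected by name before any voxelization, and the voxelized
    masks are additionally checked to be pairwise disjoint. Deterministic
    for a fixed seed.
    """
    for i, a in enumerate(config.networks):
        for b in config.networks[i + 1 :]:
            for ba in a.blobs:
                for bb in b.blobs:
                    gap = np.linalg.norm(
                        np.asarray(ba.center_mm) - np.asarray(bb.center_mm)
                    )
                    if gap < ba.radius_mm + bb.radius_mm:
                        raise ValueError(
                            f"blob specifications of networks {a.name!r} and "
                            f"{b.name!r} overlap (centers {gap:.1f} mm apart, "
                            f"radii {ba.radius_mm:g}+{bb.radius_mm:g} mm)"
                        )
    for spec in config.networks:
        if spec.share_latent_with is not None and spec.share_latent_with not in {
            s.name for s in config.networks
        }:
            raise ValueError(
                f"network {spec.name!r} shares a latent with unknown network "
                f"{spec.share_latent_with!r}"
            )

    grid = VolumeGrid.isotropic(config.grid_n, config.voxel_mm)
    networks: dict[str, BinaryMask] = {}
    for spec in config.networks:
        data = _blob_mask(grid, spec.blobs)
        if not data.any():
            raise ValueError(f"network {spec.name!r} captures no voxel centers")
        networks[spec.name] = BinaryMask(grid, data)
    names = list(networks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (networks[a].data & networks[b].data).any():
                raise ValueError(f"voxelized networks {a!r} and {b!r} overlap")

    rng = np.random.default_rng(rng_seed)
    centers = grid.voxel_centers()
    rows = []
    for spec in config.networks:
        member_idx = networks[spec.name].flat_indices()
        for c in range(spec.n_contrasts):
            replace = len(member_idx) < spec.foci_per_contrast
            chosen = rng.choice(member_idx, size=spec.foci_per_contrast, replace=replace)
            for k, vi in enumerate(chosen):
                x, y, z = centers[vi]
                rows.append(
                    {
                        "study_id": f"{spec.name}_s{c:02d}",
                        "contrast_id": f"{spec.name}_c{c:02d}",
                        "x": float(x),
                        "y": float(y),
                        "z": float(z),
                        "space": "MNI",
                    }
                )
    foci = pd.DataFrame(rows, columns=["study_id", "contrast_id", "x", "y", "z", "space"])
    return PhantomScene(
        grid=grid,
        networks=networks,
        foci=foci,
        snr=config.snr,
        n_timepoints=config.n_timepoints,
        tr_seconds=config.tr_seconds,
        config=config,
    )


def _smooth_latent(rng: np.random.Generator, n_timepoints: int, tr_seconds: float) -> np.ndarray:
    """Unit-variance Gaussian series low-pass filtered below LATENT_LOWPASS_HZ."""
    white = rng.standard_normal(n_timepoints)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    spectrum = np.fft.rfft(white)
    spectrum[freqs > LATENT_LOWPASS_HZ] = 0.0
    spectrum[0] = 0.0  # mean-free
    latent = np.fft.irfft(spectrum, n=n_timepoints)
    sd = latent.std()
    if sd == 0:  # pathological but possible at tiny T
        return latent
    return latent / sd


def simulate_motion(
    rng: np.random.Generator,
    n_timepoints: int,
    n_spikes: int = 2,
    step_mm: float = 0.02,
    step_rad: float = 0.0002,
    spike_mm: float = 1.0,
) -> np.ndarray:
    """Slow Gaussian random-walk motion with deterministic-FD spike steps.

    Spikes are 1-mm step displacements along x at randomly chosen volumes
    (alternating sign so positions stay within the 2-mm QC bound), which
    guarantees FD > 0.5 mm at those volumes.
    """
    steps = np.hstack(
        [
            rng.normal(0.0, step_mm, size=(n_timepoints, 3)),
            rng.normal(0.0, step_rad, size=(n_timepoints, 3)),
        ]
    )
    steps[0] = 0.0
    if n_spikes > 0:
        spike_at = rng.choice(np.arange(1, n_timepoints), size=min(n_spikes, n_timepoints - 1),
                              replace=False)
        for k, t in enumerate(np.sort(spike_at)):
            steps[t, 0] += spike_mm * (1.0 if k % 2 == 0 else -1.0)
    return np.cumsum(steps, axis=0)


def simulate_subject_bold(
    scene: PhantomScene, subject_seed: int
) -> tuple[BOLDSeries, np.ndarray]:
    """One subject's 4-D series and (T, 6) motion trace.

    Every voxel gets unit-variance Gaussian noise; voxels of a planted
    network additionally receive ``sign * snr *`` that network's latent
    series. Latents are drawn per subject (shared across that subject's
    member voxels), so different subject seeds give independent
    realizations over identical planted support.
    """
    rng = np.random.default_rng(subject_seed)
    cfg = scene.config
    latents: dict[str, np.ndarray] = {}
    for spec in cfg.networks:  # fixed order => deterministic draws
        if spec.share_latent_with is None:
            latents[spec.name] = _smooth_latent(rng, scene.n_timepoints, scene.tr_seconds)
    for spec in cfg.networks:
        if spec.share_latent_with is not None:
            latents[spec.name] = latents[spec.share_latent_with]

    motion = simulate_motion(
        rng,
        scene.n_timepoints,
        n_spikes=cfg.n_motion_spikes,
        step_mm=cfg.motion_step_mm,
        step_rad=cfg.motion_step_rad,
    )

    data = rng.standard_normal(scene.grid.shape + (scene.n_timepoints,)).astype(np.float32)
    for spec in cfg.networks:
        signal = (spec.sign * scene.snr * latents[spec.name]).astype(np.float32)
        data[scene.networks[spec.name].data] += signal
    return BOLDSeries(scene.grid, data, scene.tr_seconds), motion


def simulate_null_bold(
    grid: VolumeGrid, n_timepoints: int, rng_seed: int, tr_seconds: float = 2.0
) -> BOLDSeries:
    """Pure-noise series: independent standard Gaussians at every voxel."""
    if n_timepoints < 60:
        raise ValueError("n_timepoints must be >= 60")
    rng = np.random.default_rng(rng_seed)
    data = rng.standard_normal(grid.shape + (n_timepoints,)).astype(np.float32)
    return BOLDSeries(grid, data, tr_seconds)


def write_phantom_dataset(
    scene: PhantomScene,
    out_dir: str | Path,
    n_subjects: int,
    base_seed: int,
) -> pd.DataFrame:
    """Serialize a phantom dataset: per-subject BOLD NIfTI + motion text,
    the foci TSV, the ground-truth label volume with its JSON sidecar, and
    a subject roster TSV. Returns the roster."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import nibabel as nib

    rng = np.random.default_rng(base_seed)
    subject_seeds = rng.integers(0, 2**31, size=n_subjects)
    rows = []
    for i, sseed in enumerate(subject_seeds):
        sid = f"sub-{i:03d}"
        bold, motion = simulate_subject_bold(scene, int(sseed))
        bold_path = out / f"{sid}_bold.nii.gz"
        motion_path = out / f"{sid}_motion.txt"
        nib.save(bold.to_img(), str(bold_path))
        np.savetxt(motion_path, motion, fmt="%.8f")
        rows.append({"subject_id": sid, "bold": bold_path.name, "motion": motion_path.name})

    scene.foci.to_csv(out / "foci.tsv", sep="\t", index=False)
    nib.save(scene.grid.to_img(scene.network_labels(), dtype=np.int16), str(out / "truth_labels.nii.gz"))
    sidecar = {
        "networks": {name: i for i, name in enumerate(scene.networks, start=1)},
        "snr": scene.snr,
        "n_timepoints": scene.n_timepoints,
        "tr_seconds": scene.tr_seconds,
        "base_seed": int(base_seed),
        "subject_seeds": [int(s) for s in subject_seeds],
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
    roster = pd.DataFrame(rows)
    roster.to_csv(out / "subjects.tsv", sep="\t", index=False)
    return roster
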