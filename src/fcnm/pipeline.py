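"""File-based orchestration of the full coordinate-to-network pipeline.

``run_fcnm`` takes a validated :class:`RunConfig` and executes every stage
in order — parse coordinates, build contrast seeds, preprocess each
subject, compute seed FC maps, group one-sample t-tests, voxel-level FWE
thresholding, probability overlay, final network thresholding, and
(optionally) canonical-atlas overlap — writing every intermediate product
and a JSON manifest with parameters, per-stage counts and output checksums.
Reruns with identical inputs, config and seed reproduce the outputs
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .coords import SeedSpec, build_contrast_seed, foci_to_mni, group_by_contrast, parse_coordinate_table
from .fc import seed_fc_map
from .grid import BinaryMask, BOLDSeries, VolumeGrid
from .group import fwe_threshold_mask, one_sample_t, overlay_probability, threshold_probability
from .overlap import CanonicalAtlas, overlap_proportion, resample_atlas
from .preprocess import NuisanceSpec, preprocess_bold

__all__ = ["RunConfig", "run_fcnm"]


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Defaults mirror the standard analysis: 4-mm seed spheres, alpha 0.05
    voxel-level FWE (Bonferroni), strict 60% probability threshold,
    positive connectivity only, 0.01-0.1 Hz band, 6-mm FWHM smoothing,
    0.5-mm FD spike threshold.
    """

    coordinates: str
    subjects: str
    out_dir: str
    brain_mask: str | None = None
    wm_mask: str | None = None
    csf_mask: str | None = None
    atlas_labels: str | None = None
    atlas_names: str | None = None
    seed_radius_mm: float = 4.0
    alpha: float = 0.05
    fwe_method: str = "bonferroni"
    probability_thresholds: tuple[float, ...] = (0.6,)
    tail: str = "positive"
    tr_seconds: float | None = None
    fd_spike_threshold_mm: float = 0.5
    include_global: bool = True
    include_wm: bool = True
    include_csf: bool = True
    band_hz: tuple[float, float] = (0.01, 0.1)
    smoothing_fwhm_mm: float = 6.0
    drop_initial: int = 0
    rng_seed: int = 0
    save_intermediates: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "band_hz" in raw:
            raw["band_hz"] = tuple(raw["band_hz"])
        if "probability_thresholds" in raw:
            raw["probability_thresholds"] = tuple(raw["probability_thresholds"])
        return cls(**raw)

    def nuisance_spec(self) -> NuisanceSpec:
        return NuisanceSpec(
            fd_spike_threshold_mm=self.fd_spike_threshold_mm,
            include_global=self.include_global,
            include_wm=self.include_wm,
            include_csf=self.include_csf,
            band_hz=self.band_hz,
            smoothing_fwhm_mm=self.smoothing_fwhm_mm,
            drop_initial=self.drop_initial,
        )

    def validate(self) -> None:
        """Fail fast, before any computation, on missing inputs or bad ranges."""
        for name in ("coordinates", "subjects", "brain_mask", "wm_mask", "csf_mask",
                     "atlas_labels", "atlas_names"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {value}")
        if (self.atlas_labels is None) != (self.atlas_names is None):
            raise ValueError("atlas_labels and atlas_names must be given together")
        SeedSpec(radius_mm=self.seed_radius_mm)  # range check
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        for thr in self.probability_thresholds:
            if not 0 < thr < 1:
                raise ValueError(f"probability threshold must be in (0, 1), got {thr}")
        if self.tail not in ("positive", "negative"):
            raise ValueError(f"tail must be positive or negative, got {self.tail!r}")
        if self.fwe_method not in ("bonferroni", "permutation"):
            raise ValueError(f"unknown fwe_method {self.fwe_method!r}")
        self.nuisance_spec()  # range checks


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _load_mask(path: str | None, grid: VolumeGrid | None = None) -> BinaryMask | None:
    if path is None:
        return None
    mask = BinaryMask.from_img(nib.load(str(path)))
    if grid is not None and not mask.grid.matches(grid):
        raise ValueError(f"mask {path} is not on the analysis grid")
    return mask


def run_fcnm(config: RunConfig) -> dict:
    """Execute all pipeline stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nuisance = config.nuisance_spec()

    # ---- inputs ---------------------------------------------------------
    roster = pd.read_csv(config.subjects, sep="\t", dtype=str)
    if "subject_id" not in roster.columns or "bold" not in roster.columns:
        raise ValueError("subject roster needs 'subject_id' and 'bold' columns")
    roster_dir = Path(config.subjects).parent

    records = foci_to_mni(parse_coordinate_table(config.coordinates))
    contrasts = group_by_contrast(records)
    if not contrasts:
        raise ValueError(f"no foci found in {config.coordinates}")

    first_img = nib.load(str(roster_dir / roster.iloc[0]["bold"]))
    grid = VolumeGrid.from_img(first_img)
    brain = _load_mask(config.brain_mask, grid) or BinaryMask.full(grid)
    tissue = {}
    if config.include_global:
        tissue["global"] = brain
    wm = _load_mask(config.wm_mask, grid)
    csf = _load_mask(config.csf_mask, grid)
    if wm is not None:
        tissue["wm"] = wm
    if csf is not None:
        tissue["csf"] = csf

    # ---- stage 1: contrast seeds ---------------------------------------
    spec = SeedSpec(radius_mm=config.seed_radius_mm)
    seeds: dict[tuple[str, str, str], BinaryMask] = {}
    for key, foci in contrasts.items():
        direction, study, contrast = key
        seed = build_contrast_seed(foci, spec, grid)
        seed = seed & brain if config.brain_mask else seed
        if seed.is_empty:
            raise ValueError(f"seed of {study}/{contrast} has no voxels inside the brain mask")
        seeds[key] = seed
        if config.save_intermediates:
            nib.save(seed.to_img(), str(out / f"{direction}_{study}_{contrast}_seed.nii.gz"))

    # ---- stage 2: subject FC maps --------------------------------------
    z_maps = {key: [] for key in seeds}
    excluded: list[str] = []
    for _, row in roster.iterrows():
        sid = row["subject_id"]
        bold = BOLDSeries.from_img(
            nib.load(str(roster_dir / row["bold"])), tr_seconds=config.tr_seconds
        )
        if not bold.grid.matches(grid):
            raise ValueError(f"subject {sid}: BOLD grid differs from the analysis grid")
        motion = None
        if "motion" in roster.columns and isinstance(row.get("motion"), str):
            motion = np.loadtxt(roster_dir / row["motion"])
        clean, qc = preprocess_bold(bold, motion, nuisance, masks=tissue)
        if qc is not None and not qc.passed:
            excluded.append(sid)
            continue
        for key, seed in seeds.items():
            direction, study, contrast = key
            fcmap = seed_fc_map(clean, seed, brain, subject_id=sid, contrast_id=contrast)
            fcmap.z = fcmap.z.astype(np.float32)
            z_maps[key].append(fcmap)
            if config.save_intermediates:
                nib.save(fcmap.to_img(), str(out / f"{sid}_{direction}_{contrast}_zmap.nii.gz"))

    # ---- stage 3-4: group t-tests, FWE, binarize -----------------------
    rng = np.random.default_rng(config.rng_seed)
    fwe_masks: dict[tuple[str, str, str], BinaryMask] = {}
    surviving_counts: dict[str, int] = {}
    for key, maps in z_maps.items():
        direction, study, contrast = key
        stat = one_sample_t(maps, contrast_id=contrast)
        mask = fwe_threshold_mask(
            stat, alpha=config.alpha, method=config.fwe_method, tail=config.tail,
            z_maps=maps if config.fwe_method == "permutation" else None,
            seed=int(rng.integers(0, 2**31)),
        )
        fwe_masks[key] = mask
        surviving_counts[f"{direction}_{study}_{contrast}"] = mask.n_voxels
        if config.save_intermediates:
            nib.save(stat.to_img(), str(out / f"{direction}_{study}_{contrast}_tmap.nii.gz"))
            nib.save(mask.to_img(), str(out / f"{direction}_{study}_{contrast}_fwe.nii.gz"))

    # ---- stage 5: probability maps and networks ------------------------
    directions = sorted({key[0] for key in fwe_masks})
    network_checksums: dict[str, str] = {}
    network_voxels: dict[str, int] = {}
    networks: dict[tuple[str, float], BinaryMask] = {}
    for direction in directions:
        masks = [fwe_masks[k] for k in fwe_masks if k[0] == direction]
        pmap = overlay_probability(masks, direction=direction)
        nib.save(pmap.to_img(), str(out / f"{direction}_probability.nii.gz"))
        for thr in config.probability_thresholds:
            net = threshold_probability(pmap, thr)
            networks[(direction, thr)] = net
            tag = f"{direction}_network_thr{int(round(thr * 100))}"
            nib.save(net.to_img(), str(out / f"{tag}.nii.gz"))
            network_checksums[tag] = _sha256(net.data)
            network_voxels[tag] = net.n_voxels

    # ---- stage 6: canonical atlas overlap ------------------------------
    overlap_files: list[str] = []
    if config.atlas_labels is not None:
        atlas = resample_atlas(
            CanonicalAtlas.from_files(config.atlas_labels, config.atlas_names), grid
        )
        for (direction, thr), net in networks.items():
            tag = f"{direction}_network_thr{int(round(thr * 100))}"
            report = overlap_proportion(net, atlas, network_name=tag)
            report.to_frame().to_csv(out / f"{tag}_overlap.tsv", sep="\t", index=False)
            (out / f"{tag}_overlap.json").write_text(report.to_json())
            overlap_files.append(f"{tag}_overlap.json")

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "grid": {"shape": list(grid.shape), "affine": grid.affine.tolist()},
        "n_subjects": int(len(roster)),
        "n_subjects_used": int(len(roster) - len(excluded)),
        "excluded_subjects": excluded,
        "n_contrasts": {
            d: sum(1 for k in seeds if k[0] == d) for d in directions
        },
        "surviving_voxels": surviving_counts,
        "network_voxels": network_voxels,
        "network_checksums": network_checksums,
        "overlap_reports": overlap_files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
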