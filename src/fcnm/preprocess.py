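"""Formula-level resting-state preprocessing on already-normalized volumes.

Covers the steps that act on a normalized 4-D series: motion quality control
(2 mm / 2 deg exclusion), Power's framewise displacement, nuisance design
construction (linear drift, Friston-24 motion expansion, FD spike
regressors, tissue mean signals), least-squares residualization, an ideal
rectangular band-pass filter, and separable Gaussian smoothing. Spatial
normalization itself (realignment, warping) is assumed done upstream.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, BOLDSeries, VolumeGrid

__all__ = [
    "NuisanceSpec",
    "QCResult",
    "framewise_displacement",
    "motion_qc",
    "friston24",
    "build_nuisance_design",
    "bandpass",
    "regress_and_filter",
    "smooth_gaussian",
    "preprocess_bold",
]

#: sigma = FWHM * this factor
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclasses.dataclass(frozen=True)
class NuisanceSpec:
    """Nuisance / filtering configuration.

    The regressor set is fixed in kind (intercept, linear drift, Friston-24
    motion expansion, one indicator per FD-spike volume, tissue means); the
    booleans only toggle the tissue means. Band edges are in Hz and must sit
    below the Nyquist frequency of the series being filtered.
    """

    fd_spike_threshold_mm: float = 0.5
    include_global: bool = True
    include_wm: bool = True
    include_csf: bool = True
    band_hz: tuple[float, float] = (0.01, 0.1)
    smoothing_fwhm_mm: float = 6.0
    drop_initial: int = 0

    def __post_init__(self) -> None:
        low, high = self.band_hz
        if not 0 < low < high:
            raise ValueError(f"band edges must satisfy 0 < low < high, got {self.band_hz}")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        if self.drop_initial < 0:
            raise ValueError("drop_initial must be >= 0")

    def validate_for_tr(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if self.band_hz[1] >= nyquist:
            raise ValueError(
                f"band high edge {self.band_hz[1]} Hz is at or above Nyquist "
                f"{nyquist:g} Hz for TR={tr_seconds}s"
            )


@dataclasses.dataclass(frozen=True)
class QCResult:
    """Motion quality control summary; passes iff translation < 2 mm and
    rotation < 2 degrees throughout the run."""

    max_translation_mm: float
    max_rotation_deg: float
    mean_fd_mm: float
    passed: bool


def framewise_displacement(motion: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Power's framewise displacement of a (T, 6) rigid-body motion trace.

    FD(t) = sum of absolute volume-to-volume translation changes (mm) plus
    the absolute rotation changes (radians) converted to arc length on a
    sphere of ``rotation_radius_mm``. FD of the first volume is 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must be (T, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    delta = np.abs(np.diff(motion, axis=0))
    fd = delta[:, :3].sum(axis=1) + rotation_radius_mm * delta[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def motion_qc(motion: np.ndarray, rotation_radius_mm: float = 50.0) -> QCResult:
    """Apply the 2 mm / 2 degree exclusion rule to a motion trace."""
    motion = np.asarray(motion, dtype=float)
    if motion.size == 0:
        raise ValueError("empty motion trace")
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must be (T, 6), got {motion.shape}")
    max_trans = float(np.abs(motion[:, :3]).max())
    max_rot_deg = float(np.degrees(np.abs(motion[:, 3:]).max()))
    mean_fd = float(framewise_displacement(motion, rotation_radius_mm).mean()) if motion.shape[0] >= 2 else 0.0
    return QCResult(
        max_translation_mm=max_trans,
        max_rotation_deg=max_rot_deg,
        mean_fd_mm=mean_fd,
        passed=(max_trans < 2.0 and max_rot_deg < 2.0),
    )


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston-24 motion expansion: [R, R(t-1), R^2, R(t-1)^2], (T, 24).

    Lagged terms are zero-padded at t = 0.
    """
    R = np.asarray(motion, dtype=float)
    R_lag = np.vstack([np.zeros((1, 6)), R[:-1]])
    return np.hstack([R, R_lag, R**2, R_lag**2])


def _tissue_mean(bold: BOLDSeries, mask: BinaryMask) -> np.ndarray:
    if not bold.grid.matches(mask.grid):
        raise ValueError("tissue mask grid does not match BOLD grid")
    if mask.is_empty:
        raise ValueError("tissue mask is empty")
    return bold.as_matrix()[mask.flat_indices()].mean(axis=0)


def build_nuisance_design(
    bold: BOLDSeries,
    motion: np.ndarray | None,
    spec: NuisanceSpec,
    masks: dict[str, BinaryMask] | None = None,
    fd: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the (T, k) nuisance design matrix and its column names.

    Column order is deterministic: intercept, linear drift, 24 motion terms,
    one spike indicator per volume with FD above threshold, then the enabled
    tissue means (global, white matter, CSF). All-zero columns are dropped
    and exact duplicate columns collapsed (with a warning), so a zero motion
    trace or coincident spikes cannot make the design rank deficient.
    """
    T = bold.n_timepoints
    masks = masks or {}
    cols: list[np.ndarray] = [np.ones(T)]
    names: list[str] = ["intercept"]

    drift = np.linspace(-0.5, 0.5, T)
    cols.append(drift)
    names.append("drift_linear")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != T:
            raise ValueError(
                f"motion trace has {motion.shape[0]} rows but BOLD has {T} volumes"
            )
        F = friston24(motion)
        cols.extend(F.T)
        names.extend([f"motion{i:02d}" for i in range(24)])
        if fd is None:
            fd = framewise_displacement(motion)
    if fd is not None:
        fd = np.asarray(fd, dtype=float)
        if fd.shape[0] != T:
            raise ValueError(f"FD has {fd.shape[0]} values but BOLD has {T} volumes")
        for t in np.flatnonzero(fd > spec.fd_spike_threshold_mm):
            ind = np.zeros(T)
            ind[t] = 1.0
            cols.append(ind)
            names.append(f"spike_t{int(t):04d}")

    for key, enabled in (
        ("global", spec.include_global),
        ("wm", spec.include_wm),
        ("csf", spec.include_csf),
    ):
        if not enabled:
            continue
        if key not in masks:
            raise ValueError(
                f"{key} signal regression requested but no {key!r} mask supplied"
            )
        cols.append(_tissue_mean(bold, masks[key]))
        names.append(f"{key}_signal")

    X = np.column_stack(cols)

    # drop all-zero columns, collapse exact duplicates
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if not col.any():
            dropped.append(names[j])
            continue
        if any(np.array_equal(col, X[:, i]) for i in keep):
            dropped.append(names[j])
            continue
        keep.append(j)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} degenerate nuisance column(s): {dropped}",
            stacklevel=2,
        )
    X = X[:, keep]
    names = [names[j] for j in keep]

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("nuisance design is rank deficient after duplicate collapse")
    return X, names


def bandpass(series: np.ndarray, tr_seconds: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Ideal rectangular band-pass along axis 0 of a (T, ...) array.

    Frequency bins with low <= f <= high (inclusive at both edges) are kept,
    everything else — including the DC bin — is zeroed. Being a projection in
    the Fourier basis, the filter is exactly idempotent.
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spectrum = np.fft.rfft(series, axis=0)
    spectrum[~keep] = 0.0
    return np.fft.irfft(spectrum, n=T, axis=0)


def regress_and_filter(
    bold: BOLDSeries,
    design: np.ndarray | None,
    spec: NuisanceSpec,
) -> BOLDSeries:
    """Residualize each voxel series against the design, then band-pass.

    Regression precedes filtering. The residuals are exact least-squares
    residuals, orthogonal to every design column; the subsequent filter is
    the ideal band-pass of :func:`bandpass` with the spec's band edges.
    """
    spec.validate_for_tr(bold.tr_seconds)
    X = bold.as_matrix().T.astype(float)  # (T, V)
    if design is not None and design.size:
        D = np.asarray(design, dtype=float)
        if D.shape[0] != X.shape[0]:
            raise ValueError("design rows do not match BOLD volumes")
        beta, *_ = np.linalg.lstsq(D, X, rcond=None)
        X = X - D @ beta
    X = bandpass(X, bold.tr_seconds, *spec.band_hz)
    return BOLDSeries(bold.grid, X.T.reshape(bold.data.shape), bold.tr_seconds)


def smooth_gaussian(data: np.ndarray, fwhm_mm: float, grid: VolumeGrid) -> np.ndarray:
    """Separable Gaussian smoothing of a 3-D volume or 4-D series.

    sigma per axis is fwhm/(2*sqrt(2 ln 2)) in mm converted to voxels via
    the grid's voxel sizes. Replicate (nearest) padding preserves constant
    images exactly. fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    data = np.asarray(data, dtype=float)
    if data.shape[:3] != grid.shape:
        raise ValueError(f"data shape {data.shape} does not match grid {grid.shape}")
    if fwhm_mm == 0:
        return data.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_sizes_mm
    sigma = tuple(sigma_vox) + ((0.0,) if data.ndim == 4 else ())
    return ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")


def preprocess_bold(
    bold: BOLDSeries,
    motion: np.ndarray | None,
    spec: NuisanceSpec,
    masks: dict[str, BinaryMask] | None = None,
) -> tuple[BOLDSeries, QCResult | None]:
    """Full lite pipeline: drop initial volumes, QC, nuisance regression,
    band-pass, smoothing. Returns the cleaned series and the QC result
    (None when no motion trace was supplied). The caller decides whether a
    failed QC excludes the subject."""
    if spec.drop_initial:
        if spec.drop_initial >= bold.n_timepoints:
            raise ValueError("drop_initial leaves no volumes")
        bold = BOLDSeries(bold.grid, bold.data[..., spec.drop_initial :], bold.tr_seconds)
        if motion is not None:
            motion = np.asarray(motion)[spec.drop_initial :]
    qc = motion_qc(motion) if motion is not None else None
    design, _ = build_nuisance_design(bold, motion, spec, masks=masks)
    clean = regress_and_filter(bold, design, spec)
    if spec.smoothing_fwhm_mm > 0:
        smoothed = smooth_gaussian(clean.data, spec.smoothing_fwhm_mm, clean.grid)
        clean = BOLDSeries(clean.grid, smoothed, clean.tr_seconds)
    return clean, qc
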