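"""ROI-level temporal preprocessing and motion screening.

Counterparts of the standard resting-state chain, applied to region-mean
time series: initial-volume discard, linear detrend + zero-phase
band-pass (0.01-0.08 Hz), nuisance regression, Power-style framewise
displacement, and the absolute-motion exclusion rule (> 1.0 mm
translation or > 1.0 deg rotation in any direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

DEFAULT_N_DISCARD = 10
DEFAULT_BAND_HZ = (0.01, 0.08)
DEFAULT_SPHERE_RADIUS_MM = 50.0
DEFAULT_MAX_TRANSLATION_MM = 1.0
DEFAULT_MAX_ROTATION_DEG = 1.0


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's timepoints x regions signal matrix."""

    data: np.ndarray
    region_labels: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 2:
            raise ValueError("data must be a 2-D timepoints x regions matrix")
        if d.shape[0] < 2 or d.shape[1] < 2:
            raise ValueError("need at least 2 timepoints and 2 regions")
        if not np.all(np.isfinite(d)):
            raise ValueError("data contains non-finite values")
        if len(self.region_labels) != d.shape[1]:
            raise ValueError("region_labels length must match number of columns")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region_labels must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(
            data=data, region_labels=list(self.region_labels), tr_seconds=self.tr_seconds
        )


@dataclass(frozen=True)
class MotionParams:
    """Realignment parameters: 3 translations (mm) then 3 rotations (degrees)."""

    data: np.ndarray
    fd_series: np.ndarray | None = field(default=None)
    mean_fd: float | None = field(default=None)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 2 or d.shape[1] != 6:
            raise ValueError("motion parameters must have exactly 6 columns")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.data[:, 3:]


def discard_initial_volumes(
    ts: RoiTimeSeries, n_discard: int = DEFAULT_N_DISCARD
) -> RoiTimeSeries:
    """Drop the first ``n_discard`` frames (signal-equilibration volumes)."""
    if not 0 <= n_discard < ts.n_timepoints:
        raise ValueError(
            f"n_discard must be in [0, {ts.n_timepoints}), got {n_discard}"
        )
    if n_discard == 0:
        return ts
    return ts.with_data(ts.data[n_discard:])


def detrend_and_bandpass(
    ts: RoiTimeSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> RoiTimeSeries:
    """Remove each region's linear trend, then apply a zero-phase band-pass.

    The filter is a 4th-order Butterworth run forward and backward
    (``sosfiltfilt``), so the pass band is applied twice with no phase
    distortion.
    """
    nyq = ts.nyquist_hz
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band must satisfy 0 < low < high < Nyquist ({nyq:.4g} Hz); "
            f"got ({low_hz}, {high_hz})"
        )
    detrended = _signal.detrend(ts.data, axis=0, type="linear")
    sos = _signal.butter(
        4, [low_hz, high_hz], btype="band", fs=1.0 / ts.tr_seconds, output="sos"
    )
    filtered = _signal.sosfiltfilt(sos, detrended, axis=0)
    return ts.with_data(filtered)


def nuisance_regression(ts: RoiTimeSeries, confounds: np.ndarray) -> RoiTimeSeries:
    """Residualize every region on [intercept | confounds] by least squares.

    Rank-deficient confound matrices are tolerated (least-norm solution)
    with a warning.  The residuals are orthogonal to every confound
    column.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"confounds have {confounds.shape[0]} rows, expected {ts.n_timepoints}"
        )
    if confounds.shape[1] < 1:
        raise ValueError("need at least one confound column")
    design = np.column_stack([np.ones(ts.n_timepoints), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "confound matrix is rank-deficient; using least-norm solution",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return ts.with_data(ts.data - design @ beta)


def global_signal(ts: RoiTimeSeries) -> np.ndarray:
    """ROI-level surrogate of the global signal: the row mean across regions."""
    return ts.data.mean(axis=1)


def framewise_displacement(
    mp: MotionParams, sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM
) -> MotionParams:
    """Power-style framewise displacement.

    FD(t) = sum of absolute frame-to-frame translation changes plus the
    rotation changes converted to arc length on a sphere of
    ``sphere_radius_mm`` (default 50 mm).  The series is padded with a
    leading 0 so it aligns with the frames.
    """
    if mp.n_frames < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d_trans = np.abs(np.diff(mp.translations_mm, axis=0)).sum(axis=1)
    d_rot_rad = np.deg2rad(np.abs(np.diff(mp.rotations_deg, axis=0))).sum(axis=1)
    fd = d_trans + sphere_radius_mm * d_rot_rad
    fd = np.concatenate([[0.0], fd])
    return MotionParams(data=mp.data, fd_series=fd, mean_fd=float(fd[1:].mean()))


def motion_exclusion(
    mp: MotionParams,
    max_translation_mm: float = DEFAULT_MAX_TRANSLATION_MM,
    max_rotation_deg: float = DEFAULT_MAX_ROTATION_DEG,
) -> bool:
    """True (exclude the subject) iff any frame's absolute realignment
    parameter exceeds the translation or rotation limit (strict)."""
    return bool(
        np.any(np.abs(mp.translations_mm) > max_translation_mm)
        or np.any(np.abs(mp.rotations_deg) > max_rotation_deg)
    )


def preprocess(
    ts: RoiTimeSeries,
    motion: MotionParams | None = None,
    *,
    n_discard: int = DEFAULT_N_DISCARD,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    regress_global_signal: bool = True,
    extra_confounds: np.ndarray | None = None,
) -> RoiTimeSeries:
    """The standard chain: discard -> detrend+bandpass -> nuisance regression.

    Motion regressors are band-pass filtered with the same band before
    regression so the filtered data are not re-contaminated.  WM/CSF
    surrogates (or any other confounds) can be supplied via
    ``extra_confounds`` (full-length; trimmed along with the data).
    """
    out = discard_initial_volumes(ts, n_discard)
    out = detrend_and_bandpass(out, low_hz, high_hz)
    confound_cols: list[np.ndarray] = []
    if motion is not None:
        motion_trimmed = motion.data[n_discard:]
        sos = _signal.butter(
            4, [low_hz, high_hz], btype="band", fs=1.0 / ts.tr_seconds, output="sos"
        )
        motion_filtered = _signal.sosfiltfilt(
            sos, _signal.detrend(motion_trimmed, axis=0), axis=0
        )
        confound_cols.append(motion_filtered)
    if regress_global_signal:
        confound_cols.append(global_signal(out)[:, None])
    if extra_confounds is not None:
        confound_cols.append(np.atleast_2d(extra_confounds)[n_discard:])
    if confound_cols:
        out = nuisance_regression(out, np.column_stack(confound_cols))
    return out
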