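"""Resting-state connectome features for the BBS comparator.

A simplified but faithful version of a standard motion-aware resting-state
stream: framewise displacement (FD) from six rigid-body parameters,
subject-level quality screening, linear detrending, CompCor-style nuisance
regression against the top principal components of caller-supplied noise
signals, zero-phase band-pass filtering, scrubbing of high-motion frames,
ROI-pair Pearson correlation and the Fisher r-to-z transform.  The output
feature vector (upper triangle, fixed row-major order) enters the same
subjects-by-features BBS pipeline as the task contrast maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "ConnectomeFeatures",
    "framewise_displacement",
    "qc_exclude",
    "scrub",
    "bandpass",
    "nuisance_regress",
    "connectome",
    "connectome_pipeline",
]

FD_ROTATION_RADIUS_MM = 50.0   # Power convention: rotations on a 50 mm sphere


@dataclass
class ConnectomeFeatures:
    """Fisher-z ROI-pair correlations (upper triangle, row-major)."""

    values: np.ndarray
    n_rois: int
    frames_retained: int

    def __post_init__(self):
        expect = self.n_rois * (self.n_rois - 1) // 2
        if len(self.values) != expect:
            raise ValueError("feature length != R(R-1)/2")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("non-finite connectome features")


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Per-frame head displacement in mm.

    motion is (frames, 6): three translations (mm) then three rotations
    (radians); FD_t = sum |delta translations| + 50mm * sum |delta
    rotations|, with FD of the first frame defined as 0.
    """
    M = np.asarray(motion, dtype=float)
    if M.ndim != 2 or M.shape[1] != 6 or M.shape[0] < 2:
        raise ValueError("motion trace must be (frames >= 2, 6)")
    d = np.abs(np.diff(M, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def qc_exclude(fd: np.ndarray, fd_thresh: float = 0.5,
               max_prop: float = 0.25) -> bool:
    """True when the subject should be dropped: the proportion of frames
    with FD above threshold strictly exceeds ``max_prop``."""
    fd = np.asarray(fd, dtype=float)
    return bool(np.mean(fd > fd_thresh) > max_prop)


def scrub(ts: np.ndarray, fd: np.ndarray, fd_thresh: float = 0.5) -> np.ndarray:
    """Remove frames whose FD exceeds the threshold."""
    ts = np.asarray(ts, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if len(fd) != ts.shape[0]:
        raise ValueError("FD and time series are not aligned")
    keep = fd <= fd_thresh
    if not np.any(keep):
        raise ValueError("scrubbing removed every frame")
    return ts[keep]


def bandpass(ts: np.ndarray, low: float = 0.01, high: float = 0.1,
             tr: float = 0.72, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis."""
    ts = np.asarray(ts, dtype=float)
    if tr <= 0:
        raise ValueError("tr must be positive")
    nyq = 0.5 / tr
    if not 0 < low < high < nyq:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    b, a = sp_signal.butter(order, [low / nyq, high / nyq], btype="band")
    return sp_signal.filtfilt(b, a, ts, axis=0)


def nuisance_regress(ts: np.ndarray, nuisance_signals: np.ndarray,
                     n_components: int = 5) -> np.ndarray:
    """Residualize the time series on a linear trend and the top principal
    components of the supplied noise-tissue signals (CompCor style)."""
    ts = np.asarray(ts, dtype=float)
    N = np.asarray(nuisance_signals, dtype=float)
    if N.shape[0] != ts.shape[0]:
        raise ValueError("nuisance signals and time series are not aligned")
    t = ts.shape[0]
    Nc = N - N.mean(axis=0)
    if n_components > 0 and Nc.shape[1] > 0:
        _, _, Vt = np.linalg.svd(Nc, full_matrices=False)
        comps = Nc @ Vt[: min(n_components, Nc.shape[1])].T
    else:
        comps = np.empty((t, 0))
    design = np.column_stack([np.ones(t), np.linspace(-1, 1, t), comps])
    coef, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ coef


def connectome(ts: np.ndarray) -> ConnectomeFeatures:
    """ROI-pair Pearson correlations, Fisher z, upper triangle row-major."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 retained frames")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance ROI at index "
                         f"{int(np.flatnonzero(sd == 0)[0])}")
    r = np.corrcoef(ts, rowvar=False)
    iu = np.triu_indices(ts.shape[1], k=1)
    vals = r[iu]
    if np.any(np.abs(vals) >= 1.0):
        warnings.warn("perfectly correlated ROI pair clamped before Fisher "
                      "transform", RuntimeWarning, stacklevel=2)
        vals = np.clip(vals, -1 + 1e-7, 1 - 1e-7)
    return ConnectomeFeatures(values=np.arctanh(vals), n_rois=ts.shape[1],
                              frames_retained=ts.shape[0])


def connectome_pipeline(ts: np.ndarray, motion: np.ndarray,
                        nuisance_signals: np.ndarray | None = None,
                        tr: float = 0.72, fd_thresh: float = 0.5,
                        max_prop: float = 0.25,
                        low: float = 0.01, high: float = 0.1
                        ) -> ConnectomeFeatures | None:
    """Full per-subject stream: FD screening, detrend + CompCor nuisance
    regression, band-pass, scrubbing, correlation features.

    Returns None when the subject fails motion QC.  Censored frames are
    dropped after filtering (no interpolation over scrubbed frames).
    """
    fd = framewise_displacement(motion)
    if qc_exclude(fd, fd_thresh, max_prop):
        return None
    if nuisance_signals is None:
        nuisance_signals = np.empty((ts.shape[0], 0))
    clean = nuisance_regress(ts, nuisance_signals)
    filt = bandpass(clean, low=low, high=high, tr=tr)
    kept = scrub(filt, fd, fd_thresh)
    return connectome(kept)
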