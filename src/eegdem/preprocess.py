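"""Preprocessing: linked-ear re-referencing, band-pass filtering, and
high-amplitude burst rejection.

The fixed pipeline order is rereference → bandpass → reject_bursts.  Burst
rejection is a windowed variant of artifact-subspace-reconstruction-style
cleaning: the recording is cut into short windows, a per-channel noise scale
is calibrated on the cleanest half of the data, and any window in which some
channel's standard deviation exceeds ``cutoff`` times its calibrated scale is
removed outright (no subspace reconstruction).  The defaults — cutoff 17 on
0.5 s windows — correspond to a strict clinical-EEG setting.

An external linear projection hook (``apply_component_mask``) lets a
channels×channels matrix computed elsewhere (e.g. an ICA-based artifact
remover) be applied without this package depending on any pretrained labeler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import NamedChannelError, Recording, read_matrix

__all__ = ["CleanResult", "rereference", "bandpass", "reject_bursts",
           "apply_component_mask", "preprocess"]

# MAD → SD for Gaussian data.
_MAD_TO_SD = 1.4826022185056018


@dataclass
class CleanResult:
    recording: Recording
    kept_mask: np.ndarray       # boolean, one entry per window
    dropped_fraction: float


def rereference(rec: Recording) -> Recording:
    """Subtract the A1/A2 mean (linked-ears reference) from every scalp
    channel; the reference channels are dropped from the output."""
    try:
        a1 = rec.get_channel("A1")
        a2 = rec.get_channel("A2")
    except NamedChannelError as exc:
        raise NamedChannelError(
            f"{rec.subject_id}: A1/A2 required for re-referencing") from exc
    ref = 0.5 * (a1 + a2)
    ref_idx = {rec.channel_index("A1"), rec.channel_index("A2")}
    keep = [i for i in range(rec.n_channels) if i not in ref_idx]
    data = rec.data[keep] - ref
    names = [rec.channel_names[i] for i in keep]
    return Recording(rec.subject_id, rec.group, data, rec.fs, names, [])


def bandpass(rec: Recording, low: float = 0.5, high: float = 45.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward–backward), identical
    for every channel.  Default corners 0.5–45 Hz keep the EEG bands of
    interest and exclude 50 Hz line noise."""
    nyq = rec.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"need 0 < low < high < fs/2, got ({low}, {high}) at fs={rec.fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                     output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(rec.subject_id, rec.group, data, rec.fs,
                     list(rec.channel_names), list(rec.reference_names))


def reject_bursts(rec: Recording, cutoff: float = 17.0,
                  window_s: float = 0.5,
                  calibration_fraction: float = 0.5) -> CleanResult:
    """Drop windows containing high-amplitude bursts.

    Per channel, a baseline scale in SD units is estimated as 1.4826 × the
    median absolute deviation of the samples in the calibration windows (the
    ``calibration_fraction`` of windows with the lowest RMS — bursts inflate
    RMS, so the calibration set is burst-free in practice).  A window is
    rejected when any channel's within-window SD exceeds ``cutoff`` × its
    baseline; the kept windows are concatenated in order.
    """
    win = int(round(window_s * rec.fs))
    if win < 1 or rec.n_samples < win:
        raise ValueError("recording shorter than one rejection window")
    n_win = rec.n_samples // win
    trimmed = rec.data[:, : n_win * win]
    windows = trimmed.reshape(rec.n_channels, n_win, win)

    if math.isinf(cutoff):
        kept = np.ones(n_win, dtype=bool)
    else:
        rms = np.sqrt((windows ** 2).mean(axis=2))          # (ch, n_win)
        n_cal = max(1, int(round(calibration_fraction * n_win)))
        order = np.argsort(rms.mean(axis=0), kind="stable")
        cal_idx = order[:n_cal]
        cal = windows[:, cal_idx, :].reshape(rec.n_channels, -1)
        med = np.median(cal, axis=1, keepdims=True)
        baseline = _MAD_TO_SD * np.median(np.abs(cal - med), axis=1)
        baseline = np.maximum(baseline, np.finfo(float).tiny)
        sd = windows.std(axis=2)                            # (ch, n_win)
        kept = ~np.any(sd > cutoff * baseline[:, None], axis=0)

    if not kept.any():
        raise ValueError(f"{rec.subject_id}: every window rejected")
    data = windows[:, kept, :].reshape(rec.n_channels, -1)
    cleaned = Recording(rec.subject_id, rec.group, data, rec.fs,
                        list(rec.channel_names), list(rec.reference_names))
    return CleanResult(cleaned, kept, float(1.0 - kept.mean()))


def apply_component_mask(rec: Recording, mask_path: str) -> Recording:
    """Apply an externally supplied channels×channels linear projection
    (rows index output channels).  The identity matrix is a no-op."""
    mask, _ = read_matrix(mask_path)
    n = rec.n_channels
    if mask.shape != (n, n):
        raise ValueError(
            f"projection is {mask.shape}, expected ({n}, {n})")
    data = mask @ rec.data
    return Recording(rec.subject_id, rec.group, data, rec.fs,
                     list(rec.channel_names), list(rec.reference_names))


def preprocess(rec: Recording, bp_low: float = 0.5, bp_high: float = 45.0,
               butter_order: int = 4, asr_cutoff: float = 17.0,
               asr_window_s: float = 0.5,
               mask_path: str | None = None) -> CleanResult:
    """Full pipeline: rereference → band-pass → (optional projection) →
    burst rejection."""
    rec = rereference(rec)
    rec = bandpass(rec, bp_low, bp_high, butter_order)
    if mask_path is not None:
        rec = apply_component_mask(rec, mask_path)
    return reject_bursts(rec, asr_cutoff, asr_window_s)
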