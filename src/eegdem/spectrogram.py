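"""Epoching and channel×frequency spectrogram images.

Each preprocessed recording is cut into 30 s epochs (15,000 samples at
500 Hz); every epoch becomes one image in which row r is scalp channel r (in
canonical order) and column j is the single-sided DFT amplitude at one
frequency bin.  With exact-length transforms the bin spacing is
fs/N = 1/30 Hz, and the default analysis band [0.5, 40) Hz selects bins
k = 15 … 1199 → a 19 × 1185 raw image.  Amplitudes are normalized (per image,
1st–99th percentile clip by default) and pushed through a monotone-luminance
colormap to give an RGB array in [0, 1]; the CNN consumes a bilinear resize
to 150 × 150 × 3.

These are not time–frequency spectrograms: one image summarizes one epoch's
full spectrum per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize as _sk_resize

from .fourier import fft_many
from .io import CANONICAL_CHANNELS, Recording

__all__ = ["Epoch", "SpectrogramImage", "epoch_recording", "build_image",
           "resize_image", "images_from_recording", "export_images"]


@dataclass(frozen=True)
class Epoch:
    subject_id: str
    index: int
    data: np.ndarray          # (19, L) µV
    fs: float
    label: str = "UNKNOWN"

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SpectrogramImage:
    pixels: np.ndarray        # (H, W, 3) floats in [0, 1]
    raw_values: np.ndarray    # (19, W) single-sided amplitudes, µV
    freq_axis: np.ndarray     # Hz per column of raw_values
    channel_axis: tuple[str, ...]
    label: str
    subject_id: str
    epoch_index: int


def epoch_recording(rec: Recording, epoch_s: float = 30.0,
                    n_epochs: int = 20, overlap_mode: bool = False,
                    ) -> list[Epoch]:
    """Cut consecutive non-overlapping epochs from the start of a recording.

    If fewer than ``n_epochs`` fit, either return the available count with a
    warning (default) or, with ``overlap_mode``, uniformly space ``n_epochs``
    possibly-overlapping windows across the recording.
    """
    L = int(round(epoch_s * rec.fs))
    scalp = rec.scalp_data()
    n = scalp.shape[1]
    if n < L:
        raise ValueError(
            f"{rec.subject_id}: recording ({n} samples) shorter than one "
            f"{epoch_s:g} s epoch ({L} samples)")
    available = n // L
    if available >= n_epochs:
        starts = [i * L for i in range(n_epochs)]
    elif overlap_mode:
        starts = np.linspace(0, n - L, n_epochs).round().astype(int).tolist()
    else:
        warnings.warn(
            f"{rec.subject_id}: only {available} of {n_epochs} requested "
            "epochs available", stacklevel=2)
        starts = [i * L for i in range(available)]
    return [Epoch(rec.subject_id, i, scalp[:, s:s + L], rec.fs, rec.group)
            for i, s in enumerate(starts)]


def _band_bins(n: int, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Bins k (0 ≤ k ≤ N/2) with f_lo ≤ k·fs/N < f_hi; comparisons are done
    on k·fs vs f·N so exact band edges land deterministically on bins."""
    k = np.arange(n // 2 + 1)
    sel = (k * fs >= f_lo * n) & (k * fs < f_hi * n)
    bins = k[sel]
    if bins.size == 0:
        raise ValueError(f"band [{f_lo}, {f_hi}) Hz holds no bins at N={n}")
    return bins


def _viridis_table() -> np.ndarray:
    import matplotlib

    return np.asarray(matplotlib.colormaps["viridis"](np.linspace(0, 1, 256)))[:, :3]


_CMAP: np.ndarray | None = None


def _colormap(norm: np.ndarray) -> np.ndarray:
    """Map normalized values in [0,1] through a fixed 256-entry
    perceptually-uniform (monotone-luminance) table."""
    global _CMAP
    if _CMAP is None:
        _CMAP = _viridis_table()
    idx = np.clip((norm * 255).round().astype(int), 0, 255)
    return _CMAP[idx]


def build_image(epoch: Epoch, f_lo: float = 0.5, f_hi: float = 40.0,
                norm_bounds: tuple[float, float] | None = None,
                ) -> SpectrogramImage:
    """FFT every channel of an epoch and assemble the channel×frequency image.

    ``norm_bounds`` fixes global amplitude bounds for the colormap; by
    default each image is scaled to its own 1st–99th amplitude percentiles
    (clipped).
    """
    n = epoch.n_samples
    coeffs = fft_many(epoch.data, epoch.fs)
    amps = np.abs(coeffs[:, : n // 2 + 1]) / n
    if n > 1:
        last = n // 2 if n % 2 == 0 else n // 2 + 1
        amps[:, 1:last] *= 2.0
    bins = _band_bins(n, epoch.fs, f_lo, f_hi)
    raw = amps[:, bins]
    freqs = bins * (epoch.fs / n)

    if norm_bounds is None:
        lo, hi = np.percentile(raw, [1.0, 99.0])
    else:
        lo, hi = norm_bounds
    if hi <= lo:
        norm = np.zeros_like(raw)
    else:
        norm = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    return SpectrogramImage(
        pixels=_colormap(norm), raw_values=raw, freq_axis=freqs,
        channel_axis=CANONICAL_CHANNELS, label=epoch.label,
        subject_id=epoch.subject_id, epoch_index=epoch.index)


def resize_image(img: SpectrogramImage, size: int = 150,
                 order: int = 1) -> SpectrogramImage:
    """Bilinear (order=1; order=0 for nearest-neighbour) resample of the
    pixel array to ``size × size × 3``; raw values are left untouched."""
    if size < 1:
        raise ValueError("size must be >= 1")
    px = _sk_resize(img.pixels, (size, size, 3), order=order,
                    mode="edge", anti_aliasing=False, preserve_range=True)
    return replace(img, pixels=np.clip(px, 0.0, 1.0))


def export_images(images: list[SpectrogramImage], outdir: str,
                  raw: bool = False) -> str:
    """Write images as PNGs plus a tab-separated sidecar table (subject,
    epoch, label, file); with ``raw`` the amplitude matrices are also saved
    in the headered numeric format.  Returns the sidecar path."""
    import os

    import pandas as pd
    from PIL import Image

    from .io import write_matrix

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for img in images:
        stem = f"{img.subject_id}_ep{img.epoch_index:03d}"
        png = os.path.join(outdir, stem + ".png")
        Image.fromarray((img.pixels * 255).round().astype(np.uint8)).save(png)
        if raw:
            write_matrix(img.raw_values, os.path.join(outdir, stem + ".txt"),
                         subject_id=img.subject_id, label=img.label,
                         epoch=str(img.epoch_index),
                         f_lo=f"{img.freq_axis[0]:g}",
                         f_hi=f"{img.freq_axis[-1]:g}")
        rows.append({"subject_id": img.subject_id, "epoch": img.epoch_index,
                     "label": img.label, "file": os.path.basename(png)})
    sidecar = os.path.join(outdir, "images.tsv")
    pd.DataFrame(rows).to_csv(sidecar, sep="\t", index=False)
    return sidecar


def images_from_recording(rec: Recording, epoch_s: float = 30.0,
                          n_epochs: int = 20, f_lo: float = 0.5,
                          f_hi: float = 40.0, size: int | None = 150,
                          overlap_mode: bool = False) -> list[SpectrogramImage]:
    """Convenience: epoch a preprocessed recording and build (optionally
    resized) images for every epoch."""
    out = []
    for ep in epoch_recording(rec, epoch_s, n_epochs, overlap_mode):
        img = build_image(ep, f_lo, f_hi)
        if size is not None:
            img = resize_image(img, size)
        out.append(img)
    return out
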