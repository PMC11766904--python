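"""Synthetic resting-state EEG cohorts with class-conditional spectra.

Every downstream stage (preprocessing, spectrogram images, CNN, baselines,
subject-disjoint evaluation) is exercised against cohorts produced here, so
the generator emulates the statistical structure that separates the three
diagnostic groups in resting EEG:

* CN — posterior-dominant alpha rhythm (strongest over O1/O2, parietal).
* AD — generalized slowing: elevated theta, attenuated alpha and beta.
* FTD — theta elevation concentrated over frontal/temporal electrodes,
  milder posterior alpha loss than AD.

Each channel is the sum of a 1/f-shaped broadband background, five
band-limited oscillations (band-pass filtered Gaussian noise, not sinusoids,
so spectra are broadband), and white sensor noise.  Band amplitudes are
modulated per class by a band gain and a per-region weight.  High-amplitude
artifact bursts and frontal blink transients can be injected to exercise the
burst rejector.  Everything is deterministic given (cohort seed, subject seed).

Effect sizes are artifact parameters chosen so that the default cohort is
separable by the pipeline at realistic (not ceiling) accuracy; they are not
estimates of any clinical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import CANONICAL_CHANNELS, REFERENCE_CHANNELS, Recording, SubjectMeta

__all__ = [
    "BANDS", "REGIONS", "ClassProfile", "CohortSpec",
    "default_profiles", "generate_subject", "iter_cohort",
    "generate_cohort", "write_cohort", "null_profiles",
]

#: Frequency bands tiling [0.5, 45) Hz, half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 25.0),
    "gamma": (25.0, 45.0),
}

#: Assignment of the 19 scalp channels to 5 scalp regions.
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "temporal": ("T3", "T4", "T5", "T6"),
    "central": ("C3", "Cz", "C4"),
    "parietal": ("P3", "Pz", "P4"),
    "occipital": ("O1", "O2"),
}

_CHANNEL_REGION = {ch: reg for reg, chans in REGIONS.items() for ch in chans}

#: Baseline oscillation RMS per band, µV (before class gains).
_BASE_BAND_RMS = {"delta": 4.0, "theta": 3.0, "alpha": 4.0,
                  "beta": 2.0, "gamma": 1.0}


@dataclass(frozen=True)
class ClassProfile:
    """Spectral fingerprint of one diagnostic group.

    ``band_gains[band]`` multiplies that band's oscillation amplitude on all
    channels; ``region_weights[band][region]`` multiplies it further on the
    channels of one region (missing entries default to 1).
    """

    band_gains: dict[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in BANDS})
    region_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    background_exponent: float = 1.0
    background_rms: float = 5.0
    noise_sd: float = 1.0
    #: log-normal SD of per-subject band-gain (and background) variability;
    #: groups overlap spectrally, as clinical cohorts do
    subject_sd: float = 0.25

    def __post_init__(self) -> None:
        for band, g in self.band_gains.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}")
            if g <= 0:
                raise ValueError(f"gain for {band} must be positive")

    def channel_gain(self, band: str, channel: str) -> float:
        g = self.band_gains.get(band, 1.0)
        region = _CHANNEL_REGION.get(channel)
        return g * self.region_weights.get(band, {}).get(region, 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation parameters.

    Defaults mirror the clinical cohort the pipeline targets: 36 AD / 23 FTD
    / 29 CN subjects, 500 Hz, 600 s per subject (enough for twenty
    non-overlapping 30 s epochs).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"AD": 36, "FTD": 23, "CN": 29})
    duration_s: float = 600.0
    fs: float = 500.0
    seed: int = 0
    artifact_rate: float = 1.0   # bursts / minute
    blink_rate: float = 2.0      # blinks / minute


def default_profiles() -> dict[str, ClassProfile]:
    """Class profiles implementing posterior-alpha CN, slowed AD, and
    frontotemporal-theta FTD spectra."""
    return {
        "CN": ClassProfile(
            band_gains={"delta": 1.0, "theta": 1.0, "alpha": 1.0,
                        "beta": 1.0, "gamma": 1.0},
            region_weights={"alpha": {"occipital": 3.0, "parietal": 2.0,
                                      "temporal": 1.5}},
        ),
        "AD": ClassProfile(
            band_gains={"delta": 1.15, "theta": 1.5, "alpha": 0.65,
                        "beta": 0.8, "gamma": 1.0},
            region_weights={"alpha": {"occipital": 1.8, "parietal": 1.4}},
        ),
        "FTD": ClassProfile(
            band_gains={"delta": 1.0, "theta": 1.3, "alpha": 0.8,
                        "beta": 1.0, "gamma": 1.0},
            region_weights={"theta": {"frontal": 1.6, "temporal": 1.6},
                            "alpha": {"occipital": 2.0, "parietal": 1.4}},
        ),
    }


def _pink_background(rng, shape, fs, exponent, rms):
    """1/f^exponent-shaped noise (rows independent) via spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x * (rms / sd)


def _band_oscillation(rng, shape, fs, lo, hi):
    """Unit-RMS band-limited Gaussian noise, rows independent."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def generate_subject(
    profile: ClassProfile,
    spec: CohortSpec,
    subject_seed: int,
    subject_id: str = "sub-000",
    group: str = "UNKNOWN",
) -> Recording:
    """Synthesize one subject: 19 scalp channels + A1/A2 at ``spec.fs``.

    Deterministic given (``spec.seed``, ``subject_seed``).
    """
    n = int(round(spec.duration_s * spec.fs))
    if n < 1:
        raise ValueError("duration too short for a single sample")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))

    n_scalp = len(CANONICAL_CHANNELS)
    # per-subject spectral individuality: one log-normal factor per band
    # plus one for the broadband background, shared across channels
    jitter = {band: float(np.exp(rng.normal(0.0, profile.subject_sd)))
              for band in BANDS}
    bg_jitter = float(np.exp(rng.normal(0.0, profile.subject_sd)))
    data = np.empty((n_scalp + 2, n), dtype=np.float64)
    data[:n_scalp] = _pink_background(
        rng, (n_scalp, n), spec.fs, profile.background_exponent,
        bg_jitter * profile.background_rms)
    for band, (lo, hi) in BANDS.items():
        amps = np.array([_BASE_BAND_RMS[band] * profile.channel_gain(band, ch)
                         for ch in CANONICAL_CHANNELS]) * jitter[band]
        osc = _band_oscillation(rng, (n_scalp, n), spec.fs, lo, hi)
        data[:n_scalp] += amps[:, None] * osc
    data[:n_scalp] += profile.noise_sd * rng.standard_normal((n_scalp, n))

    # Ear references: mostly sensor noise plus a trace of common activity.
    common = data[:n_scalp].mean(axis=0)
    for ri in range(2):
        data[n_scalp + ri] = 0.1 * common + rng.standard_normal(n)

    _inject_bursts(rng, data[:n_scalp], spec)
    _inject_blinks(rng, data[:n_scalp], spec)

    names = list(CANONICAL_CHANNELS) + list(REFERENCE_CHANNELS)
    return Recording(subject_id, group, data.astype(np.float32), spec.fs,
                     names, list(REFERENCE_CHANNELS))


def _inject_bursts(rng, scalp, spec: CohortSpec) -> None:
    """High-amplitude transient artifacts on every channel at once:
    band-limited (1–30 Hz, so the preprocessing band-pass does not attenuate
    them) raised-cosine-enveloped noise whose RMS over the burst is 20–30×
    the channel's SD, lasting 0.3–1 s."""
    n = scalp.shape[1]
    n_bursts = rng.poisson(spec.artifact_rate * (n / spec.fs) / 60.0)
    if n_bursts == 0:
        return
    sds = scalp.std(axis=1)
    sos = sps.butter(4, [1.0, 30.0], btype="bandpass", fs=spec.fs,
                     output="sos")
    for _ in range(n_bursts):
        dur = int(rng.uniform(0.3, 1.0) * spec.fs)
        start = int(rng.integers(0, max(n - dur, 1)))
        env = _raised_cosine(dur)
        factor = rng.uniform(20.0, 30.0)
        shape = sps.sosfilt(sos, rng.standard_normal((scalp.shape[0], dur)),
                            axis=-1) * env
        rms = np.sqrt((shape ** 2).mean(axis=-1, keepdims=True))
        rms[rms == 0] = 1.0
        scalp[:, start:start + dur] += factor * sds[:, None] * shape / rms


def _inject_blinks(rng, scalp, spec: CohortSpec) -> None:
    """Frontal blink transients: 0.3 s raised-cosine pulses, 100 µV at
    Fp1/Fp2 and fading toward the other frontal electrodes."""
    n = scalp.shape[1]
    n_blinks = rng.poisson(spec.blink_rate * (n / spec.fs) / 60.0)
    weights = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.3, "F3": 0.3,
               "Fz": 0.3, "F4": 0.3, "F8": 0.3}
    dur = int(0.3 * spec.fs)
    pulse = 100.0 * _raised_cosine(dur)
    for _ in range(n_blinks):
        start = int(rng.integers(0, max(n - dur, 1)))
        for ci, ch in enumerate(CANONICAL_CHANNELS):
            w = weights.get(ch, 0.0)
            if w:
                scalp[ci, start:start + dur] += w * pulse


def _sample_meta(rng, subject_id: str, group: str, duration_s: float) -> SubjectMeta:
    age_mu, age_sd = {"AD": (66.4, 7.9), "FTD": (63.6, 8.2),
                      "CN": (67.9, 5.4)}[group]
    if group == "CN":
        mmse = 30
    else:
        mu, sd = {"AD": (17.75, 4.5), "FTD": (22.17, 8.22)}[group]
        mmse = int(np.clip(round(rng.normal(mu, sd)), 0, 30))
    male_frac = {"AD": 13 / 36, "FTD": 14 / 23, "CN": 11 / 29}[group]
    gender = "M" if rng.random() < male_frac else "F"
    age = float(np.clip(rng.normal(age_mu, age_sd), 40, 95))
    return SubjectMeta(subject_id, group, round(age, 1), mmse, gender, duration_s)


def iter_cohort(spec: CohortSpec,
                profiles: dict[str, ClassProfile] | None = None,
                groups: tuple[str, ...] | None = None):
    """Yield ``(Recording, SubjectMeta)`` pairs one at a time.

    Streaming generation keeps memory flat for large cohorts; the groups are
    emitted in AD, FTD, CN order with subject seeds equal to their index.
    ``groups`` restricts the yield without changing the identity (seed, id,
    metadata) of the subjects that are kept, because every subject draws from
    its own seed stream.
    """
    if profiles is None:
        profiles = default_profiles()
    meta_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10**6]))
    idx = 0
    for group in ("AD", "FTD", "CN"):
        for _ in range(spec.n_per_group.get(group, 0)):
            subject_id = f"sub-{idx + 1:03d}"
            meta = _sample_meta(meta_rng, subject_id, group, spec.duration_s)
            if groups is None or group in groups:
                rec = generate_subject(profiles[group], spec, idx,
                                       subject_id, group)
                yield rec, meta
            idx += 1


def generate_cohort(spec: CohortSpec,
                    profiles: dict[str, ClassProfile] | None = None,
                    ) -> tuple[list[Recording], list[SubjectMeta]]:
    """Materialize the whole cohort (use :func:`iter_cohort` for large runs)."""
    pairs = list(iter_cohort(spec, profiles))
    return [p[0] for p in pairs], [p[1] for p in pairs]


def write_cohort(spec: CohortSpec, outdir: str,
                 profiles: dict[str, ClassProfile] | None = None) -> list[str]:
    """Write the cohort as EDF files plus a participants.tsv; returns paths."""
    import os

    from .io import write_participants, write_recording

    os.makedirs(outdir, exist_ok=True)
    paths, metas = [], []
    for rec, meta in iter_cohort(spec, profiles):
        path = os.path.join(outdir, f"{rec.subject_id}.edf")
        write_recording(rec, path, "edf")
        paths.append(path)
        metas.append(meta)
    write_participants(metas, os.path.join(outdir, "participants.tsv"))
    return paths


def null_profiles() -> dict[str, ClassProfile]:
    """Identical profiles for all groups — the no-effect calibration world in
    which any classifier should sit at chance."""
    flat = ClassProfile()
    return {"AD": flat, "FTD": flat, "CN": replace(flat)}
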