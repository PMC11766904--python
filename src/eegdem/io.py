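"""Recording data model and on-disk formats.

The cohort this pipeline targets is clinical resting-state EEG: 19 scalp
electrodes of the international 10–20 system plus two ear references (A1/A2),
sampled at 500 Hz, in microvolts.  The canonical scalp order below is fixed
package-wide — spectrogram image rows are identified by position in it.

Formats:

* EDF (European Data Format, 16-bit) — the interchange format.  A minimal
  reader/writer is implemented here; the physical range is fixed at
  ±3276.7 µV so one digital count is exactly 0.1 µV.
* a headered plain-text numeric matrix — a desk-scale fixture format.
* a tab-separated participants table (subject_id, group, age, mmse, gender).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_CHANNELS",
    "REFERENCE_CHANNELS",
    "GROUPS",
    "Recording",
    "SubjectMeta",
    "read_recording",
    "write_recording",
    "read_participants",
    "write_participants",
    "read_matrix",
    "write_matrix",
]

#: The 19 scalp electrodes, in canonical (image-row) order.
CANONICAL_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

REFERENCE_CHANNELS = ("A1", "A2")

GROUPS = ("AD", "FTD", "CN", "UNKNOWN")

# Modern 10-10 names occasionally used for the temporal row.
_CHANNEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

# EDF physical range: ±3276.7 µV over ±32767 counts → 0.1 µV/count.
EDF_PHYS_MAX = 3276.7
EDF_DIG_MAX = 32767
EDF_QUANT_STEP = EDF_PHYS_MAX / EDF_DIG_MAX  # 0.1 µV


def canonical_name(name: str) -> str:
    """Map a channel label to its canonical form (case-insensitive, with
    T7/T8/P7/P8 aliases); unknown labels pass through stripped."""
    clean = name.strip()
    for cand in CANONICAL_CHANNELS + REFERENCE_CHANNELS:
        if clean.lower() == cand.lower():
            return cand
    return _CHANNEL_ALIASES.get(clean.upper(), clean)


class NamedChannelError(KeyError):
    """A required channel is absent from a recording or file."""


class FormatError(ValueError):
    """A file does not parse as the declared format."""


@dataclass
class Recording:
    """A multichannel EEG recording in µV.

    ``data`` rows follow ``channel_names``; scalp channels are expected in
    canonical order (readers enforce this), references trail behind.
    """

    subject_id: str
    group: str
    data: np.ndarray
    fs: float
    channel_names: list[str]
    reference_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        target = canonical_name(name)
        for i, ch in enumerate(self.channel_names):
            if canonical_name(ch) == target:
                return i
        raise NamedChannelError(f"channel {name!r} not present")

    def get_channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def scalp_data(self) -> np.ndarray:
        """The 19 canonical scalp rows, in canonical order."""
        idx = [self.channel_index(ch) for ch in CANONICAL_CHANNELS]
        return self.data[idx]


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    group: str
    age: float = float("nan")
    mmse: int | None = None
    gender: str = ""
    duration_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in ("AD", "FTD", "CN"):
            raise ValueError(f"group must be AD, FTD or CN, got {self.group!r}")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE must lie in [0, 30], got {self.mmse}")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _write_edf(rec: Recording, path: str) -> None:
    ns = rec.n_channels
    fs_int = int(round(rec.fs))
    if abs(rec.fs - fs_int) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    if rec.n_samples % fs_int == 0:
        spr, record_dur = fs_int, 1.0
        n_records = rec.n_samples // fs_int
    else:  # one big record keeps arbitrary lengths round-trippable
        spr, record_dur = rec.n_samples, rec.n_samples / rec.fs
        n_records = 1

    header = b"".join([
        _pad("0", 8),
        _pad(f"{rec.subject_id} G:{rec.group}", 80),
        _pad("eegdem", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad(f"{record_dur:g}"[:8], 8),
        _pad(str(ns), 4),
    ])
    labels = b"".join(_pad(ch, 16) for ch in rec.channel_names)
    transducer = _pad("", 80) * ns
    physdim = _pad("uV", 8) * ns
    physmin = _pad(f"{-EDF_PHYS_MAX}", 8) * ns
    physmax = _pad(f"{EDF_PHYS_MAX}", 8) * ns
    digmin = _pad(str(-EDF_DIG_MAX), 8) * ns
    digmax = _pad(str(EDF_DIG_MAX), 8) * ns
    prefilter = _pad("", 80) * ns
    spr_f = _pad(str(spr), 8) * ns
    reserved = _pad("", 32) * ns

    scale = EDF_DIG_MAX / EDF_PHYS_MAX
    digital = np.clip(np.round(rec.data * scale), -EDF_DIG_MAX, EDF_DIG_MAX)
    digital = digital.astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + physdim + physmin + physmax
                 + digmin + digmax + prefilter + spr_f + reserved)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(np.ascontiguousarray(block).tobytes())


def _read_edf(path: str) -> tuple[np.ndarray, float, list[str], str, str]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            patient = head[8:88].decode("ascii").strip()
            n_records = int(head[236:244])
            record_dur = float(head[244:252])
            ns = int(head[252:256])
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable EDF header") from exc
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise FormatError(f"{path}: truncated EDF signal headers")

        def col(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                    for i in range(ns)]

        labels = col(0, 16)
        # byte offsets of the fixed-width per-signal header fields
        try:
            physmin = [float(v) for v in col(104, 8)]
            physmax = [float(v) for v in col(112, 8)]
            digmin = [int(v) for v in col(120, 8)]
            digmax = [int(v) for v in col(128, 8)]
            spr = [int(v) for v in col(216, 8)]
        except ValueError as exc:
            raise FormatError(f"{path}: malformed EDF signal headers") from exc

        payload = fh.read()

    total = [s * n_records for s in spr]
    data = np.empty((ns, max(total)), dtype=np.float64)
    raw = np.frombuffer(payload, dtype="<i2")
    per_record = sum(spr)
    if raw.size < per_record * n_records:
        raise FormatError(f"{path}: EDF payload shorter than declared")
    for r in range(n_records):
        base = r * per_record
        off = 0
        for i in range(ns):
            chunk = raw[base + off: base + off + spr[i]]
            gain = (physmax[i] - physmin[i]) / (digmax[i] - digmin[i])
            data[i, r * spr[i]: r * spr[i] + spr[i]] = (
                (chunk.astype(np.float64) - digmin[i]) * gain + physmin[i]
            )
            off += spr[i]
    if len(set(spr)) != 1:
        raise FormatError(f"{path}: heterogeneous samples-per-record unsupported")
    fs = spr[0] / record_dur

    subject_id, group = patient, "UNKNOWN"
    if " G:" in patient:
        subject_id, group = patient.rsplit(" G:", 1)
        if group not in GROUPS:
            group = "UNKNOWN"
    return data, fs, labels, subject_id, group


# ---------------------------------------------------------------------------
# Headered numeric matrix (text fixture format)
# ---------------------------------------------------------------------------

def write_matrix(data: np.ndarray, path: str, **meta: str) -> str:
    """Write a 2-D array as whitespace-separated text with ``# key = value``
    header lines.  Used for fixtures and projection masks."""
    header = "\n".join(f"{k} = {v}" for k, v in meta.items())
    np.savetxt(path, np.atleast_2d(data), header=header, fmt="%.10g")
    return path


def read_matrix(path: str) -> tuple[np.ndarray, dict[str, str]]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    data = np.atleast_2d(np.loadtxt(path))
    return data, meta


def _write_numeric(rec: Recording, path: str) -> None:
    write_matrix(
        rec.data, path,
        subject_id=rec.subject_id, group=rec.group, fs=f"{rec.fs:g}",
        channel_names=",".join(rec.channel_names),
        reference_names=",".join(rec.reference_names),
    )


def _read_numeric(path: str) -> tuple[np.ndarray, float, list[str], str, str]:
    data, meta = read_matrix(path)
    for key in ("fs", "channel_names"):
        if key not in meta:
            raise FormatError(f"{path}: numeric-matrix header lacks {key!r}")
    labels = [c for c in meta["channel_names"].split(",") if c]
    return (data, float(meta["fs"]), labels,
            meta.get("subject_id", os.path.basename(path)),
            meta.get("group", "UNKNOWN"))


# ---------------------------------------------------------------------------
# Public reader/writer
# ---------------------------------------------------------------------------

def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "edf" if path.lower().endswith(".edf") else "numeric-matrix"


def read_recording(path: str, fmt: str | None = None) -> Recording:
    """Read a recording and reorder scalp channels into canonical order.

    Reference channels (A1/A2), when present, are kept after the scalp block;
    their absence is only flagged with a warning — some deposits apply the
    ear reference at acquisition time.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        data, fs, labels, subject_id, group = _read_edf(path)
    elif fmt == "numeric-matrix":
        data, fs, labels, subject_id, group = _read_numeric(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    canon = {canonical_name(lbl): i for i, lbl in enumerate(labels)}
    missing = [ch for ch in CANONICAL_CHANNELS if ch not in canon]
    if missing:
        raise NamedChannelError(
            f"{path}: required scalp channel(s) missing: {', '.join(missing)}"
        )
    refs = [ch for ch in REFERENCE_CHANNELS if ch in canon]
    if not refs:
        warnings.warn(
            f"{path}: no A1/A2 reference channels found; assuming the "
            "reference was applied at acquisition", stacklevel=2,
        )
    order = [canon[ch] for ch in CANONICAL_CHANNELS] + [canon[r] for r in refs]
    names = list(CANONICAL_CHANNELS) + refs
    return Recording(subject_id, group, data[order], fs, names, refs)


def write_recording(rec: Recording, path: str, fmt: str | None = None) -> str:
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "numeric-matrix":
        _write_numeric(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Participants table
# ---------------------------------------------------------------------------

def read_participants(path: str) -> list[SubjectMeta]:
    """Parse a tab-separated participants table; unknown columns are ignored."""
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: participants table lacks column {col!r}")
    metas = []
    for _, row in df.iterrows():
        mmse = row.get("mmse")
        metas.append(SubjectMeta(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            age=float(row.get("age", float("nan"))),
            mmse=None if pd.isna(mmse) else int(mmse),
            gender=str(row.get("gender", "")),
            duration_s=float(row.get("duration_s", float("nan"))),
        ))
    return metas


def write_participants(metas: list[SubjectMeta], path: str) -> str:
    df = pd.DataFrame([{
        "subject_id": m.subject_id, "group": m.group, "age": m.age,
        "mmse": m.mmse, "gender": m.gender, "duration_s": m.duration_s,
    } for m in metas])
    df.to_csv(path, sep="\t", index=False)
    return path
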