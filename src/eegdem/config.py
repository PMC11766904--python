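"""Flat key-value run configuration.

One dataclass holds every stage parameter of the pipeline; defaults are the
protocol's stated values (500 Hz, 0.5–45 Hz Butterworth, burst cutoff 17 on
0.5 s windows, 30 s epochs × 20, band [0.5, 40) Hz, 150×150 input, 100
training epochs, 5 folds).  Round-trips losslessly through a ``key = value``
text file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # cohort generation
    n_ad: int = 36
    n_ftd: int = 23
    n_cn: int = 29
    duration_s: float = 600.0
    fs: float = 500.0
    seed: int = 0
    artifact_rate: float = 1.0
    blink_rate: float = 2.0
    # preprocessing
    bp_low: float = 0.5
    bp_high: float = 45.0
    butter_order: int = 4
    asr_cutoff: float = 17.0
    asr_window: float = 0.5
    # spectrogram
    epoch_s: float = 30.0
    n_epochs: int = 20
    f_lo: float = 0.5
    f_hi: float = 40.0
    image_size: int = 150
    # CNN
    train_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    # evaluation
    folds: int = 5
    repeats: int = 1
    problem: str = "ad_cn"
    # baselines
    baseline: str = "mlp"
    budget: int = 10
    baseline_epoch_s: float = 2.0

    def save(self, path: str) -> str:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key} = {value}\n")
        return path

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                key, value = (part.strip() for part in line.split("=", 1))
                raw[key] = value
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for key, value in raw.items():
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)
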