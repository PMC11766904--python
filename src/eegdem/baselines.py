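"""Classical-learner baselines on Welch relative band power.

The comparison protocol replaces spectrogram images with a conventional
feature table: recordings are cut into 2 s epochs and, per epoch and channel,
the Welch PSD is integrated over the five EEG bands; each band's power is
divided by the channel's total so the 5 values sum to 1 (relative band
power).  The resulting 19 × 5 = 95-dimensional rows feed standard learners:

* ``gboost``   — gradient-boosted trees (one adapter stands in for the
                 XGBoost/LightGBM/CatBoost trio),
* ``svm_pca``  — RBF SVM on a PCA-reduced table,
* ``knn_pca``  — k-NN on a PCA-reduced table,
* ``mlp``      — a multilayer perceptron with one hidden layer of 96 units.

Hyperparameters are picked by a budgeted, seeded random search scored on a
subject-disjoint validation split carved out of the training subjects, so no
test information ever reaches model selection; PCA is likewise fitted on
training rows only (it lives inside the fitted pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import PCA
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import ParameterSampler
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import CANONICAL_CHANNELS, Recording

__all__ = ["BandScheme", "DEFAULT_BANDS", "welch_psd", "band_features",
           "fit_baseline", "BASELINE_NAMES"]

#: delta/theta/alpha/beta/gamma, half-open [lo, hi) Hz, standard mapping.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 25.0),
    ("gamma", 25.0, 45.0),
)

BASELINE_NAMES = ("gboost", "svm_pca", "knn_pca", "mlp")


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping frequency bands."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for name, lo, hi in self.bands:
            if not (prev_hi <= lo < hi):
                raise ValueError(
                    f"band {name!r} [{lo}, {hi}) overlaps or is inverted")
            prev_hi = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)


def welch_psd(x: np.ndarray, fs: float, seg_s: float = 1.0,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed averaged periodogram (density, µV²/Hz).

    Returns ``(freqs, psd)``; ``x`` may be 1-D or (channels, samples).
    """
    nperseg = int(round(seg_s * fs))
    if np.asarray(x).shape[-1] < nperseg:
        raise ValueError("segment longer than the signal")
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=int(round(overlap * nperseg)), axis=-1,
                     scaling="density")


def band_features(rec: Recording, scheme: BandScheme | None = None,
                  epoch_s: float = 2.0, seg_s: float = 1.0,
                  overlap: float = 0.5) -> pd.DataFrame:
    """Relative band power per non-overlapping epoch and channel.

    One row per 2 s epoch; columns ``<channel>_<band>`` plus ``subject_id``
    and ``label``.  Per channel the five relative powers sum to 1.
    """
    scheme = scheme or BandScheme()
    L = int(round(epoch_s * rec.fs))
    scalp = rec.scalp_data()
    n_ep = scalp.shape[1] // L
    if n_ep == 0:
        raise ValueError(
            f"{rec.subject_id}: recording shorter than one {epoch_s:g} s epoch")
    rows = []
    for e in range(n_ep):
        seg = scalp[:, e * L:(e + 1) * L]
        freqs, psd = welch_psd(seg, rec.fs, seg_s, overlap)
        band_power = np.empty((len(CANONICAL_CHANNELS), len(scheme.bands)))
        for bi, (_, lo, hi) in enumerate(scheme.bands):
            sel = (freqs >= lo) & (freqs < hi)
            band_power[:, bi] = psd[:, sel].sum(axis=1)
        total = band_power.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        rel = band_power / total
        row: dict[str, object] = {"subject_id": rec.subject_id,
                                  "label": rec.group, "epoch": e}
        for ci, ch in enumerate(CANONICAL_CHANNELS):
            for bi, bname in enumerate(scheme.names):
                row[f"{ch}_{bname}"] = rel[ci, bi]
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in table.columns
            if c not in ("subject_id", "label", "epoch")]
    return table[cols].to_numpy(dtype=float)


_SEARCH_SPACES: dict[str, dict] = {
    "gboost": {"learning_rate": [0.03, 0.1, 0.3],
               "max_depth": [2, 3, 4, 6],
               "max_iter": [50, 100, 200]},
    "svm_pca": {"clf__C": [0.1, 1.0, 10.0, 100.0],
                "clf__gamma": ["scale", 0.01, 0.1],
                "pca__n_components": [10, 20, 40]},
    "knn_pca": {"clf__n_neighbors": [3, 5, 11, 21],
                "clf__weights": ["uniform", "distance"],
                "pca__n_components": [10, 20, 40]},
    "mlp": {"clf__alpha": [1e-5, 1e-4, 1e-3, 1e-2],
            "clf__learning_rate_init": [1e-4, 1e-3, 1e-2]},
}


def _make_estimator(name: str, params: dict, seed: int):
    if name == "gboost":
        return HistGradientBoostingClassifier(random_state=seed, **params)
    if name == "svm_pca":
        est = Pipeline([("scale", StandardScaler()), ("pca", PCA()),
                        ("clf", SVC(probability=False, random_state=seed))])
    elif name == "knn_pca":
        est = Pipeline([("scale", StandardScaler()), ("pca", PCA()),
                        ("clf", KNeighborsClassifier())])
    elif name == "mlp":
        # hidden layer width fixed at 96 by the comparison protocol
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", MLPClassifier(hidden_layer_sizes=(96,),
                                              max_iter=400,
                                              random_state=seed))])
    else:
        raise ValueError(f"unknown baseline {name!r}; "
                         f"choose from {BASELINE_NAMES}")
    est.set_params(**params)
    return est


def _subject_split(subjects: np.ndarray, labels: np.ndarray, seed: int,
                   val_fraction: float = 0.2):
    """Subject-disjoint train/validation split, stratified by group."""
    rng = np.random.default_rng(seed)
    subj_label = {}
    for s, y in zip(subjects, labels):
        subj_label.setdefault(s, y)
    val: set = set()
    for cls in sorted(set(subj_label.values())):
        members = sorted(s for s, y in subj_label.items() if y == cls)
        rng.shuffle(members)
        n_val = max(1, int(round(val_fraction * len(members))))
        val.update(members[:n_val])
    is_val = np.array([s in val for s in subjects])
    if is_val.all() or not is_val.any():
        raise ValueError("validation split degenerate; need >= 2 subjects/class")
    return ~is_val, is_val


def fit_baseline(name: str, table: pd.DataFrame, labels: np.ndarray,
                 budget: int = 10, seed: int = 0):
    """Fit one baseline with a budgeted seeded random hyperparameter search.

    ``table`` must carry ``subject_id`` (used for the internal
    subject-disjoint validation split); the selected configuration is refitted
    on all provided rows.  Deterministic given ``seed``.
    """
    if budget < 1:
        raise ValueError("search budget must be >= 1")
    if name not in _SEARCH_SPACES:
        raise ValueError(f"unknown baseline {name!r}; "
                         f"choose from {BASELINE_NAMES}")
    x = feature_matrix(table)
    y = np.asarray(labels)
    subjects = table["subject_id"].to_numpy()

    space = _SEARCH_SPACES[name]
    n_total = int(np.prod([len(v) for v in space.values()]))
    candidates = list(ParameterSampler(space, n_iter=min(budget, n_total),
                                       random_state=seed))

    def _clamp(params: dict, n_rows: int) -> dict:
        if "pca__n_components" in params:
            cap = max(1, min(x.shape[1], n_rows - 1))
            params = {**params,
                      "pca__n_components": min(params["pca__n_components"],
                                               cap)}
        return params

    if len(set(subjects)) >= 2 * len(set(y)) and len(candidates) > 1:
        tr, va = _subject_split(subjects, y, seed)
        candidates = [_clamp(p, int(tr.sum())) for p in candidates]
        scores = []
        for params in candidates:
            est = _make_estimator(name, params, seed)
            est.fit(x[tr], y[tr])
            scores.append(est.score(x[va], y[va]))
        best = candidates[int(np.argmax(scores))]
    else:  # too few subjects to hold any out — fall back to first candidate
        best = _clamp(candidates[0], x.shape[0])
    final = _make_estimator(name, best, seed)
    final.fit(x, y)
    final.selected_params_ = best
    return final
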