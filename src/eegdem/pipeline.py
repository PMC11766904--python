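"""End-to-end orchestration: recordings → preprocessed epochs → spectrogram
images → LNSO-evaluated CNN (or band-power baselines).

Recordings are streamed one at a time (a full default cohort held in memory
would be several GB), preprocessed, epoched and rendered to images; only the
image tensors, labels and subject ids are retained for training.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from .baselines import band_features, feature_matrix, fit_baseline
from .cnn import ModelConfig, build_model, predict, train
from .config import RunConfig
from .evaluate import EvalReport, make_splits, problem_label, run_lnso
from .io import Recording, SubjectMeta
from .preprocess import preprocess
from .spectrogram import images_from_recording
from .synth import ClassProfile, CohortSpec, iter_cohort

__all__ = ["CNNPipeline", "cohort_spec_from_config", "prepare_images",
           "prepare_features", "run_cnn_experiment", "run_baseline_experiment"]


def cohort_spec_from_config(cfg: RunConfig) -> CohortSpec:
    return CohortSpec(
        n_per_group={"AD": cfg.n_ad, "FTD": cfg.n_ftd, "CN": cfg.n_cn},
        duration_s=cfg.duration_s, fs=cfg.fs, seed=cfg.seed,
        artifact_rate=cfg.artifact_rate, blink_rate=cfg.blink_rate)


def prepare_images(
    recordings: Iterable[tuple[Recording, SubjectMeta]],
    cfg: RunConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[SubjectMeta]]:
    """Preprocess + epoch + image every recording of the problem's groups.

    Returns (images (N, S, S, 3) float32, label strings, subject ids, metas
    of the retained subjects).
    """
    pixels, labels, subjects, metas = [], [], [], []
    for rec, meta in recordings:
        label = problem_label(meta.group, cfg.problem)
        if label is None:
            continue
        clean = preprocess(rec, cfg.bp_low, cfg.bp_high, cfg.butter_order,
                           cfg.asr_cutoff, cfg.asr_window).recording
        for img in images_from_recording(
                clean, cfg.epoch_s, cfg.n_epochs, cfg.f_lo, cfg.f_hi,
                size=cfg.image_size):
            pixels.append(img.pixels.astype(np.float32))
            labels.append(label)
            subjects.append(meta.subject_id)
        metas.append(meta)
    if not pixels:
        raise ValueError(f"no subjects match problem {cfg.problem!r}")
    return (np.stack(pixels), np.asarray(labels), np.asarray(subjects), metas)


def prepare_features(
    recordings: Iterable[tuple[Recording, SubjectMeta]],
    cfg: RunConfig,
):
    """Welch relative-band-power table for the baseline protocol."""
    import pandas as pd

    frames, metas = [], []
    for rec, meta in recordings:
        label = problem_label(meta.group, cfg.problem)
        if label is None:
            continue
        clean = preprocess(rec, cfg.bp_low, cfg.bp_high, cfg.butter_order,
                           cfg.asr_cutoff, cfg.asr_window).recording
        frame = band_features(clean, epoch_s=cfg.baseline_epoch_s)
        frame["label"] = label
        frames.append(frame)
        metas.append(meta)
    if not frames:
        raise ValueError(f"no subjects match problem {cfg.problem!r}")
    return pd.concat(frames, ignore_index=True), metas


class CNNPipeline:
    """fit/predict adapter that builds and trains a fresh CNN per fold."""

    def __init__(self, cfg: RunConfig, n_classes: int, fold_seed: int = 0):
        self.model_config = ModelConfig(
            input_size=(cfg.image_size, cfg.image_size, 3),
            n_classes=n_classes, train_epochs=cfg.train_epochs,
            batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
            seed=fold_seed)
        self.model = None
        self.report = None

    def fit(self, images, y):
        self.model = build_model(self.model_config)
        self.model, self.report = train(self.model, images, y,
                                        self.model_config)
        return self

    def predict(self, images):
        return predict(self.model, images)


class _BaselineAdapter:
    """fit/predict adapter for the classical learners; keeps per-row subject
    ids so the internal hyperparameter split stays subject-disjoint."""

    def __init__(self, name: str, table, budget: int, seed: int):
        self._name = name
        self._table = table
        self._budget = budget
        self._seed = seed

    def fit(self, rows, y):
        self._est = fit_baseline(self._name, self._table.iloc[rows], y,
                                 self._budget, self._seed)
        return self

    def predict(self, rows):
        return self._est.predict(feature_matrix(self._table.iloc[rows]))


def _iter_problem_cohort(cfg: RunConfig,
                         profiles: dict[str, ClassProfile] | None,
                         ) -> Iterator[tuple[Recording, SubjectMeta]]:
    from .evaluate import PROBLEMS

    groups = tuple(g for g, lbl in PROBLEMS[cfg.problem].items()
                   if lbl is not None)
    yield from iter_cohort(cohort_spec_from_config(cfg), profiles, groups)


def run_cnn_experiment(cfg: RunConfig,
                       profiles: dict[str, ClassProfile] | None = None,
                       recordings=None) -> EvalReport:
    """Synthesize (or accept) a cohort and run the full LNSO CNN evaluation."""
    recs = recordings if recordings is not None else _iter_problem_cohort(cfg, profiles)
    images, labels, subjects, metas = prepare_images(recs, cfg)
    plan = make_splits(metas, cfg.folds, cfg.seed)
    classes = tuple(sorted(set(labels)))

    def factory(fold: int) -> CNNPipeline:
        return CNNPipeline(cfg, len(classes), fold_seed=cfg.seed * 1000 + fold)

    return run_lnso(factory, images, labels, subjects, plan, classes)


def run_baseline_experiment(cfg: RunConfig,
                            profiles: dict[str, ClassProfile] | None = None,
                            recordings=None) -> EvalReport:
    """Same split machinery, band-power features + a classical learner."""
    recs = recordings if recordings is not None else _iter_problem_cohort(cfg, profiles)
    table, metas = prepare_features(recs, cfg)
    plan = make_splits(metas, cfg.folds, cfg.seed)
    labels = table["label"].to_numpy()
    subjects = table["subject_id"].to_numpy()
    classes = tuple(sorted(set(labels)))
    rows = np.arange(len(table))

    def factory(fold: int):
        return _BaselineAdapter(cfg.baseline, table, cfg.budget,
                                cfg.seed * 1000 + fold)

    return run_lnso(factory, rows, labels, subjects, plan, classes)
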