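"""Leave-N-subjects-out evaluation and metric aggregation.

Epoched EEG breaks the independence assumption of plain k-fold
cross-validation: epochs of one subject are strongly correlated, and letting
them straddle a split lets a classifier score by recognizing the subject
rather than the disease.  Here every split is made at the subject level:
each diagnostic group is shuffled (seeded) and dealt round-robin into K
subsets; fold k's test set is the union of the k-th subset of every group, so
folds are stratified, pairwise disjoint, and cover all subjects.  All epochs
inherit their subject's side of the split — asserted, not assumed.

Fold accuracies are summarized with a Student-t 95% interval
(t_{0.975, K-1} · sd / sqrt(K)); per-class precision (PPV), recall (TPR) and
F1 come from the pooled confusion matrix, with zero-denominator entries
flagged undefined (NaN) and excluded from macro averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import SubjectMeta

__all__ = ["SplitPlan", "EvalReport", "PROBLEMS", "problem_label",
           "make_splits", "run_lnso", "summarize", "class_metrics"]

#: Label mapping per classification problem; None drops the subject.
PROBLEMS: dict[str, dict[str, str | None]] = {
    "ad_cn": {"AD": "AD", "CN": "CN", "FTD": None},
    "ftd_cn": {"FTD": "FTD", "CN": "CN", "AD": None},
    "adftd_cn": {"AD": "AD+FTD", "FTD": "AD+FTD", "CN": "CN"},
    "ad_ftd_cn": {"AD": "AD", "FTD": "FTD", "CN": "CN"},
}


def problem_label(group: str, problem: str) -> str | None:
    if problem not in PROBLEMS:
        raise ValueError(f"unknown problem {problem!r}; choose from "
                         f"{sorted(PROBLEMS)}")
    return PROBLEMS[problem].get(group)


@dataclass(frozen=True)
class SplitPlan:
    folds: tuple[tuple[frozenset, frozenset], ...]  # (train, test) per fold
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def test_subjects(self, fold: int) -> frozenset:
        return self.folds[fold][1]

    def train_subjects(self, fold: int) -> frozenset:
        return self.folds[fold][0]


def make_splits(metas: list[SubjectMeta], k: int = 5, seed: int = 0,
                ) -> SplitPlan:
    """Stratified subject-level K-fold plan.

    Within each group the subjects are permuted (seeded) and dealt
    round-robin into K subsets, so per group the fold test counts differ by
    at most one.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for m in metas:
        by_group.setdefault(m.group, []).append(m.subject_id)
    subsets: list[set] = [set() for _ in range(k)]
    for group in sorted(by_group):
        ids = sorted(by_group[group])
        if len(ids) < k:
            raise ValueError(
                f"group {group} has {len(ids)} subjects, fewer than k={k}")
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            subsets[i % k].add(sid)
    all_ids = {m.subject_id for m in metas}
    folds = tuple((frozenset(all_ids - s), frozenset(s)) for s in subsets)
    return SplitPlan(folds, seed)


@dataclass
class EvalReport:
    classes: tuple[str, ...]
    fold_confusions: list[np.ndarray] = field(default_factory=list)
    fold_accuracies: list[float] = field(default_factory=list)
    seed: int = 0
    # provenance for post-hoc leakage audits
    fold_train_subjects: list[frozenset] = field(default_factory=list)
    fold_test_subjects: list[frozenset] = field(default_factory=list)
    image_subjects: np.ndarray | None = None

    @property
    def pooled_confusion(self) -> np.ndarray:
        return np.sum(self.fold_confusions, axis=0)

    @property
    def pooled_accuracy(self) -> float:
        pooled = self.pooled_confusion
        return float(np.trace(pooled) / pooled.sum())

    def summary(self):
        return summarize(self.fold_accuracies)

    def metrics(self) -> dict:
        return class_metrics(self.pooled_confusion)

    def to_tables(self) -> dict[str, "object"]:
        """Tab-ready DataFrames: fold accuracies + summary, per-class
        metrics, pooled confusion matrix."""
        import pandas as pd

        mean, sd, ci, lo, hi = self.summary()
        acc = pd.DataFrame({
            "fold": [*range(1, len(self.fold_accuracies) + 1),
                     "mean", "sd", "ci95", "lower", "upper"],
            "accuracy": [*self.fold_accuracies, mean, sd, ci, lo, hi],
        })
        m = self.metrics()
        cls = pd.DataFrame({
            "class": [*self.classes, "total"],
            "ppv": [*m["ppv"], m["macro_ppv"]],
            "tpr": [*m["tpr"], m["macro_tpr"]],
            "f1": [*m["f1"], m["macro_f1"]],
        })
        conf = pd.DataFrame(self.pooled_confusion,
                            index=[f"true_{c}" for c in self.classes],
                            columns=[f"pred_{c}" for c in self.classes])
        return {"accuracy": acc, "class_metrics": cls, "confusion": conf}


def run_lnso(pipeline_factory, images: np.ndarray, labels: np.ndarray,
             subjects: np.ndarray, plan: SplitPlan,
             classes: tuple[str, ...] | None = None) -> EvalReport:
    """Train and test once per fold, keeping subjects strictly disjoint.

    ``pipeline_factory(fold)`` must return an object with
    ``fit(X, y_indices)`` and ``predict(X) -> class indices or probability
    rows``.  ``labels`` are class-name strings; ``subjects`` assigns every
    image to its subject.
    """
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    if classes is None:
        classes = tuple(sorted(set(labels)))
    cls_index = {c: i for i, c in enumerate(classes)}
    y = np.array([cls_index[v] for v in labels])

    report = EvalReport(classes=classes, seed=plan.seed,
                        image_subjects=subjects.copy())
    for fold in range(plan.k):
        test_set = plan.test_subjects(fold)
        train_set = plan.train_subjects(fold)
        is_test = np.array([s in test_set for s in subjects])
        is_train = np.array([s in train_set for s in subjects])
        # the anti-leakage guarantee, enforced at the image level
        assert not np.any(is_test & is_train), "subject leaked across a fold"
        if not is_test.any():
            raise ValueError(f"fold {fold} has no test images")
        model = pipeline_factory(fold)
        model.fit(images[is_train], y[is_train])
        pred = np.asarray(model.predict(images[is_test]))
        if pred.ndim == 2:  # probability rows
            pred = pred.argmax(axis=1)
        conf = np.zeros((len(classes), len(classes)), dtype=int)
        np.add.at(conf, (y[is_test], pred), 1)
        report.fold_confusions.append(conf)
        report.fold_accuracies.append(float((pred == y[is_test]).mean()))
        report.fold_train_subjects.append(frozenset(train_set))
        report.fold_test_subjects.append(frozenset(test_set))
    return report


def summarize(fold_accs) -> tuple[float, float, float, float, float]:
    """Mean, sample sd (n−1), Student-t 95% half-width, and the CI bounds
    of per-fold accuracies."""
    vals = np.asarray(fold_accs, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two fold accuracies")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    tcrit = float(stats.t.ppf(0.975, vals.size - 1))
    half = tcrit * sd / np.sqrt(vals.size)
    return mean, sd, float(half), float(mean - half), float(mean + half)


def class_metrics(confusion: np.ndarray) -> dict:
    """Per-class PPV/TPR/F1 from a confusion matrix (rows = true class).

    Zero-denominator metrics are NaN ("undefined") and excluded from the
    macro means.  Because the printed "total" F1 of such tables is
    convention-dependent, three aggregates are reported: the macro mean,
    the support-weighted mean, and the harmonic mean of pooled macro PPV
    and TPR.
    """
    conf = np.asarray(confusion)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (conf < 0).any():
        raise ValueError("confusion matrix must be nonnegative")
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        tpr = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        f1 = 2 * ppv * tpr / (ppv + tpr)
        f1 = np.where(np.isfinite(f1), f1, np.nan)
    support = conf.sum(axis=1)
    macro_ppv = float(np.nanmean(ppv))
    macro_tpr = float(np.nanmean(tpr))
    valid = ~np.isnan(f1)
    weighted_f1 = (float(np.average(f1[valid], weights=support[valid]))
                   if valid.any() and support[valid].sum() > 0 else float("nan"))
    pooled_f1 = (2 * macro_ppv * macro_tpr / (macro_ppv + macro_tpr)
                 if macro_ppv + macro_tpr > 0 else float("nan"))
    return {
        "ppv": ppv, "tpr": tpr, "f1": f1,
        "macro_ppv": macro_ppv, "macro_tpr": macro_tpr,
        "macro_f1": float(np.nanmean(f1)),
        "weighted_f1": weighted_f1,
        "pooled_f1": float(pooled_f1),
        "accuracy": float(tp.sum() / conf.sum()) if conf.sum() else float("nan"),
    }
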