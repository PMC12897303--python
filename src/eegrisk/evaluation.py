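"""Subject-wise evaluation: splits, classifiers, and the five-metric report.

The split is by subject, never by epoch: a seeded shuffle assigns
``max(1, round(test_fraction * n_subjects))`` subjects to the test partition,
resampling (bounded retries) until every task class is present on both sides.
Train/test subject disjointness is asserted at run time as a leakage guard,
not only in tests.

Classifiers mirror common clinical-EEG baselines: an RBF-kernel SVM
(C = 1.0, gamma = "scale"), a 500-tree random forest, and 1-nearest-neighbor.
SVM and KNN see min–max-scaled features (bounds fitted on training rows
only); the forest is invariant to monotone per-feature scaling and receives
the raw features.

Metric aggregation over classes: accuracy is the global fraction correct;
sensitivity and precision and F1 are support-weighted means of the per-class
one-vs-rest values (support-weighted recall is algebraically identical to
accuracy); specificity is the unweighted (macro) mean of per-class
one-vs-rest specificities. Macro recall is also reported for imbalance
diagnostics. All headline metrics are percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .preprocessing import apply_minmax, fit_minmax
from .tasks import TaskDataset

__all__ = [
    "SplitPlan",
    "ClassifierConfig",
    "MetricsReport",
    "subject_wise_split",
    "train_and_predict",
    "compute_metrics",
    "evaluate_task",
]

MODELS = ("svm", "rf", "knn")


@dataclass(frozen=True)
class SplitPlan:
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    seed: int
    task_id: int

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError("train and test subject sets overlap")


@dataclass(frozen=True)
class ClassifierConfig:
    model: str = "rf"
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    rf_n_trees: int = 500
    knn_k: int = 1
    seed: int = 0
    class_weight: str | None = None  # off by default; "balanced" opt-in

    def build(self):
        if self.model == "svm":
            return SVC(kernel="rbf", C=self.svm_c, gamma=self.svm_gamma,
                       class_weight=self.class_weight)
        if self.model == "rf":
            return RandomForestClassifier(
                n_estimators=self.rf_n_trees, random_state=self.seed,
                class_weight=self.class_weight, n_jobs=1,
            )
        if self.model == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k)
        raise ValueError(f"unknown model {self.model!r}; known: {MODELS}")


@dataclass
class MetricsReport:
    task_id: int
    model: str
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    macro_sensitivity: float
    classes: list[str] = field(default_factory=list)
    confusion: np.ndarray | None = None
    per_class_recall: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "model": self.model,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "macro_sensitivity": self.macro_sensitivity,
            "classes": self.classes,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
            "per_class_recall": self.per_class_recall,
        }


def subject_wise_split(dataset: TaskDataset, test_fraction: float = 0.2,
                       seed: int = 0, max_retries: int = 200) -> SplitPlan:
    """Seeded subject-level split with every task class on both sides."""
    subjects = np.array(sorted(set(dataset.subjects)))
    classes = np.array(sorted(set(dataset.y)))
    # subjects carrying each class
    carriers = {
        c: set(dataset.subjects[dataset.y == c]) for c in classes
    }
    for c, who in carriers.items():
        if len(who) < 2:
            raise ValueError(
                f"class {c!r} present in only {len(who)} subject(s); "
                "a subject-wise split cannot cover both partitions"
            )
    n_test = max(1, int(round(test_fraction * len(subjects))))
    if n_test >= len(subjects):
        raise ValueError("test fraction leaves no training subjects")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        order = rng.permutation(subjects)
        test = set(order[:n_test])
        train = set(order[n_test:])
        if all(who & test and who & train for who in carriers.values()):
            return SplitPlan(
                train_subjects=tuple(sorted(train)),
                test_subjects=tuple(sorted(test)),
                seed=seed,
                task_id=dataset.task_id,
            )
    raise RuntimeError(
        f"no class-covering subject split found in {max_retries} draws"
    )


def _partition(dataset: TaskDataset, split: SplitPlan):
    train_set, test_set = set(split.train_subjects), set(split.test_subjects)
    if train_set & test_set:  # leakage guard at run time
        raise ValueError("leakage: overlapping train/test subjects")
    tr = np.isin(dataset.subjects, list(train_set))
    te = np.isin(dataset.subjects, list(test_set))
    return tr, te


def train_and_predict(cfg: ClassifierConfig, split: SplitPlan,
                      dataset: TaskDataset) -> np.ndarray:
    """Fit one classifier on the training subjects, predict the test rows."""
    tr, te = _partition(dataset, split)
    X_train, y_train = dataset.X[tr], dataset.y[tr]
    X_test = dataset.X[te]
    if len(set(y_train)) < 2:
        raise ValueError("training partition contains a single class")
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(X_test))):
        raise ValueError("non-finite feature values")
    if cfg.model in ("svm", "knn"):
        scaler = fit_minmax(X_train.T, population="train-subjects")
        X_train = apply_minmax(X_train.T, scaler).T
        X_test = apply_minmax(X_test.T, scaler).T
    clf = cfg.build()
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    task_id: int = 0, model: str = "",
                    labels: list[str] | None = None) -> MetricsReport:
    """Five-metric report (percentages) plus the per-class confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    universe = sorted(set(y_true)) if labels is None else list(labels)
    stray = set(y_pred) - set(universe)
    if stray:
        raise ValueError(f"predicted label(s) {sorted(stray)} outside universe")
    cm = confusion_matrix(y_true, y_pred, labels=universe)
    support = cm.sum(axis=1)
    accuracy = np.trace(cm) / cm.sum()
    precision_w, recall_w, f1_w, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=universe, average="weighted", zero_division=0
    )
    recall_c = np.divide(np.diag(cm), support, out=np.zeros(len(universe)),
                         where=support > 0)
    macro_recall = recall_c[support > 0].mean()
    # one-vs-rest specificity per class, macro-averaged
    total = cm.sum()
    spec_c = []
    for i in range(len(universe)):
        tn = total - support[i] - cm[:, i].sum() + cm[i, i]
        fp = cm[:, i].sum() - cm[i, i]
        spec_c.append(tn / (tn + fp) if tn + fp > 0 else 0.0)
    report = MetricsReport(
        task_id=task_id,
        model=model,
        accuracy=100 * accuracy,
        sensitivity=100 * recall_w,
        specificity=100 * float(np.mean(spec_c)),
        precision=100 * precision_w,
        f1=100 * f1_w,
        macro_sensitivity=100 * float(macro_recall),
        classes=list(universe),
        confusion=cm,
        per_class_recall={c: 100 * float(r) for c, r in zip(universe, recall_c)},
    )
    for name in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
        v = getattr(report, name)
        if not (0.0 <= v <= 100.0):
            raise AssertionError(f"{name}={v} outside [0, 100]")
    return report


def evaluate_task(dataset: TaskDataset, model: str, seed: int = 0,
                  test_fraction: float = 0.2,
                  split: SplitPlan | None = None) -> MetricsReport:
    """Split (unless given), train, predict, and score one (task, model) run."""
    if split is None:
        split = subject_wise_split(dataset, test_fraction, seed)
    cfg = ClassifierConfig(model=model, seed=seed)
    y_pred = train_and_predict(cfg, split, dataset)
    _, te = _partition(dataset, split)
    return compute_metrics(dataset.y[te], y_pred, task_id=dataset.task_id,
                           model=model, labels=sorted(set(dataset.y)))
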