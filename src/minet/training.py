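"""Training protocol, repeated subject-disjoint cross-validation, and the
(scales x filters) grid search.

Each repeat draws a fresh subject-disjoint k-fold split (seed = base + r),
trains one model per fold on the remaining folds, predicts the held-out
fold, and pools the predictions of all folds into one confusion matrix, so a
run of R repeats yields R confusion matrices and R clinical-index sets per
configuration.  The within-epoch data order is a fixed permutation shared
across model configurations for the same (repeat, fold), which pins the data
input order; weight-initialization seeds differ across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .datasets import DatasetBundle, assert_no_leakage, with_folds
from .network import ModelConfig, count_parameters, enumerate_grid
from .nn import NNetClassifier


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 300
    max_epochs: int = 200
    patience: int = 20
    monitor: str = "train_loss"  # test folds must not steer training
    order_seed: int = 1234       # shared across configurations

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _sub_seed(*entropy: int) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] & 0x7FFFFFFF)


def train_model(
    model_config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    order: np.ndarray | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[NNetClassifier, dict[str, list[float]]]:
    """Train one classifier; deterministic given (seed, data order)."""
    tc = train_config or TrainConfig()
    model = NNetClassifier(model_config, seed=seed)
    monitor = tc.monitor
    if monitor.startswith("val") and validation is None:
        raise ValueError(f"monitor {monitor!r} requires validation data")
    history = model.fit(
        X, y,
        learning_rate=tc.learning_rate,
        batch_size=tc.batch_size,
        max_epochs=tc.max_epochs,
        patience=tc.patience,
        monitor=monitor,
        order=order,
        validation=validation,
    )
    return model, history


@dataclass
class CvResult:
    """Per-repeat pooled confusion matrices and clinical indexes."""

    model_config: ModelConfig
    task: str
    k: int
    repeats: int
    confusions: np.ndarray                     # (R, C, C)
    metric_sets: list[metrics.MetricSet]       # one per repeat
    histories: list[list[dict[str, list[float]]]] = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        """Per-repeat pooled accuracy, percent."""
        return np.array([metrics.multiclass_accuracy(cm) for cm in self.confusions])

    def per_repeat_indexes(self) -> dict[str, np.ndarray]:
        """Metric vectors keyed by index name (input to compare_models)."""
        keys = metrics.DETECTION_INDEXES if self.task == "detection" else metrics.LOCATING_INDEXES
        out = {}
        for key in keys:
            values = [ms.as_dict()[key] for ms in self.metric_sets]
            arr = np.array([np.nan if v is None else v for v in values], dtype=float)
            out[key] = arr * 100.0 if key == "AUC" else arr
        out["ACC"] = self.accuracies
        return out

    def summary(self) -> dict:
        acc = self.accuracies
        return {
            "model": self.model_config.name,
            "task": self.task,
            "k": self.k,
            "repeats": self.repeats,
            "n_parameters": count_parameters(self.model_config),
            "mean_acc": round(float(acc.mean()), 2),
            "sd_acc": round(float(acc.std(ddof=1)), 2) if acc.size > 1 else 0.0,
        }


def repeated_cv(
    model_config: ModelConfig,
    bundle: DatasetBundle,
    k: int = 5,
    repeats: int = 15,
    base_seed: int = 0,
    train_config: TrainConfig | None = None,
    keep_histories: bool = False,
    resplit_per_repeat: bool = True,
) -> CvResult:
    """Repeated subject-disjoint k-fold cross-validation of one configuration.

    With ``resplit_per_repeat`` (default) each repeat uses a fresh fold
    assignment; otherwise the folds are fixed and only the weight
    initialization varies across repeats.
    """
    tc = train_config or TrainConfig()
    n_classes = len(bundle.class_names)
    if model_config.num_classes != n_classes:
        raise ValueError(
            f"model has {model_config.num_classes} classes but bundle task "
            f"{bundle.task!r} has {n_classes}"
        )
    X, y, patients = bundle.to_arrays()

    confusions = np.zeros((repeats, n_classes, n_classes), dtype=int)
    metric_sets: list[metrics.MetricSet] = []
    histories: list[list[dict[str, list[float]]]] = []

    fixed = with_folds(bundle, k, _sub_seed(base_seed, 0)) if not resplit_per_repeat else None
    for r in range(repeats):
        folded = with_folds(bundle, k, _sub_seed(base_seed, r)) if resplit_per_repeat else fixed
        assert_no_leakage(folded)
        folds = folded.segment_folds()
        pooled_true, pooled_pred, pooled_score = [], [], []
        repeat_histories = []
        for fold in range(k):
            test = folds == fold
            train = ~test
            if not np.any(test) or not np.any(train):
                raise ValueError(f"fold {fold} is empty in repeat {r}")
            if set(patients[test]) & set(patients[train]):
                raise AssertionError("patient leakage between train and test")
            order_rng = np.random.default_rng(_sub_seed(tc.order_seed, r, fold))
            order = order_rng.permutation(int(train.sum()))
            model, history = train_model(
                model_config,
                X[train], y[train],
                train_config=tc,
                seed=_sub_seed(base_seed, 100 + r, fold),
                order=order,
            )
            probs = model.predict_proba(X[test])
            pooled_true.append(y[test])
            pooled_pred.append(probs.argmax(axis=1))
            if n_classes == 2:
                pooled_score.append(probs[:, 1])
            if keep_histories:
                repeat_histories.append(history)

        y_true = np.concatenate(pooled_true)
        y_pred = np.concatenate(pooled_pred)
        cm = metrics.confusion_matrix(y_true, y_pred, n_classes)
        if cm.sum() != bundle.n_pieces:
            raise AssertionError("pooled confusion matrix does not conserve the dataset size")
        confusions[r] = cm
        if n_classes == 2:
            ms = metrics.clinical_indexes(cm, positive_index=1)
            auc = metrics.rank_auc(np.concatenate(pooled_score), y_true == 1)
            metric_sets.append(metrics.MetricSet(ms.acc, ms.sen, ms.spe, ms.f1, auc))
        else:
            metric_sets.append(metrics.MetricSet(acc=metrics.multiclass_accuracy(cm)))
        if keep_histories:
            histories.append(repeat_histories)

    return CvResult(
        model_config=model_config,
        task=bundle.task,
        k=k,
        repeats=repeats,
        confusions=confusions,
        metric_sets=metric_sets,
        histories=histories,
    )


@dataclass
class GridResult:
    """Accuracy surface over the (scales, filters) grid."""

    task: str
    entries: dict[tuple[int, int], dict]       # (S, F) -> {mean_acc, sd_acc, ...}
    results: dict[tuple[int, int], CvResult]

    @property
    def best(self) -> tuple[int, int]:
        """Argmax of mean accuracy; ties broken toward fewer parameters."""
        return min(
            self.entries,
            key=lambda sf: (-self.entries[sf]["mean_acc"], self.entries[sf]["n_parameters"]),
        )

    def table(self) -> list[dict]:
        rows = []
        for (s, f), entry in sorted(self.entries.items()):
            rows.append({"scales": s, "filters": f, **entry})
        return rows


def grid_search(
    task: str,
    bundle: DatasetBundle,
    k: int = 5,
    repeats: int = 15,
    base_seed: int = 0,
    train_config: TrainConfig | None = None,
    configs: list[ModelConfig] | None = None,
) -> GridResult:
    """Run repeated CV for every grid configuration (or a restricted subgrid)."""
    if bundle.task != task:
        raise ValueError(f"bundle task {bundle.task!r} does not match {task!r}")
    input_length = bundle.segments[0].matrix.shape[1]
    configs = configs or enumerate_grid(task, input_length=input_length)
    entries: dict[tuple[int, int], dict] = {}
    results: dict[tuple[int, int], CvResult] = {}
    for config in configs:
        result = repeated_cv(config, bundle, k=k, repeats=repeats,
                             base_seed=base_seed, train_config=train_config)
        acc = result.accuracies
        key = (config.num_scales, config.num_filters)
        entries[key] = {
            "mean_acc": float(acc.mean()),
            "sd_acc": float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
            "n_parameters": count_parameters(config),
        }
        results[key] = result
    return GridResult(task=task, entries=entries, results=results)
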