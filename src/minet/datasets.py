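"""Balanced dataset construction and subject-disjoint k-fold splitting.

Random undersampling balances the six classes: a fixed number of records per
class is drawn, a fixed number of beat segments ("pieces") per record forms
the 6-class locating dataset, and the 2-class detection dataset reuses that
selection with the HC pieces kept whole and each MI record contributing a
subsample so that HC and MI piece counts match exactly.  At full scale this
yields 7200 locating pieces (1200 per class) and 2400 detection pieces
(1200 HC vs 5 x 240 MI).

Folds are assigned at the patient level (greedy lightest-fold balancing per
class) so that no patient's beats ever appear in more than one fold.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import BeatSegment, PreprocessConfig, preprocess_record
from .records import CLASSES, MI_CLASSES
from .synthetic import CohortSpec, iter_cohort

DETECTION_CLASSES = ("HC", "MI")


@dataclass(frozen=True)
class SelectionPlan:
    """Undersampling plan: how many records and pieces enter each dataset."""

    records_per_class: int = 40
    pieces_per_record: int = 30
    detection_pieces_per_record: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.records_per_class, self.pieces_per_record,
               self.detection_pieces_per_record) < 1:
            raise ValueError("all selection counts must be >= 1")
        if self.detection_pieces_per_record > self.pieces_per_record:
            raise ValueError("detection pieces per record cannot exceed locating pieces")

    def validate_detection_balance(self) -> None:
        """HC keeps pieces_per_record per record while each of the five MI
        classes keeps detection_pieces_per_record; equality requires
        detection_pieces * 5 == pieces_per_record."""
        if self.detection_pieces_per_record * len(MI_CLASSES) != self.pieces_per_record:
            raise ValueError(
                "detection balance identity violated: "
                f"{self.detection_pieces_per_record} x {len(MI_CLASSES)} != "
                f"{self.pieces_per_record}"
            )


def tiny_selection_plan(seed: int = 0) -> SelectionPlan:
    """Reduced smoke-scale plan matching the tiny cohort preset."""
    return SelectionPlan(records_per_class=12, pieces_per_record=10,
                         detection_pieces_per_record=2, seed=seed)


@dataclass
class DatasetBundle:
    """Balanced set of beat segments plus subject-disjoint fold assignment."""

    task: str  # "detection" or "locating"
    segments: list[BeatSegment]
    labels: list[str]                     # task-level label per segment
    class_names: tuple[str, ...]
    k: int | None = None
    fold_assignment: dict[str, int] | None = None  # patient_id -> fold
    plan: SelectionPlan | None = None

    def __post_init__(self) -> None:
        if self.task not in ("detection", "locating"):
            raise ValueError(f"unknown task {self.task!r}")
        if len(self.labels) != len(self.segments):
            raise ValueError("labels and segments must align")

    @property
    def n_pieces(self) -> int:
        return len(self.segments)

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.segments])

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in self.class_names}
        for label in self.labels:
            counts[label] += 1
        return counts

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, patients): X is (n, 12, L) float32 in mV, y integer codes.

        Segments are stored in uV; the network consumes millivolts so that
        input amplitudes are of order one.
        """
        X = np.stack([s.matrix for s in self.segments]).astype(np.float32) / 1000.0
        index = {c: i for i, c in enumerate(self.class_names)}
        y = np.array([index[l] for l in self.labels], dtype=int)
        return X, y, self.patient_ids

    def segment_folds(self) -> np.ndarray:
        if self.fold_assignment is None:
            raise ValueError("bundle has no fold assignment; call subject_kfold_split")
        return np.array([self.fold_assignment[s.patient_id] for s in self.segments])

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": s.patient_id,
                "record_id": s.record_id,
                "beat_index": s.beat_index,
                "class": s.class_label,
                "label": label,
            }
            for s, label in zip(self.segments, self.labels)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# record selection and dataset assembly


def segment_cohort(
    spec: CohortSpec, config: PreprocessConfig | None = None
) -> tuple[dict[str, list[BeatSegment]], pd.DataFrame]:
    """Generate, preprocess, and segment a whole cohort record by record.

    Returns segments grouped by record_id and a manifest with per-record
    segment counts (input to :func:`select_records`).
    """
    config = config or PreprocessConfig()
    by_record: dict[str, list[BeatSegment]] = {}
    rows = []
    for record in iter_cohort(spec):
        _, _, segments, dropped = preprocess_record(record, config)
        by_record[record.record_id] = segments
        rows.append(
            {
                "patient_id": record.patient_id,
                "record_id": record.record_id,
                "class": record.class_label,
                "n_segments": len(segments),
                "n_dropped": dropped,
            }
        )
    return by_record, pd.DataFrame(rows)


def select_records(manifest: pd.DataFrame, plan: SelectionPlan) -> dict[str, list[str]]:
    """Seeded uniform selection of exactly ``records_per_class`` eligible
    records per class; raises naming the class when a class falls short."""
    rng = np.random.default_rng(plan.seed)
    selected: dict[str, list[str]] = {}
    present = [c for c in CLASSES if c in set(manifest["class"])]
    for label in present:
        sub = manifest[manifest["class"] == label]
        eligible = sub[sub["n_segments"] >= plan.pieces_per_record]["record_id"].tolist()
        if len(eligible) < plan.records_per_class:
            raise ValueError(
                f"class {label}: only {len(eligible)} eligible records "
                f"(need {plan.records_per_class}; {len(sub)} total)"
            )
        eligible = sorted(eligible)
        if len(eligible) == plan.records_per_class:
            selected[label] = eligible
        else:
            pick = rng.choice(len(eligible), size=plan.records_per_class, replace=False)
            selected[label] = [eligible[i] for i in sorted(pick)]
    return selected


def _record_rng(plan_seed: int, record_id: str, stage: int) -> np.random.Generator:
    entropy = [plan_seed, stage] + [ord(c) for c in record_id]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def build_locating_dataset(
    segments_by_record: dict[str, list[BeatSegment]],
    selected: dict[str, list[str]],
    plan: SelectionPlan,
) -> DatasetBundle:
    """Seeded uniform choice of ``pieces_per_record`` segments per selected
    record; six equal classes."""
    segments: list[BeatSegment] = []
    labels: list[str] = []
    for label in [c for c in CLASSES if c in selected]:
        for record_id in selected[label]:
            pool = segments_by_record[record_id]
            if len(pool) < plan.pieces_per_record:
                raise ValueError(
                    f"record {record_id} has {len(pool)} segments < "
                    f"{plan.pieces_per_record}; should have been filtered out"
                )
            rng = _record_rng(plan.seed, record_id, stage=1)
            idx = sorted(rng.choice(len(pool), size=plan.pieces_per_record, replace=False))
            segments.extend(pool[i] for i in idx)
            labels.extend([label] * plan.pieces_per_record)
    return DatasetBundle(
        task="locating",
        segments=segments,
        labels=labels,
        class_names=tuple(c for c in CLASSES if c in selected),
        plan=plan,
    )


def build_detection_dataset(locating: DatasetBundle, plan: SelectionPlan | None = None) -> DatasetBundle:
    """Collapse the locating selection to the balanced 2-class detection set.

    HC keeps all its pieces; each MI record contributes a seeded uniform
    subsample of ``detection_pieces_per_record`` of its locating pieces.
    """
    plan = plan or locating.plan
    if plan is None:
        raise ValueError("a SelectionPlan is required")
    plan.validate_detection_balance()

    by_record: dict[str, list[BeatSegment]] = defaultdict(list)
    for seg in locating.segments:
        by_record[seg.record_id].append(seg)

    segments: list[BeatSegment] = []
    labels: list[str] = []
    for record_id, pool in by_record.items():
        cls = pool[0].class_label
        if cls == "HC":
            segments.extend(pool)
            labels.extend(["HC"] * len(pool))
        else:
            rng = _record_rng(plan.seed, record_id, stage=2)
            idx = sorted(rng.choice(len(pool), size=plan.detection_pieces_per_record,
                                    replace=False))
            segments.extend(pool[i] for i in idx)
            labels.extend(["MI"] * plan.detection_pieces_per_record)

    n_hc = labels.count("HC")
    n_mi = labels.count("MI")
    if n_hc != n_mi:
        raise ValueError(f"detection classes unbalanced after subsampling: HC {n_hc} vs MI {n_mi}")
    return DatasetBundle(
        task="detection",
        segments=segments,
        labels=labels,
        class_names=DETECTION_CLASSES,
        plan=plan,
    )


# ---------------------------------------------------------------------------
# subject-disjoint folds


def subject_kfold_split(bundle: DatasetBundle, k: int, seed: int) -> dict[str, int]:
    """Assign patients whole to folds by seeded greedy balancing.

    Within each underlying diagnostic class, patients are shuffled and each is
    placed in the fold currently lightest in that class's piece count, so
    per-fold per-class piece counts differ by at most the largest single
    patient's piece count.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pieces: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for seg in bundle.segments:
        pieces[seg.class_label][seg.patient_id] += 1

    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    fold_load = np.zeros(k)
    for label in sorted(pieces):
        patients = sorted(pieces[label])
        if len(patients) < k:
            raise ValueError(f"class {label} has {len(patients)} patients < k={k}")
        rng.shuffle(patients)
        class_load = np.zeros(k)
        for pid in patients:
            fold = int(np.argmin(class_load))
            assignment[pid] = fold
            class_load[fold] += pieces[label][pid]
            fold_load[fold] += pieces[label][pid]
    return assignment


def with_folds(bundle: DatasetBundle, k: int, seed: int) -> DatasetBundle:
    """Return a copy of the bundle carrying a fresh fold assignment."""
    assignment = subject_kfold_split(bundle, k, seed)
    out = DatasetBundle(
        task=bundle.task,
        segments=bundle.segments,
        labels=bundle.labels,
        class_names=bundle.class_names,
        k=k,
        fold_assignment=assignment,
        plan=bundle.plan,
    )
    assert_no_leakage(out)
    return out


def assert_no_leakage(bundle: DatasetBundle) -> None:
    """Audit: every patient in exactly one fold; fold patient sets disjoint."""
    folds = bundle.segment_folds()
    patients = bundle.patient_ids
    by_fold: dict[int, set[str]] = defaultdict(set)
    for pid, fold in zip(patients, folds):
        by_fold[int(fold)].add(pid)
    all_pids: set[str] = set()
    for fold, pids in by_fold.items():
        overlap = all_pids & pids
        if overlap:
            raise AssertionError(f"patient leakage across folds: {sorted(overlap)[:5]}")
        all_pids |= pids


def build_datasets(
    spec: CohortSpec,
    plan: SelectionPlan,
    config: PreprocessConfig | None = None,
) -> tuple[DatasetBundle, DatasetBundle, pd.DataFrame]:
    """End-to-end convenience: cohort -> segments -> (locating, detection)."""
    by_record, manifest = segment_cohort(spec, config)
    selected = select_records(manifest, plan)
    locating = build_locating_dataset(by_record, selected, plan)
    detection = build_detection_dataset(locating, plan)
    return locating, detection, manifest
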