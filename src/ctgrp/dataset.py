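"""Dataset assembly: pH labeling, class balancing, RP-grid augmentation, folds.

Records are labeled by the umbilical-artery pH at delivery (normal when
pH >= 7.15), the majority class is randomly subsampled to the minority
size, and each record is expanded into one recurrence-plot image per
cell of an (m, tau, k) parameter grid — the default 2 x 10 x 10 grid
turns each record into 200 images, so a balanced 105 + 105 cohort yields
21,000 images per class.

Cross-validation folds can be built at image level (each image assigned
independently, replicating the original evaluation protocol) or at
record level (all images of one record share a fold). Image-level folds
let augmented views of the same record appear in both training and test
folds, which leaks record identity and inflates the measured accuracy;
record-level folds are the honest generalization estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .records import NORMAL, PATHOLOGICAL, FHRRecord
from .recurrence import EmbeddingParams, RPImage, signal_to_rp

__all__ = [
    "AugmentationGrid",
    "FoldAssignment",
    "label_by_ph",
    "balance_classes",
    "augment",
    "make_folds",
]

PH_THRESHOLD = 7.15


@dataclass
class AugmentationGrid:
    """(m, tau, k) grid; the default matches the 2x10x10 augmentation sweep."""
    m_values: Tuple[int, ...] = (2, 3)
    tau_values: Tuple[int, ...] = tuple(range(1, 11))
    k_values: Tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        self.m_values = tuple(sorted(int(v) for v in self.m_values))
        self.tau_values = tuple(sorted(int(v) for v in self.tau_values))
        self.k_values = tuple(sorted(int(v) for v in self.k_values))
        if not (self.m_values and self.tau_values and self.k_values):
            raise ValueError("augmentation grid must be non-empty")
        if min(self.m_values) < 2 or min(self.tau_values) < 1 or min(self.k_values) < 1:
            raise ValueError("grid values must satisfy m >= 2, tau >= 1, k >= 1")

    def __len__(self) -> int:
        return len(self.m_values) * len(self.tau_values) * len(self.k_values)

    def cells(self) -> List[EmbeddingParams]:
        """Grid cells in lexicographic (m, tau, k) order."""
        return [EmbeddingParams(m, tau, k) for m, tau, k in
                product(self.m_values, self.tau_values, self.k_values)]


def label_by_ph(ph: float, threshold: float = PH_THRESHOLD) -> str:
    """Class from umbilical-artery pH: >= threshold is normal."""
    if ph is None or not np.isfinite(ph):
        raise ValueError(f"missing or non-finite pH: {ph!r}")
    return NORMAL if ph >= threshold else PATHOLOGICAL


def balance_classes(records: Sequence[FHRRecord], seed: int = 0) -> List[FHRRecord]:
    """Subsample the majority class (without replacement) to the minority size.

    Record order within each class is preserved; output lists all normal
    records first. Seeded and deterministic.
    """
    by_class = {NORMAL: [], PATHOLOGICAL: []}
    for r in records:
        if r.label not in by_class:
            raise ValueError(f"record {r.record_id} has no class label")
        by_class[r.label].append(r)
    if not by_class[NORMAL] or not by_class[PATHOLOGICAL]:
        raise ValueError("both classes must be present to balance")
    n_min = min(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    out: List[FHRRecord] = []
    for cls in (NORMAL, PATHOLOGICAL):
        group = by_class[cls]
        if len(group) > n_min:
            keep = sorted(rng.choice(len(group), size=n_min, replace=False))
            group = [group[i] for i in keep]
        out.extend(group)
    return out


def augment(record: FHRRecord, grid: AugmentationGrid = AugmentationGrid(),
            size: int = 64) -> List[Tuple[RPImage, EmbeddingParams]]:
    """One RP image per grid cell, in lexicographic (m, tau, k) order."""
    out = []
    for params in grid.cells():
        if len(record) < params.min_length or params.k >= len(record) - (params.m - 1) * params.tau:
            raise ValueError(
                f"record {record.record_id} (length {len(record)}) too short "
                f"for grid cell (m={params.m}, tau={params.tau}, k={params.k})")
        out.append((signal_to_rp(record, params, size=size), params))
    return out


@dataclass
class FoldAssignment:
    fold_of_image: np.ndarray   # image index -> fold id in {1..n_folds}
    n_folds: int
    mode: str                   # "image" | "record"

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_image == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_image != fold)


def make_folds(n_images: int, n_folds: int = 10, mode: str = "image",
               record_ids: Optional[Sequence] = None,
               labels: Optional[Sequence[str]] = None,
               seed: int = 0) -> FoldAssignment:
    """Partition images into ``n_folds`` folds of near-equal size.

    ``mode="image"`` shuffles images independently (stratified by label
    when ``labels`` is given): the original protocol. ``mode="record"``
    requires ``record_ids`` and assigns whole records to folds so no
    record leaks across the train/test boundary; stratification then
    applies to records.
    """
    if n_images < n_folds:
        raise ValueError(f"cannot split {n_images} images into {n_folds} folds")
    rng = np.random.default_rng(seed)
    fold_of_image = np.zeros(n_images, dtype=int)

    if mode == "image":
        groups = _strata(np.arange(n_images), labels)
        counter = 0  # continuous across strata: fold sizes differ by <= 1
        for idx in groups:
            idx = idx.copy()
            rng.shuffle(idx)
            for img in idx:
                fold_of_image[img] = counter % n_folds + 1
                counter += 1
    elif mode == "record":
        if record_ids is None:
            raise ValueError("record-level folds need record_ids")
        record_ids = np.asarray(record_ids)
        uniq = list(dict.fromkeys(record_ids.tolist()))  # first-seen order
        rec_label = None
        if labels is not None:
            labels = np.asarray(labels)
            rec_label = [labels[record_ids == r][0] for r in uniq]
        groups = _strata(np.arange(len(uniq)), rec_label)
        fold_of_record: Dict = {}
        counter = 0
        for idx in groups:
            idx = idx.copy()
            rng.shuffle(idx)
            for ri in idx:
                fold_of_record[uniq[ri]] = counter % n_folds + 1
                counter += 1
        for i, rid in enumerate(record_ids):
            fold_of_image[i] = fold_of_record[rid]
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    return FoldAssignment(fold_of_image=fold_of_image, n_folds=n_folds, mode=mode)


def _strata(indices: np.ndarray, labels) -> List[np.ndarray]:
    if labels is None:
        return [indices]
    labels = np.asarray(labels)
    return [indices[labels[indices] == lab] for lab in dict.fromkeys(labels.tolist())]
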