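"""Stratified partitioning and SMOTE under the Partition-Synthesis contract.

Partition-Synthesis is the evaluation discipline in which minority
over-sampling happens strictly *after* the data has been partitioned: a
synthetic sample may only interpolate between records of the current
training partition (and, inside cross-validation, of the current training
folds), never a held-out record.  Every SMOTE call here returns full
provenance (parent ids and interpolation weight) so a leak audit can verify
the contract on every run.

All operations canonicalize the row order by record id before any seeded
shuffle, so results do not depend on file-system enumeration order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParameterError, StratificationError
from .records_io import FeatureTable


@dataclass(frozen=True)
class PartitionPlan:
    repetition_index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise IntegrityError("train/test partitions overlap")


def plans_to_json(plans: Sequence[PartitionPlan], path: str | Path) -> None:
    payload = [
        {
            "repetition_index": p.repetition_index,
            "train_ids": list(p.train_ids),
            "test_ids": list(p.test_ids),
            "seed": p.seed,
        }
        for p in plans
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def plans_from_json(path: str | Path) -> list[PartitionPlan]:
    payload = json.loads(Path(path).read_text())
    return [
        PartitionPlan(
            repetition_index=d["repetition_index"],
            train_ids=tuple(d["train_ids"]),
            test_ids=tuple(d["test_ids"]),
            seed=d["seed"],
        )
        for d in payload
    ]


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: dict[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.fold_of.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.fold_of.items() if f != fold)


@dataclass(frozen=True)
class SyntheticSample:
    record_id: str
    parents: tuple[str, str]
    lam: float


@dataclass
class LeakAudit:
    """Provenance audit of every synthetic sample created during a run."""

    checked: int = 0
    violations: int = 0
    violation_events: list = field(default_factory=list)

    def check(
        self,
        samples: Iterable[SyntheticSample],
        allowed_ids: Iterable[str],
        forbidden_ids: Iterable[str] = (),
    ) -> None:
        allowed = set(allowed_ids)
        forbidden = set(forbidden_ids)
        for s in samples:
            self.checked += 1
            bad = [p for p in s.parents if p not in allowed or p in forbidden]
            if bad:
                self.violations += 1
                self.violation_events.append((s.record_id, tuple(bad)))

    def check_parent_ids(
        self,
        parent_ids: np.ndarray,  # shape (m, 2) of record-id strings
        allowed_ids: np.ndarray,
        forbidden_ids: np.ndarray,
    ) -> None:
        """Vectorized variant of :meth:`check` for array-based callers."""
        m = len(parent_ids)
        if m == 0:
            return
        self.checked += m
        flat = parent_ids.ravel()
        ok = np.isin(flat, allowed_ids) & ~np.isin(flat, forbidden_ids)
        bad_rows = np.nonzero(~ok.reshape(m, 2).all(axis=1))[0]
        self.violations += len(bad_rows)
        for r in bad_rows[:100]:
            self.violation_events.append((f"row{r}", tuple(parent_ids[r])))

    @property
    def clean(self) -> bool:
        return self.violations == 0


def _per_class_ids(table: FeatureTable) -> dict[int, list[str]]:
    ids = pd.Series(table.labels)
    return {int(c): sorted(ids.index[ids == c]) for c in sorted(ids.unique())}


def stratified_holdout(
    table: FeatureTable,
    train_frac: float = 0.8,
    seed: int = 0,
    repetition_index: int = 0,
) -> PartitionPlan:
    """Stratified train/test split preserving class proportions to rounding."""
    if not (0.0 < train_frac < 1.0):
        raise ParameterError(f"train_frac must be in (0, 1), got {train_frac}")
    by_class = _per_class_ids(table)
    if len(by_class) < 2:
        raise StratificationError("both classes must be present")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(by_class):
        ids = by_class[cls]
        if len(ids) < 2:
            raise StratificationError(f"class {cls} has fewer than 2 members")
        n_test = int(round((1.0 - train_frac) * len(ids)))
        n_test = min(max(n_test, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        test.extend(ids[i] for i in perm[:n_test])
        train.extend(ids[i] for i in perm[n_test:])
    return PartitionPlan(
        repetition_index=repetition_index,
        train_ids=tuple(sorted(train)),
        test_ids=tuple(sorted(test)),
        seed=seed,
    )


def stratified_kfold(table: FeatureTable, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified k folds; per-class fold sizes differ by at most one."""
    by_class = _per_class_ids(table)
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for cls in sorted(by_class):
        ids = by_class[cls]
        if len(ids) < k:
            raise StratificationError(f"class {cls} has {len(ids)} < k={k} members")
        perm = rng.permutation(len(ids))
        for pos, i in enumerate(perm):
            fold_of[ids[i]] = pos % k
    return FoldAssignment(k=k, fold_of=fold_of)


def smote_arrays(
    X_min: np.ndarray,
    n_new: int,
    k_neighbors: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Numpy SMOTE core: synthesize ``n_new`` rows from minority rows.

    Returns (rows, parent_a_idx, parent_b_idx, lams); parent indices refer
    to rows of ``X_min``.  Base parents cycle through the minority class
    (classic SMOTE); the partner is a uniformly drawn one of the k nearest
    minority neighbors and the interpolation weight is uniform on [0, 1].
    """
    n_min = len(X_min)
    if n_min < 2:
        raise StratificationError("minority class of one cannot synthesize")
    k = min(k_neighbors, n_min - 1)
    d2 = ((X_min[:, None, :] - X_min[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]
    a = np.arange(n_new) % n_min
    b = nn[a, rng.integers(k, size=n_new)]
    lams = rng.random(n_new)
    rows = X_min[a] + lams[:, None] * (X_min[b] - X_min[a])
    return rows, a, b, lams


def smote_oversample(
    table: FeatureTable,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[FeatureTable, list[SyntheticSample]]:
    """Balance classes by SMOTE over the minority class.

    Synthetic rows interpolate between a minority sample and one of its
    k nearest minority neighbors (Euclidean distance in the feature space of
    the supplied table).  Originals are preserved unchanged; the target is
    exact parity with the majority count.
    """
    table = table.canonical()
    counts = table.class_counts()
    if len(counts) < 2:
        raise StratificationError("both classes must be present for SMOTE")
    minority = min(counts, key=lambda c: (counts[c], c))
    majority = max(counts, key=lambda c: (counts[c], -c))
    n_new = counts[majority] - counts[minority]
    if n_new == 0:
        return table, []
    min_ids = [i for i in table.record_ids if table.labels[i] == minority]
    X = table.values.loc[min_ids].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows, a_idx, b_idx, lams = smote_arrays(X, n_new, k_neighbors, rng)
    samples = [
        SyntheticSample(
            record_id=f"SYN_{t:05d}_{min_ids[a]}",
            parents=(min_ids[a], min_ids[b]),
            lam=float(lam),
        )
        for t, (a, b, lam) in enumerate(zip(a_idx, b_idx, lams))
    ]
    syn_ids = [s.record_id for s in samples]
    values = pd.concat(
        [
            table.values,
            pd.DataFrame(rows, index=syn_ids, columns=table.values.columns),
        ]
    )
    labels = pd.concat(
        [table.labels, pd.Series(minority, index=syn_ids, dtype=int)]
    )
    groups = None
    if table.groups is not None:
        groups = pd.concat([table.groups, pd.Series("SYN", index=syn_ids)])
    return FeatureTable(values=values, labels=labels, groups=groups), samples
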