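"""Sequential forward selection stabilized by frequency-based aggregation.

One stabilized run repeats, over ``n_reps`` fresh stratified 80/20 holdout
partitions, a full sequential-forward ranking of the feature set: at each
step the feature whose addition minimizes the stratified 5-fold
cross-validated misclassification error (MCE) on the training partition is
appended, with SMOTE balancing applied inside every CV fold only after the
fold split (Partition-Synthesis).  Each repetition contributes its
K_min-prefix (the prefix minimizing that repetition's MCE curve) to an
occurrence histogram, and its full MCE curve to an accumulated average
curve whose minimizer fixes the final subset size.  The final subset is the
corresponding number of highest histogram peaks.

Running the procedure once per (classifier x feature set) combination and
tallying the first- and second-place features of every histogram yields the
top-two candidate biomarkers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classify_eval import ClassifierSpec
from .errors import ParameterError
from .records_io import FeatureTable
from .resampling import (
    FoldAssignment,
    LeakAudit,
    PartitionPlan,
    smote_arrays,
    stratified_holdout,
    stratified_kfold,
)
from .spectral_features import (
    PA_EXCLUDED_BANDS,
    VALID_FEATURES,
    VALID_SIGNALS,
    FeatureSpec,
)
from .util import child_seed

# ---------------------------------------------------------------------------
# Feature-set definitions
# ---------------------------------------------------------------------------

_SET_BANDS = {
    "set1": ["B0", "B1", "B2", "B3", "Bb", "B0b", "B0L", "B0Lp", "B0Lpp", "B0Hp"],
    # set2 drops the least promising bands B0H' and Bb
    "set2": ["B0", "B1", "B2", "B3", "B0b", "B0L", "B0Lp", "B0Lpp"],
    # set3 keeps the most promising narrow bands plus the broadest band B0b
    "set3": ["B0L", "B0Lp", "B3", "B0b"],
    "set4": ["B0L", "B0Lp", "B3"],
}

EXPECTED_SET_SIZES = {"set1": 76, "set2": 60, "set3": 30, "set4": 24}


@dataclass(frozen=True)
class FeatureSetDef:
    name: str
    specs: tuple[FeatureSpec, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)


def build_feature_set(name: str) -> FeatureSetDef:
    """Construct one of the four canonical feature sets (76/60/30/24)."""
    if name not in _SET_BANDS:
        raise ParameterError(f"unknown feature set {name!r}; known: {sorted(_SET_BANDS)}")
    specs = [
        FeatureSpec(feature, signal, band)
        for feature in VALID_FEATURES
        for signal in VALID_SIGNALS
        for band in _SET_BANDS[name]
        if not (feature == "PA" and band in PA_EXCLUDED_BANDS)
    ]
    return FeatureSetDef(name=name, specs=tuple(specs))


ALL_FEATURE_SETS = ("set1", "set2", "set3", "set4")


# ---------------------------------------------------------------------------
# p-value pre-sort
# ---------------------------------------------------------------------------


def sort_by_pvalue(
    specs: Sequence[FeatureSpec],
    pvalues: Mapping[str, float] | None = None,
    table: FeatureTable | None = None,
) -> list[FeatureSpec]:
    """Ascending p-value order with stable tie-break by canonical name.

    p-values may be supplied externally (e.g. from a prior characterization
    of the same features) or computed here as Wilcoxon rank-sum p-values of
    premature vs term on ``table``.  With neither available the canonical
    name order is used with a warning.
    """
    if pvalues is None and table is not None:
        pvalues = {}
        y = table.y
        for s in specs:
            v = table.values[s.name].to_numpy()
            pvalues[s.name] = float(stats.ranksums(v[y == 1], v[y == 0]).pvalue)
    if pvalues is None or any(s.name not in pvalues for s in specs):
        if pvalues is not None:
            warnings.warn(
                "missing p-values for some features; falling back to canonical order",
                stacklevel=2,
            )
        else:
            warnings.warn("no p-values supplied; using canonical order", stacklevel=2)
        return sorted(specs, key=lambda s: s.name)
    return sorted(specs, key=lambda s: (pvalues[s.name], s.name))


# ---------------------------------------------------------------------------
# Cross-validated misclassification error
# ---------------------------------------------------------------------------


@dataclass
class _CVData:
    """Precomputed array view of one training partition for fast CV."""

    ids: np.ndarray  # record ids, canonical order
    X: np.ndarray  # (n, K) feature matrix, columns per `col_of`
    y: np.ndarray
    col_of: dict[str, int]
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, val_idx) per fold

    @classmethod
    def from_table(cls, train: FeatureTable, folds: FoldAssignment) -> "_CVData":
        ids = np.asarray(train.record_ids)
        pos = {rid: i for i, rid in enumerate(ids)}
        fold_pairs = []
        for fold in range(folds.k):
            val = np.array([pos[r] for r in folds.fold_ids(fold)], dtype=int)
            tr = np.array([pos[r] for r in folds.train_ids(fold)], dtype=int)
            fold_pairs.append((tr, val))
        return cls(
            ids=ids,
            X=train.values.to_numpy(dtype=float),
            y=train.y.astype(int),
            col_of={n: j for j, n in enumerate(train.feature_names)},
            folds=fold_pairs,
        )


def _cv_mce_arrays(
    data: _CVData,
    cols: Sequence[int],
    clf: ClassifierSpec,
    fold_seeds: Sequence[int],
    audit: LeakAudit | None = None,
    k_neighbors: int = 5,
) -> float:
    """Array-path CV-MCE: per fold, SMOTE-balance the training folds, train,
    and predict the untouched fold."""
    from .classify_eval import _fast_estimator

    Xs = data.X[:, list(cols)]
    n_err = 0
    n_tot = 0
    for fold, (tr_idx, val_idx) in enumerate(data.folds):
        y_tr = data.y[tr_idx]
        X_tr = Xs[tr_idx]
        counts = np.bincount(y_tr, minlength=2)
        minority = int(np.argmin(counts))
        n_new = int(abs(counts[0] - counts[1]))
        rng = np.random.default_rng(child_seed(fold_seeds[fold], 0))
        if n_new:
            min_rows = np.nonzero(y_tr == minority)[0]
            rows, a_idx, b_idx, _ = smote_arrays(
                Xs[tr_idx[min_rows]], n_new, k_neighbors, rng
            )
            if audit is not None:
                parents = np.stack(
                    [
                        data.ids[tr_idx[min_rows[a_idx]]],
                        data.ids[tr_idx[min_rows[b_idx]]],
                    ],
                    axis=1,
                )
                audit.check_parent_ids(
                    parents, data.ids[tr_idx], data.ids[val_idx]
                )
            X_fit = np.vstack([X_tr, rows])
            y_fit = np.concatenate([y_tr, np.full(n_new, minority, dtype=int)])
        else:
            X_fit, y_fit = X_tr, y_tr
        est = _fast_estimator(clf, child_seed(fold_seeds[fold], 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X_fit, y_fit)
            pred = est.predict(Xs[val_idx])
        n_err += int(np.sum(pred != data.y[val_idx]))
        n_tot += len(val_idx)
    return n_err / n_tot


def cv_mce(
    train: FeatureTable,
    subset: Sequence[str],
    clf: ClassifierSpec,
    folds: FoldAssignment,
    seed: int = 0,
    audit: LeakAudit | None = None,
    k_neighbors: int = 5,
) -> float:
    """Average 5-fold CV misclassification error with in-fold SMOTE.

    For each fold the remaining folds are SMOTE-balanced, the classifier is
    trained on them, and the untouched fold is predicted; MCE is the total
    number of misclassified samples over the total validated."""
    if not subset:
        raise ParameterError("empty feature subset")
    data = _CVData.from_table(train, folds)
    fold_seeds = [child_seed(seed, fold) for fold in range(folds.k)]
    return _cv_mce_arrays(
        data,
        [data.col_of[name] for name in subset],
        clf,
        fold_seeds,
        audit=audit,
        k_neighbors=k_neighbors,
    )


# ---------------------------------------------------------------------------
# Sequential forward selection
# ---------------------------------------------------------------------------


@dataclass
class SFSRun:
    selected: list[str]  # z_1..z_K in selection order
    mce_curve: np.ndarray  # MCE after adding the k-th feature
    k_min: int  # size of the minimizing prefix (first minimum)


def sfs_run(
    train: FeatureTable,
    ordered_specs: Sequence[FeatureSpec],
    clf: ClassifierSpec,
    seed: int = 0,
    n_folds: int = 5,
    audit: LeakAudit | None = None,
    k_neighbors: int = 5,
) -> SFSRun:
    """Greedy forward ranking of all features by CV-MCE on one training set.

    Ties in the per-step argmin are broken toward the earlier feature in the
    p-sorted order (strict improvement required to displace it)."""
    folds = stratified_kfold(train, k=n_folds, seed=child_seed(seed, 0))
    data = _CVData.from_table(train, folds)
    remaining = [s.name for s in ordered_specs]
    selected: list[str] = []
    selected_cols: list[int] = []
    curve: list[float] = []
    for step in range(len(remaining)):
        best_name = None
        best_mce = np.inf
        cand_seed = child_seed(seed, 1, step)
        # one shared seed per step: every candidate sees the same SMOTE draws
        fold_seeds = [child_seed(cand_seed, fold) for fold in range(folds.k)]
        for name in remaining:
            mce = _cv_mce_arrays(
                data,
                selected_cols + [data.col_of[name]],
                clf,
                fold_seeds,
                audit=audit,
                k_neighbors=k_neighbors,
            )
            if mce < best_mce:  # strict: earlier (lower p) feature wins ties
                best_mce = mce
                best_name = name
        selected.append(best_name)
        selected_cols.append(data.col_of[best_name])
        remaining.remove(best_name)
        curve.append(best_mce)
    curve_arr = np.asarray(curve)
    return SFSRun(selected=selected, mce_curve=curve_arr, k_min=int(np.argmin(curve_arr)) + 1)


# ---------------------------------------------------------------------------
# Stabilized selection (aggregation over repetitions)
# ---------------------------------------------------------------------------


@dataclass
class AggregationHistogram:
    counts: dict[str, int]  # H_k: occurrences in K_min-prefixes across reps
    mce_accum: np.ndarray  # M_k: accumulated MCE of the k-th added feature
    n_reps: int

    @property
    def average_mce_curve(self) -> np.ndarray:
        return self.mce_accum / self.n_reps


@dataclass
class SelectionResult:
    feature_set: str
    classifier: ClassifierSpec
    ordered_names: tuple[str, ...]  # p-sorted input order (histogram indexing)
    histogram: AggregationHistogram
    m_final: int
    final_subset: tuple[str, ...]
    per_run: list[SFSRun]
    plans: list[PartitionPlan]

    def ranked_features(self) -> list[str]:
        """Features by descending occurrence count, ties by p-sorted order."""
        order_idx = {n: i for i, n in enumerate(self.ordered_names)}
        return sorted(
            self.ordered_names,
            key=lambda n: (-self.histogram.counts.get(n, 0), order_idx[n]),
        )

    def top_two(self) -> tuple[str, str]:
        ranked = self.ranked_features()
        return ranked[0], ranked[1]


def stabilized_selection(
    table: FeatureTable,
    clf: ClassifierSpec,
    feature_set: FeatureSetDef,
    n_reps: int = 200,
    base_seed: int = 0,
    train_frac: float = 0.8,
    n_folds: int = 5,
    pvalues: Mapping[str, float] | None = None,
    audit: LeakAudit | None = None,
    k_neighbors: int = 5,
    plans: Sequence[PartitionPlan] | None = None,
) -> SelectionResult:
    """Run SFS over repeated holdout partitions and aggregate occurrences.

    Partition seeds derive from ``base_seed`` + repetition index, so a later
    evaluation phase reconstructs (or reuses, via ``plans``) the identical
    partitions."""
    table = table.canonical()
    ordered = sort_by_pvalue(feature_set.specs, pvalues=pvalues, table=table)
    K = len(ordered)
    counts: dict[str, int] = {s.name: 0 for s in ordered}
    M = np.zeros(K)
    runs: list[SFSRun] = []
    used_plans: list[PartitionPlan] = []
    for i in range(1, n_reps + 1):
        if plans is not None:
            plan = plans[i - 1]
        else:
            plan = stratified_holdout(
                table, train_frac=train_frac, seed=child_seed(base_seed, i), repetition_index=i
            )
        train = table.subset(plan.train_ids)
        run = sfs_run(
            train,
            ordered,
            clf,
            seed=child_seed(base_seed, i, 2),
            n_folds=n_folds,
            audit=audit,
            k_neighbors=k_neighbors,
        )
        for name in run.selected[: run.k_min]:
            counts[name] += 1
        M += run.mce_curve
        runs.append(run)
        used_plans.append(plan)
    hist = AggregationHistogram(counts=counts, mce_accum=M, n_reps=n_reps)
    m_final = int(np.argmin(M / n_reps)) + 1
    order_idx = {s.name: i for i, s in enumerate(ordered)}
    by_peak = sorted(counts, key=lambda n: (-counts[n], order_idx[n]))
    result = SelectionResult(
        feature_set=feature_set.name,
        classifier=clf,
        ordered_names=tuple(s.name for s in ordered),
        histogram=hist,
        m_final=m_final,
        final_subset=tuple(by_peak[:m_final]),
        per_run=runs,
        plans=used_plans,
    )
    return result


# ---------------------------------------------------------------------------
# Top-two tally across (classifier x feature set) runs
# ---------------------------------------------------------------------------


@dataclass
class TopTwoTally:
    first_place: dict[str, int]
    second_place: dict[str, int]
    n_runs: int


def tally_top2(results: Sequence[SelectionResult]) -> tuple[TopTwoTally, tuple[str, str]]:
    """Count first/second histogram peaks across runs; return the overall
    most frequent first-place (A) and second-place (B) features."""
    first: dict[str, int] = {}
    second: dict[str, int] = {}
    for res in results:
        a, b = res.top_two()
        first[a] = first.get(a, 0) + 1
        second[b] = second.get(b, 0) + 1
    feat_a = max(sorted(first), key=lambda n: first[n])
    feat_b = max(sorted(second), key=lambda n: second[n])
    return TopTwoTally(first_place=first, second_place=second, n_runs=len(results)), (
        feat_a,
        feat_b,
    )
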